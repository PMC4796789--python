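"""Scenario pipelines: the in-silico experiments at desk scale.

Each function builds its morphology, runs the deterministic (or stochastic)
engine and reduces the trajectory to the quantities of interest:

* ``run_density_sweep`` — focal Cl⁻ release in a 700 μm cylinder at a grid
  of spine densities; D_app and tortuosity per (density, seed).
* ``run_pump_conditions`` — the same release under different spatial
  layouts of the KCC2-like pump.
* ``run_plasticity`` — repetitive GABA_A activation of a 200 μm cylinder;
  Cl⁻ accumulation and E_GABA shift at probe sites, spatial profiles at the
  end of the train, and the maximum-slope profile.
* ``run_branched`` — focal release in a (synthetic or loaded) branched
  tree, metrics along a designated path.
* ``compare_det_sto`` — deterministic vs ensemble-stochastic variance on
  the same voxel graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse.linalg import expm_multiply
import scipy.sparse as sp

from . import detsim, diffmetrics, stosim
from .morphology import (
    CANONICAL_SPINE,
    SHAFT,
    Morphology,
    SpineGeometry,
    StimulusTrain,
    attach_spines,
    build_cylinder,
    make_stimulus,
    matched_diameter,
)

__all__ = [
    "Scenario",
    "SweepResult",
    "PlasticityResult",
    "AgreementReport",
    "focal_release_metrics",
    "run_density_sweep",
    "run_pump_conditions",
    "run_plasticity",
    "run_branched",
    "compare_det_sto",
    "synthetic_tree_swc",
    "primary_path",
]

PUMP_CONDITIONS = ("off", "on", "on-off-on", "spines_only", "spines_and_shafts")


@dataclass
class Scenario:
    """Serializable description of a focal-release experiment."""

    name: str = "focal_release"
    length: float = 700.0
    diameter: float = 1.0
    dx: float = 1.0
    spine_density: float = 0.0
    spine_geometry: SpineGeometry = CANONICAL_SPINE
    seed: int = 0
    release_delta: float = 5.0  # mM above rest in the central compartment
    release_width: float = 1.0  # μm
    t_end: float = 4000.0
    dt: float = 0.5
    record_dt: float = 50.0
    pump_condition: str = "off"
    has_synapses: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        g = d.get("spine_geometry")
        if isinstance(g, dict):
            d["spine_geometry"] = SpineGeometry(**g)
        return cls(**d)

    def build_morphology(self) -> Morphology:
        morph = build_cylinder(self.length, self.diameter, self.dx)
        if self.spine_density > 0:
            morph = attach_spines(
                morph, self.spine_density, self.spine_geometry, self.seed
            )
        return morph


@dataclass
class SweepResult:
    """Grid of per-(density, seed) diffusion metrics."""

    table: pd.DataFrame  # density, seed, d_app_end, tortuosity, reduction_percent
    metrics: dict = field(default_factory=dict)  # (density, seed) -> DiffusionMetrics

    def mean_by_density(self) -> pd.DataFrame:
        g = self.table.groupby("density")
        out = g.agg(
            d_app_end=("d_app_end", "mean"),
            tortuosity=("tortuosity", "mean"),
            reduction_percent=("reduction_percent", "mean"),
            sd_reduction=("reduction_percent", "std"),
            n=("seed", "count"),
        )
        return out.reset_index()


def _pump_mask(morph: Morphology, condition: str) -> np.ndarray | None:
    """Boolean pump mask per compartment for the named spatial layout."""
    if condition not in PUMP_CONDITIONS:
        raise ValueError(
            f"unknown pump condition {condition!r}; expected one of {PUMP_CONDITIONS}"
        )
    n = morph.n
    kinds = morph.kinds()
    if condition == "on":
        return np.ones(n, dtype=bool)
    if condition == "on-off-on":
        # pump in the two distal thirds of the shaft, off in the central third
        pos = morph.positions()
        length = morph.shaft_length
        mask = (kinds == SHAFT) & ((pos < length / 3) | (pos > 2 * length / 3))
        return mask
    if condition == "spines_only":
        return kinds != SHAFT
    if condition == "spines_and_shafts":
        mask = kinds != SHAFT
        for shaft_id, _, _ in morph.spines:
            mask[shaft_id] = True
        return mask
    return None  # "off"


def focal_release_metrics(
    scenario: Scenario,
    ions: detsim.IonParams | None = None,
    include_spines: bool = False,
):
    """Run one focal-release simulation and compute its diffusion metrics.

    Returns (morphology, trajectory, DiffusionMetrics).
    """
    ions = ions or detsim.IonParams()
    morph = scenario.build_morphology()
    init = np.full(morph.n, ions.cl_in_rest)
    center = morph.shaft_length / 2
    half_w = scenario.release_width / 2
    pos = morph.positions()
    shaft = morph.shaft_mask()
    sel = shaft & (np.abs(pos - center) <= half_w + 1e-9)
    if not sel.any():
        sel[morph.nearest_shaft(center)] = True
    init[sel] = ions.cl_in_rest + scenario.release_delta
    pump = None
    if scenario.pump_condition != "off":
        pump = detsim.PumpParams(mask=_pump_mask(morph, scenario.pump_condition))
    try:
        traj = detsim.run_simulation(
            morph,
            ions,
            pump=pump,
            t_end=scenario.t_end,
            dt=scenario.dt,
            record_dt=scenario.record_dt,
            initial_cl=init,
        )
    except detsim.SolverError as exc:
        raise detsim.SolverError(
            f"scenario {scenario.name!r} (density {scenario.spine_density}, "
            f"seed {scenario.seed}): {exc}"
        ) from exc
    metrics = diffmetrics.trajectory_metrics(
        traj, morph, include_spines=include_spines
    )
    return morph, traj, metrics


def run_density_sweep(
    densities,
    geometry: SpineGeometry = CANONICAL_SPINE,
    seeds=(0,),
    **scenario_kwargs,
) -> SweepResult:
    """Focal-release metrics over a (density × seed) grid on the 700 μm cylinder."""
    rows = []
    store = {}
    for density in densities:
        if density < 0:
            raise ValueError("spine densities must be >= 0")
        for seed in seeds:
            sc = Scenario(
                name=f"density_{density}",
                spine_density=density,
                spine_geometry=geometry,
                seed=seed,
                **scenario_kwargs,
            )
            _, _, m = focal_release_metrics(sc)
            rows.append(
                dict(
                    density=density,
                    seed=seed,
                    d_app_end=m.d_app_end,
                    tortuosity=m.tortuosity,
                    reduction_percent=m.reduction_percent,
                )
            )
            store[(density, seed)] = m
    return SweepResult(pd.DataFrame(rows), store)


def run_pump_conditions(
    condition: str,
    density: float = 0.0,
    seed: int = 0,
    geometry: SpineGeometry = CANONICAL_SPINE,
    **scenario_kwargs,
) -> diffmetrics.DiffusionMetrics:
    """Focal-release metrics under a named pump layout."""
    sc = Scenario(
        name=f"pump_{condition}",
        spine_density=density,
        spine_geometry=geometry,
        seed=seed,
        pump_condition=condition,
        **scenario_kwargs,
    )
    _, _, metrics = focal_release_metrics(sc)
    return metrics


@dataclass
class PlasticityResult:
    """Summary of a GABAergic-train run on the 200 μm cylinder."""

    morph: Morphology
    traj: detsim.Trajectory
    probe_positions: tuple  # μm
    probe_ids: tuple
    positions: np.ndarray  # shaft positions, sorted
    cl_profile_end: np.ndarray  # [Cl⁻]_i along the shaft at t_end, mM
    egaba_profile_end: np.ndarray  # mV
    slope_positions: np.ndarray
    max_slope: np.ndarray  # mM/ms

    def cl_at_probe(self, which: int) -> np.ndarray:
        """Time course of [Cl⁻]_i at probe 0 (middle) or 1 (distal)."""
        return self.traj.cl[:, self.probe_ids[which]]

    def egaba_at_probe(self, which: int) -> np.ndarray:
        return self.traj.e_gaba()[:, self.probe_ids[which]]


def run_plasticity(
    density: float,
    compensate_volume: bool = False,
    train: StimulusTrain | None = None,
    g_max: float = 1.0,
    n_synapses: int = 11,
    synapse_zone: tuple[float, float] = (89.0, 111.0),
    length: float = 200.0,
    diameter: float = 1.0,
    dx: float = 1.0,
    dt: float = 0.05,
    record_dt: float = 10.0,
    probe_positions: tuple[float, float] = (110.0, 190.0),
    geometry: SpineGeometry = CANONICAL_SPINE,
    seed: int = 0,
    ions: detsim.IonParams | None = None,
    pump_tau: float = 3000.0,
) -> PlasticityResult:
    """Short-term ionic plasticity protocol on a 200 μm dendritic cylinder.

    ``n_synapses`` GABA_A shaft synapses are spread evenly over
    ``synapse_zone`` (22 μm centered at 100 μm → 0.5 synapses/μm) and fire
    synchronously on every train event (default 10 Hz × 30 pulses). With
    ``compensate_volume`` the run is the *smooth volume-matched control*:
    no spines, but the diameter widened so the volume per unit length
    equals that of the spiny dendrite at ``density`` (2 spines/μm on 1 μm →
    1.22 μm control).
    """
    ions = ions or detsim.IonParams()
    if train is None:
        train = make_stimulus("periodic", 10.0, n_events=30)
    if compensate_volume:
        morph = build_cylinder(
            length, matched_diameter(diameter, density, geometry), dx
        )
    else:
        morph = build_cylinder(length, diameter, dx)
        if density > 0:
            morph = attach_spines(morph, density, geometry, seed)
    lo, hi = synapse_zone
    if not (0 <= lo < hi <= length):
        raise ValueError("synapse zone outside morphology")
    sites = np.linspace(lo + (hi - lo) / (2 * n_synapses),
                        hi - (hi - lo) / (2 * n_synapses), n_synapses)
    synapses = [
        detsim.SynapseParams(target=morph.nearest_shaft(x), train=train, g_max=g_max)
        for x in sites
    ]
    t_end = float(train.times[-1] + 100.0) if train.n_events else 1000.0
    t_end = max(t_end, 3000.0)
    traj = detsim.run_simulation(
        morph,
        ions,
        pump=detsim.PumpParams(tau_cl=pump_tau, cl_rest=ions.cl_in_rest),
        synapses=synapses,
        t_end=t_end,
        dt=dt,
        record_dt=record_dt,
    )
    probe_ids = tuple(morph.nearest_shaft(p) for p in probe_positions)
    shaft = morph.shaft_indices()
    pos = morph.positions()[shaft]
    order = np.argsort(pos)
    # profile at the end of GABAergic activity (t = 3000 ms)
    it = int(np.argmin(np.abs(traj.times - 3000.0)))
    cl_end = traj.cl[it][shaft][order]
    egaba_end = traj.e_gaba()[it][shaft][order]
    sp_pos, slopes = diffmetrics.max_slope_profile(traj, morph, window=(0.0, 3000.0))
    return PlasticityResult(
        morph=morph,
        traj=traj,
        probe_positions=probe_positions,
        probe_ids=probe_ids,
        positions=pos[order],
        cl_profile_end=cl_end,
        egaba_profile_end=egaba_end,
        slope_positions=sp_pos,
        max_slope=slopes,
    )


# ---------------------------------------------------------------------------
# branched trees
# ---------------------------------------------------------------------------


def synthetic_tree_swc(archetype: str) -> str:
    """SWC text for a small synthetic branched tree (three archetypes).

    These are synthetic stand-ins, generated procedurally: 'granule'
    (sparsely branched), 'pyramidal' (moderately branched), 'purkinje'
    (densely branched). They share 1 μm diameters and straight 2-D
    segments; they are not reconstructions of real cells.
    """
    specs = {
        "granule": dict(trunk=60.0, depth=2, child=40.0, step=10.0),
        "pyramidal": dict(trunk=40.0, depth=3, child=30.0, step=10.0),
        "purkinje": dict(trunk=20.0, depth=4, child=15.0, step=5.0),
    }
    if archetype not in specs:
        raise ValueError(f"unknown archetype {archetype!r}")
    s = specs[archetype]
    lines = ["# synthetic %s-like tree (procedural, not a reconstruction)" % archetype]
    next_id = [1]

    def emit(xyz, parent):
        nid = next_id[0]
        lines.append(f"{nid} 3 {xyz[0]:.4f} {xyz[1]:.4f} 0 0.5 {parent}")
        next_id[0] += 1
        return nid

    def grow(origin, angle, length, depth, parent):
        d = np.array([math.cos(angle), math.sin(angle)])
        nseg = max(1, int(round(length / s["step"])))
        node = parent
        p = np.asarray(origin, dtype=float)
        for _ in range(nseg):
            p = p + d * (length / nseg)
            node = emit(p, node)
        if depth > 0:
            grow(p, angle + 0.6, s["child"], depth - 1, node)
            grow(p, angle - 0.6, s["child"], depth - 1, node)

    root = emit((0.0, 0.0), -1)
    grow((0.0, 0.0), 0.0, s["trunk"], s["depth"], root)
    return "\n".join(lines) + "\n"


def primary_path(morph: Morphology) -> list[int]:
    """Longest root-to-tip chain of shaft compartments (by path distance)."""
    pos = morph.positions()
    shaft = morph.shaft_mask()
    adj = morph.adjacency()
    tip = int(np.argmax(np.where(shaft, pos, -np.inf)))
    path = [tip]
    cur = tip
    while True:
        prev = [v for v in adj[cur] if shaft[v] and pos[v] < pos[cur] - 1e-12]
        if not prev:
            break
        cur = min(prev, key=lambda v: pos[v])
        path.append(cur)
    return path[::-1]


def run_branched(
    swc_path,
    density: float = 0.0,
    seed: int = 0,
    release_path: list[int] | None = None,
    geometry: SpineGeometry = CANONICAL_SPINE,
    t_end: float = 1000.0,
    dt: float = 0.5,
    record_dt: float = 25.0,
    release_delta: float = 5.0,
    ions: detsim.IonParams | None = None,
) -> diffmetrics.DiffusionMetrics:
    """Focal-release diffusion metrics along a path through a branched tree.

    Spines are attached tree-wide at ``density``; Cl⁻ is released in the
    middle of ``release_path`` (default: the tree's primary path) and the
    variance/D_app/λ chain is evaluated over that path's compartments,
    using path distance as the axial coordinate.
    """
    from .swc import load_swc

    ions = ions or detsim.IonParams()
    morph = load_swc(swc_path)
    n_shaft = morph.n
    if density > 0:
        morph = attach_spines(morph, density, geometry, seed)
    path = release_path if release_path is not None else primary_path(morph)
    if not path or any(not 0 <= p < n_shaft for p in path):
        raise ValueError("release path not found in morphology")
    pos = morph.positions()
    mid = path[int(np.argmin(np.abs(pos[path] - pos[path[-1]] / 2)))]
    init = np.full(morph.n, ions.cl_in_rest)
    init[mid] = ions.cl_in_rest + release_delta
    traj = detsim.run_simulation(
        morph, ions, t_end=t_end, dt=dt, record_dt=record_dt, initial_cl=init
    )
    mask = np.zeros(morph.n, dtype=bool)
    mask[path] = True
    return diffmetrics.trajectory_metrics(traj, morph, mask=mask)


# ---------------------------------------------------------------------------
# deterministic vs stochastic agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    times: np.ndarray
    det_variance: np.ndarray
    sto_mean_variance: np.ndarray
    sto_se: np.ndarray  # standard error of the ensemble mean
    replicates: int
    insufficient_ensemble: bool

    @property
    def max_abs_deviation(self) -> float:
        return float(np.max(np.abs(self.sto_mean_variance - self.det_variance)))

    @property
    def within_3se(self) -> bool:
        return bool(
            np.all(
                np.abs(self.sto_mean_variance - self.det_variance)
                <= 3.0 * self.sto_se + 1e-12
            )
        )


def _det_variance_on_graph(graph: stosim.VoxelGraph, w0, times):
    """Deterministic mass-weight evolution on the voxel graph (matrix
    exponential of the jump-rate generator) and its shaft variance."""
    n = graph.n
    rows, cols, vals = [], [], []
    for i in range(n):
        for p in range(graph.nbr_ptr[i], graph.nbr_ptr[i + 1]):
            j = graph.nbr_idx[p]
            k = graph.nbr_rate[p]
            rows.extend([j, i])
            cols.extend([i, i])
            vals.extend([k, -k])
    gen = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    out = []
    for t in times:
        w = w0 if t == 0 else expm_multiply(gen * t, w0)
        ws = np.clip(w[graph.shaft], 0, None)
        ws = ws / ws.sum()
        x = graph.positions[graph.shaft]
        rm = np.dot(ws, x)
        out.append(float(np.dot(ws, (x - rm) ** 2)))
    return np.array(out)


def compare_det_sto(
    scenario: Scenario,
    replicates: int,
    seed: int,
    n_particles: int = 10_000,
    snapshot_times=None,
    target_dx: float = 1.0,
) -> AgreementReport:
    """Run both engines on the same voxel graph and compare shaft variance.

    The deterministic side evolves the expected particle mass with the
    exact matrix exponential of the jump generator, so the comparison
    isolates stochastic sampling error. Reports the ensemble mean variance,
    its standard error, and whether all snapshots agree within 3 SE.
    """
    if scenario.has_synapses:
        raise ValueError("synaptic scenarios are not supported by the stochastic engine")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    morph = scenario.build_morphology()
    graph = stosim.voxelize(morph, target_dx=target_dx, d_cl=detsim.IonParams().d_cl)
    if snapshot_times is None:
        snapshot_times = np.linspace(0, scenario.t_end, 6)[1:]
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    center = morph.shaft_length / 2
    region = (center - scenario.release_width / 2 - 1e-9,
              center + scenario.release_width / 2 + 1e-9)

    rng = np.random.default_rng(seed)
    variances = np.empty((replicates, snapshot_times.size))
    w0 = None
    for r in range(replicates):
        snaps = stosim.ssa_run(
            graph, n_particles, region, float(snapshot_times[-1]),
            snapshot_times, int(rng.integers(0, 2**31 - 1)),
        )
        if w0 is None:
            sel = graph.shaft & (graph.positions >= region[0]) & (
                graph.positions <= region[1]
            )
            w0 = np.where(sel, graph.volumes, 0.0)
            w0 = w0 / w0.sum()
        for k, state in enumerate(snaps):
            c = state.counts[graph.shaft].astype(float)
            c = c / c.sum()
            x = graph.positions[graph.shaft]
            rm = np.dot(c, x)
            variances[r, k] = np.dot(c, (x - rm) ** 2)

    det_var = _det_variance_on_graph(graph, w0, snapshot_times)
    mean = variances.mean(axis=0)
    if replicates > 1:
        se = variances.std(axis=0, ddof=1) / math.sqrt(replicates)
    else:
        se = np.full(snapshot_times.size, np.nan)
    return AgreementReport(
        times=snapshot_times,
        det_variance=det_var,
        sto_mean_variance=mean,
        sto_se=se,
        replicates=replicates,
        insufficient_ensemble=replicates < 2,
    )
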