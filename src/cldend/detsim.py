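"""Deterministic compartmental simulation of dendritic Cl⁻ dynamics.

Longitudinal diffusion is the exchange of Cl⁻ between adjacent compartments
(Fick's law on the compartment graph), solved implicitly (backward Euler)
so that thin spine necks do not constrain the time step. On top of the
diffusion operator the solver composes, per step:

* KCC2-like extrusion — closed-form monoexponential relaxation of [Cl⁻]_i
  toward its resting level with time constant τ_Cl;
* GABA_A synapses — a double-exponential conductance split into parallel
  Cl⁻ and HCO3⁻ branches by the fractional conductance P, with the Cl⁻
  current converted to a concentration change of the target compartment;
* membrane voltage — either clamped at V_rest (default) or integrated as a
  passive cable;
* dynamic reversals — E_Cl and E_GABA recomputed from the instantaneous
  [Cl⁻]_i (HCO3⁻ pools are held constant).

Optionally the shaft volume is discretized radially into a cylindrical core
plus equal-thickness concentric shells; spines then attach to the outermost
shell. Axial metrics are insensitive to this for radially uniform initial
conditions, so it is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import units
from .morphology import SHAFT, Morphology, StimulusTrain

__all__ = [
    "IonParams",
    "PumpParams",
    "SynapseParams",
    "CableParams",
    "Trajectory",
    "SolverError",
    "nernst",
    "egaba",
    "gaba_conductance",
    "synaptic_currents",
    "cl_from_current",
    "pump_step",
    "run_simulation",
    "build_diffusion_system",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class IonParams:
    """Resting ionic conditions (mM, K, μm²/ms, mV)."""

    cl_in_rest: float = 5.0
    cl_out: float = 133.5
    hco3_in: float = 16.0
    hco3_out: float = 26.0
    d_cl: float = 2.0
    temperature: float = units.BODY_TEMPERATURE_K
    p_hco3: float = 0.25  # fraction of GABA_A conductance carried by HCO3⁻
    v_rest: float = -70.0

    def __post_init__(self):
        for f in ("cl_in_rest", "cl_out", "hco3_in", "hco3_out"):
            if getattr(self, f) <= 0:
                raise ValueError(f"IonParams.{f} must be positive")
        if not 0 <= self.p_hco3 <= 1:
            raise ValueError("p_hco3 must lie in [0, 1]")
        if self.d_cl <= 0:
            raise ValueError("d_cl must be positive")

    @property
    def e_cl(self) -> float:
        return nernst(-1, self.cl_in_rest, self.cl_out, self.temperature)

    @property
    def e_hco3(self) -> float:
        return nernst(-1, self.hco3_in, self.hco3_out, self.temperature)

    @property
    def e_gaba_rest(self) -> float:
        return egaba(self.e_cl, self.e_hco3, self.p_hco3)


@dataclass(frozen=True)
class PumpParams:
    """KCC2-like extrusion: exponential recovery toward ``cl_rest``.

    ``mask`` selects the compartments carrying the pump (boolean per
    compartment); ``None`` means everywhere.
    """

    tau_cl: float = 3000.0
    cl_rest: float = 5.0
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.tau_cl <= 0:
            raise ValueError("tau_cl must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """One GABA_A synapse: double-exponential conductance on a compartment."""

    target: int
    train: StimulusTrain
    tau1: float = 0.5  # rise, ms
    tau2: float = 6.0  # decay, ms
    g_max: float = 1.0  # peak conductance, nS

    def __post_init__(self):
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")

    @property
    def t_peak(self) -> float:
        return (
            self.tau1 * self.tau2 / (self.tau2 - self.tau1)
            * math.log(self.tau2 / self.tau1)
        )

    @property
    def norm(self) -> float:
        """Normalization so the per-event peak equals g_max."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau2) - math.exp(-tp / self.tau1))


@dataclass(frozen=True)
class CableParams:
    """Passive membrane properties.

    The values are conventional placeholders for a passive dendrite, not
    measured constants; override them for any quantitative voltage work.
    """

    r_m: float = 20000.0  # specific membrane resistance, Ω·cm²
    c_m: float = 1.0  # specific capacitance, μF/cm²
    r_a: float = 150.0  # axial resistivity, Ω·cm
    area_scale: float = 1.0  # implicit-spine factor F (scales c_m·F, r_m/F)

    def __post_init__(self):
        if min(self.r_m, self.c_m, self.r_a, self.area_scale) <= 0:
            raise ValueError("cable parameters must be positive")


@dataclass
class Trajectory:
    """Recorded time series of a simulation."""

    times: np.ndarray  # (nt,), ms
    cl: np.ndarray  # (nt, n_compartments), mM
    v: np.ndarray | None = None  # (nt, n), mV
    cl_shells: np.ndarray | None = None  # (nt, n_elements) when shells on
    events: list = field(default_factory=list)  # (time, synapse index)
    ions: IonParams | None = None

    def e_cl(self) -> np.ndarray:
        p = self.ions or IonParams()
        return nernst(-1, self.cl, p.cl_out, p.temperature)

    def e_gaba(self) -> np.ndarray:
        p = self.ions or IonParams()
        return egaba(self.e_cl(), p.e_hco3, p.p_hco3)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

nernst = units.nernst


def egaba(e_cl, e_hco3, p):
    """GABA_A reversal: conductance-weighted mean (1−P)·E_Cl + P·E_HCO3."""
    if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > 1):
        raise ValueError("conductance fraction P must lie in [0, 1]")
    return (1.0 - p) * np.asarray(e_cl) + p * np.asarray(e_hco3)


def gaba_conductance(t_since_event, p: SynapseParams):
    """Conductance (nS) of one event, ``t_since_event`` ms after onset.

    g(t) = g_max·N·(exp(−t/τ2) − exp(−t/τ1)); zero at onset, peak g_max at
    t_peak, decaying back to zero. Events superpose linearly.
    """
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since event must be >= 0")
    return p.g_max * p.norm * (np.exp(-t / p.tau2) - np.exp(-t / p.tau1))


def synaptic_currents(v, g, e_cl, e_hco3, p):
    """Split an instantaneous GABA_A conductance into its ionic currents.

    Returns (I_Cl, I_HCO3) in pA for g in nS and potentials in mV. Positive
    I_Cl denotes Cl⁻ influx (raises [Cl⁻]_i, hyperpolarizing).
    """
    i_cl = (1.0 - p) * np.asarray(g) * (np.asarray(v) - np.asarray(e_cl))
    i_hco3 = p * np.asarray(g) * (np.asarray(v) - np.asarray(e_hco3))
    return i_cl, i_hco3


cl_from_current = units.delta_conc_from_current


def pump_step(cl, p: PumpParams, dt: float):
    """Advance [Cl⁻]_i one step under extrusion alone (exact exponential)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cl = np.asarray(cl, dtype=float)
    decay = math.exp(-dt / p.tau_cl)
    relaxed = p.cl_rest + (cl - p.cl_rest) * decay
    if p.mask is None:
        return relaxed
    mask = np.asarray(p.mask, dtype=bool)
    return np.where(mask, relaxed, cl)


# ---------------------------------------------------------------------------
# diffusion system assembly
# ---------------------------------------------------------------------------


@dataclass
class DiffusionSystem:
    """Volume elements + graph Laplacian for a given morphology/options."""

    volumes: np.ndarray
    laplacian: sp.csc_matrix  # dC/dt = L @ C
    n_compartments: int
    element_of: list[list[int]]  # compartment -> its element indices
    outer_element: np.ndarray  # compartment -> element facing the membrane
    positions: np.ndarray  # per element
    shaft_element: np.ndarray  # per element, True if belongs to shaft comp.

    def aggregate(self, c_elements: np.ndarray) -> np.ndarray:
        """Volume-weighted compartment means from per-element values."""
        if len(self.element_of) == self.volumes.size:
            return c_elements
        out_shape = c_elements.shape[:-1] + (self.n_compartments,)
        out = np.empty(out_shape)
        for ci, els in enumerate(self.element_of):
            w = self.volumes[els]
            out[..., ci] = (c_elements[..., els] * w).sum(axis=-1) / w.sum()
        return out


def build_diffusion_system(
    morph: Morphology, d_cl: float, radial_shells: int = 0
) -> DiffusionSystem:
    """Assemble volumes and the diffusion Laplacian L, L_ij = D·A_ij/(V_i·d_ij).

    With ``radial_shells`` > 0 every shaft compartment is split into a core
    plus that many equal-thickness concentric shells; axial coupling acts
    shell-to-matching-shell and spines couple to the outermost shell.
    """
    n = morph.n
    if radial_shells < 0:
        raise ValueError("radial_shells must be >= 0")
    m = radial_shells + 1  # radial elements per shaft compartment
    volumes: list[float] = []
    positions: list[float] = []
    shaft_el: list[bool] = []
    element_of: list[list[int]] = []
    outer: np.ndarray = np.empty(n, dtype=int)
    for c in morph.compartments:
        if c.kind == SHAFT and m > 1:
            r = c.diameter / 2
            bounds = r * np.arange(m + 1) / m
            els = []
            for k in range(m):
                els.append(len(volumes))
                volumes.append(math.pi * (bounds[k + 1] ** 2 - bounds[k] ** 2) * c.length)
                positions.append(c.axial_position)
                shaft_el.append(True)
            element_of.append(els)
            outer[c.id] = els[-1]
        else:
            element_of.append([len(volumes)])
            outer[c.id] = len(volumes)
            volumes.append(c.volume)
            positions.append(c.axial_position)
            shaft_el.append(c.kind == SHAFT)

    rows, cols, vals = [], [], []
    vol = np.array(volumes)

    def couple(i, j, area, dist):
        k = d_cl * area / dist  # μm³/ms, symmetric
        for a, b in ((i, j), (j, i)):
            rows.extend([a, a])
            cols.extend([b, a])
            vals.extend([k / vol[a], -k / vol[a]])

    for e in morph.edges:
        ci, cj = morph.compartments[e.i], morph.compartments[e.j]
        both_shaft = ci.kind == SHAFT and cj.kind == SHAFT
        if m > 1 and both_shaft:
            # shell-to-shell axial coupling: split area by annulus fractions
            ri = min(ci.diameter, cj.diameter) / 2
            bounds = ri * np.arange(m + 1) / m
            for k in range(m):
                a_k = math.pi * (bounds[k + 1] ** 2 - bounds[k] ** 2)
                couple(element_of[e.i][k], element_of[e.j][k], a_k, e.distance)
        else:
            couple(int(outer[e.i]), int(outer[e.j]), e.area, e.distance)

    if m > 1:
        # radial coupling within each shaft compartment
        for c in morph.compartments:
            if c.kind != SHAFT:
                continue
            r = c.diameter / 2
            dr = r / m
            els = element_of[c.id]
            for k in range(m - 1):
                iface = math.pi * 2 * (dr * (k + 1)) * c.length
                couple(els[k], els[k + 1], iface, dr)

    L = sp.csc_matrix((vals, (rows, cols)), shape=(vol.size, vol.size))
    return DiffusionSystem(
        vol, L, n, element_of, outer, np.array(positions), np.array(shaft_el)
    )


# ---------------------------------------------------------------------------
# main integrator
# ---------------------------------------------------------------------------


def _cable_matrices(morph: Morphology, cable: CableParams):
    """Per-compartment leak conductance (nS), capacitance (nF = nS·ms/mV),
    and axial conductance matrix (nS) for the passive cable."""
    n = morph.n
    area_cm2 = np.array([c.membrane_area for c in morph.compartments]) * 1e-8
    g_leak = area_cm2 / (cable.r_m / cable.area_scale) * 1e9  # S -> nS
    cap = area_cm2 * cable.c_m * cable.area_scale * 1e3  # μF -> nF
    rows, cols, vals = [], [], []
    for e in morph.edges:
        # g = A/(Ra·d): μm²/(Ω·cm·μm) = 1e-4/Ω -> nS factor 1e5
        g = e.area / (cable.r_a * e.distance) * 1e5
        for a, b in ((e.i, e.j), (e.j, e.i)):
            rows.extend([a, a])
            cols.extend([b, a])
            vals.extend([g, -g])
    g_ax = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return g_leak, cap, g_ax


def run_simulation(
    morph: Morphology,
    ions: IonParams | None = None,
    pump: PumpParams | None = None,
    synapses: list[SynapseParams] = (),
    cable: CableParams | None = None,
    t_end: float = 1000.0,
    dt: float = 0.5,
    record_dt: float | None = None,
    initial_cl=None,
    radial_shells: int = 0,
) -> Trajectory:
    """Integrate Cl⁻ (and optionally voltage) dynamics on a morphology.

    Operator splitting per step: implicit diffusion, exact pump relaxation,
    then synaptic influx with reversals recomputed from the current
    [Cl⁻]_i. ``initial_cl`` may be a scalar, a per-compartment array, or
    ``None`` (resting level). Without a ``cable`` the membrane potential is
    clamped at V_rest, so synaptic driving force changes only through E_Cl.

    Raises :class:`SolverError` if concentrations go negative (instability
    — reduce dt).
    """
    ions = ions or IonParams()
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if cable is not None and radial_shells:
        raise SolverError("cable voltage with radial shells is not supported")
    morph.validate()
    sys_ = build_diffusion_system(morph, ions.d_cl, radial_shells)
    n_el = sys_.volumes.size
    n = morph.n

    # initial state, per element
    if initial_cl is None:
        c_el = np.full(n_el, ions.cl_in_rest)
    elif np.isscalar(initial_cl):
        c_el = np.full(n_el, float(initial_cl))
    else:
        init = np.asarray(initial_cl, dtype=float)
        if init.shape != (n,):
            raise ValueError("initial_cl must be scalar or per-compartment")
        c_el = np.empty(n_el)
        for ci, els in enumerate(sys_.element_of):
            c_el[els] = init[ci]
    if np.any(c_el <= 0):
        raise ValueError("initial concentrations must be positive")

    n_steps = int(round(t_end / dt))
    step_of_record = max(1, int(round((record_dt or dt) / dt)))
    solver = splu(sp.identity(n_el, format="csc") - dt * sys_.laplacian)

    # pump mask per element
    pump_el_mask = None
    if pump is not None:
        if pump.mask is None:
            pump_el_mask = np.ones(n_el, dtype=bool)
        else:
            mask = np.asarray(pump.mask, dtype=bool)
            if mask.shape != (n,):
                raise ValueError("pump mask must be per-compartment")
            pump_el_mask = np.zeros(n_el, dtype=bool)
            for ci, els in enumerate(sys_.element_of):
                pump_el_mask[els] = mask[ci]
        pump_decay = math.exp(-dt / pump.tau_cl)

    # synapse bookkeeping: two-state exponential form of the double-exp
    syn_a = np.zeros(len(synapses))
    syn_b = np.zeros(len(synapses))
    syn_decay1 = np.array([math.exp(-dt / s.tau1) for s in synapses])
    syn_decay2 = np.array([math.exp(-dt / s.tau2) for s in synapses])
    syn_gpeak = np.array([s.g_max * s.norm for s in synapses])
    syn_target_el = np.array(
        [sys_.outer_element[s.target] for s in synapses], dtype=int
    )
    syn_event_ptr = [0] * len(synapses)
    for s in synapses:
        if not 0 <= s.target < n:
            raise ValueError(f"synapse target {s.target} outside morphology")
    events = []

    # voltage setup
    use_cable = cable is not None
    if use_cable:
        g_leak, cap, g_ax = _cable_matrices(morph, cable)
        v = np.full(n, ions.v_rest)
    else:
        v = None

    rec_times = [0.0]
    rec_cl = [sys_.aggregate(c_el).copy()]
    rec_v = [v.copy()] if use_cable else None
    rec_shells = [c_el.copy()] if radial_shells else None

    e_hco3 = ions.e_hco3
    for step in range(1, n_steps + 1):
        t = step * dt
        # (1) implicit diffusion
        c_el = solver.solve(c_el)
        # (2) pump
        if pump_el_mask is not None:
            relaxed = pump.cl_rest + (c_el - pump.cl_rest) * pump_decay
            c_el = np.where(pump_el_mask, relaxed, c_el)
        # (3) synapses
        if synapses:
            for k, s in enumerate(synapses):
                syn_a[k] *= syn_decay1[k]
                syn_b[k] *= syn_decay2[k]
                times = s.train.times
                while syn_event_ptr[k] < times.size and times[syn_event_ptr[k]] <= t:
                    syn_a[k] += 1.0
                    syn_b[k] += 1.0
                    events.append((float(times[syn_event_ptr[k]]), k))
                    syn_event_ptr[k] += 1
            g = syn_gpeak * (syn_b - syn_a)  # nS per synapse
            tgt = syn_target_el
            e_cl_t = units.nernst(-1, c_el[tgt], ions.cl_out, ions.temperature)
            v_t = v[[s.target for s in synapses]] if use_cable else ions.v_rest
            i_cl, i_hco3 = synaptic_currents(v_t, g, e_cl_t, e_hco3, ions.p_hco3)
            np.add.at(
                c_el,
                tgt,
                units.delta_conc_from_current(i_cl, sys_.volumes[tgt], dt),
            )
            # (4) passive voltage step (implicit), synaptic conductances
            if use_cable:
                g_syn = np.zeros(n)
                rhs_syn = np.zeros(n)
                for k, s in enumerate(synapses):
                    e_g = egaba(e_cl_t[k], e_hco3, ions.p_hco3)
                    g_syn[s.target] += g[k]
                    rhs_syn[s.target] += g[k] * e_g
                lhs = (
                    sp.diags(cap / dt + g_leak + g_syn) - g_ax
                ).tocsc()
                rhs = cap / dt * v + g_leak * ions.v_rest + rhs_syn
                v = sp.linalg.spsolve(lhs, rhs)
        elif use_cable:
            lhs = (sp.diags(cap / dt + g_leak) - g_ax).tocsc()
            v = sp.linalg.spsolve(lhs, cap / dt * v + g_leak * ions.v_rest)

        if step % step_of_record == 0 or step == n_steps:
            if np.any(c_el < 0):
                raise SolverError(
                    "negative concentration encountered — reduce dt"
                )
            rec_times.append(t)
            rec_cl.append(sys_.aggregate(c_el).copy())
            if use_cable:
                rec_v.append(np.asarray(v).copy())
            if radial_shells:
                rec_shells.append(c_el.copy())

    return Trajectory(
        times=np.array(rec_times),
        cl=np.array(rec_cl),
        v=np.array(rec_v) if use_cable else None,
        cl_shells=np.array(rec_shells) if radial_shells else None,
        events=events,
        ions=ions,
    )
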