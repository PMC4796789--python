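"""Spatial-spread metrics: normalized profiles, variance/MSD, apparent
diffusion coefficient and tortuosity, plus the Cl⁻-transient slope profile.

The spread of a focal Cl⁻ load is quantified by the spatial variance of the
normalized, baseline-subtracted concentration profile along the dendrite —
equivalent to the mean square displacement of the released ions. From the
variance the apparent diffusion coefficient follows as

    D_app(t) = (⟨x²⟩(t) − ⟨x²⟩₀) / (2t)        (1-D convention)

and the tortuosity as λ = sqrt(D_Cl / D_app) evaluated at the end of the
run: λ = 1 for unhindered diffusion, > 1 when geometry (spines, branches)
retards it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import Morphology
from .detsim import Trajectory

__all__ = [
    "Profile",
    "DiffusionMetrics",
    "profile_from_state",
    "spatial_variance",
    "apparent_diffusion",
    "tortuosity",
    "trajectory_metrics",
    "max_slope_profile",
]


@dataclass
class Profile:
    """Normalized axial mass distribution at one time point."""

    x: np.ndarray  # positions, μm
    weights: np.ndarray  # nonnegative, sum to 1
    time: float  # ms
    clipped_mass: float = 0.0  # negative residual mass removed, fraction

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.x.shape != self.weights.shape:
            raise ValueError("x and weights must have equal shape")
        if np.any(self.weights < 0):
            raise ValueError("profile weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("profile weights must sum to 1")

    @property
    def centroid(self) -> float:
        return float(np.dot(self.weights, self.x))


def profile_from_state(
    positions,
    concentration,
    volumes,
    baseline: float = 0.0,
    mask=None,
    time: float = 0.0,
) -> Profile:
    """Build a normalized mass profile from a concentration snapshot.

    Weights are baseline-subtracted concentration × compartment volume
    (a true displacement distribution of the released ions); negative
    residuals are clipped at zero and reported via ``clipped_mass``.
    ``mask`` restricts the profile (e.g. to shaft compartments).
    """
    x = np.asarray(positions, dtype=float)
    c = np.asarray(concentration, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x, c, v = x[mask], c[mask], v[mask]
    w = (c - baseline) * v
    neg = -w[w < 0].sum()
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("profile has no mass above baseline")
    return Profile(x, w / total, time, clipped_mass=float(neg / total))


def spatial_variance(profile: Profile) -> float:
    """Second central moment Σ C_n(x)(x − r_m)², μm² (= MSD)."""
    return float(np.dot(profile.weights, (profile.x - profile.centroid) ** 2))


def apparent_diffusion(variance_series, times, initial_variance: float = 0.0):
    """D_app(t) = (⟨x²⟩(t) − ⟨x²⟩₀)/(2t), μm²/ms. Times must be > 0."""
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive (t = 0 excluded)")
    return (np.asarray(variance_series, dtype=float) - initial_variance) / (2.0 * t)


def tortuosity(d_cl: float, d_app_end: float) -> float:
    """λ = sqrt(D_Cl/D_app); ``inf`` signals completely blocked diffusion."""
    if d_cl <= 0:
        raise ValueError("d_cl must be positive")
    if d_app_end <= 0:
        return float("inf")
    return float(np.sqrt(d_cl / d_app_end))


@dataclass
class DiffusionMetrics:
    """Variance/D_app time courses and the end-of-run tortuosity."""

    times: np.ndarray  # ms, excludes t = 0
    variance: np.ndarray  # μm²
    initial_variance: float
    d_app: np.ndarray  # μm²/ms
    d_cl: float
    tortuosity: float
    clipped_mass: np.ndarray | None = None

    @property
    def d_app_end(self) -> float:
        return float(self.d_app[-1])

    @property
    def reduction_percent(self) -> float:
        """100·(1 − D_app/D_Cl) at the end of the run."""
        return 100.0 * (1.0 - self.d_app_end / self.d_cl)


def trajectory_metrics(
    traj: Trajectory,
    morph: Morphology,
    d_cl: float | None = None,
    baseline: float | None = None,
    include_spines: bool = False,
    positions=None,
    mask=None,
) -> DiffusionMetrics:
    """Compute the variance → D_app → λ chain from a simulated trajectory.

    By default the profile runs over shaft compartments only (spine content
    is excluded from the axial profile); pass ``include_spines=True`` to
    fold spine mass in at its attachment position. ``positions``/``mask``
    override the axial coordinate and compartment selection, e.g. to
    restrict to a path through a branched tree.
    """
    ions = traj.ions
    if d_cl is None:
        d_cl = ions.d_cl if ions is not None else 2.0
    if baseline is None:
        baseline = ions.cl_in_rest if ions is not None else 0.0
    if mask is None:
        mask = np.ones(morph.n, dtype=bool) if include_spines else morph.shaft_mask()
    x = morph.positions() if positions is None else np.asarray(positions, float)
    vols = morph.volumes()

    p0 = profile_from_state(x, traj.cl[0], vols, baseline, mask, traj.times[0])
    var0 = spatial_variance(p0)
    times, variances, clipped = [], [], []
    for ti, ct in zip(traj.times[1:], traj.cl[1:]):
        prof = profile_from_state(x, ct, vols, baseline, mask, ti)
        times.append(ti)
        variances.append(spatial_variance(prof))
        clipped.append(prof.clipped_mass)
    times = np.array(times)
    variances = np.array(variances)
    d_app = apparent_diffusion(variances, times, var0)
    return DiffusionMetrics(
        times=times,
        variance=variances,
        initial_variance=var0,
        d_app=d_app,
        d_cl=d_cl,
        tortuosity=tortuosity(d_cl, float(d_app[-1])),
        clipped_mass=np.array(clipped),
    )


def max_slope_profile(
    traj: Trajectory, morph: Morphology, window: tuple[float, float] | None = None
):
    """Per-shaft-compartment maximum temporal slope of [Cl⁻]_i (mM/ms).

    Finite-difference slope of each compartment's Cl⁻ trace, maximized over
    the requested time window (default: the whole recording). Returns
    (positions, slopes) for shaft compartments ordered by position.
    """
    if traj.times.size < 2:
        raise ValueError("need at least two recorded time points")
    t = traj.times
    sel = np.ones(t.size, dtype=bool)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 2:
            raise ValueError("window contains fewer than two time points")
    cl = traj.cl[sel]
    dt = np.diff(t[sel])[:, None]
    slopes = np.diff(cl, axis=0) / dt
    shaft = morph.shaft_indices()
    pos = morph.positions()[shaft]
    order = np.argsort(pos)
    return pos[order], slopes.max(axis=0)[shaft][order]
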