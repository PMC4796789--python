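"""Stochastic Cl⁻ diffusion: exact spatial Gillespie SSA on a voxel graph.

Particles hop between cylindrical volume elements (voxels) with per-particle
jump propensity k_ij = D·A_ij/(V_i·d_ij). The direct-method SSA draws an
exponential waiting time from the total propensity Σ_i n_i·Σ_j k_ij and
selects the jump category with probability proportional to its propensity;
a Fenwick (binary-indexed) tree over per-voxel propensities keeps event
selection and update at O(log n_voxels). The free diffusion coefficient is
the only physical parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .morphology import SHAFT, Morphology

__all__ = ["VoxelGraph", "ParticleState", "voxelize", "ssa_run", "to_concentration"]


@dataclass
class VoxelGraph:
    """Volume partition with per-particle jump rates in CSR layout."""

    volumes: np.ndarray  # μm³
    positions: np.ndarray  # axial position, μm
    shaft: np.ndarray  # bool per voxel
    nbr_ptr: np.ndarray  # CSR row pointer, len n+1
    nbr_idx: np.ndarray  # neighbor voxel ids
    nbr_rate: np.ndarray  # k_ij, ms⁻¹
    d_cl: float

    @property
    def n(self) -> int:
        return self.volumes.size

    @property
    def out_rate(self) -> np.ndarray:
        """Total per-particle exit rate per voxel, ms⁻¹."""
        out = np.zeros(self.n)
        for i in range(self.n):
            out[i] = self.nbr_rate[self.nbr_ptr[i]: self.nbr_ptr[i + 1]].sum()
        return out

    def rate_matrix(self) -> np.ndarray:
        """Dense k_ij matrix (small graphs; for tests/inspection)."""
        k = np.zeros((self.n, self.n))
        for i in range(self.n):
            for p in range(self.nbr_ptr[i], self.nbr_ptr[i + 1]):
                k[i, self.nbr_idx[p]] = self.nbr_rate[p]
        return k


@dataclass
class ParticleState:
    """Per-voxel particle counts at one instant."""

    counts: np.ndarray
    time: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def voxelize(morph: Morphology, target_dx: float = 1.0, d_cl: float = 2.0) -> VoxelGraph:
    """Partition a morphology into diffusion voxels.

    Shaft compartments longer than ``target_dx`` are sliced into equal
    sub-voxels; each spine head/neck stays one voxel. Jump rates follow the
    discretized-diffusion formula k_ij = D·A_ij/(V_i·d_ij).
    """
    if target_dx <= 0:
        raise ValueError("target_dx must be positive")
    morph.validate()
    volumes, positions, shaft = [], [], []
    sub_of: list[list[int]] = []  # compartment -> voxel ids, in axial order
    edges: list[tuple[int, int, float, float]] = []
    for c in morph.compartments:
        if c.kind == SHAFT and c.length > target_dx:
            nsub = int(np.ceil(c.length / target_dx))
        else:
            nsub = 1
        sub_len = c.length / nsub
        start = c.axial_position - c.length / 2
        ids = []
        for k in range(nsub):
            ids.append(len(volumes))
            volumes.append(c.cross_section * sub_len)
            positions.append(start + (k + 0.5) * sub_len)
            shaft.append(c.kind == SHAFT)
            if k > 0:
                edges.append((ids[k - 1], ids[k], c.cross_section, sub_len))
        sub_of.append(ids)
    for e in morph.edges:
        ci, cj = morph.compartments[e.i], morph.compartments[e.j]
        # join the facing sub-voxels; choose by axial ordering for shafts
        ids_i, ids_j = sub_of[e.i], sub_of[e.j]
        vi = ids_i[-1] if ci.axial_position <= cj.axial_position else ids_i[0]
        vj = ids_j[0] if ci.axial_position <= cj.axial_position else ids_j[-1]
        li = ci.length / len(ids_i)
        lj = cj.length / len(ids_j)
        if ci.kind == SHAFT and cj.kind == SHAFT:
            dist = (li + lj) / 2
        else:
            dist = e.distance
        edges.append((vi, vj, e.area, dist))

    vol = np.array(volumes)
    n = vol.size
    nbrs: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, area, dist in edges:
        k = d_cl * area / dist
        nbrs[i].append((j, k / vol[i]))
        nbrs[j].append((i, k / vol[j]))
    ptr = np.zeros(n + 1, dtype=np.int64)
    idx, rate = [], []
    for i in range(n):
        ptr[i + 1] = ptr[i] + len(nbrs[i])
        for j, k in nbrs[i]:
            idx.append(j)
            rate.append(k)
    return VoxelGraph(
        vol,
        np.array(positions),
        np.array(shaft, dtype=bool),
        ptr,
        np.array(idx, dtype=np.int64),
        np.array(rate),
        d_cl,
    )


@njit(cache=True)
def _fenwick_update(tree, i, delta):
    i += 1
    while i <= tree.size - 1:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fenwick_find(tree, n, u):
    """Largest prefix with cumulative sum < u; returns that index."""
    pos = 0
    bit = 1
    while bit * 2 <= n:
        bit *= 2
    rem = u
    while bit > 0:
        nxt = pos + bit
        if nxt <= n and tree[nxt] < rem:
            pos = nxt
            rem -= tree[nxt]
        bit //= 2
    return pos  # 0-based voxel index

@njit(cache=True)
def _ssa_kernel(counts, out_rate, nbr_ptr, nbr_idx, nbr_rate,
                snapshot_times, seed):
    np.random.seed(seed)
    n = counts.size
    tree = np.zeros(n + 1)
    for i in range(n):
        _fenwick_update(tree, i, counts[i] * out_rate[i])
    total = 0.0
    for i in range(n):
        total += counts[i] * out_rate[i]
    t = 0.0
    n_snap = snapshot_times.size
    out = np.zeros((n_snap, n), dtype=np.int64)
    snap = 0
    while snap < n_snap:
        if total <= 0.0:
            while snap < n_snap:
                out[snap] = counts
                snap += 1
            break
        dt = -np.log(np.random.random()) / total
        t_next = t + dt
        while snap < n_snap and snapshot_times[snap] < t_next:
            out[snap] = counts
            snap += 1
        if snap >= n_snap:
            break
        t = t_next
        # pick source voxel by propensity, then neighbor by rate
        u = np.random.random() * total
        src = _fenwick_find(tree, n, u)
        if src >= n:  # guard against float drift in the running total
            src = n - 1
        if counts[src] == 0 or nbr_ptr[src] == nbr_ptr[src + 1]:
            continue
        r = np.random.random() * out_rate[src]
        acc = 0.0
        dst = nbr_idx[nbr_ptr[src]]
        for p in range(nbr_ptr[src], nbr_ptr[src + 1]):
            acc += nbr_rate[p]
            if r < acc:
                dst = nbr_idx[p]
                break
        counts[src] -= 1
        counts[dst] += 1
        _fenwick_update(tree, src, -out_rate[src])
        _fenwick_update(tree, dst, out_rate[dst])
        total += out_rate[dst] - out_rate[src]
    return out


def ssa_run(
    graph: VoxelGraph,
    n_particles: int,
    release_region,
    t_end: float,
    snapshot_times,
    seed: int,
) -> list[ParticleState]:
    """Exact SSA run; returns snapshots at the requested times.

    ``release_region`` is an (x_lo, x_hi) axial interval — the initial
    particles are distributed over the shaft voxels inside it, multinomially
    with volume weights — or an explicit array of voxel indices. Runs are
    bit-reproducible for a given seed.
    """
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    if np.any(snapshot_times < 0) or np.any(snapshot_times > t_end):
        raise ValueError("snapshot times must lie in [0, t_end]")
    if np.any(np.diff(snapshot_times) < 0):
        raise ValueError("snapshot times must be sorted")
    rng = np.random.default_rng(seed)
    counts = np.zeros(graph.n, dtype=np.int64)
    if isinstance(release_region, tuple):
        lo, hi = release_region
        sel = graph.shaft & (graph.positions >= lo) & (graph.positions <= hi)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            raise ValueError("release region contains no shaft voxels")
        w = graph.volumes[idx] / graph.volumes[idx].sum()
        counts[idx] = rng.multinomial(n_particles, w)
    else:
        idx = np.asarray(release_region, dtype=int)
        w = graph.volumes[idx] / graph.volumes[idx].sum()
        counts[idx] = rng.multinomial(n_particles, w)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    snaps = _ssa_kernel(
        counts.copy(),
        graph.out_rate,
        graph.nbr_ptr,
        graph.nbr_idx,
        graph.nbr_rate,
        snapshot_times,
        kernel_seed,
    )
    return [
        ParticleState(snaps[k].copy(), float(snapshot_times[k]))
        for k in range(snapshot_times.size)
    ]


def to_concentration(
    state: ParticleState, graph: VoxelGraph, particles_per_mM_um3: float
) -> np.ndarray:
    """Convert particle counts to mM: C_i = n_i/(factor·V_i)."""
    if particles_per_mM_um3 <= 0:
        raise ValueError("conversion factor must be positive")
    return state.counts / (particles_per_mM_um3 * graph.volumes)
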