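"""Synthetic spiny/smooth dendritic morphologies and stimulus trains.

A morphology is a connected graph of cylindrical compartments: a chain (or
tree) of shaft compartments, with spines hanging off it. Each spine is two
concentric cylinders — a thin neck joining the shaft to a bulbous head — and
couples to the shaft through the neck cross-section only, which is what
makes spines act as diffusional traps.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpineGeometry",
    "CANONICAL_SPINE",
    "GRANULE_SPINE",
    "Compartment",
    "Edge",
    "Morphology",
    "StimulusTrain",
    "build_cylinder",
    "attach_spines",
    "matched_diameter",
    "implicit_spine_factors",
    "make_stimulus",
]


@dataclass(frozen=True)
class SpineGeometry:
    """Dimensions of one dendritic spine (μm).

    Defaults are the STED-derived values used for the cylinder experiments:
    head 0.6 μm × 0.55 μm, neck 0.2 μm × 1.25 μm.
    """

    head_diameter: float = 0.6
    head_length: float = 0.55
    neck_diameter: float = 0.2
    neck_length: float = 1.25

    def __post_init__(self):
        for name in ("head_diameter", "head_length", "neck_diameter", "neck_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SpineGeometry.{name} must be positive")
        if self.neck_diameter > self.head_diameter:
            warnings.warn(
                "spine neck wider than head — unusual geometry", stacklevel=2
            )

    @property
    def head_volume(self) -> float:
        return math.pi * (self.head_diameter / 2) ** 2 * self.head_length

    @property
    def neck_volume(self) -> float:
        return math.pi * (self.neck_diameter / 2) ** 2 * self.neck_length

    @property
    def total_volume(self) -> float:
        """Volume added per spine, μm³ (≈0.195 for the canonical spine)."""
        return self.head_volume + self.neck_volume

    @property
    def neck_cross_section(self) -> float:
        """Coupling area through the neck, μm² (≈0.0314 canonical)."""
        return math.pi * (self.neck_diameter / 2) ** 2

    def membrane_area(self, include_head_cap: bool = True) -> float:
        """Membrane area contributed per spine, μm².

        Lateral areas of neck and head; the head additionally contributes
        its distal end cap when ``include_head_cap`` (default, the adopted
        convention for implicit-spine scaling).
        """
        area = math.pi * (
            self.head_diameter * self.head_length
            + self.neck_diameter * self.neck_length
        )
        if include_head_cap:
            area += math.pi * (self.head_diameter / 2) ** 2
        return area


#: Spine used for the 700 μm cylinder experiments.
CANONICAL_SPINE = SpineGeometry()

#: Smaller spine of the dentate granule cell model.
GRANULE_SPINE = SpineGeometry(0.5, 0.5, 0.18, 0.75)

SHAFT = "shaft"
SPINE_NECK = "spine_neck"
SPINE_HEAD = "spine_head"


@dataclass
class Compartment:
    """One cylindrical volume element.

    ``axial_position`` is the distance of the cylinder midpoint along the
    parent dendritic path (μm); spine compartments inherit the position of
    the shaft compartment they attach to, so axial profiles can place spine
    content at its point of attachment.
    """

    id: int
    kind: str
    axial_position: float
    length: float
    diameter: float

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("compartment length and diameter must be positive")
        if self.kind not in (SHAFT, SPINE_NECK, SPINE_HEAD):
            raise ValueError(f"unknown compartment kind {self.kind!r}")

    @property
    def volume(self) -> float:
        return math.pi * (self.diameter / 2) ** 2 * self.length

    @property
    def cross_section(self) -> float:
        return math.pi * (self.diameter / 2) ** 2

    @property
    def membrane_area(self) -> float:
        """Lateral area; spine heads add their distal cap."""
        area = math.pi * self.diameter * self.length
        if self.kind == SPINE_HEAD:
            area += self.cross_section
        return area


@dataclass(frozen=True)
class Edge:
    """Undirected diffusive coupling between two compartments."""

    i: int
    j: int
    area: float  # coupling cross-section, μm²
    distance: float  # center-to-center, μm

    def __post_init__(self):
        if self.area <= 0 or self.distance <= 0:
            raise ValueError("edge area and distance must be positive")


@dataclass
class Morphology:
    compartments: list[Compartment]
    edges: list[Edge]
    #: (shaft_id, neck_id, head_id) per spine
    spines: list[tuple[int, int, int]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    # ---- array views -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compartments)

    def volumes(self) -> np.ndarray:
        return np.array([c.volume for c in self.compartments])

    def positions(self) -> np.ndarray:
        return np.array([c.axial_position for c in self.compartments])

    def kinds(self) -> np.ndarray:
        return np.array([c.kind for c in self.compartments])

    def shaft_mask(self) -> np.ndarray:
        return np.array([c.kind == SHAFT for c in self.compartments])

    def shaft_indices(self) -> np.ndarray:
        return np.flatnonzero(self.shaft_mask())

    @property
    def total_volume(self) -> float:
        return float(self.volumes().sum())

    @property
    def shaft_length(self) -> float:
        return float(sum(c.length for c in self.compartments if c.kind == SHAFT))

    def adjacency(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n)]
        for e in self.edges:
            nbrs[e.i].append(e.j)
            nbrs[e.j].append(e.i)
        return nbrs

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        n = self.n
        for e in self.edges:
            if not (0 <= e.i < n and 0 <= e.j < n) or e.i == e.j:
                raise ValueError(f"edge {e} references invalid compartments")
        # connectivity
        if n:
            seen = np.zeros(n, dtype=bool)
            stack = [0]
            seen[0] = True
            adj = self.adjacency()
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            if not seen.all():
                raise ValueError("morphology graph is not connected")
        # spine topology: head connects only through its neck to one shaft
        adj = self.adjacency()
        for shaft_id, neck_id, head_id in self.spines:
            if sorted(adj[head_id]) != [neck_id]:
                raise ValueError("spine head must connect only to its neck")
            if sorted(adj[neck_id]) != sorted([shaft_id, head_id]):
                raise ValueError("spine neck must join exactly head and shaft")

    def nearest_shaft(self, position: float) -> int:
        shaft = self.shaft_indices()
        pos = self.positions()[shaft]
        return int(shaft[np.argmin(np.abs(pos - position))])

    # ---- serialization ----------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "compartments": [
                    [c.id, c.kind, c.axial_position, c.length, c.diameter]
                    for c in self.compartments
                ],
                "edges": [[e.i, e.j, e.area, e.distance] for e in self.edges],
                "spines": self.spines,
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Morphology":
        d = json.loads(text)
        return cls(
            compartments=[Compartment(*row) for row in d["compartments"]],
            edges=[Edge(*row) for row in d["edges"]],
            spines=[tuple(s) for s in d["spines"]],
            provenance=d.get("provenance", {}),
        )

    def copy(self) -> "Morphology":
        return Morphology.from_json(self.to_json())


def build_cylinder(length: float, diameter: float, dx: float = 1.0) -> Morphology:
    """Discretize a sealed dendritic cylinder into a chain of compartments.

    ``ceil(length/dx)`` compartments; the last one is shortened so the total
    length is exact. Sealed (zero-flux) ends are implicit: boundary
    compartments simply have a single neighbor.
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("cylinder length and diameter must be positive")
    if not (0 < dx <= length):
        raise ValueError("dx must satisfy 0 < dx <= length")
    n = math.ceil(length / dx)
    lengths = np.full(n, dx)
    lengths[-1] = length - dx * (n - 1)
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    comps = [
        Compartment(i, SHAFT, float(starts[i] + lengths[i] / 2), float(lengths[i]), diameter)
        for i in range(n)
    ]
    area = math.pi * (diameter / 2) ** 2
    edges = [
        Edge(i, i + 1, area, float((lengths[i] + lengths[i + 1]) / 2))
        for i in range(n - 1)
    ]
    return Morphology(
        comps,
        edges,
        provenance={"generator": "build_cylinder", "length": length,
                    "diameter": diameter, "dx": dx},
    )


def attach_spines(
    morph: Morphology,
    density: float,
    geom: SpineGeometry = CANONICAL_SPINE,
    seed: int | None = None,
    region: tuple[float, float] | None = None,
) -> Morphology:
    """Return a copy of ``morph`` with spines attached at random positions.

    ``round(density × span)`` spines are placed at positions drawn uniformly
    i.i.d. (several spines may share a shaft compartment). Each spine is a
    neck + head chain off the nearest shaft compartment; the shaft–neck and
    neck–head couplings both use the neck cross-section.

    ``region`` restricts placement to an axial interval; by default spines
    are distributed over the whole shaft, length-weighted across shaft
    compartments (identical to uniform axial placement on an unbranched
    cylinder, and well defined on trees).
    """
    if density < 0:
        raise ValueError("spine density must be >= 0")
    out = morph.copy()
    out.provenance = dict(morph.provenance)
    out.provenance.update({"spine_density": density, "spine_seed": seed,
                           "spine_geometry": vars(geom) if hasattr(geom, "__dict__")
                           else {f: getattr(geom, f) for f in
                                 ("head_diameter", "head_length",
                                  "neck_diameter", "neck_length")}})
    rng = np.random.default_rng(seed)
    shaft = out.shaft_indices()
    if region is not None:
        lo, hi = region
        pos = out.positions()
        ext_lo = min(pos[shaft])
        ext_hi = max(pos[shaft])
        if not (ext_lo - 1.0 <= lo < hi <= ext_hi + 1.0):
            raise ValueError("region outside shaft extent")
        span = hi - lo
        n_spines = int(round(density * span))
        targets = [out.nearest_shaft(p) for p in rng.uniform(lo, hi, n_spines)]
    else:
        lengths = np.array([out.compartments[i].length for i in shaft])
        span = lengths.sum()
        n_spines = int(round(density * span))
        cum = np.cumsum(lengths)
        draws = rng.uniform(0, span, n_spines)
        idx = np.minimum(np.searchsorted(cum, draws, side="right"), len(shaft) - 1)
        targets = [int(shaft[k]) for k in idx]
    for s in targets:
        sc = out.compartments[s]
        neck_id = out.n
        out.compartments.append(
            Compartment(neck_id, SPINE_NECK, sc.axial_position,
                        geom.neck_length, geom.neck_diameter)
        )
        head_id = out.n
        out.compartments.append(
            Compartment(head_id, SPINE_HEAD, sc.axial_position,
                        geom.head_length, geom.head_diameter)
        )
        out.edges.append(
            Edge(s, neck_id, geom.neck_cross_section,
                 sc.diameter / 2 + geom.neck_length / 2)
        )
        out.edges.append(
            Edge(neck_id, head_id, geom.neck_cross_section,
                 (geom.neck_length + geom.head_length) / 2)
        )
        out.spines.append((s, neck_id, head_id))
    return out


def matched_diameter(
    base_diameter: float, density: float, geom: SpineGeometry = CANONICAL_SPINE
) -> float:
    """Diameter of the smooth cylinder with the same volume per unit length
    as a ``base_diameter`` cylinder carrying ``density`` spines/μm.

    π d'²/4 = π d²/4 + density·V_spine; e.g. 1 μm at 2 spines/μm → ≈1.22 μm,
    at 5 spines/μm → ≈1.50 μm.
    """
    if base_diameter <= 0:
        raise ValueError("base diameter must be positive")
    if density < 0:
        raise ValueError("spine density must be >= 0")
    return math.sqrt(base_diameter**2 + 4 * density * geom.total_volume / math.pi)


def implicit_spine_factors(
    morph: Morphology,
    density: float,
    geom: SpineGeometry = CANONICAL_SPINE,
    include_head_cap: bool = True,
) -> float:
    """Membrane-area scale factor F >= 1 for implicit spines.

    F = (shaft area + spine area per unit length) / (shaft area per unit
    length). Spines are absorbed into the shaft membrane by multiplying the
    specific capacitance by F and dividing the specific membrane resistance
    by F. The shaft diameter is the length-weighted mean over shaft
    compartments.
    """
    if density < 0:
        raise ValueError("spine density must be >= 0")
    shaft = [c for c in morph.compartments if c.kind == SHAFT]
    if not shaft:
        raise ValueError("morphology has no shaft compartments")
    total_len = sum(c.length for c in shaft)
    mean_d = sum(c.diameter * c.length for c in shaft) / total_len
    shaft_area_per_um = math.pi * mean_d
    return 1.0 + density * geom.membrane_area(include_head_cap) / shaft_area_per_um


@dataclass(frozen=True)
class StimulusTrain:
    """Sorted synaptic event times (ms)."""

    times: np.ndarray
    mode: str
    rate: float
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ValueError("event times must be sorted and nonnegative")

    @property
    def n_events(self) -> int:
        return int(self.times.size)


def make_stimulus(
    mode: str,
    rate: float,
    n_events: int | None = None,
    duration: float | None = None,
    seed: int | None = None,
) -> StimulusTrain:
    """Build a periodic or homogeneous-Poisson stimulus train.

    Periodic: ``n_events`` events at k·1000/rate ms, k = 0..n-1 (10 Hz × 30
    pulses spans 2900 ms of onsets, i.e. activity over 3 s). Poisson: events
    over ``duration`` ms at the given mean rate, seeded.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if mode == "periodic":
        if n_events is None:
            if duration is None:
                raise ValueError("periodic mode needs n_events or duration")
            n_events = int(math.floor(duration * rate / 1000.0)) + (1 if rate > 0 else 0)
        if n_events > 0 and rate == 0:
            raise ValueError("periodic mode with events requires rate > 0")
        times = np.arange(n_events) * (1000.0 / rate) if n_events else np.empty(0)
        return StimulusTrain(times, "periodic", rate, seed)
    if mode == "poisson":
        if duration is None:
            raise ValueError("poisson mode needs a duration")
        rng = np.random.default_rng(seed)
        if rate == 0:
            return StimulusTrain(np.empty(0), "poisson", rate, seed)
        # expected count rate·duration/1000; draw gaps until past duration
        times = []
        t = rng.exponential(1000.0 / rate)
        while t < duration:
            times.append(t)
            t += rng.exponential(1000.0 / rate)
        return StimulusTrain(np.array(times), "poisson", rate, seed)
    raise ValueError(f"unknown stimulus mode {mode!r}")
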