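"""Read and write neuronal morphologies in the standard 7-column SWC format.

Columns: id, type, x, y, z, radius, parent (μm). Each child node defines one
cylindrical compartment between itself and its parent, with diameter equal
to the mean of the two node diameters; a type-1 root is treated as a single
soma-like compartment. Types 3/4 (basal/apical dendrite) and everything
else map onto shaft compartments — spines are attached afterwards with
:func:`cldend.morphology.attach_spines`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import SHAFT, Compartment, Edge, Morphology

__all__ = ["load_swc", "write_swc", "SwcFormatError"]


class SwcFormatError(ValueError):
    """Malformed SWC record, reported with its line number."""


@dataclass
class _Node:
    id: int
    type: int
    xyz: np.ndarray
    radius: float
    parent: int


def _parse(text: str) -> dict[int, _Node]:
    nodes: dict[int, _Node] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcFormatError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            ntype = int(parts[1])
            xyz = np.array([float(p) for p in parts[2:5]])
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise SwcFormatError(f"line {lineno}: {exc}") from None
        if radius <= 0:
            raise SwcFormatError(f"line {lineno}: nonpositive radius")
        if nid in nodes:
            raise SwcFormatError(f"line {lineno}: duplicate node id {nid}")
        nodes[nid] = _Node(nid, ntype, xyz, radius, parent)
    for n in nodes.values():
        if n.parent != -1 and n.parent not in nodes:
            raise SwcFormatError(f"node {n.id}: orphan parent {n.parent}")
    return nodes


def load_swc(path) -> Morphology:
    """Load an SWC file into a compartmental :class:`Morphology`."""
    with open(path) as fh:
        nodes = _parse(fh.read())
    if not nodes:
        raise SwcFormatError("empty SWC file")

    order = sorted(nodes)  # stable topological-ish order (ids ascend in practice)
    comps: list[Compartment] = []
    edges: list[Edge] = []
    # compartment index owned by each node: for the root this is its soma
    # compartment (if any), for others the compartment ending at the node
    comp_of_node: dict[int, int] = {}
    # path distance of each node from the root
    path_pos: dict[int, float] = {}

    roots = [nid for nid in order if nodes[nid].parent == -1]
    if len(roots) != 1:
        raise SwcFormatError(f"expected exactly one root, found {len(roots)}")
    root = nodes[roots[0]]
    path_pos[root.id] = 0.0
    if root.type == 1:
        # soma as a single equivalent cylinder (L = d = 2r)
        comps.append(Compartment(0, SHAFT, 0.0, 2 * root.radius, 2 * root.radius))
        comp_of_node[root.id] = 0

    for nid in order:
        node = nodes[nid]
        if node.parent == -1:
            continue
        parent = nodes[node.parent]
        if node.parent not in path_pos:
            raise SwcFormatError(f"node {nid}: parent {node.parent} appears after child")
        length = float(np.linalg.norm(node.xyz - parent.xyz))
        if length <= 0:
            raise SwcFormatError(f"node {nid}: zero-length segment")
        diameter = node.radius + parent.radius  # mean of the two diameters
        path_pos[nid] = path_pos[node.parent] + length
        cid = len(comps)
        comps.append(
            Compartment(cid, SHAFT, path_pos[node.parent] + length / 2, length, diameter)
        )
        comp_of_node[nid] = cid
        if node.parent in comp_of_node:
            pid = comp_of_node[node.parent]
            pc = comps[pid]
            area = math.pi * (min(pc.diameter, diameter) / 2) ** 2
            edges.append(Edge(pid, cid, area, (pc.length + length) / 2))

    morph = Morphology(comps, edges, provenance={"swc_path": str(path)})
    morph.validate()
    return morph


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology to SWC.

    Shaft compartments are laid out along +x at their cumulative path
    positions; spine necks/heads branch off in +y. The node radii reproduce
    compartment diameters exactly for piecewise-constant-diameter chains, so
    a generated cylinder round-trips with identical total length and volume.
    """
    adj = morph.adjacency()
    lines = ["# generated by cldend.swc.write_swc"]
    node_of_comp: dict[int, int] = {}
    next_id = 1

    def emit(nid, ntype, xyz, radius, parent):
        lines.append(
            f"{nid} {ntype} {xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g} {radius:.9g} {parent}"
        )

    # root node at the proximal end of compartment 0
    c0 = morph.compartments[0]
    emit(next_id, 3, (c0.axial_position - c0.length / 2, 0.0, 0.0), c0.diameter / 2, -1)
    root_node = next_id
    next_id += 1

    seen = {0}
    stack = [(0, root_node)]
    spine_of = {}
    for s, nk, hd in morph.spines:
        spine_of[nk] = s
    while stack:
        cid, parent_node = stack.pop()
        c = morph.compartments[cid]
        if c.kind == SHAFT:
            xyz = (c.axial_position + c.length / 2, 0.0, 0.0)
        else:
            # stack spine compartments upward at their attachment position
            base = morph.compartments[parent_of_spine(morph, cid, spine_of)]
            y = c.length if c.kind == "spine_neck" else c.length + neck_len(morph, cid)
            xyz = (base.axial_position, y, 0.0)
        emit(next_id, 3, xyz, c.diameter / 2, parent_node)
        node_of_comp[cid] = next_id
        my_node = next_id
        next_id += 1
        for nb in adj[cid]:
            if nb not in seen:
                seen.add(nb)
                stack.append((nb, my_node))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parent_of_spine(morph, cid, spine_of):
    for s, nk, hd in morph.spines:
        if cid in (nk, hd):
            return s
    raise ValueError(f"compartment {cid} is not part of a spine")


def neck_len(morph, head_id):
    for s, nk, hd in morph.spines:
        if hd == head_id:
            return morph.compartments[nk].length
    raise ValueError(f"compartment {head_id} is not a spine head")
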