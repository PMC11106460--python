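"""Morphological feature extraction from labelled SWC morphologies.

Lengths are reported in millimetres, counts as plain integers.  "Nodes" in
the per-tree census means bifurcation points (branch points): an unbranched
oblique has 0 nodes, and CA1 obliques average just under one node per tree.
Trifurcations count as two binary-equivalent bifurcations so counts stay
additive under tree decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

from .compartments import CompartmentLabeling, apical_roots, soma_depth_fraction
from .swc import BASAL, DENDRITIC_CLASSES, SOMA, LayerAnnotation, Morphology, SWCError

EARLY_BIFURCATION_CUTOFF_UM = 200.0

#: canonical ordering of the 12 morphological/anatomical features
MORPH_FEATURE_NAMES = (
    "tdl_total", "tdl_basal", "tdl_oblique", "tdl_apical_trunk_tuft",
    "n_basal_trees", "n_oblique_trees",
    "nodes_per_tree_basal", "nodes_per_tree_oblique",
    "n_early_bifurcations", "n_total_bifurcations", "n_terminal_branches",
    "soma_depth_fraction",
)


@dataclass
class MorphFeatures:
    """The 12 morphological/anatomical features of one cell.

    ``tdl_*`` in mm; ``soma_depth_fraction`` in [0, 1] or NaN when no layer
    annotation was available; apical-dependent counts are NaN for purely
    basal cells.
    """

    tdl_total: float
    tdl_basal: float
    tdl_oblique: float
    tdl_apical_trunk_tuft: float
    n_basal_trees: float
    n_oblique_trees: float
    nodes_per_tree_basal: float
    nodes_per_tree_oblique: float
    n_early_bifurcations: float
    n_total_bifurcations: float
    n_terminal_branches: float
    soma_depth_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> None:
        parts = self.tdl_basal + self.tdl_oblique + self.tdl_apical_trunk_tuft
        if abs(parts - self.tdl_total) > 1e-6:
            raise ValueError(
                f"compartment lengths ({parts} mm) do not sum to TDL ({self.tdl_total} mm)"
            )
        if not math.isnan(self.n_early_bifurcations):
            if self.n_early_bifurcations > self.n_total_bifurcations:
                raise ValueError("early bifurcations exceed total bifurcations")


def _dendritic_segments(morph: Morphology):
    """(node, length) for every parent->child segment whose child is dendritic."""
    for n in morph.nodes:
        if n.structure in DENDRITIC_CLASSES and n.parent_id != -1:
            yield n, morph.segment_length(n.id)


def total_dendritic_length(morph: Morphology) -> float:
    """Summed Euclidean length (mm) of all dendritic segments.

    A segment belongs to the dendrite when its child node is basal or
    apical class; soma and axon segments are excluded.
    """
    total = sum(length for _, length in _dendritic_segments(morph))
    if total == 0.0:
        warnings.warn("morphology has no dendritic segments; TDL = 0", UserWarning,
                      stacklevel=2)
    return total / 1000.0


def compartment_lengths(
    morph: Morphology, labeling: CompartmentLabeling
) -> tuple[float, float, float]:
    """(basal, oblique, trunk+tuft) lengths in mm; they sum to the TDL."""
    sums = {"basal": 0.0, "oblique": 0.0, "trunk": 0.0, "tuft": 0.0}
    for node, length in _dendritic_segments(morph):
        label = labeling.labels.get(node.id)
        if label is None or label not in sums:
            raise SWCError(f"dendritic node {node.id} has no compartment label")
        sums[label] += length
    return (
        sums["basal"] / 1000.0,
        sums["oblique"] / 1000.0,
        (sums["trunk"] + sums["tuft"]) / 1000.0,
    )


def _bifurcation_count(morph: Morphology, tree_root: int, member) -> int:
    """Binary-equivalent branch points in one subtree (trifurcation = 2)."""
    ch = morph.children()
    count = 0
    stack = [tree_root]
    while stack:
        nid = stack.pop()
        kids = [c for c in ch[nid] if member(c)]
        if len(kids) >= 2:
            count += len(kids) - 1
        stack.extend(kids)
    return count


def tree_census(
    morph: Morphology, labeling: CompartmentLabeling
) -> tuple[int, int, float, float]:
    """Primary-tree counts and mean bifurcations ("nodes") per tree.

    Returns ``(n_basal_trees, n_oblique_trees, nodes_per_tree_basal,
    nodes_per_tree_oblique)``.  Basal trees are basal stems attached to the
    soma; oblique trees are oblique subtrees attached to a trunk node.
    """
    ch = morph.children()
    basal_roots = [
        n.id for n in morph.nodes
        if n.structure == BASAL and n.parent_id != -1
        and morph.node(n.parent_id).structure == SOMA
    ]
    oblique_roots = [
        nid for nid, lab in labeling.labels.items()
        if lab == "oblique" and labeling.labels.get(morph.node(nid).parent_id) == "trunk"
    ]
    oblique_roots.sort()

    def in_label(label):
        return lambda c: labeling.labels.get(c) == label

    basal_bifs = [_bifurcation_count(morph, r, in_label("basal")) for r in basal_roots]
    oblique_bifs = [_bifurcation_count(morph, r, in_label("oblique")) for r in oblique_roots]
    mean = lambda xs: float(sum(xs)) / len(xs) if xs else 0.0
    return len(basal_roots), len(oblique_roots), mean(basal_bifs), mean(oblique_bifs)


def path_distances_from(morph: Morphology, root: int) -> dict[int, float]:
    """Path distance (μm) along the tree from ``root`` to each subtree node."""
    ch = morph.children()
    dist = {root: 0.0}
    stack = [root]
    while stack:
        nid = stack.pop()
        for c in ch[nid]:
            dist[c] = dist[nid] + morph.segment_length(c)
            stack.append(c)
    return dist


def early_bifurcations(
    morph: Morphology,
    labeling: CompartmentLabeling,
    cutoff_um: float = EARLY_BIFURCATION_CUTOFF_UM,
) -> int:
    """Trunk bifurcations within ``cutoff_um`` path distance of the apical root.

    A trunk bifurcation is a trunk node with ≥2 trunk-labelled children;
    the number of main apical trees equals this count + 1.
    """
    if not labeling.has_apical:
        raise SWCError("no apical tree: early-bifurcation count undefined")
    ch = morph.children()
    count = 0
    for root in apical_roots(morph):
        dist = path_distances_from(morph, root)
        for nid, d in dist.items():
            if labeling.labels.get(nid) != "trunk" or d > cutoff_um:
                continue
            trunk_kids = [c for c in ch[nid] if labeling.labels.get(c) == "trunk"]
            if len(trunk_kids) >= 2:
                count += len(trunk_kids) - 1
    return count


def total_bifurcations(morph: Morphology) -> int:
    """Binary-equivalent branch points over all dendritic nodes."""
    ch = morph.children()
    count = 0
    for n in morph.nodes:
        if n.structure not in DENDRITIC_CLASSES and n.structure != SOMA:
            continue
        kids = [c for c in ch[n.id] if morph.node(c).structure in DENDRITIC_CLASSES]
        if n.structure == SOMA:
            continue  # soma is a root hub, not a dendritic branch point
        if len(kids) >= 2:
            count += len(kids) - 1
    return count


def terminal_branches(morph: Morphology) -> int:
    """Number of dendritic tips (terminal branches)."""
    ch = morph.children()
    return sum(
        1 for n in morph.nodes
        if n.structure in DENDRITIC_CLASSES
        and not any(morph.node(c).structure in DENDRITIC_CLASSES for c in ch[n.id])
    )


def morph_feature_vector(
    morph: Morphology,
    labeling: CompartmentLabeling,
    layers: LayerAnnotation | None = None,
) -> MorphFeatures:
    """Assemble the full 12-feature morphological record for one cell."""
    tdl = total_dendritic_length(morph)
    basal, oblique, trunk_tuft = compartment_lengths(morph, labeling)
    nb, nob, npb, npo = tree_census(morph, labeling)
    if labeling.has_apical:
        early = float(early_bifurcations(morph, labeling))
    else:
        early = math.nan
    depth = soma_depth_fraction(morph, layers) if layers is not None else math.nan
    feats = MorphFeatures(
        tdl_total=tdl,
        tdl_basal=basal,
        tdl_oblique=oblique,
        tdl_apical_trunk_tuft=trunk_tuft,
        n_basal_trees=float(nb),
        n_oblique_trees=float(nob),
        nodes_per_tree_basal=npb,
        nodes_per_tree_oblique=npo,
        n_early_bifurcations=early,
        n_total_bifurcations=float(total_bifurcations(morph)),
        n_terminal_branches=float(terminal_branches(morph)),
        soma_depth_fraction=depth,
    )
    feats.validate()
    return feats
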