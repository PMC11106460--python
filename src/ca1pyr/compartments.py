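"""Compartment classification: basal / trunk / oblique / tuft labelling.

CA1 pyramidal cell dendrites decompose into basal trees (from the soma),
the main apical trunk(s), oblique side branches emerging from the trunk,
and the distal tuft in stratum lacunosum-moleculare.  Reconstructions carry
only the coarse SWC classes (basal vs. apical), so the apical subtree must
be split algorithmically.

Trunk definition
----------------
With a layer annotation, the trunk is the set of apical paths from the
apical root to the SR|SLM border: walking distally, the first node at or
beyond the border starts a tuft subtree.  At an apical bifurcation, every
child whose subtree reaches the border continues as trunk (two or more
reaching children form a trunk bifurcation — a "main apical tree" split);
children that never reach the border are oblique subtrees.  Without layers
a principal-path heuristic is used: greedily follow the child with the
larger total subtree length, stopping at the first bifurcation whose child
subtrees each hold ≥10% of the remaining apical length (that node starts
the tuft).

Both rules are deterministic and invariant under rigid transforms of the
coordinates (the layer rule depends only on the radial coordinate relative
to the borders, which move with the cell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .swc import (
    APICAL, AXON, BASAL, SOMA,
    LayerAnnotation, Morphology, SWCStructureError,
)

PRINCIPAL_PATH_BRANCH_FRACTION = 0.10


class NoApicalTreeWarning(UserWarning):
    pass


@dataclass
class CompartmentLabeling:
    """Per-node compartment labels for one morphology."""

    labels: dict[int, str]
    has_apical: bool = True
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, node_id: int) -> str:
        return self.labels[node_id]

    def nodes_with(self, label: str) -> list[int]:
        return [nid for nid, lab in self.labels.items() if lab == label]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def _subtree_stats(morph: Morphology, roots: list[int], coord, orientation: float):
    """Iterative post-order pass: per node, subtree total length and max
    signed radial coordinate."""
    ch = morph.children()
    length: dict[int, float] = {}
    max_coord: dict[int, float] = {}
    for root in roots:
        stack = [(root, False)]
        while stack:
            nid, processed = stack.pop()
            if not processed:
                stack.append((nid, True))
                stack.extend((c, False) for c in ch[nid])
            else:
                tot = 0.0
                mc = orientation * coord(morph.node(nid))
                for c in ch[nid]:
                    tot += length[c] + morph.segment_length(c)
                    mc = max(mc, max_coord[c])
                length[nid] = tot
                max_coord[nid] = mc
    return length, max_coord


def _label_subtree(morph: Morphology, root: int, label: str, labels: dict[int, str]):
    ch = morph.children()
    stack = [root]
    while stack:
        nid = stack.pop()
        labels[nid] = label
        stack.extend(ch[nid])


def apical_roots(morph: Morphology) -> list[int]:
    """Apical-class nodes attached to the soma (usually exactly one)."""
    roots = []
    for n in morph.nodes:
        if n.structure == APICAL and n.parent_id != -1:
            if morph.node(n.parent_id).structure == SOMA:
                roots.append(n.id)
    return roots


def classify_compartments(
    morph: Morphology, layers: LayerAnnotation | None = None
) -> CompartmentLabeling:
    """Label every node soma/axon/basal/trunk/oblique/tuft.

    Basal labels coincide with SWC class 3; the apical subtree is split per
    the trunk definition in the module docstring.  A morphology without an
    apical subtree is labelled (basal only) with ``has_apical=False`` and a
    warning, so apical-dependent features can be recorded as undefined.
    """
    morph.validate()
    labels: dict[int, str] = {}
    for n in morph.nodes:
        if n.structure == SOMA:
            labels[n.id] = "soma"
        elif n.structure == AXON:
            labels[n.id] = "axon"
        elif n.structure == BASAL:
            labels[n.id] = "basal"

    roots = apical_roots(morph)
    if not roots:
        # purely basal cell: nothing apical to split
        if any(n.structure == APICAL for n in morph.nodes):
            raise SWCStructureError("apical nodes present but none attach to the soma")
        warnings.warn("morphology has no apical tree; apical features undefined",
                      NoApicalTreeWarning, stacklevel=2)
        return CompartmentLabeling(labels, has_apical=False)

    if layers is not None:
        _classify_with_layers(morph, roots, layers, labels)
    else:
        for root in roots:
            _classify_principal_path(morph, root, labels)
    return CompartmentLabeling(labels, has_apical=True)


def _classify_with_layers(morph, roots, layers: LayerAnnotation, labels):
    sign = layers.orientation
    border = sign * layers.sr_slm
    coord = layers.coord
    length, max_coord = _subtree_stats(morph, roots, coord, sign)
    ch = morph.children()
    for root in roots:
        stack = [root]
        while stack:
            nid = stack.pop()
            if sign * coord(morph.node(nid)) >= border:
                _label_subtree(morph, nid, "tuft", labels)
                continue
            labels[nid] = "trunk"
            kids = ch[nid]
            if not kids:
                continue
            reaching = [c for c in kids if max_coord[c] >= border]
            if reaching:
                stack.extend(reaching)
                for c in kids:
                    if c not in reaching:
                        _label_subtree(morph, c, "oblique", labels)
            else:
                # truncated trunk that never reaches SLM: follow the longest
                # child so the principal path stays trunk
                main = max(kids, key=lambda c: (length[c] + morph.segment_length(c), -c))
                stack.append(main)
                for c in kids:
                    if c != main:
                        _label_subtree(morph, c, "oblique", labels)


def _classify_principal_path(morph, root, labels):
    ch = morph.children()
    length, _ = _subtree_stats(morph, [root], lambda n: 0.0, 1.0)

    def total(c):
        return length[c] + morph.segment_length(c)

    nid = root
    while True:
        kids = ch[nid]
        if not kids:
            labels[nid] = "trunk"  # unbranched path: trunk to the terminus
            return
        remaining = sum(total(c) for c in kids)
        big = [c for c in kids if remaining > 0 and total(c) >= PRINCIPAL_PATH_BRANCH_FRACTION * remaining]
        if len(kids) >= 2 and len(big) >= 2:
            # tuft-start bifurcation: everything distal is tuft
            labels[nid] = "trunk"
            for c in kids:
                _label_subtree(morph, c, "tuft", labels)
            return
        labels[nid] = "trunk"
        main = max(kids, key=lambda c: (total(c), -c))
        for c in kids:
            if c != main:
                _label_subtree(morph, c, "oblique", labels)
        nid = main


def soma_depth_fraction(morph: Morphology, layers: LayerAnnotation) -> float:
    """Radial soma position as a fraction of the SO-side -> SLM-side span.

    0 at the SO|SP border, 1 at the SR|SLM border, linear in between;
    somata outside the annotated span clamp to [0, 1] with a warning.
    """
    soma = morph.soma_centroid()
    axis_index = {"x": 0, "y": 1, "z": 2}[layers.axis]
    frac = (soma[axis_index] - layers.so_sp) / (layers.sr_slm - layers.so_sp)
    if frac < 0.0 or frac > 1.0:
        warnings.warn(
            f"soma lies outside the annotated laminar span (fraction {frac:.3f}); clamped",
            UserWarning, stacklevel=2,
        )
        frac = min(max(frac, 0.0), 1.0)
    return float(frac)
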