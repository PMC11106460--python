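"""Reading, validating and writing SWC neuron morphologies.

The SWC dialect used throughout the package: seven whitespace-separated
columns ``id type x y z radius parent``, 1-based node ids, root parent −1,
``#`` comment lines, coordinates and radii in micrometres.  Structure classes
follow the standard convention (1 soma, 2 axon, 3 basal dendrite,
4 apical dendrite).  Radii are carried through I/O but no downstream feature
depends on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
DENDRITIC_CLASSES = (BASAL, APICAL)

COMPARTMENT_LABELS = ("soma", "axon", "basal", "trunk", "oblique", "tuft")


class SWCError(ValueError):
    """Base class for SWC reading/validation failures."""


class SWCParseError(SWCError):
    """Malformed SWC line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class SWCStructureError(SWCError):
    """Topologically invalid morphology (orphans, cycles, multiple roots)."""


@dataclass
class MorphNode:
    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 marks the root

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Morphology:
    """A rooted tree of 3-D points with SWC structure classes.

    Exactly one connected component rooted at a soma node; node ids unique;
    every non-root parent reference resolves.  ``metadata`` holds free-form
    annotations (case id, species tag); comment lines encountered while
    reading are preserved in ``comments``.
    """

    nodes: list[MorphNode]
    metadata: dict = field(default_factory=dict)
    comments: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[int, MorphNode] = {}
        self._children: dict[int, list[int]] | None = None
        for n in self.nodes:
            if n.id in self._index:
                raise SWCStructureError(f"duplicate node id {n.id}")
            self._index[n.id] = n

    # -- accessors ---------------------------------------------------------
    def node(self, node_id: int) -> MorphNode:
        return self._index[node_id]

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._index

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self) -> dict[int, list[int]]:
        """Map of node id -> child ids, in node order (cached)."""
        if self._children is None:
            ch: dict[int, list[int]] = {n.id: [] for n in self.nodes}
            for n in self.nodes:
                if n.parent_id != -1:
                    ch[n.parent_id].append(n.id)
            self._children = ch
        return self._children

    def root(self) -> MorphNode:
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def soma_nodes(self) -> list[MorphNode]:
        return [n for n in self.nodes if n.structure == SOMA]

    def soma_centroid(self) -> np.ndarray:
        """Single soma anchor; multi-point soma contours collapse to centroid."""
        soma = self.soma_nodes()
        if not soma:
            raise SWCStructureError("morphology has no soma node")
        return np.mean([[n.x, n.y, n.z] for n in soma], axis=0)

    def segment_length(self, node_id: int) -> float:
        """Euclidean length of the parent->node segment (0 for the root)."""
        n = self._index[node_id]
        if n.parent_id == -1:
            return 0.0
        p = self._index[n.parent_id]
        return math.dist(n.xyz, p.xyz)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        root = self.root()
        if root.structure != SOMA:
            raise SWCStructureError(
                f"root node {root.id} has structure class {root.structure}, expected soma (1)"
            )
        for n in self.nodes:
            if n.radius < 0:
                raise SWCStructureError(f"node {n.id} has negative radius")
            if n.parent_id != -1 and n.parent_id not in self._index:
                raise SWCStructureError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
        # reachability from root doubles as the acyclicity check
        seen = {root.id}
        stack = [root.id]
        ch = self.children()
        while stack:
            for c in ch[stack.pop()]:
                if c in seen:
                    raise SWCStructureError(f"cycle detected at node {c}")
                seen.add(c)
                stack.append(c)
        if len(seen) != len(self.nodes):
            missing = sorted(set(self._index) - seen)
            raise SWCStructureError(
                f"{len(missing)} node(s) not reachable from root, e.g. id {missing[0]}"
            )

    def topological_order(self) -> list[MorphNode]:
        """Nodes ordered parent-before-child (stable within siblings)."""
        ch = self.children()
        order: list[MorphNode] = []
        stack = [self.root().id]
        while stack:
            nid = stack.pop()
            order.append(self._index[nid])
            stack.extend(reversed(ch[nid]))
        return order


@dataclass
class LayerAnnotation:
    """Radial laminar border positions (μm) along one coordinate axis.

    Borders must be strictly ordered going from stratum oriens toward
    stratum lacunosum-moleculare.  ``axis`` names the radial coordinate
    ('x', 'y' or 'z'); the optional ``dg_apex`` is a transverse reference.
    """

    so_sp: float
    sp_sr: float
    sr_slm: float
    axis: str = "y"
    dg_apex: float | None = None

    def __post_init__(self):
        span = self.sr_slm - self.so_sp
        if span == 0:
            raise ValueError("layer borders must be distinct")
        sign = 1.0 if span > 0 else -1.0
        if not (sign * self.so_sp < sign * self.sp_sr < sign * self.sr_slm):
            raise ValueError(
                "layer borders must be strictly ordered SO|SP < SP|SR < SR|SLM along the radial axis"
            )

    @property
    def orientation(self) -> float:
        """+1 if SLM lies at larger coordinate than SO, else −1."""
        return 1.0 if self.sr_slm > self.so_sp else -1.0

    def coord(self, node: MorphNode) -> float:
        return getattr(node, self.axis)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Read a standard 7-column SWC file into a validated :class:`Morphology`."""
    path = Path(path)
    nodes: list[MorphNode] = []
    comments: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"expected 7 whitespace-separated columns, got {len(parts)}", lineno
                )
            try:
                nid = int(parts[0])
                struct = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), lineno) from None
            if nid <= 0:
                raise SWCParseError(f"node id must be positive, got {nid}", lineno)
            nodes.append(MorphNode(nid, struct, x, y, z, radius, parent))
    morph = Morphology(nodes, metadata={"source": str(path)}, comments=comments)
    morph.validate()
    return morph


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as standard SWC, parent-before-child node order."""
    morph.validate()
    path = Path(path)
    with open(path, "w") as fh:
        for c in morph.comments:
            fh.write(c + "\n")
        for n in morph.topological_order():
            fh.write(
                f"{n.id} {n.structure} {n.x:.3f} {n.y:.3f} {n.z:.3f} "
                f"{n.radius:.3f} {n.parent_id}\n"
            )


def read_label_sidecar(path: str | Path) -> dict[int, str]:
    """Read the two-column ``node_id<TAB>label`` compartment-label sidecar."""
    labels: dict[int, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SWCParseError("expected 'node_id<TAB>label'", lineno)
            label = parts[1].strip()
            if label not in COMPARTMENT_LABELS:
                raise SWCParseError(f"unknown compartment label {label!r}", lineno)
            labels[int(parts[0])] = label
    return labels


def write_label_sidecar(labels: dict[int, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for nid in sorted(labels):
            fh.write(f"{nid}\t{labels[nid]}\n")


def read_layers(path: str | Path) -> LayerAnnotation:
    """Read a key-value layer annotation file (``SO|SP: -70.6`` style)."""
    values: dict[str, float] = {}
    axis = "y"
    dg = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            key = key.strip()
            if key == "axis":
                axis = val.strip()
            elif key == "DG_apex":
                dg = float(val)
            else:
                values[key] = float(val)
    try:
        return LayerAnnotation(
            so_sp=values["SO|SP"], sp_sr=values["SP|SR"], sr_slm=values["SR|SLM"],
            axis=axis, dg_apex=dg,
        )
    except KeyError as exc:
        raise SWCError(f"layer annotation missing border {exc}") from None


def write_layers(layers: LayerAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"axis: {layers.axis}\n")
        fh.write(f"SO|SP: {layers.so_sp:.3f}\n")
        fh.write(f"SP|SR: {layers.sp_sr:.3f}\n")
        fh.write(f"SR|SLM: {layers.sr_slm:.3f}\n")
        if layers.dg_apex is not None:
            fh.write(f"DG_apex: {layers.dg_apex:.3f}\n")
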