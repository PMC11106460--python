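"""Synthetic SWC morphology generator with exact ground-truth features.

Trees are grown by segment accretion with fixed 10 μm segments in 3-D
coordinates (branch angles are cosmetic; every feature the package measures
is length- or topology-based).  The generator emits, per cell:

* a valid :class:`~ca1pyr.swc.Morphology`,
* the compartment-label sidecar (ground truth, consistent with the
  layer-based trunk definition of :mod:`ca1pyr.compartments`),
* a :class:`~ca1pyr.swc.LayerAnnotation`, and
* the exact :class:`~ca1pyr.morphometrics.MorphFeatures` ground truth,
  computed from the generator's own bookkeeping of what it built.

Layout: the soma sits at the origin; basal trees fan downward (−y); the
main apical trunk ascends +y, optionally with "early" trunk bifurcations
within the first 200 μm of path distance (each adds one main apical tree);
oblique side trees grow laterally in the x–z plane (constant y, so they
never reach the SR|SLM border); each main trunk crosses the border and
ends in a tuft subtree.  Coordinates are rounded to 0.001 μm at build time
so SWC round trips are exact.

The default configuration is calibrated to the human CA1 population
statistics the study conditions require: TDL ~ Normal(18.6, 3.9) mm,
median 7 basal stems, median 20 oblique trees with ~0.9 bifurcations per
tree, ~5 bifurcations per basal tree, and 0–3 early trunk bifurcations
(uniform).  A mouse preset provides deterministic compartment lengths
(TDL 3.32 mm) and counts (5 basal + 11 obliques + 1 apical tree, m = 17).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .morphometrics import MorphFeatures
from .swc import APICAL, BASAL, SOMA, LayerAnnotation, MorphNode, Morphology

SEGMENT_UM = 10.0


# ---------------------------------------------------------------------------
# samplable count/length distributions (config-file friendly)
# ---------------------------------------------------------------------------

@dataclass
class Constant:
    value: float

    def sample(self, rng):
        return self.value


@dataclass
class RoundedNormal:
    mean: float
    sd: float
    lo: float = 0.0

    def sample(self, rng):
        return max(int(round(rng.normal(self.mean, self.sd))), int(self.lo))


@dataclass
class Normal:
    mean: float
    sd: float
    lo: float = 0.0

    def sample(self, rng):
        return max(float(rng.normal(self.mean, self.sd)), self.lo)


@dataclass
class RoundedLogNormal:
    """Round(exp(Normal(log median, sigma))), clipped below at ``lo``."""

    median: float
    sigma: float
    lo: float = 0.0

    def sample(self, rng):
        return max(int(round(math.exp(rng.normal(math.log(self.median), self.sigma)))),
                   int(self.lo))


@dataclass
class Choice:
    values: tuple
    probs: tuple | None = None

    def sample(self, rng):
        return rng.choice(self.values, p=self.probs)


_DIST_KINDS = {
    "constant": Constant, "rounded_normal": RoundedNormal, "normal": Normal,
    "rounded_lognormal": RoundedLogNormal, "choice": Choice,
}


def dist_from_dict(d):
    if isinstance(d, (int, float)):
        return Constant(d)
    d = dict(d)
    kind = d.pop("kind")
    return _DIST_KINDS[kind](**d)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MorphGenConfig:
    n_basal_trees: object = field(default_factory=lambda: RoundedNormal(7.0, 1.8, lo=3))
    n_oblique_trees: object = field(default_factory=lambda: RoundedLogNormal(20.0, 0.21, lo=8))
    basal_bifs_per_tree: object = field(default_factory=lambda: RoundedNormal(5.0, 1.5, lo=1))
    oblique_bifs_per_tree: object = field(
        default_factory=lambda: Choice((0, 1, 2), (0.3, 0.5, 0.2)))
    tuft_bifs_per_tree: object = field(default_factory=lambda: RoundedNormal(8.0, 2.0, lo=2))
    n_early_bifurcations: object = field(default_factory=lambda: Choice((0, 1, 2, 3)))
    tdl_total_um: object = field(default_factory=lambda: Normal(18600.0, 3900.0, lo=8000.0))
    frac_basal: float = 0.40
    frac_oblique: float = 0.38
    border_um: float = 400.0          # SR|SLM border height above the soma
    soma_depth_fraction: float = 0.15  # radial soma position within SO|SP..SR|SLM
    soma_radius_um: float = 10.0
    species: str = "human"

    def sample_counts(self, rng):
        return {
            "n_basal": int(self.n_basal_trees.sample(rng)),
            "n_oblique": int(self.n_oblique_trees.sample(rng)),
            "n_early": int(self.n_early_bifurcations.sample(rng)),
            "tdl": float(self.tdl_total_um.sample(rng)),
        }


def human_config() -> MorphGenConfig:
    """Defaults calibrated to the human CA1 population statistics."""
    return MorphGenConfig()


def mouse_config() -> MorphGenConfig:
    """Deterministic mouse preset: 5 basal + 11 oblique trees, one apical
    tree, TDL 3.32 mm (basal 1.20, oblique 1.10, trunk 0.30, tuft 0.72 mm)."""
    return MorphGenConfig(
        n_basal_trees=Constant(5),
        n_oblique_trees=Constant(11),
        basal_bifs_per_tree=Constant(4),
        oblique_bifs_per_tree=Choice((0, 1), (0.6, 0.4)),
        tuft_bifs_per_tree=Constant(4),
        n_early_bifurcations=Constant(0),
        tdl_total_um=Constant(3320.0),
        frac_basal=1200.0 / 3320.0,
        frac_oblique=1100.0 / 3320.0,
        border_um=300.0,
        species="mouse",
    )


@dataclass
class GeneratedCell:
    morphology: Morphology
    labels: dict[int, str]          # ground-truth sidecar
    layers: LayerAnnotation
    truth: MorphFeatures
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tree building machinery
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self):
        self.nodes: list[MorphNode] = []
        self.labels: dict[int, str] = {}

    def add(self, structure, xyz, parent_id, label, radius=1.0) -> int:
        nid = len(self.nodes) + 1
        x, y, z = (round(float(c), 3) for c in xyz)
        self.nodes.append(MorphNode(nid, structure, x, y, z, radius, parent_id))
        self.labels[nid] = label
        return nid

    def pos(self, nid) -> np.ndarray:
        n = self.nodes[nid - 1]
        return np.array([n.x, n.y, n.z])


def _rot(direction: np.ndarray, angle_rad: float, plane: str) -> np.ndarray:
    """Rotate a unit direction within the x–y or x–z plane."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    x, y, z = direction
    if plane == "xy":
        return np.array([c * x - s * y, s * x + c * y, z])
    return np.array([c * x - s * z, y, s * x + c * z])


def _split_segments(rng, n_segs: int, n_branches: int) -> list[int]:
    """Distribute ``n_segs`` whole segments over branches, each >= 1."""
    if n_segs < n_branches:
        raise ValueError("not enough segments for the requested branches")
    extra = n_segs - n_branches
    alloc = np.ones(n_branches, dtype=int)
    if extra > 0:
        bins = rng.integers(0, n_branches, size=extra)
        np.add.at(alloc, bins, 1)
    return alloc.tolist()


def _grow_branch(b: _Builder, rng, attach: int, direction, n_segs, structure, label,
                 plane: str) -> int:
    pos = b.pos(attach)
    nid = attach
    for _ in range(n_segs):
        pos = pos + np.asarray(direction) * SEGMENT_UM
        nid = b.add(structure, pos, nid, label)
    return nid


def _build_subtree(b: _Builder, rng, attach: int, direction, n_bifs: int,
                   n_segs: int, structure, label, plane: str,
                   angle_rad: float = 0.55) -> tuple[int, int]:
    """Grow a binary subtree with ``n_bifs`` bifurcations and exactly
    ``n_segs`` 10 μm segments.  Returns (n_bifurcations_built, n_tips)."""
    n_branches = 2 * n_bifs + 1
    if n_segs < n_branches:       # infeasible branching for the length budget
        n_bifs = max((n_segs - 1) // 2, 0)
        n_branches = 2 * n_bifs + 1

    def rec(attach, direction, bifs, segs):
        branches = 2 * bifs + 1
        if bifs == 0:
            _grow_branch(b, rng, attach, direction, segs, structure, label, plane)
            return 1  # one tip
        stem = max(segs - (branches - 1), 1)
        stem = min(stem, max(int(round(segs / branches)), 1))
        end = _grow_branch(b, rng, attach, direction, stem, structure, label, plane)
        rest = segs - stem
        b1 = int(rng.integers(0, bifs))
        b2 = bifs - 1 - b1
        br1, br2 = 2 * b1 + 1, 2 * b2 + 1
        s1 = int(round(rest * br1 / (br1 + br2)))
        s1 = min(max(s1, br1), rest - br2)
        s2 = rest - s1
        a = angle_rad * (0.8 + 0.4 * rng.random())
        tips = rec(end, _rot(direction, +a, plane), b1, s1)
        tips += rec(end, _rot(direction, -a, plane), b2, s2)
        return tips

    tips = rec(attach, np.asarray(direction, float), n_bifs, n_segs)
    return n_bifs, tips


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_morphology(config: MorphGenConfig, seed=None,
                        rng: np.random.Generator | None = None) -> GeneratedCell:
    """Grow one synthetic CA1-like pyramidal cell (see module docstring)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = config.sample_counts(rng)
    n_basal, n_oblique = counts["n_basal"], counts["n_oblique"]
    n_early, tdl_target = counts["n_early"], counts["tdl"]
    border = config.border_um
    if border <= 0:
        raise ValueError("SR|SLM border must lie above the soma")

    b = _Builder()
    soma = b.add(SOMA, (0.0, 0.0, 0.0), -1, "soma", radius=config.soma_radius_um)

    # ---- length budget (whole 10 μm segments) ----------------------------
    basal_segs_total = int(round(tdl_target * config.frac_basal / SEGMENT_UM))
    oblique_segs_total = int(round(tdl_target * config.frac_oblique / SEGMENT_UM))

    # ---- basal trees ------------------------------------------------------
    basal_bifs_built, basal_tips = [], 0
    per_tree = _split_segments(rng, max(basal_segs_total, n_basal * 3), n_basal)
    for j in range(n_basal):
        alpha = math.pi + (j + 0.5) / n_basal * math.pi - math.pi / 2.0
        direction = np.array([math.sin(alpha), -abs(math.cos(alpha)) - 0.3, 0.0])
        direction /= np.linalg.norm(direction)
        bifs = int(config.basal_bifs_per_tree.sample(rng))
        built, tips = _build_subtree(b, rng, soma, direction, bifs, per_tree[j],
                                     BASAL, "basal", "xy")
        basal_bifs_built.append(built)
        basal_tips += tips

    # ---- apical trunk(s) with early bifurcations --------------------------
    main_path_segs = int(math.ceil(border / SEGMENT_UM)) + 1  # first node >= border is tuft
    early_seg_idx = [5 + 5 * k for k in range(n_early)]       # path distances 50/100/150 μm
    if n_early and early_seg_idx[-1] >= main_path_segs - 2:
        raise ValueError("early bifurcations do not fit below the SR|SLM border")

    trunk_nodes_below: list[int] = []   # oblique attachment candidates
    tuft_roots: list[int] = []          # first trunk-path node at/beyond border
    trunk_segs = 0

    def grow_trunk_path(attach: int, direction: np.ndarray, spawn_at: dict[int, float]):
        """March a trunk path upward until crossing the border; spawn side
        trunks at the given segment indices (slant angles)."""
        nonlocal trunk_segs
        pos = b.pos(attach)
        nid = attach
        step = 0
        while True:
            pos = pos + direction * SEGMENT_UM
            nid = b.add(APICAL, pos, nid, "trunk")
            trunk_segs += 1
            step += 1
            if pos[1] >= border:
                b.labels[nid] = "tuft"   # crossed: this node starts the tuft
                tuft_roots.append(nid)
                return
            trunk_nodes_below.append(nid)
            if step in spawn_at:
                ang = spawn_at[step]
                grow_trunk_path(nid, _rot(direction, ang, "xy"), {})

    spawn = {idx: (0.35 if k % 2 == 0 else -0.35) for k, idx in enumerate(early_seg_idx)}
    grow_trunk_path(soma, np.array([0.0, 1.0, 0.0]), spawn)
    assert len(tuft_roots) == n_early + 1

    # ---- obliques ---------------------------------------------------------
    candidates = [nid for nid in trunk_nodes_below
                  if 20.0 <= b.pos(nid)[1] <= border - 20.0]
    if len(candidates) * 2 < n_oblique:
        raise ValueError("trunk too short for the requested number of obliques")
    picks = list(rng.choice(candidates, size=n_oblique, replace=False)) \
        if len(candidates) >= n_oblique else \
        list(candidates) + list(rng.choice(candidates, size=n_oblique - len(candidates)))
    oblique_bifs_built, oblique_tips = [], 0
    per_obl = _split_segments(rng, max(oblique_segs_total, n_oblique * 3), n_oblique)
    for j, attach in enumerate(picks):
        side = 1.0 if j % 2 == 0 else -1.0
        direction = np.array([side, 0.0, 0.3 * (rng.random() - 0.5)])
        direction /= np.linalg.norm(direction)
        bifs = int(config.oblique_bifs_per_tree.sample(rng))
        built, tips = _build_subtree(b, rng, int(attach), direction, bifs,
                                     per_obl[j], APICAL, "oblique", "xz")
        oblique_bifs_built.append(built)
        oblique_tips += tips

    # ---- tufts ------------------------------------------------------------
    # trunk_segs already includes the border-crossing segments (tuft roots)
    used = basal_segs_total + oblique_segs_total + trunk_segs
    tuft_segs_total = max(int(round(tdl_target / SEGMENT_UM)) - used,
                          len(tuft_roots) * 3)
    tuft_bifs_built, tuft_tips = [], 0
    per_tuft = _split_segments(rng, max(tuft_segs_total, len(tuft_roots)),
                               len(tuft_roots))
    for j, root in enumerate(tuft_roots):
        bifs = int(config.tuft_bifs_per_tree.sample(rng))
        built, tips = _build_subtree(b, rng, root, np.array([0.0, 1.0, 0.0]), bifs,
                                     per_tuft[j], APICAL, "tuft", "xy",
                                     angle_rad=0.45)
        tuft_bifs_built.append(built)
        tuft_tips += tips

    # ---- assemble + layer annotation --------------------------------------
    morph = Morphology(b.nodes, metadata={"species": config.species,
                                          "generator": "ca1pyr.morphgen"})
    morph.validate()
    f = config.soma_depth_fraction
    so_sp = round(-f * border / (1.0 - f), 3)
    sp_sr = round(so_sp + 0.3 * (border - so_sp), 3)
    layers = LayerAnnotation(so_sp=so_sp, sp_sr=sp_sr, sr_slm=border, axis="y")
    truth_depth = (0.0 - so_sp) / (border - so_sp)  # soma sits at the origin

    # ---- exact ground truth from builder bookkeeping ----------------------
    sums = {"basal": 0.0, "oblique": 0.0, "trunk": 0.0, "tuft": 0.0}
    for n in b.nodes:
        if n.parent_id == -1:
            continue
        lab = b.labels[n.id]
        if lab in sums:
            sums[lab] += morph.segment_length(n.id)
    mean = lambda xs: float(sum(xs)) / len(xs) if xs else 0.0
    truth = MorphFeatures(
        tdl_total=sum(sums.values()) / 1000.0,
        tdl_basal=sums["basal"] / 1000.0,
        tdl_oblique=sums["oblique"] / 1000.0,
        tdl_apical_trunk_tuft=(sums["trunk"] + sums["tuft"]) / 1000.0,
        n_basal_trees=float(n_basal),
        n_oblique_trees=float(n_oblique),
        nodes_per_tree_basal=mean(basal_bifs_built),
        nodes_per_tree_oblique=mean(oblique_bifs_built),
        n_early_bifurcations=float(n_early),
        # every oblique attachment and every early trunk split is a branch
        # point of the dendritic tree, on top of the within-tree bifurcations
        n_total_bifurcations=float(sum(basal_bifs_built) + sum(oblique_bifs_built)
                                   + sum(tuft_bifs_built) + n_early + n_oblique),
        n_terminal_branches=float(basal_tips + oblique_tips + tuft_tips),
        soma_depth_fraction=truth_depth,
    )
    truth.validate()
    return GeneratedCell(morphology=morph, labels=b.labels, layers=layers,
                         truth=truth,
                         meta={"tdl_target_um": tdl_target, "n_early": n_early})


def generate_cohort(config: MorphGenConfig, n_cells: int, seed=0) -> list[GeneratedCell]:
    """Generate ``n_cells`` independent cells from one seeded stream."""
    root = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        cells.append(generate_morphology(config, rng=np.random.default_rng(
            int(root.integers(0, 2**31 - 1)))))
    return cells
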