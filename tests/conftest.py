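"""Shared fixtures: hand-built morphologies and small generator configs."""

import numpy as np
import pytest

from ca1pyr.morphgen import Choice, Constant, MorphGenConfig, Normal, RoundedNormal
from ca1pyr.swc import APICAL, BASAL, SOMA, LayerAnnotation, MorphNode, Morphology


def build_morph(rows):
    """rows: (id, structure, x, y, z, parent) with radius 1."""
    return Morphology([MorphNode(i, s, float(x), float(y), float(z), 1.0, p)
                       for i, s, x, y, z, p in rows])


@pytest.fixture
def chain_morph():
    """Soma + three collinear 10 μm basal segments (TDL = 30 μm)."""
    return build_morph([
        (1, SOMA, 0, 0, 0, -1),
        (2, BASAL, 0, -10, 0, 1),
        (3, BASAL, 0, -20, 0, 2),
        (4, BASAL, 0, -30, 0, 3),
    ])


@pytest.fixture
def labeled_tree():
    """Hand-built cell: basal 100 μm, one 50 μm oblique, 80 μm trunk.

    The trunk never reaches the SR|SLM border (truncated cell), so the
    classifier's longest-child fallback keeps the main path trunk.
    """
    rows = [(1, SOMA, 0, 0, 0, -1)]
    # basal chain: 10 segments of 10 μm
    for j in range(10):
        rows.append((2 + j, BASAL, 0, -10 * (j + 1), 0, 1 + j))
    # trunk: 8 segments up
    base = 12
    rows.append((base, APICAL, 0, 10, 0, 1))
    for j in range(1, 8):
        rows.append((base + j, APICAL, 0, 10 * (j + 1), 0, base + j - 1))
    # oblique: 5 segments sideways from the trunk node at y = 20 (proximal,
    # so the remaining trunk path is longer than the side branch)
    ob = base + 8
    attach = base + 1
    rows.append((ob, APICAL, 10, 20, 0, attach))
    for j in range(1, 5):
        rows.append((ob + j, APICAL, 10 * (j + 1), 20, 0, ob + j - 1))
    return build_morph(rows)


@pytest.fixture
def census_tree():
    """2 basal stems (one with 1 bifurcation) + 3 unbranched obliques.

    Expected census: (2, 3, 0.5, 0.0).
    """
    rows = [(1, SOMA, 0, 0, 0, -1)]
    nid = 2
    # basal stem A: straight chain of 3
    rows += [(2, BASAL, 0, -10, 0, 1), (3, BASAL, 0, -20, 0, 2),
             (4, BASAL, 0, -30, 0, 3)]
    # basal stem B: stem then a bifurcation
    rows += [(5, BASAL, 10, -10, 0, 1), (6, BASAL, 20, -20, 0, 5),
             (7, BASAL, 30, -30, 0, 6), (8, BASAL, 10, -30, 0, 6)]
    # trunk to the border at y = 100 and a bit beyond (tuft)
    trunk = []
    parent = 1
    for j in range(12):
        rows.append((9 + j, APICAL, 0, 10 * (j + 1), 0, parent))
        parent = 9 + j
        trunk.append(parent)
    # obliques at y = 30, 50, 70 (trunk nodes 11, 13, 15), unbranched
    nid = 21
    for attach in (11, 13, 15):
        rows.append((nid, APICAL, 15, (attach - 8) * 10, 0, attach))
        rows.append((nid + 1, APICAL, 30, (attach - 8) * 10, 0, nid))
        nid += 2
    return build_morph(rows)


@pytest.fixture
def census_layers():
    return LayerAnnotation(so_sp=-50.0, sp_sr=5.0, sr_slm=100.0, axis="y")


def small_human_config(**overrides):
    """Down-scaled human-like generator config for fast population tests."""
    defaults = dict(
        tdl_total_um=Normal(3000.0, 400.0, lo=2000.0),
        basal_bifs_per_tree=RoundedNormal(3.0, 1.0, lo=1),
        tuft_bifs_per_tree=Constant(3),
        border_um=250.0,
    )
    defaults.update(overrides)
    return MorphGenConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
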