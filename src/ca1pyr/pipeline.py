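"""End-to-end orchestration: synthesize -> features -> capacity -> cluster.

Library-level entry points used by the command-line interface (and by the
examples).  Each step is deterministic given its configuration and seed,
reads/writes the plain-text formats defined by the I/O modules, and
returns the in-memory objects so it can be scripted directly.

On disk a synthesized cohort looks like::

    out/
      manifest.json                  # config hash, seeds, per-file checksums
      cell_000/
        cell_000.swc                 # morphology
        cell_000.labels.tsv          # ground-truth compartment sidecar
        cell_000.layers.txt          # laminar border annotation
        cell_000_steps.csv/.json     # step-protocol sweep family
        cell_000_chirp.csv/.json     # chirp sweep
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import capacity as cap
from . import diversity as div
from .compartments import classify_compartments
from .ephys import extract_ephys_features
from .membrane import (
    APTemplate, MembraneParams, calibrate_h_conductance, inject_ap_templates,
    simulate_chirp, simulate_membrane, simulate_step_family,
)
from .morphgen import GeneratedCell, generate_morphology, human_config, mouse_config
from .morphometrics import MORPH_FEATURE_NAMES, morph_feature_vector
from .swc import read_label_sidecar, read_layers, read_swc, write_label_sidecar, write_layers, write_swc
from .sweeps import SweepSet, read_sweepset, step_current, write_sweepset
from .tables import FeatureGenConfig, generate_feature_table

log = logging.getLogger("ca1pyr")


class MissingParameterError(ValueError):
    """A required scientific parameter (e.g. spine densities) is absent."""


@dataclass
class RunConfig:
    out_dir: str = "ca1pyr_run"
    seed: int = 0
    n_cells: int = 35
    species: str = "human"
    fs_hz: float = 20000.0
    noise_sd_mv: float = 0.1
    chirp_f1_hz: float = 30.0
    chirp_dur_s: float = 10.0
    capacity_mode: str = "conservative"
    spine_densities: dict | None = None
    n_branches: int = 3
    gap_k_max: int = 10
    gap_n_refs: int = 2000
    tsne_perplexity: float = 10.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# synthesize
# ---------------------------------------------------------------------------

def _cell_membrane_params(rng: np.random.Generator, noise_sd: float) -> MembraneParams:
    """Per-cell subthreshold parameters scattered around the population
    medians (Rin ~ 38 MΩ, tau ~ 22 ms, F_res ~ 2.9 Hz)."""
    r_mohm = math.exp(rng.normal(math.log(38.0), 0.20))
    tau_ms = math.exp(rng.normal(math.log(21.7), 0.18))
    f_res = math.exp(rng.normal(math.log(2.9), 0.12))
    g_l = 1000.0 / r_mohm
    base = MembraneParams(c_pf=tau_ms * g_l, g_l_ns=g_l, g_h_ns=0.0,
                          tau_h_ms=50.0, noise_sd_mv=noise_sd,
                          seed=int(rng.integers(0, 2**31 - 1)))
    return calibrate_h_conductance(f_res, base)


def _synthesize_cell_sweeps(rng: np.random.Generator, params: MembraneParams,
                            fs_hz: float, f1_hz: float, dur_s: float):
    """Step family (hyperpolarizing + depolarizing up to rheobase) and chirp."""
    hyper = simulate_step_family(params, np.arange(-150.0, 0.0, 25.0), fs_hz=fs_hz)

    rheobase = float(np.clip(round(rng.normal(300.0, 75.0) / 25.0) * 25.0, 50.0, 1000.0))
    template = APTemplate(peak_mv=float(rng.normal(35.0, 5.0)),
                          rise_w_ms=float(rng.uniform(0.35, 0.55)),
                          fall_w_ms=float(rng.uniform(0.7, 1.1)))
    depol = []
    for amp in np.arange(25.0, rheobase + 1.0, 25.0):
        t, i, onset, offset = step_current(amp, fs_hz)
        p = dataclasses.replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        sweep = simulate_membrane(p, t, i, onset, offset, "step", fs_hz)
        if amp >= rheobase:
            times = [onset + float(rng.uniform(0.05, 0.3))]
            if rng.random() < 0.4:
                times.append(times[0] + float(rng.uniform(0.1, 0.3)))
            sweep, _ = inject_ap_templates(sweep, template, times)
        depol.append(sweep)
    steps = SweepSet(hyper.sweeps + depol)
    chirp = simulate_chirp(params, f1_hz=f1_hz, dur_s=dur_s, fs_hz=fs_hz)
    return steps, chirp


def cmd_synthesize(config: RunConfig) -> Path:
    """Generate the synthetic cohort (SWC + sidecars + sweeps) and manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    morph_cfg = mouse_config() if config.species == "mouse" else human_config()
    files: dict[str, str] = {}
    for j in range(config.n_cells):
        cell_id = f"cell_{j:03d}"
        cdir = out / cell_id
        cdir.mkdir(exist_ok=True)
        cell: GeneratedCell = generate_morphology(
            morph_cfg, rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
        write_swc(cell.morphology, cdir / f"{cell_id}.swc")
        write_label_sidecar(cell.labels, cdir / f"{cell_id}.labels.tsv")
        write_layers(cell.layers, cdir / f"{cell_id}.layers.txt")

        params = _cell_membrane_params(rng, config.noise_sd_mv)
        steps, chirp = _synthesize_cell_sweeps(rng, params, config.fs_hz,
                                               config.chirp_f1_hz, config.chirp_dur_s)
        write_sweepset(steps, cdir / f"{cell_id}_steps.csv")
        write_sweepset(SweepSet([chirp]), cdir / f"{cell_id}_chirp.csv")
        for p in sorted(cdir.iterdir()):
            files[str(p.relative_to(out))] = _sha256(p)
        log.info("synthesized %s (%d nodes)", cell_id, len(cell.morphology))
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "n_cells": config.n_cells, "species": config.species,
                "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def cmd_features(config: RunConfig) -> div.FeatureTable:
    """Extract morphological + electrophysiological features for a cohort.

    Cells failing extraction are dropped with a logged reason; the run only
    fails if no cell could be processed.  Writes ``morph_features.csv``,
    ``ephys_features.csv`` and the joined ``features22.csv``.
    """
    out = Path(config.out_dir)
    cell_dirs = sorted(d for d in out.iterdir() if d.is_dir() and d.name.startswith("cell_"))
    if not cell_dirs:
        raise FileNotFoundError(f"no cell directories under {out}")
    morph_rows, ephys_rows, failures = {}, {}, {}
    for cdir in cell_dirs:
        cid = cdir.name
        try:
            morph = read_swc(cdir / f"{cid}.swc")
            layers = read_layers(cdir / f"{cid}.layers.txt")
            labeling = classify_compartments(morph, layers)
            morph_rows[cid] = morph_feature_vector(morph, labeling, layers).as_dict()
            steps = read_sweepset(cdir / f"{cid}_steps.csv")
            chirp = read_sweepset(cdir / f"{cid}_chirp.csv").sweeps[0]
            ephys_rows[cid] = extract_ephys_features(steps, chirp)
        except Exception as exc:  # per-cell failures never abort the cohort
            failures[cid] = f"{type(exc).__name__}: {exc}"
            log.warning("cell %s failed: %s", cid, failures[cid])
    if not morph_rows:
        raise RuntimeError(f"feature extraction failed for every cell: {failures}")
    morph_df = pd.DataFrame.from_dict(morph_rows, orient="index")
    ephys_df = pd.DataFrame.from_dict(ephys_rows, orient="index")
    morph_df.to_csv(out / "morph_features.csv", index_label="cell_id")
    ephys_df.to_csv(out / "ephys_features.csv", index_label="cell_id")
    table = div.assemble_feature_table(morph_df, ephys_df)
    table.data.to_csv(out / "features22.csv", index_label="cell_id")
    if failures:
        with open(out / "feature_failures.json", "w") as fh:
            json.dump(failures, fh, indent=1)
    return table


# ---------------------------------------------------------------------------
# capacity
# ---------------------------------------------------------------------------

def cmd_capacity(config: RunConfig, morph_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell memory capacity + population summary JSON.

    Spine densities are a mandatory scientific input for human runs; the
    ``mouse`` preset is built in.
    """
    out = Path(config.out_dir)
    if morph_df is None:
        morph_df = pd.read_csv(out / "morph_features.csv", index_col="cell_id")
    if config.spine_densities is not None:
        missing = {"basal", "oblique", "trunk", "tuft"} - set(config.spine_densities)
        if missing:
            raise MissingParameterError(
                f"spine density config missing class(es): {sorted(missing)}")
        dens = cap.SpineDensityConfig(**{k: config.spine_densities[k]
                                         for k in ("basal", "oblique", "trunk", "tuft")})
    elif config.species == "mouse":
        dens = cap.MOUSE_SPINE_DENSITY
    else:
        raise MissingParameterError(
            "spine densities must be configured for non-mouse cohorts "
            "(classes: basal, oblique, trunk, tuft)")
    rows = []
    from .morphometrics import MorphFeatures
    for cid, row in morph_df.iterrows():
        feats = MorphFeatures(**{k: row[k] for k in MORPH_FEATURE_NAMES})
        res = cap.cell_capacity(feats, dens, config.capacity_mode)
        record = {"cell_id": cid, "m": res.inputs.m, "s": res.inputs.s,
                  "d": res.inputs.d, "k": res.inputs.k, "bits": res.bits,
                  "mode": config.capacity_mode}
        if config.capacity_mode == "conservative":
            for name, frac in cap.removal_analysis(feats, dens,
                                                   config.capacity_mode).items():
                record[f"remaining_after_{name}_removal"] = frac
        rows.append(record)
    df = pd.DataFrame(rows).set_index("cell_id")
    df.to_csv(out / "capacity.csv")
    summary = cap.population_summary(df["bits"])
    summary["mode"] = config.capacity_mode
    removal_cols = [c for c in df.columns if c.startswith("remaining_after_")]
    for c in removal_cols:
        summary[c] = float(df[c].mean())
    with open(out / "capacity_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return df


# ---------------------------------------------------------------------------
# cluster / diversity
# ---------------------------------------------------------------------------

def cmd_cluster(config: RunConfig, table: div.FeatureTable | None = None) -> dict:
    """PC retention, hierarchical branches, gap statistic and branch stats."""
    out = Path(config.out_dir)
    if table is None:
        df = pd.read_csv(out / "features22.csv", index_col="cell_id")
        table = div.FeatureTable(df)
    if table.n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    pc = div.pca_retain(table)
    branches = div.hierarchical_cluster(pc.scores, n_branches=config.n_branches)
    gap = div.gap_statistic(pc.scores, k_max=min(config.gap_k_max, table.n_cells - 1),
                            n_refs=config.gap_n_refs, seed=config.seed)
    stats_report = div.group_stats(table, branches.branches, pc.dominant_features)
    embedding = None
    if table.n_cells >= 5 and config.tsne_perplexity < table.n_cells:
        embedding = div.embed_2d(pc.scores, seed=config.seed,
                                 perplexity=config.tsne_perplexity).tolist()
    report = {
        "n_cells": table.n_cells,
        "retained_pcs": pc.n_retained,
        "explained_variance": pc.explained_variance.tolist(),
        "normalized_coefficients": pc.coefficients.round(6).to_dict(),
        "dominant_features": pc.dominant_features,
        "branches": {cid: int(b) for cid, b in zip(table.data.index, branches.branches)},
        "estimated_k": gap.estimated_k,
        "gap_curve": gap.gap_curve.tolist(),
        "gap_k_grid": gap.k_grid.tolist(),
        "group_stats": stats_report,
        "tsne": embedding,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    with open(out / "cluster_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_all(config: RunConfig) -> dict:
    """synthesize -> features -> capacity (if densities available) -> cluster."""
    cmd_synthesize(config)
    table = cmd_features(config)
    if config.spine_densities is not None or config.species == "mouse":
        cmd_capacity(config)
    report = cmd_cluster(config, table)
    return report
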