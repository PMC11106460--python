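"""Synthetic morpho-electric feature tables with controlled covariance.

Draws cells × 22 feature tables from a single correlated multivariate
normal (optionally a mixture of such components), emulating a homogeneous
population whose single-parameter ranges span the 2- to 6-fold spread
seen across real cells.  Used to probe the diversity pipeline — e.g. the
gap statistic should report one cluster on a single-component draw and
recover the component count for well-separated mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import FEATURE_NAMES, FeatureTable

#: plausible population-scale feature centres (units as in the feature table)
DEFAULT_MEANS = {
    "tdl_total": 18.6, "tdl_basal": 7.4, "tdl_oblique": 7.1,
    "tdl_apical_trunk_tuft": 4.1, "n_basal_trees": 7.0, "n_oblique_trees": 20.0,
    "nodes_per_tree_basal": 5.0, "nodes_per_tree_oblique": 0.9,
    "n_early_bifurcations": 1.5, "n_total_bifurcations": 80.0,
    "n_terminal_branches": 90.0, "soma_depth_fraction": 0.2,
    "input_resistance": 38.0, "tau": 21.7, "sag_ratio": 0.23,
    "resonance_frequency": 2.9, "rheobase": 250.0, "ap_threshold": -45.0,
    "ap_amplitude": 80.0, "ap_halfwidth": 1.0, "ap_upstroke": 220.0,
    "ap_downstroke": -80.0,
}


@dataclass
class FeatureGenConfig:
    n_cells: int = 31
    means: np.ndarray = field(default_factory=lambda: np.array(
        [DEFAULT_MEANS[f] for f in FEATURE_NAMES]))
    cov: np.ndarray | None = None
    feature_names: tuple = FEATURE_NAMES
    mixture_means: list | None = None    # optional extra component centres
    mixture_weights: list | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.cov is None:
            self.cov = default_covariance(self.means)
        self.cov = np.asarray(self.cov, float)
        if self.cov.shape != (len(self.means), len(self.means)):
            raise ValueError("covariance shape does not match the feature count")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("covariance must be positive semidefinite")


def default_covariance(means: np.ndarray, cv: float = 0.22, rho: float = 0.35) -> np.ndarray:
    """Heterogeneous variances with moderate short-range correlations.

    Per-feature SD is ``cv``×|mean| (floored), which yields roughly 2- to
    6-fold min/max ranges across a cohort; the correlation structure is
    rho^|i−j| between features ordered as in the table.
    """
    means = np.asarray(means, float)
    sd = np.maximum(cv * np.abs(means), 0.05)
    p = len(means)
    idx = np.arange(p)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return corr * np.outer(sd, sd)


def generate_feature_table(config: FeatureGenConfig) -> FeatureTable:
    """Seeded draw of an n × 22 feature table (single component or mixture)."""
    rng = np.random.default_rng(config.seed)
    centres = [np.asarray(config.means, float)]
    weights = [1.0]
    if config.mixture_means:
        centres = [np.asarray(m, float) for m in config.mixture_means]
        weights = (list(config.mixture_weights) if config.mixture_weights
                   else [1.0 / len(centres)] * len(centres))
    weights = np.asarray(weights, float) / np.sum(weights)
    comp = rng.choice(len(centres), size=config.n_cells, p=weights)
    rows = np.empty((config.n_cells, len(config.means)))
    for j in range(config.n_cells):
        rows[j] = rng.multivariate_normal(centres[comp[j]], config.cov)
    df = pd.DataFrame(rows, columns=list(config.feature_names),
                      index=[f"cell_{j:03d}" for j in range(config.n_cells)])
    df.attrs["component"] = comp.tolist()
    return FeatureTable(df)
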