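"""Morpho-electric diversity analysis.

Assembles the 22-feature table (12 morphological/anatomical + 10
electrophysiological), reduces it by PCA keeping only components that
explain more than 5% of the variance, clusters the retained scores by
agglomerative hierarchical clustering (Ward linkage on Euclidean
distances), estimates the number of clusters with the gap statistic
against uniform reference null distributions, and runs the nonparametric
branch statistics (Kruskal-Wallis with Dunn's post hoc, Mann-Whitney,
Spearman correlations with Bonferroni 0.05/20).  A seeded t-SNE embedding
is provided for visualization only.

Features are z-scored before PCA; missing entries are mean-imputed per
feature with the missingness mask carried into reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .morphometrics import MORPH_FEATURE_NAMES
from .ephys import EPHYS_FEATURE_NAMES

FEATURE_NAMES = tuple(MORPH_FEATURE_NAMES) + tuple(EPHYS_FEATURE_NAMES)
PC_VARIANCE_THRESHOLD = 0.05
GAP_N_REFS = 2000
SPEARMAN_ALPHA = 0.05 / 20  # Bonferroni over the 20 tested pairs


@dataclass
class FeatureTable:
    """Cells × 22 features with a missingness mask."""

    data: pd.DataFrame                 # raw values, NaN where missing
    mask: pd.DataFrame | None = None   # True where missing

    def __post_init__(self):
        if self.mask is None:
            self.mask = self.data.isna()
        if len(self.data.columns) != len(FEATURE_NAMES):
            warnings.warn(
                f"feature table has {len(self.data.columns)} columns, expected "
                f"{len(FEATURE_NAMES)}", UserWarning, stacklevel=2)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def imputed(self) -> pd.DataFrame:
        """Per-feature mean imputation of missing entries."""
        return self.data.fillna(self.data.mean())

    def zscored(self) -> pd.DataFrame:
        df = self.imputed()
        sd = df.std(ddof=0).replace(0.0, 1.0)
        return (df - df.mean()) / sd


def assemble_feature_table(morph_rows: pd.DataFrame, ephys_rows: pd.DataFrame) -> FeatureTable:
    """Join per-cell morphological and electrophysiological records by cell id.

    Unmatched cells are dropped with a warning; duplicate ids are an error.
    Rows are sorted by cell id, so input order does not matter.
    """
    for df, kind in ((morph_rows, "morphological"), (ephys_rows, "electrophysiological")):
        if df.index.duplicated().any():
            raise ValueError(f"duplicate cell ids in the {kind} table")
    common = morph_rows.index.intersection(ephys_rows.index)
    dropped = set(morph_rows.index).symmetric_difference(ephys_rows.index)
    if dropped:
        warnings.warn(f"{len(dropped)} unmatched cell id(s) dropped: {sorted(dropped)[:5]}",
                      UserWarning, stacklevel=2)
    joined = morph_rows.loc[common, list(MORPH_FEATURE_NAMES)].join(
        ephys_rows.loc[common, list(EPHYS_FEATURE_NAMES)])
    return FeatureTable(joined.sort_index())


@dataclass
class PCModel:
    n_retained: int
    explained_variance: np.ndarray       # fractions, retained components
    coefficients: pd.DataFrame           # normalized loadings, features × PCs
    scores: np.ndarray                   # cells × retained components
    dominant_features: list[str] = field(default_factory=list)


def pca_retain(table: FeatureTable, threshold: float = PC_VARIANCE_THRESHOLD) -> PCModel:
    """PCA on the z-scored table, keeping components explaining > threshold.

    Loadings are normalized per component so the feature with maximal
    absolute contribution has coefficient magnitude 1.  ``dominant_features``
    lists, per retained component, that maximal-contribution feature.
    """
    if table.n_cells < 2:
        raise ValueError("PCA requires at least 2 cells")
    x = table.zscored().to_numpy()
    pca = PCA()
    scores = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    keep = evr > threshold
    n_keep = max(int(keep.sum()), 1)
    comps = pca.components_[:n_keep]                      # PCs × features
    norms = np.abs(comps).max(axis=1, keepdims=True)
    coeff = (comps / norms).T                             # features × PCs
    coeff_df = pd.DataFrame(coeff, index=table.data.columns,
                            columns=[f"PC{i+1}" for i in range(n_keep)])
    dominant = [table.data.columns[int(np.argmax(np.abs(comps[i])))]
                for i in range(n_keep)]
    return PCModel(
        n_retained=n_keep,
        explained_variance=evr[:n_keep].copy(),
        coefficients=coeff_df,
        scores=scores[:, :n_keep],
        dominant_features=dominant,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    branches: np.ndarray                 # branch label per cell (1..n)
    estimated_k: int | None = None
    gap_curve: np.ndarray | None = None
    gap_se: np.ndarray | None = None
    k_grid: np.ndarray | None = None


def hierarchical_cluster(scores: np.ndarray, n_branches: int = 3) -> ClusterResult:
    """Ward-linkage agglomerative clustering cut into ``n_branches``."""
    scores = np.asarray(scores, dtype=float)
    if n_branches > len(scores):
        raise ValueError("more branches requested than cells")
    z = linkage(scores, method="ward")
    branches = fcluster(z, t=n_branches, criterion="maxclust")
    return ClusterResult(linkage=z, branches=branches)


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _cluster_log_w(x: np.ndarray, k_grid) -> np.ndarray:
    z = linkage(x, method="ward") if len(x) > 1 else None
    out = np.empty(len(k_grid))
    for j, k in enumerate(k_grid):
        labels = fcluster(z, t=int(k), criterion="maxclust") if k > 1 else np.ones(len(x))
        w = _within_dispersion(x, labels)
        out[j] = np.log(w) if w > 0 else -np.inf
    return out


def gap_statistic(
    scores: np.ndarray,
    k_max: int = 10,
    n_refs: int = GAP_N_REFS,
    seed: int | None = None,
) -> ClusterResult:
    """Estimate the number of clusters by the gap statistic.

    gap(k) = E*[log W_k] − log W_k, with the expectation over ``n_refs``
    reference datasets drawn uniformly over the per-dimension bounding box
    of the data, clustered by the same hierarchical procedure.  The
    estimate is the argmax of the gap over k = 1..k_max.  Degenerate
    (zero-variance) data return k = 1.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(x) < k_max:
        raise ValueError("need at least k_max cells")
    k_grid = np.arange(1, k_max + 1)
    if np.allclose(x.std(axis=0), 0.0):
        return ClusterResult(linkage=linkage(x, "ward"), branches=np.ones(len(x), int),
                             estimated_k=1, gap_curve=np.zeros(k_max),
                             gap_se=np.zeros(k_max), k_grid=k_grid)
    log_w = _cluster_log_w(x, k_grid)
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref_log_w = np.empty((n_refs, len(k_grid)))
    for r in range(n_refs):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_log_w[r] = _cluster_log_w(ref, k_grid)
    with np.errstate(invalid="ignore"):
        gap = ref_log_w.mean(axis=0) - log_w
        se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    # a degenerate partition (zero within-cluster dispersion, e.g. all
    # singletons) yields log W = -inf; exclude it from the argmax
    gap = np.where(np.isfinite(log_w) & np.isfinite(ref_log_w).all(axis=0),
                   gap, -np.inf)
    est = int(k_grid[int(np.argmax(gap))])
    z = linkage(x, method="ward")
    branches = fcluster(z, t=est, criterion="maxclust")
    return ClusterResult(linkage=z, branches=branches, estimated_k=est,
                         gap_curve=gap, gap_se=se, k_grid=k_grid)


# ---------------------------------------------------------------------------
# branch statistics
# ---------------------------------------------------------------------------

def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based post hoc z tests with Bonferroni adjustment."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    labels = np.unique(groups)
    rows = []
    pairs = list(combinations(labels, 2))
    for a, bb in pairs:
        ra, rb = ranks[groups == a], ranks[groups == bb]
        na, nb = len(ra), len(rb)
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        zstat = (ra.mean() - rb.mean()) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(zstat))
        rows.append({"group_a": a, "group_b": bb, "z": zstat,
                     "p": p, "p_adjusted": min(p * len(pairs), 1.0)})
    return pd.DataFrame(rows)


def group_stats(table: FeatureTable, branches: np.ndarray,
                dominant_features: list[str] | None = None) -> dict:
    """Per-feature branch comparisons and pairwise feature correlations.

    Three or more branches: Kruskal-Wallis with Dunn's post hoc.  Two
    branches: Mann-Whitney.  Branches with fewer than 2 members are
    skipped and flagged.  ``dominant_features`` (default: all features)
    enter the Spearman matrix; the TDL vs. basal-TDL pair is excluded
    (the latter is a component of the former) and significance uses the
    Bonferroni 0.05/20 threshold.
    """
    branches = np.asarray(branches)
    df = table.imputed()
    labels, counts = np.unique(branches, return_counts=True)
    usable = labels[counts >= 2]
    skipped = [int(l) for l in labels[counts < 2]]
    report: dict = {"skipped_branches": skipped, "features": {}}
    use_mask = np.isin(branches, usable)

    for feat in df.columns:
        vals = df[feat].to_numpy()[use_mask]
        grp = branches[use_mask]
        entry: dict = {}
        if len(usable) >= 3:
            h, p = stats.kruskal(*[vals[grp == l] for l in usable])
            entry["kruskal_h"] = float(h)
            entry["kruskal_p"] = float(p)
            entry["dunn"] = dunn_posthoc(vals, grp).to_dict("records")
        elif len(usable) == 2:
            u, p = stats.mannwhitneyu(vals[grp == usable[0]], vals[grp == usable[1]],
                                      alternative="two-sided")
            entry["mannwhitney_u"] = float(u)
            entry["mannwhitney_p"] = float(p)
        else:
            entry["skipped"] = True
        report["features"][feat] = entry

    feats = list(dominant_features) if dominant_features else list(df.columns)
    corr_rows = []
    for a, bb in combinations(feats, 2):
        if {a, bb} == {"tdl_total", "tdl_basal"}:
            continue  # basal TDL is embedded in total TDL
        rho, p = stats.spearmanr(df[a], df[bb])
        corr_rows.append({"feature_a": a, "feature_b": bb, "rho": float(rho),
                          "p": float(p), "significant": bool(p < SPEARMAN_ALPHA)})
    report["spearman"] = corr_rows
    report["spearman_alpha"] = SPEARMAN_ALPHA
    return report


def embed_2d(x: np.ndarray, seed: int = 0, perplexity: float = 10.0) -> np.ndarray:
    """Seeded t-SNE embedding for visualization only (no inference)."""
    from sklearn.manifold import TSNE

    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("t-SNE embedding needs at least 5 cells")
    if perplexity >= len(x):
        raise ValueError("perplexity must be smaller than the number of cells")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(x)
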