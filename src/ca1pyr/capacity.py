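"""Two-layer dendritic memory capacity.

A pyramidal neuron is abstracted as m independent nonlinear dendritic
subunits of k = s/m synapses each, sampling d distinct afferent input
lines (s total synapses).  The number of distinguishable input-output
functions such a two-layer unit can implement gives a capacity, in bits:

    B(m, k, d) = 2 * log2( C( C(k + d - 1, k) + m - 1, m ) )

Subunit mapping (conservative mode): m = primary basal trees + oblique
trees + main apical trees (early trunk bifurcations + 1); d = s/5.
Liberal mode: m = terminal branches and d = s/1.2.  Synapse counts come
from compartment lengths times branch-specific spine densities; the mouse
preset density reproduces the reference mouse totals (s = 5312, m = 17).

Because d and k are generally non-integer (d = s/5, k = s/m), binomial
coefficients are evaluated through the log-gamma generalization, which is
smooth and order-preserving; for astronomically large inner coefficients
the outer term uses its exact large-N asymptotic m*ln(N) - ln(m!), whose
neglected correction is O(m^2/N) and identically zero at double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.special import gammaln

from .morphometrics import MorphFeatures

CONSERVATIVE_D_DIVISOR = 5.0
LIBERAL_D_DIVISOR = 1.2
MODES = ("conservative", "liberal")


@dataclass
class SpineDensityConfig:
    """Spine (synapse) densities per compartment class, synapses/μm.

    There is no universal human CA1 density; values must be supplied
    explicitly (they come from anatomical literature, not from the
    recordings this package analyses).
    """

    basal: float
    oblique: float
    trunk: float
    tuft: float
    note: str = ""

    def __post_init__(self):
        if min(self.basal, self.oblique, self.trunk, self.tuft) < 0:
            raise ValueError("spine densities must be non-negative")

    @property
    def apical_mean(self) -> float:
        """Density applied to pooled trunk+tuft lengths."""
        return 0.5 * (self.trunk + self.tuft)


#: mouse preset: uniform 1.6 synapses/μm; with the mouse morphology preset
#: (TDL 3.32 mm) this reproduces the reference total s = 5312.
MOUSE_SPINE_DENSITY = SpineDensityConfig(
    basal=1.6, oblique=1.6, trunk=1.6, tuft=1.6,
    note="synthetic mouse preset, uniform density calibrated to s = 5312 at TDL 3.32 mm",
)


@dataclass
class CapacityInputs:
    m: float
    s: float
    d: float
    k: float
    mode: str = "conservative"

    def __post_init__(self):
        if self.m < 1 or self.s <= 0 or self.d <= 0:
            raise ValueError("require m >= 1, s > 0, d > 0")
        if abs(self.k - self.s / self.m) > 1e-9 * max(self.k, 1.0):
            raise ValueError("k must equal s/m")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_counts(cls, m: float, s: float, mode: str = "conservative") -> "CapacityInputs":
        div = CONSERVATIVE_D_DIVISOR if mode == "conservative" else LIBERAL_D_DIVISOR
        return cls(m=m, s=s, d=s / div, k=s / m, mode=mode)


@dataclass
class CapacityResult:
    bits: float
    inputs: CapacityInputs
    removal_fractions: dict[str, float] = field(default_factory=dict)


def _ln_binomial(n: float, k: float) -> float:
    """ln C(n, k) via log-gamma, valid for non-integer arguments."""
    if n < k or k < 0:
        raise ValueError(f"binomial arguments out of domain: C({n}, {k})")
    return float(gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0))


def memory_capacity(inputs: CapacityInputs, log_base: float = 2.0) -> CapacityResult:
    """Evaluate B(m, k, d); result in bits (or the chosen log base)."""
    import numpy as np

    m, k, d = inputs.m, inputs.k, inputs.d
    ln_inner = _ln_binomial(k + d - 1.0, k)  # ln C(k+d-1, k)
    if abs(m - round(m)) < 1e-9 and m < 1e6:
        # exact product form C(N+m-1, m) = prod_{j=0}^{m-1}(N+j) / m!, free of
        # the cancellation a gammaln difference suffers when N is large;
        # ln(N+j) = ln N + log1p(j/N) stays finite for astronomical N
        j = np.arange(int(round(m)), dtype=float)
        inv_n = math.exp(-ln_inner) if ln_inner < 745.0 else 0.0
        ln_outer = float(np.sum(ln_inner + np.log1p(j * inv_n)) - gammaln(m + 1.0))
    elif ln_inner < 500.0:
        ln_outer = _ln_binomial(math.exp(ln_inner) + m - 1.0, m)
    else:
        # smooth non-integer m with astronomically large inner coefficient:
        # ln C(N+m-1, m) = m ln N - ln Γ(m+1) + O(m^2/N)
        ln_outer = m * ln_inner - float(gammaln(m + 1.0))
    bits = 2.0 * ln_outer / math.log(log_base)
    return CapacityResult(bits=bits, inputs=inputs)


# ---------------------------------------------------------------------------
# morphology -> (m, s) mapping
# ---------------------------------------------------------------------------

def count_subunits(features: MorphFeatures, mode: str = "conservative") -> int:
    """Number of independent dendritic subunits m.

    Conservative: primary basal trees + oblique trees + main apical trees
    (early trunk bifurcations + 1).  Liberal: terminal branches.
    """
    if mode == "conservative":
        if math.isnan(features.n_early_bifurcations):
            raise ValueError("apical features undefined: cannot count subunits")
        return int(features.n_basal_trees + features.n_oblique_trees
                   + features.n_early_bifurcations + 1)
    if mode == "liberal":
        return int(features.n_terminal_branches)
    raise ValueError(f"mode must be one of {MODES}")


def synapse_count(
    lengths_mm: tuple[float, float, float],
    densities: SpineDensityConfig,
) -> int:
    """Total synapses s = Σ_c length_c(μm) × density_c, nearest integer.

    ``lengths_mm`` is the (basal, oblique, trunk+tuft) triple; the pooled
    apical length uses the mean of the trunk and tuft densities.
    """
    basal, oblique, trunk_tuft = lengths_mm
    s = (basal * 1000.0 * densities.basal
         + oblique * 1000.0 * densities.oblique
         + trunk_tuft * 1000.0 * densities.apical_mean)
    return int(round(s))


def cell_capacity(
    features: MorphFeatures,
    densities: SpineDensityConfig,
    mode: str = "conservative",
) -> CapacityResult:
    """Full-cell capacity from a morphology's feature record."""
    m = count_subunits(features, mode)
    s = synapse_count(
        (features.tdl_basal, features.tdl_oblique, features.tdl_apical_trunk_tuft),
        densities)
    return memory_capacity(CapacityInputs.from_counts(m, s, mode))


# ---------------------------------------------------------------------------
# compartment-removal analysis
# ---------------------------------------------------------------------------

def removal_analysis(
    features: MorphFeatures,
    densities: SpineDensityConfig,
    mode: str = "conservative",
) -> dict[str, float]:
    """Capacity remaining after virtually removing one compartment class.

    For each of oblique / basal / apical (trunk+tuft), recompute m and s
    with that class's subunits and synapses removed; the reported fraction
    is B_removed / B_full.  NaN (flagged) when removal leaves m < 1 or
    s <= 0.
    """
    if mode == "liberal":
        # terminal branches per class are not tracked in the 12-feature
        # record; removal analysis is defined for the conservative mapping
        raise ValueError("removal analysis supports the conservative subunit mapping")

    # an apical-less cell contributes no apical trees (rather than erroring,
    # so degenerate removals can be reported as flagged fractions)
    n_apical_trees = (0.0 if math.isnan(features.n_early_bifurcations)
                      else features.n_early_bifurcations + 1)
    m_full = features.n_basal_trees + features.n_oblique_trees + n_apical_trees
    s_full = synapse_count(
        (features.tdl_basal, features.tdl_oblique, features.tdl_apical_trunk_tuft),
        densities)
    full_bits = memory_capacity(CapacityInputs.from_counts(m_full, s_full, mode)).bits

    scenarios = {
        "oblique": (features.n_oblique_trees,
                    features.tdl_oblique * 1000.0 * densities.oblique),
        "basal": (features.n_basal_trees,
                  features.tdl_basal * 1000.0 * densities.basal),
        "apical": (n_apical_trees,
                   features.tdl_apical_trunk_tuft * 1000.0 * densities.apical_mean),
    }
    fractions: dict[str, float] = {}
    for name, (dm, ds) in scenarios.items():
        m_r = m_full - dm
        s_r = s_full - int(round(ds))
        if m_r < 1 or s_r <= 0:
            fractions[name] = math.nan
            continue
        b_r = memory_capacity(CapacityInputs.from_counts(m_r, s_r, mode)).bits
        fractions[name] = b_r / full_bits if full_bits > 0 else math.nan
    return fractions


def population_summary(cohort_bits, comparison_bits=None) -> dict:
    """Mean ± SD per cohort and the fold difference of mean capacities."""
    import numpy as np

    a = np.asarray(list(cohort_bits), dtype=float)
    if a.size == 0:
        raise ValueError("empty cohort")
    out = {"mean_bits": float(a.mean()),
           "sd_bits": float(a.std(ddof=1)) if a.size > 1 else 0.0,
           "n": int(a.size)}
    if comparison_bits is not None:
        b = np.asarray(list(comparison_bits), dtype=float)
        if b.size == 0:
            raise ValueError("empty comparison cohort")
        out["comparison_mean_bits"] = float(b.mean())
        out["comparison_sd_bits"] = float(b.std(ddof=1)) if b.size > 1 else 0.0
        out["comparison_n"] = int(b.size)
        out["fold_difference"] = float(a.mean() / b.mean())
    return out
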