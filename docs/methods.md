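# Methods

This note documents the models, algorithmic choices and limitations of
the package, in the order of the processing chain.

## Compartment classification

Reconstructions carry only the coarse SWC classes (soma/axon/basal/
apical), so splitting the apical tree into trunk, obliques and tuft is
algorithmic. Two deterministic rules are implemented:

* **Layer-based** (preferred, used whenever a laminar annotation is
  available). Walking distally from the apical root, the first node at or
  beyond the SR|SLM border starts a tuft subtree. At a bifurcation, every
  child whose subtree reaches the border continues as trunk; two or more
  reaching children form a trunk bifurcation (one extra "main apical
  tree" each); children that never reach the border are obliques. If no
  child reaches the border (truncated reconstruction) the longest child
  continues the trunk.
* **Principal-path heuristic** (no layers): greedily follow the child
  with the larger total subtree length; stop at the first bifurcation
  whose child subtrees each hold ≥10% of the remaining apical length —
  that node starts the tuft; earlier side branches are obliques.

Manual anatomical labelling has no unique algorithmic equivalent; these
rules are a documented, reproducible surrogate. They agree exactly with
the synthetic generator's construction-time labels (a tested invariant),
but on real, heavily truncated reconstructions the heuristic's tuft split
is a judgement call — the 10% threshold is exposed as a constant. Edge
cases worth knowing: a side branch longer than the remaining trunk will
be followed by the no-layer fallback (supply layer borders for truncated
cells), and multi-point soma contours are collapsed to their centroid.

"Nodes" in per-tree censuses are bifurcation points; a trifurcation
counts as two binary-equivalent bifurcations so counts stay additive.
Early bifurcations are trunk bifurcations within 200 μm *path* distance
(not Euclidean) of the apical root. Segment radii are read and written
but no feature depends on them.

## Linear membrane model

The subthreshold membrane is the minimal linear resonator

    C dv/dt    = −g_L v − g_h w + I(t)
    τ_h dw/dt  = v − w

(v is the deviation from rest; units pF, nS, ms, pA, mV). The slow
feedback w is the standard phenomenological linearization of the
hyperpolarization-activated current I_h: it produces both the sag rebound
under hyperpolarizing steps and a subthreshold resonance peak, with the
closed-form impedance Z(ω) = [g_L + iωC + g_h/(1+iωτ_h)]⁻¹ and
|Z(0)| = 1/(g_L+g_h). Pharmacological HCN block is emulated by setting
g_h = 0, which abolishes sag and resonance.

Default base parameters target the human population medians: g_L = 25 nS
and C = 500 pF give a 40 MΩ / 20 ms passive cell; τ_h = 50 ms sits in the
range of slow HCN kinetics near rest; g_h is calibrated per use by
root-finding against the closed form (to a target F_res or a target sag
ratio). All parameters are config-exposed.

Simulation uses exact zero-order-hold stepping of the diagonalized
2-variable system (each mode advanced as a first-order recursive filter),
so there is no integration error beyond the stimulus sampling; the
simulated step response matches the eigen-decomposition closed form to
<1e-9 mV in the tests. Spiking is *not* modelled — action potentials are
injected as analytic Gaussian-flank templates whose ground-truth features
are computed on a ×100 oversampled grid.

## Feature extraction conventions

Unstated-in-the-field windowing choices were fixed as follows: baseline =
mean of the 100 ms before stimulus onset; steady state = mean of the
final 200 ms of the 1 s step; sag-peak search = first 300 ms after onset
(widened with a warning if the minimum sits on the window edge); τ fitted
on [onset+2 ms, onset+150 ms]; dV/dt by central differences at native
sampling. The sag sweep is the one whose steady-state deviation is
closest to −3 mV (ties toward larger current).

The ZAP divides the voltage spectrum by the current spectrum over the
*full* trace (capturing the post-stimulus response tail; truncating at
stimulus offset leaks the residual transient and biases the ratio by a
few percent), restricts to the stimulated band, smooths with a 0.25 Hz
moving average and takes the argmax. A cell is "resonant" iff
F_res > 1 Hz. Against the closed form the pipeline is accurate to ~1e-4
relative in |Z| and 0.003 Hz in F_res on noiseless simulations, and
F_res is invariant (±0.1 Hz) to the 10 s/30 Hz vs. 20 s/40 Hz protocol
variants.

Spike detection requires a sustained (≥2 samples) dV/dt crossing of
23 mV/ms followed by a voltage peak above −20 mV within 5 ms; the peak
criterion gives zero false positives at 0.3 mV voltage noise in 100
seeded trials. AP threshold is the interpolated 23 mV/ms crossing leading
into the peak; "between 30 and 70% of the AP" is read as an *amplitude*
band (the time-band reading has no natural anchor), and the band mean of
dV/dt is computed as ΔV/Δt between interpolated band-crossing times,
which is exact for the band-average and stable at native sampling.

## Memory capacity

B(m,k,d) = 2·log₂(C(C(k+d−1,k)+m−1,m)). The logarithm base is taken as 2
(bits), the convention of the two-layer model literature; it is an
argument of `memory_capacity`. d = s/5 and k = s/m are generally
non-integer and are *not* rounded: binomials go through the log-gamma
generalization, which is smooth and order-preserving. For integral m the
outer coefficient uses the exact product form Σⱼ ln(N+j) − ln m!, which
is immune to the catastrophic cancellation a log-gamma difference suffers
once the inner coefficient N is large; for ln N ≥ 500 with non-integer m
the asymptotic m·ln N − ln Γ(m+1) applies (the neglected correction is
O(m²/N), identically zero at double precision). The implementation agrees
with an adaptive-precision mpmath oracle to ~1e-15 relative across the
tested range.

One regime condition surfaced by the oracle: B is **not** globally
monotone in m at fixed s — once k = s/m falls below roughly 5, splitting
a fixed synapse pool over more subunits shrinks the per-subunit function
space faster than the combinatorial gain, and B decreases. Real CA1
parameters sit at k in the hundreds, where B is monotone in m; the tests
check monotonicity in that regime (k ≥ 50) and monotonicity in d
unconditionally.

Spine densities are a mandatory scientific input (they come from
anatomical literature, not from recordings); there is deliberately no
silent human default. The built-in mouse preset uses a uniform
1.6 synapses/μm with deterministic compartment lengths (basal 1200,
oblique 1100, trunk 300, tuft 720 μm; TDL 3.32 mm), chosen so one preset
cell reproduces the reference mouse totals s = 5312 and m = 17 exactly —
it is a synthetic stand-in, not measured mouse anatomy. Removal analysis
is defined for the conservative subunit mapping (per-class terminal
branch counts are not part of the 12-feature record, so liberal-mode
removal raises).

## Diversity pipeline

Features are z-scored before PCA (the scaling actually used upstream of
published analyses of this kind is rarely stated; z-scoring is the
field's default for mixed-unit tables and is config-exposed). Components
explaining >5% of variance are retained; loadings are normalized per
component to a maximal absolute coefficient of 1. Clustering is
agglomerative with Ward linkage on Euclidean distances over the retained
PC scores. The gap statistic draws its null sets uniformly over the
per-dimension bounding box of the data (the simple-box variant), runs the
same hierarchical procedure on each, and estimates k as the argmax of
gap(k) = E*[log Wₖ] − log Wₖ over k = 1..10; degenerate partitions with
zero within-cluster dispersion are excluded from the argmax, and
zero-variance data short-circuit to k = 1. Dunn's post hoc uses
rank-based z statistics with a tie correction and Bonferroni adjustment
across pairwise contrasts. The Spearman matrix excludes the total-TDL vs.
basal-TDL pair (one embeds the other) and applies the 0.05/20 threshold.
t-SNE is seeded and used for visualization only.

## Synthetic data: what it emulates, what it does not

The morphology generator grows trees by fixed 10 μm segment accretion;
branch angles are cosmetic (every measured feature is length- or
topology-based). Coordinates are rounded to 0.001 μm at build time so SWC
round trips are byte-stable, and ground-truth features are computed from
the generator's own construction bookkeeping — the tested recovery of
that truth through write → read → classify → measure exercises the whole
morphology chain.

Human defaults are calibrated to the published population statistics:
per-cell TDL ~ Normal(18.6, 3.9) mm with compartment fractions
basal/oblique/trunk+tuft ≈ 0.40/0.38/0.22; basal stems ~ round
Normal(7, 1.8); oblique counts ~ rounded log-normal with median 20 and
σ_log = 0.21 (splitting the asymmetry of the published quartiles 18.5 and
24.5 around the median); oblique bifurcations per tree ∈ {0,1,2} with
probabilities (0.3, 0.5, 0.2) (mean 0.9); basal bifurcations ~ round
Normal(5, 1.5); early trunk bifurcations uniform on {0,1,2,3}. Published
medians and quartiles do not pin down the distribution families; the
log-normal/rounded-normal choices are ours and are config-exposed. A
consequence worth noting: the implied mean conservative subunit count is
≈30 ± 5, marginally below the published 31 ± 6, because component
*medians* rather than (unpublished) means were calibrated.

The generator does not emulate: truncation artifacts of slice
reconstruction, diameter/taper, spines, 3-D space-filling realism, or any
correlation between morphology and electrophysiology across cells (the
pipeline draws membrane parameters independently). Passing tests
therefore demonstrate correctness of the measurement chain under known
ground truth — not that real reconstructions satisfy the generator's
statistics.

Feature tables are drawn from a single correlated multivariate normal
(variances ≈ (0.22·mean)², correlation 0.35^|i−j|), giving the ~2- to
6-fold min/max ranges typical of real cohorts; mixtures of shifted
components provide positive controls for cluster recovery.

## Problem sizes and reproducibility

Default study sizes are those of the emulated conditions: 35 cells for
morphology cohorts (31 for the joined morpho-electric table), 20 kHz
sampling, 10 s chirps, 2000 gap-statistic reference sets. Unit and
property tests run the same code on smaller cohorts, lower sampling rates
and fewer reference sets — sizes chosen so the whole suite stays quick
while every check retains its discriminating power. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds give bit-identical synthetic data, sweeps and reports.
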