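# Methods

This note describes the models, estimators and numerical choices behind
`ampconn`, and what the synthetic cohorts do and do not emulate.

## Problem setting

During a staged cognitive task (here: overt picture naming, six latency
windows t1–t6 between 0 and 535 ms after stimulus onset), two different
principles identify "important" cortical regions: high source **amplitude**
(hotspots) and a central position in the **functional connectivity** network
(hubs). `ampconn` quantifies the relationship between the two — the
amplitude–connectivity coupling — per group, stage and network threshold,
and classifies every region as hothub, coldhub, non-hub hotspot or non-hub
coldspot. The subgraph induced by coldhubs (strongly connected but weakly
activated regions, invisible to amplitude-based mapping) is the *dark
functional network*.

## Connectivity model

**PLV.** Phase-locking between regions i and j is estimated across trials:

    PLV_ij(s) = | (1/T) Σ_t exp(i(φ_i(t,s) − φ_j(t,s))) |

per epoch sample s, then averaged over the samples of a stage window.
Phases come from the analytic signal of the gamma-band (30–45 Hz) filtered
epochs. With T independent trials the null expectation is
√π/(2√T) ≈ 0.114 at T = 60, which the tests verify against a Monte-Carlo
oracle.

**Filtering.** Zero-phase FIR band-pass, Hamming design, transition width
15% of the band edges; the filter order follows the Hamming rule
(≈3.3/Δf_norm) and is capped so reflect padding fits the epoch. The
band-pass and the analytic signal are applied in a single FFT pass
(spectrum × |H(f)|² × one-sided step); the response is identical to
forward–backward filtering followed by a Hilbert transform away from the
epoch edges. Samples with numerically zero envelope have undefined phase;
they are set to 0 and flagged with a warning.

**Baseline normalization.** Stage PLV matrices are z-scored edgewise
against the pre-stimulus baseline (−200–0 ms): the per-edge mean and SD are
estimated from seeded trial-bootstrap PLV replicates computed on the
baseline window (default `n_boot=200`). The bootstrap is an assumption —
the estimator behind the original "mean and standard deviation matrix of
the baseline" is not documented — and is the package's chosen convention.
Edges with zero bootstrap SD get z = 0 and are excluded from graphs.

**Stage amplitude.** Mean over the stage window of the rectified trial
average per region (picoampere scale), z-scored against the mean/sample-SD
of the rectified trial average over the baseline samples.

## Network model

Edges are normalized PLV values strictly greater than 1.96 (≈ one-sided
2.5% of a standard normal), giving an undirected weighted graph without
loops or multi-edges.

**Island thresholding.** An m-island is a maximal connected cluster C with
3 ≤ |C| ≤ m such that some spanning tree of C has a minimum edge weight
strictly exceeding every edge leaving C (a *line island*). The
implementation builds the maximum-spanning-forest dendrogram in one
weight-ordered union-find pass (O(E log E)); the merge weight of a cluster
equals the maximum weight leaving it, so all maximal islands for the whole
maximum-size continuum (default grid 50, 100, …, 750 plus 388 and 776) are
read off one hierarchy. Equality between the internal minimum and the
external maximum rejects the cluster (strict inequality), so an
equal-weight clique admits no proper sub-island. Correctness is checked
against exhaustive subset enumeration with the maximality filter on 200
random graphs.

**Node measures.** Nine per-node measures with the following conventions:

| column | measure | weights |
| ------ | ------- | ------- |
| DEG  | strength (sum of incident weights) | weighted |
| BET  | betweenness, distance = 1/weight (default) or weight ("raw" mode) | weighted |
| TRA  | Barrat local clustering, ordered neighbor pairs | weighted |
| KVL  | k-coreness | unweighted |
| LAP  | Laplacian centrality, energy Σ d²+d drop on node removal | unweighted |
| EIG  | principal adjacency eigenvector, per connected component, max = 1 | weighted |
| PART | participation 1 − Σ_M (κ_vM/s_v)² | weighted |
| GATE | gateway (Vargas & Wahl), g_vM = 1 − ā_vM·b̄_vM | weighted |
| WMDZ | within-module strength z (population SD, Guimerà convention) | weighted |

Notes: Barrat's coefficient reduces to the unweighted clustering
coefficient under constant weights and always lies in [0, 1]. The gateway
b-term uses strength by default (betweenness available); GATE ≥ PART holds
identically and a node with all-intramodular edges scores 0 on both. A node
connected equally to all M modules scores 1 − 1/M on participation (the
"equal to one" reading is the M → ∞ limit). Per-island metric tables are
computed on each island's induced subgraph; nodes outside every island are
omitted at that m.

## Statistics

**Subject-adjusted coupling.** The partial Pearson correlation between node
amplitude and a node measure treats the subject as a nuisance factor:
residualizing on subject indicators equals within-subject centering, and

    df = N − (S − 1) − 2

for N node observations from S subjects. Two-sided p from the t
distribution on df; the CI is Fisher-z with SE = 1/√(df − 1). Coefficients
with p < 0.05 are "coupling", others "uncoupling"; no multiplicity
correction is applied across stages or measures (by design).

**Group differences.** The group difference of coupling coefficients is
tested by permutation: the 10 subjects are reassigned 5/5 without
replacement (within a draw; duplicate draws across the default 1,000
permutations are allowed), both pooled coefficients are recomputed from
per-subject centered sufficient statistics, and the observed difference is
compared against the 2.5–97.5 percentile interval of the permutation
differences. For the 5/5 design there are 252 distinct assignments; the
sampled interval converges to the exhaustive-enumeration interval (tested).
The permutation RNG stream is kept disjoint from the bootstrap streams.

**Amplitude tests.** Per-node permutation t-tests (pooled-variance t,
label shuffling, p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)) on original-scout
amplitude z-scores. Demographic comparisons are two-tailed *paired* t-tests
across the five matched pairs; this pairing reproduces the published
p-values (0.30, 0.24, 0.00092) where unpaired tests do not.

**Node taxonomy.** Hotspots: amplitude strictly above mean + 1 sample SD
(on a Gaussian field ≈ 15.9% of nodes, matching the observed 11.86–16.37%
hub share). Hubs: top-k eigenvector centrality with k = hotspot count,
computed on group-averaged z-matrices (averaged before thresholding); ties
at the k boundary are broken by node id and logged. Refined-scout labels
aggregate to original scouts by "at least one hothub child".

## Synthetic cohorts

The generator emulates the *inputs* of the study design — two groups of 5
subjects, 60 correct trials, epochs −200–600 ms at 600 Hz, gamma band — with
a mechanism whose ground truth is recoverable:

- **Connectivity:** regions in the same functional module share a uniform
  per-trial driver phase; each region adds von Mises jitter with
  concentration κ_i, so a same-module pair has asymptotic PLV
  R(κ_i)R(κ_j), R(κ) = I₁(κ)/I₀(κ). Cross-module pairs sit at the null
  level. The baseline segment uses a separate weak concentration
  (default 0.3) so normalization is meaningful. κ is mapped to target PLV by
  closed-form inversion of R.
- **Amplitude:** a slow evoked offset per region (baseline level before
  onset, planted level after) that survives trial averaging; the gamma
  carrier cancels in the trial average because its driver phase is uniform
  per trial. By a rotation argument the measured amplitude is independent
  of the phase-coupling draws — without this separation the amplitude
  estimate would be confounded with κ and a null cohort would not be null.
- **Planted coupling:** per subject, the amplitude score is an exact linear
  blend ρ·s̃ + √(1−ρ²)·w̃ of the standardized planted strength s̃ with an
  orthogonalized Gaussian vector w̃, so the planted amplitude–strength
  Pearson correlation equals ρ exactly. Fields are drawn independently for
  every subject: under ρ = 0 in both groups all 10 subjects are
  exchangeable, which is precisely the null hypothesis of the 5/5
  permutation test. Group-level fields would break that null.

What the generator does **not** emulate: source leakage and field spread,
inter-regional distance structure, 1/f background spectra, evoked latency
dynamics across stages (the planted structure is stationary over the task
window, so stages differ only by estimation noise), lesioned anatomy, or
inter-subject registration error. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to those real-data complications.

## Problem sizes and numerics

Public defaults are the study conditions: n_roi = 120 (776 supported), 16
modules, 60 trials, n_boot = 200, n_perm = 1,000, threshold 1.96, the full
six-stage grid. Simulation studies in the test suite and acceptance script
use desk-scale cohorts chosen once for single-core runtime: 48 regions / 8
modules for sign-recovery and power, 24 regions / 4 modules for the type-I
study (200 replicates at n_perm = 200), stage t4 only, baseline bootstrap
n_boot = 30 with every 4th baseline sample (neighboring samples of a
narrowband signal are strongly correlated), and the analytic transform in
complex64 (phase error < 1e-5 rad, orders of magnitude below PLV sampling
noise). Time-to-sample mapping uses half-open ms windows
[start, end) with floor(ms·sfreq/1000).

## Known limitations

- PLV carries no leakage correction; leakage-robust metrics (wPLI,
  imaginary coherence) are out of scope by design.
- The baseline bootstrap SD is one of several defensible estimators of the
  baseline fluctuation; z magnitudes (and hence graph density at the 1.96
  threshold) depend on it.
- With 5 subjects per group the permutation test has a granularity of
  1/252; reported "95%" intervals are percentile intervals of a discrete
  distribution.
- The island hierarchy returns maximal islands per m (not the full nested
  hierarchy), matching the thresholding use-case.
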