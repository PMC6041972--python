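# Methods

## Statistical standardization

Published QTL reports are harmonized to a common triple (LOD, R², 95% CI)
before any spatial analysis.

* `LOD = LRS / 4.6` converts a likelihood-ratio statistic to a LOD score.
* `R² = 1 − 10^(−2·LOD/N)` estimates the variance fraction from the LOD and
  the population size N. A published R² always takes precedence over this
  derivation; the source of each filled statistic is recorded
  (`reported` / `from_lrs` / `from_lod`).
* The analysis CI is the Darvasi–Soller empirical width
  `CI95 = k / (N·R²)` cM, centered on the reported most-likely position,
  with `k = 530` for F2/F3 populations and `k = 163` for RILs/IRILs. The
  constants are configuration (`mqtl.standardize.K_CONSTANTS`); any other
  population type must be mapped explicitly. A reported support interval is
  retained as provenance only — the standardized CI replaces it for all
  downstream computation, including de-duplication.

De-duplication groups records by (study, trait, chromosome), chains them
into connected components by closed-interval overlap of the standardized
CIs, and keeps the highest-R² member of each component. Ties go to the
narrower reported CI, then the lexicographically smallest QTL id, so output
is deterministic. Whether overlap is tested on standardized or reported CIs
is a flag (`use_reported_ci`, default standardized): reports rarely state
which interval they de-duplicated on, and the standardized interval is the
one actually analyzed.

## Map and QTL projection

Coordinates are 0-based cM with closed CI intervals. For each chromosome
shared by a component map and the reference:

1. Markers present in both maps form candidate anchors, ordered by
   component position.
2. Inverted markers are removed by computing the maximum-cardinality subset
   whose reference positions are strictly increasing (longest increasing
   subsequence on reference rank). When several subsets tie in size, the one
   spanning the larger reference interval wins — anchors far apart constrain
   the transform better than close ones. Anchors left at identical component
   positions are collapsed to the first.
3. Fewer than two surviving anchors is a *no-anchors* signal: the
   chromosome's markers and QTL are excluded and logged rather than
   projected.

A position interior to two consecutive anchors maps linearly between them;
a position outside the anchored span extrapolates from the nearest terminal
anchor using the chromosome-wide global ratio (reference span over
component span of the retained anchors). The transform is monotone
non-decreasing by construction. QTL CI bounds are projected independently
of the point estimate; if the transform locally reverses them they are
re-ordered and clamped so the projected position stays inside the interval.
A CI that straddles several anchor intervals therefore rescales piecewise
rather than by a single ratio — the simplest behavior consistent with
per-bound homothety. Any QTL with a projected coordinate below zero is
discarded (`discarded_negative`) and logged.

Consensus-map construction processes components in descending order of
shared-marker count with the reference (tie-break: map id) as a proxy for
map similarity — the most compatible maps are merged first so later, sparser
maps can anchor against markers already inserted. Reference marker positions
are never moved; re-submitting a component is a no-op.

## Mixture model and model selection

On one chromosome and tissue, projected QTL positions are modeled as a
K-component normal mixture with *known* per-observation variances:

    L = Π_i Σ_k p_k · φ(x_i; μ_k, s_i²),   s_i = CI95_i / 3.92.

Only μ_1..μ_K and the K−1 free weights are estimated, so ν = 2K − 1. This
is the classic fixed-variance meta-analysis model: a precise QTL (narrow
CI) pulls its component mean harder than a vague one.

* **EM.** E-step responsibilities in log space; M-step means are
  responsibility-and-precision weighted (`Σ r_ik x_i / s_i² / Σ r_ik / s_i²`),
  weights are mean responsibilities. The likelihood trace is recorded and
  is non-decreasing (asserted in tests). Tolerance 1e-8 on the
  log-likelihood, at most 500 iterations, 10 restarts from k-means++-style
  initial means; all randomness from one integer seed. K = 1 is solved in
  closed form (inverse-variance weighted mean).
* **Criteria.** AIC = −2ℓ + 2ν; AICc adds 2ν(ν+1)/(n−ν−1) and is reported
  as +∞ when n ≤ ν + 1 so it cannot vote there; AIC3 = −2ℓ + 3ν;
  BIC = −2ℓ + ν·ln n; AWE = −2ℓ_c + 2ν(3/2 + ln n) with ℓ_c the
  classification log-likelihood under argmax-hardened assignments
  (Banfield–Raftery form — the least standardized of the five, hence
  documented explicitly).
* **Vote.** Each criterion votes for its minimizing K (ties toward smaller
  K); the default strategy takes the majority, ties again toward smaller K.
  `aicc_only` and `consensus_min` (smallest voted K) are alternatives, since
  "the lowest value among five criteria" admits several readings.
  Kmax defaults to min(n, 10) per chromosome.

Declared MQTL take the inverse-variance weighted mean of their hardened
members, sd = √(1/Σ 1/s_i²), CI = position ± 1.96·sd, membership fractions
from the soft responsibilities, and flanking markers as the nearest
reference markers at/outside the CI bounds (terminal markers when the CI
overruns the mapped ends). Naming is `<LIR|SIR|KIR><ordinal>` in
chromosome-then-position order per tissue. Components emptied by hardening
are dropped.

## Coverage accounting

QTL coverage merges overlapping CIs per chromosome before summing (a union
length); MQTL coverage is the raw sum of CI widths. The asymmetry is
deliberate: published per-tissue panels tabulate MQTL coverage as the plain
column sum, while QTL coverage is explicitly overlap-corrected. Percentages
are taken against the reference-map length (default 7 980.637 cM) and, for
physical coverage, against the B73 v2 assembly length (2 066 432 718 bp).
Rounding (half-up, 2 decimals) happens only at report time.

Physical anchoring takes the flanking markers of the genetic CI and walks
outward along the reference marker order until an anchored marker is found;
a side that exhausts the chromosome is an *open* end, closed only by a
user-supplied chromosome physical length (never bundled). Cross-tissue
overlap regions are connected components of the CI-overlap graph restricted
to components mixing ≥ 2 tissue classes, computed on genetic CIs by default
with a physical mode, since region boundaries are not uniquely defined by
either coordinate system alone.

## Bundled catalog

`mqtl.catalog` ships the curated table of 86 published maize
insect-resistance MQTL (24 LIR / 42 SIR / 20 KIR). Its CI(95%) column is
kept as reported (`reported_ci_width`) and preferred by coverage sums over
`ci_end − ci_start`, because the published coverage totals are sums of that
column and the two disagree slightly for a few rows. One stem MQTL has an
open-ended physical interval. Note the catalog's own mean stem CI is
26.3055 cM, which prints as 26.31 at 2 decimals though 26.30 is sometimes
quoted — an upstream truncation, not a computational difference.

## Synthetic data generator

`mqtl.simulate` emulates a multi-study literature corpus at the
summary-statistic level:

* reference map: markers at sorted uniform positions per chromosome;
* component maps: each reference marker kept with probability
  `shared_marker_fraction` (default 0.8), inter-marker gaps rescaled by
  `exp(N(0, distortion_sd))` (default 0.1) — strictly positive factors, so
  marker order is preserved and inverted-marker handling is exercised by a
  separate adversarial fixture that explicitly swaps two markers;
* studies: population type uniform over {F2, F3, RIL, IRIL}, size uniform
  on 100–472, matching the spread of published bi-parental maize studies;
* QTL: for each planted MQTL assigned to a study, R² ~ Beta(1.2, 8)
  truncated to [0.005, 0.47] (the span of published variance fractions),
  CI width exactly `k/(N·R²)`, reported position ~ Normal(true position on
  the component scale, CI/3.92). Generator and standardizer therefore agree
  on CI widths exactly, by construction.

All randomness flows from one config seed via `numpy.random.SeedSequence`
(study streams spawned by index), so equal configs give byte-identical
output files.

What the generator does *not* emulate: genotype/phenotype noise, selective
reporting and publication bias, map curation errors, chromosome-specific
marker densities, and correlated QTL across traits within a study. Passing
recovery tests therefore demonstrates that the pipeline's arithmetic and
inference behave as designed under the stated model — not that real
literature corpora satisfy that model.

## Problem sizes used in checks

The parameter-recovery experiment (`mqtl.recovery`) plants three stem MQTL
at 40/150/260 cM on a 300 cM chromosome and simulates ten studies per
replicate with N ∈ [200, 472] and R² ∈ [0.08, 0.47], bounding the largest
possible QTL sd at ~8.4 cM so the 110 cM separation exceeds five times the
noise scale — the regime in which the criterion vote is expected to find
the planted K. One hundred replicates score the fraction with chosen K = 3
and declared positions within 2 cM of the planted ones. Projection
properties are checked on 100 random map pairs (15 markers, 70% sharing,
distortion 0.2); EM-versus-enumeration equivalence on 50 instances with
n ≤ 6 and K ≤ 2, where exhaustive hard-assignment scoring is feasible.

## Known limitations

* The exact published MQTL set cannot be regenerated from first principles
  without the original study-by-study map and QTL files and the precise
  internals of the original clustering software; the bundled catalog stands
  in as the real-data fixture, and the machinery is validated by property
  and recovery tests instead.
* The count of cross-tissue overlap regions depends on the region
  definition; under the connected-component definition here the catalog
  yields a number in the mid-teens, and no canonical value is targeted.
* AWE's exact form varies across software; the hardened-classification
  variant used here is documented above.
* EM with few, widely spread points and large K can leave components empty
  after hardening; such components are dropped and the effective K reported
  accordingly.
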