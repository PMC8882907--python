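# Methods

This note documents the statistical model behind `pediconn`, the
choices made where the design was genuinely open, and what the
synthetic generator does and does not emulate.

## Connectome model and preprocessing

A connectome is a symmetric, zero-diagonal matrix of nonnegative
integer streamline counts over an ordered node table (default: the
68-region Desikan–Killiany gyral parcellation, 34 per hemisphere).
Node identity is by label, never by file row order; the packaged
default region list is the standard FreeSurfer gyral set, which is an
assumption — studies occasionally use variant naming, and a custom
node table TSV can be supplied.

Two thresholds appear, with different roles:

- **Streamline-count threshold** (`min_count`, default 5), applied per
  subject before any metric: entries with `0 < w < min_count` are
  zeroed.  An entry equal to the threshold survives — "minimum"
  denotes the smallest admissible count.  The operation is idempotent.
- **Sparsity threshold** (default 15%), applied only to group-average
  networks for hub identification: the mean matrix keeps its
  `round(s·N(N−1)/2)` strongest undirected edges.  Ties are broken by
  lexicographic node-pair order so results are reproducible.

## Graph measures

All distances use the standard weighted-connectome convention
`d_ij = 1/w_ij`: more streamlines, shorter effective length.  Shortest
paths are computed with Dijkstra's algorithm per source node
(`scipy.sparse.csgraph`); the test suite verifies agreement with an
independent Floyd–Warshall oracle to 1e-9 on randomized small graphs.

Thresholded single-subject networks are frequently disconnected, so
disconnected pairs contribute zero to efficiencies (`1/∞ = 0`) and the
characteristic path length averages finite lengths only; a network with
no finite pair yields `Lp = NaN`.  Network strength is the *mean* of
nodal strengths (rather than the sum); group contrasts are invariant to
that choice up to a constant factor.  The identity
`mean_i E_nodal(i) = Eg` holds by construction and is asserted
property-wise.

Hubs are nodes whose nodal efficiency is at least one sample standard
deviation (divisor N−1) above the across-node mean, read inclusively
(`≥`).  An all-equal profile has SD 0 and therefore returns every node;
this degenerate case is documented rather than special-cased.  Group
hub sets are computed on the group-average network at 15% sparsity;
per-subject hub sets are also available.

## Group inference

The inferential core is ordinary least squares on small design
matrices, hand-rolled on numpy (QR factorisation, Student-t two-sided
p); `statsmodels` is used as an independent oracle in the tests, not in
the implementation.  Models:

- group difference: `y ~ 1 + group + age`.  The group indicator codes
  TD = 1, ASD = 0, so the reported coefficient and t are **TD − ASD**:
  measures elevated in the clinical group carry negative t.  A constant
  age column is dropped automatically, which reduces the test exactly
  to the pooled two-sample t.
- interaction: `y ~ 1 + group + age + group×age`.  The interaction
  coefficient is the TD slope minus the ASD slope; per-group fitted
  slopes are returned.
- clinical association: partial correlation of measure and score
  controlling age (both residualised on `[1, age]`; p from t on n−3
  df), clinical subjects only, equivalent to the score term of
  `measure ~ score + age`.

Zero-residual (numerically exact) fits are flagged with infinite t and
p = 0 rather than raising.  Regional p-values are corrected with
Benjamini–Hochberg **within each hemisphere** (two families of 34 in
the default scheme); NaN p-values pass through untested.  Demographic
age comparisons use the two-sided Wilcoxon rank-sum test, exact when
both groups have ≤ 10 untied observations.

Printed regional tables report raw GLM p-values alongside the
BH-adjusted ones; both columns are always emitted.

## Network-based statistic

Per-edge inference uses the same GLM (`weight ~ 1 + group + age`),
vectorised across edges.  An edge is eligible when nonzero in at least
90% of subjects (configurable) and non-degenerate; ineligible edges are
NaN in the t/p maps.  Components are formed from eligible edges with
`p < primary_p` (default 0.05, uncorrected) whose t matches the tested
direction — `asd_gt_td` (t < 0 under the TD − ASD convention) is the
default, matching the hyper-connectivity question; `td_gt_asd` and
`two_sided` are available.  Component size is counted in edges.

The permutation null shuffles group labels only; each subject keeps its
age, and the full GLM is refit inside every permutation (an alternative
that residualises age once and permutes two-sample t on the residuals
is exposed as `residualize_first`).  The corrected p of a component of
size `N` is the proportion of permutation maxima **≥ N**.  The
strictly-greater variant (`count_equal=False`) is also exposed because
some descriptions phrase the proportion as "larger than N"; on the
coarsely discrete null of component sizes that reading is
anticonservative — measured family-wise error ≈ 0.17 at nominal 0.05
under null simulations versus ≈ 0.04 for the `≥` estimator — so `≥` is
the default.  A `(b+1)/(m+1)` estimator that can never return exactly
zero is available via `plus_one`.

All permutation draws come from one `numpy` generator seeded
explicitly; identical seeds give bit-identical results.

## Synthetic cohorts

The generator emulates the statistical structure of a small
developmental case–control study: 21 TD subjects aged 1.99–5.96 y and
30 ASD subjects aged 2.33–7.00 y (uniform ages, males only — sex is
not a generator dimension), 68 nodes, integer edge counts thresholded
at 5.

A cohort-wide template first draws edge existence (intra-hemisphere
probability 0.45, inter-hemisphere 0.15, overall density ≈ 0.30,
typical of count-thresholded parcellation networks) and log-normal
baseline mean counts (log-mean 4.1, log-sd 0.8 → median ≈ 60
streamlines with a heavy right tail).  Subject-level counts are then
negative-binomial — streamline counts are overdispersed integers —
with

```
log μ_ij = log base_ij + β_group,ij · (age − 4.0) + δ_ij · 1[ASD] + s
```

where `s ~ N(0, 0.08)` is a per-subject global yield factor (overall
tractography output varies between subjects; this is the dominant noise
source for whole-network summaries), dispersion r = 8, and the
reference age 4.0 y sits mid-range so intercepts are interpretable.
Age effects act on the log scale, so planted slopes compound
multiplicatively, mimicking developmental strengthening.  The true
joint distribution of streamline counts is unknown; the NB form is an
explicit modelling assumption recorded in the config.

The frozen study-like preset plants:

- a global effect: β_TD = 0.10/y, β_ASD = 0.03/y, ASD offset 0.08 —
  calibrated so the TD age–Eg Pearson correlation averages ≈ 0.80, the
  ASD one ≈ 0.42, the age-adjusted global group t ≈ −3.2, and the
  slope-gap interaction is detected in ≈ 83% of cohorts at α = 0.05;
- nodal offsets δ = 0.15 at six regions (bilateral precuneus, caudal
  middle frontal and anterior-cingulate/isthmus/precentral picks
  mirroring reported hyper-connected sets).  The resulting standardised
  nodal-efficiency differences land near d ≈ 1.3; pushing them down to
  exactly d = 1 drops hemisphere-FDR detection below the 80% the preset
  is designed to deliver, because the planted slope gap dilutes the
  age-adjusted group coefficient;
- clinical scores with the published instrument means/SDs (ABC total
  94.39 ± 7.41, ADI-R 52.77 ± 6.92, CARS 41.03 ± 3.79, CABS
  18.03 ± 1.96), generated as baseline + κ·z(mean weight over coupled
  edges) + noise with (κ, σ) chosen to give both the printed SD and an
  age-adjusted partial correlation ≈ 0.45; ADI-R is deliberately
  uncoupled as a negative control.  TD subjects carry no scores.

Because the global offset applies to every edge, many non-designated
regions also shift; the designated nodes carry an additional local
offset on top.  Recovery tests therefore score detection on the
designated set only.

What the generator does **not** emulate: image-level physics
(no diffusion signal, tractography biases, motion), spatial
autocorrelation of neighbouring regions beyond the shared global
factor, non-uniform age distributions, and site/scanner effects.
Passing recovery tests demonstrates that the statistical machinery
detects the planted structure at the study's sample sizes — not that
any particular real-data finding is correct.

## Simulation sizes and numerical choices

- Family-wise-error calibration runs 500 study-size null cohorts
  (21 + 30 subjects, 68 nodes) at 200 permutations, giving a binomial
  standard error ≈ 0.009 on the rate in about a minute and a half; the
  long-run rate is ≈ 0.046, slightly below nominal because the
  max-component-size null is discrete.  On much smaller networks the
  discreteness is coarser and the estimator measurably more
  conservative (≈ 0.03 on 20-node cohorts).
- Power and correlation summaries use 200 full-size preset cohorts;
  interaction type-I error uses 2,000 GLM replicates on the study
  design.
- OLS uses QR with a rank check that names collinear columns; residual
  sums of squares at floating-point rounding level are treated as
  exact fits.
- Shortest-path agreement tolerance is 1e-9 relative; determinism
  checks compare output files byte-for-byte.

## Known limitations

- The regional report covers nodal efficiency (the regional measure the
  workflow is built around); other nodal metrics are computed and
  exported but not wired into the FDR report.
- The NBS assumes exchangeability of subjects under the null; no
  exchangeability blocks (e.g. for site) are implemented.
- No binary-graph metrics, small-worldness, rich-club or modularity;
  no mixed-effects or robust-regression variants; no motion covariates.
- Clinical correlations are exploratory (uncorrected p-values) and are
  restricted to regions that survive the group-difference FDR, as in
  the workflow the package reproduces.
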