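# Methods notes

This note records the modelling choices behind each stage, the parameters
that matter, what the synthetic generator does and does not emulate, and the
numerical details a maintainer would need.

## Synthetic study generator (`synth`)

The generator emulates the data layout of a grade-stratified TF study:

- **Binding prior**: an Erdős–Rényi digraph on `n_tfs = 500` TFs with edge
  probability `prior_density = 0.3` (≈75,000 ordered edges), standing in for
  a promoter motif-scan. Real binding priors are not ER — they have hub
  motifs and family structure — but for testing the coexpression filter only
  the prior's role as a candidate set matters.
- **Planted structures**: per grade, `planted_edges_per_grade = 50` single
  regulator→target edges plus `planted_ffls_per_grade = 21` FFL triples are
  drawn from the prior by rejection sampling. Structures are node-disjoint
  within a grade, pair edges must have no reverse prior edge, and FFL
  triples must realize the FFL pattern exactly (induced) in the prior. These
  restrictions make recovery metrics well-defined: without them, the
  reverse edge of a strongly correlated pair would pass any correlation
  filter and be scored a false positive, and a planted FFL with an extra
  prior edge among its TFs would not be an induced FFL downstream. 21 FFLs
  puts the last-grade FFL count at the order of magnitude of a real
  grade-specific network while keeping every TF triple distinct.
- **Expression**: non-planted TFs are iid Gaussian (mean 8, sd 1, a log2
  microarray scale). A planted edge u→v sets
  x_v = μ + a·(x_u − μ) + σ·ε with `σ = noise_sd = 1` and
  a = σρ/√(1−ρ²), so corr(x_u, x_v) = ρ = `planted_correlation = 0.8` in
  expectation. FFL bottoms respond to the standardized sum of top and
  middle with the weight w = ρσ/√((1+ρ)(1−ρ)(1+2ρ)), which gives all three
  FFL edges the same expected correlation ρ. ρ = 1 (or σ = 0) degenerates
  to an exact copy. Not emulated: microarray/RNA-seq noise families, batch
  effects, nonlinear regulation, negative planted correlations. Passing
  tests therefore demonstrate the filter's behaviour under clean linear
  coexpression at the configured strength, not robustness to real-data
  artefacts.
- **Grade dynamics**: each structure survives into the next grade with
  probability 1 − `edge_turnover` (default 0.7) and is otherwise redrawn,
  which reproduces the strong grade-specificity of real networks (~20–30%
  edge sharing at the default).
- **Survival**: exponential times with rate (1/12)·exp(Σβᵢ(xᵢ − x̄ᵢ)) on
  the three TFs of the prognostic FFL (`ffl_betas = (0.8, 0.8, 0.8)` per
  expression unit; the null median is ≈8 time units, nominally months).
  Censoring is independent Uniform(0, c) with the horizon c solved by
  1-D root finding so the expected censored fraction equals
  `censoring_rate = 0.2`. The IDH label is an independent
  Bernoulli(0.3) — deliberately unassociated with risk, so the Fisher test
  has a true null. Sample sizes default to 60 per grade per dataset (tens
  of samples per grade, as in real cohorts).
- **Reproducibility**: one global seed; every component (prior, truth, each
  (dataset, grade) expression block, each survival table) uses its own
  child stream keyed by fixed component tags, so any component can be
  regenerated bit-identically in isolation.

## Preprocessing (`preprocess`)

Redundant probes are collapsed by arithmetic mean; quantile normalization
maps every sample onto the row-mean-of-sorted-columns reference with ties
averaged over tied positions (exactly idempotent only on tie-free columns —
tie averaging perturbs the reference, which is why the idempotence test
generates tie-free matrices); the log transform is log2(x + 1), skipped for
data flagged as already log-scale; low-expression filtering drops the
⌈fraction·n⌉ genes with lowest mean expression (default 1%), computed per
dataset across all its samples, with ties broken by stable input order.
"Lowest mean expression" is our reading of the top-1%-low-expressed idiom;
the fraction is configurable.

## Network construction (`netbuild`)

Spearman is the default correlation (Pearson is a switch — the field uses
both and the choice is visible in the output evidence); p-values come from
the t approximation with n − 2 df and are deliberately uncorrected, since
the filter is a fixed raw threshold (|r| > 0.5, p < 0.01) replicated in
≥ 2 independent datasets. With k > 2 datasets the criterion is "met in at
least `min_datasets` of them". Sign consistency across supporting datasets
is required by default (a coexpression edge supported by opposite signs in
two cohorts is biologically incoherent) and can be disabled. Constant
expression vectors make the correlation undefined; such pairs are excluded
rather than aborting the run. Edges retained are always a subset of the
prior; network nodes are the TFs incident to a retained edge.

## Triad census and significance profiles (`motifs`)

Counts are induced-subgraph counts: each weakly connected unordered triple
increments exactly one of the 13 classes, so counts are disjoint and sum to
the number of connected triples. The class table is built by exhausting the
64 labeled 3-node digraphs and grouping by isomorphism; classes are ordered
by minimal adjacency encoding (stable across runs) and labeled with
standard sociometric names (030T = feedforward loop, 030C = cycle,
300 = clique, 201 = regulated mutual).

The null model is edge switching: random (a→b, c→d) ⇒ (a→d, c→b) swaps
that preserve every in/out degree, rejecting swaps that would create
self-loops or duplicates. With `preserve_mutual` (default), single edges
and mutual dyads are switched in separate pools (mutual pairs rewired as
undirected edges), so the reciprocal-dyad count is invariant — the
conventional choice for regulatory-network nulls; the flag exists because
"randomized networks of the same size" admits either reading.
`swaps_per_edge = 100` attempted switches per edge is the default mixing
heuristic; the heavier test-suite ensembles use 10, which the ER-null
calibration test shows is already well mixed at test scale (all invariants
hold for any swap count by construction). Z-scores use the sample sd
(ddof 1) of the randomized ensemble; a class with zero null sd gets Z = 0
when its real count equals the null mean and is flagged degenerate
otherwise (degenerate classes are reported, never dropped). The normalized
profile is Z/‖Z‖₂; an all-zero Z has no profile (the standalone normalizer
raises; the pipeline records an all-zero vector).

A caution from the test suite: a dense ER graph's TSP is pure noise
(|z| ≲ 2), but unit-normalizing noise can produce spuriously large cosines
with a real profile, so qualitative "profiles differ" claims are asserted
on Z magnitudes, not cosines.

## Hierarchy (`hierarchy`)

h = (O − I)/(O + I) with thresholds ±1/3 splitting [−1, 1] into equal
thirds (the literature says "h ~ 1 / ~ 0 / ~ −1" without printing cutoffs;
ours are config-exposed). Isolated TFs are unassigned rather than forced
into a level. Level transitions are reported for every ordered grade pair,
with TFs absent from the later grade recorded as dropped, and retention
computed among TFs assigned in both grades. The simulated-annealing
variant of hierarchy extraction is out of scope; the formula-based method
is the implementation.

## FFLs (`ffl`)

Induced matching is the default (consistent with the census, so the FFL
count equals the census's 030T entry — asserted cross-module in the tests);
a non-induced mode counts every (top, middle, bottom) assignment whose
three edges exist (a 3-clique then yields six). Positions map
driver/first-passenger/second-passenger to top/middle/bottom. Cross-grade
conservation counts a triple as identically maintained only with the same
induced wiring; "maintained as a combination" means connected in both
grades under any wiring. The conserved-edge profile runs the motif
pipeline on the edge-intersection network of two grades.

## Survival screen (`survival`)

Univariate Cox fits use a 1-D Newton maximization of the Breslow partial
likelihood with step halving and a Wald two-sided p. Breslow was chosen as
the simplest standard tie rule; the fit is cross-checked in the tests
against a brute-force grid maximization of an independently coded partial
likelihood (tolerance 1e-3) and against lifelines on tie-free data (where
Breslow and Efron coincide). Coefficients beyond |β| = 50 terminate the
iteration (separation); the FFL's regulatory structure is *not* used in
scoring — three independent univariate fits, by design. Risk-score ties at
the threshold go to the low-risk group (deterministic). The train/test
split is a seeded permutation with |train| = round(fraction·n); the
training median threshold and coefficients are reused unchanged on the
test half. No multiple-testing correction across FFLs by default (the
screen is a fixed raw p < 0.05 in both halves); a Benjamini–Hochberg
option exists but is off. k-means validation standardizes each TF to zero
mean/unit variance (flag-controlled), uses 10 restarts with the best
inertia, and reports the log-rank p between the two clusters, labels being
descriptive only. The bidirectional protocol screens in cohort A,
validates survivors in B, repeats in reverse, and intersects.

## Problem sizes

Defaults are the study conditions: 500 TFs, prior density 0.3, 3 grades,
2 datasets × 60 samples/grade, 1000 randomized networks per significance
profile. The test suite uses reduced ensembles (n_random = 100,
swaps_per_edge = 10, 48–50 replicate studies for screen calibration and
power) — sizes chosen so the whole suite runs in a few minutes while the
Monte-Carlo assertions retain comfortable margins.

## Known limitations

- The ER binding prior and linear Gaussian coexpression are idealized; no
  claim is made about robustness to real microarray/RNA-seq artefacts.
- The exact census is feasible to a few thousand edges; no sampling
  estimator is provided for larger networks.
- Only two-group log-rank, univariate Cox and k = 2 clustering are
  implemented — no covariate adjustment, competing risks or time-dependent
  effects.
- Indirect (partial-correlation) regulation is out of scope; edges are
  prior-constrained pairwise coexpression calls.
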