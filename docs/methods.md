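# Methods

This note documents the statistical models and procedures implemented in
`soilbiome`, the conventions chosen where several were defensible, and
what the synthetic-data tests do and do not establish about real data.

## Community preprocessing

**Rarefaction** subsamples each replicate's reads to a common depth
without replacement (one multivariate-hypergeometric draw per row, from a
seeded generator).  Rows below the depth are dropped with a logged
warning rather than raising: retaining partially sequenced replicates
would re-introduce the depth bias rarefaction exists to remove.  With the
default depth of 2000 reads, simulated replicates whose Poisson totals
fall below 2000 are discarded, so sites enter the analysis with between
one and five surviving replicates — a realistic source of between-site
noise that the downstream checks inherit.

**Replicate averaging** takes the arithmetic mean of the surviving
replicate rows per site, giving one representative community whose row
sum equals the rarefaction depth when all replicates reached it.

**Bray–Curtis** uses `scipy.spatial.distance.pdist`; the matrix is held
in a `skbio.DistanceMatrix`.  A row of all zeros is an error (its
dissimilarity to anything is undefined).

## PERMANOVA

One-way PERMANOVA follows the distance-based sum-of-squares partition:
`SS_total = (1/N) Σ_{i<j} d²_ij`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`,
`pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a))`, `R² = SS_between/SS_total`.
Significance is by free permutation of the group labels with the
`(1 + count)/(1 + n_perm)` convention, so p can never be zero and its
floor at 999 permutations is 0.001.  Note that when the observed grouping
is globally optimal, permutations that recreate it tie the statistic
exactly and are counted, so even a perfectly separated design typically
reports p slightly above the floor.  Pairwise tests rerun the statistic
on each pair's sub-matrix; the adjustment defaults to Bonferroni
(Benjamini–Hochberg available).  `skbio`'s PERMANOVA serves as an
independent cross-check of the pseudo-F in the test suite, and an
exhaustive enumeration over all label assignments validates the
Monte-Carlo p at 8 sites.

## Ward clustering and cut selection

`ward_cluster` implements Ward's minimum-variance agglomeration in the
Ward.D2 convention: the Lance–Williams update operates on squared
dissimilarities,
`d(AB,C)² = [(a+c)d(A,C)² + (b+c)d(B,C)² − c·d(A,B)²]/(a+b+c)`.
Ties are broken by the lexicographically lowest pair of cluster indices,
making the merge order fully deterministic.  Ward's coefficients satisfy
the reducibility condition, so greedy merging produces non-decreasing
heights; this is asserted.  The test suite compares the full merge
sequence against a brute-force oracle that recomputes each candidate
merge cost from the original squared dissimilarities via the
pseudo-centroid closed form, and against SciPy's `linkage(…, "ward")`.

Chemistry is standardized per variable (zero mean, unit variance over
complete rows) before Euclidean distances: the seven variables span
three orders of magnitude in natural units, and without standardization
AMN alone would dominate the geometry.

**Cut-level selection** computes, for every candidate k: mean silhouette
width (`s(i) = (b−a)/max(a,b)`, singletons 0 by convention), the Pearson
correlation over the strict lower triangle between the dissimilarity and
the binary different-cluster indicator, and — when an abundance table is
supplied — a species-fidelity profile (the count, and summed value, of
OTUs whose best cluster reaches IndVal = A·B ≥ 0.25).  Candidates whose
smallest cluster falls below `min_cluster_size` (default 5) are excluded
so every cluster keeps enough sites for stratified modelling.  The chosen
k is best on the most criteria, ties to the smaller k.  The vote makes an
inherently judgmental step auditable and deterministic; the full
diagnostics table is always returned.  A caveat observed in simulation:
the fidelity count is maximal at small k for diffuse assemblages (at
k = 2 every ubiquitous OTU has A ≈ 0.5, B ≈ 1), so it effectively votes
conservative; the silhouette and matrix-correlation criteria carry the
structure signal, and on planted-cluster scenarios the vote recovers the
true k in ≥ 90% of replicates.

**Dunn's test** ranks all observations jointly with mid-ranks, computes
`z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`
per pair, two-sided normal p, Bonferroni over the pairs.  Validated
against an independent rank-sum computation to 1e−10 including heavy
ties.

## Indicator statistics

For OTU k and cluster g, specificity `A(k,g)` is the group-size-corrected
abundance share (mean abundance in g divided by the sum of per-cluster
means; sums to 1 over clusters) and fidelity `B(k,g)` is the fraction of
g's sites where the OTU occurs.  Selection keeps OTUs with some cluster
where `A > a_min` **and** `B > b_min` — strict inequalities, so
thresholds of 1.0 select nothing.  Output is ordered by descending best
IndVal (A·B), ties by OTU ID.  Both components are computed per single
OTU; combination indicators are out of scope.  Whether published
specificity/fidelity screens use abundance- or presence-based components
varies; abundance-A with presence-B is the convention here, and both
matrices are exposed so callers can re-screen differently.  Selection is
provably monotone in the thresholds and invariant to global rescaling of
the table (property-tested).

## Probabilistic PCA

Chemistry ordination uses the latent-variable model `x = Wz + μ + ε`
with isotropic noise, fitted by EM.  Missing entries are marginalized
exactly in the E-step: for each site the posterior of `z` is computed
from its observed coordinates only (`M = W_oᵀW_o + σ²I`,
`E[z] = M⁻¹W_oᵀ(x_o − μ_o)`, `Cov[z] = σ²M⁻¹`).  The M-step updates μ, W
(row-wise over the sites observing each variable) and σ² as sequential
conditional maximizations, so the observed-data log-likelihood is
non-decreasing — asserted at 1e−8 every iteration.  Convergence is
relative log-likelihood change below `tol` (default 1e−8); σ² is floored
at 1e−9 so exactly low-rank data cannot make the likelihood singular.
After convergence W is rotated by SVD to the orthogonal,
variance-ordered form with a deterministic sign convention
(dominant loading positive), which makes the solution comparable to
classical PCA: on complete data the principal angles to the sample-PCA
subspace are below 1e−6 in the tests.  Variables are standardized on
their observed entries before fitting; two components are retained by
default.  This EM formulation was chosen over a full variational Bayesian
PCA with automatic relevance priors because the scores are consumed
directly (as regression targets and ordination axes) and the PPCA
maximum likelihood has a verifiable contract against classical PCA.

## Random-forest models

Splitting is stratified: within every stratum (land use, or chemistry
cluster), `round(0.8·n)` sites (nearest, ties up — e.g. strata of
61/72/139/334 sites give 49/58/111/267 training sites) are drawn without
replacement, with both sides kept non-empty.  Train/test disjointness is
asserted before every evaluation; leakage is a hard error.

Forests use 500 trees with sqrt(p) candidate features per split for
classification and p/3 for regression (the customary defaults of the
field's reference implementation), OOB scoring on, single-threaded for
determinism under a seed.  Regression accuracy is summarised by OLS of
predicted on actual held-out values — slope, intercept and
`adj R² = 1 − (1−R²)(n−1)/(n−2)` — with predicted as the response, the
direction that matches plotting predictions against an identity line.
Random-forest predictions shrink toward the training mean at the edges
of the target range, so slopes below 1 are expected even for strong
models; this matters for category scoring (below).

Permutation importance permutes one feature column at a time on
caller-supplied evaluation data (the pipeline passes the held-out set)
and reports the mean percentage increase in error (MSE for regression,
misclassification rate for classification) over `n_repeats` draws; if
the baseline error is exactly zero the absolute increase is reported.
Held-out data were chosen over out-of-bag samples because scikit-learn
exposes no stable per-tree OOB interface, and an explicit permutation on
a named dataset is reproducible and implementation-independent.  Top-k
(default 15) OTUs can be aggregated to phylum counts (missing taxonomy →
"unclassified") and across models into an overlap histogram.

## Quality categories

Breakpoint configs are YAML: per variable, per context (e.g. land use),
exactly four strictly increasing breakpoints delimiting the five ordered
categories, plus an optimal category (default "normal").  Intervals are
lower-closed/upper-open, so a value exactly on a breakpoint takes the
higher category — an arbitrary but documented and tested convention.  A
missing context falls back to `default`.  Outcome comparison works on
signed deviations from the optimal category: equal deviations → correct;
equal magnitude, opposite sign (nonzero) → opposite; strictly smaller
magnitude → better; otherwise worse.  The shipped
`example_thresholds.yaml` is synthetic and non-normative: it is shaped
like published guideline tables but is not a reproduction of any
authority's values, and real assessments must supply their own file.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with ground
truth recorded for recovery tests.

- **Design**: four land uses (indigenous forest, exotic forest,
  horticulture, pastoral grassland) drawn at configurable proportions
  (default 61/72/139/334 ≈ 0.10/0.12/0.23/0.55); five replicate cores
  per site; expected sequencing depth 2000 reads (Poisson).
- **Chemistry**: per-land-use multivariate normal on natural scales.
  Default means are plausible for temperate managed topsoils —
  carbon-rich, low-P natural forest (pH 5.75, C 8%, Olsen P 8 mg/kg);
  acidic exotic forest (pH 5.15); limed, heavily fertilized, compacted
  horticulture (pH 6.40, Olsen P 70 mg/kg, bulk density 1.20 t/m³);
  nutrient-enriched pastoral soils in between.  SDs
  (0.30, 1.5, 0.08, 25, 12, 3.5, 0.12) give realistic within-land-use
  spread.  The only structural correlation is macroporosity vs bulk
  density (default −0.6; compaction closes large pores).  pH is clipped
  to [3, 10], percentages to [0, 100], concentrations and bulk density
  floored just above zero — clipping on natural scales keeps the values
  directly usable by the threshold machinery.  Missingness is completely
  at random at a configurable rate (the simplest mechanism that
  exercises the PPCA missing-data path).
- **Counts**: per site, expected relative abundances are
  `softmax(baseline_k + Σ_v β_kv z_v + γ_k[land use])` with z the
  column-standardized latent chemistry.  Baselines are N(0, 1.5²),
  giving a right-skewed abundance distribution.  A random subset of
  `n_responsive_otus` OTUs carries the signal: each responds to a random
  half of the variables and land uses with coefficients of magnitude
  exactly `effect_size_chem` / `effect_size_landuse` and random sign.
  Replicates draw their composition from a Dirichlet with total
  concentration `overdispersion` (default 200 — substantial core-to-core
  heterogeneity, the reason the design averages five cores) and counts
  from the resulting multinomial.  The softmax link guarantees a valid
  simplex for any coefficients; the Dirichlet-multinomial (rather than
  plain multinomial) makes replicate overdispersion an explicit dial.
- **Determinism**: one scenario seed feeds independent per-stage streams
  (labels, chemistry, coefficients/counts, regions); identical configs
  are bit-identical.

**What passing tests show, and what they do not.**  The generator
produces exchangeable sites with no spatial autocorrelation, no
sequencing artefacts (chimeras, taxonomy error, variable library
quality), linear (in logits) chemistry–composition coupling, and
Gaussian chemistry.  Recovery of planted structure under these
conditions demonstrates that the chain is implemented correctly and has
the claimed power when its assumptions hold; it does not establish
field performance, where coupling is nonlinear, confounded with
geography and management history, and the responsive taxa are unknown.

## Reference scenarios and their outcomes

`soilbiome.scenarios` packages the desk-scale conditions used by the
reproduction script and the headline tests: a 300-site strong-signal
scenario (500 OTUs, 60 responsive, both effect sizes 2) for land-use
classification and the seven variable regressions, optionally with the
pH coefficients doubled; and a 200-site scenario whose chemistry means
form four clusters separated along two multivariate contrasts (a
pH/Olsen P/compaction pattern and a carbon/TN/AMN pattern, ±2.5
within-cluster SDs per variable) — separation on correlated blocks, as
in real soil condition classes, because standardization caps the
separation attainable on any single variable near 2 SD regardless of the
planted gap.

One known shortfall is documented rather than tuned away: the proportion
of held-out sites whose predicted pH maps to the correct quality
category plateaus near 80–85% under these conditions, short of the
87.5% reference. The boosted-pH forests reach adj R² ≈ 0.90–0.94
(slope ≈ 0.9), i.e. ~0.12–0.15 pH units of prediction error, and with
the default pH distribution a substantial share of sites lies within
half a within-class SD of a category breakpoint, so boundary sites set a
ceiling of roughly `1 − (boundary density × RMSE)`. Nearly all misses
are one category off, most of them "better" — the same behaviour seen on
real data.  The corresponding check is left failing with this analysis
rather than widened.

## Problem sizes and numerical choices

Simulated checks run at 40–300 sites, 80–500 OTUs, depths 300–2000 and
99–2000 permutations — sizes chosen so the whole suite exercises every
path at desk scale.  Convergence and tolerance defaults: PPCA tol 1e−8
(tests tighten to 1e−13 when comparing subspaces), EM σ² floor 1e−9,
Ward tie-break by lowest pair index, permutation p floor by the +1
convention, importance tie-break by OTU ID, stratified rounding
nearest-ties-up.  All randomness flows from explicit integer seeds;
reruns of any pipeline invocation are byte-identical.

## Known limitations

- Single-OTU indicators only; no permutation significance on IndVal.
- No NMDS/ordination plotting; figures are out of scope.
- The example thresholds file is illustrative; category accuracies
  under it reflect the synthetic conditions, not any guideline's
  difficulty.
- PERMANOVA is one-way only (land use or cluster), matching the design
  it serves; no nested or multi-factor designs.
- OOB-based permutation importance is not offered; importance is
  computed on a named evaluation set.
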