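# Methods

This note records the models implemented in `adaptscape`, the assumptions
behind them, the parameters that matter, and the design choices made where
the methodology admitted more than one defensible construction. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Genotype QC (`adaptscape.genotype`)

Filters operate on the biallelic dosage matrix (0/1/2, NaN missing):
per-genotype depth mask (`DP < 5` → missing; skipped with a log line when
the VCF carries no DP), then sequentially mean depth < 5, MAF < 0.01
(computed on non-missing genotypes), and missingness ≥ 10% — the boundary
itself is removed for missingness and retained for depth, matching the
strict/inclusive reading of the filter definitions. LD pruning slides
windows of 50 variants by steps of 10; within a window, while any surviving
pair has squared dosage correlation above 0.1, the later-positioned member
of the worst pair is removed. This greedy later-removal rule is one of
several deterministic choices that satisfy the only property that matters
downstream — no surviving within-window pair exceeds the threshold — and
small numerical differences from PLINK's genotype-count r² estimator are
expected and acceptable. "Most common" imputation is the modal dosage class
per SNP, ties broken toward the smaller dosage (deterministic, and unbiased
toward the reference allele for balanced ties).

## Structure and GEA (`adaptscape.structure`)

* **PCA** is the SVD of the column-centered dosage matrix.
* **Distances**: Haversine on a 6371-km sphere for geography; Euclidean on
  imputed dosages for genotypes; Euclidean on standardized climate for
  environment.
* **Mantel / partial Mantel**: Pearson correlation of lower triangles;
  one-sided permutation test shuffling rows/columns of one matrix jointly,
  `p = (count + 1)/(n_perm + 1)` (999 permutations by default — the
  permutation count is configurable since published analyses rarely state
  it). The partial test correlates residuals of both triangles after linear
  regression on the covariate triangle, permuting the first matrix.
* **RDA / pRDA**: with conditioning variables Z, both the response and the
  predictors are replaced by their least-squares residuals on [1, Z]; the
  constrained axes are the SVD of the fitted values of the multivariate
  regression of Y on X. Fitted values are computed by orthogonal projection
  onto the *effective* predictor space: predictor directions whose singular
  value collapses under conditioning (below 1e-9 of the pre-conditioning
  spectral norm) are dropped, so that conditioning on Z = X correctly yields
  zero constrained variance instead of amplifying numerical residue.
* **Variance partitioning** reports each group's unique fraction (pRDA
  conditioned on the other two groups), the confounded remainder of the
  full-model fraction, and the unexplained fraction; they sum to 1 by
  construction. Significance is by permutation of the residualized
  predictor rows.
* **Outlier scan**: geography is encoded as standardized lat, lon and their
  product; structure as PC1 (the number of PCs is configurable — a single
  PC is the conventional, deliberately light-handed structure correction
  for range-wide data with high gene flow). Constrained-axis significance
  uses 250 row permutations of the residualized climate on a subset of at
  most 100 000 loci; the leading run of axes significant at 0.05 is
  retained. Each locus's loadings on the retained axes are z-scaled per
  axis; the Mahalanobis distance is the sum of squared z-scores; the
  genomic inflation factor is `median(d²)/χ²₀.₅(K)`; p-values come from
  `χ²(d²/GIF, df = K)`; candidates are `p < 0.01/n`. When no axis is
  significant the outlier set is empty (with a warning), but the d²/GIF
  machinery still runs on the leading axes as a calibration diagnostic.
  This Mahalanobis/GIF construction is the established companion procedure
  to pRDA-based outlier detection; the permutation test for axis
  significance is known to be anti-conservative when predictors are
  spatially replicated, which is why the Bonferroni locus-level threshold —
  not the axis count — carries the error control.

## Offset engines (`adaptscape.offsets`)

All engines are fitted on candidate loci against standardized climate at
the sampled individuals; grids are standardized with the *recent* scenario's
mean/SD only, matching the train-on-current / predict-on-future contract.
Each engine exposes `embed` / `pair_offset` so per-cell surfaces and dense
donor × recipient transfer matrices use the same code path, and
`adaptedness = −offset` is enforced at the container level.

**Gradient forest.** One random forest per locus (default 500 trees, all
features available per split, `min_samples_leaf = 15`). Dosages are noisy
three-level responses, so small leaves would spend split importance on
binomial noise; the leaf floor keeps splits on genuine turnover, and with a
single driving variable > 90% of cumulative importance lands on it (this is
asserted in the tests). Per locus, split impurity reductions are normalized
to sum to one and weighted by the out-of-bag R² (floored at 0; loci with
R² ≤ 0 are excluded, and an all-negative set is an error). Per variable,
importances are binned into 101 bins over the observed range, standardized
by the ratio to the observed data density (floored at 1e-6), rescaled to
preserve the total, and cumulated into a monotone turnover curve. Curve
evaluation is a left-continuous step function (the mass of bins whose right
edge is ≤ x), zero at the variable's minimum, clamped to the end value
beyond the fitted range — so out-of-range future climates saturate rather
than extrapolate.

**RDA adaptive index.** The climate coefficients of the retained constrained
axes define linear indices; the offset is the eigenvalue-share-weighted
Euclidean distance between index vectors. The default retains the same
number of axes the outlier scan found significant (two, in the analysis
this package reproduces). Being linear, this engine does not clamp.

**GDM.** The response is the pairwise Euclidean distance between site
allele-frequency vectors, rescaled into [0, 1); per variable, three
order-2 I-splines (integrated tent densities) with knots at the min, median
and max of the site values; `η = intercept + Σ c_b |I_b(v_i) − I_b(v_j)|`,
dissimilarity `1 − exp(−η)`, with `c_b ≥ 0` and intercept ≥ 0 fitted by
Gauss–Newton iterations, each solving a non-negativity-constrained least
squares on the linearized link (initialized at the exact solution of the
log-linearized problem). The intercept is a between-site sampling effect
and is excluded from the within-cell current→future prediction — otherwise
the defining identity offset(c, c) = 0 would fail. Euclidean frequency
distance (rather than Fst) is the default response; it is configurable via
the precomputed-response argument.

**Variable importance** is engine-native: total curve height (GF), summed
spline coefficients (GDM), eigenvalue-weighted squared coefficients (RDA);
ties break alphabetically.

## Seed transfer (`adaptscape.transfer`)

The transfer offset of (donor d, recipient r) is the engine offset between
d's current-climate embedding and r's future-climate embedding; the same
matrix underlies reverse (row-mean) and forward (column-mean) adaptedness.
Priority uses a strict inequality — a donor that merely ties the recipient's
no-transfer baseline counts as no improvement — and the distance from a
donor cell to a focal *site* is the minimum Haversine distance to any focal
cell (the inclusive reading of a radius around a site). Cells are the
atomic unit: no sub-cell donors or recipients.

## Method comparison (`adaptscape.compare`)

Raw offsets are not comparable across engines (different spaces and units),
so comparison is scale-free: (i) Spearman rank correlation between per-cell
offset maps, per scenario; (ii) orthogonal Procrustes superimposition of
per-cell engine embeddings reduced to three principal components, after
centering and unit-norm scaling, with per-cell residuals mapping the spatial
disagreement and an optional PROTEST-style permutation p (999 by default).
Configurations of unequal dimension are padded with zero columns before
rotation. The nested protection ANOVA
(`adaptedness ~ protection * model/rcp/year`) is computed by explicit
sequential (Type I) decomposition with rank-increment degrees of freedom —
this reproduces R's `aov` semantics exactly and keeps the df partition
complete even when the nesting expansion is column-redundant; Tukey HSD
uses the studentized-range adjustment. Grid cells are treated as
independent observations, as the fixed-effects formula implies; spatial
autocorrelation is a known limitation, acknowledged rather than modeled.

## The synthetic landscape (`adaptscape.landscape`)

The generator produces the conditions the analysis assumes, at desk scale:

* **Grid**: 30 × 30 cells of 10 km (longitude spacing corrected by
  1/cos(latitude)), six climate variables. Each variable is a planar
  broad-scale gradient (random orientation, spanned by lat/lon/lat×lon —
  the classic trend-surface space) plus a dominant cell-level component
  (`noise_sd = 2.0` before standardization) that mimics fine-scale
  topographic climate variation; the recent grid is standardized to
  mean 0 / SD 1 over cells.
* **Scenarios**: eight futures (warm-wet and hot-dry model analogues × RCP
  4.5/8.5 × two periods), each displacing variables by a nominal SD shift
  scaled by RCP and period. The displacement varies smoothly in space
  (`perturbation_sd = 0.5`) and is partly anti-correlated with the baseline
  field (`displacement_baseline_coupling = −0.6`; cooler/higher cells shift
  more), so displacement magnitude — not only position on the turnover
  curve — structures the offset maps.
* **Sampling**: 171 individuals at 10 sites (unbalanced by default, a few
  intensively sampled sites among sparser ones; configurable to balanced),
  scattered within ±3 cells of the site center, so each site spans a local
  climate gradient — the within-site sampling resolution the downstream
  conditioning depends on.
* **Neutral loci**: site-level logit-normal frequency fields with two
  components — a weak range-wide cline (Gaussian kernel, range 100 km, SD
  0.2) producing isolation by distance, and stronger site-idiosyncratic
  drift (SD 2.0) that dominates the leading axes of genetic structure. The
  drift term is what makes PC1 a *structure* covariate rather than a proxy
  for the climate cline at this locus count; at whole-genome scale the
  same role is played by the sheer number of neutral loci.
* **Adaptive loci**: logit p = logit(p₀) + effect × driver value *at the
  individual's cell* (default effect 2 per SD of tmx), with p₀ drawn at
  intermediate frequency (0.25–0.75) so clines stay unsaturated and
  polymorphic; frequencies are clamped to [0.01, 0.99] with a logged count.
  Dosages are Binomial(2, p); missingness is uniform (default 2%).
* **Determinism**: one `numpy` Generator keyed by the config seed; identical
  config + seed gives bit-identical grids, genotypes and fixtures.

What the generator does **not** emulate: coalescent genealogies, linkage
between loci, selection dynamics through time, realistic site-frequency
spectra, or the paper-scale ratio of neutral to adaptive loci. The
fixture's isolation-by-distance signal (Mantel r² ≈ 0.4, driven by site
drift) is considerably stronger than the weak IBD typical of
high-gene-flow, range-wide tree samples; passing tests therefore
demonstrate that the pipeline's statistics behave correctly under a
*known* spatial-genetic structure, not that any particular real dataset
would yield the same maps.

## Numerical and scale choices

* Null calibration and power checks run at 100 individuals × 1000 neutral
  loci (20–50 replicates) and 171 × 1020 with 20 planted clines (3
  replicates); the full pipeline fixture is the 30 × 30 / 171-tree default.
  These sizes keep any single check under a few minutes on one core while
  leaving the Bonferroni threshold (≈ 1e-5) meaningfully strict.
* Axis permutations: 250; Mantel: 999 (199 inside the pipeline);
  variance-partition permutations: 49–99.
* Degenerate inputs: 1×1 grids, empty donor/recipient sets, all-missing
  SNP columns, zero-variance climate variables and mismatched grid
  geometries are rejected with named errors; an all-equal ANOVA response
  returns F = 0 throughout.
* All stochastic fits accept a seed and record their parameters; the run
  manifest stores artifact paths relative to the run directory so two runs
  of the same config and seed are byte-identical.
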