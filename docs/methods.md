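# Methods

This note documents the models, conventions and design choices behind
`adiponiche`, in the order the pipeline runs them.

## Transcript quality control and binning

Per-transcript decoding quality (QV) is filtered strictly: a transcript is
retained iff QV > 35, so a transcript at exactly 35 is removed. The filter
is idempotent and order-preserving.

The segmentation-free tissue map uses half-open square bins
`[x0+i·s, x0+(i+1)·s) × [y0+j·s, y0+(j+1)·s)` with s = 50 µm. The grid
origin is the minimum retained coordinate floored to a multiple of the bin
size — deterministic per sample and stable under data duplication; bins are
anchored per sample, not globally across samples. A bin is kept downstream
iff its total transcript count is strictly greater than 10. Conservation
holds by construction: bin totals sum to the number of retained
transcripts.

## Transcript-to-cell assignment

**Nucleus mode.** Distance is measured to the nucleus polygon (0 inside),
falling back to the centroid when no polygon exists; the convention used is
recorded in the output metadata. "Within 2 µm" is closed (≤ 2.0): the
inclusive reading of *within*, applied consistently everywhere, including
boundary mode and tests. Assignment is single-target — the nearest nucleus,
ties broken by the smaller object id. Cells are kept iff they have strictly
more than 40 transcripts. The STRtree-based search is required by tests to
agree exactly with exhaustive polygon-distance scans.

**Boundary mode.** Adipocytes are pixel masks (area = pixel count × pixel
area; 1 µm pixels by default). Cells are gated strictly to areas in
(1,000, 25,000) µm². Transcripts the caller attributes to non-adipocytes
(typically nucleus-mode assignments to non-adipocyte cells) are dropped
before assignment. A transcript whose containing pixel belongs to exactly
one retained cell is that cell's at distance 0; otherwise it is assigned to
*every* retained cell whose nearest mask pixel centre lies within 2 µm —
multi-assignment is deliberate, and a multi-assigned transcript contributes
a full count to each cell. The mask-based workflow replaces manual
gap-closing of weak membrane stains with the requirement that input masks
be closed, plus an optional marker-fraction contaminant flag
(`flag_contaminants`); this simplification is recorded in the matrix
provenance (`uns`).

**Normalization.** Nucleus-mode matrices are scaled to 10,000 counts per
cell (the single-nucleus convention); boundary-mode matrices to per-cell
proportions (target 1), since the purpose there is the size–expression
correlation. The ln layer is log1p of the normalized layer in both cases.

## Gene-set (stress) scoring

Genes are stratified into 25 equal-frequency bins by mean ln expression
over all cells; min-ranking keeps tied genes in one stratum, so a constant
matrix degenerates gracefully to a single stratum. For each target gene, 50
control genes are drawn uniformly without replacement from its stratum
(excluding all targets; with replacement plus a warning when the pool is
smaller). The score is the mean ln expression of the targets minus the mean
over the pooled controls. The same routine scores cells and 50-µm bins.
Control matching makes the score location-invariant in expectation:
shifting all genes equally cancels.

A caveat inherent to control matching: a shift applied to target genes
*moves them across strata*, so the score recovers a planted shift only when
the targets remain inside their stratum (wide strata or within-stratum
shifts). The test suite constructs its shift-recovery oracle accordingly.

**Stress maps.** Bin-level scores can be displayed raw (`identity`) or, by
default, clipped below at zero and log1p-transformed (`log1p_clipped`) —
the clipped log keeps the zero-stress baseline at 0 while compressing high
scores; negative scores (below-control expression) carry no meaning for a
"stress burden" map. The transform used is recorded in the output metadata.

## Zonation

Cells are binned on the 50-µm grid; each cell inherits its bin's mean
score; quartile cut points are the empirical quantiles over *cells*, pooled
across conditions (cell-level rather than bin-level quantiles, because the
readout is the percentage of cells per quartile; a per-sample option
exists). Intervals are left-closed with ties resolved downward, so a
constant score puts every cell in Q1. Cells in dropped (low-count) bins are
excluded and reported as an unzoned remainder. Each populated state's
quartile percentages sum to 100.

## Niches

Each cell's neighbourhood is the set of cells within 300 µm (closed) in
the same sample, excluding itself — a cell should not count toward its own
microenvironment. The composition row is the percentage of neighbours per
state; rows with zero neighbours are flagged and excluded from clustering.
Percentage normalization is what removes the density asymmetry: obese
adipocyte hypertrophy halves the neighbour count, and on matched synthetic
lean/obese tissue the mean L1 difference between matched niches' mean
compositions stays below 10 percentage points.

Clustering builds a symmetrised k-nearest-neighbour graph (k = 30) on the
composition vectors (z-centred per sample when a batch key is given — a
simple, auditable alternative to embedding-level batch correction) and runs
Leiden at resolution 0.2. Cluster pairs whose mean compositions lie within
Jensen–Shannon distance 0.05 are merged iteratively, each merge logged.
Because compositions blend smoothly across niche borders, the graph cut can
land off-centre in the transition zone; three nearest-centroid sweeps
re-centre the decision boundary at the composition midpoint (set
`refine_iters=0` for the raw partition). The k/resolution defaults were
chosen so that five planted niches at realistic separations are recovered
stably; higher resolutions fragment the composition gradient into boundary
strips.

The niche × state summary divides each state's niche percentages by the
state's maximum across niches (per-state scaling to [0, 1]).

**Colocalization** answers a contact-scale question (default radius 30 µm,
distinct from the 300-µm niche scale): observed state-pair adjacency counts
are compared to shuffling state labels over fixed positions within sample.
z = (obs − mean)/sd of the null; where the null is degenerate (sd = 0) the
z is reported as 0 and flagged. The empirical upper-tail p uses the
standard (1 + exceedances)/(1 + permutations) estimator. This permutation
machinery is this package's own construction — a stated stand-in for a
procedure whose details are not standardised.

## Size–expression correlation

Areas come from pixel masks with the strict (1,000, 25,000) µm² gate.
Spearman ρ (average ranks for ties, Pearson on ranks) relates per-cell
normalized expression to area in each condition separately and combined;
p-values are two-sided, via the t approximation for n ≥ 10 and exact
permutation enumeration below. A gene is selected when p < 10⁻⁵ in at
least two of the computed correlations; selected genes are ranked
high-to-low by the combined-stratum ρ (the combined column is the ranking
key; configurable). Constant genes yield missing ρ and are never selected.
Rank-based correlation makes any additional monotone per-cell transform of
expression irrelevant; the cross-cell normalization choice (proportions)
is recorded in the matrix metadata.

## Exact binomial sign tests

The two-sided p-value uses the minimum-likelihood rule: sum the null
probability of every outcome whose point mass does not exceed the observed
one, with a relative tie tolerance of 10⁻⁷ to stabilise floating-point
comparisons at the fringe. All point masses are log-factorials and the sum
is log-sum-exp, so the test is exact and underflow-free far below
p = 10⁻³⁰⁰ (`log10_p` stays finite). The doubling-the-smaller-tail rule
would produce different values for the published anchor inputs; the
minimum-likelihood rule reproduces them, which the acceptance suite checks
at two significant figures. Benjamini–Hochberg step-up (with cumulative
minimum) is the FDR procedure throughout. Wilcoxon/Mann–Whitney rank tests
delegate to scipy with exact small-sample modes below n = 25.

## Synthetic tissue

The generator emulates the statistical structure of the real sections, not
their morphology:

* **Geometry.** Cells are discs: adipocytes large (log-normal diameters,
  median 55/110/75 µm for lean/obese/weight-loss, σ_log = 0.25 — obese
  twice lean), other states small (6 µm). Only nuclei (4-µm 12-gons) are
  packed without overlap (12 µm minimum separation, dart throwing;
  impossible packings raise). Adipocyte masks are rasterised at 1 µm.
* **Field and niches.** 2,000 × 5,000 µm with five horizontal 1,000-µm
  bands (adipocyte, stress, stem, arterial, venous niches), each with its
  own state-composition vector; band height was chosen large relative to
  the 300-µm neighbourhood radius so planted communities are recoverable,
  and configs whose compositions differ by less than a configurable L1
  margin are rejected at validation.
* **Density asymmetry.** 2,000/1,000/1,400 cells per condition in the same
  field reproduce the ~2× lean:obese neighbour-count ratio that motivates
  the composition normalization.
* **Expression.** Per cell × gene Poisson counts at per-state rates. The
  default 128-gene panel has the 24-gene stress set (strong in stressed
  adipocytes, moderate in adipocytes), two markers per state, and 90
  background genes spanning five expression strata (so the scorer's
  control pools cover the stress genes' strata).
* **Area coupling.** The stress-gene rate multiplier in adipocytes is
  exp(τ·w) with τ = 0.8, where w is a latent normal correlated with the
  diameter's latent z at Pearson c = 2·sin(π·ρ_s/6) — the inverse of the
  bivariate-normal rank-correlation formula — so the rate–area Spearman
  equals the configured target. Poisson discretisation attenuates the
  *count*-level correlation; `area_coupling_config` provides a
  high-expression (mean 30/cell) all-adipocyte tissue in which the planted
  ρ = 0.5 is recovered within ±0.15 through the full boundary-assignment
  and normalization path.
* **Noise.** Transcript positions are uniform in the cell disc (40%
  perinuclear) plus 0.5 µm Gaussian jitter, exercising the 2-µm radius.
  QV is a two-component normal mixture (high N(40, 2), low N(25, 5)) whose
  low-component weight is solved so P(QV ≤ 35) equals the configured
  fraction (default 0.10). Background transcripts (2 × 10⁻⁵ /µm²) carry
  random genes and no source cell.
* **Determinism.** One `numpy` generator seeded from the config; identical
  (config, seed) reproduces every table bit-for-bit.

What the generator does *not* emulate: irregular cell morphology (discs
only), crown-like macrophage ring geometry (an open question in the field's
quantification; not claimed), 3-D structure, optical artefacts, or
per-gene overdispersion beyond Poisson. Passing tests therefore demonstrate
algorithmic correctness and statistical behaviour under the planted model,
not performance on real sections.

## Problem sizes

Defaults were sized so a full three-condition pipeline runs in well under a
minute on one core: ~2,000 cells and ~200k transcripts per lean section.
The acceptance script uses 10 generator seeds for niche recovery and one
500-adipocyte section for the coupling measurement; the test suite uses 20
seeds for the recovery criterion.

## Known limitations

* Niche recovery is measured against planted bands whose borders are
  genuinely ambiguous at the neighbourhood scale; ARI ≈ 0.9 is the
  practical ceiling under the default geometry, not a method failure.
* The colocalization null conditions on positions and label counts only;
  it does not model within-state spatial autocorrelation.
* Batch handling for niche clustering is per-sample z-centring, not an
  embedding-level correction; with strongly imbalanced state abundances
  across samples the two can differ.
* The boundary-mode distance is measured to pixel *centres*; at 1 µm
  pixels this differs from the true mask boundary by at most ~0.7 µm.
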