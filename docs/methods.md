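# Methods

## Indices and their conventions

All five indices are computed per site from non-negative specimen counts and
a taxon trait table (family, order, dispersal ability group, tolerance).

- **H′** uses the natural logarithm by default (`base` is an option). An
  all-zero site is undefined (NaN), never zero.
- **BMWP** is presence-based: any count ≥ 1 makes a family "present", each
  scoring family counts once. Taxa whose family is missing from the score
  table are excluded and tallied in `n_excluded_taxa` rather than scored
  zero. The packaged score table is the original UK family score set;
  regional tables can be supplied because scores are known to transfer
  poorly between biogeographic regions.
- **ASPT** = BMWP / number of scoring families; undefined when no scoring
  family is present, and such sites drop out of the ASPT grading
  denominator.
- **BI** is computed at taxon level with taxon tolerances; taxa without a
  tolerance value are removed from both the numerator and the denominator
  (they carry no information about tolerance composition). An opt-in
  family-level fallback can fill missing taxon tolerances from the packaged
  family table; it is off by default because no single fallback rule is
  standard.
- **EPT** deduplicates at family level: several genera of one mayfly family
  contribute one unit.

## Health grading

Each index maps to five ordered classes over right-closed intervals
"(a, b]". The BI scheme is inverted (low BI = Excellent). The printed
criteria leave two gaps, which we close by extending the *lower* class so a
gap can never raise a site's grade: ASPT has no class on (3.0, 3.1], so Fair
becomes (3.0, 3.5]; the EPT criteria skip (27, 28], so Good becomes
(20, 28]. The bottom class of each scheme is closed at its printed lower
bound (e.g. H′ = 0 grades Very poor) so grading is total over each index's
attainable range; a dense-sweep property test enforces totality and
uniqueness. Grade percentages are always reported over the denominator of
sites with a *defined* index value — undefined values are excluded, not
imputed.

## Dispersal-group filtering

The modified community matrix removes whole dispersal ability groups
(default {DAG01, DAG04}); which groups are "dispersal dominated" is a
configuration parameter, not something this package re-derives — the
variance-partitioning evidence for the default lives upstream. Taxa with an
unrecognised or missing DAG are never removed. Sites are retained even when
the filter empties them (their modified indices become undefined). Removal
is monotone for the presence-sum indices (EPT, BMWP, family richness) and
idempotent; both are asserted as properties.

## Comparison statistics

**Collinearity screen.** Pairwise Spearman correlations over the environment
table; pairs with |r| ≥ 0.75 are flagged. Callers can name the variables to
drop (the ecological choice — e.g. dropping NO3–N in favour of TN because
nitrate is a component of total nitrogen); otherwise a greedy heuristic
removes the flagged variable with the highest mean |r| against the remaining
set until no flagged pair survives. Constant variables have undefined
correlations and are dropped up front.

**Spearman matrix.** Two-sided r/p per (index, variable) pair on pairwise
complete cases; pairs with fewer than three observations stay undefined.
Display orders come from complete-linkage hierarchical clustering on
Euclidean distances of the correlation rows/columns (the convention of the
common heatmap tools); the clustering only orders output, it never changes
values.

**Random-forest regression.** 500 trees, `mtry = ⌊p/3⌋` (min 1), terminal
nodes of ≥ 5 samples — the standard regression-forest defaults. The forest
is built from seeded bootstrap draws over regression trees so each tree's
out-of-bag (OOB) set is known. %IncMSE for predictor j is

    100 × mean over trees of (OOB MSE with column j permuted − OOB MSE) / forest OOB MSE,

a literal percent increase in out-of-bag error under permutation. (The
widely used R implementation's `scale=TRUE` variant divides by a standard
error and is a z-score despite the % label; we report the interpretable
percent form.) Model fit is OOB percent variance explained,
R² = 1 − MSE_oob/Var(y), which is negative when the forest predicts worse
than the mean — the expected outcome for a pure-noise response.
Per-predictor significance is a response-permutation p-value: the response
is permuted (default 500 times), the forest refit on 100-tree null forests,
and p is the upper-tail frequency of null %IncMSE ≥ observed, with the +1
correction. The 100-tree null size and the smaller permutation counts used
by the analysis drivers are problem-size choices documented here; p-values
are reported raw (star thresholds .05/.01), with an optional Holm
adjustment helper. Within each analysis, sites with undefined index values
are dropped case-wise.

**Kruskal–Wallis.** Two-group, tie-corrected H with the chi-squared
approximation (df = 1). When every pooled value ties, H = 0 and p = 1 by
convention. Tests compare the distribution of each original index against
its modified counterpart across sites.

## Synthetic metacommunity generator

The generator emulates the sampling design the analysis assumes rather than
any particular catchment: 147 sites uniform on a unit square; an
"elevation-like" latent axis following the spatial layout plus noise and an
independent "pollution-like" axis, both standardised; 147 taxa split
49/70/11/17 across DAG01–DAG04, drawn from field-realistic family pools so
BMWP/EPT machinery operates on real family names.

Expected abundance is a product of Gaussian niche responses on the two axes
with common breadth σ = 0.75, and a lognormal base abundance (median 2,
log-sd 1.0) giving a realistic rank–abundance profile; counts are Poisson
(negative-binomial overdispersion is an optional knob). These defaults were
chosen to produce field-plausible communities — median site richness ≈ 15–25
taxa, H′ spanning the Good/Fair grades, EPT ≈ 5–15 — rather than the
saturated communities a flat parameterisation yields. Pollution optima are
drawn uniformly on [−3, 1.5] (skewed low: most macroinvertebrate taxa are
pollution sensitive), so richness and diversity decline along the pollution
axis; tolerance values are the affine image of the pollution optimum in
[0, 10] plus Gaussian noise (sd 1.2, then clipped), and 10% of taxa lack a
tolerance value to exercise the BI exclusion rule.

Dispersal corruption: DAG01 expected abundance is multiplied by
exp(−d/λ) from a per-taxon random source locus (default λ = 0.2 on the unit
square, i.e. strong limitation; λ = ∞ disables it). DAG04 abundance is the
mixture (1−w)·niche + w·field with default w = 0.9, where the field is a
smooth random-bump surface independent of the environment (range 0.3). The
defaults therefore represent a regime where dispersal processes strongly
structure both groups, which is the condition under which removing them
should pay off; w = 0 with λ = ∞ is the species-sorting control.

The environment table embeds the axes in named variables with fixed
loadings (chemistry on pollution; terrain on elevation; land use on both),
derives NO3–N from TN (r ≈ .9) and Cropland/Impervious from Forest
(|r| ≳ .8) so the collinearity screen has realistic work, and fills the
remaining variables with i.i.d. noise; all columns are affine-rescaled to
field-plausible means/ranges and clipped. Ground truth (axes, niche
parameters, loadings, coordinates) travels with the bundle.

**What the generator does not emulate:** dendritic river-network topology
(sites live on a plane with Euclidean distances — the mechanisms tested,
distance decay and smooth fields, do not need network structure), temporal
dynamics, sampling-effort variation between sites, taxonomic misidentification,
and any real species pool. Passing tests therefore show that the pipeline
detects dispersal-induced signal loss *when the generating mechanisms are as
modelled*, not that any particular field dataset behaves this way.

## Operationalising the headline comparison

The claim under test is directional: with strong dispersal corruption,
removing DAG01/DAG04 should *increase* the seed-averaged |Spearman r|
between H′/BI and the true pollution axis. The control (w = 0, λ = ∞)
cannot show a systematic *improvement* — removal only discards
environment-informative taxa there, so a small loss is expected — and the
check asserts exactly that: gain > 0 under dispersal, gain ≤ 0.05 (no
spurious improvement beyond noise) in the control, and dispersal gain >
control gain. Twenty seeds per regime at the default scale keep the
comparison stable and desk-fast.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded per run;
  pipeline outputs are a pure function of (inputs, config, seed), asserted
  byte-for-byte on the CSVs.
- Undefined index values propagate as NaN everywhere; they are excluded
  from grading denominators, correlation pairs and RF training cases, and
  never filled.
- Grading boundary ties resolve to the lower class by the right-closed
  convention; the out-of-range case (a value below a scheme's bottom bound)
  is a hard error rather than a silent clamp.
- The Kruskal–Wallis all-tied case short-circuits to H = 0, p = 1 because
  the tie-corrected statistic is 0/0 there.
- `FilterSpec` rejects unknown group names; "unknown" DAG taxa always stay.

## Known limitations

- BMWP scores and tolerance values are biogeographically specific; the
  packaged UK/North-American tables are reference defaults, not regional
  truth, and absolute BMWP/ASPT/BI levels shift with the table choice.
- %IncMSE permutation p-values are a pragmatic stand-in: no standard
  significance procedure exists for RF importance, and permutation nulls at
  500 × 100 trees are Monte-Carlo noisy below p ≈ 0.01.
- The greedy collinearity heuristic is order-dependent in pathological
  correlation structures; overrides exist precisely because the right drop
  is an ecological judgement.
- The simulator's DAG04 mass-effect field is spatially smooth but static;
  real source–sink dynamics are temporal.
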