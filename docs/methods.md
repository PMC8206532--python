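# Methods

## Model and selection criterion

The core task is best-subset linear regression: for a response y (a
developmental composite score) and t candidate predictors X (baseline
scores and per-taxon relative-abundance fractions at two timepoints),
find for each size p the support S, |S| ≤ p, minimizing the residual sum
of squares of the OLS fit, and then the 2nd…k-th best distinct supports
of each size. Predictors and response are standardized to mean 0 and
sample SD 1 (n−1 denominator) before the search, so a coefficient is the
response change in SD units per SD of predictor; zero-variance columns
cannot be standardized and are removed with a report.

Written with binary inclusion indicators z_u, the objective
η̂ᵀη̂ − 2(Xᵀy)ᵀβ̂ + yᵀy (= ‖y − Xβ̂‖², arranged so the quadratic term has N
rather than t variables) is minimized subject to z_u ∈ {0,1},
(1−z_u)β̂_u = 0, Σz_u ≤ p and η̂ = Xβ̂. Lower ranks are produced
iteratively: after each solution S, the exclusion constraint
Σ_{u∈S} z_u ≤ |S| − 1 is appended and the solve repeated, which forbids
exactly that support (the direct generalization of forbidding one found
pair via z₁ + z₂ < 2).

## Exact solvers

Both backends are exact; no relaxation gap or heuristic enters the
reported models.

**Branch-and-bound** branches depth-first on the inclusion indicators,
strongest marginal correlation first, include-branch before exclude so
good incumbents appear early; a greedy forward-selection incumbent seeds
the search. At a node with committed set I and remaining pool C, any
completion has RSS at least that of the unrestricted fit on I ∪ C
(adding predictors never increases RSS), which is an informative bound
whenever |I ∪ C| < N. The indicator constraint (1−z_u)β̂_u = 0 is
enforced combinatorially — coefficients are simply refit on the integer
support — so no big-M linearization exists and big-M truncation cannot
occur. A configurable time limit (default 600 s per solve) returns the
incumbent flagged non-certified instead of failing.

**Vectorized enumeration** evaluates every size-p support in chunks
through the Gram matrix (batched p×p solves of G_SS β = c_S), keeping the
top of the ranking. For pools wider than the sample size any unrestricted
fit on more than N columns has RSS 0, so no polynomial-time relaxation
bound can prune near the root; complete enumeration is then the honest
exact strategy and is fast at the sizes of interest (C(200, 3) ≈ 1.3
million candidates in under a second). A cap (default 2×10⁶ candidates)
refuses larger requests, stating the exact count.

The default `auto` backend uses branch-and-bound for pools that fit
under the sample size (t ≤ 40 and t < N) and enumeration otherwise.

**Ties and determinism.** Exact RSS ties (e.g. duplicated columns) are
broken lexicographically by sorted support IDs after quantizing RSS to a
1e-9 tolerance, in the solver and the oracle alike, so ranked outputs
are deterministic. Rank-deficient support submatrices fall back to the
minimum-norm least-squares solution and are flagged degenerate.

**Size semantics.** The cardinality constraint is "≤ p", but since RSS
never increases with support growth the ranked size-p lists are built
from supports of exactly p elements; a smaller optimal support reappears
padded by its best extension, which is the same model set the ≤-p
formulation certifies.

**Verification oracle.** `exhaustive_best_subsets` ranks all supports by
recursive sequential orthogonalization (Gram–Schmidt projection of the
response and later columns against each chosen column, vectorized at the
last level) and polishes coefficients with `numpy.linalg.lstsq`. It
shares no linear-algebra route with either backend, which makes
solver-vs-oracle agreement a meaningful cross-check; columns rendered
linearly dependent during orthogonalization contribute zero gain, the
exact minimum-norm behaviour.

## Refits, cross-validation, ensemble summaries

Selected supports are refit by OLS with intercept on the original
measurement scale (statsmodels behind the module surface): standard
errors from the unbiased residual variance, p-values from the t
distribution with N − p − 1 df, adjusted R² as 1 − (1−R²)(N−1)/(N−p−1).
Cross-validation partitions subjects with a seeded generator into folds
of stated sizes (the 139-subject default is six folds of 20 and one of
19), refits leaving each fold out, and averages held-out RMSE unweighted
over folds; the "null" benchmark is the sample SD (n−1) of the response,
i.e. the intercept-only RMSE. Ensemble consensus is summarised by
per-predictor (and per-pair) inclusion counts over chosen model sizes,
and the collinearity regime by the number of column pairs with Pearson
correlation above a threshold.

## Raster plots

The ensemble raster assigns one row per model (grouped by size, largest
sizes on top, nondecreasing RSS within a group) and one column per
predictor. Cell values are coefficients on a common predictor scale —
default: the centered predictor rescaled to unit Euclidean norm, which
differs from SD-1 scaling only by √(N−1), a global factor removed by the
final normalization to the grid-wide maximum — so pixel intensity is
comparable across predictors, sign mapped blue (negative) to red
(positive).

## Differential-abundance screen

Subjects split at the composite-score population mean (below 100 versus
100 or higher; the boundary is inclusive on the upper side). Each ASV
resolved to species level (taxonomic identity ≥ 97%) is tested with the
two-sided Mann–Whitney U test; relative abundances are zero-inflated
mixtures, which a rank test handles without distributional assumptions —
zeros tie at the lowest ranks. scipy's implementation chooses the exact
null for small tie-free samples and otherwise the normal approximation
with tie and continuity corrections, the standard choice at group sizes
in the tens; a pooled all-equal column short-circuits to p = 1.
Direction is the comparison of mean ranks (undefined only at an exact
tie). Raw p-values are reported against the expected false-positive
count n·α, matching the screen's design as an exploratory complement to
the model selection; a Benjamini–Hochberg column is attached as a
clearly-marked extension, not used by the screen itself.

## Core microbiota and MAPI

ASVs pool to species by summed abundance (ambiguous calls pool at genus
level); pooling conserves per-subject totals. Prevalence at a detection
threshold is the fraction of subjects at or above it (closed
comparison); the core profile ranks taxa by prevalence at the 0.1%
anchor and evaluates 30 log-spaced thresholds from 0.1% to 100%.

MAPI is ln(Ae/Ana) with Ae and Ana the summed relative abundances of
aerotolerant and strictly anaerobic taxa; taxa without a known class are
excluded, and a sample with no classified taxon raises an
undefined-value error. A pseudocount of 10⁻⁶ enters only when a class
sum is exactly zero, keeping all non-degenerate values untouched. The
group comparison reports five-number summaries (box-plot statistics) and
a two-sided Mann–Whitney p-value — the rank-sum variant is this
implementation's choice.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture. Defaults: 139 subjects; 7 baseline predictors (intervention
indicator; three anthropometric z-scores centred at the moderate-stunting
range, HAZ ≈ −2.5; cognition/language/motor composites at mean 100,
SD 15, with language–cognition correlation 0.7); 542 and 621 ASV columns
at 24 and 36 months. Abundances are zero-inflated (default zero fraction
0.35, matching prevalence in the 60–80% range for typical taxa)
log-normal intensities with per-taxon log-means spread with SD 1.5,
within-taxon log-SD 1, block-correlated latent factors (blocks of 10,
default correlation 0.3), closed per timepoint to per-subject fractions.
The response is intercept 57 plus a planted sparse signal — 0.44 on the
24-month language score and 1929 and 417 on one ASV fraction per
timepoint — plus Gaussian noise with SD 12. The planted columns'
log-means are pinned so their post-closure mean fractions are 0.2% (24m)
and 0.6% (36m), which puts the planted terms' implied t-ratios in the
4–7 range of a well-determined three-term fit; their maxima stay in the
low-percent range typical of subdominant gut taxa. Because planting acts
after compositional closure, the planted coefficients are exactly on the
fraction scale. A reduced 200-predictor variant (7 + 100 + 93, planted
support {5, 57, 157}) keeps the identical signal at a size where the
exhaustive oracle runs alongside the solver. A single integer seed
drives one generator stream in fixed draw order, so cohorts are
bit-exact in (spec, seed).

What the generator does **not** emulate: real rank-abundance curves
fitted to any cohort, phylogenetic correlation structure, longitudinal
coupling between the 24- and 36-month blocks, and non-Gaussian score
noise. Passing tests therefore demonstrate correctness of the machinery
and calibration under the stated generative assumptions, not biological
validity on real data.

## Problem sizes used in validation

The test-suite and acceptance-script sizes were chosen so each property
is measured where it is informative: solver/oracle equivalence on ≥50
random instances at N ≤ 80, t ≤ 20 (where both backends and the oracle
all run); planted-support recovery and coefficient coverage on the
200-predictor cohort (10–16 dual-route replicates, 100 coverage
replicates); screen calibration pooled over five full-size null cohorts
(~400 species-resolved tests each) at the fixed 61/78 split. The full
1170-predictor size-3 and size-4 searches are counted exactly
(266,251,440 and 77,678,857,620 candidates) but not enumerated; running
them requires either the branch-and-bound backend with a generous time
budget or a raised enumeration cap, and is a batch job by design.

## Known limitations

- Enumeration memory and time grow as C(t, p); size-4 searches over
  pools beyond a few hundred predictors need the branch-and-bound
  backend and patience — there is no commercial-solver shortcut in this
  implementation.
- The branch-and-bound lower bound is uninformative when t ≥ N, where
  the code deliberately switches to enumeration.
- Interaction (synergy/antagonism) terms are out of scope; the candidate
  space over pairwise products of ~1163 taxa adds ~675,703 terms, beyond
  any exact search implemented here.
- The screen models no compositional (log-ratio) structure; it is a rank
  test on fractions by design.
- Fold assignment, and hence the exact CV RMSE, depends on the recorded
  seed; only the seed-averaged level is meaningful.
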