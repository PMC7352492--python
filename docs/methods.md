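# Methods

This note documents the models, conventions, and numerical choices
behind each pipeline stage, what the synthetic-cohort generator does and
does not emulate, and the problem sizes used by the test suite and the
acceptance script.

## FFQ processing

Daily intake of an item is `portion_g × f(category)` where `f` maps the
five frequency categories to occasions/day.  Published FFQ pipelines do
not agree on these multipliers, so they are configuration, not
constants.  Defaults use interval midpoints: 2 occasions/month for
"1–3/month" (month = 365.25/12 = 30.44 days), 3/week for "2–4/week", and
5.5/week for the open-ended "≥4/week".  The 5.5 value is a documented
convention for a top category whose upper bound is unstated; pipelines
that cap at daily consumption can pass `{" >=4/week": 1.0}`-style
overrides.  Volumes (mL) are treated as grams (density 1) because the
instrument records either unit without item densities.  Group
aggregation is a plain sum over the user-supplied item→group map; the
map is data, not code, since validated FFQs differ by region.

## Anthropometry and DMPW

BMI subtracts a fixed uniform mass (default 100 g) from the scale
reading.  Status bands on the BMI-for-age percentile are closed on the
left — [0,3), [3,85), [85,97), [97,100] — reading the ≥/< boundary
symbols literally.  WHO 2007 LMS reference tables are deliberately not
bundled: the percentile is an input column, and `lms_percentile`
computes it from a user-supplied (L, M, S) row via the standard
`z = ((BMI/M)^L − 1)/(L·S)` transform when needed.  This keeps the
package free of bundled reference data and independent of any specific
growth standard revision.

DMPW compares two ordinal levels.  Perception collapses
{very thin, thin} → thin(0), normal(1), {fat, very fat} → fat(2).
Measured status maps underweight → 0, normal → 1, overweight → 2,
obese → 2: merging overweight and obese is forced by the perception
scale topping out at "fat", and is the only reading under which the
classification is a total function on all 12 cells.  Agreed iff the
levels are equal; Underestimated/Overestimated iff perceived is
below/above measured.  Two impossibilities follow structurally:
underweight subjects cannot underestimate, overweight/obese subjects
cannot overestimate.  The (obese, fat) cell classifies as Agreed under
the ordinal rule.

## Abundance and dietary patterns

Abundance divides each subject's gram vector by its total, so rows sum
to 1 and the transform is scale-invariant; a zero-total subject has no
defined composition and is reported by id rather than emitted as NaN.
Clustering is agglomerative Ward linkage on Euclidean distances over the
raw fractions — no per-group standardization by default, because the
fractions already share a scale (z-scoring is available as an option).
The cut at k = 4 is a convention of this literature, exposed as a
parameter, with `silhouette_scan` available for transparency across
k ∈ 2..8.  Cluster labels are renumbered by first occurrence in subject
order, making assignments deterministic given the input ordering (SciPy
breaks merge ties by lowest cluster index).  Pattern profiles report
mean ± SD (ddof = 1; singleton patterns get SD 0 plus a flag) and a
per-food-group one-way ANOVA across patterns, Holm-adjusted over the G
groups.

Note that per-pattern mean abundances are fractions in [0,1] and are
displayed as percentages by multiplying by 100; column sums across food
groups within a pattern are therefore ≤ 100 by construction.  Published
tables of this quantity sometimes use other (unrecoverable) scalings;
this package implements the definition and makes no attempt to match
such tables numerically.

## Comparison statistics

Kruskal–Wallis uses SciPy's tie-corrected H.  Dunn's pairwise z-test is
implemented directly (no maintained implementation exists in the
installed stack): `z = (R̄ᵢ − R̄ⱼ) / sqrt((N(N+1)/12 − T/(12(N−1)))(1/nᵢ + 1/nⱼ))`
with T = Σ(t³ − t) over tied groups, two-sided normal p, Holm adjustment
across pairs; the two-group case is verified against the asymptotic
Mann–Whitney test, to which it is equivalent.  Holm–Bonferroni is also
implemented in-package (`adj₍ᵢ₎ = cummax((m − i + 1)·p₍ᵢ₎)` clipped at 1)
because it sits inside the bootstrap hot loop where the statsmodels
entry point's per-call overhead is prohibitive; a test pins exact
agreement with `statsmodels.multipletests(method="holm")`.  Chi-square
is Pearson's, without continuity correction, via SciPy.

## Multinomial pattern model

The model is a baseline-category multinomial logit with the dietary
pattern as outcome (baseline: pattern 2, the profile with no predominant
food group and the lowest abundances), DMPW as exposure (reference:
Agreed) and sex/status adjustment dummies.  It is fit by damped
Newton–Raphson on the weighted log-likelihood with the analytic Fisher
information; Wald CIs come from the inverse information at the optimum.
The in-package implementation exists because sampling weights are
needed (cluster-sampled surveys) and `statsmodels.MNLogit` does not
accept them; unweighted fits are cross-checked against MNLogit and
binary Logit in the tests, and weight-w duplication equivalence is
tested directly.  (Quasi-)separation — |coef| > 15 or Wald SE > 50,
typically an empty outcome × predictor cell — is an explicit diagnostic:
an exception by default, or a warning plus `identified = False` row
flags in exploratory runs.

The exact survey-weighting procedure used by complex-survey software
cannot be reconstructed from a methods section alone; this package
implements cluster-size-proportional weights (each conglomerate
contributes equally) plus the design-effect diagnostic
`Deff = 1 + (m̄ − 1)·ICC`, with the ICC from one-way ANOVA variance
components (clamped at 0) and, for the categorical pattern outcome, the
mean ICC over per-level binary indicators.  Deff > 3 is flagged as
sampling-influenced.  Full linearization/replicate-weight variance
estimation is out of scope.

## Bootstrap correlation networks

Spearman ρ uses average ranks (tie-corrected) with two-sided p from the
t approximation on n − 2 df.  A constant food group in a subset is a
degenerate node: ρ = 0, p = 1 on its pairs, flagged, never an edge.
Each stratum is resampled with replacement B = 100 times at the original
n.  Edge criteria are applied *within each replicate*: Holm-adjusted
p < α (= 0.05) over the G(G−1)/2 tests of that replicate, and |ρ|
strictly > 0.5.  The adjustment-within-replicate choice follows the
stricter of the two published phrasings of this filter (raw vs adjusted
p); a flag disables it.  An edge is retained when one *sign* qualifies
in ≥ persistence·B replicates (default 50%, boundary inclusive: 50 of
100 retains, 49 drops); replicates qualifying with the opposite sign do
not count, since mixing signs would make the edge sign meaningless.
Retained edges carry the median ρ over their qualifying replicates.

Density is L/(N(N−1)/2).  For between-stratum comparison, the density
is computed per replicate (criteria i–ii within the replicate), giving B
values per stratum — the only within-stratum distribution the procedure
generates — compared by Kruskal–Wallis + Dunn + Holm.  Node analysis is
the degree count per food group.

## Synthetic-cohort generator

Defaults emulate a ~1,500-adolescent conglomerate-sampled school survey:
n = 1496, 57.1% female, DMPW (0.683, 0.197, 0.120), status marginals
(0.081, 0.772, 0.088, 0.059), 30 school clusters, 14 food groups whose
gram scales anchor to realistic published medians (e.g. sweetened
beverages ≈ 480 g/day, oils ≈ 29 g/day).

* **Marginals** are matched by largest-remainder integer allocation and
  random placement, so configured proportions are exact up to rounding.
  Sex is drawn independently of DMPW; the printed-count worked examples
  that carry a sex–DMPW association are inputs to the statistics, not
  generator output.
* **Status given DMPW** is drawn from the status marginal renormalized
  over the statuses that can realise the label; configurations in which
  a requested DMPW label has no feasible status (e.g. overestimation
  with only obese mass) are rejected at validation time.  The perceived
  response is then drawn by inverting the ordinal truth table, so
  re-classification recovers the planted DMPW label for 100% of
  subjects, and the BMI-for-age percentile is uniform within the
  assigned status band.
* **Intakes** come from a Gaussian copula on the log scale: per stratum,
  normal scores with Pearson correlation 2·sin(πρ_S/6) of the target
  Spearman matrix, exponentiated around the subject's pattern centroid
  with log-SD `noise_scale` (default 0.8).  Rank correlations are
  invariant under exp, so planted Spearman values are calibrated, not
  approximate.  Non-PSD targets are repaired by eigenvalue clipping with
  diagonal rescaling; repairs moving any entry by more than 0.075 are an
  error, and the post-repair ("effective") targets are recorded in the
  planted truth.  The default per-stratum structure is block-disjoint
  (hence PSD as specified): positive-only cliques in
  Agreed/Underestimated, and in Overestimated a sparser set with
  negative blocks (roots–oils −0.7, roots–processed-meat −0.55,
  vegetables–sweetened-beverages −0.6) plus two positive edges.
* **Patterns and clusters**: subjects sit in near-equal contiguous
  school blocks; pattern labels are drawn from per-cluster mixture
  weights Dirichlet-perturbed with concentration (1 − ICC)/ICC, which
  plants the configured ICC on the pattern indicators.  The default
  ICC = 0.0025 puts the planted Deff near 1.12 at ~50 subjects/cluster —
  the low-clustering regime typical of these surveys; it is a chosen
  default, not an estimated quantity.
* **FFQ responses** invert the FFQ module: group grams are split evenly
  over mapped items, the frequency category is chosen so the implied
  portion is closest (log scale) to the item's typical portion, and the
  portion is set to target/factor exactly.  The round trip is therefore
  exact to floating precision — comfortably inside any frequency-grid
  quantization bound — at the cost of continuous rather than
  fixed-portion responses.

What the generator does **not** emulate: the 97 items of a validated
instrument (items are synthetic placeholders), seasonal/day-to-day
intake variation, FFQ recall error, missing data, or any real
association between diet and DMPW beyond the planted correlation
structure.  Passing recovery tests therefore demonstrate that the
pipeline recovers structure *of the kind the model family can express*,
not that real cohorts satisfy the model.

## Power

The sample-size check simulates the design directly: log-normal intakes
with common CV, one of three groups shifted by the fold change,
Kruskal–Wallis at level α, power = rejection fraction.  The
distributional assumptions (log-normal, CV = 1.2) are this package's
own; with 50 subjects/group, 2-fold change, α = 0.01 they put power in
the high-80s–90% region, consistent with the design claim this kind of
survey makes.

## Problem sizes and determinism

Tests and the acceptance script use: full-size cohorts (n = 1496) for
marginal checks, the round trip, and Deff; n = 2000 for copula-fidelity
convergence; 300 subjects/stratum × B = 100 bootstraps (×20 seeds in the
acceptance suite) for network recovery; n = 600 for pattern recovery;
200 fits at n = 1500 for regression null calibration.  These sizes give
stable pass/fail behavior at comfortable runtimes.  Every stochastic
stage draws from a substream derived from a single top-level seed
(`SeedSequence([seed, stage_id])`), so stages can be rerun in isolation
and full pipeline reruns are byte-identical.

## Known limitations

* Real cohort tables beyond printed marginal counts are not
  reproducible by construction; recovery tests are against planted
  synthetic truth.
* The multinomial model's weighting approximates, not replicates,
  complex-survey estimation.
* Dunn's test uses the asymptotic normal approximation; very small
  per-group counts (< ~5) deserve exact methods the package does not
  provide.
* Optional figure outputs (heatmaps, chord layouts, forest plots) are
  not implemented; all results are emitted as delimited text /
  `networkx` objects for downstream plotting.
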