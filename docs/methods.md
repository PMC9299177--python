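# Methods

This note documents the models behind craniosort, the calibrations of its
synthetic-data generators, and the numerical and design choices a
maintainer or reviewer would want spelled out. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The screening problem

Commingling at the atlanto-occipital joint leaves a set of crania and a
set of atlases whose pairings are unknown. Re-association must reason
about *pairs*: for n individuals there are n² candidate cranium–atlas
pairings of which only n are correct, so the positive class is rarer than
the negative by a factor of n. Any claimed method must therefore be
judged on skew-robust criteria (PPV, sensitivity on the positives), and
an honest negative result — "this signal cannot re-associate" — is as
informative as a positive one.

## Osteometric arm

**Data model.** Sixteen linear distances in mm: per individual, eight on
the occipital condylar region and eight mechanically corresponding ones
on the atlas. The fixed pairing order is AR–BRS, AL–BLS, CR–DRS, CL–DLS,
E–F, G–H, I–J, K–L (right/left condyle width, right/left condyle length,
foramen magnum vs vertebral foramen AP and ML diameters, lateral facet
span, medial facet separation). All values must be finite and strictly
positive.

**Features.** `f_i = m_OC,i − m_C1,i` for the eight pairings, and
`f_9 = ‖m_OC‖₂ − ‖m_C1‖₂`. The occipital-minus-atlas direction is used
throughout; it is the direction under which the published feature means
are reproduced by the published per-measurement means. A squared-norm
variant of `f_9` (sum of squares instead of its root) exists behind
`squared_norm=True` for sensitivity analysis but is off by default: the
Euclidean form is the one whose scale matches the feature statistics.

**TEM.** Repeatability uses the Dahlberg absolute technical error of
measurement, `TEM = sqrt(Σ d_i² / 2N)` over paired differences, with
`rTEM = 100·TEM / grand mean` of all 2N values; `rTEM ≤ 7.5 %`
(inclusive) is acceptable. This is the standard anthropometric
convention; TEM is symmetric in its two series, scales linearly under
uniform rescaling, and rTEM is scale-free — all property-tested.

**Classifiers.** Six families, no hyperparameter search: linear
discriminant analysis, logistic regression, quadratic discriminant
analysis, Gaussian-kernel SVM, AdaBoost over 50 decision trees, and a
single-hidden-layer feed-forward network with 50 tanh units. The SVM and
network operate on standardised features (the RBF kernel scale and
network training are otherwise dominated by the largest-variance
feature). The network holds out 15 % of each training fold for
early-stopping validation; a further held-out "test" share would play no
role in weight updates, so it is folded into training.

**Evaluation.** Stratified 10-fold cross-validation (stratification is a
deliberate choice: with n positives in n² rows, unstratified folds can be
positive-free and the fold metrics degenerate). Hard predictions use the
estimator's native 0.5 probability / zero-margin threshold; the confusion
matrix, PPV, sensitivity and specificity are pooled over out-of-fold
predictions, and the AUC is computed threshold-free from pooled
out-of-fold scores. PPV and sensitivity are reported as "n.a." when a
model never emits a positive prediction — with this degree of skew that
is the typical outcome and is exactly the point: specificity ≈ 1 is
trivially achievable by predicting all-negative, so specificity is always
reported *alongside* PPV, never instead of it.

**Correlation report.** Pearson r between correspondent measurements
across individuals, with two-sided p, R², and strength bands half-open on
the right: poor (r ≤ 0.3), low (0.3 < r ≤ 0.5), moderate
(0.5 < r ≤ 0.7), strong (r > 0.7). A zero-variance column yields an
undefined entry rather than an error.

## 3D surface arm

**Registration.** Two rigid stages, no scaling, no reflection (both
patches are real-size mm scans):

1. *Landmark stage*: closed-form least-squares (Kabsch/SVD) fit of the
   label-matched edge landmarks (anterior, posterior, lateral, medial on
   each of the left and right facets). Degenerate configurations (fewer
   than three non-collinear points) raise an error. The closed form is
   verified in tests against both an independent 6-dof numerical
   minimiser and a general Procrustes routine.
2. *ICP stage*: alternate (a) nearest point-on-surface correspondence for
   every transformed moving vertex and (b) the closed-form rigid update
   to the current footpoints, re-fitted from the untransformed source
   each iteration to avoid compounding drift. Each update minimises
   distance to the current footpoints, so the RMS trace is non-increasing
   (property-tested). Defaults: at most 100 iterations, stop when the
   RMS changes by less than 1e-6 mm. Non-convergence sets a flag on the
   result instead of raising.

**Distances.** "Point-to-point" distance is implemented as unsigned
vertex-to-nearest-surface-point (point-to-triangle) distance, robust to
the two scans having different mesh resolutions; a vertex-to-vertex mode
exists behind `mode="vertex"` for sensitivity analysis. The nearest-point
query is an exact all-pairs point-to-triangle computation — the ROI
patches are a few hundred faces, where brute force is both exact and
fast — and is verified against an independently written scalar
per-triangle oracle. The summary reports RMS, min, max and SD of the
per-vertex field; min ≤ max and rms = sqrt(mean d²) are invariants, but
RMS is *not* constrained to lie between min and mean.

**Direction.** The occipital patch moves onto the atlas patch by
default; the CLI `--swap` flag reverses. The final RMS is invariant
under any rigid motion applied to both surfaces (property-tested at
1e-6 mm).

**ROI cropping.** The analyst's closed contour is projected onto its own
best-fit plane (PCA of the contour points); mesh vertices are kept when
their in-plane projection falls inside the polygon, and faces survive
when all three vertices survive. Collinear contours, open contours and
empty selections are rejected. Both facets of a bone are kept in a
single mesh at their original separation, so inter-facet geometry takes
part in the superimposition.

**Screening.** The exclusion threshold is the maximum RMS over the match
group. Verdicts are exclusion-only: RMS strictly above the threshold ⇒
*excluded*; a tie or anything below ⇒ *inconclusive* (the conservative
choice at the boundary — exclusion claims must not rest on ties, and the
match/mismatch distributions overlap below the threshold, so no
affirmative verdict is ever issued). Group statistics: two-way ANOVA on
group × sex with the interaction term, type-II sums of squares because
the 46-match / 260-mismatch design is unbalanced; Levene's test for
homoscedasticity across cells and the Jarque–Bera test for normality per
cell, α = 0.05. An incomplete group × sex grid degrades to a one-way
ANOVA on group with a warning.

**Experiment design.** All n match pairs plus a seeded uniform draw,
without replacement, of ordered same-sex mismatch pairs (a selection
rule the original protocol leaves unspecified; random-without-replacement
is the neutral choice and is reproducible by seed). The reference layout
— 46 individuals (26 F, 20 M) with 130 mismatches per sex — yields 306
superimposition tasks.

## Synthetic-data generators

Three independent levels, so the statistical calibration does not depend
on an un-calibratable surface-physics model.

**Measurements.** Per pairing i, occipital and atlas values share a
per-individual standard-normal factor s:
`m = μ + σ·(√r_i·s + √(1−r_i)·e)`, with independent e on each side, so
the pair correlation is r_i in expectation while s also induces overall
size correlation across measurements. Defaults are the published
population means/SDs (e.g. AR_OC 10.5 ± 1.3 mm, F_C1 35.4 ± 2.8 mm) and
pair correlations (0.514, 0.481, 0.650, 0.622, 0.671, 0.591, 0.606,
0.402); sex is drawn at the study's 83/150 male fraction; draws below
0.1 mm are resampled. What this emulates: marginal scales and
correspondent-pair correlation. What it does not: skewness, left–right
asymmetry structure, sex-specific means, measurement error. Passing
classifier tests on this population therefore show that *correlations of
this strength do not make pairs separable* — not that any conceivable
real population is inseparable.

**RMS outcomes.** Match and mismatch superimposition RMS are drawn from
a truncated lognormal (default; a truncated normal is available): the
parent is moment-matched to the group mean/SD (match 0.29 ± 0.09 mm,
mismatch 0.46 ± 0.20 mm), then sampled by inverse CDF restricted to the
group range (match [0.15, 0.53], mismatch [0.14, 1.49] mm; sex-specific
rows are provided as constants). The lognormal is the natural
right-skewed positive family here — the mismatch mean sits well below
its range midpoint. Truncation is applied after moment-matching, so the
realised moments are the truncated ones; at these parameters the
truncated tails carry ≈0.5 % mass and the shift is well inside the
generator's own tolerance tests. Match draws cannot exceed 0.53 mm by
construction, hence the derived threshold never does. The analytic
exceedance P(RMS > 0.53) of the calibrated mismatch family is ≈0.29, so
single-run exclusion percentages at n = 260 scatter around 29 with a
binomial SD of ≈2.8 points.

**Surfaces.** Each condyle is a convex elliptical dome patch (fan-ring
triangulation); per-individual anteroposterior length ~ N(22.6, 2.3²) mm,
mediolateral width ~ N(10.5, 1.3²) mm, dome height 0.18 × length, and
bilateral placement with medial separation ~ N(16.0, 2.2²) mm. The
matching atlas facet occupies the *same* articulated interface surface —
congruent by construction — plus a smooth random deformation field
(sum of low-frequency sinusoids, normalised to unit RMS) of amplitude
σ_c; a mismatching facet is built from an independent individual's
geometry. The atlas patch is emitted in a random pose (≤15°, ≤8 mm) so
registration has real work to do. Landmarks are the four extremal
boundary vertices per facet. σ_c defaults to 0.3 mm — a free model
parameter chosen once so that simulated match registrations land in the
few-tenths-of-a-mm regime of real articular congruency; it is *not* a
published value. The lateral span of the flat-patch model is emergent
(medial separation + two facet widths) and smaller than the oblique
caliper span of real condyles; the model makes no claim to anatomical
realism (no condyle shape atlas, no taphonomy, no scanner artifacts) and
is validated by ordering and recovery properties, not by moments.

## Problem sizes and tolerances

The package's own test-suite sizes, chosen to keep the default run
around a minute while still exercising study-scale structure: the full
22,500-pair dataset is used for the linear and quadratic discriminants;
the all-six-family check (including the SVM and network) runs at n = 60
individuals (3,600 pairs); mesh tests use 4-ring × 12-sector facets
(98 vertices per bone); Monte-Carlo properties use 10–30 seeded
replicates. Generator self-checks use n = 5,000 individuals
(means ± 0.1 mm, correlations ± 0.05) and 10,000 RMS draws
(mean ± 0.01, SD ± 0.01 mm). `scripts/acceptance.py` runs the
study-scale configuration exactly: 150 individuals, 10 folds, 46 + 260
RMS draws.

## Known limitations

* The surface generator is a geometric cartoon; its σ_c knob summarises
  everything real articular surfaces do (cartilage loss, erosion,
  scanner noise) in one smooth field.
* The RMS generator reproduces group moments and ranges, not the joint
  dependence of RMS on individual size or sex beyond the provided
  per-sex rows.
* Exclusion rates inherit binomial noise at realistic sample sizes; at
  n = 260 a ±5-point spread between runs is ordinary.
* The screen is one-sided by design: it can never confirm a match, and
  its sensitivity for re-association is identically zero. Confirmation
  requires independent evidence (e.g. DNA).
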