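# Methods

This note documents the measurement models, estimator constructions,
statistical machinery, simulation designs and numerical conventions used
in `ommatidics`, and states what the test suite does and does not
demonstrate.

## Brightness protocol

Brightness follows the HSB convention of image editors' color pickers:
per pixel B = max(R,G,B)/255 × 100 (a grayscale value is its own
maximum). A patch's brightness is the mean over its pixels (the field
protocol samples an 11 × 11 patch ≈ 8 mm² of cuticle at print scale); a
worker's brightness averages the head, mesosoma and gaster patches; a
species' brightness averages its workers. Missing tagmata are averaged
over with a logged warning rather than invalidating the worker, since a
partially occluded specimen still carries information.

Two classification schemes are exposed. The main-study rule exploits an
empirical gap in the focal genera — every dark species mean fell below
60 and every pale mean above 65 — so B > 65 ⇒ pale, B < 60 ⇒ dark, the
gap ⇒ indeterminate. Survey screens across other genera use a single
B > 70 cut. Neither threshold is tunable at call sites by design: they are
the definitions of the classes, not fitting parameters.

The pale/dark group comparison is a pooled-variance two-sample t on
species means (the printed df of n₁+n₂−2 identifies the pooled rather
than Welch variant). The statistic is oriented dark-minus-pale, matching
the ascending alphabetical factor coding of common statistical software,
so pale > dark yields a negative t. The packaged species table reproduces
t = −10.1 on 24 df; note that the group means recomputed from species
means (74.4 / 45.7) differ in the first decimal from the published
worker-weighted figures (74.6 / 45.4) — the report prints both rather
than asserting equality.

## Interommatidial angle by radius of curvature

Input is an ordered digitization of the eye's profile edge with points at
facet-row boundaries and a marked apex point. From the apex, chords are
drawn to the points `rows_per_step` boundaries anterior and posterior;
the perpendicular bisectors of these chords intersect at the local center
of curvature. On a circle of radius R with facet pitch D, the bisector
through a chord's midpoint passes through the center along the angular
bisector of the chord's endpoints, so the angle between the two
perpendicular bisectors spans `rows_per_step` facet arcs on each side of
the apex midpointed — i.e. `rows_per_step × D/R` radians in total. The
per-facet angle is therefore the bisector angle divided by
`rows_per_step`; with the conventional two-row step this is exactly "the
bisector angle divided by two". The division is a consequence of the
midpoint geometry, not a convention: the oracle identity Δφ = D/R holds
to ≤ 1e-9 relative error for any step size in {1, 2, 3} and any
R ∈ [0.1, 2] mm, pitch/R ∈ [0.01, 0.2] (property-tested).

The construction is exactly invariant under translation, rotation and
uniform scaling, since it uses only incidence and angles. Degeneracy
(collinear construction points, i.e. a locally flat eye edge) is detected
when the normalized bisector directions' cross product falls below 1e-12,
and raises a dedicated error rather than returning a meaningless angle.
Replicated measurements (the field protocol repeats the construction
three times in the same region) are averaged arithmetically; a degenerate
replicate fails loudly with its index.

Angles are computed internally in radians and reported in degrees.

## Visual field span

The span is the angle between the outward surface normals at the
anterior and posterior ends of the profile, in (0°, 180°]. Each edge
normal is taken at the outermost point, directed through the circumcenter
of the three outermost points — the local osculating circle. For points
on a circle this is exact, so the estimator recovers the generating arc
angle to ≤ 1e-9 (property-tested), and 180° for a semicircular profile.

A two-point secant tangent was considered and rejected: the secant
through the two outermost points has the direction of the tangent at the
*midpoint* of their arc, so its normal recovers (arc − one facet step)
rather than the arc itself and cannot satisfy the estimator's own oracle
identity. The three-point construction uses the minimum number of points
that determine a curvature, and the implementation requires exactly
those three points at each end.

## Derived optics

ρ = D[μm] × Δφ[rad]; facet area π/4 D²; sensitivity fold
(D_num/D_den)²; relative eye size = eye area / mesosoma length (mm);
regional facet diameter = (length of three facets in a row)/3 with an
explicit unit scale; centroid facet diameter = mean of the four facets
adjoining the eye centroid. Unit conversions (degrees/radians, mm/μm)
happen inside the functions; interfaces take the units the measurements
are recorded in.

## Covariate-adjusted comparisons

All model fitting uses a shared multiresponse least-squares core: the
design matrix holds an intercept, reference-coded group dummies and the
covariate (sum-to-zero coding for the two-factor model, so type-III main
effects are well defined under the interaction). Hypothesis SSCP
matrices for a coefficient block come from H = B̂ᵀ M⁻¹ B̂ with M the
corresponding block of (XᵀX)⁻¹ — type-III tests for the terms involved.
Wilks' λ = det(E)/det(H+E) uses Rao's F approximation; Pillai's trace
V = tr(H(H+E)⁻¹) uses its standard F approximation. With one response
both collapse to the univariate F (tested to 1e-8); with several they
match an independent multivariate implementation to 1e-10.

EMMs are model predictions per group at a fixed covariate value — by
default the grand mean of the included observations, overridable to match
a published evaluation point (the packaged tables record the per-genus
points, e.g. 1.7434 mm for the largest genus). EMM contrasts use the full
coefficient covariance, not the sum of squared EMM standard errors, since
EMMs share the intercept and slope.

Post-hoc machinery: LSD is unadjusted pairwise t on EMM contrasts at the
model's error df; Tukey(-Kramer) uses the studentized range with
SE = √(MSE/2 (1/nᵢ + 1/nⱼ)). Compact letter displays are built by the
insert-and-absorb sweep (split every column containing a significantly
different pair, absorb subset columns), letters assigned in descending
mean order so 'a' always marks the largest mean. The resulting columns
are exactly the maximal cliques of the non-significance graph
(cross-checked against a clique-enumeration oracle), and every display is
re-validated against its own p matrix at construction time. The post-hoc
alpha is a per-analysis parameter because heteroscedastic genera warrant
a stricter 0.01 convention.

Assumption battery: Box's M with the standard χ² approximation, judged
at the conventional 0.001 level because the test is oversensitive;
Levene's test with mean centering; homogeneity of regression slopes as a
multivariate test of the group × covariate interaction. When Box's M
rejects at 0.001 the criterion-selection policy recommends Pillai's trace
over Wilks' λ (logged); both criteria are always reported. Response
transformations (log/√) are explicit per-response options, never applied
silently.

Repeated-measures ANOVA (for regional facet-diameter variation across
the five eye regions) reports the sphericity-assumed within-subjects F
(df = k−1, (k−1)(n−1)), Mauchly's W on normalized-Helmert contrasts with
the χ² approximation (df = k(k−1)/2 − 1, which is 9 for five regions),
a multivariate Hotelling/Wilks test on difference scores, and paired-t
LSD comparisons of region means. Small-sample exact Mauchly p-values are
not attempted; the χ² approximation is the documented convention.
Incomplete subjects are dropped listwise with a warning.

Fisher's exact test for r × c tables enumerates every table with the
observed margins recursively and sums the probabilities of tables no more
probable than the observed one (relative tie tolerance 1e-7) — the
conventional two-sided definition, stated explicitly because r × c
two-sided conventions vary. An enumeration guard (default 10⁷ tables)
raises a resource error suggesting a Monte-Carlo approach instead of
silently approximating.

## Synthetic generators

The generators define the conditions under which the machinery is
validated:

- **Eye profiles**: constant-curvature (circular) arcs, because the Δφ
  construction *is* a radius-of-curvature method — the circle is the
  geometry on which its correctness can be stated exactly. Points sit at
  facet boundaries; the realized span is the largest whole number of facet
  steps inside the requested span and is reported back as ground truth.
  Digitization error is isotropic Gaussian jitter. Defaults (R = 0.5 mm,
  pitch = 0.02 mm ⇒ Δφ = 2.29°, jitter ≈ 0.4 μm) sit in the middle of the
  measured ant range (Δφ 3.5–7° at smaller radii).
- **Morphometry**: per-species linear trait models against mesosoma
  length with Gaussian residuals — the structure the covariate-adjusted
  comparisons assume (traits increase with body size within species).
  Defaults use 12 workers/species from 4 colonies over 1.0–2.3 mm, with
  residual SDs of the order of the reported standard errors; the
  pale/dark facet-diameter offset used in power checks is +6 μm, the gap
  between size-matched congeners.
- **Patches**: Gaussian pixel noise truncated to [0, 255] around the
  target brightness; unbiased away from the boundaries, saturating at
  them.
- **Regional diameters**: additive subject + region effects with
  i.i.d. residuals, hence compound-symmetric covariance — sphericity holds
  in truth, so Mauchly should not reject and the within-subjects F is
  calibrated. The power-check effect (+2 μm ventral at n = 14) mirrors
  the measured regional contrast at the study's sample size.

One top-level seed per generator; multi-species streams are spawned from
a `SeedSequence`, so outputs are bit-reproducible and adding a species
does not perturb the others.

What passing tests show — and do not. The synthetic conditions establish
correctness of the geometry on constant-curvature profiles, calibration
of the tests under their null hypotheses, and parameter recovery under
the assumed linear structure. Real eyes are not perfectly circular in
profile, digitization error is not isotropic, trait-size relations need
not be linear, and worker samples are clustered by colony (colonies are
labelled but not given random effects). Conclusions about real data rest
on the robustness of these methods to such deviations, which the suite
does not quantify.

## Reproduction scope

The packaged tables carry species-level summaries only; the underlying
per-worker measurements are unpublished. The reproduction report
therefore re-derives exactly the statistics computable from summaries —
the brightness t-test, the contingency-table exact test, the pale/dark
partition, EMM diameter ratios, facet-area folds, and the survey screen —
while the model-fitting battery is exercised on synthetic or user data.
The per-genus survey screen compares each candidate's relative eye size
against the *maximum* over that genus's five dark congeners, because only
those maxima are recorded; per-species dark-congener rows are not
available.

## Numerical conventions

Degeneracy tolerances: parallel bisectors at 1e-12 on normalized cross
products; perfect model fits flagged when the residual SS falls below
1e-10 of the hypothesis SS (F reported as ∞, p as 0, with a flag rather
than an exception). Report display rounds ratios to two decimals and t
to one, matching print precision; JSON output retains full precision.
Profile coordinates round-trip text formats at six decimals. Checksums
of the packaged tables are verified before any reproduction run.

## Problem sizes

The default test and acceptance runs use: estimator sweeps over 27
(R, pitch, step) combinations; 1000-replicate noise studies; 500-replicate
null calibrations in the test suite and 300-replicate calibration and
coverage runs in the acceptance script; two-species MANCOVA recovery at
12 workers/species. These sizes give Monte-Carlo standard errors small
enough for the stated binomial bounds while keeping a full run in the
tens of seconds on one core.
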