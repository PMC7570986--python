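# Methods

## Data model and pretreatment

Input is a wide table of replicate emission spectra (rows = wells of a
microplate, columns = a strictly increasing wavelength grid in nm) plus
per-well metadata (sample id, replicate index, blank flag, condition).
Each *condition* is one fingerprinting protocol — typically one added
fluorophore — and every metric is computed per condition, then conditions
are compared.

Normalization computes the formal degree of quenching
Q(λ) = (I(λ) − Ī₀(λ)) / Ī₀(λ), where Ī₀ is the per-wavelength mean over the
wells flagged blank *within the same condition*. Q is dimensionless,
negative under quenching and ≥ −1 when intensities are non-negative; blank
rows average to exactly zero at every wavelength by construction, and the
transform is invertible (I = Ī₀·(Q + 1)). A blank whose mean intensity is
zero at any wavelength is a hard error naming that wavelength. Instrument
artifacts that live outside the informative band (e.g. a plate-material
peak at 420 nm) are handled purely by windowing — the default closed
window is 430–550 nm — never by peak subtraction.

## PCA score clouds

The (normalized) matrix is column-centered — no variance scaling, since
Q is already a relative quantity on a common scale — and decomposed by SVD.
Wells are projected on the top k = 2 right singular vectors; component
signs are fixed so each loading's largest-magnitude element is positive,
making scores reproducible. Blank wells participate in the fit as ordinary
rows but are excluded from every separability metric. Model adequacy is
the residual dispersion 1 − Σ explained-variance fractions; above 5% a
warning is logged but the computation proceeds (an inadequate projection is
itself informative about a poor fingerprinting condition).

## Confidence ellipses and the crossing number

For each sample with n ≥ 3 non-collinear replicates the confidence region
is { x : (x − c)ᵀ Σ⁻¹ (x − c) ≤ s² } with c the replicate mean and Σ the
sample covariance. The default boundary radius is the *coverage* scaling
s² = t²(1 − α/2, n − 1) (two-sided Student quantile; 2.3507 for n = 5 at
80%), chosen because such ellipses visibly enclose the replicate points;
the exact Hotelling-T² region for the class mean,
s² = 2(n−1)/(n(n−2)) · F(level; 2, n−2), is available as a switch and is
substantially tighter.

Boundary intersections are computed exactly. Ellipse A is mapped to the
unit circle (Cholesky factor of s²_A Σ_A); the circle is rationally
parametrized by u = ((1−t²)/(1+t²), 2t/(1+t²)) and substituted into B's
boundary quadric, giving a quartic P(t) whose real roots are the
transversal crossings. The parametrization's antipode (t → ∞) is recovered
whenever the quartic's leading coefficient vanishes. Candidate points are
polished with two or three Newton steps on the 2×2 quadric system (skipped
near-singular Jacobians, i.e. tangencies) and accepted when both boundary
residuals, relative to the boundary level, fall below 1e−6; accepted
points in the test suite agree with a dense boundary-sampling oracle on
count for 1000 random pairs. Tangency appears as a numerically double root
and is reported as two coincident points — i.e. counted as a crossing,
conservative toward declaring overlap.

Pair crossing numbers: transversal crossings count as themselves (0–4);
if the boundaries do not meet, one center lying strictly inside the other
ellipse means containment, postulated as 4 crossings to reflect maximal
overlap (coincident ellipses are classified the same way); otherwise 0.
CrN is the sum over all unordered sample pairs. The *number of groups* is
the number of connected components of the graph with an edge wherever the
pair crossing number is positive; an alternative separation predicate —
an edge when the Mahalanobis distance between class centers under the
pooled covariance is below 4, the classical rule that corresponds to
visual non-intersection of 80% ellipses — is exposed as an option.
Overlap *areas* of ellipses are deliberately not computed; CrN is designed
to be countable by eye on a scores plot.

## Relative position (RP)

Each group is summarized by its center of mass C (mean of all points, not
only hull vertices) and its convex hull — the simplest distribution-free
boundary. For an ordered pair (1, 2), with u the unit vector C₁→C₂:

- A₁ = hull vertex of group 1 minimizing the scalar projection of C₂→A₁
  on C₂→C₁ (the point of group 1 reaching farthest toward group 2);
- A₂ = hull vertex of group 2 minimizing the scalar projection of C₁→A₂
  on C₁→C₂ (the point of group 2 reaching farthest toward group 1);
- RP₁₂ = ((A₂ − C₁)·u) / ((A₁ − C₁)·u).

Because the minimum of a linear functional over a convex polygon is
attained at a vertex, restricting candidates to hull vertices is exact;
ties break by smallest vertex index for determinism. The signed
projections give the threshold semantics (separated > 1, intersecting in
(0, 1), merged < 0); boundary values resolve toward the worse regime
(RP = 1 → intersecting, RP = 0 → merged). The index is invariant to
rotation, translation and uniform scaling, and is computed on raw score
coordinates — axes are *not* standardized (an option exists), which is why
well-separated plots produce values in the tens. Symmetric pair value:
min(RP₁₂, RP₂₁). Plot-level value: the mean of the pair minima over
unordered pairs; a variant normalization that divides the doubled
double-sum by N(N−1)/2 (exactly twice the mean) is available behind a
flag for comparability with that convention. Identical group centers make
the direction u undefined and raise an error identifying the pair.

## Total sensitivity, QDA, SVM

TS uses per-class Mahalanobis distances (own class covariance per class):
a well belongs to class k when D_M ≤ 4. Status per well: *correct* iff
the membership set is exactly its own class; *multi-class* when it matches
more than one (potentially misclassified); *unowned* when it matches none;
*misassigned* when it matches only a wrong class. TS = #correct / #wells.
By default the evaluated well is included in its own class statistics
(training-set sensitivity, which is what a rating of conditions on a fixed
dataset uses); a leave-one-out switch recomputes the own-class center and
covariance without the well. Classes need ≥ 3 wells and a non-singular
covariance (checked relative to the trace).

QDA assigns each well to the class minimizing the quadratic discriminant
score with per-class covariance and log-determinant term (uniform priors),
via scikit-learn; the rank-check tolerance is rescaled by the data
variance because score units can be small. With equal class covariances
this reduces to the plain Mahalanobis rule. SVM sensitivities (linear,
poly-3, RBF kernels) delegate to scikit-learn's SVC with library-default
hyperparameters — the comparison needs a fixed standard protocol, not a
tuned classifier. All sensitivities reported are training-set values;
cross-validation is out of scope.

## Rating and correlations

Per metric, conditions are ranked best→worst respecting polarity (CrN
lower-better; groups, RP and all sensitivities higher-better); ties share
the mean rank. The overall rating is the row sum of places, smaller is
better; output ordering breaks rating ties by condition name. Metric
correlations are Pearson on the metric values as given (Spearman
optional); zero-variance columns are reported as missing.

## Synthetic data generator

`generate_spectra` emulates the study's plate: 36 samples × 5 replicate
wells + 6 blanks on a 301-point 400–700 nm grid. The blank baseline is a
fixed smooth two-band curve (scale ≈ 100 a.u. + offset); each sample's
mean spectrum adds a sample-specific non-negative mixture of `n_latent`
(default 2) Gaussian emission bands (centers spread over 440–590 nm,
width 28 nm) with mixing weights drawn uniformly up to
100·`between_sample_spread` a.u. — default spread 1.0 makes the sample
bands comparable to the baseline. Replicate noise is multiplicative,
1 + ε with ε ~ N(0, `noise_fraction`²) i.i.d. per wavelength (default 1%),
because fluorescence repeatability error scales with signal. After
centering, the sample structure is rank-`n_latent` up to noise, so a
2-component PCA of the default design leaves well under 5% residual
dispersion; this is the regime the adequacy gate encodes.

What the generator does *not* emulate: photophysics (quenching mechanisms,
inner-filter effects), correlated instrument drift across a plate,
non-Gaussian band shapes, and heteroscedastic blank behavior. Passing
tests therefore demonstrate the correctness of the geometry and metric
definitions and their monotone response to separation — not classification
performance on real spectra.

`generate_score_groups` bypasses spectra entirely: labeled isotropic
Gaussian groups (σ = `spread`) with centers on a circle of radius
`separation`, so separation is a single dial. The test harness uses it to
verify, averaged over 20 seeds per setting, that CrN is non-increasing and
the overall RP non-decreasing in separation, and that TS → 1 and the group
count → the true number of groups at large separation.

## Numerical choices and edge cases

- Quartic roots via the companion matrix (`numpy.roots`); imaginary parts
  below 1e−7 (relative) are treated as real because double roots at
  tangency split as ±√ε.
- Collinear replicate clouds (singular covariance) and classes with < 3
  wells raise errors naming the sample/class.
- Collinear point groups degenerate to 2-vertex segment hulls; RP handles
  them as long as the group has extent along the center line.
- CSV output uses 6 significant digits throughout, so re-running a
  pipeline on identical inputs is byte-stable.
- Problem sizes in the test harness (6-group score configurations, 20
  seeds per setting, 1000 random ellipse pairs against the sampling
  oracle) were chosen as the smallest sizes at which the stochastic
  properties are stable.

## Known limitations

- CrN's containment postulate makes it discontinuous as one ellipse slips
  inside another (2 → 4 without passing through 3); this is inherent to
  the definition.
- RP is a projection onto the center line: strongly curved or L-shaped
  groups can overlap while RP still exceeds 1.
- The quartic solver assumes well-conditioned covariances; eccentricities
  beyond ~1e6 may lose intersection points to the residual filter.
- TS at its default is a training-set quantity and flatters all
  conditions equally; use the leave-one-out switch for honest absolute
  numbers.
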