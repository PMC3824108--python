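# Methods

## Compositions, closure and the filling value

Tissue data enter as strictly positive nutrient concentrations on a
dry-mass basis. All columns are converted to mg kg⁻¹ at read time and the
composition is closed to `κ = 10⁶ mg kg⁻¹` after appending a filling value
`Fv = κ − Σ nutrients`, the C/H/O-dominated remainder. Including `Fv`
makes the composition a genuine partition of the dry mass and lets ilr
coordinates back-transform to familiar concentration units. Rows whose
nutrients reach or exceed `κ` are rejected, as are zero or negative
concentrations: the data model is strictly positive and zero-replacement
imputation is deliberately out of scope (it would silently change
results). The closure invariant is checked to a relative `1e-6` to absorb
CSV rounding.

## Balances

A sequential binary partition (SBP) is an ordered `(D−1)×D` matrix of
`{+1, −1, 0}` codes: row 1 splits all parts, each later row splits exactly
one group created earlier, and every non-singleton group is eventually
split. Validation enforces precisely this hierarchy. The basis compiled
from row *i* carries `+√(n₋/(n₊(n₊+n₋)))` on `+1` parts and
`−√(n₊/(n₋(n₊+n₋)))` on `−1` parts, giving orthonormal log-contrasts
(`ψψᵀ = I` to 1e−10). Balance labels are always generated from the codes
as `[−1 group | +1 group]` — the minus group left of the bar, so a
negative value leans left — never trusted from input text. ilr coordinate
*i* always corresponds to SBP row *i*; there are `D!(D−1)!/2^(D−1)`
distinct SBPs, a count the test suite verifies by exhaustive enumeration
up to D = 5.

The packaged foliar SBP for the 11-nutrient mango ionome encodes prior
knowledge of nutrient interactions (nutrients vs. filling value, macro vs.
cationic micro, anionic vs. cationic macros, protein/energy [P | S,N],
mono- vs. divalent cations, fungicide-related micros). Any other valid SBP
on the same parts is an orthogonal rotation of it.

## The imbalance index

A specimen's imbalance is its Mahalanobis distance from reference norms:
`d = √((z−c)ᵀ COV⁻ (z−c))` with Moore–Penrose pseudo-inversion
(singular values below `1e−10` of the largest are dropped), so
rank-deficient references degrade gracefully instead of failing.

The centre `c` is the **spatial (geometric) median** of the reference
balances (Weiszfeld iteration with the Vardi–Zhang correction; step
tolerance 1e−12). The design is deliberate: a robust, median-type centre
is needed for survey data with extreme values, and the spatial median —
unlike the coordinate-wise median — is equivariant under orthogonal
rotations, which is exactly what makes the fitted imbalance index
independent of the SBP used to express the balances (verified to 1e−8 in
the tests). Univariate reporting (per-balance medians and confidence
ranges) still uses the ordinary coordinate-wise median, which is what a
table of per-balance statistics means.

The covariance is the classical `n−1` estimator on the outlier-cleaned
reference. Outliers are screened at `α = 0.01` by a two-pass rule:
distances about the spatial median, cut at `√χ²₁₋α(D−1)`, with one
re-estimation after removing flagged rows; displacements outside the
covariance column space count as infinitely distant. This is a
reproducible, dependency-free approximation of adjusted-quantile robust
outlier detection; minimum-covariance-determinant estimation is a
non-goal.

## Calibration by iterative ROC partition

Yield is continuous, so both delimiters are estimated. For a fixed yield
cut-off (condition-positive = yield below it): the reference is seeded
with all high-yielders; norms are fitted; all distances computed
(test-positive = distance above threshold); the ROC curve is swept over
the unique distances; the critical distance is the Youden-optimal
threshold (ties to the smallest threshold, keeping the reference most
exclusive); specimens are relabelled into TN/TP/FN/FP quadrants; and the
TN set becomes the new reference. The loop stops when two successive
iterations label identically, with a 2-cycle detector (return the iterate
with larger step AUC, flagged unconverged) and a cap of 50 iterations.

The cut-off scan uses midpoints between consecutive unique yields by
default (an explicit grid can be supplied), discards candidates that fail
to converge or leave fewer than `min_tn = 20` true negatives, and selects
the maximal ROC step AUC, ties toward the larger cut-off. The step AUC
sums rectangles under the step curve in threshold order (tied predictor
values count as concordant); the binormal AUC fits
`probit(sens) = a + b·probit(1−spec)` by least squares over interior
operating points (minimum 3) and reports `Φ(a/√(1+b²))` with a 95% CI by
the delta method on `(a, b)`. Confusion metrics with empty denominators
are reported as NaN, never 0.

**Known behaviour of the scan.** The AUC is an apparent (in-sample) AUC:
reference specimens are scored by the very norms fitted to them, and with
11 balances a reference near the minimum size of 20 scores outsiders
optimistically far (the expected squared distance of a new same-population
point is roughly three times the in-sample one at `n_ref = 20`). The AUC
therefore tends to creep upward as the cut-off rises and the reference
shrinks, and the selected cut-off often sits at the feasibility boundary
where the TN count reaches `min_tn` rather than at the generative yield
boundary. The minimum-TN constraint is the procedure's only guard, and
cross-validating the calibration is a declared non-goal; users should read
the selected cut-off as "the most exclusive reference the data support",
and treat the absolute AUC as optimistic. The synthetic-data tests
document this: with the yield link switched off, distances from the *true*
norms give AUC ≈ 0.5, while the full scan still reports high apparent AUC
at boundary cut-offs.

## Pan-balance reports

Each balance of a diagnosed specimen is judged against the univariate
reference range `median ± t₀.₉₇₅,ₙ₋₁·s/√n` of the reference group
(centred on the median for consistency with median-based norms; the
half-width is the usual standard error form — the compact `±t s²/n`
notation seen in print is ambiguous and the `s/√n` reading is adopted).
The global verdict compares the Mahalanobis distance with the calibrated
critical distance. Both are reported because they answer different
questions: the univariate ranges depend on the SBP and localise trouble;
the global distance is SBP-invariant. Pan concentrations are the
back-transformed balances of the specimen and of the reference medians,
each closing to `κ`.

Group comparison (TP vs TN) reports the per-balance mean difference
(TP − TN; negative means the left-of-bar parts load more in TP) with the
studentized-range test, which for two groups is exactly the pooled
t-test. Because `D−1` balances are examined simultaneously, the
significance flags control the family-wise error across balances by
Holm's step-down adjustment; raw p-values are reported alongside.

## Legacy comparators

Implemented solely to exhibit the biases the balance approach removes:

- **log-concentration Mahalanobis** — same robust recipe over
  `ln(concentration)` of the nutrients, no closure, no `Fv`. On clean
  logistic-normal data this ranking nearly coincides with the balance
  distance: with `Fv` carrying ~97% of the dry mass, the map from balances
  to log-concentrations is nearly affine and the Mahalanobis distance is
  affine-invariant. The divergence seen in real surveys comes from
  features (gross contamination, heavy tails) that the clean generator
  deliberately does not model.
- **DRIS** — dual-ratio norms (mean and CV% per ordered pair) from the
  reference, the Walworth–Sumner piecewise ratio function with `k = 1`
  (one member of a family with no canonical form), indices averaging the
  functions per nutrient (antisymmetry supplies reversed pairs, so indices
  sum to zero) and NII as the absolute-index sum.
- **CND-clr** — standardized clr indices against reference clr means and
  SDs. Both clr and DRIS are subcompositionally incoherent: doubling `Fv`
  shifts every index of unchanged nutrients, while all `Fv`-free balances
  are untouched (asserted in the tests).

## Synthetic data generator

Balanced specimens draw their balances from a multivariate normal — the
logistic-normal on the simplex once back-transformed — whose mean and
covariance default to the packaged reference norms (median balances and
TN covariance of the mango survey). A fraction (default 0.6) of specimens
is shifted by −2 reference SD on `[P | S,N]` and `[Mn | Cu,Zn]`, the two
balances flagged in low-yield orchards, the direction matching the
observed TP−TN differences (TP lower on both). Yields (kg fruit tree⁻¹)
are drawn at 165 ± 20 for balanced and 95 ± 20 for imbalanced trees, and
a balanced tree yields from the low component with probability 0.3 —
emulating alternate bearing and other non-nutritional yield losses, which
is what caps NPV near 0.65 while PPV stays near 1. Default `n = 175`
mirrors the survey scale. The covariance is sampled through its
eigendecomposition with negative eigenvalues (possible from printed
rounding) clipped at zero; as packaged, the matrix is positive definite
(smallest eigenvalue ≈ 8e−4). All randomness flows from a single seed.

What the generator does **not** emulate: variety structure, gross
nutrient contamination and heavy tails, spatial/temporal correlation, or
any continuous distance→yield dose response. Tests passing on this
generator therefore show the machinery is correct under the stated
statistical model, not that real surveys will reach the same AUC or
recover cut-offs exactly.

The companion soil table uses log-normal marginals for nutrient pools,
normal pH values, and derives exchangeable acidity from the simulated SMP
buffer pH as `(H+Al) = 10^(7.76 − 1.053·pH_SMP)` mmol꜀ dm⁻³ — the
decreasing form required by the buffer method's chemistry (an acidity
*increasing* with buffer pH would be physically inverted; a buffer
reading near 7.37 corresponds to unit acidity).

## Numerical choices

- Orthonormality, clr zero-sum and ilr round trips asserted to 1e−10;
  SBP-invariance of distances to 1e−8.
- Pseudo-inverse rcond 1e−10; spatial-median tolerance 1e−12 (1000
  iteration cap); closure check 1e−6 relative.
- Youden ties → smallest threshold; AUC ties in the cut-off scan → larger
  cut-off; binormal fit requires ≥3 interior points.
- Degenerate inputs raise with diagnostics: single-class ROC input,
  reference collapse below 2 specimens, `min_tn` above the sample size,
  non-positive concentrations (named row and column), out-of-range SMP pH.

## Problem sizes in the test suite

Unit and acceptance tests run at the survey scale the method targets
(n = 175 specimens, 20 calibration seeds), with 100,000 draws for
generator fidelity, 10,000 rows for outlier-rate checks, and 50
replicates at n = 80 per group for comparison power — about 90 seconds in
total.
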