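# Methods

## Model

HKNN classifies a query by its distance to, per class, the affine hull of
its k nearest same-class neighbors. For class c with neighbors N₁ᶜ…N_kᶜ,
centroid N̄ᶜ and difference vectors Vᵢᶜ = Nᵢᶜ − N̄ᶜ, the coefficients α
minimize ‖x − N̄ᶜ − Σαᵢ Vᵢᶜ‖² + λ‖α‖², giving the normal equations
(VVᵀ + λI)α = V(x − N̄ᶜ) with V the k×d matrix of difference rows. Two
quantities are kept separate: the *objective value* (with the ridge term)
and the *decision distance* (the unpenalized residual); only the latter
enters the class decision. The ridge term exists to regularize the solve,
not to rank classes.

The kernelized form (KHKNN) centers the query in input space first,
x̄ = x − N̄ᶜ, then maps x̄ and the Vᵢᶜ through a feature map and solves
the same system on kernel values: α = (K(V,V) + λI)⁻¹K(V,x̄), with
decision distance K(x̄,x̄) − 2αᵀK(V,x̄) + αᵀK(V,V)α. Input-space
centering before the map is part of the model definition — it is *not*
equivalent to centering in feature space, and the implementation
deliberately does not "correct" it. With the linear kernel the two
formulations coincide (tested to 1e−8), which is the main internal
consistency check of the kernel path.

Neighbors are found by Euclidean distance in input space on both paths;
re-ranking neighbors by the kernel-induced metric is a conceivable variant
but is not implemented. Limiting behaviors, all asserted in tests:

- k = 1: the single difference vector is zero, α contributes nothing, and
  the decision distance is the squared distance to the per-class nearest
  neighbor (on the RBF path the distance is a monotone transform of it, so
  predictions coincide).
- λ → ∞ (linear path): distances tend to ‖x − N̄ᶜ‖², a local-centroid
  classifier.
- λ → ∞ (RBF path): every distance tends to K(x̄,x̄) = 1 and the
  classifier becomes uninformative. This degeneracy is documented and
  asserted rather than hidden.

## Parameters

- **k** (neighbors per class, default 4): capped at the class size when a
  class is smaller than k (routine under leave-one-out on small cohorts);
  the effective k is recorded on the result.
- **γ** (RBF bandwidth, dimensionless, default 2⁻³): swept over
  2⁻⁵…2⁵ in multiplicative steps of 2 (11 values) by the grid search.
  γ = 0 is rejected — it would make every kernel value 1 and the Gram
  system degenerate.
- **λ** (ridge weight, default 1): fixed at 1 for robustness rather than
  tuned; the kernel path requires λ > 0 so the regularized Gram system is
  guaranteed nonsingular. At λ = 0 on the linear path a rank-deficient
  system is resolved by the minimum-norm solution and flagged.
- **standardize** (default on): continuous columns are scaled to zero
  mean/unit variance (population sd, ddof 0) with statistics fitted on the
  training part of each fold only; binary columns and constant columns
  pass through. Local distance methods are scale-sensitive (a constructed
  test shows a 1000× column rescale flipping a prediction), so scaling
  defaults on even though the core accepts raw features.

## Evaluation protocol

Leave-one-out (jackknife): each sample is predicted by a model built on
the remaining n−1 rows, standardization refitted per fold to avoid
leakage, and the n pooled predictions yield one confusion matrix. The
seven metrics (ACC, SN, Spec, PE, NPV, F-score, MCC) are stored as
fractions; percentage rendering (two decimals) happens only in the report
writer. Any metric whose defining denominator is zero is NaN — never
coerced to 0 and never an exception — so a degenerate predict-all-positive
model reports SN=1, Spec=0, NPV=NaN, MCC=NaN. The MCC denominator is
computed as a product of two float square roots to avoid integer overflow
on large counts.

The grid search evaluates every (k, γ) pair by jackknife and selects the
best *finite* MCC; NaN never wins, and exact MCC ties are broken toward
smaller k, then smaller γ (prefer the simpler/smoother model). MCC is the
selection criterion because it is the one metric of the seven that remains
informative under the cohort's 25/34 imbalance. The default grid is
7 × 11 = 77 configurations and runs in a few seconds on a 59-row table.

## Numerical choices

- (Gram + λI) systems are solved by Cholesky factorization (never an
  explicit inverse), with one iterative-refinement step when the residual
  exceeds 1e−10 relative to the right-hand side.
- RBF squared distances are accumulated from explicit coordinate
  differences rather than the ‖a‖² + ‖b‖² − 2aᵀb expansion, so
  near-identical vectors cannot yield negative squared distances.
- A kernel decision distance driven negative by cancellation is clamped to
  0 and logged at debug level.
- Tie-breaking is deterministic and documented: equidistant neighbors by
  ascending training-row index (stable sort), equal class distances toward
  the smaller class id.

## Synthetic cohorts

The generator emulates the study design the method was developed on: 59
patients, a fixed 25 low-risk / 34 high-risk label split, and 32 mixed
predictors (6 binary, 26 continuous — demographics, comorbidities,
biochemistry, nutrition, calcification, and the two stroke scores), each
specified by a mean ± sd or a positive proportion plus a target Pearson
correlation with the label. The label split is fixed, not Bernoulli,
because leave-one-out behavior depends on the realized class sizes.

Each feature is drawn from a single latent factor, z = r·s + √(1−r²)·ε
with s the standardized label and ε independent standard normal noise, so
corr(z, label) ≈ r. Continuous features are affinely mapped to (mean, sd);
binary features are thresholded at the empirical quantile matching their
positive proportion. Consequences, stated rather than corrected:

- Feature–feature correlations are *not* matched (no joint summaries were
  available to match); each feature correlates with the label only.
- Thresholding attenuates the realized point-biserial correlation of
  binary features below |r|.
- Skewed nonnegative quantities (CRP, FGF23, IL-6 have sd comparable to
  or larger than the mean) are generated as plain Gaussians and can go
  negative. An optional `clip_nonnegative` flag floors them at 0, but it
  is off by default because truncation shifts the realized means well away
  from their targets; the default keeps the moments faithful at the price
  of physiologically impossible tails.

Passing tests on these cohorts therefore show the pipeline is correct and
well-behaved under the stated design — not that the classifier would reach
any particular performance on real patients, whose features are skewed,
mutually correlated and measured with error.

When evaluating a generated (or similarly shaped) table, the CHADS2 and
CHA2DS2-VASc columns are excluded from the predictors by default: both
define or near-define the risk-group label and would leak it. The
exclusion list is overridable.

Problem sizes used by the checked examples: classifier equivalences on
100 random instances (n ≤ 60, d ≤ 10), generator fidelity at n = 10⁴,
blob-recovery sanity at 100 points per class in 5 dimensions, and the full
77-point grid on a 59-row cohort — all chosen to make the Monte-Carlo
tolerances tight while keeping the suite fast.

## Clinical scores

CHADS2: 1 point each for age ≥ 75, hypertension, diabetes, congestive
heart failure; 2 for prior stroke/TIA (range 0–6). CHA2DS2-VASc: 1 point
each for CHF, hypertension, diabetes, female sex, vascular disease, age
65–74; 2 each for prior stroke and age ≥ 75, the age bands mutually
exclusive (range 0–9). A score of 0–1 is "low" risk, ≥ 2 "high". The age
threshold is implemented as ≥ 75 throughout.

GNRI = 14.89 × albumin (g/dl) + 41.7 × (actual/ideal body weight). Ideal
body weight is an input, not computed (no formula is part of the scope).
Albumin must be in g/dl; labs commonly report g/L, so a ÷10 converter is
provided and values above 10 g/dl trigger a unit-confusion warning.

AACS: each of eight aortic wall segments (anterior/posterior × L1–L4) is
banded by calcified-length fraction — 0 for none, 1 below one third, 2
from one third to two thirds, 3 above two thirds — and summed (0–24). The
band wording leaves the boundaries open; exactly 1/3 and 2/3 are assigned
to the middle band (closed middle interval), a documented choice.

## Known limitations

- Multi-class input is accepted by the core (C ≥ 2) but all protocol-level
  tests exercise the two-class clinical setting.
- No probability calibration: decision distances rank classes but are not
  calibrated scores.
- Neighbor search is exact brute force; fine at cohort scale, quadratic in
  n. Tree-based acceleration is out of scope.
- The generator's Gaussian marginals understate the heavy tails of acute-
  phase markers; treat absolute performance numbers on synthetic cohorts
  as pipeline diagnostics, not clinical estimates.
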