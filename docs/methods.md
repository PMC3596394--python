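# Methods

## Model

For a random population sample with binary X, Y and an m-vector of
covariates Z, the joint distribution of the pair (X, Y) given Z = z is
modelled by multinomial (softmax) logistic regression over the four
categories (0,0), (0,1), (1,0), (1,1), with (0,0) as reference:

P(X=x, Y=y | z) = exp(α_xy + β_xyᵀ z) / Σ_{x',y'} exp(α_x'y' + β_x'y'ᵀ z),
α₀₀ = 0, β₀₀ = 0,

giving 3 intercepts and 3m slopes. The subject-specific log odds ratio is

η(z) = (α₁₁ − α₁₀ − α₀₁) + (β₁₁ − β₀₁ − β₁₀)ᵀ z = log ψ + δᵀ z,

so δ = β₁₁ − β₀₁ − β₁₀ = 0 ("homogeneity") is exactly the statement that
a single summary odds ratio exp(log ψ) is meaningful. The generalized
Mantel–Haenszel estimator replaces observed stratum cell fractions with
fitted classification probabilities,

OR_gen = Σᵢ p₁₁(zᵢ) p₀₀(zᵢ) / Σᵢ p₁₀(zᵢ) p₀₁(zᵢ),

which (a) is symmetric in X and Y, (b) is a weighted mean of the
subject-specific odds ratios and hence lies between their extremes, and
(c) reduces exactly to the classical Mantel–Haenszel estimator when Z is
one categorical variable and the fit is saturated. Under the homogeneity
constraint, the constrained-ML contrast α̂₁₁ − α̂₁₀ − α̂₀₁ coincides with
log OR_gen evaluated on the constrained fit's probabilities; both
identities are enforced in the test suite at 1e-8/1e-6 relative
tolerance and hold at ~1e-10/1e-16 in practice.

## Fitting

Both fits maximize the same multinomial likelihood by Newton–Raphson on
the observed information, with step-halving when a full step does not
ascend. The constrained fit is a reparameterization: free parameters
(α₀₁, α₁₀, α₁₁, β₀₁, β₁₀) with category (1,1) assigned slope β₀₁ + β₁₀;
a linear "map" per category lets one solver serve the unconstrained,
constrained and binary-logistic (two-category) cases. The constrained
covariance is expanded to the full (3+3m) space through the Jacobian of
the constraint map, so delta-method code downstream is fit-agnostic (the
expanded covariance is singular in exactly m directions, which is checked
in tests).

Numerical choices:

* initialization at zero (uniform probabilities) — the likelihood is
  concave, so initialization is uncritical;
* convergence when the gradient max-norm falls below 1e-8, or when the
  Newton step is already in the quadratic regime (max step < 1e-4, taken
  unconditionally, since log-likelihood differences are then at
  floating-point noise level) and further gains fall below the
  double-precision floor with gradient below 1e-5; iteration cap 200;
* separation is declared when any linear-predictor coefficient exceeds 30
  in magnitude and raises a dedicated error rather than returning
  divergent estimates; no penalization is applied, keeping estimates
  plain ML;
* a collinear design (e.g. a constant covariate column) yields a singular
  information matrix; the covariance then falls back to the Moore–Penrose
  pseudoinverse, which leaves identified contrasts — including the
  intercept contrast log ψ and the OR_gen gradient, both orthogonal to
  the flat directions — correct;
* empty marginal (X,Y) cells make the intercepts unidentifiable and raise
  before fitting; saturated categorical fits additionally need every cell
  in every stratum, so the identity checks redraw degenerate datasets.

## Inference

The SE of log OR_gen comes from the delta method: the gradient of
log Σ p₁₁p₀₀ − log Σ p₁₀p₀₁ is propagated analytically through the
softmax (∂p_c/∂η_d = p_c(1[c=d] − p_d), ∂p₀₀/∂η_d = −p₀₀ p_d; each
product term picks up a −2p_d plus its own indicator) and sandwiched with
the ML covariance. A central finite-difference gradient (h = 1e-6) guards
the algebra in tests (observed max gap ~1e-10), and a nonparametric
bootstrap (B = 500) cross-checks the SE within 10%. Homogeneity is tested
by Wald (δ̂ᵀV_δ⁻¹δ̂) and likelihood-ratio (2Δloglik) statistics against
χ²(m); with m = 0 both tests are vacuous and return p = 1. Confidence
intervals are Wald intervals on the log scale, exponentiated, using
z = 1.959964. The classical MH estimator carries the
Robins–Breslow–Greenland SE (delegated to statsmodels), the standard
companion since the MH point estimator itself comes with no likelihood.
The average-of-subject-specific-log-ORs estimator is linear in the
parameters, so its delta-method SE (gradient = average per-subject
contrast gradient) is exact given the ML covariance.

## Conditional-logistic comparison

Factorizing the joint model as P(Y|X,Z)·P(X|Z) induces a binary logistic
model with γ₀ = α₀₁, γ₁ = log ψ, γ₂ = β₀₁, γ₃ = δ (mirrored for
X given Y). Directly fitted conditional regressions estimate the same
γ₁ but not identically in finite samples, because they ignore the
marginal distribution of the conditioning variable that the joint
likelihood models; the gap is O_p(n^{-1/2}) and is asserted to shrink
with n in tests. With the interaction term included, the Wald test of
γ₃ = 0 is the conditional counterpart of the joint-model homogeneity
test. The default report fits both directions without interaction and a
discrepancy between the two conditional ORs serves as an informal
misspecification/heterogeneity signal.

## Synthetic data

The simulator draws covariates i.i.d. from per-column normal, Bernoulli
or uniform laws — enough to emulate the typical epidemiological mix of a
continuous age-type variable, binary group indicators and dummy-coded
ordinal groups — then samples categories from the model's own softmax
probabilities. Because the truth lives in the fitted parameterization,
log ψ and δ are known exactly. A master seed spawns independent
`SeedSequence` substreams per replicate, so studies are reproducible and
replicates independent. What the generator does **not** emulate: survey
sampling weights and design effects, covariate measurement error,
informative missingness, or model misspecification (the data really are
multinomial-logistic). Passing calibration tests therefore demonstrates
correctness of the estimators and their asymptotic inference under the
assumed model, not robustness to violations of it.

## Study conditions and sizes

The calibration experiments use: n = 2000 with one standard-normal and
one Bernoulli(0.4) covariate, common OR 2 (δ = 0), 500 replicates for
bias and CI coverage (coverage required in [0.92, 0.97]); n = 500, m = 2,
1000 replicates for type-I error of the homogeneity tests at α = 0.05
(rejection rate required in [0.035, 0.065], LR statistic mean in
[1.8, 2.2] against χ²(2)); 50 datasets each for the two identity checks;
B = 500 for the bootstrap cross-check. Confounding in the default
homogeneous scenario is induced by slopes β₀₁ = (0.3, 0.3) and
β₁₀ = (−0.2, −0.2), chosen to attenuate the crude OR noticeably while
keeping all cell probabilities comfortably interior at these sample
sizes.

## Data handling

Input is delimited text with a header; rows missing any selected column
are dropped (complete-case) with the count logged — no imputation.
Categorical covariates get reference-cell dummy coding with the
lexicographically first level as reference unless overridden. Continuous
covariates are not standardized by default (an optional flag exists): the
OR estimators are invariant to affine covariate rescaling at the optimum,
and raw scale keeps coefficients interpretable. No automated
plausible-value screening is attempted; deciding what constitutes an
"improbable value" is left to the analyst.

## Limitations

* Asymptotic (Wald/χ²) inference throughout; no small-sample or sparse-
  strata (matched-pair) corrections, no exact conditional inference, no
  continuity corrections.
* No survey weights.
* The multinomial logistic form is assumed correct; goodness-of-fit
  assessment of that model is out of scope.
* Separation is detected and reported, not resolved (no Firth-type
  penalization).
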