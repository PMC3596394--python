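# genmh — symmetric covariate-adjusted odds ratios

`genmh` estimates the association between two binary variables X and Y
(say, smoking and a persistent viral infection in a cross-sectional
survey) adjusted for confounders Z, with an estimator that treats X and Y
**symmetrically** — unlike binary logistic regression, where regressing Y
on X and Z generally gives a different adjusted odds ratio (and standard
error) than regressing X on Y and Z.

The classical Mantel–Haenszel (MH) estimator is symmetric but only works
when Z defines a limited number of discrete strata:

```
OR_MH = Σ_i (n11i · n00i / n_i) / Σ_i (n10i · n01i / n_i)
```

`genmh` generalizes it to continuous and vector-valued Z by replacing the
observed stratum cell counts with subject-specific classification
probabilities from a joint multinomial logistic model of the four (X, Y)
categories given Z (reference category (0,0)):

```
P(X=x, Y=y | z) ∝ exp(α_xy + β_xyᵀ z),      α_00 = 0, β_00 = 0
OR_gen = Σ_i p11(z_i) p00(z_i) / Σ_i p10(z_i) p01(z_i)
```

When Z is a single categorical variable the saturated fit makes OR_gen
**identical** to the classical MH estimator. Under the homogeneity
hypothesis — the subject-specific odds ratio does not depend on Z, i.e.
δ = β₁₁ − β₀₁ − β₁₀ = 0 — the log odds ratio is also a simple contrast of
the three intercepts, log ψ = α₁₁ − α₁₀ − α₀₁, estimated by constrained
maximum likelihood, and this constrained-ML estimate coincides with OR_gen
computed from the homogeneity model's probabilities. The package provides:

* unconstrained and homogeneity-constrained Newton–Raphson ML fits of the
  multinomial model, with observed-information covariances;
* the classical MH estimator (Robins–Breslow–Greenland SE), the
  generalized probability-based estimator (delta-method SE), the
  constrained-ML estimator, the average of subject-specific log odds
  ratios, and both conditional binary-logistic estimators;
* Wald and likelihood-ratio tests of homogeneity (χ² with df = m), a
  nonparametric bootstrap cross-check, and the algebraic map between the
  joint model and the conditional logistic parameterizations;
* a model-based simulator and a Monte-Carlo study runner for bias,
  coverage and test-size experiments;
* a CLI: `genmh estimate | test-homogeneity | simulate | study`.

## Worked example

Simulate 2000 subjects from a homogeneous model with a common odds ratio
of 2 (log ψ = 0.6931) and two confounders — one standard-normal, one
Bernoulli(0.4) — both positively associated with X and negatively with Y,
then estimate:

```sh
cat > spec.json <<'JSON'
{"n": 2000, "covariates": [["normal", 0, 1], ["bernoulli", 0.4]],
 "alpha": [0.0, 0.0, 0.6931],
 "beta": [[0.3, 0.3], [-0.2, -0.2], [0.1, 0.1]], "seed": 7}
JSON
genmh simulate --spec spec.json --out data.csv
genmh estimate --input data.csv --x x --y y --z z1,z2
```

prints

```
n = 2000 subjects, m = 2 covariate columns

estimator                   OR              95% CI  SE(log OR)
crude                    1.974      [1.643, 2.372]      0.0937
generalized_mh           2.130      [1.766, 2.569]      0.0957
constrained_ml           2.130      [1.765, 2.569]      0.0958
avg_subject_specific     2.134      [1.768, 2.576]      0.0961
logistic_y_on_x          2.131      [1.766, 2.571]      0.0958
logistic_x_on_y          2.130      [1.765, 2.569]      0.0958

homogeneity of the odds ratio over covariates:
  wald   chi2 =    1.855  df = 2  p = 0.3955
  lr     chi2 =    1.858  df = 2  p = 0.3950
  recommended estimate: constrained ML OR (homogeneity not rejected at alpha = 0.05)
```

The crude OR (1.97) is attenuated by the confounding built into the
simulation; every adjusted estimator recovers an OR near 2 within one
standard error (this draw lands at 2.13), the symmetric probability-based
and constrained-ML estimates agree to three decimals, and the homogeneity
tests correctly fail to reject δ = 0, so the report recommends the
constrained-ML estimate.

The same analysis is available programmatically:

```python
from genmh import load_dataset, analyze
data = load_dataset("data.csv", "x", "y", ["z1", "z2"])
print(analyze(data).render())
```

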