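import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genmh import (Dataset, StratifiedTable, classical_mh, constrained_ml_or,
                   crude_or, fit_constrained, fit_unconstrained, generalized_mh,
                   predict_probs, stratify, subject_log_ors)
from genmh.estimators import avg_subject_specific
from genmh.simulate import SimulationSpec, simulate_dataset, simulate_stratified

Z95 = 1.959964


class TestClassicalMH:
    def test_single_stratum_equals_crude(self):
        s = classical_mh(StratifiedTable([[10, 5, 5, 10]]))
        assert s.or_value == pytest.approx(4.0)

    def test_replication_invariance(self):
        one = classical_mh(StratifiedTable([[8, 3, 5, 12]]))
        two = classical_mh(StratifiedTable([[8, 3, 5, 12]] * 2))
        assert two.or_value == pytest.approx(one.or_value)

    def test_zero_margin_stratum_contributes_nothing(self):
        base = classical_mh(StratifiedTable([[8, 3, 5, 12]]))
        withz = classical_mh(StratifiedTable([[8, 3, 5, 12], [0, 0, 4, 6]]))
        assert withz.or_value == pytest.approx(base.or_value)

    def test_zero_denominator_reports_infinite_or(self):
        s = classical_mh(StratifiedTable([[5, 0, 0, 5]]))
        assert np.isinf(s.log_or) and s.log_or > 0
        assert np.isnan(s.se_log_or)

    def test_zero_numerator_reports_zero_or(self):
        s = classical_mh(StratifiedTable([[0, 5, 5, 0]]))
        assert np.isneginf(s.log_or)

    def test_both_zero_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            classical_mh(StratifiedTable([[0, 5, 0, 5]]))

    def test_rbg_se_single_stratum(self):
        # one stratum: RBG variance reduces to the crude 1/a+1/b+1/c+1/d
        s = classical_mh(StratifiedTable([[20, 10, 8, 25]]))
        assert s.se_log_or == pytest.approx(
            np.sqrt(1 / 20 + 1 / 10 + 1 / 8 + 1 / 25))

    @given(st.lists(st.tuples(*[st.integers(1, 40)] * 4), min_size=1, max_size=5))
    @settings(deadline=None, max_examples=50)
    def test_between_stratum_or_extremes(self, cells):
        tab = StratifiedTable(list(map(list, cells)))
        per = [c[3] * c[0] / (c[2] * c[1]) for c in cells]
        s = classical_mh(tab)
        assert min(per) - 1e-12 <= s.or_value <= max(per) + 1e-12


class TestGeneralizedMH:
    def test_uniform_probs_give_or_one(self):
        from genmh.multinomial import ClassificationProbs
        s = generalized_mh(ClassificationProbs(np.full((50, 4), 0.25)))
        assert s.or_value == pytest.approx(1.0)

    def test_saturated_m0_equals_crude(self, tiny_m0_data):
        fit = fit_unconstrained(tiny_m0_data)
        s = generalized_mh(predict_probs(fit, tiny_m0_data))
        assert s.or_value == pytest.approx(crude_or(tiny_m0_data).or_value,
                                           rel=1e-8)

    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 3), (2, 5)])
    def test_categorical_identity_with_classical(self, seed, k):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.full(4, 2.0), size=k)
        d = simulate_stratified(k, probs, [120] * k, seed=seed + 100)
        cl = classical_mh(stratify(d, "stratum"))
        ge = generalized_mh(predict_probs(fit_unconstrained(d), d))
        assert ge.or_value == pytest.approx(cl.or_value, rel=1e-6)

    def test_weighted_mean_of_subject_specific_ors(self, heterogeneous_data):
        p = predict_probs(fit_unconstrained(heterogeneous_data),
                          heterogeneous_data).p
        ratios = p[:, 3] * p[:, 0] / (p[:, 2] * p[:, 1])
        s = generalized_mh(predict_probs(fit_unconstrained(heterogeneous_data),
                                         heterogeneous_data))
        assert ratios.min() - 1e-12 <= s.or_value <= ratios.max() + 1e-12


class TestSubjectLogORs:
    def test_constant_under_constrained_fit(self, heterogeneous_data):
        fit = fit_constrained(heterogeneous_data)
        eta = subject_log_ors(fit, heterogeneous_data).eta
        np.testing.assert_allclose(eta, fit.log_psi, atol=1e-12)

    def test_affine_in_covariates_recovers_delta(self, heterogeneous_data):
        fit = fit_unconstrained(heterogeneous_data)
        eta = subject_log_ors(fit, heterogeneous_data).eta
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(heterogeneous_data.n),
                             heterogeneous_data.z]), eta, rcond=None)
        np.testing.assert_allclose(coef[0], fit.log_psi, atol=1e-9)
        np.testing.assert_allclose(coef[1:], fit.delta, atol=1e-9)

    def test_average_estimator_has_finite_se(self, homogeneous_data):
        fit = fit_unconstrained(homogeneous_data)
        s = avg_subject_specific(fit, homogeneous_data)
        assert 0 < s.se_log_or < 1


class TestConstrainedMLOR:
    def test_requires_constrained_fit(self, homogeneous_data):
        with pytest.raises(ValueError, match="constrained"):
            constrained_ml_or(fit_unconstrained(homogeneous_data))

    def test_m0_equals_crude_closed_form(self, tiny_m0_data):
        s = constrained_ml_or(fit_constrained(tiny_m0_data))
        assert s.log_or == pytest.approx(np.log(25 * 20 / (8 * 10)), abs=1e-9)

    def test_identity_with_generalized_mh_on_constrained_probs(
            self, heterogeneous_data):
        fit = fit_constrained(heterogeneous_data)
        s_param = constrained_ml_or(fit)
        s_gmh = generalized_mh(predict_probs(fit, heterogeneous_data))
        assert s_gmh.log_or == pytest.approx(s_param.log_or, abs=1e-6)

    def test_recovers_truth_in_large_sample(self):
        spec = SimulationSpec.homogeneous(
            5000, np.log(2), [("normal", 0, 1)], seed=13)
        d = simulate_dataset(spec)
        s = constrained_ml_or(fit_constrained(d))
        assert abs(s.log_or - np.log(2)) < 3 * s.se_log_or


class TestORSummaryContracts:
    def test_ci_endpoints_formula(self, tiny_m0_data):
        s = crude_or(tiny_m0_data)
        assert s.ci_low == pytest.approx(np.exp(s.log_or - Z95 * s.se_log_or))
        assert s.ci_high == pytest.approx(np.exp(s.log_or + Z95 * s.se_log_or))
        assert s.ci_low < s.or_value < s.ci_high


class TestSymmetries:
    def test_xy_swap_invariance_all_estimators(self, homogeneous_data):
        d, ds = homogeneous_data, homogeneous_data.swapped()
        for data_pair in [(d, ds)]:
            a, b = data_pair
            assert crude_or(a).log_or == pytest.approx(crude_or(b).log_or,
                                                       abs=1e-12)
            fa, fb = fit_unconstrained(a), fit_unconstrained(b)
            ga = generalized_mh(predict_probs(fa, a))
            gb = generalized_mh(predict_probs(fb, b))
            assert ga.log_or == pytest.approx(gb.log_or, abs=1e-10)
            ca = constrained_ml_or(fit_constrained(a))
            cb = constrained_ml_or(fit_constrained(b))
            assert ca.log_or == pytest.approx(cb.log_or, abs=1e-10)
            assert ca.se_log_or == pytest.approx(cb.se_log_or, abs=1e-10)

    def test_x_relabel_inverts_every_or(self, homogeneous_data):
        d, dr = homogeneous_data, homogeneous_data.relabel_x()
        assert crude_or(dr).log_or == pytest.approx(-crude_or(d).log_or,
                                                    abs=1e-12)
        g = generalized_mh(predict_probs(fit_unconstrained(d), d))
        gr = generalized_mh(predict_probs(fit_unconstrained(dr), dr))
        assert gr.log_or == pytest.approx(-g.log_or, abs=1e-10)
        c = constrained_ml_or(fit_constrained(d))
        cr = constrained_ml_or(fit_constrained(dr))
        assert cr.log_or == pytest.approx(-c.log_or, abs=1e-10)

    def test_m0_limit_all_estimators_equal_crude(self, tiny_m0_data):
        d = tiny_m0_data
        target = crude_or(d).log_or
        fit_u, fit_c = fit_unconstrained(d), fit_constrained(d)
        assert generalized_mh(predict_probs(fit_u, d)).log_or == pytest.approx(
            target, abs=1e-8)
        assert constrained_ml_or(fit_c).log_or == pytest.approx(target, abs=1e-8)
        assert avg_subject_specific(fit_u, d).log_or == pytest.approx(
            target, abs=1e-8)
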