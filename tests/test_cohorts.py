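"""Generator-level checks: sampling structure, truncation moments,
the power-map deformation, the true-SLODR construction, item responses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slodrlab import (
    CaseSelectionParams,
    CorrelationSpec,
    TaskDensityParams,
    TrueSlodrParams,
    apply_case_selection,
    apply_task_density,
    make_detection_bank,
    make_item_bank,
    sample_mvn,
    simulate_item_responses,
    simulate_true_slodr,
    task_density_skewness_oracle,
    truncation_moment_oracle,
)
from slodrlab.cohorts import NonPositiveSemidefiniteError, _piecewise_power


class TestCorrelationSpec:
    def test_default_specs_are_valid(self):
        for spec in (
            CorrelationSpec.case_selection_default(),
            CorrelationSpec.task_density_default(),
            CorrelationSpec.identity(),
            CorrelationSpec.equicorrelated(0.5),
        ):
            assert np.allclose(spec.matrix, spec.matrix.T)
            assert np.allclose(np.diag(spec.matrix), 1.0)

    def test_case_selection_default_values(self):
        m = CorrelationSpec.case_selection_default().matrix
        assert m[0, 1] == 0.71
        assert m[2, 3] == 0.66
        assert m[0, 2] == m[0, 3] == m[1, 2] == m[1, 3] == 0.57

    def test_non_psd_rejected_with_eigenvalue(self):
        with pytest.raises(NonPositiveSemidefiniteError) as err:
            CorrelationSpec.equicorrelated(-0.5)
        assert err.value.eigenvalue < 0


class TestSampleMvn:
    def test_independence_case(self):
        n = 10_000
        c = sample_mvn(CorrelationSpec.identity(), n, seed=0)
        r = np.corrcoef(c.scores, rowvar=False)
        off = r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 4 / np.sqrt(n))

    def test_target_correlation_reached(self):
        c = sample_mvn(CorrelationSpec.case_selection_default(), 17_000, seed=1)
        r = np.corrcoef(c.scores, rowvar=False)
        assert r[0, 1] == pytest.approx(0.71, abs=0.02)
        assert r[2, 3] == pytest.approx(0.66, abs=0.02)

    def test_marginals_standard_normal(self):
        c = sample_mvn(CorrelationSpec.case_selection_default(), 20_000, seed=2)
        assert np.allclose(c.scores.mean(axis=0), 0.0, atol=0.03)
        assert np.allclose(c.scores.std(axis=0), 1.0, atol=0.03)

    def test_seeded_determinism(self):
        spec = CorrelationSpec.case_selection_default()
        a = sample_mvn(spec, 500, seed=7)
        b = sample_mvn(spec, 500, seed=7)
        assert np.array_equal(a.scores, b.scores)

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            sample_mvn(CorrelationSpec.identity(), 5, seed=0)


class TestCaseSelection:
    def test_retained_count_exact(self):
        c = sample_mvn(CorrelationSpec.case_selection_default(), 17_000, seed=3)
        out = apply_case_selection(c, CaseSelectionParams())
        assert out.n == 12_218

    def test_noop_selection(self, small_mvn_cohort):
        params = CaseSelectionParams(
            n_initial=small_mvn_cohort.n, retained_count=small_mvn_cohort.n
        )
        out = apply_case_selection(small_mvn_cohort, params)
        assert np.array_equal(out.scores, small_mvn_cohort.scores)

    def test_cannot_retain_more_than_n(self, small_mvn_cohort):
        with pytest.raises(ValueError):
            apply_case_selection(
                small_mvn_cohort,
                CaseSelectionParams(n_initial=10**6, retained_count=10**6),
            )

    def test_selection_scores_match_truncation_oracle(self):
        """Mean/variance/skewness of the retained PC1 scores agree with the
        closed-form lower-truncated normal within Monte-Carlo error."""
        from slodrlab.cohorts import _standardized_pc1
        from slodrlab.scaling import skewness_g1

        n, kept = 17_000, 12_218
        c = sample_mvn(CorrelationSpec.case_selection_default(), n, seed=4)
        pc1 = _standardized_pc1(c.scores)
        out = apply_case_selection(c, CaseSelectionParams())
        sel = np.sort(pc1)[:kept]
        mean_o, var_o, skew_o = truncation_moment_oracle(kept / n)
        # 3 MC standard errors (normal-theory scaling for var and skew)
        se_mean = np.sqrt(var_o / kept)
        assert sel.mean() == pytest.approx(mean_o, abs=3 * se_mean)
        assert sel.var(ddof=1) == pytest.approx(var_o, abs=3 * var_o * np.sqrt(2 / kept))
        assert skewness_g1(sel) == pytest.approx(skew_o, abs=3 * np.sqrt(6 / kept))
        assert out.provenance["selection_scores_retained_variance"] == pytest.approx(
            var_o, rel=0.05
        )

    def test_threshold_rule(self):
        c = sample_mvn(CorrelationSpec.case_selection_default(), 17_000, seed=5)
        out = apply_case_selection(
            c,
            CaseSelectionParams(
                selection_rule="threshold_on_standardized_score", threshold=0.3
            ),
        )
        # standardized scores below 0.3 retain ~61.8% of the sample
        assert out.n == pytest.approx(0.618 * 17_000, rel=0.02)


class TestTruncationOracle:
    def test_half_normal(self):
        mean, _, _ = truncation_moment_oracle(0.5)
        assert mean == pytest.approx(-np.sqrt(2 / np.pi), abs=1e-10)

    def test_study_fraction_moments(self):
        mean, var, skew = truncation_moment_oracle(12_218 / 17_000)
        assert var == pytest.approx(0.5081, abs=5e-4)
        assert skew == pytest.approx(-0.766, abs=2e-3)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_invalid_fraction(self, bad):
        with pytest.raises(ValueError):
            truncation_moment_oracle(bad)


class TestTaskDensity:
    def test_fixed_points(self):
        x = np.array([[-1.0, 0.0, 1.0, 0.5]])
        out = _piecewise_power(x, 1.7, 0.3)
        assert out[0, 0] == -1.0 and out[0, 1] == 0.0 and out[0, 2] == 1.0

    def test_printed_formula_values(self):
        assert _piecewise_power(np.array([2.0]), 1.08, 0.93)[0] == pytest.approx(
            2**0.93, abs=1e-12
        )
        assert _piecewise_power(np.array([-2.0]), 1.08, 0.93)[0] == pytest.approx(
            -(2**1.08), abs=1e-12
        )

    def test_population_skewness_oracle(self):
        assert task_density_skewness_oracle() == pytest.approx(-0.19, abs=0.01)

    def test_oracle_matches_large_n_simulation(self):
        from slodrlab.scaling import skewness_g1

        rng = np.random.default_rng(6)
        z = rng.standard_normal(1_000_000)
        sim = skewness_g1(_piecewise_power(z, 1.08, 0.93))
        assert sim == pytest.approx(task_density_skewness_oracle(), abs=0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-5000, max_value=5000), min_size=3,
            max_size=30, unique=True,
        ),
        st.floats(min_value=0.2, max_value=3.0),
        st.floats(min_value=0.2, max_value=3.0),
    )
    def test_strictly_order_preserving(self, values, left, right):
        # grid-valued inputs keep x**exponent away from float underflow
        x = np.array(values) / 1000.0
        out = _piecewise_power(x, left, right)
        assert np.array_equal(np.argsort(out), np.argsort(x))

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            TaskDensityParams(left_exponent=0.0)

    def test_unstandardized_input_warns(self, small_mvn_cohort):
        big = small_mvn_cohort.with_transform(
            small_mvn_cohort.scores * 10.0, {"step": "scale"}
        )
        with pytest.warns(UserWarning):
            apply_task_density(big, TaskDensityParams())


class TestTrueSlodr:
    def test_unmoderated_special_case(self):
        params = TrueSlodrParams(
            lambda_f1=(0, 0, 0, 0), theta1=(0, 0, 0, 0),
            theta0=(0.47, 0.47, 0.47, 0.47),
        )
        c = simulate_true_slodr(params, 60_000, seed=7)
        r = np.corrcoef(c.scores, rowvar=False)
        expected = 0.5745**2 + 0.4471**2  # within-pair population correlation
        assert r[0, 1] == pytest.approx(expected, abs=0.02)
        assert r[2, 3] == pytest.approx(expected, abs=0.02)

    def test_default_population_correlations(self):
        c = simulate_true_slodr(TrueSlodrParams(), 10_000, seed=8)
        r = np.corrcoef(c.scores, rowvar=False)
        within = 0.5 * (r[0, 1] + r[2, 3])
        between = np.mean([r[0, 2], r[0, 3], r[1, 2], r[1, 3]])
        assert within == pytest.approx(0.54, abs=0.02)
        assert between == pytest.approx(0.33, abs=0.02)

    def test_third_moment_cancellation(self):
        """theta1 = -2*lambda_f0*lambda_f1 zeroes the population third
        moment of every indicator."""
        from slodrlab.scaling import skewness_g1

        p = TrueSlodrParams()
        assert p.theta1[0] == pytest.approx(-2 * p.lambda_f0[0] * p.lambda_f1[0],
                                            abs=2e-4)
        n = 100_000
        c = simulate_true_slodr(p, n, seed=9)
        for col in c.scores.T:
            assert abs(skewness_g1(col)) < 3 * np.sqrt(6 / n)

    def test_latent_g_stored(self):
        c = simulate_true_slodr(TrueSlodrParams(), 500, seed=10)
        assert c.latent is not None and c.latent["g"].shape == (500,)

    def test_invalid_params_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            TrueSlodrParams(theta0=(0.4, -0.1, 0.4, 0.4))
        with pytest.raises(ValueError):
            TrueSlodrParams(pair_map=(0, 0, 0, 1))


class TestItemResponses:
    def test_logistic_midpoint(self):
        bank = make_item_bank(items_per_scale=30, a=1.7, b_range=(0.5, 0.5))
        resp = simulate_item_responses(bank, np.full(4000, 0.5), seed=11)
        assert resp.responses.mean() == pytest.approx(0.5, abs=0.02)

    def test_guesser_expected_score(self):
        bank = make_item_bank(items_per_scale=30)
        resp = simulate_item_responses(
            bank, np.zeros(2000), guesser_ids=range(2000), seed=12
        )
        assert resp.responses.sum(axis=1).mean() == pytest.approx(6.0, abs=0.3)

    def test_seeded_determinism(self):
        bank = make_item_bank(items_per_scale=12)
        theta = np.linspace(-2, 2, 100)
        a = simulate_item_responses(bank, theta, seed=13)
        b = simulate_item_responses(bank, theta, seed=13)
        assert np.array_equal(a.responses, b.responses)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            from slodrlab.cohorts import ItemBank

            ItemBank(a=np.array([]), b=np.array([]), scale_ids=())

    def test_detection_bank_layout(self):
        bank = make_detection_bank(n_scales=3, n_easy=2, n_hard=5)
        assert bank.n_items == 21
        assert len(bank.scales) == 3
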