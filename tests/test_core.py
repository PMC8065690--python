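"""Unit tests for the generic Bayes-factor engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bftrim as bt
from bftrim import gaussian
from bftrim.core import CorrectionTerm, LogRatioSeries
from bftrim.errors import (
    DegenerateSupportError,
    EmptySubsetError,
    EstimateZeroError,
    InsufficientDrawsError,
    InvalidCorrectionError,
    SchemaError,
    TailPointError,
    UsageError,
    ZeroProbabilityError,
)
from bftrim.models import ModelDensities
from bftrim.student_t import StudentTConfig, student_t_models
from bftrim.trim import TrimRegion

from conftest import make_draws


# ---------------------------------------------------------------------------
# log_ratio_terms
# ---------------------------------------------------------------------------
class TestLogRatioTerms:
    def test_identical_models_give_zero_ratio(self, conj_models):
        g_u, _ = conj_models
        draws = make_draws(["mu"], [[0.1], [2.0], [-3.0]])
        series = bt.log_ratio_terms(draws, g_u, g_u, "sampling_density", y=np.zeros(4))
        assert np.all(series.values == 0.0)

    def test_student_t_sampling_ratio_hand_value(self):
        # T=2, y=(1,-1), h=(1,1), mu=0.5: exponent -mu^2/2*2 + mu*(1-1) = -0.25
        cfg = StudentTConfig(T=2)
        m_u, m_r = student_t_models(cfg)
        draws = make_draws(["mu", "v", "h_1", "h_2"], [[0.5, 8.0, 1.0, 1.0]])
        series = bt.log_ratio_terms(draws, m_u, m_r, "sampling_density", y=np.array([1.0, -1.0]))
        assert series.values[0] == pytest.approx(-0.25, abs=1e-12)

    def test_shift_invariance_of_ratio(self, conj_models):
        g_u, g_r = conj_models
        y = np.array([0.4, -0.2, 1.0])
        draws = make_draws(["mu"], [[0.3], [-1.2], [0.0]])
        base = bt.log_ratio_terms(draws, g_u, g_r, "sampling_density", y=y)

        def shifted(model):
            return ModelDensities(
                model_id=model.model_id,
                log_sampling_density=lambda yy, p, h, f=model.log_sampling_density: f(yy, p, h)
                + 17.3,
                log_param_prior=model.log_param_prior,
                common_params=model.common_params,
                specific_params=model.specific_params,
            )

        shifted_series = bt.log_ratio_terms(
            draws, shifted(g_u), shifted(g_r), "sampling_density", y=y
        )
        np.testing.assert_allclose(shifted_series.values, base.values, atol=1e-12)

    def test_missing_column_is_schema_error(self, conj_models):
        g_u, g_r = conj_models
        draws = make_draws(["not_mu"], [[0.0]])
        with pytest.raises(SchemaError):
            bt.log_ratio_terms(draws, g_u, g_r, "sampling_density", y=np.zeros(2))

    def test_zero_denominator_raises_with_index(self):
        num = ModelDensities("a", lambda y, p, h: np.zeros(len(p["x"])), common_params=("x",))
        den = ModelDensities(
            "b",
            lambda y, p, h: np.where(p["x"] > 0, 0.0, -np.inf),
            common_params=("x",),
        )
        draws = make_draws(["x"], [[1.0], [-1.0], [2.0]])
        with pytest.raises(DegenerateSupportError) as exc:
            bt.log_ratio_terms(draws, num, den, "sampling_density", y=np.zeros(1))
        assert exc.value.draw_index == 1

    def test_latent_and_param_prior_kinds(self):
        cfg = StudentTConfig(T=3)
        m_u, m_r = student_t_models(cfg)
        draws = make_draws(
            ["mu", "v", "h_1", "h_2", "h_3"], [[0.2, 8.0, 1.0, 0.5, 2.0], [0.0, 4.0, 1.0, 1.0, 1.0]]
        )
        # same latent prior in both models -> latent ratio is identically 0
        series = bt.log_ratio_terms(draws, m_u, m_r, "latent_prior")
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)
        # same prior on the shared v block -> param-prior ratio 0
        series = bt.log_ratio_terms(draws, m_u, m_r, "param_prior")
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# bf_uncorrected / bf_corrected
# ---------------------------------------------------------------------------
class TestArithmeticMeans:
    def test_mean_of_one_and_three(self):
        series = LogRatioSeries(np.log([1.0, 3.0]), "full", ("a", "b"))
        est = bt.bf_uncorrected(series)
        assert est.log10_bf == pytest.approx(np.log10(2.0), abs=1e-12)
        assert est.k_retained == est.k_total == 2

    def test_constant_series_is_exact(self):
        series = LogRatioSeries(np.full(50, np.log(0.37)), "full", ("a", "b"))
        est = bt.bf_uncorrected(series)
        assert est.log10_bf == pytest.approx(np.log10(0.37), abs=1e-13)
        assert est.nse_log10 < 1e-15  # numerically zero for a constant series

    def test_all_zero_ratios_raise(self):
        series = LogRatioSeries(np.full(5, -np.inf), "full", ("a", "b"))
        with pytest.raises(EstimateZeroError):
            bt.bf_uncorrected(series)

    def test_corrected_reduces_to_uncorrected_bit_for_bit(self, rng):
        values = rng.normal(size=400)
        series = LogRatioSeries(values, "full", ("a", "b"))
        plain = bt.bf_uncorrected(series)
        reduced = bt.bf_corrected(series, np.ones(400, bool), [])
        assert reduced.log10_bf == plain.log10_bf  # bit-for-bit
        assert reduced.nse_log10 == plain.nse_log10
        full_corr = bt.bf_corrected(
            series, np.ones(400, bool), [CorrectionTerm("Pr(D)", 1.0, "divide")]
        )
        assert full_corr.log10_bf == plain.log10_bf

    def test_self_comparison_is_exactly_zero(self, conj_models):
        g_u, _ = conj_models
        draws = make_draws(["mu"], [[x] for x in np.linspace(-2, 2, 64)])
        series = bt.log_ratio_terms(draws, g_u, g_u, "sampling_density", y=np.zeros(3))
        assert bt.bf_uncorrected(series).log10_bf == 0.0
        est = bt.bf_corrected(
            series,
            np.ones(64, bool),
            [
                CorrectionTerm("p1", 0.25, "divide"),
                CorrectionTerm("p2", 0.25, "multiply"),
            ],
        )
        assert est.log10_bf == pytest.approx(0.0, abs=1e-13)

    def test_empty_subset_and_invalid_correction(self):
        series = LogRatioSeries(np.zeros(10), "full", ("a", "b"))
        with pytest.raises(EmptySubsetError):
            bt.bf_corrected(series, np.zeros(10, bool), [])
        with pytest.raises(InvalidCorrectionError):
            CorrectionTerm("p", 0.0, "divide")
        with pytest.raises(InvalidCorrectionError):
            CorrectionTerm("p", 1.5, "divide")

    @given(st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance_of_estimate(self, shift):
        # adding a constant to both models' log densities cancels in the
        # ratio, so the full estimate must be unchanged to 1e-12
        g_u, g_r = gaussian.gaussian_models()
        y = np.array([0.4, -0.2, 1.0])
        draws = make_draws(["mu"], [[0.3], [-1.2], [0.0], [0.8]])

        def shifted(model):
            return ModelDensities(
                model_id=model.model_id,
                log_sampling_density=lambda yy, p, h, f=model.log_sampling_density: f(yy, p, h)
                + shift,
                log_param_prior=model.log_param_prior,
                common_params=model.common_params,
                specific_params=model.specific_params,
            )

        base = bt.bf_uncorrected(
            bt.log_ratio_terms(draws, g_u, g_r, "sampling_density", y=y)
        ).log10_bf
        moved = bt.bf_uncorrected(
            bt.log_ratio_terms(draws, shifted(g_u), shifted(g_r), "sampling_density", y=y)
        ).log10_bf
        assert moved == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# prob_subset
# ---------------------------------------------------------------------------
class TestProbSubset:
    def test_unbounded_box_gives_one(self):
        draws = make_draws(["x"], [[0.1], [5.0], [-3.0]])
        region = TrimRegion(box={"x": (-np.inf, np.inf)})
        p, se = bt.prob_subset(draws, region)
        assert p == 1.0 and se == 0.0

    def test_half_inside(self):
        draws = make_draws(["x"], [[float(i)] for i in range(10)])
        region = TrimRegion(box={"x": (0.0, 4.0)})
        p, se = bt.prob_subset(draws, region)
        assert p == 0.5
        assert se == pytest.approx(np.sqrt(0.25 / 10), abs=1e-12)

    def test_own_range_box_contains_all(self, rng):
        x = rng.normal(size=200)
        draws = make_draws(["x"], x[:, None])
        region = TrimRegion(box={"x": (float(x.min()), float(x.max()))})
        p, _ = bt.prob_subset(draws, region)
        assert p == 1.0

    def test_zero_probability_raises(self):
        draws = make_draws(["x"], [[0.0], [1.0]])
        with pytest.raises(ZeroProbabilityError):
            bt.prob_subset(draws, TrimRegion(box={"x": (5.0, 6.0)}))

    def test_band_requires_ratios(self):
        draws = make_draws(["x"], [[0.0]])
        region = TrimRegion(box={"x": (-1, 1)}, log_band=(-1.0, 1.0))
        with pytest.raises(ValueError):
            bt.prob_subset(draws, region)


# ---------------------------------------------------------------------------
# NSE
# ---------------------------------------------------------------------------
class TestNSE:
    def test_constant_series_zero(self):
        assert bt.nse_log10(np.zeros(200)) == 0.0

    def test_insufficient_draws(self):
        with pytest.raises(InsufficientDrawsError):
            bt.nse_log10(np.zeros(10), n_batches=20)

    def test_iid_scaling_one_over_sqrt_k(self, rng):
        # NSE should shrink like k^(-1/2): slope ~ -0.5 on log-log
        ks = [1000, 10_000, 100_000]
        nses = []
        for k in ks:
            values = rng.normal(0.0, 1.0, size=k)
            nses.append(bt.nse_log10(values))
        slope = np.polyfit(np.log10(ks), np.log10(nses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_nse_coverage_on_conjugate_example(self, conj_models):
        # two independent runs should agree within 4x combined NSE almost always
        g_u, g_r = conj_models
        rng = np.random.default_rng(99)
        y = gaussian.simulate_data(8, 0.2, rng)
        hits = 0
        n_trials = 100
        for _ in range(n_trials):
            ests = []
            for _run in range(2):
                prior = gaussian.prior_mu_draws(20_000, rng)
                est = bt.estimate_bf_nested(
                    "U_vs_R",
                    "sampling_density",
                    models=(g_u, g_r),
                    y=y,
                    prior_specific=prior,
                    corrected=False,
                )
                ests.append(est)
            diff = abs(ests[0].log10_bf - ests[1].log10_bf)
            tol = 4.0 * np.hypot(ests[0].nse_log10, ests[1].nse_log10)
            hits += diff < tol
        assert hits >= 95


def test_untrimmed_ratio_mean_loses_nse_coverage_in_higher_dimension(conj_models):
    """The pseudo-bias phenomenon on the conjugate pair: with T=30 the
    untrimmed R-vs-U ratio mean has (provably) infinite variance, its
    batch-means NSE stops covering the true error, while the trimmed,
    probability-corrected estimator keeps near-nominal coverage."""
    g_u, g_r = conj_models
    hits_unc = hits_cor = 0
    n_runs = 30
    for seed in range(n_runs):
        rng = np.random.default_rng(42_000 + seed)
        y = gaussian.simulate_data(30, 0.2, rng)
        truth_ru = -gaussian.closed_form_log10_bf_ur(y)
        post = gaussian.posterior_mu_draws(y, 50_000, rng)
        prior = gaussian.prior_mu_draws(50_000, rng)
        unc = bt.estimate_bf_nested(
            "R_vs_U", "sampling_density", models=(g_u, g_r), y=y, draws_u=post, corrected=False
        )
        cor = bt.estimate_bf_nested(
            "R_vs_U",
            "sampling_density",
            models=(g_u, g_r),
            y=y,
            draws_u=post,
            prior_specific=prior,
        )
        hits_unc += abs(unc.log10_bf - truth_ru) < 4.0 * unc.nse_log10
        hits_cor += abs(cor.log10_bf - truth_ru) < 4.0 * cor.nse_log10
    assert hits_cor >= int(0.9 * n_runs)
    assert hits_unc < hits_cor  # trimming + correction restores calibration


# ---------------------------------------------------------------------------
# reciprocal consistency
# ---------------------------------------------------------------------------
class TestReciprocal:
    @staticmethod
    def _est(lbf, nse, direction):
        return bt.BFEstimate(lbf, nse, 100, 100, direction)

    def test_exact_reciprocal_passes(self):
        chk = bt.reciprocal_consistency(
            self._est(0.5, 0.01, ("a", "b")), self._est(-0.5, 0.01, ("b", "a"))
        )
        assert chk.passed and chk.discrepancy_log10 == 0.0

    def test_large_discrepancy_fails(self):
        chk = bt.reciprocal_consistency(
            self._est(1.0, 0.01, ("a", "b")), self._est(-0.2, 0.01, ("b", "a"))
        )
        assert not chk.passed
        assert chk.discrepancy_log10 == pytest.approx(0.8)

    def test_same_direction_is_usage_error(self):
        with pytest.raises(UsageError):
            bt.reciprocal_consistency(
                self._est(1.0, 0.1, ("a", "b")), self._est(1.0, 0.1, ("a", "b"))
            )


# ---------------------------------------------------------------------------
# posterior model probabilities
# ---------------------------------------------------------------------------
class TestModelProbs:
    def test_two_models_even(self):
        np.testing.assert_allclose(
            bt.posterior_model_probs([0.5, 0.5], [1.0, 1.0]), [0.5, 0.5]
        )

    def test_two_models_bf_three(self):
        # B_21 = 3 with equal priors: p(M2|y) = 3/4
        np.testing.assert_allclose(
            bt.posterior_model_probs([0.5, 0.5], [1.0, 3.0]), [0.25, 0.75], atol=1e-14
        )

    @given(st.integers(0, 2**31 - 1))
    def test_reference_invariance(self, seed):
        rng = np.random.default_rng(seed)
        prior = rng.dirichlet(np.ones(3))
        ml = rng.lognormal(size=3)  # implied marginal likelihoods
        p_ref1 = bt.posterior_model_probs(prior, ml / ml[0])
        p_ref2 = bt.posterior_model_probs(prior, ml / ml[1])
        np.testing.assert_allclose(p_ref1, p_ref2, atol=1e-12)
        assert p_ref1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bt.posterior_model_probs([0.5, 0.5], [1.0, -1.0])
        with pytest.raises(ValueError):
            bt.posterior_model_probs([0.7, 0.5], [1.0, 1.0])


# ---------------------------------------------------------------------------
# Savage–Dickey
# ---------------------------------------------------------------------------
class TestSavageDickey:
    def test_posterior_equals_prior(self, rng):
        draws = rng.standard_normal(200_000)
        prior_ln = -0.5 * np.log(2 * np.pi)  # ln N(0|0,1)
        assert bt.savage_dickey_log_bf(draws, prior_ln, 0.0) == pytest.approx(0.0, abs=0.02)

    def test_shrunk_posterior_gives_log10_four(self, rng):
        # posterior N(0, 0.25^2) vs prior N(0,1): density ratio at 0 is 4
        draws = rng.normal(0.0, 0.25, size=200_000)
        prior_ln = -0.5 * np.log(2 * np.pi)
        val = bt.savage_dickey_log_bf(draws, prior_ln, 0.0)
        assert val == pytest.approx(np.log10(4.0), abs=0.02)

    def test_point_outside_draws_raises(self, rng):
        draws = rng.standard_normal(5_000)
        with pytest.raises(TailPointError):
            bt.savage_dickey_log_bf(draws, 0.0, 50.0)

    def test_few_draws_warn(self, rng):
        with pytest.warns(UserWarning):
            bt.savage_dickey_log_bf(rng.standard_normal(500), 0.0, 0.0)


# ---------------------------------------------------------------------------
# estimate serialization
# ---------------------------------------------------------------------------
def test_bf_estimate_serializes_with_conventions():
    est = bt.BFEstimate(
        0.31,
        0.02,
        100,
        40,
        ("M_U", "M_R"),
        corrections=[CorrectionTerm("Pr(D|y,M_U)", 0.5, "divide", 0.01)],
    )
    d = est.to_dict()
    assert d["log10_bf"] == 0.31
    assert "decimal" in d["convention"]
    assert est.log10_corrections == [("Pr(D|y,M_U)", 0.5)]
    pd.testing.assert_frame_equal(pd.DataFrame([d]).iloc[:0], pd.DataFrame([d]).iloc[:0])
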