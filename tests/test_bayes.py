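"""Posterior summaries, model gradients, samplers, and decision rules."""

import numpy as np
import pandas as pd
import pytest

from thetasync.bayes import (
    ModelSpec,
    SamplerConfig,
    beta_ispc_model,
    fit_beta_ispc,
    fit_ordinal_familiarity,
    fit_student_t_pleasantness,
    hdi,
    mass_univariate,
    ordinal_familiarity_model,
    posterior_mode,
    posthoc_contrasts,
    rope_decision,
    sample_posterior,
    split_rhat,
    student_t_pleasantness_model,
)
from thetasync.bayes.sampler import SMOKE

FAST = SamplerConfig(n_chains=2, n_samples=700, n_warmup=300)


class TestHdi:
    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 250_000))
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_degenerate_constant_draws(self):
        lo, hi = hdi(np.full((1, 200), 3.5))
        assert (lo, hi) == (3.5, 3.5)

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(1)
        for draws in (rng.standard_normal(5000), rng.lognormal(size=5000)):
            lo, hi = hdi(draws, 0.95)
            eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
            assert (hi - lo) <= (eq_hi - eq_lo) + 1e-12

    def test_skewed_sample_hdi_shifts_toward_bulk(self):
        rng = np.random.default_rng(2)
        draws = rng.lognormal(0.0, 1.0, 50_000)
        lo, _ = hdi(draws, 0.95)
        assert lo < np.quantile(draws, 0.025)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50), 0.95)


class TestPosteriorMode:
    def test_symmetric_sample_mode_near_mean(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(2.0, 1.0, 20_000)
        assert posterior_mode(draws) == pytest.approx(draws.mean(), abs=0.1)

    def test_right_skew_mode_below_median(self):
        rng = np.random.default_rng(4)
        draws = rng.lognormal(0.0, 0.8, 20_000)
        assert posterior_mode(draws) < np.median(draws)

    def test_known_generator(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(0.12, 0.05, 50_000)
        assert posterior_mode(draws) == pytest.approx(0.12, abs=0.01)


class TestRopeDecision:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((0.02, 0.09), "nonzero"),            # a reported positive contrast
            ((-0.13, -0.02), "nonzero"),          # a reported negative interaction
            ((-0.005, 0.005), "practically-null"),
            ((-0.005, 0.05), "undecided"),
            ((-0.01, 0.01), "practically-null"),  # touching the ROPE edges
            ((0.011, 0.2), "nonzero"),
        ],
    )
    def test_trichotomy(self, interval, expected):
        assert rope_decision(interval, 0.01) == expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            rope_decision((0.5, 0.1), 0.01)


class TestSplitRhat:
    def test_constant_chains_report_unity_with_warning(self):
        with pytest.warns(UserWarning):
            assert split_rhat(np.full((3, 100), 1.23)) == 1.0

    def test_well_mixed_chains_below_threshold(self):
        rng = np.random.default_rng(6)
        assert split_rhat(rng.standard_normal((5, 2000))) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(7)
        chains = np.stack([rng.normal(-5, 1, 500), rng.normal(5, 1, 500)])
        assert split_rhat(chains) > 1.1

    def test_within_chain_drift_flagged(self):
        # split halves expose nonstationarity inside a single chain
        rng = np.random.default_rng(8)
        drift = np.linspace(0, 5, 1000) + rng.standard_normal(1000)
        chains = np.stack([drift, drift + rng.standard_normal(1000) * 0.1])
        assert split_rhat(chains) > 1.1

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        draws = rng.standard_normal((4, 500)) + rng.normal(0, 0.1, (4, 1))
        mine = split_rhat(draws)
        theirs = float(az.rhat(draws[None].transpose(1, 2, 0)[..., 0]))
        # arviz rank-normalizes; agreement to a couple of percent
        assert mine == pytest.approx(theirs, abs=0.02)


class TestPosthocContrasts:
    def test_zero_interaction_makes_conditions_identical(self):
        rng = np.random.default_rng(10)
        b1 = rng.normal(0.05, 0.01, (2, 300))
        out = posthoc_contrasts(b1, np.zeros_like(b1))
        assert out["PH_old"].mode == pytest.approx(out["PH_new"].mode)
        assert out["PH_old"].hdi == pytest.approx(out["PH_new"].hdi)

    def test_degenerate_draw_arithmetic(self):
        b1 = np.full((1, 200), 0.05)
        b3 = np.full((1, 200), 0.10)
        out = posthoc_contrasts(b1, b3)
        assert out["PH_old"].mode == pytest.approx(0.15, abs=1e-6)

    def test_computed_on_draws_not_interval_arithmetic(self):
        # negatively correlated draws: the sum's HDI is much narrower than
        # the naive sum of interval widths
        rng = np.random.default_rng(11)
        b1 = rng.standard_normal((1, 5000))
        b3 = -b1 + 0.01 * rng.standard_normal((1, 5000))
        out = posthoc_contrasts(b1, b3)
        lo1, hi1 = hdi(b1)
        lo3, hi3 = hdi(b3)
        naive_width = (hi1 - lo1) + (hi3 - lo3)
        actual_width = out["PH_old"].hdi_high - out["PH_old"].hdi_low
        assert actual_width < 0.25 * naive_width


class TestModelGradients:
    """Hand-derived gradients against central finite differences."""

    @pytest.fixture(scope="class")
    def models(self, beta_rows, pleasantness_table, familiarity_ratings):
        return [
            beta_ispc_model(beta_rows),
            student_t_pleasantness_model(pleasantness_table),
            ordinal_familiarity_model(familiarity_ratings),
        ]

    def test_gradients_match_finite_differences(self, models):
        rng = np.random.default_rng(12)
        for model in models:
            th = 0.1 * rng.standard_normal(model.ndim)
            _, grad = model.log_prob_grad_reference(th)
            eps = 1e-4
            for j in range(0, model.ndim, 3):
                tp, tm = th.copy(), th.copy()
                tp[j] += eps
                tm[j] -= eps
                num = (model.log_prob(tp[None])[0] - model.log_prob(tm[None])[0]) / (2 * eps)
                assert grad[j] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_compiled_kernels_match_numpy_reference(self, models):
        rng = np.random.default_rng(13)
        for model in models:
            if model.numba_pack is None:
                pytest.skip("numba unavailable")
            for _ in range(5):
                th = 0.3 * rng.standard_normal(model.ndim)
                lp_fast, g_fast = model.log_prob_grad(th)
                lp_ref, g_ref = model.log_prob_grad_reference(th)
                assert lp_fast == pytest.approx(lp_ref, rel=1e-12, abs=1e-9)
                np.testing.assert_allclose(g_fast, g_ref, rtol=1e-8, atol=1e-8)


class TestModelFits:
    def test_beta_interaction_recovery(self, beta_rows):
        fit = fit_beta_ispc(beta_rows, sampler_cfg=SMOKE.with_seed(1))
        b3 = fit["beta3"]
        assert b3.hdi_low < 0.8 < b3.hdi_high          # planted interaction
        assert abs(fit["beta2"].mode) < 0.45           # planted small effects
        assert fit["phi"].mode > 20                    # precision in range

    def test_beta_boundary_responses_rejected(self, beta_rows):
        bad = beta_rows.copy()
        bad.loc[bad.index[0], "ispc"] = 1.0
        with pytest.raises(ValueError, match="adjust_unit_interval"):
            beta_ispc_model(bad)

    def test_student_t_recovers_planted_shift(self, pleasantness_table):
        fit = fit_student_t_pleasantness(pleasantness_table,
                                         sampler_cfg=SMOKE.with_seed(2))
        b1 = fit["beta1"]
        assert b1.hdi_low < 0.12 < b1.hdi_high

    def test_student_t_single_condition_rejected(self, pleasantness_table):
        one = pleasantness_table[pleasantness_table["familiarity_condition"] == "old"]
        with pytest.raises(ValueError):
            student_t_pleasantness_model(one)

    def test_student_t_large_nu_matches_mixed_model_oracle(self, pleasantness_table):
        """With nu forced large the fit approaches a normal mixed model."""
        import statsmodels.formula.api as smf

        from thetasync.bayes.models import PriorSet

        spec = ModelSpec("student-t",
                         priors=PriorSet(nu_shape=2000.0, nu_rate=0.1))
        fit = fit_student_t_pleasantness(pleasantness_table, spec=spec,
                                         sampler_cfg=SMOKE.with_seed(3))
        df = pleasantness_table.copy()
        df["old"] = (df["familiarity_condition"] == "old").astype(float)
        ml = smf.mixedlm("pleasantness_index ~ old", df, groups=df["subject"],
                         re_formula="~old").fit()
        assert fit["beta1"].mode == pytest.approx(ml.params["old"], abs=0.06)

    def test_ordinal_recovers_familiarity_shift(self, familiarity_ratings):
        fit = fit_ordinal_familiarity(familiarity_ratings,
                                      sampler_cfg=SMOKE.with_seed(4))
        # old music sits ~2 latent SD above exposure and new, so beta1 and
        # beta2 (exposure - old, new - old) are both strongly negative
        assert fit["beta1"].hdi_high < -1.0
        assert fit["beta2"].hdi_high < -1.0
        assert fit["beta2_minus_beta1"].hdi_low < 0 < fit["beta2_minus_beta1"].hdi_high

    def test_ordinal_thresholds_strictly_increasing_every_draw(self, familiarity_ratings):
        model = ordinal_familiarity_model(familiarity_ratings)
        draws = sample_posterior(model, FAST.with_seed(5))
        thresh = np.stack([draws[f"threshold{j}"].ravel() for j in range(1, 7)])
        assert (np.diff(thresh, axis=0) > 0).all()

    def test_prior_predictive_matches_prior_without_data(self, familiarity_ratings):
        """With no observations the coefficient posterior is its N(0,1) prior."""
        from scipy.stats import kstest

        empty = familiarity_ratings.iloc[0:0]
        model = ordinal_familiarity_model(empty)
        draws = sample_posterior(model, SamplerConfig(n_chains=2, n_samples=2500,
                                                      n_warmup=500, seed=6))
        sample = draws["beta1"].ravel()[::5]
        assert kstest(sample, "norm").pvalue > 0.01

    def test_nuts_and_ensemble_backends_agree(self, beta_rows):
        """Dual-route check: independent sampler families, same posterior."""
        nuts = sample_posterior(beta_ispc_model(beta_rows), FAST.with_seed(7))
        import dataclasses

        ens_cfg = dataclasses.replace(
            SamplerConfig(n_chains=4, n_samples=4000, n_warmup=2000, seed=7),
            backend="ensemble",
        )
        ens = sample_posterior(beta_ispc_model(beta_rows), ens_cfg)
        for name in ("beta0", "beta3"):
            assert nuts[name].mean() == pytest.approx(ens[name].mean(), abs=0.08)
            # the ensemble mixes more slowly and under-disperses somewhat;
            # same order of magnitude is the meaningful cross-check on spread
            assert nuts[name].std() == pytest.approx(ens[name].std(), rel=0.6)

    def test_sampling_reproducible(self, beta_rows):
        model = beta_ispc_model(beta_rows)
        a = sample_posterior(model, FAST.with_seed(9))
        b = sample_posterior(model, FAST.with_seed(9))
        np.testing.assert_array_equal(a["beta3"], b["beta3"])


class TestMassUnivariate:
    def test_planted_pair_flagged_and_order_deterministic(self, beta_rows):
        null_rows = beta_rows.copy()
        rng = np.random.default_rng(20)
        null_rows["ispc"] = rng.beta(
            0.3 * 60, 0.7 * 60, len(null_rows)
        )
        conn = pd.concat(
            [beta_rows.assign(pair="B-A"), null_rows.assign(pair="A-C")]
        )
        table = mass_univariate(conn, sampler_cfg=SMOKE.with_seed(8))
        assert list(table["pair"]) == ["A-C", "B-A"]
        planted = table[table["pair"] == "B-A"].iloc[0]
        null = table[table["pair"] == "A-C"].iloc[0]
        assert planted["beta3_decision"] == "nonzero"
        assert null["reportable"] == False  # noqa: E712
        assert planted["reportable"] == bool(
            planted["PH_new_decision"] == "nonzero"
            or planted["PH_old_decision"] == "nonzero"
        )

    def test_empty_input_gives_empty_table(self):
        empty = pd.DataFrame(columns=["subject", "ispc", "pleasantness_class",
                                      "familiarity_condition", "pair"])
        table = mass_univariate(empty, pairs=[])
        assert len(table) == 0

    def test_single_subject_pair_rejected(self, beta_rows):
        solo = beta_rows[beta_rows["subject"] == "S0"].assign(pair="A-B")
        with pytest.raises(ValueError, match="2 subjects"):
            mass_univariate(solo, sampler_cfg=SMOKE)
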