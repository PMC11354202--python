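"""Distributional-measure tests: CDF/CAF construction, the repeated-measures
ANOVA against a hand-computed sums-of-squares decomposition (and pingouin),
the posterior overlap indicator's calibration, credible bands, and the
growth-function integration time against a frozen quadrature oracle."""

import numpy as np
import pingouin as pg
import pandas as pd
import pytest

from tvddm import (
    DDMParams,
    PosteriorDraws,
    SimConfig,
    caf,
    cdf_quantiles,
    credible_band,
    group_summary,
    growth_theta,
    integration_time,
    model_summary,
    posterior_overlap,
    rm_anova,
    summarize_trials,
)

from conftest import DDM_REF_PURE


class TestCdfQuantiles:
    def test_uniform_sample_recovers_levels(self, rng):
        q = cdf_quantiles(rng.uniform(0, 1, 100_000))
        assert np.allclose(q, np.arange(0.10, 0.9001, 0.05), atol=0.01)

    def test_seventeen_levels(self, rng):
        assert len(cdf_quantiles(rng.uniform(0, 1, 100))) == 17

    def test_constant_sample(self):
        assert np.all(cdf_quantiles(np.full(20, 0.42)) == 0.42)

    def test_nondecreasing(self, rng):
        assert np.all(np.diff(cdf_quantiles(rng.gamma(3, 0.2, 500))) >= 0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            cdf_quantiles(np.arange(16))


class TestCaf:
    def test_all_correct_data(self, rng):
        rt, acc = caf(rng.uniform(0.3, 1.0, 200), np.ones(200))
        assert len(rt) == len(acc) == 5
        assert np.all(acc == 1.0)
        assert np.all(np.diff(rt) > 0)

    def test_independent_correctness_is_flat(self, rng):
        # coin-flip correctness independent of RT: every band's accuracy
        # sits within 3 binomial SEs of the overall rate
        n = 5000
        rts = rng.gamma(3, 0.2, n)
        correct = rng.random(n) < 0.5
        _rt, acc = caf(rts, correct)
        se = np.sqrt(0.25 / (n / 5))
        assert np.all(np.abs(acc - correct.mean()) < 3 * se)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            caf(np.arange(9) + 0.3, np.ones(9))


class TestModelSummary:
    def test_easy_decision_has_no_errors(self):
        s = model_summary(DDMParams(A=0.3, ter=0.2, v=0.5), 2000, seed=1)
        assert s.error_rate < 0.005

    def test_driftless_decision_is_chance(self):
        s = model_summary(DDMParams(A=0.15, ter=0.2, v=0.0), 2000, seed=2)
        assert s.error_rate == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 2000))

    def test_group_summary_averages(self, rng):
        summaries = [
            model_summary(DDM_REF_PURE, 500, seed=s) for s in (1, 2, 3)
        ]
        g = group_summary(summaries)
        assert g.error_rate == pytest.approx(
            np.mean([s.error_rate for s in summaries])
        )
        assert np.allclose(
            g.cdf_rts, np.mean([s.cdf_rts for s in summaries], axis=0)
        )


def _synthetic_posterior(rng, center, sd_scale, n=400):
    """Posterior-draw stand-in: independent normal draws around a center
    (synthetic; no sampler involved)."""
    d = len(center)
    x = center + sd_scale * np.abs(center) * rng.standard_normal((2, n, d))
    x = np.abs(x)
    return PosteriorDraws(x, DDMParams.names(), burn_in=0)


class TestCredibleBand:
    def test_degenerate_posterior_gives_zero_width(self):
        center = DDM_REF_PURE.to_vector()
        draws = PosteriorDraws(
            np.tile(center, (2, 50, 1)), DDMParams.names(), burn_in=0
        )
        lo, hi = credible_band([draws], DDMParams, n_samples=20, n_trials=300, seed=3)
        assert np.allclose(lo, hi)

    def test_width_tracks_posterior_spread(self, rng):
        center = DDM_REF_PURE.to_vector()
        widths = []
        for scale in (0.1, 0.05):
            draws = _synthetic_posterior(rng, center, scale)
            lo, hi = credible_band(
                [draws], DDMParams, n_samples=40, n_trials=300, seed=4
            )
            widths.append(np.mean(hi - lo))
        assert widths[1] < widths[0]

    def test_band_covers_central_summary(self, rng):
        # a tight synthetic posterior around the truth: the EAP-based
        # summary should fall inside the band at nearly every point
        center = DDM_REF_PURE.to_vector()
        draws = _synthetic_posterior(rng, center, 0.08)
        lo, hi = credible_band([draws], DDMParams, n_samples=60, n_trials=400, seed=5)
        s = model_summary(DDMParams.from_vector(draws.flat().mean(axis=0)),
                          400, seed=6).stack()
        frac_inside = np.mean((s >= lo) & (s <= hi))
        assert frac_inside >= 0.9


class TestRmAnova:
    # 4 participants x 3 conditions; sums of squares by hand: grand mean 5,
    # condition means (4, 5, 6) -> SS_cond = 4*(1+0+1) = 8; subject means
    # (13, 17, 16, 14)/3 -> SS_subj = 3*(4/9+4/9+1/9+1/9) = 10/3;
    # SS_total = 14 -> SS_err = 14 - 8 - 10/3 = 8/3;
    # F = (8/2) / ((8/3)/6) = 9.0 with df = (2, 6)
    TABLE = np.array([
        [3.0, 4.0, 6.0],
        [5.0, 5.0, 7.0],
        [4.0, 6.0, 6.0],
        [4.0, 5.0, 5.0],
    ])

    def test_hand_computed_sums_of_squares(self):
        f, df1, df2, _p = rm_anova(self.TABLE)
        assert (f, df1, df2) == (pytest.approx(9.0), 2, 6)

    def test_matches_pingouin(self):
        n, k = self.TABLE.shape
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
            "y": self.TABLE.ravel(),
        })
        res = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        f, _d1, _d2, p = rm_anova(self.TABLE)
        pcol = "p_unc" if "p_unc" in res.columns else "p-unc"
        assert f == pytest.approx(float(res["F"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(res[pcol].iloc[0]), rel=1e-6)

    def test_no_condition_effect(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        f, _d1, _d2, p = rm_anova(x)
        assert f == 0.0 and p == 1.0

    def test_location_invariance(self, rng):
        x = rng.standard_normal((6, 4))
        f1, *_ = rm_anova(x)
        f2, *_ = rm_anova(x + 100.0)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rm_anova(np.ones((2, 3)))  # too few participants
        bad = self.TABLE.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(bad)


class TestPosteriorOverlap:
    @staticmethod
    def _cells(rng, shift_per_condition):
        return {
            f"p{i}": {
                f"c{j}": rng.normal(j * shift_per_condition, 1.0, 500)
                for j in range(4)
            }
            for i in range(8)
        }

    def test_null_is_calibrated(self, rng):
        res = posterior_overlap(self._cells(rng, 0.0), n_reps=1000, seed=1)
        assert res.proportion_significant <= 0.10
        assert not res.decision

    def test_separated_posteriors_always_reject(self, rng):
        res = posterior_overlap(self._cells(rng, 10.0), n_reps=200, seed=2)
        assert res.proportion_significant == 1.0
        assert res.decision

    def test_decision_threshold(self):
        from tvddm.measures import OverlapResult
        assert OverlapResult(0.95, 1000, 10, 0.05).decision
        assert not OverlapResult(0.949, 1000, 10, 0.05).decision


class TestIntegrationTime:
    def test_single_stage_closed_form(self):
        # n=1: theta(t) = 1 - exp(-beta t) -> t* = -ln(1-level)/beta
        assert integration_time(25.0, 1.0, 0.97) == pytest.approx(
            -np.log(0.03) / 25.0, abs=1e-9
        )

    def test_faster_growth_shortens_integration(self):
        times = [integration_time(b, 5.0) for b in (10.0, 25.0, 80.0)]
        assert times[0] > times[1] > times[2]

    def test_frozen_quadrature_oracle_value(self):
        # regression value computed once by adaptive quadrature of the
        # incomplete-gamma integrand plus bisection on the 97% level
        assert integration_time(25.0, 5.0, 0.97) == pytest.approx(
            0.3984382002, abs=1e-6
        )

    def test_consistent_with_growth_function(self):
        t = integration_time(30.0, 4.0, 0.97)
        assert growth_theta(t, 30.0, 4.0) == pytest.approx(0.97, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            integration_time(-1.0, 5.0)
        with pytest.raises(ValueError):
            integration_time(25.0, 5.0, level=1.0)
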