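"""Concentration indices, equity gaps, bounds, curves, and the suite."""
import numpy as np
import pandas as pd
import pytest

import vaxequity as vx
from vaxequity.metrics import quintile_summary
from vaxequity.simulate import DoseEffects

from conftest import manual_population

TOY_Y = np.array([0, 0, 1, 1, 1], dtype=float)
TOY_F = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


class TestWagstaff:
    def test_five_person_toy(self):
        # mu=0.6, Cov=E[yF]-E[y]E[F]=0.42-0.30=0.12, CI=2/0.6*0.12=0.4
        assert vx.wagstaff_ci(TOY_Y, TOY_F) == pytest.approx(0.4, abs=1e-12)

    def test_constant_coverage_has_zero_index(self):
        assert vx.wagstaff_ci(np.ones(5), TOY_F) == pytest.approx(0.0, abs=1e-12)

    def test_reversing_the_ranking_negates_the_index(self):
        assert vx.wagstaff_ci(TOY_Y, 1 - TOY_F) == pytest.approx(-0.4, abs=1e-12)

    def test_zero_mean_coverage_is_undefined(self):
        with pytest.raises(ValueError, match="mean coverage is zero"):
            vx.wagstaff_ci(np.zeros(5), TOY_F)

    def test_weight_scale_invariance(self):
        w = np.array([1.0, 2, 3, 4, 5])
        a = vx.wagstaff_ci(TOY_Y, TOY_F, w)
        b = vx.wagstaff_ci(TOY_Y, TOY_F, w * 17.3)
        assert a == pytest.approx(b, abs=1e-14)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        perm = rng.permutation(5)
        w = np.array([1.0, 2, 1, 2, 1])
        assert vx.wagstaff_ci(TOY_Y[perm], TOY_F[perm], w[perm]) == \
            pytest.approx(vx.wagstaff_ci(TOY_Y, TOY_F, w), abs=1e-14)


class TestErreygers:
    def test_product_formula(self):
        assert vx.erreygers_ci(0.6, 0.4) == pytest.approx(0.96)
        assert vx.erreygers_ci(0.25, 0.2) == pytest.approx(0.2)
        assert vx.erreygers_ci(0.77, 0.0) == 0.0

    def test_mu_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            vx.erreygers_ci(1.2, 0.1)


class TestAbsoluteEquityGap:
    def test_two_stratum_population_recovers_planted_gap(self):
        # deterministic construction: each quintile of 200 children gets
        # exact coverage — bottom 0.5, middle 0.7, top 0.9 -> AEG 0.4
        cov = {1: 0.5, 2: 0.7, 3: 0.7, 4: 0.7, 5: 0.9}
        y = np.concatenate([np.r_[np.ones(int(200 * cov[q])),
                                  np.zeros(200 - int(200 * cov[q]))]
                            for q in range(1, 6)])
        frank = (np.arange(1000) + 0.5) / 1000
        aeg, summary = vx.absolute_equity_gap(y, frank)
        assert summary.loc[1, "coverage"] == pytest.approx(0.5, abs=1e-12)
        assert summary.loc[5, "coverage"] == pytest.approx(0.9, abs=1e-12)
        assert aeg == pytest.approx(0.4, abs=1e-12)

    def test_uniform_coverage_gives_zero_gap(self):
        y = np.tile([0.0, 1.0], 500)
        frank = (np.arange(1000) + 0.5) / 1000
        aeg, _ = vx.absolute_equity_gap(y, frank)
        assert aeg == pytest.approx(0.0, abs=1e-12)

    def test_everyone_vaccinated_gives_zero_gap(self):
        frank = (np.arange(100) + 0.5) / 100
        aeg, _ = vx.absolute_equity_gap(np.ones(100), frank)
        assert aeg == 0.0

    def test_empty_extreme_quintile_errors(self):
        with pytest.raises(ValueError, match="extreme rank quintile"):
            vx.absolute_equity_gap(np.array([1.0, 0.0]), np.array([0.5, 0.5]))


class TestConfidenceBounds:
    def test_printed_formula_arithmetic(self):
        y = np.r_[np.zeros(50), np.full(50, 0.4)]  # Var(y) = 0.04 exactly
        low, high = vx.ci_confidence_bounds(0.1, y, mode="as_printed")
        assert (low, high) == (pytest.approx(0.1 - 0.392), pytest.approx(0.1 + 0.392))

    def test_estimator_mode_narrows_with_sample_size(self):
        y = np.r_[np.zeros(50), np.full(50, 0.4)]
        low, high = vx.ci_confidence_bounds(0.1, y, mode="estimator")
        assert (high - low) == pytest.approx(2 * 1.96 * 0.2 / 10)  # sqrt(0.04/100)

    def test_degenerate_variance_gives_point_interval(self):
        low, high = vx.ci_confidence_bounds(0.3, np.ones(10), mode="as_printed")
        assert low == high == 0.3

    def test_bounds_are_symmetric_about_the_index(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50).astype(float)
        for mode in ("as_printed", "estimator"):
            low, high = vx.ci_confidence_bounds(0.123, y, mode=mode)
            assert (low + high) / 2 == pytest.approx(0.123, abs=1e-12)

    def test_aeg_bounds_toy(self):
        summary = pd.DataFrame({"n": [100, 0, 0, 0, 100],
                                "coverage": [0.5, np.nan, np.nan, np.nan, 0.9],
                                "s": [0.5, np.nan, np.nan, np.nan, 0.3]},
                               index=pd.Index([1, 2, 3, 4, 5], name="quintile"))
        low, high = vx.aeg_confidence_bounds(0.4, summary)
        assert low == pytest.approx(0.286, abs=5e-4)
        assert high == pytest.approx(0.514, abs=5e-4)

    def test_aeg_bounds_zero_variance_point_interval(self):
        summary = pd.DataFrame({"n": [10, 0, 0, 0, 10],
                                "coverage": [0.2, np.nan, np.nan, np.nan, 0.8],
                                "s": [0.0, np.nan, np.nan, np.nan, 0.0]},
                               index=pd.Index([1, 2, 3, 4, 5], name="quintile"))
        assert vx.aeg_confidence_bounds(0.6, summary) == (0.6, 0.6)


class TestEquityLevel:
    def test_complement_of_absolute_index(self):
        assert vx.equity_level(0.0) == 1.0
        assert vx.equity_level(-0.3) == pytest.approx(0.7)

    def test_report_rounding_is_half_up(self):
        assert vx.round_half_up(vx.equity_level(0.425), 2) == 0.58
        assert vx.round_half_up(vx.equity_level(0.427), 2) == 0.57


class TestConcentrationCurve:
    def test_constant_outcome_lies_on_the_diagonal(self):
        frank = (np.arange(20) + 0.5) / 20
        px, py = vx.concentration_curve(np.ones(20), frank)
        assert np.allclose(px, py)

    def test_endpoints_are_exact(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 30).astype(float)
        y[0] = 1.0
        px, py = vx.concentration_curve(y, rng.random(30), rng.random(30) + 0.5)
        assert (px[0], py[0]) == (0.0, 0.0)
        assert (px[-1], py[-1]) == (1.0, 1.0)
        assert np.all(np.diff(px) >= 0) and np.all(np.diff(py) >= 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_curve_area_reproduces_covariance_index(self, seed):
        """Twice the area between the curve and the 45-degree line must
        equal the covariance form, including under ties and weights."""
        rng = np.random.default_rng(seed)
        n = 200
        y = rng.integers(0, 2, n).astype(float)
        y[0] = 1.0
        values = rng.integers(0, 20, n).astype(float)  # many ties
        w = rng.random(n) + 0.2
        frank = vx.fractional_rank(values, w)
        ci = vx.wagstaff_ci(y, frank, w)
        assert vx.ci_from_curve(*vx.concentration_curve(y, frank, w)) == \
            pytest.approx(ci, abs=1e-10)


class TestEquitySuite:
    def test_planted_pro_privileged_gradient_yields_positive_index(self):
        effects = {"bcg": DoseEffects(0.5, {"residence": {"rural": -1.2}})}
        cfg = vx.SimConfig(n_children=20_000, seed=6, effects=effects,
                           child_effect_sd=0.0)
        pop = vx.generate_population(cfg)
        outcomes = vx.derive_outcomes(pop, cfg.schedule)
        res = vx.compute_equity_suite(pop, outcomes, vx.FairnessSpec(), ["bcg"])["bcg"]
        assert res.ci_wagstaff > 0.01
        assert res.aeg > 0.0
        assert res.ci_erreygers == pytest.approx(4 * res.mu * res.ci_wagstaff)

    def test_wealth_only_and_composite_agree_when_only_ses_drives_coverage(self):
        """If coverage depends on the SES quintile alone, ranking by the
        continuous SES score and by predicted coverage give the same
        concentration index up to Monte-Carlo error."""
        from scipy.special import expit
        pop = manual_population(30_000, seed=7)
        rng = np.random.default_rng(7)
        p = expit(-0.5 + 0.45 * (pop["ses_quintile"].to_numpy() - 3))
        y = (rng.random(len(pop)) < p).astype(float)
        outcomes = pd.DataFrame({"bcg": y}, index=pop.index)
        spec = vx.FairnessSpec()
        comp = vx.compute_equity_suite(pop, outcomes, spec, ["bcg"])["bcg"]
        wealth = vx.compute_equity_suite(pop, outcomes, spec, ["bcg"],
                                         ranking_kind="wealth_only")["bcg"]
        assert comp.ci_wagstaff == pytest.approx(wealth.ci_wagstaff, abs=0.02)

    def test_stronger_planted_gap_increases_index_and_gap(self):
        """Monotone inequity response: widening the privileged vs
        disadvantaged coverage gap raises both CI and AEG."""
        results = []
        for beta in (np.log(2), np.log(6)):
            effects = {"bcg": DoseEffects(0.0, {"residence": {"rural": -beta}})}
            cfg = vx.SimConfig(n_children=20_000, seed=8, effects=effects,
                               child_effect_sd=0.0)
            pop = vx.generate_population(cfg)
            outcomes = vx.derive_outcomes(pop, cfg.schedule)
            results.append(vx.compute_equity_suite(pop, outcomes,
                                                   vx.FairnessSpec(), ["bcg"])["bcg"])
        assert results[1].ci_wagstaff > results[0].ci_wagstaff
        assert results[1].aeg > results[0].aeg

    def test_quintile_summary_counts_cover_everyone(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 500).astype(float)
        frank = vx.fractional_rank(rng.random(500))
        summary = quintile_summary(y, frank)
        assert summary["n"].sum() == 500
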