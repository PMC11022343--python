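"""Demography: pcgr, interval selection, pooled fits, influence
exclusion, carrying capacity with delta-method variance."""

import math

import numpy as np
import pandas as pd
import pytest

from strainlink.demography import (
    DensityDependenceFit,
    GrowthObservation,
    InfluenceRule,
    build_observations,
    carrying_capacity,
    compute_pcgr,
    exclude_influential,
    fit_curve,
    select_intervals,
)


def _obs(n_start, pcgr_value, cond="c1", rep=1, dil=0.5):
    """Observation engineered to have a given pcgr at a given N_start."""
    return GrowthObservation(
        condition_id=cond,
        replicate=rep,
        dilution=dil,
        n_start=n_start,
        n_end=n_start * math.exp(pcgr_value),
        t_start=0.0,
        t_end=1.0,
        interval_label="t0->t1",
    )


class TestPcgr:
    def test_doubling_in_a_day(self):
        assert compute_pcgr(100, 200, 0, 1) == pytest.approx(math.log(2), abs=1e-4)

    def test_no_growth(self):
        assert compute_pcgr(500, 500, 0, 1) == 0.0

    def test_e_fold_over_two_days(self):
        assert compute_pcgr(100, 100 * math.e, 0, 2) == pytest.approx(0.5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            compute_pcgr(0, 100, 0, 1)
        with pytest.raises(ValueError):
            compute_pcgr(100, 200, 1, 1)


def _samples_table(densities_by_tp, assay_id="a1", dilutions=(0.2, 0.5, 0.8)):
    """Small samples table: same fold pattern at every dilution."""
    rows = []
    for dil_scale, dil in zip((1.0, 1.0, 1.0), dilutions):
        for tp, (t, dens) in enumerate(densities_by_tp):
            rows.append(
                {
                    "sample_id": f"{assay_id}|{dil}|{tp}",
                    "condition_id": "c1",
                    "assay_id": assay_id,
                    "species": "X",
                    "strain": "X-S1",
                    "temperature": 22.0,
                    "pollutant": 0.0,
                    "replicate": 1,
                    "dilution": dil,
                    "time_point": tp,
                    "t_days": t,
                    "density": dens * dil * dil_scale,
                }
            )
    return pd.DataFrame(rows)


class TestIntervalSelection:
    def test_first_interval_when_growth_sufficient(self):
        df = _samples_table([(0.0, 100.0), (0.25, 300.0), (0.5, 500.0)])
        iv = select_intervals(df, min_fold_change=1.5)
        assert iv.iloc[0]["interval_label"] == "t0->t1"

    def test_falls_back_to_longer_interval(self):
        """fold(t0->t1)=1.1, fold(t0->t2)=2.4, fold(t1->t2)~2.2: the
        first candidate meeting the threshold is t0->t2."""
        df = _samples_table([(0.0, 100.0), (0.25, 110.0), (0.5, 240.0)])
        iv = select_intervals(df, min_fold_change=1.5)
        assert iv.iloc[0]["interval_label"] == "t0->t2"
        assert iv.iloc[0]["median_fold_change"] == pytest.approx(2.4)

    def test_forced_to_last_pair_when_t0_unusable(self):
        df = _samples_table([(0.0, 0.0), (0.25, 110.0), (0.5, 240.0)])
        iv = select_intervals(df, min_fold_change=1.5)
        assert iv.iloc[0]["interval_label"] == "t1->t2"

    def test_max_fold_fallback_when_none_qualify(self):
        df = _samples_table([(0.0, 100.0), (0.25, 110.0), (0.5, 130.0)])
        iv = select_intervals(df, min_fold_change=1.5)
        assert iv.iloc[0]["interval_label"] == "t0->t2"

    def test_observations_use_chosen_interval(self):
        df = _samples_table([(0.0, 100.0), (0.25, 110.0), (0.5, 240.0)])
        iv = select_intervals(df)
        obs = build_observations(df, iv)
        assert len(obs) == 3
        assert all(o.t_start == 0.0 and o.t_end == 0.5 for o in obs)
        assert obs[0].pcgr == pytest.approx(math.log(2.4) / 0.5)


class TestFitCurve:
    def test_exact_recovery_from_noiseless_points(self):
        mu, alpha = 1.0, -0.001
        obs = [_obs(n, mu + alpha * n) for n in (200, 350, 500, 650, 800)]
        fit = fit_curve(obs)
        assert fit.mu == pytest.approx(mu, abs=1e-10)
        assert fit.alpha == pytest.approx(alpha, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_hand_computed_two_point_ols(self):
        """Symmetric +/- eps at two N_start values: closed-form OLS."""
        eps = 0.05
        obs = [
            _obs(200, 0.8 + eps), _obs(200, 0.8 - eps),
            _obs(800, 0.2 + eps), _obs(800, 0.2 - eps),
        ]
        fit = fit_curve(obs)
        # perturbations cancel: line through (200, 0.8), (800, 0.2)
        slope = (0.2 - 0.8) / (800 - 200)
        assert fit.alpha == pytest.approx(slope, abs=1e-12)
        assert fit.mu == pytest.approx(0.8 - slope * 200, abs=1e-10)

    def test_flat_response_gives_zero_slope(self):
        obs = [_obs(n, 0.42) for n in (200, 400, 600, 800)]
        fit = fit_curve(obs)
        assert fit.mu == pytest.approx(0.42)
        assert fit.alpha == pytest.approx(0.0, abs=1e-15)

    def test_rank_deficient_design_raises(self):
        obs = [_obs(500, 0.5), _obs(500, 0.6), _obs(500, 0.4)]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_curve(obs)

    def test_nonlinearity_screen_flags_quadratic_truth(self, rng):
        x = np.tile([200, 350, 500, 650, 800], 3).astype(float)
        y = 1.0 - 0.001 * x - 2e-6 * (x - 500) ** 2 + rng.normal(0, 0.01, 15)
        obs = [_obs(xi, yi) for xi, yi in zip(x, y)]
        fit = fit_curve(obs)
        assert fit.nonlinearity_p < 0.05

    def test_nonlinearity_screen_silent_on_linear_and_constant(self, rng):
        x = np.tile([200, 350, 500, 650, 800], 3).astype(float)
        y = 1.0 - 0.001 * x + rng.normal(0, 0.02, 15)
        assert fit_curve([_obs(a, b) for a, b in zip(x, y)]).nonlinearity_p > 0.05
        const = fit_curve([_obs(a, 0.3) for a in x])
        assert const.nonlinearity_p == 1.0


def _loo_cooks(x, y):
    """Brute-force Cook's distance via leave-one-out refits."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    yhat = X @ beta
    p = 2
    s2 = ((y - yhat) ** 2).sum() / (len(x) - p)
    out = []
    for i in range(len(x)):
        keep = np.arange(len(x)) != i
        bi = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        d = ((X @ beta - X @ bi) ** 2).sum() / (p * s2)
        out.append(d)
    return np.array(out)


class TestExclusion:
    def _clean(self):
        x = np.tile([200, 350, 500, 650, 800], 3).astype(float)
        # symmetric perturbation pattern: no point is influential
        wiggle = 0.01 * np.resize([1.0, -1.0, 0.0], 15)
        y = 1.0 - 0.001 * x + wiggle
        return x, y

    def test_clean_data_no_exclusions(self):
        x, y = self._clean()
        obs = [_obs(a, b) for a, b in zip(x, y)]
        fit = fit_curve(obs)
        refit, excl = exclude_influential(fit, obs)
        assert excl == []
        assert refit.mu == fit.mu

    def test_gross_outlier_at_extreme_density_excluded(self):
        """One corrupted point at the largest N_start: the leave-one-out
        oracle confirms it alone crosses both thresholds, and exactly it
        is removed."""
        x, y = self._clean()
        y = y.copy()
        y[-1] += 0.8  # failed assay at N_start = 800
        obs = [_obs(a, b) for a, b in zip(x, y)]
        cooks = _loo_cooks(x, y)
        assert np.argmax(cooks) == len(x) - 1
        assert cooks[-1] >= 0.5 and (np.delete(cooks, -1) < 0.5).all()
        fit = fit_curve(obs)
        refit, excl = exclude_influential(fit, obs)
        assert len(excl) == 1
        assert excl[0][0].n_start == 800
        assert refit.n_points == 14
        assert abs(refit.alpha + 0.001) < abs(fit.alpha + 0.001)

    def test_outlier_at_mean_density_retained(self):
        """A residual outlier with low leverage stays: its Cook's D is
        below the border even though the residual is large."""
        x, y = self._clean()
        y = y.copy()
        y[2] += 0.06  # at N_start = 500 ~ x-bar, moderate residual
        cooks = _loo_cooks(x, y)
        assert cooks[2] < 0.5
        obs = [_obs(a, b) for a, b in zip(x, y)]
        fit = fit_curve(obs)
        _, excl = exclude_influential(fit, obs)
        assert excl == []

    def test_single_pass_bounded_exclusions(self):
        x, y = self._clean()
        y = y.copy()
        y[0] += 0.9
        y[-1] -= 0.9
        obs = [_obs(a, b) for a, b in zip(x, y)]
        fit = fit_curve(obs)
        refit, excl = exclude_influential(fit, obs, InfluenceRule(max_exclusions=2))
        assert len(excl) <= 2
        # a second pass on the refit removes at most max_exclusions more
        survivors = [o for o in obs if o not in [e[0] for e in excl]]
        _, excl2 = exclude_influential(refit, survivors, InfluenceRule(max_exclusions=2))
        assert len(excl2) <= 2


class TestCarryingCapacity:
    def _fit(self, mu, alpha, s2_mu=0.0, s2_alpha=0.0, cov=0.0):
        return DensityDependenceFit("c", mu, alpha, s2_mu, s2_alpha, cov, 15, 1.0, 1.0)

    def test_definition(self):
        est = carrying_capacity(self._fit(2.0, -0.01))
        assert est.k == pytest.approx(200.0)
        assert est.valid

    def test_variance_plug_in(self):
        est = carrying_capacity(self._fit(1.0, -1.0, s2_mu=0.01, s2_alpha=0.01))
        assert est.s2_k == pytest.approx(0.02)

    def test_delta_method_vs_monte_carlo(self):
        from strainlink.validation import k_variance_delta_vs_mc

        res = k_variance_delta_vs_mc(
            mu=1.2, alpha=-0.002, s2_mu=0.0025, s2_alpha=1e-8, cov=-4e-6,
            n_draws=1_000_000, seed=5,
        )
        assert res["cv_mu"] <= 0.10 and res["cv_alpha"] <= 0.10
        assert res["rel_err"] < 0.05

    def test_extreme_negative_k_invalid(self):
        est = carrying_capacity(self._fit(-1.0, -0.001))
        assert est.k == pytest.approx(-1000.0)
        assert not est.valid

    def test_positive_alpha_invalid(self):
        est = carrying_capacity(self._fit(1.0, 0.001))
        assert not est.valid

    def test_alpha_zero_flagged(self):
        est = carrying_capacity(self._fit(1.0, 0.0))
        assert not est.valid and np.isnan(est.k)

    def test_k_positive_whenever_mu_pos_alpha_neg(self, rng):
        for _ in range(50):
            mu = rng.uniform(0.1, 3.0)
            alpha = -rng.uniform(1e-5, 1e-2)
            assert carrying_capacity(self._fit(mu, alpha)).k > 0


class TestRecovery:
    def test_parameter_recovery_medians(self):
        """Pipeline-level recovery at the nominal study conditions."""
        from strainlink.validation import eq1_recovery

        res = eq1_recovery(n_assays=60, seed=11)
        assert res["median_mu_rel_err"] <= 0.10
        assert res["median_alpha_rel_err"] <= 0.15
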