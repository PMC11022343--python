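"""Density-dependent demography from per-sample densities.

The per-capita growth rate over an interval,

    pcgr = ln(N_end / N_start) / (t_end - t_start),

decreases approximately linearly with starting density over short
intervals, so regressing pcgr on N_start across the dilution series
yields the intrinsic growth rate mu (intercept) and the conspecific
interaction coefficient alpha (slope). One pooled curve is fitted per
condition over all replicate assays (15 points for the default 5
dilutions x 3 replicates). Carrying capacity is K = -mu/alpha with a
first-order Taylor (delta-method) variance:

    s2(-mu/alpha) ~ (mu^2/alpha^2) (s2_mu/mu^2
                     - 2 cov(mu, alpha)/(mu alpha) + s2_alpha/alpha^2)

Influence diagnostics (Cook's distance + externally studentized
residuals) exclude points produced by failed assays or sampling errors
before a single refit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GrowthObservation",
    "DensityDependenceFit",
    "KEstimate",
    "InfluenceRule",
    "compute_pcgr",
    "select_intervals",
    "build_observations",
    "fit_curve",
    "exclude_influential",
    "carrying_capacity",
    "fit_all_conditions",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class GrowthObservation:
    """One pcgr point on a density-dependence curve."""

    condition_id: str
    replicate: int
    dilution: float
    n_start: float  # cells/mL
    n_end: float  # cells/mL
    t_start: float  # days
    t_end: float  # days
    interval_label: str  # "t0->t1", "t0->t2" or "t1->t2"

    @property
    def pcgr(self) -> float:
        return compute_pcgr(self.n_start, self.n_end, self.t_start, self.t_end)


@dataclass
class DensityDependenceFit:
    condition_id: str
    mu: float  # per day
    alpha: float  # per day per (cells/mL)
    s2_mu: float
    s2_alpha: float
    cov_mu_alpha: float
    n_points: int
    r_squared: float
    nonlinearity_p: float  # quadratic-term screen; diagnostic only
    excluded: list = field(default_factory=list)  # (observation, reason)

    @property
    def se_mu(self) -> float:
        return math.sqrt(self.s2_mu)

    @property
    def se_alpha(self) -> float:
        return math.sqrt(self.s2_alpha)

    def covariance(self) -> np.ndarray:
        return np.array(
            [[self.s2_mu, self.cov_mu_alpha], [self.cov_mu_alpha, self.s2_alpha]]
        )


@dataclass
class KEstimate:
    condition_id: str
    k: float  # cells/mL
    s2_k: float
    valid: bool
    reason: str = ""


@dataclass
class InfluenceRule:
    """Thresholds of the two-criterion exclusion rule.

    A point is excluded iff its Cook's distance reaches
    ``cooks_threshold`` (the border contour of standard diagnostic
    plots) AND its externally studentized residual magnitude reaches
    ``resid_threshold`` (an influential outlier on the residual-based
    plots), removing at most ``max_exclusions`` points per curve, most
    extreme first, followed by exactly one refit.
    """

    cooks_threshold: float = 0.5
    resid_threshold: float = 2.0
    max_exclusions: int = 2
    min_points_after: int = 3


# ---------------------------------------------------------------------------
# operations


def compute_pcgr(n_start: float, n_end: float, t_start: float, t_end: float) -> float:
    """Per-capita growth rate ln(N_end/N_start)/(t_end - t_start), /day."""
    if n_start <= 0 or n_end <= 0:
        raise ValueError("densities must be positive to compute pcgr")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    return math.log(n_end / n_start) / (t_end - t_start)


def select_intervals(
    samples: pd.DataFrame,
    min_fold_change: float = 1.5,
) -> pd.DataFrame:
    """Choose the growth interval for every replicate assay.

    ``samples`` needs columns assay_id, condition_id, replicate,
    dilution, time_point, t_days, density. Candidate intervals are
    t0->t1, t0->t2 and t1->t2 (in that preference order); an assay takes
    the first whose median density fold-change across its dilution
    microcosms reaches ``min_fold_change`` — growth below that is too
    small to measure precisely against counting noise — falling back to
    the candidate with the largest median fold-change. One interval per
    assay keeps the 15 points of a curve on a common time base.

    Returns one row per assay: assay_id, t_start_point, t_end_point,
    interval_label. Assays with fewer than two usable time points are
    dropped (reason rows carry NaN points).
    """
    required = {"assay_id", "replicate", "dilution", "time_point", "t_days", "density"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns: {sorted(missing)}")
    tps = sorted(samples["time_point"].unique())
    if len(tps) < 2:
        raise ValueError("need at least two time points")
    candidates = [(tps[0], tps[1])]
    if len(tps) >= 3:
        candidates = [(tps[0], tps[1]), (tps[0], tps[2]), (tps[1], tps[2])]

    rows = []
    for assay_id, grp in samples.groupby("assay_id", sort=False):
        wide = grp.pivot_table(index="dilution", columns="time_point", values="density")
        folds = {}
        for a, b in candidates:
            if a not in wide.columns or b not in wide.columns:
                continue
            ratio = wide[b] / wide[a]
            ratio = ratio[np.isfinite(ratio) & (wide[a] > 0)]
            if len(ratio):
                folds[(a, b)] = float(ratio.median())
        usable = [c for c in candidates if c in folds]
        if not usable:
            rows.append(
                {
                    "assay_id": assay_id,
                    "t_start_point": np.nan,
                    "t_end_point": np.nan,
                    "interval_label": "dropped",
                    "median_fold_change": np.nan,
                }
            )
            continue
        chosen = next((c for c in usable if folds[c] >= min_fold_change), None)
        if chosen is None:
            chosen = max(usable, key=lambda c: folds[c])
        rows.append(
            {
                "assay_id": assay_id,
                "t_start_point": chosen[0],
                "t_end_point": chosen[1],
                "interval_label": f"t{chosen[0]}->t{chosen[1]}",
                "median_fold_change": folds[chosen],
            }
        )
    return pd.DataFrame(rows)


def build_observations(
    samples: pd.DataFrame, intervals: pd.DataFrame
) -> list[GrowthObservation]:
    """Join samples with their assay's chosen interval into pcgr points.

    Microcosms with a non-positive density at either endpoint are
    skipped (they cannot produce a finite log-ratio).
    """
    merged = samples.merge(intervals, on="assay_id", how="inner")
    out: list[GrowthObservation] = []
    for (assay_id, dilution), grp in merged.groupby(["assay_id", "dilution"], sort=False):
        first = grp.iloc[0]
        a, b = first["t_start_point"], first["t_end_point"]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        by_tp = grp.set_index("time_point")
        if a not in by_tp.index or b not in by_tp.index:
            continue
        start, end = by_tp.loc[a], by_tp.loc[b]
        if start["density"] <= 0 or end["density"] <= 0:
            continue
        out.append(
            GrowthObservation(
                condition_id=first["condition_id"],
                replicate=int(first["replicate"]),
                dilution=float(dilution),
                n_start=float(start["density"]),
                n_end=float(end["density"]),
                t_start=float(start["t_days"]),
                t_end=float(end["t_days"]),
                interval_label=first["interval_label"],
            )
        )
    return out


def fit_curve(
    observations: list[GrowthObservation],
    cov_type: str = "HC3",
) -> DensityDependenceFit:
    """Pooled OLS of pcgr on N_start for one condition.

    The default covariance is heteroscedasticity-robust (HC3): counting
    noise makes pcgr variance fall with density, which classical OLS
    standard errors understate at the intercept. ``cov_type of
    "nonrobust"`` reproduces textbook OLS errors.
    """
    if len(observations) < 3:
        raise ValueError("need at least 3 observations to fit a curve")
    cond = observations[0].condition_id
    if any(o.condition_id != cond for o in observations):
        raise ValueError("observations mix conditions")
    x = np.array([o.n_start for o in observations])
    if len(np.unique(x)) < 2:
        raise ValueError(f"condition {cond}: rank-deficient design (single N_start)")
    y = np.array([o.pcgr for o in observations])
    model = sm.OLS(y, sm.add_constant(x)).fit(cov_type=cov_type)
    cov = np.asarray(model.cov_params())
    return DensityDependenceFit(
        condition_id=cond,
        mu=float(model.params[0]),
        alpha=float(model.params[1]),
        s2_mu=float(cov[0, 0]),
        s2_alpha=float(cov[1, 1]),
        cov_mu_alpha=float(cov[0, 1]),
        n_points=len(observations),
        r_squared=float(model.rsquared),
        nonlinearity_p=_nonlinearity_screen(x, y),
    )


def _nonlinearity_screen(x: np.ndarray, y: np.ndarray) -> float:
    """p-value of the quadratic term added to the linear fit.

    Diagnostic only — it never alters the fitted line. Returns 1.0 when
    the quadratic term is inestimable (fewer than 3 distinct densities
    or degenerate response).
    """
    if len(np.unique(x)) < 3 or len(x) < 4 or np.allclose(y, y[0]):
        return 1.0
    design = sm.add_constant(np.column_stack([x, x**2]))
    try:
        quad = sm.OLS(y, design).fit()
        return float(quad.pvalues[2])
    except Exception:
        return 1.0


def exclude_influential(
    fit: DensityDependenceFit,
    observations: list[GrowthObservation],
    rule: InfluenceRule | None = None,
    cov_type: str = "HC3",
) -> tuple[DensityDependenceFit, list[tuple[GrowthObservation, str]]]:
    """Apply the two-criterion influence rule and refit once.

    Candidates must cross BOTH the Cook's-distance and the studentized-
    residual thresholds; at most ``rule.max_exclusions`` are removed
    (largest Cook's D first) while keeping ``rule.min_points_after``
    points. Excluded observations remain available to the trait data —
    exclusion only concerns the density-dependence curve.
    """
    rule = rule or InfluenceRule()
    if len(observations) < 4:
        return fit, []
    x = np.array([o.n_start for o in observations])
    y = np.array([o.pcgr for o in observations])
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    infl = ols.get_influence()
    cooks = infl.cooks_distance[0]
    resid = infl.resid_studentized_external
    flagged = [
        (cooks[i], i)
        for i in range(len(observations))
        if cooks[i] >= rule.cooks_threshold and abs(resid[i]) >= rule.resid_threshold
    ]
    flagged.sort(reverse=True)
    excluded: list[tuple[GrowthObservation, str]] = []
    drop: set[int] = set()
    for cook_d, i in flagged:
        if len(excluded) >= rule.max_exclusions:
            break
        if len(observations) - len(drop) - 1 < rule.min_points_after:
            break
        drop.add(i)
        excluded.append(
            (observations[i], f"cooks_d={cook_d:.3g}, ext_resid={resid[i]:.3g}")
        )
    if not drop:
        return fit, []
    survivors = [o for i, o in enumerate(observations) if i not in drop]
    refit = fit_curve(survivors, cov_type=cov_type)
    refit.excluded = excluded
    return refit, excluded


def carrying_capacity(
    fit: DensityDependenceFit, k_invalid_below: float = -400.0
) -> KEstimate:
    """K = -mu/alpha with its delta-method variance.

    Estimates below ``k_invalid_below`` are flagged invalid: they arise
    from positive density dependence (alpha >= 0 or a sign-flipped
    ratio), where the fitted K is not a meaningful carrying capacity.
    """
    cond = fit.condition_id
    if fit.alpha == 0:
        return KEstimate(cond, np.nan, np.nan, False, "alpha=0: K undefined")
    k = -fit.mu / fit.alpha
    s2_k = (fit.mu**2 / fit.alpha**2) * (
        fit.s2_mu / fit.mu**2
        - 2 * fit.cov_mu_alpha / (fit.mu * fit.alpha)
        + fit.s2_alpha / fit.alpha**2
    )
    if k < k_invalid_below:
        return KEstimate(cond, k, s2_k, False, f"K < {k_invalid_below:g}")
    if fit.alpha > 0:
        return KEstimate(cond, k, s2_k, False, "positive density dependence")
    return KEstimate(cond, k, s2_k, True)


def fit_all_conditions(
    samples: pd.DataFrame,
    min_fold_change: float = 1.5,
    rule: InfluenceRule | None = None,
    cov_type: str = "HC3",
) -> tuple[pd.DataFrame, pd.DataFrame, list[GrowthObservation]]:
    """Interval selection, pooled fits, influence exclusion and K for
    every condition in a samples table.

    Returns (fits table, intervals table, all observations). The fits
    table has one row per condition with mu, alpha, their (co)variances,
    R^2, K, s2_K, K validity and exclusion count.
    """
    intervals = select_intervals(samples, min_fold_change=min_fold_change)
    observations = build_observations(samples, intervals)
    rows = []
    by_cond: dict[str, list[GrowthObservation]] = {}
    for o in observations:
        by_cond.setdefault(o.condition_id, []).append(o)
    for cond, obs in by_cond.items():
        fit = fit_curve(obs, cov_type=cov_type)
        fit, excluded = exclude_influential(fit, obs, rule=rule, cov_type=cov_type)
        kest = carrying_capacity(fit)
        first = obs[0]
        meta = samples.loc[samples["condition_id"] == cond].iloc[0]
        rows.append(
            {
                "condition_id": cond,
                "species": meta.get("species", ""),
                "strain": meta.get("strain", ""),
                "temperature": meta.get("temperature", np.nan),
                "pollutant": meta.get("pollutant", np.nan),
                "mu": fit.mu,
                "alpha": fit.alpha,
                "s2_mu": fit.s2_mu,
                "s2_alpha": fit.s2_alpha,
                "cov_mu_alpha": fit.cov_mu_alpha,
                "n_points": fit.n_points,
                "r_squared": fit.r_squared,
                "nonlinearity_p": fit.nonlinearity_p,
                "n_excluded": len(excluded),
                "k": kest.k,
                "s2_k": kest.s2_k,
                "k_valid": kest.valid,
            }
        )
    return pd.DataFrame(rows), intervals, observations
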