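"""Survival-strategy index.

Movement (speed, linearity) and morphology (size, shape) are
standardized at the species level and combined with equal weights:

    index = z(speed) + z(linearity) - z(size) + z(shape)

Small values describe a sit-and-wait phenotype (slow, tortuous, large,
round), large values a flee phenotype (fast, straight, small,
elongated). The response of a microcosm is the change in the index's
sample mean and variance over the same time interval used to measure
growth (Delta-mean and Delta-variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from strainlink.config import TRAIT_NAMES

__all__ = [
    "SpeciesStandardization",
    "IndexSample",
    "IndexResponse",
    "fit_standardization",
    "compute_index",
    "compute_index_per_trajectory",
    "index_response",
    "compute_index_responses",
]

# combination weights of the index, in TRAIT_NAMES order
INDEX_WEIGHTS = {"speed": 1.0, "linearity": 1.0, "size": -1.0, "shape": 1.0}


@dataclass(frozen=True)
class SpeciesStandardization:
    """Pooled mean/SD per trait over one species' standardization pool."""

    species: str
    means: dict[str, float]
    sds: dict[str, float]
    n_samples: int

    def z(self, trait: str, value: float) -> float:
        return (value - self.means[trait]) / self.sds[trait]


@dataclass(frozen=True)
class IndexSample:
    sample_id: str
    mean_index: float
    variance_index: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.mean_index))


@dataclass(frozen=True)
class IndexResponse:
    condition_id: str
    replicate: int
    dilution: float
    delta_mean: float
    delta_variance: float
    interval_label: str


def fit_standardization(samples: pd.DataFrame, species: str = "") -> SpeciesStandardization:
    """Pooled per-trait mean and SD over sample-level trait means.

    ``samples`` holds one row per sample with ``<trait>_mean`` columns;
    the pool should contain only time points contributing to the
    density-dependence curves. A constant trait raises — silent division
    by a zero SD would poison every downstream z-score.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to standardize")
    means, sds = {}, {}
    for trait in TRAIT_NAMES:
        col = samples[f"{trait}_mean"].dropna()
        if len(col) < 2:
            raise ValueError(f"trait {trait}: fewer than 2 defined samples")
        m, s = float(col.mean()), float(col.std(ddof=1))
        if s == 0.0:
            raise ValueError(f"trait {trait} is constant in the standardization pool")
        means[trait], sds[trait] = m, s
    return SpeciesStandardization(species=species, means=means, sds=sds, n_samples=len(samples))


def compute_index(sample, std: SpeciesStandardization) -> IndexSample:
    """Index mean and variance of one sample.

    ``sample`` is any mapping with ``<trait>_mean`` / ``<trait>_var``
    entries (a SampleSummary's dict or a samples-table row). The mean
    index applies the +/- 1 weights to species z-scores of the sample's
    trait means; the variance index sums the species-scaled trait
    variances — the index variance when traits vary independently
    within a sample, since every weight is +/-1.
    """
    get = sample.get if hasattr(sample, "get") else lambda k: getattr(sample, k)
    vals = {t: get(f"{t}_mean") for t in TRAIT_NAMES}
    variances = {t: get(f"{t}_var") for t in TRAIT_NAMES}
    sid = get("sample_id") or ""
    if any(v is None or not np.isfinite(v) for v in vals.values()):
        return IndexSample(sid, np.nan, np.nan)
    mean_index = sum(INDEX_WEIGHTS[t] * std.z(t, vals[t]) for t in TRAIT_NAMES)
    if any(v is None or not np.isfinite(v) for v in variances.values()):
        variance_index = np.nan
    else:
        variance_index = sum(variances[t] / std.sds[t] ** 2 for t in TRAIT_NAMES)
    return IndexSample(sid, float(mean_index), float(variance_index))


def compute_index_per_trajectory(
    trajectories, std: SpeciesStandardization, sample_id: str = ""
) -> IndexSample:
    """Alternative mode: one index value per trajectory, then moments.

    Takes tracked `Trajectory` objects (speed, linearity, mean_area,
    mean_aspect), standardizes each trajectory's traits with the species
    pool and returns the mean and unbiased variance of the per-cell
    index values. Equivalent to the moments mode for the mean; the
    variance additionally captures within-sample trait covariances.
    """
    vals = []
    for t in trajectories:
        traits = {
            "speed": t.speed,
            "linearity": t.linearity,
            "size": t.mean_area,
            "shape": t.mean_aspect,
        }
        if any(not np.isfinite(v) for v in traits.values()):
            continue
        vals.append(sum(INDEX_WEIGHTS[k] * std.z(k, v) for k, v in traits.items()))
    if not vals:
        return IndexSample(sample_id, np.nan, np.nan)
    mean = float(np.mean(vals))
    var = float(np.var(vals, ddof=1)) if len(vals) >= 2 else np.nan
    return IndexSample(sample_id, mean, var)


def index_response(start: IndexSample, end: IndexSample, **meta) -> IndexResponse:
    """Componentwise change end - start over the growth interval."""
    return IndexResponse(
        condition_id=meta.get("condition_id", ""),
        replicate=meta.get("replicate", 0),
        dilution=meta.get("dilution", np.nan),
        delta_mean=end.mean_index - start.mean_index,
        delta_variance=end.variance_index - start.variance_index,
        interval_label=meta.get("interval_label", ""),
    )


def compute_index_responses(
    samples: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, SpeciesStandardization]]:
    """Standardize per species and compute Delta responses per microcosm.

    The standardization pool of a species is the set of its samples at
    the time points its assays contribute to the curves (both endpoints
    of each assay's chosen interval); pool moments are frozen before
    any Delta is computed. Returns (responses table, standardizations).
    """
    merged = samples.merge(intervals, on="assay_id", how="inner")
    contributing = merged[
        (merged["time_point"] == merged["t_start_point"])
        | (merged["time_point"] == merged["t_end_point"])
    ].copy()
    stds = {
        sp: fit_standardization(grp, species=sp)
        for sp, grp in contributing.groupby("species")
    }
    rows = []
    for (assay_id, dilution), grp in contributing.groupby(["assay_id", "dilution"], sort=False):
        first = grp.iloc[0]
        std = stds[first["species"]]
        by_tp = grp.set_index("time_point")
        a, b = first["t_start_point"], first["t_end_point"]
        if a not in by_tp.index or b not in by_tp.index:
            continue
        start = compute_index(by_tp.loc[a], std)
        end = compute_index(by_tp.loc[b], std)
        if not (start.defined and end.defined):
            continue
        resp = index_response(
            start,
            end,
            condition_id=first["condition_id"],
            replicate=int(first["replicate"]),
            dilution=float(dilution),
            interval_label=first["interval_label"],
        )
        rows.append(
            {
                "condition_id": resp.condition_id,
                "assay_id": assay_id,
                "species": first["species"],
                "strain": first["strain"],
                "temperature": first["temperature"],
                "pollutant": first["pollutant"],
                "replicate": resp.replicate,
                "dilution": resp.dilution,
                "interval_label": resp.interval_label,
                "delta_mean": resp.delta_mean,
                "delta_variance": resp.delta_variance,
            }
        )
    return pd.DataFrame(rows), stds
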