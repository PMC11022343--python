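"""Linking demography to trait responses across all strains.

Each of the 54 conditions contributes one record joining its
species-standardized demographic parameters (mu, alpha, K) to its index
responses averaged over replicates and dilutions. A family of linear
model variants — intercepts and/or slopes common, per strain, or per
strain of only one species (strainC / strainT codings) — is then ranked
by AICc for each demographic response, separately for Delta-mean and
Delta-variance predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelVariant",
    "ComparisonRow",
    "MODEL_FAMILY",
    "build_condition_records",
    "fit_variant",
    "select_best",
    "model_selection",
]


@dataclass(frozen=True)
class ModelVariant:
    """One member of the intercept/slope model family.

    ``intercept_structure`` / ``slope_structure`` take values
    ``common``, ``strain`` (every strain its own level), ``strainC``
    (only the first species' strains distinct, the other species pooled)
    or ``strainT`` (the mirror image). ``predictor`` is delta_mean,
    delta_variance or none (the Null model).
    """

    name: str
    predictor: str  # "delta_mean" | "delta_variance" | "none"
    intercept_structure: str = "common"
    slope_structure: str = "common"


def _family() -> list[ModelVariant]:
    out = [ModelVariant("Null", "none")]
    for label, pred in (("Mean", "delta_mean"), ("Variance", "delta_variance")):
        out += [
            ModelVariant(f"{label} 1", pred, "common", "common"),
            ModelVariant(f"{label} 2", pred, "strain", "common"),
            ModelVariant(f"{label} 3", pred, "strainC", "common"),
            ModelVariant(f"{label} 4", pred, "strainT", "common"),
            ModelVariant(f"{label} 5", pred, "strain", "strain"),
            ModelVariant(f"{label} 6", pred, "strainC", "strainC"),
            ModelVariant(f"{label} 7", pred, "strainT", "strainT"),
        ]
    return out


MODEL_FAMILY: list[ModelVariant] = _family()


@dataclass
class ComparisonRow:
    name: str
    response: str
    n: int
    k: int  # parameter count incl. residual variance
    rss: float
    aicc: float
    aic: float
    adj_r2: float
    coefficients: dict
    rank: int = 0
    is_best: bool = False


def _zscore(col: pd.Series) -> pd.Series:
    return (col - col.mean()) / col.std(ddof=1)


def build_condition_records(
    fits: pd.DataFrame, responses: pd.DataFrame
) -> pd.DataFrame:
    """One record per condition: standardized demography + averaged
    index responses.

    mu and alpha are z-scored within species over all of that species'
    conditions; K is z-scored over the K-valid conditions only.
    Delta-mean / Delta-variance are averaged over every surviving
    replicate x dilution cell of the condition. Conditions without any
    surviving response are flagged (``has_response`` False) and play no
    part in the linkage fits.
    """
    required = {"condition_id", "species", "strain", "temperature", "pollutant",
                "mu", "alpha", "k", "k_valid"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table lacks columns: {sorted(missing)}")
    rec = fits.copy()
    dup = rec["condition_id"].duplicated()
    if dup.any():
        raise ValueError("more than one fit per condition")
    rec["mu_z"] = rec.groupby("species")["mu"].transform(_zscore)
    rec["alpha_z"] = rec.groupby("species")["alpha"].transform(_zscore)
    rec["k_z"] = np.nan
    for sp, grp in rec.groupby("species"):
        ok = grp["k_valid"].astype(bool)
        vals = grp.loc[ok, "k"]
        if len(vals) >= 2:
            rec.loc[vals.index, "k_z"] = _zscore(vals)
    means = (
        responses.groupby("condition_id")[["delta_mean", "delta_variance"]]
        .mean()
        .rename(columns={"delta_mean": "delta_mean_bar", "delta_variance": "delta_variance_bar"})
    )
    rec = rec.merge(means, on="condition_id", how="left")
    rec["has_response"] = rec["delta_mean_bar"].notna()
    cols = [
        "condition_id", "species", "strain", "temperature", "pollutant",
        "mu_z", "alpha_z", "k_z", "k_valid", "delta_mean_bar",
        "delta_variance_bar", "has_response",
    ]
    return rec[cols]


def _strain_coding(records: pd.DataFrame, structure: str) -> pd.Series:
    """Factor column realizing the strain / strainC / strainT codings.

    The species whose strains stay distinct under ``strainC`` is the
    alphabetically first species (Colpidium before Tetrahymena in the
    default design); ``strainT`` mirrors it.
    """
    if structure == "strain":
        return records["strain"].astype(str)
    species = sorted(records["species"].unique())
    focal = species[0] if structure == "strainC" else species[-1]
    return np.where(
        records["species"] == focal, records["strain"].astype(str), "pooled"
    )


def _design_matrix(records: pd.DataFrame, variant: ModelVariant) -> tuple[np.ndarray, list[str]]:
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if variant.intercept_structure != "common":
        coding = pd.Series(_strain_coding(records, variant.intercept_structure))
        levels = sorted(coding.unique())
        for lev in levels[1:]:
            cols.append((coding == lev).to_numpy(dtype=float))
            names.append(f"intercept[{lev}]")
    if variant.predictor != "none":
        x = records[f"{variant.predictor}_bar"].to_numpy(dtype=float)
        cols.append(x)
        names.append(variant.predictor)
        if variant.slope_structure != "common":
            coding = pd.Series(_strain_coding(records, variant.slope_structure))
            levels = sorted(coding.unique())
            for lev in levels[1:]:
                cols.append(x * (coding == lev).to_numpy(dtype=float))
                names.append(f"{variant.predictor}[{lev}]")
    return np.column_stack(cols), names


def fit_variant(
    variant: ModelVariant, records: pd.DataFrame, response: str
) -> ComparisonRow | None:
    """OLS fit of one variant; AICc with the residual variance counted.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1) with k = p + 1
    coefficients-plus-variance. Returns None when n - k - 1 <= 0 (the
    variant cannot be scored at this sample size).
    """
    df = records.dropna(subset=[response]).copy()
    if variant.predictor != "none":
        df = df.dropna(subset=[f"{variant.predictor}_bar"])
    n = len(df)
    y = df[response].to_numpy(dtype=float)
    X, names = _design_matrix(df, variant)
    p = int(np.linalg.matrix_rank(X))
    k = p + 1
    if n - k - 1 <= 0 or n <= p:
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    # guard the log for perfect fits
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    adj_r2 = 1.0 - (rss / (n - p)) / (tss / (n - 1)) if n > p and tss > 0 else np.nan
    return ComparisonRow(
        name=variant.name,
        response=response,
        n=n,
        k=k,
        rss=rss,
        aicc=float(aicc),
        aic=float(aic),
        adj_r2=float(adj_r2),
        coefficients=dict(zip(names, beta)),
    )


def select_best(rows: list[ComparisonRow]) -> list[ComparisonRow]:
    """Rank by ascending AICc; near-ties (< 1e-9) prefer fewer
    parameters, then the fixed family name order."""
    name_order = {v.name: i for i, v in enumerate(MODEL_FAMILY)}
    if len(rows) < 2:
        raise ValueError("need at least 2 fitted variants to rank")

    def key(r: ComparisonRow):
        return (round(r.aicc / 1e-9) * 1e-9, r.k, name_order.get(r.name, 99))

    ranked = sorted(rows, key=key)
    for i, r in enumerate(ranked):
        r.rank = i + 1
        r.is_best = i == 0
    return ranked


def model_selection(
    records: pd.DataFrame,
    responses: tuple[str, ...] = ("mu_z", "k_z", "alpha_z"),
) -> pd.DataFrame:
    """Fit the whole family for each demographic response.

    Records lacking a response value (e.g. K-invalid conditions for the
    K column, conditions without surviving trait responses) drop out of
    that column's fits, mirroring the n = 54 / 51 / 54 bookkeeping.
    Returns a long table with one row per (response, variant).
    """
    usable = records[records["has_response"]].copy()
    out = []
    for resp in responses:
        rows = [r for v in MODEL_FAMILY if (r := fit_variant(v, usable, resp))]
        for r in select_best(rows):
            out.append(
                {
                    "response": resp,
                    "model": r.name,
                    "n": r.n,
                    "k": r.k,
                    "aicc": r.aicc,
                    "adj_r2": r.adj_r2,
                    "rank": r.rank,
                    "is_best": r.is_best,
                    "coefficients": r.coefficients,
                }
            )
    return pd.DataFrame(out)
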