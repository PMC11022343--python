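"""Factorial linear models of demography and index responses.

Per species, pcgr is modelled against starting density and the crossed
strain x temperature x atrazine factors: the factor main effects and
interactions describe differences in mu (intercepts) while each term's
interaction with N_start describes differences in alpha (slopes). Index
responses (Delta-mean, Delta-variance) are modelled against the three
factors without density terms. Tables report sequential (Type I) sums
of squares in a fixed term order, F and p against the residual mean
square, and partial eta squared for every term; Type III sums of
squares (sum-to-zero contrasts) are available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = ["AnovaTable", "demography_anova", "index_anova"]


class AnovaTable:
    """Ordered effect rows plus metadata; behaves like a DataFrame."""

    def __init__(self, species: str, response: str, formula: str, table: pd.DataFrame):
        self.species = species
        self.response = response
        self.formula = formula
        self.table = table

    @property
    def residual_df(self) -> float:
        return float(self.table.loc[self.table["term"] == "Residuals", "df"].iloc[0])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AnovaTable({self.species!r}, {self.response!r})\n"
            + self.table.to_string(index=False)
        )


def _check_factors(df: pd.DataFrame, factors: list[str]) -> None:
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f} has a single level; empty cells in design")


def _anova_frame(model, order: list[tuple[str, str]], ss_type: int) -> pd.DataFrame:
    raw = anova_lm(model, typ=ss_type)
    ss_res = float(raw.loc["Residual", "sum_sq"])
    rows = []
    for patsy_term, label in order:
        if patsy_term not in raw.index:
            continue
        r = raw.loc[patsy_term]
        ss = float(r["sum_sq"])
        rows.append(
            {
                "term": label,
                "df": float(r["df"]),
                "sum_sq": ss,
                "F": float(r["F"]),
                "p": float(r["PR(>F)"]),
                "eta_p2": ss / (ss + ss_res) if (ss + ss_res) > 0 else 0.0,
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "df": float(raw.loc["Residual", "df"]),
            "sum_sq": ss_res,
            "F": np.nan,
            "p": np.nan,
            "eta_p2": np.nan,
        }
    )
    return pd.DataFrame(rows)


def _fac(name: str, ss_type: int) -> str:
    # Type III needs sum-to-zero contrasts to be meaningful
    return f"C({name}, Sum)" if ss_type == 3 else f"C({name})"


def demography_anova(
    observations: pd.DataFrame,
    species: str = "",
    ss_type: str = "I",
) -> AnovaTable:
    """Factorial model of pcgr for one species.

    ``observations`` requires columns pcgr, n_start, strain,
    temperature, pollutant. Terms enter in the fixed order N_start, the
    factor main effects and interactions (differences in mu), then each
    factor term crossed with N_start (differences in alpha).
    """
    typ = {"I": 1, "III": 3}[ss_type]
    df = observations.copy()
    _check_factors(df, ["strain", "temperature", "pollutant"])
    A, T, S = _fac("pollutant", typ), _fac("temperature", typ), _fac("strain", typ)
    factor_terms = [
        (A, "Atrazine"),
        (T, "Temperature"),
        (S, "Strain"),
        (f"{A}:{T}", "Atrazine x Temperature"),
        (f"{A}:{S}", "Atrazine x Strain"),
        (f"{T}:{S}", "Temperature x Strain"),
        (f"{A}:{T}:{S}", "Atrazine x Temperature x Strain"),
    ]
    order = [("n_start", "Starting density (N_start)")]
    order += factor_terms
    order += [(f"n_start:{t}", f"N_start x {label}") for t, label in factor_terms]
    formula = "pcgr ~ " + " + ".join(t for t, _ in order)
    if df["pcgr"].nunique() == 1:
        # degenerate response: well-formed all-zero table
        rows = [
            {"term": label, "df": np.nan, "sum_sq": 0.0, "F": 0.0, "p": np.nan, "eta_p2": 0.0}
            for _, label in order
        ]
        rows.append({"term": "Residuals", "df": float(len(df) - 1), "sum_sq": 0.0,
                     "F": np.nan, "p": np.nan, "eta_p2": np.nan})
        return AnovaTable(species, "pcgr", formula, pd.DataFrame(rows))
    model = smf.ols(formula, data=df).fit()
    return AnovaTable(species, "pcgr", formula, _anova_frame(model, order, typ))


def index_anova(
    responses: pd.DataFrame,
    which: str = "delta_mean",
    species: str = "",
    ss_type: str = "I",
) -> AnovaTable:
    """Factorial model of an index response for one species.

    ``which`` selects delta_mean or delta_variance. Term order follows
    the response tables: Atrazine, Temperature, Strain, the two-way
    interactions, then the three-way.
    """
    if which not in ("delta_mean", "delta_variance"):
        raise ValueError("which must be delta_mean or delta_variance")
    typ = {"I": 1, "III": 3}[ss_type]
    df = responses.dropna(subset=[which]).copy()
    _check_factors(df, ["strain", "temperature", "pollutant"])
    A, T, S = _fac("pollutant", typ), _fac("temperature", typ), _fac("strain", typ)
    order = [
        (A, "Atrazine"),
        (T, "Temperature"),
        (S, "Strain"),
        (f"{A}:{T}", "Atrazine x Temperature"),
        (f"{A}:{S}", "Atrazine x Strain"),
        (f"{T}:{S}", "Temperature x Strain"),
        (f"{A}:{T}:{S}", "Atrazine x Temperature x Strain"),
    ]
    formula = f"{which} ~ " + " + ".join(t for t, _ in order)
    if df[which].nunique() == 1:
        rows = [
            {"term": label, "df": np.nan, "sum_sq": 0.0, "F": 0.0, "p": np.nan, "eta_p2": 0.0}
            for _, label in order
        ]
        rows.append({"term": "Residuals", "df": float(len(df) - 1), "sum_sq": 0.0,
                     "F": np.nan, "p": np.nan, "eta_p2": np.nan})
        return AnovaTable(species, which, formula, pd.DataFrame(rows))
    model = smf.ols(formula, data=df).fit()
    return AnovaTable(species, which, formula, _anova_frame(model, order, typ))
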