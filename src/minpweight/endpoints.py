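"""Endpoint statistics: two-factor fixed-effects ANOVA and Tukey HSD.

Endpoint tables are long-format records of (animal_id, genotype, treatment,
endpoint, value).  The ANOVA uses Type-II sums of squares (equal to Type-I on
balanced designs); normality and homoscedasticity screens are reported as
diagnostics only and never switch the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError, DataError, ProcedureError

__all__ = ["AnovaResult", "factorial_anova", "tukey_hsd"]

ENDPOINT_COLUMNS = ["animal_id", "genotype", "treatment", "endpoint", "value"]


def _validate_endpoints(table: pd.DataFrame) -> None:
    missing = set(ENDPOINT_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"endpoint table is missing columns: {sorted(missing)}")
    dup = table.duplicated(["animal_id", "endpoint"])
    if dup.any():
        pair = table.loc[dup, ["animal_id", "endpoint"]].iloc[0].tolist()
        raise DataError(f"more than one value per (animal, endpoint): {pair}")


@dataclass
class AnovaResult:
    """Per-endpoint factorial ANOVA table plus assumption diagnostics."""

    endpoint: str
    terms: pd.DataFrame  # term, sum_sq, df, F, p
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "terms": {
                r.term: {"sum_sq": r.sum_sq, "df": r.df, "F": r.F, "p": r.p}
                for r in self.terms.itertuples()
            },
            "diagnostics": self.diagnostics,
        }


def factorial_anova(table: pd.DataFrame, interaction: bool = True) -> list[AnovaResult]:
    """Genotype x treatment fixed-effects ANOVA for each endpoint.

    Type-II sums of squares; F ratios against the residual mean square.
    Terms with zero sum of squares report F = 0, p = 1.  An empty design cell
    with ``interaction=True`` raises an error suggesting main-effects-only
    mode.
    """
    _validate_endpoints(table)
    results = []
    for endpoint, sub in table.groupby("endpoint", sort=True):
        for factor in ("genotype", "treatment"):
            if sub[factor].nunique() < 2:
                raise ProcedureError(
                    f"endpoint {endpoint!r}: factor {factor!r} needs >= 2 levels"
                )
        cells = sub.groupby(["genotype", "treatment"]).size().unstack(fill_value=0)
        if interaction and (cells.to_numpy() == 0).any():
            raise ProcedureError(
                f"endpoint {endpoint!r}: empty genotype x treatment cell; "
                "rerun with interaction=False (main effects only)"
            )
        op = "*" if interaction else "+"
        model = smf.ols(f"value ~ C(genotype) {op} C(treatment)", data=sub).fit()
        if model.df_resid < 1:
            raise ProcedureError(f"endpoint {endpoint!r}: residual df < 1")
        with np.errstate(divide="ignore", invalid="ignore"):
            aov = sm.stats.anova_lm(model, typ=2)

        rename = {
            "C(genotype)": "genotype",
            "C(treatment)": "treatment",
            "C(genotype):C(treatment)": "genotype:treatment",
            "Residual": "residual",
        }
        # zero-signal guard: a term whose SS is numerically zero relative to
        # the data's total variation (e.g. all values identical) gets F=0, p=1
        total_ss = float(((sub["value"] - sub["value"].mean()) ** 2).sum())
        ss_floor = 1e-10 * max(total_ss, np.finfo(float).eps)
        rows = []
        for term, r in aov.iterrows():
            name = rename.get(term, term)
            f_val, p_val = r["F"], r["PR(>F)"]
            if name != "residual" and (r["sum_sq"] <= ss_floor or not np.isfinite(f_val)):
                if r["sum_sq"] <= ss_floor:
                    f_val, p_val = 0.0, 1.0
            rows.append(
                {
                    "term": name,
                    "sum_sq": float(r["sum_sq"]),
                    "df": float(r["df"]),
                    "F": float(f_val) if np.isfinite(f_val) or name == "residual" else np.nan,
                    "p": float(p_val) if name != "residual" else np.nan,
                }
            )
        terms = pd.DataFrame(rows)

        resid = model.resid.to_numpy()
        groups = [g["value"].to_numpy() for _, g in sub.groupby(["genotype", "treatment"])]
        diagnostics = {}
        if len(resid) >= 3 and np.ptp(resid) > 0:
            sw = stats.shapiro(resid)
            diagnostics["shapiro_wilk"] = {"statistic": float(sw.statistic), "p": float(sw.pvalue)}
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            if any(np.ptp(g) > 0 for g in groups):
                lev = stats.levene(*groups)
                diagnostics["levene"] = {"statistic": float(lev.statistic), "p": float(lev.pvalue)}
        results.append(AnovaResult(endpoint=endpoint, terms=terms, diagnostics=diagnostics))
    return results


def tukey_hsd(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """All-pairs Tukey HSD over the levels of ``factor``, per endpoint.

    Returns a DataFrame with columns endpoint, group_a, group_b, mean_diff,
    p_adjusted, ci_low, ci_high, reject.
    """
    _validate_endpoints(table)
    if factor not in ("genotype", "treatment"):
        raise ConfigError(f"factor must be 'genotype' or 'treatment', got {factor!r}")
    frames = []
    for endpoint, sub in table.groupby("endpoint", sort=True):
        if sub[factor].nunique() < 2:
            raise ProcedureError(f"endpoint {endpoint!r}: need >= 2 groups for Tukey HSD")
        res = pairwise_tukeyhsd(sub["value"].to_numpy(), sub[factor].to_numpy())
        tbl = pd.DataFrame(
            res.summary().data[1:],
            columns=["group_a", "group_b", "mean_diff", "p_adjusted", "ci_low", "ci_high", "reject"],
        )
        # statsmodels rounds the summary table; take exact values from attributes
        tbl["mean_diff"] = res.meandiffs
        tbl["p_adjusted"] = res.pvalues
        tbl["ci_low"] = res.confint[:, 0]
        tbl["ci_high"] = res.confint[:, 1]
        tbl.insert(0, "endpoint", endpoint)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)
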