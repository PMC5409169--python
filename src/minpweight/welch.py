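"""Per-week, per-contrast Welch two-sample t-tests.

These raw p-values are the test statistics consumed by the minP
multiple-comparison procedure.  The moment-based kernel
:func:`welch_from_moments` is shared between the observed-data tests and the
bootstrap resamples so the null distribution reflects the exact statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError

__all__ = ["ContrastSpec", "WelchResult", "welch_t", "weekly_tests", "default_contrasts"]

TEST_COLUMNS = [
    "contrast",
    "week",
    "n_a",
    "n_b",
    "mean_a",
    "mean_b",
    "percent_diff",
    "t_stat",
    "df",
    "p_raw",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A named comparison between two disjoint sets of study arms.

    Arm labels may name a treatment (matches both genotypes), a genotype
    (matches all its treatments) or a fully qualified ``"genotype:treatment"``
    pair.  ``pool_genotypes`` records whether the contrast is meant to pool
    over genotype; the pipeline uses it when the genotype gate fails.
    """

    name: str
    side_a: frozenset = field(default_factory=frozenset)
    side_b: frozenset = field(default_factory=frozenset)
    pool_genotypes: bool = True

    def __post_init__(self):
        object.__setattr__(self, "side_a", frozenset(self.side_a))
        object.__setattr__(self, "side_b", frozenset(self.side_b))
        if not self.side_a or not self.side_b:
            raise ConfigError(f"contrast {self.name!r}: both sides must be non-empty")
        if self.side_a & self.side_b:
            raise ConfigError(f"contrast {self.name!r}: sides must be disjoint")

    def matches(self, labels: frozenset, genotype: str, treatment: str) -> bool:
        return bool({genotype, treatment, f"{genotype}:{treatment}"} & labels)

    def side_of(self, genotype: str, treatment: str) -> str | None:
        in_a = self.matches(self.side_a, genotype, treatment)
        in_b = self.matches(self.side_b, genotype, treatment)
        if in_a and in_b:
            raise ConfigError(
                f"contrast {self.name!r}: arm {genotype}:{treatment} matches both sides"
            )
        return "a" if in_a else ("b" if in_b else None)


def default_contrasts() -> list[ContrastSpec]:
    """The study's two simultaneous treatment hypotheses.

    Side A of the second contrast is the treated arm, so its percent
    difference is negative when treatment reduces body mass.
    """
    return [
        ContrastSpec("saline_vs_control_aso", frozenset({"saline"}), frozenset({"ctrl_aso"})),
        ContrastSpec(
            "htt_aso_vs_pooled_controls",
            frozenset({"htt_aso"}),
            frozenset({"saline", "ctrl_aso"}),
        ),
    ]


class WelchResult(NamedTuple):
    t_stat: float
    df: float
    p_raw: float


def welch_from_moments(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Vectorized Welch t statistic, Welch–Satterthwaite df and two-sided p.

    Degenerate cells (zero variance on both sides) get t = 0, p = 1 when the
    means are equal and p = 0 otherwise, with df = n_a + n_b - 2.
    """
    mean_a, var_a, mean_b, var_b = (
        np.asarray(x, dtype=float) for x in (mean_a, var_a, mean_b, var_b)
    )
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    va = var_a / n_a
    vb = var_b / n_b
    se2 = va + vb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
        df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    df = np.where(degenerate, n_a + n_b - 2, df)
    t = np.where(degenerate, np.where(mean_a == mean_b, 0.0, np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    return t, df, p


def welch_t(sample_a, sample_b) -> WelchResult:
    """Welch's two-sample t-test on two vectors.

    Requires >= 2 finite values per side.  Two zero-variance samples with
    equal means return p = 1 by convention; with unequal means the data are
    degenerate and an error is raised.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for label, x in (("sample_a", a), ("sample_b", b)):
        if x.size < 2:
            raise InsufficientDataError(f"{label}: need >= 2 observations, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise InsufficientDataError(f"{label}: non-finite values present")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a + var_b == 0 and a.mean() != b.mean():
        raise InsufficientDataError("zero variance on both sides with unequal means")
    t, df, p = welch_from_moments(a.mean(), var_a, a.size, b.mean(), var_b, b.size)
    return WelchResult(float(t), float(df), float(p))


def _animal_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per animal with its (genotype, treatment)."""
    arms = cohort[["animal_id", "genotype", "treatment"]].drop_duplicates()
    if arms["animal_id"].duplicated().any():
        dup = arms.loc[arms["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ConfigError(f"animal {dup!r} maps to more than one (genotype, treatment)")
    return arms


def resolve_sides(contrast: ContrastSpec, arms: pd.DataFrame) -> pd.Series:
    """Assign each animal to side 'a', 'b' or None; validates arm labels."""
    known = {
        lab
        for g, t in arms[["genotype", "treatment"]].drop_duplicates().itertuples(index=False)
        for lab in (g, t, f"{g}:{t}")
    }
    unknown = (contrast.side_a | contrast.side_b) - known
    if unknown:
        raise ConfigError(f"contrast {contrast.name!r}: unknown arm labels {sorted(unknown)}")
    sides = arms.apply(lambda r: contrast.side_of(r["genotype"], r["treatment"]), axis=1)
    return pd.Series(sides.to_numpy(), index=arms["animal_id"].to_numpy())


def weekly_tests(
    cohort: pd.DataFrame,
    contrasts: Iterable[ContrastSpec],
    min_n: int = 2,
) -> pd.DataFrame:
    """Welch tests for every (contrast, week) with >= ``min_n`` animals per side.

    Excluded observations are omitted; weeks with insufficient data on either
    side produce no record, shrinking the downstream minP family accordingly.
    ``percent_diff`` is (mean_a - mean_b) / mean_b, a signed fraction.
    """
    d = cohort
    if "excluded" in d.columns:
        d = d[~d["excluded"].astype(bool)]
    arms = _animal_table(d)
    pivot = d.pivot(index="animal_id", columns="week", values="mass_g")
    pivot = pivot.reindex(arms["animal_id"].to_numpy())
    weeks = pivot.columns.to_numpy()
    values = pivot.to_numpy()

    rows = []
    for contrast in contrasts:
        side = resolve_sides(contrast, arms)
        mask_a = (side == "a").to_numpy()
        mask_b = (side == "b").to_numpy()
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ConfigError(f"contrast {contrast.name!r}: one side matches no animals")
        a = values[mask_a]
        b = values[mask_b]
        n_a = np.sum(~np.isnan(a), axis=0)
        n_b = np.sum(~np.isnan(b), axis=0)
        eligible = (n_a >= min_n) & (n_b >= min_n)
        if not eligible.any():
            continue
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # ineligible weeks
            mean_a = np.nanmean(a, axis=0)
            mean_b = np.nanmean(b, axis=0)
            var_a = np.nanvar(a, axis=0, ddof=1)
            var_b = np.nanvar(b, axis=0, ddof=1)
        t, df, p = welch_from_moments(
            mean_a[eligible],
            var_a[eligible],
            n_a[eligible],
            mean_b[eligible],
            var_b[eligible],
            n_b[eligible],
        )
        rows.append(
            pd.DataFrame(
                {
                    "contrast": contrast.name,
                    "week": weeks[eligible],
                    "n_a": n_a[eligible],
                    "n_b": n_b[eligible],
                    "mean_a": mean_a[eligible],
                    "mean_b": mean_b[eligible],
                    "percent_diff": (mean_a[eligible] - mean_b[eligible]) / mean_b[eligible],
                    "t_stat": t,
                    "df": df,
                    "p_raw": p,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TEST_COLUMNS)
    return pd.concat(rows, ignore_index=True)
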