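"""Spurious-weight QC: the log-normalized-percent (LNP) statistic and exclusion rule.

For an animal weighed W_T grams in study week T (1-based), with the previous
week's weight W_{T-1} present,

    LNP = | 100 * (ln W_T - ln W_{T-1}) / (ln T - ln(T-1)) |

An observation week is *flagged* when LNP exceeds a threshold (default 130,
strict inequality), and weights are *excluded* when the flag persists for a
run of at least ``run_length`` consecutive weeks (default 2).  LNP is
undefined for an animal's first observed week and for any week whose
predecessor observation is missing; a missing week therefore breaks a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = ["LNP_THRESHOLD", "RUN_LENGTH", "compute_lnp", "apply_exclusion", "QcResult"]

LNP_THRESHOLD = 130.0
RUN_LENGTH = 2

REPORT_COLUMNS = ["animal_id", "week", "lnp", "flagged", "excluded"]


def _validate_cohort(cohort: pd.DataFrame) -> None:
    required = {"animal_id", "week", "mass_g"}
    missing = required - set(cohort.columns)
    if missing:
        raise DataError(f"cohort is missing columns: {sorted(missing)}")
    if len(cohort) and (cohort["week"] < 1).any():
        raise DataError("week indices must be >= 1 (1-based study weeks)")
    if len(cohort) and (cohort["mass_g"] <= 0).any():
        raise DataError("all masses must be positive")
    if cohort.duplicated(["animal_id", "week"]).any():
        raise DataError("duplicate (animal_id, week) pairs in cohort")


def compute_lnp(cohort: pd.DataFrame, threshold: float = LNP_THRESHOLD) -> pd.DataFrame:
    """Per-observation LNP report for every week with a consecutive predecessor.

    Returns a DataFrame with columns ``animal_id, week, lnp, flagged,
    excluded`` (``excluded`` all False until :func:`apply_exclusion` runs).
    Already-excluded cohort rows are ignored.
    """
    _validate_cohort(cohort)
    d = cohort
    if "excluded" in d.columns:
        d = d[~d["excluded"].astype(bool)]
    d = d.sort_values(["animal_id", "week"], kind="stable")

    grp = d.groupby("animal_id", sort=False)
    prev_week = grp["week"].shift(1)
    prev_mass = grp["mass_g"].shift(1)
    consecutive = prev_week == d["week"] - 1

    week = d.loc[consecutive, "week"].to_numpy(dtype=float)
    w_t = d.loc[consecutive, "mass_g"].to_numpy(dtype=float)
    w_prev = prev_mass[consecutive].to_numpy(dtype=float)
    lnp = np.abs(100.0 * (np.log(w_t) - np.log(w_prev)) / (np.log(week) - np.log(week - 1)))

    report = pd.DataFrame(
        {
            "animal_id": d.loc[consecutive, "animal_id"].to_numpy(),
            "week": d.loc[consecutive, "week"].to_numpy(),
            "lnp": lnp,
            "flagged": lnp > threshold,  # strict: lnp == threshold is not flagged
            "excluded": False,
        }
    )
    return report.reset_index(drop=True)


@dataclass
class QcResult:
    """Outcome of the exclusion rule."""

    report: pd.DataFrame
    cohort: pd.DataFrame
    n_excluded: int
    exclusion_fraction: float
    excluded_animals: list


def apply_exclusion(
    report: pd.DataFrame,
    cohort: pd.DataFrame,
    run_length: int = RUN_LENGTH,
    exclude_animal: bool = False,
) -> QcResult:
    """Exclude observations in any run of >= ``run_length`` consecutive flagged weeks.

    All weeks of a qualifying run are excluded (the run is the spurious unit);
    with ``exclude_animal=True`` every observation of an affected animal is
    dropped instead.  Returns the updated report and cohort plus the fraction
    of cohort observations excluded.
    """
    if run_length < 1:
        raise ConfigError("run_length must be >= 1")

    report = report.copy()
    report["excluded"] = False
    cohort = cohort.copy()
    if "excluded" not in cohort.columns:
        cohort["excluded"] = False

    excluded_pairs: list[tuple] = []
    affected_animals: list = []
    for animal, sub in report[report["flagged"]].groupby("animal_id", sort=False):
        weeks = np.sort(sub["week"].to_numpy())
        # split flagged weeks into maximal runs of consecutive study weeks
        breaks = np.where(np.diff(weeks) != 1)[0] + 1
        for run in np.split(weeks, breaks):
            if len(run) >= run_length:
                excluded_pairs.extend((animal, int(w)) for w in run)
                if animal not in affected_animals:
                    affected_animals.append(animal)

    if excluded_pairs:
        idx = pd.MultiIndex.from_tuples(excluded_pairs)
        rep_key = pd.MultiIndex.from_frame(report[["animal_id", "week"]])
        report.loc[rep_key.isin(idx), "excluded"] = True
        if exclude_animal:
            cohort.loc[cohort["animal_id"].isin(affected_animals), "excluded"] = True
        else:
            coh_key = pd.MultiIndex.from_frame(cohort[["animal_id", "week"]])
            cohort.loc[coh_key.isin(idx), "excluded"] = True

    n_excluded = int(cohort["excluded"].sum())
    frac = n_excluded / len(cohort) if len(cohort) else 0.0
    return QcResult(
        report=report,
        cohort=cohort,
        n_excluded=n_excluded,
        exclusion_fraction=frac,
        excluded_animals=affected_animals,
    )
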