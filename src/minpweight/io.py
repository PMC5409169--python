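"""Delimited-text I/O and structured configuration parsing.

Cohort tables are CSV with header ``animal_id,genotype,treatment,week,mass_g``
(an optional ``excluded`` boolean column is honoured).  Endpoint tables are
CSV with header ``animal_id,genotype,treatment,endpoint,value``.  Configs are
YAML.  Parse failures report 1-based file line numbers (header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .simulate import (
    ArmSpec,
    ContaminationSpec,
    CovarianceSpec,
    EffectSpec,
    MeanCurve,
    SimSpec,
    default_spec,
)
from .welch import ContrastSpec

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_endpoints",
    "load_config",
    "sim_spec_from_dict",
    "contrasts_from_config",
]

_COHORT_REQUIRED = ["animal_id", "genotype", "treatment", "week", "mass_g"]
_MAX_REPORTED = 5


def _line(i: int) -> int:
    return i + 2  # 0-based data row -> 1-based file line below the header


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface any parser failure as DataError
        raise DataError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing} (line 1)")

    problems = []
    week = pd.to_numeric(df["week"], errors="coerce")
    bad = df.index[week.isna() | (week < 1) | (week != week.round())]
    problems += [f"line {_line(i)}: week must be a positive integer" for i in bad[:_MAX_REPORTED]]
    mass = pd.to_numeric(df["mass_g"], errors="coerce")
    bad = df.index[mass.isna() | (mass <= 0)]
    problems += [f"line {_line(i)}: mass_g must be a positive number" for i in bad[:_MAX_REPORTED]]
    if not problems:
        df["week"] = week.astype(int)
        df["mass_g"] = mass.astype(float)
        dup = df.duplicated(["animal_id", "week"])
        problems += [
            f"line {_line(i)}: duplicate (animal_id, week)" for i in df.index[dup][:_MAX_REPORTED]
        ]
        arms = df[["animal_id", "genotype", "treatment"]].drop_duplicates()
        multi = arms["animal_id"].duplicated()
        if multi.any():
            problems.append(
                f"animal {arms.loc[multi, 'animal_id'].iloc[0]!r} maps to more than one arm"
            )
    if problems:
        raise DataError(f"{path}: " + "; ".join(problems))
    if "excluded" not in df.columns:
        df["excluded"] = False
    else:
        df["excluded"] = df["excluded"].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in [*_COHORT_REQUIRED, "excluded"] if c in cohort.columns]
    cohort.to_csv(path, columns=cols, index=False)


def read_endpoints(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ["animal_id", "genotype", "treatment", "endpoint", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing} (line 1)")
    value = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[value.isna() & df["value"].notna()]
    if len(bad):
        raise DataError(f"{path}: line {_line(bad[0])}: value is not numeric")
    df["value"] = value
    return df.dropna(subset=["value"])


def load_config(path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def contrasts_from_config(entries) -> list[ContrastSpec]:
    contrasts = []
    for e in entries:
        try:
            contrasts.append(
                ContrastSpec(
                    name=e["name"],
                    side_a=frozenset(e["side_a"]),
                    side_b=frozenset(e["side_b"]),
                    pool_genotypes=bool(e.get("pool_genotypes", True)),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"contrast entry missing key {exc}") from exc
    return contrasts


def sim_spec_from_dict(cfg: dict) -> SimSpec:
    """Build a SimSpec from a config mapping; unset fields take the defaults."""
    cfg = dict(cfg or {})
    kwargs = {}
    if "mean_curve" in cfg:
        kwargs["mean_curve"] = MeanCurve(**cfg.pop("mean_curve"))
    if "effect" in cfg:
        kwargs["effect"] = EffectSpec(**cfg.pop("effect"))
    if "covariance" in cfg:
        kwargs["covariance"] = CovarianceSpec(**cfg.pop("covariance"))
    if "contamination" in cfg:
        kwargs["contamination"] = ContaminationSpec(**cfg.pop("contamination"))
    arms = cfg.pop("arms", None)
    n_per_arm = cfg.pop("n_per_arm", 16)
    effect_size = cfg.pop("effect_size", None)
    known = {"n_weeks", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown simulate config keys: {sorted(unknown)}")
    kwargs.update(cfg)
    if effect_size is not None:
        if "effect" in kwargs:
            raise ConfigError("give either effect_size or an effect block, not both")
        kwargs["effect"] = EffectSpec(size=float(effect_size))
    if arms is not None:
        arm_specs = tuple(
            ArmSpec(
                genotype=a["genotype"],
                treatment=a["treatment"],
                n_animals=int(a.get("n_animals", n_per_arm)),
                treated=bool(a.get("treated", False)),
            )
            for a in arms
        )
        spec = SimSpec(arms=arm_specs, **kwargs)
    else:
        spec = default_spec(n_per_arm=n_per_arm, **kwargs)
    spec.validate()
    return spec
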