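"""End-to-end weight-trajectory analysis.

Sequence: LNP QC -> genotype gate (a single-contrast minP family comparing
the two genotypes across all weeks) -> if the gate is non-significant, pool
genotypes and test the two treatment contrasts simultaneously with the joint
minP family.  If the gate *is* significant, pooling is skipped and the
treatment contrasts are run separately within each genotype, with a warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mwio
from .errors import ConfigError
from .minp import arm_sizes_from_cohort, estimate_covariance, minp_adjust
from .qc import LNP_THRESHOLD, RUN_LENGTH, apply_exclusion, compute_lnp
from .welch import ContrastSpec, default_contrasts, weekly_tests
from .endpoints import factorial_anova, tukey_hsd

__all__ = ["RunConfig", "run_weight_analysis", "run_endpoint_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one weight-analysis run; defaults are the study settings
    (LNP threshold 130, run length 2, B = 10,000 bootstrap resamples)."""

    input: str | None = None
    lnp_threshold: float = LNP_THRESHOLD
    lnp_run_length: int = RUN_LENGTH
    exclude_animal: bool = False
    gate_alpha: float = 0.05
    contrasts: list = field(default_factory=default_contrasts)
    n_bootstrap: int = 10000
    seed: int = 0
    family_mode: str = "joint"
    significance_alpha: float = 0.05
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        if "contrasts" in cfg:
            cfg["contrasts"] = mwio.contrasts_from_config(cfg["contrasts"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(mwio.load_config(path))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_weight_analysis(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Run the full body-weight pipeline; returns the machine-readable report.

    With ``config.out_dir`` set, also writes ``report.json`` plus CSV tables
    (LNP report, QC-filtered cohort, weekly tests, per-week adjusted
    p-values).
    """
    if cohort is None:
        if config.input is None:
            raise ConfigError("no input cohort: set config.input or pass a cohort")
        cohort = mwio.read_cohort(config.input)

    logger.info(
        "QC: LNP threshold=%s run_length=%s exclude_animal=%s",
        config.lnp_threshold,
        config.lnp_run_length,
        config.exclude_animal,
    )
    report_lnp = compute_lnp(cohort, threshold=config.lnp_threshold)
    qc = apply_exclusion(
        report_lnp,
        cohort,
        run_length=config.lnp_run_length,
        exclude_animal=config.exclude_animal,
    )
    clean = qc.cohort

    cov = estimate_covariance(clean)
    arm_sizes = arm_sizes_from_cohort(clean)
    root = np.random.SeedSequence(config.seed)
    gate_seed, main_seed = (int(s) & 0x7FFFFFFF for s in root.generate_state(2))

    genotypes = sorted(clean["genotype"].unique())
    report: dict = {
        "config": {
            "lnp_threshold": config.lnp_threshold,
            "lnp_run_length": config.lnp_run_length,
            "exclude_animal": config.exclude_animal,
            "gate_alpha": config.gate_alpha,
            "n_bootstrap": config.n_bootstrap,
            "seed": config.seed,
            "family_mode": config.family_mode,
            "significance_alpha": config.significance_alpha,
        },
        "qc": {
            "n_observations": int(len(cohort)),
            "n_excluded": qc.n_excluded,
            "exclusion_fraction": qc.exclusion_fraction,
            "excluded_animals": list(qc.excluded_animals),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    tables = {"lnp_report": qc.report, "cohort_qc": clean}

    if len(genotypes) == 2:
        gate_contrast = ContrastSpec(
            "genotype_gate", frozenset({genotypes[0]}), frozenset({genotypes[1]})
        )
        gate_tests = weekly_tests(clean, [gate_contrast])
        gate_result = minp_adjust(
            gate_tests,
            cov,
            arm_sizes,
            [gate_contrast],
            B=config.n_bootstrap,
            seed=gate_seed,
            family_mode=config.family_mode,
        )
        gate = gate_result.contrasts["genotype_gate"]
        gate_pass = gate.p_adjusted > config.gate_alpha
        report["genotype_gate"] = {
            "contrast": f"{genotypes[0]} vs {genotypes[1]}",
            "p_min": gate.p_min,
            "argmin_week": gate.argmin_week,
            "p_adjusted": gate.p_adjusted,
            "alpha": config.gate_alpha,
            "pooled": bool(gate_pass),
        }
    else:
        logger.warning("genotype gate skipped: %d genotype level(s)", len(genotypes))
        gate_pass = True
        report["genotype_gate"] = {"skipped": True, "pooled": True}

    def _run_contrast_block(data: pd.DataFrame, label: str, seed: int) -> dict:
        tests = weekly_tests(data, config.contrasts)
        block_cov = cov if data is clean else estimate_covariance(data)
        result = minp_adjust(
            tests,
            block_cov,
            arm_sizes_from_cohort(data),
            config.contrasts,
            B=config.n_bootstrap,
            seed=seed,
            family_mode=config.family_mode,
        )
        tables[f"weekly_tests{label}"] = tests
        per_week = pd.concat(
            [c.per_week.assign(contrast=name) for name, c in result.contrasts.items()],
            ignore_index=True,
        )
        tables[f"per_week_adjusted{label}"] = per_week
        out = result.to_dict()
        for name, c in result.contrasts.items():
            sig = c.per_week[c.per_week["p_adjusted"] <= config.significance_alpha]
            out["contrasts"][name]["significant_weeks"] = [int(w) for w in sig["week"]]
        return out

    if gate_pass:
        report["treatment_analysis"] = _run_contrast_block(clean, "", main_seed)
    else:
        logger.warning(
            "genotype gate significant (p_adjusted <= %s): genotypes are NOT pooled; "
            "running treatment contrasts within each genotype",
            config.gate_alpha,
        )
        per_geno = {}
        for i, g in enumerate(genotypes):
            sub = clean[clean["genotype"] == g]
            per_geno[g] = _run_contrast_block(sub, f"_{g}", main_seed + i + 1)
        report["treatment_analysis_by_genotype"] = per_geno

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        for name, tbl in tables.items():
            tbl.to_csv(out / f"{name}.csv", index=False)
    return report


def run_endpoint_analysis(
    table: pd.DataFrame,
    interaction: bool = True,
    tukey_factor: str = "treatment",
    out_path=None,
) -> dict:
    """Factorial ANOVA + Tukey HSD for every endpoint in the table."""
    if table.empty:
        report = {"endpoints": {}}
    else:
        anova = factorial_anova(table, interaction=interaction)
        tukey = tukey_hsd(table, tukey_factor)
        report = {"endpoints": {}}
        for res in anova:
            pairs = tukey[tukey["endpoint"] == res.endpoint]
            entry = res.to_dict()
            entry["tukey"] = {
                "factor": tukey_factor,
                "pairs": [
                    {
                        "group_a": r.group_a,
                        "group_b": r.group_b,
                        "mean_diff": float(r.mean_diff),
                        "p_adjusted": float(r.p_adjusted),
                    }
                    for r in pairs.itertuples()
                ],
            }
            report["endpoints"][res.endpoint] = entry
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report
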