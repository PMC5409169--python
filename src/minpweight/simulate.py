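"""Synthetic weekly body-weight cohorts for a two-genotype, three-treatment trial.

The generator emulates the statistical structure the downstream analysis
assumes: a monotone saturating mean growth curve shared by both genotypes, a
multiplicative treatment effect that ramps in linearly and reaches full size
at a configurable onset week, a per-animal random intercept, an AR(1) serial
residual, white measurement noise, rare spurious measurement spikes, and
occasional completely-at-random missing weeks.

Masses are in grams; weeks are 1-based study-week indices (week of first
injection = 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "ArmSpec",
    "MeanCurve",
    "EffectSpec",
    "CovarianceSpec",
    "ContaminationSpec",
    "SimSpec",
    "ramp",
    "generate_cohort",
    "default_spec",
]

COHORT_COLUMNS = ["animal_id", "genotype", "treatment", "week", "mass_g", "excluded"]

# Default arm labels used throughout the package.
GENOTYPES = ("Q111", "WT")
TREATMENT_ACTIVE = "htt_aso"
TREATMENT_CONTROL = "ctrl_aso"
TREATMENT_SALINE = "saline"


@dataclass(frozen=True)
class ArmSpec:
    """One study arm: a genotype x treatment combination with its group size."""

    genotype: str
    treatment: str
    n_animals: int = 16
    treated: bool = False


@dataclass(frozen=True)
class MeanCurve:
    """Exponential approach to an asymptote: m(t) = a - (a - b) * exp(-k t).

    ``baseline_g`` is the expected mass at week 0, ``asymptote_g`` the adult
    plateau, ``rate_per_week`` the approach rate.  Any smooth monotone curve
    would do — the downstream tests are week-wise — but a saturating curve
    matches the shape of adult mouse growth.
    """

    baseline_g: float = 22.0
    asymptote_g: float = 32.0
    rate_per_week: float = 0.08

    def value(self, week):
        w = np.asarray(week, dtype=float)
        return self.asymptote_g - (self.asymptote_g - self.baseline_g) * np.exp(
            -self.rate_per_week * w
        )


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative treatment effect on mean mass.

    ``size`` is the full fractional reduction (0.05 = treated animals weigh 5%
    less); the effect ramps in linearly over ``ramp_weeks`` and reaches full
    size at ``onset_week``.
    """

    size: float = 0.05
    onset_week: int = 30
    ramp_weeks: int = 10


@dataclass(frozen=True)
class CovarianceSpec:
    """Within-animal covariance components, all in grams.

    ``serial_sd_g`` is the stationary standard deviation of the AR(1)
    residual process with lag-1 correlation ``serial_rho``.
    """

    intercept_sd_g: float = 1.5
    serial_rho: float = 0.9
    serial_sd_g: float = 0.7
    noise_sd_g: float = 0.2

    def implied_covariance(self, n_weeks: int) -> np.ndarray:
        """Closed-form residual covariance: Sigma(t,s) = sa^2 + sr^2 rho^|t-s| + se^2 1{t=s}."""
        lags = np.abs(np.subtract.outer(np.arange(n_weeks), np.arange(n_weeks)))
        cov = self.intercept_sd_g**2 + self.serial_sd_g**2 * self.serial_rho ** lags
        cov[np.diag_indices(n_weeks)] += self.noise_sd_g**2
        return cov


@dataclass(frozen=True)
class ContaminationSpec:
    """Spurious measurement spikes and missing weeks.

    A spike multiplies ``spike_run_weeks`` consecutive observations of one
    animal by (1 +/- spike_magnitude); the default run of 1 is the unit the
    LNP filter targets.  Missingness is completely at random.
    """

    spike_prob: float = 0.002
    spike_magnitude: float = 0.3
    missing_prob: float = 0.01
    spike_run_weeks: int = 1


@dataclass(frozen=True)
class SimSpec:
    """Full generative description of a synthetic cohort."""

    arms: tuple[ArmSpec, ...]
    mean_curve: MeanCurve = field(default_factory=MeanCurve)
    effect: EffectSpec = field(default_factory=EffectSpec)
    covariance: CovarianceSpec = field(default_factory=CovarianceSpec)
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    n_weeks: int = 35
    seed: int = 0

    def validate(self) -> None:
        if not self.arms:
            raise ConfigError("arms: at least one arm is required")
        for arm in self.arms:
            if arm.n_animals < 1:
                raise ConfigError(f"arms[{arm.genotype}:{arm.treatment}].n_animals must be >= 1")
        mc = self.mean_curve
        if mc.baseline_g <= 0 or mc.asymptote_g <= 0:
            raise ConfigError("mean_curve: baseline_g and asymptote_g must be positive")
        if mc.rate_per_week < 0:
            raise ConfigError("mean_curve.rate_per_week must be >= 0")
        eff = self.effect
        if not 0.0 <= eff.size < 1.0:
            raise ConfigError("effect.size must be in [0, 1)")
        if eff.onset_week < 1:
            raise ConfigError("effect.onset_week must be >= 1")
        if eff.ramp_weeks < 0:
            raise ConfigError("effect.ramp_weeks must be >= 0")
        cov = self.covariance
        for name in ("intercept_sd_g", "serial_sd_g", "noise_sd_g"):
            if getattr(cov, name) < 0:
                raise ConfigError(f"covariance.{name} must be >= 0")
        if not 0.0 <= cov.serial_rho < 1.0:
            raise ConfigError("covariance.serial_rho must be in [0, 1)")
        cont = self.contamination
        for name in ("spike_prob", "missing_prob"):
            if not 0.0 <= getattr(cont, name) <= 1.0:
                raise ConfigError(f"contamination.{name} must be in [0, 1]")
        if not 0.0 <= cont.spike_magnitude < 1.0:
            raise ConfigError("contamination.spike_magnitude must be in [0, 1)")
        if cont.spike_run_weeks < 1:
            raise ConfigError("contamination.spike_run_weeks must be >= 1")
        if self.n_weeks < 1:
            raise ConfigError("n_weeks must be >= 1")

    def replace(self, **kwargs) -> "SimSpec":
        return dataclasses.replace(self, **kwargs)


def default_spec(
    n_per_arm: int = 16,
    effect_size: float = 0.05,
    n_weeks: int = 35,
    seed: int = 0,
    **overrides,
) -> SimSpec:
    """The standard six-arm design: 2 genotypes x {active ASO, control ASO, saline}.

    16 animals per arm (~96 total) with a 5% treatment effect at full size
    after 30 weeks of dosing.  The genotype never alters the mean curve.
    """
    arms = tuple(
        ArmSpec(g, t, n_per_arm, treated=(t == TREATMENT_ACTIVE))
        for g in GENOTYPES
        for t in (TREATMENT_ACTIVE, TREATMENT_CONTROL, TREATMENT_SALINE)
    )
    return SimSpec(
        arms=arms,
        effect=EffectSpec(size=effect_size),
        n_weeks=n_weeks,
        seed=seed,
        **overrides,
    )


def ramp(week, onset_week: int, ramp_weeks: int):
    """Linear ramp from 0 to 1: 0 before onset_week - ramp_weeks, 1 at onset_week.

    ramp_weeks = 0 gives a step function at onset_week.
    """
    if onset_week < 1:
        raise ConfigError("onset_week must be >= 1")
    if ramp_weeks < 0:
        raise ConfigError("ramp_weeks must be >= 0")
    w = np.asarray(week, dtype=float)
    if ramp_weeks == 0:
        out = (w >= onset_week).astype(float)
    else:
        out = np.clip((w - (onset_week - ramp_weeks)) / ramp_weeks, 0.0, 1.0)
    if np.isscalar(week):
        return float(out)
    return out


def generate_cohort(spec: SimSpec, return_log: bool = False):
    """Simulate one cohort; deterministic given ``spec.seed``.

    Returns a long-format DataFrame with columns
    ``animal_id, genotype, treatment, week, mass_g, excluded`` (one row per
    retained animal-week).  With ``return_log=True`` also returns a
    contamination log DataFrame (``animal_id, week, kind, factor``) recording
    every injected spike and dropped week.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_weeks = spec.n_weeks
    weeks = np.arange(1, n_weeks + 1)
    base = spec.mean_curve.value(weeks)
    eff = spec.effect
    cov = spec.covariance
    cont = spec.contamination
    ramp_frac = ramp(weeks, eff.onset_week, eff.ramp_weeks)

    frames = []
    log_rows = []
    for arm in spec.arms:
        mu = base * (1.0 - eff.size * ramp_frac) if arm.treated else base
        n = arm.n_animals
        ids = [f"{arm.genotype}-{arm.treatment}-{i:03d}" for i in range(n)]

        intercept = rng.normal(0.0, cov.intercept_sd_g, size=n)
        eps = rng.standard_normal((n, n_weeks))
        serial = np.empty((n, n_weeks))
        serial[:, 0] = cov.serial_sd_g * eps[:, 0]
        innov_sd = cov.serial_sd_g * np.sqrt(1.0 - cov.serial_rho**2)
        for t in range(1, n_weeks):
            serial[:, t] = cov.serial_rho * serial[:, t - 1] + innov_sd * eps[:, t]
        noise = rng.normal(0.0, cov.noise_sd_g, size=(n, n_weeks))
        mass = mu[None, :] + intercept[:, None] + serial + noise

        spike_start = rng.random((n, n_weeks)) < cont.spike_prob
        spike_sign = rng.choice([-1.0, 1.0], size=(n, n_weeks))
        factor = np.ones((n, n_weeks))
        for i, t in zip(*np.nonzero(spike_start)):
            f = 1.0 + spike_sign[i, t] * cont.spike_magnitude
            for k in range(cont.spike_run_weeks):
                if t + k < n_weeks:
                    factor[i, t + k] *= f
                    log_rows.append((ids[i], int(weeks[t + k]), "spike", f))
        mass = mass * factor

        missing = rng.random((n, n_weeks)) < cont.missing_prob
        for i, t in zip(*np.nonzero(missing)):
            log_rows.append((ids[i], int(weeks[t]), "missing", np.nan))

        if np.any(mass[~missing] <= 0):
            raise DataError(
                "simulated mass <= 0; noise or contamination settings are too "
                "large for the mean curve"
            )

        keep = ~missing
        n_obs = keep.sum()
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(ids, n_weeks)[keep.ravel()],
                    "genotype": arm.genotype,
                    "treatment": arm.treatment,
                    "week": np.tile(weeks, n)[keep.ravel()],
                    "mass_g": mass[keep],
                    "excluded": np.zeros(n_obs, dtype=bool),
                }
            )
        )

    cohort = pd.concat(frames, ignore_index=True)
    if return_log:
        log = pd.DataFrame(log_rows, columns=["animal_id", "week", "kind", "factor"])
        return cohort, log
    return cohort
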