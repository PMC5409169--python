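"""minP multiple-comparison procedure via parametric bootstrap.

The family of hypotheses is the set of (contrast, week) cells tested by
:func:`minpweight.welch.weekly_tests`.  The null distribution of the minimum
raw Welch p-value over the family is approximated by drawing, B times, one
week-vector per animal from a mean-zero multivariate normal with the
covariance estimated from arm-centered residuals, re-running the identical
Welch statistic on each resample, and recording the family-wise minimum.

Adjusted p-values use add-one counting, (1 + #{b : m_b <= p}) / (B + 1),
which guarantees validity and puts a floor of 1/(B+1) on every adjusted
p-value (1/10001 ~= 0.0001 at the default B = 10,000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ProcedureError
from .simulate import SimSpec, generate_cohort
from .qc import compute_lnp, apply_exclusion, LNP_THRESHOLD, RUN_LENGTH
from .welch import ContrastSpec, weekly_tests, welch_from_moments, default_contrasts

__all__ = [
    "CovarianceEstimate",
    "MinPResult",
    "ContrastMinP",
    "estimate_covariance",
    "minp_adjust",
    "arm_sizes_from_cohort",
    "fwer_simulation",
    "power_simulation",
    "FwerEstimate",
]

logger = logging.getLogger(__name__)

_CHUNK = 256  # bootstrap resamples per vectorized block; fixed for determinism


@dataclass
class CovarianceEstimate:
    """Week-by-week residual covariance (grams^2) over the eligible weeks."""

    matrix: np.ndarray
    weeks: list
    method: str
    n_animals: int
    dropped_weeks: list = field(default_factory=list)
    repaired: bool = False
    shrinkage_lambda: float | None = None

    def factor(self) -> np.ndarray:
        """A matrix A with A A' = matrix (eigen factor; tolerates singular PSD)."""
        sym = 0.5 * (self.matrix + self.matrix.T)
        w, v = np.linalg.eigh(sym)
        if np.any(w < -1e-8 * max(w.max(), 1.0)):
            raise ProcedureError("covariance matrix is not PSD-repairable")
        return v * np.sqrt(np.clip(w, 0.0, None))


def _shrinkage_intensity(resid: np.ndarray, corr: np.ndarray) -> float:
    """Analytic shrinkage intensity for the correlation matrix (toward identity).

    Schafer-Strimmer estimator: lambda* = sum Var(r_ij) / sum r_ij^2 over
    off-diagonal cells, with pairwise-complete moments under missing data.
    """
    sd = np.nanstd(resid, axis=0, ddof=1)
    z = (resid - np.nanmean(resid, axis=0)) / np.where(sd > 0, sd, 1.0)
    present = ~np.isnan(z)
    z0 = np.where(present, z, 0.0)
    n_pair = present.astype(float).T @ present.astype(float)
    w_all = z0[:, :, None] * z0[:, None, :]
    w_bar = corr * np.maximum(n_pair - 1, 1) / np.maximum(n_pair, 1)
    pair_mask = present[:, :, None] & present[:, None, :]
    var_w = ((w_all - w_bar[None]) ** 2 * pair_mask).sum(axis=0)
    n_eff = np.maximum(n_pair, 2.0)
    var_r = n_eff / np.maximum(n_eff - 1.0, 1.0) ** 3 * var_w
    off = ~np.eye(corr.shape[0], dtype=bool)
    denom = float((corr[off] ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))


def estimate_covariance(cohort: pd.DataFrame, shrinkage: str = "analytic") -> CovarianceEstimate:
    """Pooled covariance of arm-centered residual week-vectors, shrunk by default.

    Each animal's weekly masses are centered by its arm's per-week mean
    (removing treatment and genotype means, as the mean-zero null requires);
    the covariance of the residual vectors is pooled over all animals with
    pairwise-complete handling of missing cells.  Weeks with fewer than two
    observations are dropped with a warning.

    With ``shrinkage='analytic'`` (default) the correlation matrix is shrunk
    toward identity with the Schafer-Strimmer analytic intensity; at the week
    counts typical of a year-long study the raw sample covariance is noisy
    enough to make the downstream minP adjustment mildly anticonservative,
    and the shrinkage (which vanishes as animals accumulate) restores nominal
    family-wise error.  ``shrinkage='none'`` gives the raw pooled estimator.
    The result is symmetrized and eigenvalue-clipped to the nearest
    positive-semidefinite matrix if needed.
    """
    if shrinkage not in ("analytic", "none"):
        raise ConfigError(f"unknown shrinkage mode {shrinkage!r}")
    d = cohort
    if "excluded" in d.columns:
        d = d[~d["excluded"].astype(bool)]
    if d.empty:
        raise ProcedureError("no observations available for covariance estimation")

    arm_mean = d.groupby(["genotype", "treatment", "week"])["mass_g"].transform("mean")
    resid = d.assign(resid=d["mass_g"] - arm_mean)
    pivot = resid.pivot(index="animal_id", columns="week", values="resid")

    counts = pivot.notna().sum(axis=0)
    dropped = [int(w) for w in counts.index[counts < 2]]
    if dropped:
        logger.warning("dropping weeks with < 2 observations from the family: %s", dropped)
        pivot = pivot.drop(columns=dropped)
    if pivot.shape[1] == 0:
        raise ProcedureError("no week has >= 2 observations")

    cov = pivot.cov(min_periods=2)
    n_missing = int(cov.isna().sum().sum())
    if n_missing:
        logger.warning("%d covariance cells had < 2 complete pairs; set to 0", n_missing)
        cov = cov.fillna(0.0)

    mat = cov.to_numpy()
    mat = 0.5 * (mat + mat.T)

    lam = None
    if shrinkage == "analytic":
        sd = np.sqrt(np.diag(mat))
        sd_safe = np.where(sd > 0, sd, 1.0)
        corr = mat / np.outer(sd_safe, sd_safe)
        np.fill_diagonal(corr, 1.0)
        lam = _shrinkage_intensity(pivot.to_numpy(), corr)
        corr = (1.0 - lam) * corr
        np.fill_diagonal(corr, 1.0)
        mat = corr * np.outer(sd, sd)

    w = np.linalg.eigvalsh(mat)
    repaired = bool(w.min() < 0)
    if repaired:
        ww, v = np.linalg.eigh(mat)
        mat = (v * np.clip(ww, 0.0, None)) @ v.T
        mat = 0.5 * (mat + mat.T)
    method = "pooled arm-centered residuals, pairwise-complete"
    if shrinkage == "analytic":
        method += f", correlation shrinkage lambda={lam:.4f}"
    return CovarianceEstimate(
        matrix=mat,
        weeks=[int(wk) for wk in cov.columns],
        method=method,
        n_animals=pivot.shape[0],
        dropped_weeks=dropped,
        repaired=repaired,
        shrinkage_lambda=lam,
    )


@dataclass
class ContrastMinP:
    """minP summary for one contrast: its P_min, where it occurs, and the
    FWER-adjusted p-value, plus per-week adjusted p-values."""

    name: str
    p_min: float
    argmin_week: int
    p_adjusted: float
    per_week: pd.DataFrame  # columns: week, p_raw, p_adjusted

    def to_dict(self) -> dict:
        return {
            "p_min": self.p_min,
            "argmin_week": self.argmin_week,
            "p_adjusted": self.p_adjusted,
            "per_week": {
                int(r.week): {"p_raw": float(r.p_raw), "p_adjusted": float(r.p_adjusted)}
                for r in self.per_week.itertuples()
            },
        }


@dataclass
class MinPResult:
    contrasts: dict
    family: list  # (contrast name, week) cells
    B: int
    seed: int
    family_mode: str
    covariance_method: str

    def to_dict(self) -> dict:
        return {
            "contrasts": {name: c.to_dict() for name, c in self.contrasts.items()},
            "family": [[name, int(week)] for name, week in self.family],
            "B": self.B,
            "seed": self.seed,
            "family_mode": self.family_mode,
            "covariance_method": self.covariance_method,
        }


def arm_sizes_from_cohort(cohort: pd.DataFrame) -> list:
    """Number of distinct animals per (genotype, treatment) arm."""
    counts = cohort.groupby(["genotype", "treatment"])["animal_id"].nunique()
    return [(g, t, int(n)) for (g, t), n in counts.items()]


def minp_adjust(
    tests: pd.DataFrame,
    cov: CovarianceEstimate,
    arm_sizes,
    contrasts,
    B: int = 10000,
    seed: int = 0,
    family_mode: str = "joint",
) -> MinPResult:
    """Single-step minP adjustment of the (contrast, week) family.

    ``arm_sizes`` is a list of (genotype, treatment, n_animals); bootstrap
    resamples reuse these original group sizes with complete week-vectors.
    ``family_mode='joint'`` takes the bootstrap minimum over all contrasts and
    weeks jointly (the contrasts are tested simultaneously);
    ``'per-contrast'`` uses each contrast's own cells as its family.
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    if family_mode not in ("joint", "per-contrast"):
        raise ConfigError(f"unknown family_mode {family_mode!r}")
    contrasts = list(contrasts)
    names = [c.name for c in contrasts]
    fam = tests[tests["contrast"].isin(names)]
    if fam.empty:
        raise ProcedureError("empty family: no (contrast, week) cells to adjust")
    week_index = {int(w): i for i, w in enumerate(cov.weeks)}
    bad = sorted(set(int(w) for w in fam["week"]) - set(week_index))
    if bad:
        raise ProcedureError(f"tests contain weeks absent from the covariance estimate: {bad}")

    # assign bootstrap animals to arms, then to contrast sides
    arms = pd.DataFrame(
        [(g, t) for g, t, n in arm_sizes for _ in range(n)],
        columns=["genotype", "treatment"],
    )
    if arms.empty:
        raise ProcedureError("arm sizes are empty")
    n_total = len(arms)
    W = len(cov.weeks)

    side_masks = []
    for c in contrasts:
        sides = arms.apply(lambda r: c.side_of(r["genotype"], r["treatment"]), axis=1)
        mask_a = (sides == "a").to_numpy()
        mask_b = (sides == "b").to_numpy()
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise ProcedureError(
                f"contrast {c.name!r}: arm sizes give < 2 bootstrap animals on one side"
            )
        side_masks.append((mask_a, mask_b))

    # observed family quantities
    obs = {}
    cell_weeks = []
    cell_p_obs = []
    cell_slices = []
    pos = 0
    family_cells = []
    for c in contrasts:
        sub = fam[fam["contrast"] == c.name].sort_values("week")
        if sub.empty:
            raise ProcedureError(f"contrast {c.name!r} has no eligible weeks")
        weeks = sub["week"].to_numpy(dtype=int)
        p_raw = sub["p_raw"].to_numpy(dtype=float)
        i_min = int(np.argmin(p_raw))
        obs[c.name] = {
            "p_min": float(p_raw[i_min]),
            "argmin_week": int(weeks[i_min]),
            "weeks": weeks,
            "p_raw": p_raw,
        }
        cell_weeks.append(np.array([week_index[int(w)] for w in weeks]))
        cell_p_obs.append(p_raw)
        cell_slices.append(slice(pos, pos + len(weeks)))
        pos += len(weeks)
        family_cells.extend((c.name, int(w)) for w in weeks)

    A = cov.factor()
    rng = np.random.default_rng(seed)

    count_contrast = np.zeros(len(contrasts))
    count_cells = np.zeros(pos)
    done = 0
    while done < B:
        c_size = min(_CHUNK, B - done)
        Z = rng.standard_normal((c_size, n_total, W))
        X = Z @ A.T
        p_cells = np.empty((c_size, pos))
        for k, (c, (mask_a, mask_b)) in enumerate(zip(contrasts, side_masks)):
            Xa = X[:, mask_a, :]
            Xb = X[:, mask_b, :]
            _, _, p = welch_from_moments(
                Xa.mean(axis=1),
                Xa.var(axis=1, ddof=1),
                mask_a.sum(),
                Xb.mean(axis=1),
                Xb.var(axis=1, ddof=1),
                mask_b.sum(),
            )
            p_cells[:, cell_slices[k]] = p[:, cell_weeks[k]]
        m_joint = p_cells.min(axis=1)
        for k, c in enumerate(contrasts):
            sl = cell_slices[k]
            ref = m_joint if family_mode == "joint" else p_cells[:, sl].min(axis=1)
            count_contrast[k] += np.sum(ref <= obs[c.name]["p_min"])
            count_cells[sl] += np.sum(ref[:, None] <= cell_p_obs[k][None, :], axis=0)
        done += c_size

    results = {}
    for k, c in enumerate(contrasts):
        o = obs[c.name]
        sl = cell_slices[k]
        per_week = pd.DataFrame(
            {
                "week": o["weeks"],
                "p_raw": o["p_raw"],
                "p_adjusted": (1.0 + count_cells[sl]) / (B + 1.0),
            }
        )
        results[c.name] = ContrastMinP(
            name=c.name,
            p_min=o["p_min"],
            argmin_week=o["argmin_week"],
            p_adjusted=float((1.0 + count_contrast[k]) / (B + 1.0)),
            per_week=per_week,
        )
    return MinPResult(
        contrasts=results,
        family=family_cells,
        B=B,
        seed=seed,
        family_mode=family_mode,
        covariance_method=cov.method,
    )


@dataclass
class FwerEstimate:
    """Monte-Carlo estimate of the family-wise error rate (or power)."""

    rate: float
    ci_low: float
    ci_high: float
    n_rejections: int
    n_replicates: int
    alpha: float
    B: int

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_rejections": self.n_rejections,
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "B": self.B,
        }


def _rejection_simulation(
    spec: SimSpec,
    n_replicates: int,
    alpha: float,
    B: int,
    seed: int,
    contrasts=None,
    lnp_threshold: float = LNP_THRESHOLD,
    run_length: int = RUN_LENGTH,
    family_mode: str = "joint",
    reject_contrasts=None,
) -> FwerEstimate:
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    contrasts = list(contrasts) if contrasts is not None else default_contrasts()
    reject_names = (
        [c.name for c in contrasts] if reject_contrasts is None else list(reject_contrasts)
    )
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    k = 0
    for child in children:
        sim_seed, boot_seed = (int(s) & 0x7FFFFFFF for s in child.generate_state(2))
        cohort = generate_cohort(spec.replace(seed=sim_seed))
        report = compute_lnp(cohort, threshold=lnp_threshold)
        qc = apply_exclusion(report, cohort, run_length=run_length)
        tests = weekly_tests(qc.cohort, contrasts)
        cov = estimate_covariance(qc.cohort)
        result = minp_adjust(
            tests,
            cov,
            arm_sizes_from_cohort(qc.cohort),
            contrasts,
            B=B,
            seed=boot_seed,
            family_mode=family_mode,
        )
        if any(result.contrasts[name].p_adjusted <= alpha for name in reject_names):
            k += 1
    ci = stats.binomtest(k, n_replicates).proportion_ci(confidence_level=0.95, method="exact")
    return FwerEstimate(
        rate=k / n_replicates,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_rejections=k,
        n_replicates=n_replicates,
        alpha=alpha,
        B=B,
    )


def fwer_simulation(
    spec: SimSpec,
    n_replicates: int = 500,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> FwerEstimate:
    """Estimated FWER of the full QC + Welch + minP chain under a null cohort.

    ``spec`` must carry a zero treatment effect; the estimate is the fraction
    of replicate cohorts in which any contrast attains p_adjusted <= alpha,
    with an exact 95% binomial confidence interval.
    """
    if spec.effect.size != 0:
        raise ConfigError("fwer_simulation requires a null spec (effect.size == 0)")
    return _rejection_simulation(spec, n_replicates, alpha, B, seed, **kwargs)


def power_simulation(
    spec: SimSpec,
    n_replicates: int = 200,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> FwerEstimate:
    """Descriptive rejection rate under a non-null spec (same machinery as FWER)."""
    return _rejection_simulation(spec, n_replicates, alpha, B, seed, **kwargs)
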