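# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical conventions.

## Spurious-weight filter

The log-normalized-percent statistic for an observation in study week
`T >= 2` whose predecessor week was observed is

    LNP = | 100 * (ln W_T - ln W_(T-1)) / (ln T - ln(T-1)) |

Flagging uses a strict threshold (`LNP > 130`); exclusion requires a run of
at least `run_length = 2` consecutive flagged weeks.

Conventions, chosen where the rule alone does not decide:

- `T` is the 1-based study-week index (week of first dose = 1), so the
  earliest computable LNP is at `T = 2`; the denominator is undefined at
  `T = 1`.
- After a missing week the LNP is undefined rather than computed against the
  last available observation — the formula is strictly consecutive-week —
  and an undefined week breaks a flag run.
- All weeks of a qualifying run are excluded (the run is the spurious unit);
  `exclude_animal=True` instead drops every observation of an affected
  animal, for analysts who prefer the stricter reading.

Behavioral notes that follow from the formula: a single-week multiplicative
spike flags its own week (jump out) and the next week (jump back), forming a
run of two, so the default rule catches it — at the price of also discarding
the (valid) return-week observation. A sustained level shift flags only the
transition week and survives. Because `ln T − ln(T−1)` shrinks like `1/T`, a
spike of a given relative size is invisible in the earliest weeks and
increasingly conspicuous later; equal-magnitude spikes on two adjacent weeks
cancel in the middle and evade the filter. These are properties of the rule,
not of this implementation.

## Weekly Welch tests

For each contrast and week with at least 2 non-excluded animals per side:
Welch's two-sample t statistic, Welch–Satterthwaite degrees of freedom, and
a two-sided p-value. Weeks with insufficient data produce no record and the
downstream minP family shrinks accordingly. `percent_diff` is
`(mean_a - mean_b) / mean_b`. Degenerate cells (zero variance on both
sides) return `p = 1` when the means are equal; with unequal means the
scalar API raises and the vectorized path returns `p = 0` (unreachable with
continuous data). Tests are two-sided throughout.

The moment-based kernel (`welch_from_moments`) is shared between observed
data and bootstrap resamples, so the bootstrap null reflects exactly the
statistic being tested, including its small-sample df behavior.

## Covariance estimation

Each animal's weekly masses are centered by its arm's per-week mean — this
removes treatment and genotype means, as the mean-zero null requires — and
the residual week-vectors of all animals are pooled into one sample
covariance, pairwise-complete over missing cells. Weeks with fewer than two
observations are dropped from the family with a warning. The matrix is
symmetrized and, if indefinite (possible under pairwise completion),
eigenvalue-clipped at zero to the nearest positive-semidefinite matrix.

Arm means are estimated, so the estimator is deflated by roughly
`(n - k)/(n - 1)` (~5% at 96 animals, 6 arms). This is deliberate and
harmless downstream: Welch statistics are scale-invariant, so the minP null
depends on the correlation structure only.

**Shrinkage.** By default the correlation matrix is shrunk toward identity
with the Schäfer–Strimmer analytic intensity (the ratio of the summed
sampling variances of the off-diagonal correlations to their summed
squares, computed pairwise-complete and clipped to [0, 1]). The motivation
is empirical and specific to this procedure: a raw 35 × 35 sample
covariance estimated from ~90 residual degrees of freedom carries enough
noise in its smallest-eigenvalue directions that the plug-in minP
adjustment becomes mildly anticonservative — in null simulations at the
default design the family-wise error ran near 0.07 at nominal 0.05, while
supplying the generator's true covariance gave 0.048 and tripling the
animals restored 0.04. With the analytic shrinkage (λ ≈ 0.02–0.03 at study
scale) the simulated FWER is 0.050–0.055 across serial correlations 0, 0.3
and 0.9 (600 null replicates each). The intensity vanishes as animals
accumulate, so the shrunk and raw estimators agree asymptotically;
`shrinkage="none"` selects the raw pooled covariance.

## minP parametric bootstrap

For `b = 1..B`: draw one week-vector per animal from `N(0, Sigma_hat)`
(eigen-factor draw, so singular covariances such as rank-one are handled),
assign vectors to arms at the original arm sizes, recompute every
(contrast, week) Welch p through the shared kernel, and record the family
minimum `m_b`. Then for contrast `h`:

    p_adj(h)   = (1 + #{b : m_b <= P_min,h}) / (B + 1)
    p_adj(h,t) = (1 + #{b : m_b <= p_raw,h,t}) / (B + 1)

Design choices:

- **Family definition.** The default family is the joint grid of all
  contrasts × weeks — the simultaneous-testing reading. A `per-contrast`
  mode (each contrast's own weeks as its family) is provided because
  per-hypothesis reporting is also a defensible reading.
- **Single-step, not step-down.** One reference distribution for all cells;
  a step-down variant would be more powerful but reports a different object
  than "the adjusted p-value of the hypothesis".
- **Add-one counting** guarantees valid p-values and gives the floor
  `1/(B+1)` (0.0001 at `B = 10,000`, the default).
- **Complete resamples.** Bootstrap animals have complete week-vectors at
  the original arm sizes; missingness in the observed data is not
  re-simulated. At the ~1% missingness the generator produces, the
  difference is negligible; with heavily missing data the bootstrap n would
  overstate the observed n.
- **Randomness.** One root seed; resamples are drawn in fixed-size blocks
  (256) from a single generator, so results are bit-reproducible for a
  given seed and B.

Calibration was verified against closed forms (single cell: adjusted ≈ raw;
independent cells: Šidák; rank-one covariance: effective family size 1 —
see the test suite) and by Monte-Carlo: with the generator's true covariance
supplied, 10,000 self-consistent replicates reject at 0.043 and 1,500
cohort-based replicates at 0.048, at nominal 0.05.

## Pipeline sequence

QC → genotype gate → pooling → simultaneous treatment contrasts. The gate is
itself a minP family (one contrast, genotype A vs genotype B across all
weeks, both run through the same machinery) rather than an informal look at
means, so the "no genotype effect, therefore pool" step is explicit and
testable. If the gate rejects, pooling is skipped and the treatment
contrasts run within each genotype, with a warning — a path the pooled
design never needs but a reusable tool must have.

Defaults reproduce the study settings: LNP threshold 130, run length 2,
`B = 10,000`, gate alpha 0.05, joint family.

## Endpoint ANOVA

Two-factor fixed-effects linear model, Type-II sums of squares (equal to
Type-I on balanced designs; the sensible default for mildly unbalanced
ones), F against residual mean square; Tukey HSD on the studentized range
distribution for pairwise comparisons. Shapiro-Wilk (residual normality)
and Levene (homoscedasticity) screens are reported as diagnostics only and
never switch the test. Terms whose sum of squares is numerically zero
(below `1e-10` of total SS, e.g. all values identical) report `F = 0, p = 1`
rather than `0/0`. An empty design cell with the interaction requested is an
error that points to main-effects-only mode.

## Synthetic cohorts

The generator emulates the design the analysis assumes:

| parameter | default | rationale |
| --- | --- | --- |
| arms | 2 genotypes × {active ASO, control ASO, saline}, 16 animals each | six-arm design; ~96 animals matches the behavioral-cohort scale |
| mean curve | exponential approach, 22 g → 32 g asymptote, rate 0.08/week | adult mouse growth: fast early gain flattening by study end; any smooth monotone curve suffices since testing is week-wise |
| weeks | 35 | study duration |
| effect | 5% multiplicative reduction, full at week 30, 10-week linear ramp | treated animals end ~5% lighter after 30 weeks of dosing; a gradual onset is physiologically more plausible than a step |
| random intercept | SD 1.5 g | between-animal spread of adult weight |
| serial residual | AR(1), rho 0.9, stationary SD 0.7 g | slowly wandering physiological weight |
| measurement noise | SD 0.2 g | scale/handling error |
| spikes | 0.2% of observations, ±30%, single-week | transcription-error-like outliers; each detected spike costs ~2 excluded observations, keeping the exclusion level below 1% of observations |
| missingness | 1%, completely at random | exercises missing-data paths |

The genotype never alters the mean curve (no genotype effect on weight is
part of the emulated design), and the effect applies only to arms flagged
as treated.

Noise levels were calibrated jointly against the LNP filter: week-to-week
fluctuation (SD ≈ 0.4 g, ~1.4% of adult mass) is set so that natural
variation stays below the filter's late-week sensitivity and only injected
spikes reach exclusion level, keeping exclusions "rare" (< 1% of
observations) as the emulated design specifies. Raising the serial or noise
SDs materially above these values makes the late-study LNP flag ordinary
fluctuations — a genuine property of the time-normalized statistic that
users with noisier scales should keep in mind when choosing a threshold.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: non-normal weight distributions,
informative missingness (e.g. removal of sick animals), cage effects or
other clustering beyond the animal, dose interruptions, seasonal or
batch-structured drift, and heteroscedasticity across arms. The minP
procedure's validity under those violations is untested here.

## Numerical conventions

- Eigen-factor sampling (eigenvalues clipped at zero) instead of Cholesky,
  so semidefinite covariances are valid inputs.
- Strict inequalities: flagging (`lnp > threshold`) and bootstrap counting
  (`m_b <= p_obs`) follow the definitions; ties in float comparisons are
  effectively measure-zero.
- The LNP filter, Welch tests and ANOVA are deterministic; everything
  stochastic (generator, bootstrap, simulations) is reproducible from a
  single integer seed, with per-replicate streams spawned via
  `numpy.random.SeedSequence`.
- Problem sizes in the shipped simulations: FWER estimates use 500 (tests)
  or 300 (acceptance script) replicate cohorts at `B = 1,000`; effect
  recovery uses 400 animals per arm so the designed 5% dominates sampling
  noise; power at study scale is reported descriptively from 100
  replicates.

## Known limitations

- The plug-in bootstrap treats the estimated covariance as known; the
  default shrinkage compensates for the resulting anticonservatism at the
  shipped design, but the correction was validated by simulation at that
  design, not proved in general.
- Per-week adjusted p-values use the single-step reference, so they are
  conservative for all but the best week.
- The exclusion rule inherits the LNP statistic's blind spots (early-week
  spikes, adjacent equal spikes, final-week spikes) — see above.
- `weekly_tests` assumes one record per (animal, week); pre-aggregated or
  replicated weighings must be reduced upstream.
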