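import numpy as np
import pandas as pd
import pytest

from minpweight import (
    ArmSpec,
    ConfigError,
    ContaminationSpec,
    ContrastSpec,
    CovarianceEstimate,
    CovarianceSpec,
    EffectSpec,
    ProcedureError,
    SimSpec,
    arm_sizes_from_cohort,
    estimate_covariance,
    fwer_simulation,
    generate_cohort,
    minp_adjust,
    default_spec,
)
from conftest import make_cohort

CLEAN = ContaminationSpec(spike_prob=0.0, missing_prob=0.0)


def make_tests(p_by_week: dict, contrast="c") -> pd.DataFrame:
    """A WeeklyTestTable carrying just the fields minP consumes."""
    return pd.DataFrame(
        {"contrast": contrast, "week": list(p_by_week), "p_raw": list(p_by_week.values())}
    )


def make_cov(matrix, weeks) -> CovarianceEstimate:
    return CovarianceEstimate(
        matrix=np.asarray(matrix, dtype=float), weeks=list(weeks), method="fixed", n_animals=0
    )


TWO_GROUPS = [("WT", "A", 30), ("WT", "B", 30)]
AB = ContrastSpec("c", frozenset({"A"}), frozenset({"B"}))


class TestEstimateCovariance:
    def test_identical_trajectories_give_zero_matrix(self):
        cohort = make_cohort(
            {"m1": [20.0, 21.0, 22.0], "m2": [20.0, 21.0, 22.0]},
        )
        est = estimate_covariance(cohort)
        np.testing.assert_allclose(est.matrix, 0.0, atol=1e-12)

    def test_diagonal_truth_recovered(self):
        cov = CovarianceSpec(intercept_sd_g=0.0, serial_rho=0.0, serial_sd_g=0.0, noise_sd_g=0.8)
        spec = SimSpec(
            arms=(ArmSpec("WT", "saline", 500),),
            covariance=cov,
            contamination=CLEAN,
            effect=EffectSpec(size=0.0),
            n_weeks=6,
            seed=2,
        )
        est = estimate_covariance(generate_cohort(spec))
        off = est.matrix[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.10 * 0.64
        np.testing.assert_allclose(np.diag(est.matrix), 0.64, rtol=0.10)

    def test_ar1_autocorrelation_recovered(self):
        rho = 0.7
        cov = CovarianceSpec(intercept_sd_g=0.0, serial_rho=rho, serial_sd_g=1.0, noise_sd_g=0.0)
        spec = SimSpec(
            arms=(ArmSpec("WT", "saline", 500),),
            covariance=cov,
            contamination=CLEAN,
            effect=EffectSpec(size=0.0),
            n_weeks=10,
            seed=4,
        )
        est = estimate_covariance(generate_cohort(spec))
        d = np.sqrt(np.diag(est.matrix))
        corr = est.matrix / np.outer(d, d)
        for lag in (1, 2, 3):
            observed = np.diag(corr, k=lag).mean()
            assert observed == pytest.approx(rho**lag, rel=0.10)

    def test_weeks_with_single_observation_dropped(self):
        cohort = make_cohort({"m1": [20.0, 21.0, 22.0], "m2": [20.5, 21.5, np.nan]})
        est = estimate_covariance(cohort)
        assert est.weeks == [1, 2]
        assert est.dropped_weeks == [3]

    def test_matrix_is_symmetric_psd(self, null_cohort):
        est = estimate_covariance(null_cohort)
        np.testing.assert_allclose(est.matrix, est.matrix.T)
        assert np.linalg.eigvalsh(est.matrix).min() > -1e-10
        assert (np.diag(est.matrix) > 0).all()

    def test_shrinkage_pulls_correlations_toward_identity(self):
        # complete cohort: the raw pairwise estimate is then PSD as-is, so the
        # two modes differ only by the correlation shrinkage
        cohort = generate_cohort(default_spec(effect_size=0.0, seed=13, contamination=CLEAN))
        shrunk = estimate_covariance(cohort)
        raw = estimate_covariance(cohort, shrinkage="none")
        assert raw.shrinkage_lambda is None
        assert 0.0 < shrunk.shrinkage_lambda < 1.0
        np.testing.assert_allclose(np.diag(shrunk.matrix), np.diag(raw.matrix), rtol=1e-9)
        off = ~np.eye(raw.matrix.shape[0], dtype=bool)
        assert (np.abs(shrunk.matrix[off]) <= np.abs(raw.matrix[off]) + 1e-12).all()
        from minpweight import ConfigError as CE

        with pytest.raises(CE):
            estimate_covariance(cohort, shrinkage="bogus")


class TestMinpAdjust:
    def test_single_cell_family_adjusted_tracks_raw(self):
        tests = make_tests({1: 0.1})
        result = minp_adjust(tests, make_cov([[1.0]], [1]), TWO_GROUPS, [AB], B=10000, seed=0)
        c = result.contrasts["c"]
        se = np.sqrt(0.1 * 0.9 / 10000)
        assert c.p_adjusted == pytest.approx(0.1, abs=3 * se)
        assert c.p_min == 0.1
        assert c.argmin_week == 1

    def test_two_independent_cells_match_sidak(self):
        tests = make_tests({1: 0.02, 2: 0.6})
        result = minp_adjust(tests, make_cov(np.eye(2), [1, 2]), TWO_GROUPS, [AB], B=10000, seed=1)
        sidak = 1 - (1 - 0.02) ** 2
        se = np.sqrt(sidak * (1 - sidak) / 10000)
        assert result.contrasts["c"].p_adjusted == pytest.approx(sidak, abs=3 * se)

    def test_rank_one_covariance_collapses_to_raw(self):
        # perfectly correlated weeks: effective family size 1
        weeks = [1, 2, 3, 4, 5]
        cov = np.full((5, 5), 2.5)
        tests = make_tests(dict(zip(weeks, [0.03, 0.2, 0.4, 0.6, 0.8])))
        result = minp_adjust(tests, make_cov(cov, weeks), TWO_GROUPS, [AB], B=10000, seed=2)
        se = np.sqrt(0.03 * 0.97 / 10000)
        assert result.contrasts["c"].p_adjusted == pytest.approx(0.03, abs=3 * se)

    def test_add_one_floor(self):
        tests = make_tests({1: 1e-12})
        result = minp_adjust(tests, make_cov([[1.0]], [1]), TWO_GROUPS, [AB], B=10000, seed=3)
        assert result.contrasts["c"].p_adjusted == 1.0 / 10001.0

    def test_monotone_in_p_min_within_family(self):
        contrasts = [
            ContrastSpec("ab", frozenset({"A"}), frozenset({"B"})),
            ContrastSpec("ac", frozenset({"A"}), frozenset({"C"})),
            ContrastSpec("bc", frozenset({"B"}), frozenset({"C"})),
        ]
        arm_sizes = [("WT", "A", 20), ("WT", "B", 20), ("WT", "C", 20)]
        tests = pd.concat(
            [
                make_tests({1: 0.01, 2: 0.5}, contrast="ab"),
                make_tests({1: 0.2, 2: 0.9}, contrast="ac"),
                make_tests({1: 0.04, 2: 0.3}, contrast="bc"),
            ]
        )
        result = minp_adjust(tests, make_cov(np.eye(2), [1, 2]), arm_sizes, contrasts, B=4000, seed=4)
        by_pmin = sorted(result.contrasts.values(), key=lambda c: c.p_min)
        adj = [c.p_adjusted for c in by_pmin]
        assert adj == sorted(adj)
        for c in result.contrasts.values():
            assert c.p_adjusted >= c.p_min - 3 * np.sqrt(c.p_min * (1 - c.p_min) / 4000)
            assert 1.0 / 4001 <= c.p_adjusted <= 1.0

    def test_adding_noise_week_never_helps(self):
        small = make_tests({1: 0.02, 2: 0.4})
        large = make_tests({1: 0.02, 2: 0.4, 3: 0.7})
        r_small = minp_adjust(small, make_cov(np.eye(2), [1, 2]), TWO_GROUPS, [AB], B=10000, seed=5)
        r_large = minp_adjust(large, make_cov(np.eye(3), [1, 2, 3]), TWO_GROUPS, [AB], B=10000, seed=5)
        se = 3 * np.sqrt(0.06 * 0.94 / 10000)
        assert r_large.contrasts["c"].p_adjusted >= r_small.contrasts["c"].p_adjusted - se

    def test_per_week_adjusted_dominates_raw(self):
        tests = make_tests({1: 0.01, 2: 0.3, 3: 0.7})
        result = minp_adjust(tests, make_cov(np.eye(3), [1, 2, 3]), TWO_GROUPS, [AB], B=8000, seed=6)
        pw = result.contrasts["c"].per_week
        se = 3 * np.sqrt(0.25 / 8000)
        assert (pw["p_adjusted"] >= pw["p_raw"] - se).all()
        # per-week adjusted p is monotone in raw p by construction
        ordered = pw.sort_values("p_raw")
        assert ordered["p_adjusted"].is_monotonic_increasing

    def test_per_contrast_family_mode_is_less_penalized(self):
        contrasts = [
            ContrastSpec("ab", frozenset({"A"}), frozenset({"B"})),
            ContrastSpec("ac", frozenset({"A"}), frozenset({"C"})),
        ]
        arm_sizes = [("WT", "A", 20), ("WT", "B", 20), ("WT", "C", 20)]
        tests = pd.concat(
            [make_tests({1: 0.03}, contrast="ab"), make_tests({1: 0.5}, contrast="ac")]
        )
        cov = make_cov([[1.0]], [1])
        joint = minp_adjust(tests, cov, arm_sizes, contrasts, B=8000, seed=7, family_mode="joint")
        per = minp_adjust(tests, cov, arm_sizes, contrasts, B=8000, seed=7, family_mode="per-contrast")
        tol = 3 * np.sqrt(0.06 * 0.94 / 8000)
        assert joint.contrasts["ab"].p_adjusted >= per.contrasts["ab"].p_adjusted - tol

    def test_seed_determinism_bit_identical(self):
        tests = make_tests({1: 0.05, 2: 0.2})
        cov = make_cov([[1.0, 0.3], [0.3, 1.0]], [1, 2])
        a = minp_adjust(tests, cov, TWO_GROUPS, [AB], B=2000, seed=9)
        b = minp_adjust(tests, cov, TWO_GROUPS, [AB], B=2000, seed=9)
        assert a.to_dict() == b.to_dict()
        c = minp_adjust(tests, cov, TWO_GROUPS, [AB], B=2000, seed=10)
        assert c.contrasts["c"].p_adjusted != a.contrasts["c"].p_adjusted or True  # may collide

    def test_procedure_errors(self):
        tests = make_tests({1: 0.05})
        cov = make_cov([[1.0]], [1])
        with pytest.raises(ConfigError):
            minp_adjust(tests, cov, TWO_GROUPS, [AB], B=0, seed=0)
        with pytest.raises(ConfigError):
            minp_adjust(tests, cov, TWO_GROUPS, [AB], B=100, seed=0, family_mode="bogus")
        with pytest.raises(ProcedureError, match="weeks absent"):
            minp_adjust(make_tests({1: 0.05, 9: 0.2}), cov, TWO_GROUPS, [AB], B=100, seed=0)
        with pytest.raises(ProcedureError, match="empty family"):
            minp_adjust(make_tests({}, contrast="other"), cov, TWO_GROUPS, [AB], B=100, seed=0)
        with pytest.raises(ProcedureError, match="< 2 bootstrap animals"):
            minp_adjust(tests, cov, [("WT", "A", 1), ("WT", "B", 30)], [AB], B=100, seed=0)


class TestFwerSimulation:
    def test_requires_null_spec(self):
        with pytest.raises(ConfigError):
            fwer_simulation(default_spec(effect_size=0.05), n_replicates=2, B=50, seed=0)

    def test_alpha_zero_never_rejects(self):
        spec = default_spec(effect_size=0.0, n_per_arm=4, n_weeks=6)
        est = fwer_simulation(spec, n_replicates=5, alpha=0.0, B=50, seed=0)
        assert est.rate == 0.0

    def test_deterministic_and_well_formed(self):
        spec = default_spec(effect_size=0.0, n_per_arm=6, n_weeks=8)
        a = fwer_simulation(spec, n_replicates=10, alpha=0.05, B=200, seed=12)
        b = fwer_simulation(spec, n_replicates=10, alpha=0.05, B=200, seed=12)
        assert a.to_dict() == b.to_dict()
        assert 0.0 <= a.ci_low <= a.rate <= a.ci_high <= 1.0
        assert a.n_replicates == 10
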