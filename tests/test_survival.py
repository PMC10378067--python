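import numpy as np
import pandas as pd
import pytest

from thermoparam.simulate import GeneratorConfig, generate_cohort
from thermoparam.survival import (
    CoxResult,
    cox_backward_bic,
    cox_screen,
    cox_univariate,
    km_median_split,
    pfs_analysis,
    rmst_compare,
    rmst_greenwood,
)


def _exp_cohort(rng, n=200, beta=0.0, censor_at=None):
    z = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.15 * np.exp(beta * z)))
    e = np.ones(n, bool)
    if censor_at is not None:
        e = t <= censor_at
        t = np.minimum(t, censor_at)
    return z, t, e


class TestCoxUnivariate:
    def test_hazard_ratio_is_exp_of_coefficient(self):
        rng = np.random.default_rng(0)
        z, t, e = _exp_cohort(rng, beta=0.5)
        res = cox_univariate(z, t, e, "z")
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient), rel=1e-12)
        assert res.ci[0] < res.hazard_ratio < res.ci[1]

    def test_published_coefficient_formats_to_printed_row(self):
        # SE back-derived from the printed interval bounds
        se = (0.553 - np.log(1.17)) / 1.959963984540054
        res = CoxResult(
            parameter="PC3", coefficient=0.553, se=se,
            hazard_ratio=float(np.exp(0.553)),
            ci=(float(np.exp(0.553 - 1.959963984540054 * se)),
                float(np.exp(0.553 + 1.959963984540054 * se))),
            p=0.007, n=74, n_events=48,
        )
        assert res.format_hazard_ratio() == "1.74 (1.17–2.58)"

    def test_null_coverage(self):
        rng = np.random.default_rng(1)
        covered = 0
        reps = 40
        for _ in range(reps):
            z, t, e = _exp_cohort(rng, n=120, beta=0.0, censor_at=15.0)
            res = cox_univariate(z, t, e, "z")
            covered += res.ci[0] <= 1.0 <= res.ci[1]
        assert covered >= 0.85 * reps

    def test_beta_recovery(self):
        """Exponential cohorts with log-hazard 0.553·z, n=500: the mean
        estimate over replicates stays within 0.05 of the truth."""
        rng = np.random.default_rng(2)
        est = []
        for _ in range(60):
            z, t, e = _exp_cohort(rng, n=500, beta=0.553)
            est.append(cox_univariate(z, t, e, "z").coefficient)
        assert np.mean(est) == pytest.approx(0.553, abs=0.05)

    def test_requires_events_and_positive_times(self):
        with pytest.raises(ValueError):
            cox_univariate([1.0, 2.0], [1.0, 2.0], [False, False])
        with pytest.raises(ValueError):
            cox_univariate([1.0, 2.0], [0.0, 2.0], [True, True])


class TestCoxScreen:
    def test_fdr_attached(self, cohort_table):
        active = cohort_table[cohort_table.status == "active"]
        screen, results = cox_screen(active, ["PC3", "Area", "Max"])
        assert np.all(screen.p_adjusted >= screen.p - 1e-15)
        for r in results:
            assert r.hazard_ratio == pytest.approx(np.exp(r.coefficient), rel=1e-12)


class TestBackwardBIC:
    def test_generator_oracle_retains_latent_factor(self):
        """Only the latent prognostic factor drives hazard; sex and a noise
        covariate are eliminated."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 20
        for _ in range(reps):
            z, t, e = _exp_cohort(rng, n=150, beta=0.7, censor_at=20.0)
            df = pd.DataFrame({
                "z": z, "sex_male": rng.integers(0, 2, 150).astype(float),
                "noise": rng.normal(size=150),
                "os_time": t, "os_event": e,
            })
            kept = cox_backward_bic(df, ["z", "sex_male", "noise"])
            hits += [r.parameter for r in kept] == ["z"]
        assert hits >= 0.85 * reps

    def test_all_noise_prefers_empty_model(self):
        rng = np.random.default_rng(4)
        empties = 0
        reps = 20
        for _ in range(reps):
            _, t, e = _exp_cohort(rng, n=120)
            df = pd.DataFrame({
                "a": rng.normal(size=120), "b": rng.normal(size=120),
                "os_time": t, "os_event": e,
            })
            empties += cox_backward_bic(df, ["a", "b"]) == []
        assert empties > reps / 2

    def test_single_strong_candidate_retained(self):
        rng = np.random.default_rng(5)
        z, t, e = _exp_cohort(rng, n=300, beta=0.8)
        df = pd.DataFrame({"z": z, "os_time": t, "os_event": e})
        kept = cox_backward_bic(df, ["z"])
        assert [r.parameter for r in kept] == ["z"]


class TestKMSplit:
    def test_identical_arms_give_null_logrank(self):
        t = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        e = np.ones(10, bool)
        x = np.r_[np.zeros(5), np.ones(5)]  # arms have identical outcomes
        res = km_median_split(x, t, e)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-6)

    def test_detects_rate_ratio_two(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 20
        for _ in range(reps):
            x = np.r_[np.zeros(100), np.ones(100)]
            t = np.r_[rng.exponential(5.0, 100), rng.exponential(2.5, 100)]
            res = km_median_split(x, t, np.ones(200, bool))
            hits += res.logrank_p < 0.05
        assert hits >= 0.9 * reps

    def test_exact_median_goes_to_lower_arm(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        t = np.arange(1.0, 6.0)
        e = np.ones(5, bool)
        res = km_median_split(x, t, e)
        # median is 2.0; both 2.0 values belong to the at-or-below arm
        assert res.n == {"above": 2, "at-or-below": 3}

    def test_constant_values_cannot_split(self):
        with pytest.raises(ValueError):
            km_median_split(np.ones(10), np.arange(1.0, 11.0), np.ones(10, bool))

    def test_curves_non_increasing(self, cohort_table):
        active = cohort_table[cohort_table.status == "active"]
        res = km_median_split(active["PC3"], active["os_time"], active["os_event"])
        for kmf in res.fitters.values():
            sf = kmf.survival_function_.iloc[:, 0].to_numpy()
            assert np.all(np.diff(sf) <= 1e-12)


class TestRMST:
    def test_all_survival_past_tau_gives_tau(self):
        t = np.full(20, 12.0)
        e = np.ones(20, bool)
        mu, var = rmst_greenwood(t, e, 8.0)
        assert mu == 8.0 and var == 0.0

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5.0, 4000)
        mu, _ = rmst_greenwood(t, np.ones(4000, bool), 8.0)
        assert mu == pytest.approx((1 - np.exp(-1.6)) / 0.2, abs=0.1)

    def test_matches_r_survival_package(self):
        """Frozen oracle: survfit(Surv(t,e)~1) with rmean=8 gives
        rmean 5.2902380952, se(rmean) 0.8085919347."""
        t = np.array([0.5, 1.2, 2.0, 2.0, 3.1, 4.0, 4.5, 5.5, 6.0, 7.5, 8.5, 9.0])
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 0], bool)
        mu, var = rmst_greenwood(t, e, 8.0)
        assert mu == pytest.approx(5.2902380952, abs=1e-9)
        assert np.sqrt(var) == pytest.approx(0.8085919347, abs=1e-9)

    def test_rectangle_sum_oracle(self):
        """RMST equals an independent rectangle sum over the KM curve."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        t = rng.exponential(4.0, 80)
        e = rng.uniform(size=80) < 0.7
        if not e.any():
            e[0] = True
        mu, _ = rmst_greenwood(t, e, 6.0)
        kmf = KaplanMeierFitter().fit(t, e)
        times = kmf.survival_function_.index.to_numpy()
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        area = 0.0
        prev_t, prev_s = 0.0, 1.0
        for ti, si in zip(times, surv):
            if ti > 6.0:
                break
            area += prev_s * (min(ti, 6.0) - prev_t)
            prev_t, prev_s = ti, si
        area += prev_s * (6.0 - prev_t)
        assert mu == pytest.approx(area, abs=1e-10)

    def test_identical_groups_difference_zero(self):
        t = np.tile([1.0, 2.5, 4.0, 6.0, 9.0], 4)
        e = np.ones(20, bool)
        g = np.r_[np.zeros(10), np.ones(10)]
        res = rmst_compare(g, t, e, tau=8.0, level_order=(0.0, 1.0))
        assert res.difference == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_tau_clipped_with_warning(self):
        t = np.r_[np.linspace(0.5, 4.0, 10), np.linspace(0.5, 12.0, 10)]
        e = np.ones(20, bool)
        g = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(UserWarning, match="clipped"):
            rmst_compare(g, t, e, tau=8.0, level_order=(0.0, 1.0))

    def test_restricted_means_within_bounds(self, cohort_table):
        active = cohort_table[cohort_table.status == "active"]
        med = float(active["PC3"].median())
        arm = np.where(active["PC3"] > med, "above", "at-or-below")
        res = rmst_compare(arm, active["os_time"], active["os_event"],
                           tau=8.0, level_order=("above", "at-or-below"))
        for mu in res.rmst.values():
            assert 0.0 < mu <= 8.0


class TestPFS:
    def test_null_ned_pfs_rarely_significant(self):
        """The NED recurrence process carries no parameter effects; adjusted
        p-values below 0.1 should be rare."""
        hits = 0
        reps = 10
        for i in range(reps):
            cohort = generate_cohort(seed=300 + i)
            from thermoparam import pipeline

            table = pipeline.build_cohort_table(cohort.curves, cohort.clinical, n_pcs=4)
            screen, _ = pfs_analysis(table, ["Area", "TPeak2", "PC1", "PC2", "PC3"])
            hits += (screen.p_adjusted < 0.1).any()
        assert hits <= reps / 2

    def test_low_event_regime_fits_with_wide_intervals(self, cohort_table):
        ned = cohort_table[cohort_table.status == "NED"].dropna(subset=["pfs_time"])
        assert len(ned) == 32
        screen, results = pfs_analysis(cohort_table, ["PC3"])
        assert results[0].n_events >= 1
        assert results[0].ci[1] / results[0].ci[0] > 1.5  # low events → wide CI

    def test_zero_events_is_clean_error(self):
        df = pd.DataFrame({
            "status": ["NED"] * 5,
            "pfs_time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "pfs_event": [False] * 5,
            "PC3": np.arange(5.0),
        })
        with pytest.raises(ValueError, match="event"):
            pfs_analysis(df, ["PC3"])
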