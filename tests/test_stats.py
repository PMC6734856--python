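import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cathsim import (
    PowerSpec,
    compare_groups,
    fit_learning_curve,
    group_summary,
    power_rm_anova,
    rm_anova,
)
from cathsim.errors import MissingGroupError, UnbalancedDesignError
from cathsim.stats import (
    greenhouse_geisser_epsilon,
    long_table_from_results,
    rm_anova_cells,
)
from oracles import definitional_rm_anova


def make_long(data: np.ndarray, groups=None) -> pd.DataFrame:
    """(g, n, m) array -> long table."""
    g, n, m = data.shape
    groups = groups or [f"g{i}" for i in range(g)]
    rows = []
    for i in range(g):
        for j in range(n):
            for k in range(m):
                rows.append(
                    {"subject": f"{groups[i]}-s{j}", "group": groups[i],
                     "repetition": k + 1, "value": data[i, j, k]}
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_table():
    # 2 subjects x 2 repetitions per group
    data = np.array([[[3.0, 5.0], [4.0, 6.0]], [[1.0, 2.0], [2.0, 3.0]]])
    return make_long(data, groups=["beginner", "expert"]), data


class TestGroupSummary:
    def test_constant_table(self):
        table = make_long(np.full((2, 3, 4), 2.0))
        s = group_summary(table)
        assert list(s["mean"]) == [2.0, 2.0]
        assert list(s["sd"]) == [0.0, 0.0]

    def test_toy_table_hand_arithmetic(self, toy_table):
        table, _ = toy_table
        s = group_summary(table).set_index("group")
        assert s.loc["beginner", "mean"] == pytest.approx(4.5)
        assert s.loc["expert", "mean"] == pytest.approx(2.0)

    def test_streaming_recount_oracle(self, rng):
        data = rng.normal(5, 2, (2, 6, 8))
        table = make_long(data)
        s = group_summary(table).set_index("group")
        for i, g in enumerate(["g0", "g1"]):
            total, count = 0.0, 0
            for v in data[i].ravel():
                total += v
                count += 1
            assert s.loc[g, "mean"] == pytest.approx(total / count)

    def test_missing_group_error(self):
        table = make_long(np.zeros((1, 2, 2)))
        with pytest.raises((MissingGroupError, UnbalancedDesignError)):
            rm_anova(table)


class TestRmAnova:
    def test_additive_table_zero_interaction(self):
        g_eff = np.array([1.0, 4.0])
        r_eff = np.array([0.5, 1.5, 3.0])
        data = g_eff[:, None, None] + r_eff[None, None, :] + np.zeros((2, 4, 3))
        res = rm_anova_cells(data + 0.0)
        assert res.effects["group:repetition"].ss == pytest.approx(0.0, abs=1e-10)

    def test_toy_table_matches_definitional_oracle(self, toy_table):
        table, data = toy_table
        res = rm_anova(table)
        oracle = definitional_rm_anova(data)
        for name in ("group", "repetition", "group:repetition"):
            assert res.effects[name].ss == pytest.approx(oracle["ss"][name], rel=1e-10)
            assert res.effects[name].df == oracle["df"][name]
            assert res.effects[name].F == pytest.approx(oracle["F"][name], rel=1e-10)
        assert res.errors["subjects_within_groups"].ss == pytest.approx(
            oracle["ss"]["subjects_within_groups"], rel=1e-10
        )
        assert res.errors["within_error"].ss == pytest.approx(
            oracle["ss"]["within_error"], rel=1e-10, abs=1e-10
        )

    @pytest.mark.parametrize("shape", [(2, 3, 2), (2, 5, 4), (3, 4, 6)])
    def test_random_tables_match_definitional_oracle(self, shape, rng):
        data = rng.normal(10, 3, shape)
        res = rm_anova_cells(data)
        oracle = definitional_rm_anova(data)
        for name in ("group", "repetition", "group:repetition"):
            assert res.effects[name].ss == pytest.approx(oracle["ss"][name], rel=1e-8)
            assert res.effects[name].F == pytest.approx(oracle["F"][name], rel=1e-8)

    def test_ss_additivity_and_df_bookkeeping(self, rng):
        for _ in range(25):
            g = rng.integers(2, 4)
            n = rng.integers(2, 6)
            m = rng.integers(2, 7)
            data = rng.normal(0, rng.uniform(0.5, 4), (g, n, m))
            res = rm_anova_cells(data)
            parts = (
                res.effects["group"].ss
                + res.errors["subjects_within_groups"].ss
                + res.effects["repetition"].ss
                + res.effects["group:repetition"].ss
                + res.errors["within_error"].ss
            )
            assert parts == pytest.approx(res.ss_total, rel=1e-8)
            dfs = (
                res.effects["group"].df
                + res.errors["subjects_within_groups"].df
                + res.effects["repetition"].df
                + res.effects["group:repetition"].df
                + res.errors["within_error"].df
            )
            assert dfs == g * n * m - 1

    def test_group_f_reduces_to_oneway_on_subject_means(self, rng):
        for m in (2, 5):
            data = rng.normal(3, 1, (2, 6, m))
            res = rm_anova_cells(data)
            means = data.mean(axis=2)
            f, _ = sps.f_oneway(means[0], means[1])
            assert res.effects["group"].F == pytest.approx(f, rel=1e-9)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(8, 2, (2, 6, 4))
        table = make_long(data)
        res = rm_anova(table)
        aov = pg.mixed_anova(
            data=table, dv="value", within="repetition",
            between="group", subject="subject", correction=False,
        ).set_index("Source")
        assert res.effects["group"].F == pytest.approx(aov.loc["group", "F"], rel=1e-6)
        assert res.effects["repetition"].F == pytest.approx(
            aov.loc["repetition", "F"], rel=1e-6
        )
        assert res.effects["group:repetition"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-6
        )
        assert res.effects["group"].p == pytest.approx(
            aov.loc["group", "p_unc"], rel=1e-6
        )

    def test_invariance_under_relabeling_and_shift(self, rng):
        data = rng.normal(0, 1, (2, 5, 4))
        res = rm_anova_cells(data)
        shifted = rm_anova_cells(data + 117.3)
        perm = data[:, rng.permutation(5), :]
        permuted = rm_anova_cells(perm)
        for name in ("group", "repetition", "group:repetition"):
            assert shifted.effects[name].F == pytest.approx(res.effects[name].F, rel=1e-8, abs=1e-10)
            assert permuted.effects[name].F == pytest.approx(res.effects[name].F, rel=1e-8)

    def test_gg_epsilon_bounds_and_compound_symmetry(self, rng):
        m = 5
        data = rng.normal(0, 1, (2, 40, m))
        eps = greenhouse_geisser_epsilon(data)
        assert 1.0 / (m - 1) <= eps <= 1.0
        # compound-symmetric data: epsilon near 1
        subj = rng.normal(0, 1, (2, 200, 1))
        cs = subj + rng.normal(0, 1, (2, 200, m))
        assert greenhouse_geisser_epsilon(cs) > 0.9

    def test_gg_correction_inflates_p(self, rng):
        subj = rng.normal(0, 1, (2, 8, 1))
        trend = np.linspace(0, 1.0, 6)
        data = subj + trend[None, None, :] + rng.normal(0, 0.7, (2, 8, 6))
        p_raw = rm_anova_cells(data).effects["repetition"].p
        p_gg = rm_anova_cells(data, gg_correction=True).effects["repetition"].p
        assert p_gg >= p_raw

    def test_unbalanced_rejected(self, toy_table):
        table, _ = toy_table
        with pytest.raises(UnbalancedDesignError):
            rm_anova(table.iloc[:-1])


class TestCompareGroups:
    def test_identical_groups_f_zero_p_one(self):
        data = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]])[None], (2, 1, 1))
        table = make_long(data)
        out = compare_groups(table)
        assert out["F"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_toy_table_direction(self, toy_table):
        table, _ = toy_table
        out = compare_groups(table)
        assert out["direction"] == "expert < beginner"
        assert out["means"]["beginner"] > out["means"]["expert"]

    def test_permutation_calibration(self, rng):
        # permuting group labels on a null table: p approximately uniform
        n, m = 6, 3
        values = rng.normal(0, 1, (2 * n, m))
        ps = []
        for _ in range(300):
            perm = rng.permutation(2 * n)
            data = np.stack([values[perm[:n]], values[perm[n:]]])
            ps.append(rm_anova_cells(data).effects["group"].p)
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            data = rng.normal(0, 1, (2, 8, 4))
            if rm_anova_cells(data).effects["group"].p < 0.05:
                rejections += 1
        lo, hi = sps.binom.interval(0.999, n_sim, 0.05)
        assert lo <= rejections <= hi


class TestLearningCurve:
    def test_exact_recovery_noiseless(self):
        k = np.arange(1, 21)
        y = 1.0 + 4.0 * np.exp(-0.3 * (k - 1))
        fit = fit_learning_curve(y)
        assert fit["a"] == pytest.approx(4.0, abs=1e-6)
        assert fit["b"] == pytest.approx(1.0, abs=1e-6)
        assert fit["lam"] == pytest.approx(0.3, abs=1e-6)
        assert fit["rss"] < 1e-12

    def test_constant_series_degenerate(self):
        fit = fit_learning_curve(np.full(10, 3.5))
        assert fit["lam"] == 0.0
        assert fit["a"] == 0.0
        assert fit["b"] == pytest.approx(3.5)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_learning_curve([1.0, 2.0, 3.0])

    def test_recovery_under_noise(self, rng):
        k = np.arange(1, 21)
        errs = []
        for _ in range(120):
            lam = rng.uniform(0.1, 0.6)
            y = 1.0 + 4.0 * np.exp(-lam * (k - 1)) + rng.normal(0, 0.5, 20)
            errs.append(abs(fit_learning_curve(y)["lam"] - lam))
        assert np.median(errs) < 0.1


def simulate_within_effect(rng, f, N, g, m, rho, n_sims):
    """Generate RM tables with a within (repetition) effect of Cohen's f
    under compound symmetry with correlation rho; total variance 1."""
    n = N // g
    k = np.arange(m)
    tau = np.sqrt(2.0) * f * np.cos(2 * np.pi * k / m)
    for _ in range(n_sims):
        subj = rng.normal(0, np.sqrt(rho), (g, n, 1))
        eps = rng.normal(0, np.sqrt(1 - rho), (g, n, m))
        yield tau[None, None, :] + subj + eps


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        for effect in ("between", "within", "interaction"):
            spec = PowerSpec(alpha=0.07, effect_size_f=0.0)
            assert power_rm_anova(spec, effect) == pytest.approx(0.07, abs=1e-12)

    def test_monotone_in_n_and_f(self):
        for effect in ("between", "within"):
            p_n = [
                power_rm_anova(PowerSpec(n_total=N, measurements=5), effect)
                for N in (8, 16, 32, 64)
            ]
            assert all(a < b for a, b in zip(p_n, p_n[1:]))
            p_f = [
                power_rm_anova(
                    PowerSpec(effect_size_f=f, measurements=5), "within"
                )
                for f in (0.1, 0.2, 0.3, 0.5)
            ]
            assert all(a < b for a, b in zip(p_f, p_f[1:]))

    def test_within_power_matches_simulation(self, rng):
        # reduced-size Monte-Carlo oracle (the acceptance suite runs 10k)
        spec = PowerSpec(alpha=0.05, effect_size_f=0.3, n_total=16, groups=2,
                         measurements=5, correlation=0.5)
        analytic = power_rm_anova(spec, "within")
        n_sim = 1500
        rej = sum(
            rm_anova_cells(d).effects["repetition"].p < spec.alpha
            for d in simulate_within_effect(rng, 0.3, 16, 2, 5, 0.5, n_sim)
        )
        lo, hi = sps.binom.interval(0.999, n_sim, analytic)
        assert lo <= rej <= hi

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5).validate()
        with pytest.raises(ValueError):
            PowerSpec(correlation=1.0).validate()
        with pytest.raises(ValueError):
            power_rm_anova(PowerSpec(), "sideways")


class TestEndToEnd:
    def test_default_cohorts_detect_group_and_learning_effects(self, env, config):
        # group effect rejected in a majority of replicates; the beginner
        # repetition effect detected more often than the expert one
        from cathsim.agents import CohortDesign, DEFAULT_PROFILES, simulate_cohort

        group_rej = beg_rej = exp_rej = 0
        R = 8
        for b in range(R):
            df = simulate_cohort(CohortDesign(8, 20, "free", 2000 + b),
                                 DEFAULT_PROFILES["beginner"],
                                 DEFAULT_PROFILES["expert"], config, env)
            table = long_table_from_results(df)
            group_rej += compare_groups(table)["p"] < 0.05
            for grp, counter in (("beginner", "b"), ("expert", "e")):
                sub = table[table.group == grp].copy()
                n = sub.subject.nunique()
                data = (
                    sub.pivot(index="subject", columns="repetition", values="value")
                    .to_numpy()[None]
                )
                halves = np.stack([data[0, : n // 2], data[0, n // 2:]])
                p = rm_anova_cells(halves).effects["repetition"].p
                if grp == "beginner":
                    beg_rej += p < 0.05
                else:
                    exp_rej += p < 0.05
        assert group_rej > R / 2
        assert beg_rej >= exp_rej

    def test_long_table_from_results_maps_metrics(self, env, config):
        from cathsim.agents import CohortDesign, DEFAULT_PROFILES, simulate_cohort

        df = simulate_cohort(CohortDesign(2, 2, "free", 0),
                             DEFAULT_PROFILES["beginner"], DEFAULT_PROFILES["expert"],
                             config, env)
        t1 = long_table_from_results(df, "collisions")
        t2 = long_table_from_results(df, "completion_time")
        assert (t1.value == df.n_collisions.astype(float).values).all()
        assert (t2.value == df.completion_time_s.values).all()
        with pytest.raises(ValueError):
            long_table_from_results(df, "speed")
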