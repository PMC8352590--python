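"""Outlier filtering, ANOVA/t-test validity and summary-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cortifilo.groupstats import (
    GroupedValues,
    RoutConfig,
    build_summary_table,
    experiment_means,
    one_way_anova,
    rout_filter,
    star_code,
    students_t,
)


class TestRout:
    def test_identical_values_flag_nothing(self):
        kept, flags = rout_filter(np.full(50, 3.14))
        assert not flags.any()
        assert kept.size == 50

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            kept, flags = rout_filter(np.arange(5.0))
        assert not flags.any()

    def test_gross_contaminant_caught(self):
        rng = np.random.default_rng(70)
        caught = 0
        for _ in range(50):
            x = np.concatenate([rng.normal(size=100), [50.0]])
            _, flags = rout_filter(x)
            caught += bool(flags[-1])
        assert caught >= 49

    def test_clean_normal_low_false_positive_rate(self):
        rng = np.random.default_rng(71)
        fracs = [rout_filter(rng.normal(size=1000))[1].mean() for _ in range(30)]
        assert np.mean(fracs) <= 0.005

    def test_q_validated(self):
        with pytest.raises(ValueError):
            RoutConfig(q=0.0)


class TestAnova:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(72)
        a, b = rng.normal(size=14), rng.normal(0.5, 1.2, size=9)
        f = one_way_anova({"a": a, "b": b}).statistic
        t = students_t(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_hand_computed_sum_of_squares_fixture(self):
        groups = {
            "g1": np.array([4.1, 5.0, 6.2, 5.5, 4.8]),
            "g2": np.array([5.9, 6.3, 7.1, 6.0, 6.6]),
            "g3": np.array([7.8, 8.1, 7.2, 8.8, 7.9]),
        }
        # textbook sum-of-squares computed from scratch
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 12)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert res.df == (2, 12)
        assert res.p_value == pytest.approx(sps.f.sf(f_oracle, 2, 12), abs=1e-12)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(73)
        groups = [rng.normal(0.0, 1, 8), rng.normal(0.6, 1, 8), rng.normal(0.3, 1, 8)]
        res = one_way_anova(groups, posthoc="none")
        flat = np.concatenate(groups)
        # vectorized permutation F statistics
        n_perm = 10000
        sizes = [8, 8, 8]
        grand = flat.mean()
        sst = ((flat - grand) ** 2).sum()
        fs = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(flat)
            parts = np.split(perm, [8, 16])
            ssb = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
            fs[i] = (ssb / 2) / ((sst - ssb) / 21)
        p_perm = (fs >= res.statistic).mean()
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm + 1e-9)
        assert abs(res.p_value - p_perm) <= max(0.01, mc_err + 0.01)

    def test_tukey_adjusted_not_below_raw(self):
        rng = np.random.default_rng(74)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 12) for i in range(4)}
        res = one_way_anova(groups, posthoc="tukey")
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_dunnett_compares_only_to_control(self):
        rng = np.random.default_rng(75)
        groups = {"ctrl": rng.normal(size=10), "t1": rng.normal(1, 1, 10),
                  "t2": rng.normal(2, 1, 10)}
        res = one_way_anova(groups, posthoc="dunnett", control="ctrl")
        assert len(res.pairwise) == 2
        assert (res.pairwise["group1"] == "ctrl").all()

    def test_all_constant_groups_error(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": np.ones(5), "b": np.full(5, 2.0)})

    def test_star_codes(self):
        assert star_code(0.2) == "ns"
        assert star_code(0.03) == "*"
        assert star_code(0.004) == "**"
        assert star_code(5e-4) == "***"
        assert star_code(5e-6) == "****"


class TestStudentsT:
    def test_identical_groups(self):
        x = np.ones(6)
        res = students_t(x, x.copy())
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_pure_shift_direction_and_significance(self):
        rng = np.random.default_rng(76)
        a = rng.normal(size=20)
        res = students_t(a + 2.0, a)  # same values shifted by +2
        assert res.statistic > 0
        assert res.p_value < 1e-6

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(77)
        a, b = rng.normal(0.5, 1, 10), rng.normal(0.0, 1, 12)
        res = students_t(a, b)
        flat = np.concatenate([a, b])
        n_perm = 10000
        ts = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(flat)
            pa, pb = perm[:10], perm[10:]
            sp = np.sqrt(((pa.var(ddof=1) * 9) + (pb.var(ddof=1) * 11)) / 20)
            ts[i] = (pa.mean() - pb.mean()) / (sp * np.sqrt(1 / 10 + 1 / 12))
        p_perm = (np.abs(ts) >= abs(res.statistic)).mean()
        assert abs(res.p_value - p_perm) <= 0.02


class TestExperimentMeans:
    def test_single_experiment_equals_group_mean(self):
        gv = GroupedValues(np.array([1.0, 2, 3]), np.array(["a"] * 3),
                           np.array(["e0"] * 3))
        df = experiment_means(gv)
        assert len(df) == 1
        assert df["experiment_mean"].iloc[0] == pytest.approx(2.0)
        assert df["pooled_mean"].iloc[0] == pytest.approx(2.0)

    def test_known_per_experiment_means_echoed(self):
        gv = GroupedValues(
            np.array([1.0, 1, 5, 5, 5, 5]),
            np.array(["a"] * 6),
            np.array(["e0", "e0", "e1", "e1", "e1", "e1"]),
        )
        df = experiment_means(gv)
        assert sorted(df["experiment_mean"]) == [1.0, 5.0]
        # unweighted grand mean of experiment means != pooled mean here
        assert df["mean_of_experiment_means"].iloc[0] == pytest.approx(3.0)
        assert df["pooled_mean"].iloc[0] == pytest.approx(22 / 6)


class TestSummaryTable:
    def test_constructed_condition(self):
        df = pd.DataFrame(
            {
                "group": ["c"] * 5,
                "experiment_id": ["e0", "e0", "e1", "e1", "e1"],
                "filopodia_count": [0, 0, 1, 3, 4],
                "cortex_cyto_ratio": [1.0, 1.1, 1.2, 1.3, 1.4],
            }
        )
        out = build_summary_table(df)
        row = out.iloc[0]
        assert row["percent_with_filopodia"] == pytest.approx(60.0)
        assert row["filopodia_mean_positive"] == pytest.approx(8 / 3)
        pos = np.array([1.0, 3, 4])
        assert row["filopodia_sem_positive"] == pytest.approx(
            pos.std(ddof=1) / np.sqrt(3)
        )
        ratios = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
        assert row["cortex_cyto_ratio_mean"] == pytest.approx(1.2)
        assert row["cortex_cyto_ratio_sem"] == pytest.approx(
            ratios.std(ddof=1) / np.sqrt(5)
        )
        assert row["N_experiments"] == 2 and row["n_cells"] == 5

    def test_sem_columns_are_sd_over_sqrt_n(self):
        rng = np.random.default_rng(78)
        df = pd.DataFrame(
            {
                "group": ["g"] * 40,
                "experiment_id": ["e0"] * 40,
                "filopodia_count": rng.integers(0, 5, 40),
                "cortex_cyto_ratio": rng.normal(1.2, 0.05, 40),
            }
        )
        out = build_summary_table(df)
        ratios = df["cortex_cyto_ratio"].to_numpy()
        kept, _ = rout_filter(ratios)
        assert out["cortex_cyto_ratio_sem"].iloc[0] == pytest.approx(
            kept.std(ddof=1) / np.sqrt(kept.size)
        )
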