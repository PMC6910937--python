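import numpy as np
import pandas as pd
import pytest
from scipy import stats

from censomet.design import PairedDesign, UnpairedDesign
from censomet.tables import AbundanceTable, SampleInfo
from censomet.univariate import (adjusted_compare, bonferroni_threshold,
                                 compare_groups, volcano_table,
                                 welch_t_from_moments)

from oracles import welch_by_formula


def _table_from_logs(logs, samples=None, mets=None):
    logs = np.asarray(logs, dtype=float)
    samples = samples or [f"S{i}" for i in range(logs.shape[0])]
    mets = mets or [f"M{j}" for j in range(logs.shape[1])]
    return AbundanceTable(pd.DataFrame(np.exp(logs), index=samples, columns=mets))


class TestBonferroni:
    def test_identity_at_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_scales_inversely_with_m(self):
        assert bonferroni_threshold(0.05, 500) == pytest.approx(1e-4)

    def test_zero_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        logs = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        t = _table_from_logs(logs)
        design = UnpairedDesign(group1=("S0", "S1", "S2"), group2=("S3", "S4", "S5"))
        res = compare_groups(t, design)
        assert res[0].t_stat == 0.0 and res[0].p == 1.0

    def test_zero_variance_everywhere_warns(self):
        t = _table_from_logs(np.ones((6, 1)))
        design = UnpairedDesign(group1=("S0", "S1", "S2"), group2=("S3", "S4", "S5"))
        with pytest.warns(UserWarning, match="zero variance"):
            res = compare_groups(t, design)
        assert res[0].p == 1.0

    def test_welch_matches_hand_formula(self):
        t = _table_from_logs(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]))
        design = UnpairedDesign(group1=("S0", "S1", "S2"), group2=("S3", "S4", "S5"))
        res = compare_groups(t, design)[0]
        t_o, df_o, p_o = welch_by_formula([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t_stat == pytest.approx(t_o, abs=1e-10)
        assert res.df == pytest.approx(df_o, abs=1e-10)
        assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_welch_vectorised_matches_scipy(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 1, (8, 12))
        x2 = rng.normal(0.5, 2, (11, 12))
        t, df, p = welch_t_from_moments(x1.mean(0), x1.var(0, ddof=1), 8,
                                        x2.mean(0), x2.var(0, ddof=1), 11)
        ref = stats.ttest_ind(x1, x2, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(1)
        logs = rng.normal(size=(10, 7))
        logs2 = logs[:5] + rng.normal(0, 0.5, size=(5, 7))
        t = _table_from_logs(np.vstack([logs[:5], logs2]))
        design = PairedDesign(pairs=tuple((f"S{i}", f"S{i+5}") for i in range(5)))
        res = compare_groups(t, design)
        ref = stats.ttest_rel(np.vstack([logs[:5]]), logs2)
        for j, r in enumerate(res):
            assert r.t_stat == pytest.approx(ref.statistic[j], abs=1e-10)
            assert r.p == pytest.approx(ref.pvalue[j], abs=1e-10)
            assert r.df == 4

    def test_minimum_group_sizes_enforced(self):
        t = _table_from_logs(np.zeros((4, 1)))
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups(t, UnpairedDesign(group1=("S0", "S1"),
                                             group2=("S2", "S3")))


def _paired_info(n, rng, sex_mixed=True):
    info = []
    for i in range(n):
        sex_d = "M" if (not sex_mixed or rng.random() < 0.5) else "F"
        sex_r = "M" if (not sex_mixed or rng.random() < 0.5) else "F"
        info.append(SampleInfo(f"D{i}", "donor", "D", pair_id=f"P{i}",
                               age=float(rng.uniform(30, 60)), sex=sex_d,
                               bmi=float(rng.uniform(20, 30))))
        info.append(SampleInfo(f"R{i}", "recipient", "Rs", pair_id=f"P{i}",
                               age=float(rng.uniform(30, 60)), sex=sex_r,
                               bmi=float(rng.uniform(20, 30))))
    return info


class TestAdjustedCompare:
    def test_independent_covariates_leave_p_similar(self):
        rng = np.random.default_rng(2)
        n, K = 40, 30
        logs = rng.normal(size=(2 * n, K))
        logs[n:] += np.where(np.arange(K) < 10, 0.8, 0.0)
        samples = [f"D{i}" for i in range(n)] + [f"R{i}" for i in range(n)]
        t = _table_from_logs(logs, samples=samples)
        info = _paired_info(n, rng)
        design = UnpairedDesign(group1=tuple(f"R{i}" for i in range(n)),
                                group2=tuple(f"D{i}" for i in range(n)))
        plain = compare_groups(t, design)
        adj = adjusted_compare(t, design, info)
        lp = -np.log10([r.p for r in plain])
        la = -np.log10([r.p for r in adj])
        assert np.corrcoef(lp, la)[0, 1] > 0.95

    def test_confounded_effect_vanishes_after_adjustment(self):
        rng = np.random.default_rng(3)
        n = 50
        bmi_g1 = rng.uniform(28, 34, n)
        bmi_g2 = rng.uniform(20, 26, n)
        # metabolite driven purely by BMI, not by group
        logs = np.concatenate([0.3 * bmi_g1, 0.3 * bmi_g2])[:, None] \
            + rng.normal(0, 0.5, (2 * n, 1))
        samples = [f"R{i}" for i in range(n)] + [f"D{i}" for i in range(n)]
        t = _table_from_logs(logs, samples=samples)
        info = []
        for i in range(n):
            info.append(SampleInfo(f"R{i}", "recipient", "Rs",
                                   age=float(rng.uniform(30, 60)),
                                   sex="M" if rng.random() < 0.5 else "F",
                                   bmi=float(bmi_g1[i])))
            info.append(SampleInfo(f"D{i}", "donor", "D",
                                   age=float(rng.uniform(30, 60)),
                                   sex="M" if rng.random() < 0.5 else "F",
                                   bmi=float(bmi_g2[i])))
        design = UnpairedDesign(group1=tuple(f"R{i}" for i in range(n)),
                                group2=tuple(f"D{i}" for i in range(n)))
        plain = compare_groups(t, design)[0]
        adj = adjusted_compare(t, design, info)[0]
        assert plain.p < 1e-6
        assert adj.p > 0.01

    def test_zero_variance_covariate_rejected(self):
        rng = np.random.default_rng(4)
        n = 10
        logs = rng.normal(size=(2 * n, 2))
        samples = [f"R{i}" for i in range(n)] + [f"D{i}" for i in range(n)]
        t = _table_from_logs(logs, samples=samples)
        info = ([SampleInfo(f"R{i}", "recipient", "Rs", age=50.0, sex="M",
                            bmi=float(rng.uniform(20, 30))) for i in range(n)]
                + [SampleInfo(f"D{i}", "donor", "D", age=50.0, sex="M",
                              bmi=float(rng.uniform(20, 30))) for i in range(n)])
        design = UnpairedDesign(group1=tuple(f"R{i}" for i in range(n)),
                                group2=tuple(f"D{i}" for i in range(n)))
        with pytest.raises(ValueError, match="zero variance"):
            adjusted_compare(t, design, info)

    def test_paired_adjustment_runs_and_detects_shift(self):
        rng = np.random.default_rng(5)
        n = 30
        logs_d = rng.normal(size=(n, 3))
        logs_r = logs_d + rng.normal(0, 0.4, (n, 3)) + np.array([1.5, 0, 0])
        samples = [f"D{i}" for i in range(n)] + [f"R{i}" for i in range(n)]
        t = _table_from_logs(np.vstack([logs_d, logs_r]), samples=samples)
        info = _paired_info(n, rng)
        design = PairedDesign(pairs=tuple((f"R{i}", f"D{i}") for i in range(n)))
        adj = adjusted_compare(t, design, info)
        assert adj[0].p < 1e-6 and adj[1].p > 1e-4


class TestVolcano:
    def test_table_contents(self):
        logs = np.vstack([np.random.default_rng(6).normal(size=(6, 2))])
        logs[3:, 0] += 5.0
        t = _table_from_logs(logs)
        design = UnpairedDesign(group1=("S0", "S1", "S2"), group2=("S3", "S4", "S5"))
        res = compare_groups(t, design)
        v = volcano_table(res)
        assert set(v.columns) == {"log_fc", "neg_log10_p", "significant"}
        assert (v.neg_log10_p >= 0).all()
        for r in res:
            assert v.loc[r.metabolite_id, "significant"] == r.significant

    def test_p_one_maps_to_zero(self):
        logs = np.tile([[0.0], [1.0], [2.0]], (2, 1))
        t = _table_from_logs(logs)
        design = UnpairedDesign(group1=("S0", "S1", "S2"), group2=("S3", "S4", "S5"))
        v = volcano_table(compare_groups(t, design))
        assert v.neg_log10_p.iloc[0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            volcano_table([])


class TestFamilywiseError:
    def test_bonferroni_fwer_under_global_null(self):
        # 500 null replicates, M=100: FWER <= alpha + 2 MC sd
        rng = np.random.default_rng(7)
        n_rep, M, n = 500, 100, 10
        thr = bonferroni_threshold(0.05, M)
        fw = 0
        for _ in range(n_rep):
            x1 = rng.normal(size=(n, M))
            x2 = rng.normal(size=(n, M))
            _, _, p = welch_t_from_moments(x1.mean(0), x1.var(0, ddof=1), n,
                                           x2.mean(0), x2.var(0, ddof=1), n)
            fw += (p < thr).any()
        rate = fw / n_rep
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)
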