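import numpy as np
import pandas as pd
import pytest

from censomet.multivariate import lasso_logistic, ora, pca, splsda

from oracles import hypergeom_upper_tail_exact, logistic_mle_newton


class TestPca:
    def test_collinear_data_one_component(self):
        x = np.linspace(0, 1, 10)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        scores, loadings, var = pca(X, n_comp=2)
        assert var[0] == pytest.approx(1.0)

    def test_variance_explained_bounded_and_ordered(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        X.columns = [f"m{j}" for j in range(6)]
        _, _, var = pca(X, n_comp=4)
        assert var.sum() <= 1.0 + 1e-12
        assert (np.diff(var) <= 1e-12).all()

    def test_matches_eigendecomposition_oracle(self):
        X = pd.DataFrame([[1.0, 2.0], [3.0, 1.0], [5.0, 7.0]],
                         columns=["a", "b"])
        scores, loadings, var = pca(X, n_comp=2)
        C = np.cov((X - X.mean()).to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(var, w / w.sum(), atol=1e-10)
        for c in range(2):
            vec = v[:, c] * np.sign(v[np.argmax(np.abs(v[:, c])), c])
            np.testing.assert_allclose(loadings.iloc[:, c], vec, atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            scores, loadings, _ = pca(X, n_comp=1)
        assert list(loadings.index) == ["a"]

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError):
            pca(X)


class TestSplsda:
    def test_single_informative_variable_selected(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 40
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(size=(n, 51))
            X[:, 0] += 2.0 * y
            Xf = pd.DataFrame(X, columns=[f"m{j}" for j in range(51)])
            sel = splsda(Xf, y, n_comp=1, keep_per_comp=5)
            hits += "m0" in sel[0].selected_ids
        assert hits >= 19  # >= 95% selection rate

    def test_dense_case_matches_pls_regression(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(1)
        n, k = 30, 8
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, k)) + 0.5 * y[:, None]
        Xf = pd.DataFrame(X, columns=[f"m{j}" for j in range(k)])
        sel = splsda(Xf, y, n_comp=1, keep_per_comp=k)
        ref = PLSRegression(n_components=1, scale=True).fit(X, y.astype(float))
        w_ref = ref.x_weights_[:, 0]
        w = sel[0].loadings.to_numpy()
        if np.sign(w_ref[np.argmax(np.abs(w_ref))]) != np.sign(w[np.argmax(np.abs(w))]):
            w_ref = -w_ref
        np.testing.assert_allclose(w, w_ref, atol=1e-8)

    def test_selection_size_respected(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(24, 30)),
                         columns=[f"m{j}" for j in range(30)])
        y = np.repeat([0, 1], 12)
        sels = splsda(X, y, n_comp=2, keep_per_comp=7)
        for s in sels:
            assert len(s.selected_ids) <= 7
            assert (s.loadings[~s.loadings.index.isin(s.selected_ids)] == 0).all()

    def test_permuted_labels_select_null_variables(self):
        # under label permutation the selected variables should look like
        # any other variable: their univariate p-values stay spread out
        from scipy import stats

        rng = np.random.default_rng(3)
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 40)),
                         columns=[f"m{j}" for j in range(40)])
        pvals = []
        for rep in range(10):
            y = rng.permutation(np.repeat([0, 1], n // 2))
            sel = splsda(X, y, n_comp=1, keep_per_comp=5)
            for m in sel[0].selected_ids:
                x = X[m].to_numpy()
                pvals.append(stats.ttest_ind(x[y == 0], x[y == 1]).pvalue)
        # selected-by-chance variables are the extremes of 40 nulls, so
        # small p-values dominate but the distribution is not degenerate
        assert np.median(pvals) > 0.005

    def test_two_classes_required(self):
        X = pd.DataFrame(np.random.default_rng(4).normal(size=(9, 3)),
                         columns=list("abc"))
        with pytest.raises(ValueError):
            splsda(X, np.array([0, 1, 2] * 3))

    def test_keep_too_large_rejected(self):
        X = pd.DataFrame(np.random.default_rng(5).normal(size=(12, 3)),
                         columns=list("abc"))
        with pytest.raises(ValueError):
            splsda(X, np.repeat([0, 1], 6), keep_per_comp=10)


class TestLassoLogistic:
    def test_huge_lambda_shrinks_everything(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        y = np.repeat([0, 1], 15)
        fit = lasso_logistic(X, y, lambda_grid=[10.0])
        assert (fit["coef_path"].iloc[0] == 0).all()

    def test_tiny_lambda_matches_newton_oracle(self):
        rng = np.random.default_rng(7)
        n = 200
        X = rng.normal(size=(n, 2))
        eta = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        Xf = pd.DataFrame(X, columns=["a", "b"])
        fit = lasso_logistic(Xf, y, lambda_grid=[1e-8])
        # the oracle works on the same standardised design
        Z = (X - X.mean(0)) / X.std(0)
        b0, coefs = logistic_mle_newton(Z, y)
        np.testing.assert_allclose(fit["coef_path"].iloc[0], coefs, atol=1e-4)
        assert fit["intercepts"][0] == pytest.approx(b0, abs=1e-4)

    def test_injected_signal_recovered(self):
        rng = np.random.default_rng(8)
        n = 60
        X = rng.normal(size=(n, 103))
        beta = np.zeros(103)
        beta[:3] = 2.0
        eta = X @ beta
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        Xf = pd.DataFrame(X, columns=[f"m{j}" for j in range(103)])
        fit = lasso_logistic(Xf, y, n_lambda=30)
        assert len(set(fit["selected"]) & {"m0", "m1", "m2"}) >= 2

    def test_bic_choice_is_deterministic(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(40, 10)),
                         columns=[f"m{j}" for j in range(10)])
        y = np.repeat([0, 1], 20)
        f1 = lasso_logistic(X, y, n_lambda=20)
        f2 = lasso_logistic(X, y, n_lambda=20)
        assert f1["lambda_best"] == f2["lambda_best"]
        assert f1["selected"] == f2["selected"]


def _annotation(path_sizes):
    rows = []
    i = 0
    for name, size in path_sizes.items():
        for _ in range(size):
            rows.append({"metabolite_id": f"M{i:03d}", "super_pathway": "x",
                         "sub_pathway": name, "microbial": False,
                         "xenobiotic": False})
            i += 1
    return pd.DataFrame(rows).set_index("metabolite_id")


class TestOra:
    def test_balanced_selection_gives_unit_enrichment(self):
        # k/m == (n-k)/(N-m)  =>  E = 1
        ann = _annotation({"p1": 10, "p2": 90})
        selected = {f"M{i:03d}" for i in range(2)} | \
                   {f"M{i:03d}" for i in range(10, 28)}
        res = {r.sub_pathway: r for r in ora(selected, ann, set(ann.index))}
        assert res["p1"].E == pytest.approx(1.0)

    def test_printed_formula_example(self):
        # N=100, m=10, n=20, k=5 -> E = (5/10)/(15/90) = 3
        ann = _annotation({"p1": 10, "rest": 90})
        selected = ({f"M{i:03d}" for i in range(5)}
                    | {f"M{i:03d}" for i in range(10, 25)})
        res = {r.sub_pathway: r for r in ora(selected, ann, set(ann.index))}
        r = res["p1"]
        assert (r.k, r.m, r.n, r.N) == (5, 10, 20, 100)
        assert r.E == pytest.approx(3.0)

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            N = int(rng.integers(8, 41))
            m = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            ann = _annotation({"p1": m, "rest": N - m})
            ids = list(ann.index)
            selected = set(rng.choice(ids, size=n, replace=False))
            for r in ora(selected, ann, set(ids)):
                expect = hypergeom_upper_tail_exact(r.k, N, r.m, r.n)
                assert r.p == pytest.approx(expect, abs=1e-12)

    def test_pathway_counts_sum_to_selection_when_partition(self):
        ann = _annotation({"p1": 7, "p2": 13, "p3": 10})
        rng = np.random.default_rng(11)
        selected = set(rng.choice(list(ann.index), size=12, replace=False))
        res = ora(selected, ann, set(ann.index))
        assert sum(r.k for r in res) == 12

    def test_everything_selected_rejected(self):
        ann = _annotation({"p1": 4, "p2": 4})
        with pytest.raises(ValueError, match="every metabolite"):
            ora(set(ann.index), ann, set(ann.index))

    def test_selection_outside_universe_rejected(self):
        ann = _annotation({"p1": 4})
        with pytest.raises(ValueError):
            ora({"ZZZ"}, ann, set(ann.index))
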