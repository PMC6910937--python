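"""Step 4 and ordination — PCA, sparse PLS-DA, lasso logistic regression
and pathway overrepresentation analysis.

The sample-to-variable ratio in this setting (tens of subjects, hundreds
of metabolites) rules out cross-validated model selection; PLS-DA output
is descriptive, and the lasso penalty is chosen by BIC over a
deterministic path.  ORA scores how strongly the selected metabolites
concentrate in each sub-pathway: with N analyzed metabolites, m in the
pathway, n selected overall and k selected in the pathway, the
enrichment ratio is E = (k/m) / ((n-k)/(N-m)) and the p-value is the
upper tail of the hypergeometric distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OraResult", "SparseSelection", "pca", "splsda", "lasso_logistic",
           "ora"]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X: pd.DataFrame, n_comp: int = 2
        ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal component analysis of an imputed, log, z-scored table.

    Returns (scores, loadings, fraction of variance explained).  Constant
    columns are dropped with a warning; component signs are fixed so the
    largest-|loading| element of each component is positive.
    """
    from sklearn.decomposition import PCA

    if X.isna().any().any():
        raise ValueError("PCA input must have no missing values")
    variances = X.var(axis=0)
    constant = variances[np.isclose(variances, 0.0)].index
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant columns", stacklevel=2)
        X = X.drop(columns=constant)
    n_comp = min(n_comp, X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X.to_numpy())
    loadings = model.components_.T  # variables x components
    for c in range(n_comp):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{c + 1}" for c in range(n_comp)]
    return (pd.DataFrame(scores, index=X.index, columns=comp_names),
            pd.DataFrame(loadings, index=X.columns, columns=comp_names),
            model.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class SparseSelection:
    component_index: int
    selected_ids: list[str]
    loadings: pd.Series
    scores: pd.Series


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold a weight vector so exactly ``keep`` entries remain
    nonzero (lasso-style: shrink by the (keep+1)-th largest magnitude)."""
    if keep >= len(w):
        return w.copy()
    cut = np.sort(np.abs(w))[::-1][keep]
    out = np.sign(w) * np.clip(np.abs(w) - cut, 0.0, None)
    return out


def splsda(X: pd.DataFrame, y, n_comp: int = 2, keep_per_comp: int = 20
           ) -> list[SparseSelection]:
    """Sparse PLS discriminant analysis for two classes.

    Columns are centred and unit-scaled; the response is the centred
    class indicator.  Each component's weight vector (proportional to
    X'y) is soft-thresholded to ``keep_per_comp`` nonzero variables and
    normalised, scores are X w, and X and y are deflated before the next
    component.  With ``keep_per_comp`` = all variables this is ordinary
    PLS-DA.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("splsda requires exactly two classes")
    if min((y == c).sum() for c in classes) < 3:
        raise ValueError("need at least 3 samples per class")
    if keep_per_comp > X.shape[1]:
        raise ValueError("keep_per_comp exceeds the metabolite count")

    ids = list(X.columns)
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xc = Xc / sd
    yc = (y == classes[1]).astype(float)
    yc = yc - yc.mean()

    out: list[SparseSelection] = []
    for h in range(n_comp):
        w = Xc.T @ yc
        if np.allclose(w, 0):
            warnings.warn(f"component {h + 1}: response fully deflated",
                          stacklevel=2)
            break
        w = _soft_threshold_keep(w, keep_per_comp)
        w = w / np.linalg.norm(w)
        t = Xc @ w
        tt = float(t @ t)
        p_load = Xc.T @ t / tt
        c_load = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_load)
        yc = yc - t * c_load
        selected = [ids[j] for j in np.nonzero(w)[0]]
        out.append(SparseSelection(
            component_index=h + 1,
            selected_ids=sorted(selected, key=lambda m: -abs(w[ids.index(m)])),
            loadings=pd.Series(w, index=ids),
            scores=pd.Series(t, index=X.index)))
    return out


# ---------------------------------------------------------------------------
# lasso logistic regression
# ---------------------------------------------------------------------------

def lasso_logistic(X: pd.DataFrame, y, lambda_grid=None, n_lambda: int = 50
                   ) -> dict:
    """L1-penalised logistic regression over a decreasing lambda path,
    with the reported "predictive set" = nonzero coefficients at the
    BIC-minimising lambda.  The intercept is unpenalised; columns are
    standardised internally.

    Returns a dict with ``lambdas``, ``coef_path`` (lambdas x variables,
    on the standardised scale), ``intercepts``, ``bic``, ``lambda_best``
    and ``selected`` ids.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary response required")
    yb = (y == classes[1]).astype(float)
    n, K = X.shape
    Z = X.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0, ddof=0) == 0, 1.0,
                                        Z.std(axis=0, ddof=0))

    if lambda_grid is None:
        lam_max = np.max(np.abs(Z.T @ (yb - yb.mean()))) / n
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    coef_path = np.zeros((len(lambda_grid), K))
    intercepts = np.zeros(len(lambda_grid))
    bic = np.zeros(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        model = LogisticRegression(
            penalty="l1", C=1.0 / (n * lam), solver="saga",
            max_iter=5_000, tol=1e-7, fit_intercept=True, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # capped iterations near separation
            model.fit(Z, yb)
        coef_path[i] = model.coef_[0]
        intercepts[i] = model.intercept_[0]
        eta = Z @ coef_path[i] + intercepts[i]
        loglik = float(np.sum(yb * eta - np.log1p(np.exp(eta))))
        df = int(np.sum(coef_path[i] != 0)) + 1
        bic[i] = -2.0 * loglik + df * np.log(n)

    best = int(np.argmin(bic))
    selected = [X.columns[j] for j in np.nonzero(coef_path[best])[0]]
    return {"lambdas": lambda_grid,
            "coef_path": pd.DataFrame(coef_path, index=lambda_grid,
                                      columns=X.columns),
            "intercepts": intercepts, "bic": bic,
            "lambda_best": float(lambda_grid[best]), "selected": selected}


# ---------------------------------------------------------------------------
# overrepresentation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OraResult:
    sub_pathway: str
    k: int  # selected metabolites in the pathway
    m: int  # pathway size within the universe
    n: int  # selected metabolites overall
    N: int  # universe size
    E: float  # enrichment ratio (k/m) / ((n-k)/(N-m))
    p: float  # upper-tail hypergeometric probability


def ora(selected: set[str], annotation: pd.DataFrame, universe: set[str]
        ) -> list[OraResult]:
    """Hypergeometric overrepresentation of the selected metabolites in
    each sub-pathway of the universe (the metabolites surviving the
    missingness filter).  p = P(X >= k), X ~ Hypergeometric(N, m, n)."""
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected metabolites must lie within the universe")
    N, n = len(universe), len(selected)
    if n == N:
        raise ValueError("every metabolite selected: enrichment undefined")
    ann = annotation.loc[annotation.index.intersection(universe)]
    out = []
    for sub, members in ann.groupby("sub_pathway").groups.items():
        m = len(members)
        k = len(selected & set(members))
        if N == m:
            continue  # single-pathway universe: no outside set to compare
        if n - k == 0:
            e = float("inf") if k > 0 else 0.0
        else:
            e = (k / m) / ((n - k) / (N - m))
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        out.append(OraResult(str(sub), k, m, n, N, float(e), p))
    return sorted(out, key=lambda r: r.p)
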