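"""Step 2 — per-metabolite log-scale group comparison.

After filtering and imputation each metabolite is compared between the
two groups on the natural-log scale: Welch's unequal-variance t test
(Aspin-Welch, Satterthwaite degrees of freedom) for unpaired designs,
the paired t test (one-sample t on within-pair log differences) for
paired designs.  Significance is controlled family-wise by Bonferroni
over the M analyzed metabolites with strict inequality, p < alpha/M.

Covariate-adjusted variants regress log amounts (or within-pair log
differences) on the group indicator plus age, sex and BMI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import PairedDesign, UnpairedDesign
from .tables import AbundanceTable, SampleInfo

__all__ = ["UnivariateResult", "bonferroni_threshold", "compare_groups",
           "adjusted_compare", "volcano_table", "results_frame",
           "welch_t_from_moments", "paired_t_from_moments"]

_EPS = 1e-300


@dataclass(frozen=True)
class UnivariateResult:
    metabolite_id: str
    mean_log_g1: float
    mean_log_g2: float
    log_fc: float
    t_stat: float
    df: float
    p: float
    p_bonferroni_threshold: float
    significant: bool
    adjusted_p: float | None = None


def bonferroni_threshold(alpha: float, M: int) -> float:
    """Family-wise threshold alpha / M."""
    if M < 1:
        raise ValueError("M must be a positive integer")
    return alpha / M


# ---------------------------------------------------------------------------
# vectorised t machinery (shared with the ratio network)
# ---------------------------------------------------------------------------

def welch_t_from_moments(m1, v1, n1, m2, v2, n2):
    """Welch t statistic, Satterthwaite df and two-sided p from group
    means, sample variances (ddof=1) and sizes.  Vectorised; the
    zero-variance/zero-difference convention gives t=0, p=1."""
    m1, v1, m2, v2 = (np.asarray(a, dtype=float) for a in (m1, v1, m2, v2))
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 <= _EPS
    t = np.where(degenerate, np.where(np.abs(diff) <= 1e-12, 0.0, np.inf), t)
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, np.minimum(p, 1.0)


def paired_t_from_moments(md, vd, n):
    """One-sample t on within-pair differences from mean, variance
    (ddof=1) and pair count."""
    md, vd = np.asarray(md, dtype=float), np.asarray(vd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / np.sqrt(vd / n)
    degenerate = vd <= _EPS
    t = np.where(degenerate, np.where(np.abs(md) <= 1e-12, 0.0, np.inf), t)
    df = float(n - 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.full_like(np.atleast_1d(t), df, dtype=float), np.minimum(p, 1.0)


def _log_values(t: AbundanceTable) -> np.ndarray:
    vals = t.data.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("table contains missing cells; impute first")
    if (vals <= 0).any():
        raise ValueError("non-positive values cannot be log-transformed")
    return np.log(vals)


def compare_groups(t: AbundanceTable,
                   design: PairedDesign | UnpairedDesign,
                   alpha: float = 0.05) -> list[UnivariateResult]:
    """Per-metabolite two-sided t test on natural-log amounts with a
    Bonferroni threshold alpha / M (M = analyzed metabolite count)."""
    L = _log_values(t)
    ids = t.metabolite_ids
    M = len(ids)
    thr = bonferroni_threshold(alpha, M)
    idx = {s: i for i, s in enumerate(t.sample_ids)}

    if isinstance(design, PairedDesign):
        if design.n_pairs < 3:
            raise ValueError("need at least 3 pairs")
        i1 = [idx[s] for s in design.group1]
        i2 = [idx[s] for s in design.group2]
        m1, m2 = L[i1].mean(axis=0), L[i2].mean(axis=0)
        D = L[i1] - L[i2]
        degenerate = D.var(axis=0, ddof=1) <= _EPS
        tstat, df, p = paired_t_from_moments(D.mean(axis=0),
                                             D.var(axis=0, ddof=1),
                                             D.shape[0])
    elif isinstance(design, UnpairedDesign):
        i1 = [idx[s] for s in design.group1]
        i2 = [idx[s] for s in design.group2]
        if len(i1) < 3 or len(i2) < 3:
            raise ValueError("need at least 3 subjects per group")
        m1, m2 = L[i1].mean(axis=0), L[i2].mean(axis=0)
        v1, v2 = L[i1].var(axis=0, ddof=1), L[i2].var(axis=0, ddof=1)
        degenerate = (v1 <= _EPS) & (v2 <= _EPS)
        tstat, df, p = welch_t_from_moments(m1, v1, len(i1), m2, v2, len(i2))
    else:
        raise TypeError(f"unsupported design {type(design).__name__}")

    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} metabolites with zero "
                      "variance; p set to 1 where the means also agree",
                      stacklevel=2)
    return [UnivariateResult(ids[j], float(m1[j]), float(m2[j]),
                             float(m1[j] - m2[j]), float(tstat[j]),
                             float(np.atleast_1d(df)[j] if np.ndim(df) else df),
                             float(p[j]), thr, bool(p[j] < thr))
            for j in range(M)]


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def _check_covariates(X: pd.DataFrame) -> None:
    for col in X.columns:
        if np.isclose(X[col].var(), 0.0):
            raise ValueError(f"covariate {col!r} has zero variance")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        # name an offending column: one whose removal restores full rank
        for col in X.columns:
            rest = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), rest])) == rank:
                raise ValueError(f"collinear covariate: {col!r}")
        raise ValueError("collinear covariates")


def adjusted_compare(t: AbundanceTable,
                     design: PairedDesign | UnpairedDesign,
                     info: list[SampleInfo],
                     alpha: float = 0.05,
                     covariates: tuple[str, ...] = ("age", "sex", "bmi"),
                     ) -> list[UnivariateResult]:
    """Covariate-adjusted comparison.

    Unpaired: per metabolite, OLS of log amount on group + age + sex +
    BMI; p from the group coefficient.  Paired: OLS of the within-pair
    log difference on the age difference, BMI difference and a sex-match
    indicator; p from the intercept (the group contrast at zero
    covariate difference).
    """
    import statsmodels.api as sm

    L = _log_values(t)
    ids = t.metabolite_ids
    M = len(ids)
    thr = bonferroni_threshold(alpha, M)
    idx = {s: i for i, s in enumerate(t.sample_ids)}
    meta = {s.sample_id: s for s in info}

    if isinstance(design, UnpairedDesign):
        samples = list(design.group1) + list(design.group2)
        g = np.array([1.0] * len(design.group1) + [0.0] * len(design.group2))
        cov = pd.DataFrame({
            "age": [meta[s].age for s in samples],
            "sex": [1.0 if meta[s].sex == "M" else 0.0 for s in samples],
            "bmi": [meta[s].bmi for s in samples],
        })[list(covariates)]
        _check_covariates(cov)
        X = sm.add_constant(np.column_stack([g, cov.to_numpy()]))
        rows = [idx[s] for s in samples]
        target_coef = 1  # the group column
        Y = L[rows]
    else:
        pairs = design.pairs
        d_age = np.array([meta[a].age - meta[b].age for a, b in pairs])
        d_bmi = np.array([meta[a].bmi - meta[b].bmi for a, b in pairs])
        sex_match = np.array([1.0 if meta[a].sex == meta[b].sex else 0.0
                              for a, b in pairs])
        cov = pd.DataFrame({"age": d_age, "sex": sex_match, "bmi": d_bmi})
        cov = cov[[c for c in ("age", "sex", "bmi") if c in covariates]]
        _check_covariates(cov)
        X = sm.add_constant(cov.to_numpy())
        target_coef = 0  # the intercept = mean pair difference at covariate 0
        i1 = [idx[a] for a, _ in pairs]
        i2 = [idx[b] for _, b in pairs]
        Y = L[i1] - L[i2]

    results = []
    base = compare_groups(t, design, alpha)
    for j in range(M):
        fit = sm.OLS(Y[:, j], X).fit()
        adj_p = float(fit.pvalues[target_coef])
        r = base[j]
        results.append(UnivariateResult(
            r.metabolite_id, r.mean_log_g1, r.mean_log_g2, r.log_fc,
            float(fit.tvalues[target_coef]), float(fit.df_resid),
            adj_p, thr, bool(adj_p < thr), adjusted_p=adj_p))
    return results


def volcano_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """log fold-change vs -log10 p, with the Bonferroni significance flag."""
    if not results:
        raise ValueError("no results")
    return pd.DataFrame({
        "metabolite_id": [r.metabolite_id for r in results],
        "log_fc": [r.log_fc for r in results],
        "neg_log10_p": [-np.log10(max(r.p, _EPS)) for r in results],
        "significant": [r.significant for r in results],
    }).set_index("metabolite_id")


def results_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("metabolite_id")
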