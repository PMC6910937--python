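"""Independent brute-force oracles used by the tests.

These are deliberately naive: exact rational arithmetic and full
enumeration, sharing no code with the package implementations they
check.
"""

from fractions import Fraction
from math import comb


def binom_two_sided_exact(b: int, c: int) -> float:
    """Two-sided exact binomial p for b successes in b+c trials at 1/2,
    by full pmf enumeration: min(1, 2*min(lower tail, upper tail))."""
    n = b + c
    if n == 0:
        return 1.0
    pmf = [Fraction(comb(n, x), 2 ** n) for x in range(n + 1)]
    lower = sum(pmf[: b + 1])
    upper = sum(pmf[b:])
    return float(min(Fraction(1), 2 * min(lower, upper)))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating every table with the observed
    margins and summing the hypergeometric probabilities of those at most
    as probable as the observed table (exact rational comparison)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    def prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def hypergeom_upper_tail_exact(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n), by exact enumeration."""
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(k, min(m, n) + 1):
        total += Fraction(comb(m, x) * comb(N - m, n - x), denom)
    return float(total)


def welch_by_formula(x1, x2):
    """Welch t, Satterthwaite df and two-sided p from the textbook
    formulas, computed step by step with plain Python floats."""
    from scipy.stats import t as tdist

    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    v1 = sum((x - m1) ** 2 for x in x1) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in x2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / se2 ** 0.5
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def critical_threshold_by_grid(p_matrix) -> float:
    """Largest threshold keeping the graph connected, by grid search over
    every distinct off-diagonal p value (checking connectivity with a
    hand-written breadth-first search)."""
    import numpy as np

    p = np.asarray(p_matrix, dtype=float)
    k = p.shape[0]

    def connected_at(thr):
        adj = (p >= thr)
        np.fill_diagonal(adj, False)
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for i in frontier:
                for j in np.nonzero(adj[i])[0]:
                    if j not in seen:
                        seen.add(j)
                        nxt.append(j)
            frontier = nxt
        return len(seen) == k

    candidates = sorted({p[i, j] for i in range(k) for j in range(k) if i != j})
    best = None
    for thr in candidates:
        if connected_at(thr):
            best = thr
        else:
            break
    assert best is not None, "graph must be connected at the smallest p"
    return float(best)


def logistic_mle_newton(X, y, tol=1e-12, max_iter=200):
    """Unpenalised logistic regression by hand-rolled Newton-Raphson on
    the design [1, X]; returns (intercept, coefs)."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = Z.T @ (y - mu)
        hess = Z.T @ (Z * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta[0], beta[1:]
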