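"""Step 3 — the compositional pairwise log-ratio network.

Rather than absolute amounts, the *relative* amounts between metabolites
are compared: for every unordered pair (i, j) the between-group change
of log(x_i) - log(x_j) is tested with the same t-test family as the
univariate step.  An undirected graph is built over metabolites in which
an edge means the pair's ratio is statistically unchanged; edges with
p < p_max are removed.  Under the no-change null the graph is a single
clique, so any extra connected component signals a group of metabolites
whose relative behaviour changed; the largest component is read as the
"no change" set.

The threshold p_max is calibrated by Monte-Carlo simulation: on null
datasets of independent log-normal metabolites of the same shape, the
largest threshold keeping each simulated graph connected (its
*critical threshold*, the bottleneck edge of the maximum spanning tree
of the p matrix) is recorded; p_max is the 5th percentile of these, so
that at most 5% of null datasets split.  The operational value is the
lower 95% bootstrap confidence bound, truncated (floored) to two
decimals — conservative in the direction of fewer false splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .design import PairedDesign, UnpairedDesign
from .tables import AbundanceTable
from .univariate import paired_t_from_moments, welch_t_from_moments

__all__ = ["RatioGraph", "CalibrationResult", "pairwise_ratio_pvalues",
           "build_graph", "critical_threshold", "calibrate_pmax",
           "restricted_network"]


# ---------------------------------------------------------------------------
# pairwise ratio p-values
# ---------------------------------------------------------------------------

def _pair_p_from_logs_paired(D: np.ndarray) -> np.ndarray:
    """p matrix for paired designs from the pair-difference log matrix D
    (n_pairs x K).  The ratio (i, j) statistic is the one-sample t on
    D[:, i] - D[:, j]; its moments come from the mean vector and
    covariance of D, so all K(K-1)/2 tests are done at once."""
    n, K = D.shape
    m = D.mean(axis=0)
    S = np.cov(D, rowvar=False, ddof=1)
    v = np.clip(np.diag(S)[:, None] + np.diag(S)[None, :] - 2.0 * S, 0.0, None)
    md = m[:, None] - m[None, :]
    _, _, p = paired_t_from_moments(md, v, n)
    np.fill_diagonal(p, 1.0)
    return p


def _pair_p_from_logs_unpaired(L1: np.ndarray, L2: np.ndarray) -> np.ndarray:
    """Welch p matrix for unpaired designs from the two groups' log
    matrices (n_g x K)."""
    def moments(L):
        m = L.mean(axis=0)
        S = np.cov(L, rowvar=False, ddof=1)
        v = np.clip(np.diag(S)[:, None] + np.diag(S)[None, :] - 2.0 * S, 0.0, None)
        return m[:, None] - m[None, :], v

    md1, v1 = moments(L1)
    md2, v2 = moments(L2)
    _, _, p = welch_t_from_moments(md1, v1, L1.shape[0], md2, v2, L2.shape[0])
    np.fill_diagonal(p, 1.0)
    return p


def pairwise_ratio_pvalues(t: AbundanceTable,
                           design: PairedDesign | UnpairedDesign) -> pd.DataFrame:
    """Symmetric matrix of two-sided p-values for the between-group change
    of every pairwise log ratio.  Requires an imputed, strictly positive
    table.  Per-sample rescaling leaves the matrix unchanged (ratios
    cancel any sample-level factor)."""
    vals = t.data.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("table contains missing cells; impute first")
    if (vals <= 0).any():
        raise ValueError("non-positive values; impute/clip upstream")
    if t.n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    L = np.log(vals)
    idx = {s: i for i, s in enumerate(t.sample_ids)}
    if isinstance(design, PairedDesign):
        D = L[[idx[a] for a in design.group1]] - L[[idx[b] for b in design.group2]]
        p = _pair_p_from_logs_paired(D)
    elif isinstance(design, UnpairedDesign):
        p = _pair_p_from_logs_unpaired(L[[idx[s] for s in design.group1]],
                                       L[[idx[s] for s in design.group2]])
    else:
        raise TypeError(f"unsupported design {type(design).__name__}")
    return pd.DataFrame(p, index=t.metabolite_ids, columns=t.metabolite_ids)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class RatioGraph:
    """Undirected metabolite graph; an edge means the pair's ratio is
    unchanged (p >= p_max_used)."""

    nodes: list[str]
    p_matrix: pd.DataFrame
    p_max_used: float
    components: list[set[str]]
    no_change_component: set[str]
    node_attributes: pd.DataFrame | None = None

    @property
    def edges(self) -> list[tuple[str, str]]:
        p = self.p_matrix.to_numpy()
        ii, jj = np.nonzero(np.triu(p >= self.p_max_used, k=1))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj)]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_frame(self) -> pd.DataFrame:
        rows = []
        for cid, comp in enumerate(self.components):
            for m in sorted(comp):
                rows.append({"metabolite_id": m, "component": cid,
                             "no_change": comp is self.no_change_component})
        return pd.DataFrame(rows).set_index("metabolite_id")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        comp_id = {m: cid for cid, comp in enumerate(self.components) for m in comp}
        for m in self.nodes:
            attrs = {"component": comp_id[m],
                     "no_change": m in self.no_change_component}
            if self.node_attributes is not None and m in self.node_attributes.index:
                row = self.node_attributes.loc[m]
                attrs.update({k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                              for k, v in row.items()})
            g.add_node(m, **attrs)
        g.add_edges_from(self.edges)
        return g


def build_graph(p_matrix: pd.DataFrame, p_max: float,
                node_attributes: pd.DataFrame | None = None) -> RatioGraph:
    """Keep edges with p >= p_max; extract connected components; the
    largest is the no-change component (ties broken toward the component
    containing the lexicographically smallest id, with a warning)."""
    nodes = list(p_matrix.index)
    p = p_matrix.to_numpy()
    adj = csr_matrix(np.triu(p >= p_max, k=1))
    n_comp, labels = connected_components(adj, directed=False)
    comps = [set() for _ in range(n_comp)]
    for m, lab in zip(nodes, labels):
        comps[lab].add(m)
    comps.sort(key=lambda c: (-len(c), min(c)))
    biggest = comps[0]
    if len(comps) > 1 and len(comps[1]) == len(biggest):
        warnings.warn("tie for the largest component; picked the one with "
                      "the lexicographically smallest member", stacklevel=2)
    return RatioGraph(nodes=nodes, p_matrix=p_matrix, p_max_used=p_max,
                      components=comps, no_change_component=biggest,
                      node_attributes=node_attributes)


def critical_threshold(p_matrix) -> float:
    """Largest p_max at which the graph stays connected: the bottleneck
    (minimum) edge p along the maximum spanning tree of the p matrix.
    The graph built at any threshold <= this value is connected; above
    it, at least two components appear."""
    p = np.asarray(p_matrix, dtype=float)
    # minimum spanning tree of (2 - p) = maximum spanning tree of p;
    # csgraph drops zero entries, and 2 - p >= 1 > 0 keeps every edge.
    w = 2.0 - p
    np.fill_diagonal(w, 0.0)
    tree = minimum_spanning_tree(w)
    c = 2.0 - tree.data.max()
    # snap to the exact matrix entry (the 2 - p transform costs one ulp)
    off = p[~np.eye(p.shape[0], dtype=bool)]
    return float(off[np.argmin(np.abs(off - c))])


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of p_max
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    n_sim: int
    k_nodes: int
    n_per_group: int
    design: str
    target_split_rate: float
    p_max_point: float
    p_max_ci_low: float
    p_max_operational: float
    achieved_split_rate: float
    seed: int
    critical_thresholds: np.ndarray = field(repr=False, default=None)


def _simulate_critical(rng: np.random.Generator, k: int, n_per_group: int,
                       design: str) -> float:
    if design == "paired":
        # pair differences of independent log-normals are normal on the
        # log scale; the t statistic is scale-free, so simulate them directly
        D = rng.standard_normal((n_per_group, k))
        p = _pair_p_from_logs_paired(D)
    else:
        L1 = rng.standard_normal((n_per_group, k))
        L2 = rng.standard_normal((n_per_group, k))
        p = _pair_p_from_logs_unpaired(L1, L2)
    return critical_threshold(p)


def _percentile_stat(crit_sorted: np.ndarray, target: float) -> float:
    # order statistic such that the fraction of simulations strictly
    # below it is at most `target`
    m = int(np.floor(target * len(crit_sorted)))
    return float(crit_sorted[m])


def calibrate_pmax(k_nodes: int, n_per_group: int, design: str = "unpaired",
                   n_sim: int = 10_000, target: float = 0.05,
                   seed: int = 0, n_boot: int = 2_000) -> CalibrationResult:
    """Calibrate the edge-removal threshold by null simulation.

    Each of ``n_sim`` null datasets (independent log-normal metabolites,
    matched node count and per-group sample size, paired or unpaired to
    match the analyzed comparison) yields its critical threshold; the
    point estimate of p_max is their ``target`` (5th) percentile, the CI
    comes from a bootstrap over the simulated thresholds, and the
    operational value floors the CI lower bound at two decimals.
    """
    if k_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if n_per_group < 3:
        raise ValueError("need at least 3 per group")
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if n_sim * target < 20:
        warnings.warn(f"n_sim={n_sim} is small for the {target:.0%} percentile; "
                      "the estimate will be noisy", stacklevel=2)

    rng = np.random.default_rng(seed)
    crit = np.array([_simulate_critical(rng, k_nodes, n_per_group, design)
                     for _ in range(n_sim)])
    crit_sorted = np.sort(crit)
    p_point = _percentile_stat(crit_sorted, target)

    boot = np.empty(n_boot)
    for b in range(n_boot):
        sample = np.sort(rng.choice(crit, size=n_sim, replace=True))
        boot[b] = _percentile_stat(sample, target)
    ci_low = float(np.quantile(boot, 0.025))

    operational = float(np.floor(ci_low * 100.0) / 100.0)
    achieved = float(np.mean(crit < operational))
    return CalibrationResult(
        n_sim=n_sim, k_nodes=k_nodes, n_per_group=n_per_group, design=design,
        target_split_rate=target, p_max_point=p_point, p_max_ci_low=ci_low,
        p_max_operational=operational, achieved_split_rate=achieved,
        seed=seed, critical_thresholds=crit)


def validate_split_rate(calibration: CalibrationResult, n_sim: int,
                        seed: int) -> float:
    """Fresh-seed check of the calibration's operating characteristic:
    the fraction of new null simulations whose graph splits into two or
    more components at the operational p_max."""
    rng = np.random.default_rng(seed)
    splits = 0
    for _ in range(n_sim):
        c = _simulate_critical(rng, calibration.k_nodes,
                               calibration.n_per_group, calibration.design)
        if c < calibration.p_max_operational:
            splits += 1
    return splits / n_sim


# ---------------------------------------------------------------------------
# restricted (candidate-pathway) networks
# ---------------------------------------------------------------------------

def restricted_network(t: AbundanceTable,
                       design: PairedDesign | UnpairedDesign,
                       annotation: pd.DataFrame,
                       sub_pathways: list[str],
                       n_sim: int = 2_000,
                       seed: int = 0,
                       ) -> tuple[RatioGraph, CalibrationResult]:
    """Ratio network restricted to metabolites of candidate sub-pathways,
    with its own calibration for the reduced node count.  Node attributes
    carry sub-pathway and microbial flags for display."""
    present = set(annotation["sub_pathway"])
    missing = [s for s in sub_pathways if s not in present]
    if missing:
        raise ValueError(f"sub-pathways absent from annotation: {missing}")
    members = [m for m in t.metabolite_ids
               if m in annotation.index
               and annotation.loc[m, "sub_pathway"] in set(sub_pathways)]
    if len(members) < 3:
        raise ValueError("fewer than 3 metabolites in the requested pathways")
    sub = t.select_metabolites(members)
    n_per_group = (design.n_pairs if isinstance(design, PairedDesign)
                   else min(len(design.group1), len(design.group2)))
    calib = calibrate_pmax(len(members), n_per_group, design=design.kind,
                           n_sim=n_sim, seed=seed)
    p = pairwise_ratio_pvalues(sub, design)
    attrs = annotation.loc[members, ["sub_pathway", "microbial"]]
    graph = build_graph(p, calib.p_max_operational, node_attributes=attrs)
    return graph, calib
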