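"""Step 1 — detectability screening.

UPLC-MS/MS leaves a metabolite's cell empty whenever its amount falls
below the limit of quantification, so the *pattern* of non-detection is
itself informative: a metabolite that is missing preferentially in one
group is present at lower amounts there.  Each metabolite's
detected/missing indicator is compared between groups with an exact test
(McNemar's exact binomial for paired designs, Fisher's exact 2x2 for
unpaired), under Bonferroni control over the analyzed metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import PairedDesign, UnpairedDesign
from .tables import AbundanceTable

__all__ = ["DetectTestResult", "detect_matrix", "mcnemar_exact",
           "fisher_exact_2x2", "detectability_screen", "results_frame"]


@dataclass(frozen=True)
class DetectTestResult:
    metabolite_id: str
    n_missing_g1: int
    n_missing_g2: int
    #: discordant pair counts (paired designs only): detected in g1 but
    #: missing in g2 (b), and the reverse (c)
    discordant_b: int | None
    discordant_c: int | None
    p: float
    significant_raw: bool
    significant_bonferroni: bool
    color: str  # green / orange / red, matching the profile-plot legend

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p out of [0, 1]")
        if self.color == "red" and not self.significant_raw:
            raise ValueError("red implies raw significance")


def detect_matrix(t: AbundanceTable) -> pd.DataFrame:
    """1 where an amount was detected, 0 where the cell is below LOQ."""
    return (~t.data.isna()).astype(int)


def mcnemar_exact(b: int, c: int) -> float:
    """Exact McNemar test: two-sided exact binomial comparing the
    proportion of discordant pairs in one direction to 0.5.

    Two-sided p is ``min(1, 2*min(P(X<=b), P(X>=b)))`` for
    ``X ~ Binomial(b+c, 1/2)``; with no discordant pairs, p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    lower = stats.binom.cdf(b, n, 0.5)
    upper = stats.binom.sf(b - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test for a 2x2 table, summing hypergeometric
    probabilities of all tables (at fixed margins) at most as probable as
    the observed one."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (arr < 0).any():
        raise ValueError("cell counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def detectability_screen(t: AbundanceTable,
                         design: PairedDesign | UnpairedDesign,
                         alpha: float = 0.05,
                         ) -> tuple[list[DetectTestResult], pd.DataFrame]:
    """Per-metabolite exact test of differential detectability, with
    Bonferroni control over the ``M`` analyzed metabolites.

    Returns the per-metabolite results and a summary of the distinct
    missingness profiles — ordered pairs (missing in group 1, missing in
    group 2) with the number of metabolites showing each — the per-line
    display of the detectability profile figures.

    Colors follow the figure legend: green = not significant, orange =
    p < alpha but not after correction, red = significant after
    Bonferroni correction (p < alpha / M).
    """
    M = t.n_metabolites
    if M < 1:
        raise ValueError("no metabolites to analyze")
    cutoff = alpha / M
    det = detect_matrix(t)

    results: list[DetectTestResult] = []
    if isinstance(design, PairedDesign):
        g1 = det.loc[design.group1].to_numpy()
        g2 = det.loc[design.group2].to_numpy()
        b_all = ((g1 == 1) & (g2 == 0)).sum(axis=0)
        c_all = ((g1 == 0) & (g2 == 1)).sum(axis=0)
        miss1 = (g1 == 0).sum(axis=0)
        miss2 = (g2 == 0).sum(axis=0)
        for j, m in enumerate(t.metabolite_ids):
            p = mcnemar_exact(int(b_all[j]), int(c_all[j]))
            results.append(_mk_result(m, int(miss1[j]), int(miss2[j]),
                                      int(b_all[j]), int(c_all[j]), p,
                                      alpha, cutoff))
    elif isinstance(design, UnpairedDesign):
        g1 = det.loc[list(design.group1)].to_numpy()
        g2 = det.loc[list(design.group2)].to_numpy()
        n1, n2 = g1.shape[0], g2.shape[0]
        miss1 = (g1 == 0).sum(axis=0)
        miss2 = (g2 == 0).sum(axis=0)
        for j, m in enumerate(t.metabolite_ids):
            tab = [[n1 - miss1[j], miss1[j]], [n2 - miss2[j], miss2[j]]]
            p = fisher_exact_2x2(tab)
            results.append(_mk_result(m, int(miss1[j]), int(miss2[j]),
                                      None, None, p, alpha, cutoff))
    else:
        raise TypeError(f"unsupported design {type(design).__name__}")

    profiles = (pd.DataFrame({"n_missing_g1": [r.n_missing_g1 for r in results],
                              "n_missing_g2": [r.n_missing_g2 for r in results]})
                .value_counts().rename("n_metabolites").reset_index()
                .sort_values(["n_missing_g1", "n_missing_g2"])
                .reset_index(drop=True))
    return results, profiles


def _mk_result(m, miss1, miss2, b, c, p, alpha, cutoff) -> DetectTestResult:
    sig_raw = p < alpha
    sig_bonf = p < cutoff
    color = "red" if sig_bonf else ("orange" if sig_raw else "green")
    return DetectTestResult(m, miss1, miss2, b, c, p, sig_raw, sig_bonf, color)


def results_frame(results: list[DetectTestResult]) -> pd.DataFrame:
    """One row per metabolite, for CSV export."""
    return pd.DataFrame([vars(r) for r in results]).set_index("metabolite_id")
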