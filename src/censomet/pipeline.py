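"""Orchestration of the full analysis over one or two cohorts.

The analysis runs exploratory-first: filters are learned on the
exploratory cohort and transferred verbatim to the confirmatory cohort,
which re-runs the identical procedure.  Stages: detectability screen ->
missingness filter -> below-LOQ imputation -> univariate comparison
(optionally covariate-adjusted) -> calibrated ratio network (full and
candidate-pathway restricted) -> multivariate selection and ORA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import censoring, detectability, multivariate, ratio_network, univariate
from .design import PairedDesign, UnpairedDesign, build_design
from .synthetic import CANDIDATE_SUB_PATHWAYS
from .tables import AbundanceTable, SampleInfo

__all__ = ["ComparisonPlan", "PipelineConfig", "run_pipeline", "match_1to1",
           "hclust_ward", "radar_table"]


@dataclass(frozen=True)
class ComparisonPlan:
    """Which comparison to run and how.

    The recipient-vs-recipient comparison considers natural metabolites
    only (bacteria/fungi-derived included, drugs and assimilated
    compounds excluded): after transplantation all recipients change
    their intake behaviour, so xenobiotic differences are uninformative.
    """

    name: Literal["D_vs_Rs", "D_vs_Ra", "Rs_vs_Ra"]
    design: Literal["paired", "unpaired"]
    metabolite_scope: Literal["all", "natural_only"] = "all"
    adjustment: bool = False
    sensitivity: Literal["none", "matched_1to1", "all_donors"] = "none"

    def __post_init__(self):
        if self.name == "Rs_vs_Ra" and self.metabolite_scope != "natural_only":
            raise ValueError("Rs_vs_Ra must exclude xenobiotics "
                             "(metabolite_scope='natural_only')")
        expected = "unpaired" if self.name == "Rs_vs_Ra" else "paired"
        if self.design != expected:
            raise ValueError(f"{self.name} is a {expected} comparison")


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    missing_threshold: float = 0.5
    imputation: censoring.ImputationConfig = field(
        default_factory=censoring.ImputationConfig)
    calib_n_sim: int = 2_000
    restricted_pathways: tuple[str, ...] = CANDIDATE_SUB_PATHWAYS
    run_full_network: bool = True
    full_network_n_sim: int = 300
    n_comp: int = 2
    keep_per_comp: int = 20
    seed: int = 0


def _scoped_table(t: AbundanceTable, annotation: pd.DataFrame,
                  scope: str) -> AbundanceTable:
    if scope == "all":
        return t
    natural = [m for m in t.metabolite_ids
               if m in annotation.index and not annotation.loc[m, "xenobiotic"]]
    return t.select_metabolites(natural)


def _design_for(plan: ComparisonPlan, info: Sequence[SampleInfo]):
    if plan.name == "Rs_vs_Ra" and plan.sensitivity == "matched_1to1":
        cases = [s for s in info if s.group == "Ra"]
        controls = [s for s in info if s.group == "Rs"]
        pairing = match_1to1(cases, controls)
        return PairedDesign(pairs=tuple((c, k) for c, k in pairing["pairs"]),
                            labels=("Ra", "Rs"))
    return build_design(list(info), plan.name)


def run_pipeline(plan: ComparisonPlan,
                 cohorts: dict[str, tuple[AbundanceTable, list[SampleInfo]]],
                 annotation: pd.DataFrame,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the full procedure.

    ``cohorts`` maps cohort name to (table, metadata); the first entry is
    the exploratory cohort whose learned exclusion list is applied to all
    others.  Returns a report bundle: per-cohort stage outputs plus a run
    manifest of seeds, thresholds and stage-wise metabolite counts.
    """
    config = config or PipelineConfig()
    names = list(cohorts)
    if not names:
        raise ValueError("no cohorts supplied")
    for name, (t, info) in cohorts.items():
        known = {s.sample_id for s in info}
        missing = [s for s in t.sample_ids if s not in known]
        if missing:
            raise ValueError(f"cohort {name!r}: samples without metadata: "
                             f"{missing[:5]}")

    bundle: dict = {"plan": plan, "cohorts": {}, "manifest": {
        "comparison": plan.name, "design": plan.design,
        "scope": plan.metabolite_scope, "seed": config.seed,
        "exploratory_cohort": names[0], "counts": {}}}

    discarded_ref: list[str] | None = None
    for name in names:
        table, info = cohorts[name]
        scoped = _scoped_table(table, annotation, plan.metabolite_scope)
        design = _design_for(plan, info)
        used = (set(design.group1) | set(design.group2))
        scoped = scoped.select_samples([s for s in scoped.sample_ids if s in used])
        res: dict = {}

        det_results, profiles = detectability.detectability_screen(
            scoped, design, alpha=config.alpha)
        res["detectability"] = detectability.results_frame(det_results)
        res["detectability_profiles"] = profiles

        groups = {s: design.labels[0] for s in design.group1}
        groups.update({s: design.labels[1] for s in design.group2})
        if discarded_ref is None:  # learn on the exploratory cohort only
            _, discarded_ref = censoring.filter_by_missingness(
                scoped, groups, threshold=config.missing_threshold)
        filtered = censoring.apply_filter_list(scoped, discarded_ref)
        imputed = censoring.impute_blq(filtered, config.imputation)
        res["discarded"] = list(discarded_ref)

        uni = univariate.compare_groups(imputed, design, alpha=config.alpha)
        res["univariate"] = univariate.results_frame(uni)
        res["volcano"] = univariate.volcano_table(uni)
        if plan.adjustment:
            adj = univariate.adjusted_compare(imputed, design, list(info),
                                              alpha=config.alpha)
            res["univariate_adjusted"] = univariate.results_frame(adj)

        n_per_group = (design.n_pairs if isinstance(design, PairedDesign)
                       else min(len(design.group1), len(design.group2)))
        if config.run_full_network:
            calib = ratio_network.calibrate_pmax(
                imputed.n_metabolites, n_per_group, design=design.kind,
                n_sim=config.full_network_n_sim, seed=config.seed)
            pmat = ratio_network.pairwise_ratio_pvalues(imputed, design)
            graph = ratio_network.build_graph(pmat, calib.p_max_operational)
            res["network"] = graph
            res["network_calibration"] = calib
        rgraph, rcalib = ratio_network.restricted_network(
            imputed, design, annotation, list(config.restricted_pathways),
            n_sim=config.calib_n_sim, seed=config.seed)
        res["restricted_network"] = rgraph
        res["restricted_calibration"] = rcalib

        logz = _zscored_logs(imputed)
        y = np.array([groups[s] for s in logz.index])
        res["pca_scores"], res["pca_loadings"], res["pca_var"] = \
            multivariate.pca(logz, n_comp=config.n_comp)
        sels = multivariate.splsda(logz, y, n_comp=config.n_comp,
                                   keep_per_comp=min(config.keep_per_comp,
                                                     logz.shape[1]))
        res["splsda"] = sels
        selected = sorted({m for s in sels for m in s.selected_ids})
        res["splsda_selected"] = selected
        res["lasso"] = multivariate.lasso_logistic(logz, y)
        res["ora"] = pd.DataFrame(
            [vars(r) for r in multivariate.ora(
                set(selected), annotation, set(imputed.metabolite_ids))])

        sig = res["univariate"][res["univariate"].significant].index.tolist()
        if len(sig) >= 2:
            Z, order, heat = hclust_ward(logz[sig])
            res["heatmap"] = heat
        bundle["cohorts"][name] = res
        bundle["manifest"]["counts"][name] = {
            "metabolites_screened": scoped.n_metabolites,
            "metabolites_discarded": len(discarded_ref),
            "metabolites_analyzed": imputed.n_metabolites,
            "bonferroni_threshold": univariate.bonferroni_threshold(
                config.alpha, imputed.n_metabolites),
            "significant_univariate": len(sig),
            "detectability_red": int((res["detectability"].color == "red").sum()),
            "restricted_p_max": rcalib.p_max_operational,
        }

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _zscored_logs(t: AbundanceTable) -> pd.DataFrame:
    L = np.log(t.data)
    sd = L.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (L - L.mean(axis=0)) / sd


def _write_bundle(bundle: dict, outdir: Path) -> None:
    import networkx as nx

    outdir.mkdir(parents=True, exist_ok=True)
    for name, res in bundle["cohorts"].items():
        d = outdir / name
        d.mkdir(exist_ok=True)
        for key in ("detectability", "detectability_profiles", "univariate",
                    "univariate_adjusted", "volcano", "ora"):
            if key in res:
                res[key].to_csv(d / f"{key}.csv")
        pd.Series(res["discarded"], name="metabolite_id").to_csv(
            d / "discarded.csv", index=False)
        for key in ("network", "restricted_network"):
            if key in res:
                res[key].component_frame().to_csv(d / f"{key}_components.csv")
        nx.write_graphml(res["restricted_network"].to_networkx(),
                         d / "restricted_network.graphml")
        res["pca_scores"].to_csv(d / "pca_scores.csv")
        pd.Series(res["splsda_selected"], name="metabolite_id").to_csv(
            d / "splsda_selected.csv", index=False)
        pd.Series(res["lasso"]["selected"], name="metabolite_id").to_csv(
            d / "lasso_selected.csv", index=False)
        if "heatmap" in res:
            res["heatmap"].to_csv(d / "heatmap.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)


# ---------------------------------------------------------------------------
# 1:1 matching sensitivity analysis
# ---------------------------------------------------------------------------

def match_1to1(cases: list[SampleInfo], controls: list[SampleInfo]) -> dict:
    """Greedy 1:1 matching of each case to the unused control of the same
    sex with the closest age; when no same-sex control remains, the
    closest-age control of either sex is taken and counted as a sex
    mismatch.  Cases are matched in descending-age order (fixed order for
    determinism).  Returns the pairing plus mismatch count and the range
    of within-pair age differences (case minus control).
    """
    if len(controls) < len(cases):
        raise ValueError("not enough controls for 1:1 matching")
    available = list(controls)
    pairs: list[tuple[str, str]] = []
    mismatches = 0
    age_diffs: list[float] = []
    for case in sorted(cases, key=lambda s: (-s.age, s.sample_id)):
        same_sex = [c for c in available if c.sex == case.sex]
        pool = same_sex if same_sex else available
        best = min(pool, key=lambda c: (abs(c.age - case.age), c.sample_id))
        if not same_sex:
            mismatches += 1
        available.remove(best)
        pairs.append((case.sample_id, best.sample_id))
        age_diffs.append(case.age - best.age)
    return {"pairs": pairs, "sex_mismatches": mismatches,
            "age_diff_range": (min(age_diffs), max(age_diffs)) if age_diffs else None}


# ---------------------------------------------------------------------------
# clustering / display tables
# ---------------------------------------------------------------------------

def hclust_ward(X: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Ward-linkage hierarchical clustering of samples on Euclidean
    distances over z-scored log values.  Returns the linkage matrix, the
    leaf order (sample ids) and the reordered heatmap table."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    if X.shape[0] < 2:
        return np.empty((0, 4)), list(X.index), X.copy()
    Z = linkage(X.to_numpy(), method="ward")
    order = [X.index[i] for i in leaves_list(Z)]
    return Z, order, X.loc[order]


def radar_table(t: AbundanceTable, groups: dict[str, str],
                annotation: pd.DataFrame, sub_pathways: Sequence[str],
                numerator: str = "Ra", denominator: str = "Rs") -> pd.DataFrame:
    """Per-metabolite ratio of raw-scale group means (numerator group over
    denominator group) with dispersions, restricted to the requested
    sub-pathways; the no-change reference value is 1."""
    num_samples = [s for s, g in groups.items() if g == numerator]
    den_samples = [s for s, g in groups.items() if g == denominator]
    if not num_samples or not den_samples:
        raise ValueError("both groups must be present")
    members = [m for m in t.metabolite_ids
               if m in annotation.index
               and annotation.loc[m, "sub_pathway"] in set(sub_pathways)]
    sub = t.data[members]
    mean_num = sub.loc[num_samples].mean(axis=0)
    mean_den = sub.loc[den_samples].mean(axis=0)
    out = pd.DataFrame({
        "sub_pathway": annotation.loc[members, "sub_pathway"],
        "mean_num": mean_num, "sd_num": sub.loc[num_samples].std(axis=0, ddof=1),
        "mean_den": mean_den, "sd_den": sub.loc[den_samples].std(axis=0, ddof=1),
        "ratio": mean_num / mean_den.replace(0.0, np.nan),
        "zero_denominator": mean_den == 0.0,
        "reference": 1.0,
    })
    return out
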