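"""Synthetic paired-cohort generator.

Emulates the statistical structure the downstream analysis assumes:
log-normal metabolite amounts on an integer-like raw-area scale, paired
donor/recipient subjects with a shared per-pair log intercept, group
effects on the log scale, per-metabolite left-censoring at an unknown
LOQ (realised as a quantile of the generated values), and multiplicative
run-day block factors.  Ground truth (which metabolites changed, and the
per-metabolite LOQ) is returned alongside so recovery can be scored.

What it does *not* emulate: chromatographic drift, adducts, isotope
patterns, or correlated metabolite modules beyond the pair intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleInfo

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "generate_null",
           "CANDIDATE_SUB_PATHWAYS"]

#: The six candidate pathway groups used for restricted ratio networks.
CANDIDATE_SUB_PATHWAYS = (
    "polyamine metabolism",
    "tryptophan metabolism",
    "urea cycle; arginine & proline metabolism",
    "bacterial or fungal",
    "plasmalogen or lysoplasmalogen",
    "primary or secondary bile acid metabolism",
)

_FILLER_SUB_PATHWAYS = (
    ("fatty acid metabolism", "Lipid", False, False),
    ("phospholipid metabolism", "Lipid", False, False),
    ("sphingolipid metabolism", "Lipid", False, False),
    ("branched chain amino acid metabolism", "Amino Acid", False, False),
    ("taurine metabolism", "Amino Acid", False, False),
    ("purine metabolism", "Nucleotide", False, False),
    ("TCA cycle", "Energy", False, False),
    ("hemoglobin and porphyrin metabolism", "Cofactors and Vitamins", False, False),
    ("xanthine metabolism", "Xenobiotics", False, True),
    ("food component or plant", "Xenobiotics", True, True),
    ("drug", "Xenobiotics", False, True),
)

_CANDIDATE_META = {
    "polyamine metabolism": ("Amino Acid", False, False),
    "tryptophan metabolism": ("Amino Acid", True, False),
    "urea cycle; arginine & proline metabolism": ("Amino Acid", False, False),
    "bacterial or fungal": ("Xenobiotics", True, False),
    "plasmalogen or lysoplasmalogen": ("Lipid", False, False),
    "primary or secondary bile acid metabolism": ("Lipid", True, False),
}

#: latent log amounts are scaled to integer-like raw areas so that the
#: additive imputation noise (variance 100) is small relative to signal.
RAW_SCALE = 1.0e4


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the deposited cohorts' shape: ~650 metabolites,
    ~40 donor-recipient sibling pairs, roughly 40% of recipients at acute
    GvHD onset, unit log-scale dispersion, moderate within-pair
    correlation, 20% left-censoring and a handful of run-day blocks.
    """

    n_pairs: int = 40
    n_metabolites: int = 650
    frac_gvhd: float = 0.4
    mu_log: float | Sequence[float] = 0.0
    sigma_log: float = 1.0
    pair_corr: float = 0.5
    #: metabolite id -> (lfc recipient vs donor, lfc Ra vs Rs), log scale
    effect_map: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    censor_quantile: float = 0.2
    n_rundays: int = 4
    runday_sigma: float = 0.25
    #: optional explicit annotation plan:
    #: metabolite id -> (super_pathway, sub_pathway, microbial, xenobiotic)
    pathway_plan: Mapping[str, tuple[str, str, bool, bool]] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.censor_quantile < 1):
            raise ValueError("censor_quantile must be in [0, 1)")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if not (0 <= self.pair_corr < 1):
            raise ValueError("pair_corr must be in [0, 1)")
        if not (0 <= self.frac_gvhd <= 1):
            raise ValueError("frac_gvhd must be a proportion")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort."""

    lfc_recipient: dict[str, float]
    lfc_gvhd: dict[str, float]
    loq_per_metabolite: dict[str, float]

    @property
    def changed_ids(self) -> set[str]:
        """Metabolites with a nonzero effect in either contrast."""
        return ({m for m, v in self.lfc_recipient.items() if v != 0}
                | {m for m, v in self.lfc_gvhd.items() if v != 0})


def _default_annotation(met_ids: Sequence[str]) -> pd.DataFrame:
    subs = list(CANDIDATE_SUB_PATHWAYS) + [s for s, *_ in _FILLER_SUB_PATHWAYS]
    meta = dict(_CANDIDATE_META)
    meta.update({s: (sup, mic, xen) for s, sup, mic, xen in _FILLER_SUB_PATHWAYS})
    rows = []
    for i, m in enumerate(met_ids):
        sub = subs[i % len(subs)]
        sup, microbial, xeno = meta[sub]
        rows.append({"metabolite_id": m, "super_pathway": sup,
                     "sub_pathway": sub, "microbial": microbial,
                     "xenobiotic": xeno})
    return pd.DataFrame(rows).set_index("metabolite_id")


def generate_cohort(cfg: SimConfig
                    ) -> tuple[AbundanceTable, list[SampleInfo], pd.DataFrame, SimTruth]:
    """Generate one paired cohort: donors plus recipients, a fraction of
    whom are at GvHD onset, with left-censored integer-like raw areas.

    Identical ``cfg`` (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    K, P = cfg.n_metabolites, cfg.n_pairs
    met_ids = [f"M{i:04d}" for i in range(K)]
    unknown = set(cfg.effect_map) - set(met_ids)
    if unknown:
        raise ValueError(f"effect_map refers to unknown metabolites: {sorted(unknown)[:5]}")

    mu = np.broadcast_to(np.asarray(cfg.mu_log, dtype=float), (K,))
    lfc_rec = np.array([cfg.effect_map.get(m, (0.0, 0.0))[0] for m in met_ids])
    lfc_gvhd = np.array([cfg.effect_map.get(m, (0.0, 0.0))[1] for m in met_ids])

    n_ra = int(round(cfg.frac_gvhd * P))
    ra_pairs = rng.choice(P, size=n_ra, replace=False)
    is_ra = np.zeros(P, dtype=bool)
    is_ra[ra_pairs] = True

    # shared per-pair log intercept induces the within-pair correlation
    rho, sig = cfg.pair_corr, cfg.sigma_log
    pair_int = rng.normal(0.0, 1.0, size=P)
    log_donor = (mu[None, :]
                 + np.sqrt(rho) * sig * pair_int[:, None]
                 + np.sqrt(1 - rho) * sig * rng.normal(size=(P, K)))
    log_recip = (mu[None, :]
                 + np.sqrt(rho) * sig * pair_int[:, None]
                 + np.sqrt(1 - rho) * sig * rng.normal(size=(P, K)))
    log_recip = log_recip + lfc_rec[None, :] + np.where(is_ra[:, None], lfc_gvhd[None, :], 0.0)

    donor_ids = [f"D{p:03d}" for p in range(P)]
    recip_ids = [f"R{p:03d}" for p in range(P)]
    sample_ids = donor_ids + recip_ids
    log_all = np.vstack([log_donor, log_recip])

    # run-day blocks assigned round-robin, with a multiplicative factor
    rundays = [f"day{(i % cfg.n_rundays) + 1}" for i in range(2 * P)]
    block_factor = np.exp(rng.normal(0.0, cfg.runday_sigma, size=cfg.n_rundays))
    factors = np.array([block_factor[i % cfg.n_rundays] for i in range(2 * P)])

    raw = np.rint(np.exp(log_all) * RAW_SCALE * factors[:, None])
    raw = np.maximum(raw, 1.0)

    # per-metabolite LOQ at the censoring quantile of the generated values
    loq = np.quantile(raw, cfg.censor_quantile, axis=0)
    censored = raw < loq[None, :]
    values = raw.copy()
    values[censored] = np.nan

    table = AbundanceTable(
        pd.DataFrame(values, index=sample_ids, columns=met_ids),
        provenance=f"synthetic cohort (seed={cfg.seed})",
    )

    donor_age = np.clip(rng.normal(50, 10, size=P), 20, 70)
    recip_age = np.clip(donor_age + rng.normal(0, 5, size=P), 18, 75)
    sexes = rng.choice(["M", "F"], size=2 * P)
    bmi = np.clip(rng.normal(25, 4, size=2 * P), 16, 42)

    info: list[SampleInfo] = []
    for p in range(P):
        info.append(SampleInfo(
            sample_id=donor_ids[p], subject_role="donor", group="D",
            pair_id=f"P{p:03d}", age=float(donor_age[p]), sex=str(sexes[p]),
            bmi=float(bmi[p]), runday=rundays[p]))
    for p in range(P):
        info.append(SampleInfo(
            sample_id=recip_ids[p], subject_role="recipient",
            group="Ra" if is_ra[p] else "Rs",
            pair_id=f"P{p:03d}", age=float(recip_age[p]), sex=str(sexes[P + p]),
            bmi=float(bmi[P + p]), runday=rundays[P + p]))

    if cfg.pathway_plan is not None:
        rows = [{"metabolite_id": m, "super_pathway": v[0], "sub_pathway": v[1],
                 "microbial": v[2], "xenobiotic": v[3]}
                for m, v in cfg.pathway_plan.items()]
        annotation = pd.DataFrame(rows).set_index("metabolite_id")
    else:
        annotation = _default_annotation(met_ids)

    truth = SimTruth(
        lfc_recipient={m: float(v) for m, v in zip(met_ids, lfc_rec) if v != 0},
        lfc_gvhd={m: float(v) for m, v in zip(met_ids, lfc_gvhd) if v != 0},
        loq_per_metabolite={m: float(v) for m, v in zip(met_ids, loq)},
    )
    return table, info, annotation, truth


def generate_null(n_per_group: int, k: int, seed: int, sigma_log: float = 1.0
                  ) -> tuple[AbundanceTable, dict[str, str]]:
    """Two independent groups of independent log-normal metabolites with no
    group effect — the null model the ratio-network calibration assumes."""
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    if k < 2:
        raise ValueError("need at least 2 metabolites")
    rng = np.random.default_rng(seed)
    log_all = sigma_log * rng.normal(size=(2 * n_per_group, k))
    raw = np.maximum(np.rint(np.exp(log_all) * RAW_SCALE), 1.0)
    sample_ids = [f"N{i:03d}" for i in range(2 * n_per_group)]
    met_ids = [f"M{i:04d}" for i in range(k)]
    table = AbundanceTable(pd.DataFrame(raw, index=sample_ids, columns=met_ids),
                           provenance=f"null simulation (seed={seed})")
    groups = {sid: ("g1" if i < n_per_group else "g2")
              for i, sid in enumerate(sample_ids)}
    return table, groups
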