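"""Missingness filtering and below-LOQ imputation.

Metabolites undetectable in at least half the subjects — overall or in
any single group — carry too little quantitative information and are
discarded.  The remaining below-LOQ cells are imputed with a fraction
(default one half) of the metabolite's minimal observed value; a small
Gaussian noise (default variance 100, on the raw-area scale) breaks the
ties that constant imputation would create in variance estimates, and
the result is rounded to the nearest integer to keep the character of
raw peak areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = ["ImputationConfig", "filter_by_missingness", "apply_filter_list",
           "impute_blq", "SENSITIVITY_FRACTIONS"]

#: fractions of the minimal observed value swept in the sensitivity analysis
SENSITIVITY_FRACTIONS = (0.25, 0.5, 0.75, 0.9, 0.95, 0.99, 1.0)


@dataclass(frozen=True)
class ImputationConfig:
    """Parameters of below-LOQ imputation.

    fraction : multiple of the per-metabolite minimal observed value used
        as the imputed centre (0.5 = the usual LOQ/2 surrogate).
    noise_variance : variance of the additive Gaussian tie-breaking noise,
        on the raw-area scale.
    round_to_integer : round imputed cells to the nearest integer.
    """

    fraction: float = 0.5
    noise_variance: float = 100.0
    round_to_integer: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")
        if self.fraction not in SENSITIVITY_FRACTIONS:
            warnings.warn(
                f"fraction {self.fraction} is outside the standard "
                f"sensitivity set {SENSITIVITY_FRACTIONS}", stacklevel=2)


def filter_by_missingness(t: AbundanceTable,
                          groups: Mapping[str, str] | pd.Series,
                          threshold: float = 0.5,
                          ) -> tuple[list[str], list[str]]:
    """Split metabolite ids into (kept, discarded).

    A metabolite is discarded iff its missing fraction is at least
    ``threshold`` overall **or** within any single group.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing_samples = [s for s in t.sample_ids if s not in groups.index]
    if missing_samples:
        raise ValueError(f"samples without group label: {missing_samples[:5]}")
    groups = groups.loc[t.sample_ids]
    if (groups.value_counts() == 0).any() or groups.nunique() < 1:
        raise ValueError("empty group")

    miss = t.data.isna()
    discard = miss.mean(axis=0) >= threshold
    for _, idx in groups.groupby(groups).groups.items():
        discard |= miss.loc[idx].mean(axis=0) >= threshold
    kept = [m for m in t.metabolite_ids if not discard[m]]
    discarded = [m for m in t.metabolite_ids if discard[m]]
    return kept, discarded


def apply_filter_list(t: AbundanceTable, discarded: Sequence[str]) -> AbundanceTable:
    """Drop the given metabolites — used to transfer the exclusion list
    learned on the exploratory cohort onto the confirmatory cohort."""
    unknown = [m for m in discarded if m not in t.data.columns]
    if unknown:
        raise KeyError(f"unknown metabolite ids: {unknown[:5]}")
    kept = [m for m in t.metabolite_ids if m not in set(discarded)]
    if not kept:
        raise ValueError("filter would discard every metabolite")
    return AbundanceTable(t.data[kept], t.provenance)


def impute_blq(t: AbundanceTable, cfg: ImputationConfig = ImputationConfig()
               ) -> AbundanceTable:
    """Impute below-LOQ cells.

    Each missing cell becomes ``fraction * min(observed values of that
    metabolite) + N(0, noise_variance)``, rounded to the nearest integer
    (if configured) and clipped to be at least 1 so logs stay defined.
    Detected cells are never altered; identical seeds give identical
    output.
    """
    data = t.data.to_numpy().copy()
    miss = np.isnan(data)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [m for m, a in zip(t.metabolite_ids, all_missing) if a]
        raise ValueError(
            f"metabolites with no detected value must be filtered first: {bad[:5]}")
    if not miss.any():
        return AbundanceTable(t.data.copy(), t.provenance)

    rng = np.random.default_rng(cfg.seed)
    mins = np.nanmin(data, axis=0)
    centre = cfg.fraction * mins
    rows, cols = np.nonzero(miss)
    imputed = centre[cols]
    if cfg.noise_variance > 0:
        imputed = imputed + rng.normal(0.0, np.sqrt(cfg.noise_variance),
                                       size=imputed.shape)
    if cfg.round_to_integer:
        imputed = np.rint(imputed)
    imputed = np.maximum(imputed, 1.0)
    data[rows, cols] = imputed
    return AbundanceTable(pd.DataFrame(data, index=t.sample_ids,
                                       columns=t.metabolite_ids),
                          t.provenance)
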