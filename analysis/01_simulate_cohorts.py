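#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

Creates an exploratory and a confirmatory paired cohort (donors plus
recipients, ~40% of recipients at acute GvHD onset) with a shared ground
truth: 20 metabolites shifted between recipients and donors and 12
additional metabolites shifted at GvHD onset, 20% left-censoring, and
4 run-day blocks.  Writes the abundance/metadata/annotation/truth CSVs
that the later numbered scripts consume.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from censomet.synthetic import SimConfig, generate_cohort
from censomet.tables import write_abundance, write_sample_info

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEEDS = {"exploratory": 1_001, "confirmatory": 2_002}
N_METABOLITES = 650
N_PAIRS = {"exploratory": 22, "confirmatory": 28}


def shared_effect_map(rng):
    met = [f"M{i:04d}" for i in range(N_METABOLITES)]
    recip = rng.choice(N_METABOLITES, 20, replace=False)
    gvhd = rng.choice(N_METABOLITES, 12, replace=False)
    eff = {}
    for j in recip:
        eff[met[j]] = (float(rng.choice([-1, 1]) * rng.uniform(1.5, 2.5)), 0.0)
    for j in gvhd:
        base = eff.get(met[j], (0.0, 0.0))[0]
        eff[met[j]] = (base, float(rng.choice([-1, 1]) * rng.uniform(1.5, 2.5)))
    return eff


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    eff = shared_effect_map(np.random.default_rng(77))
    for name, seed in SEEDS.items():
        cfg = SimConfig(n_pairs=N_PAIRS[name], n_metabolites=N_METABOLITES,
                        frac_gvhd=0.4, censor_quantile=0.2, effect_map=eff,
                        seed=seed)
        table, info, annotation, truth = generate_cohort(cfg)
        d = OUT / name
        d.mkdir(exist_ok=True)
        write_abundance(table, d / "abundance.csv")
        write_sample_info(info, d / "samples.csv")
        annotation.to_csv(d / "annotation.csv")
        pd.DataFrame([
            {"metabolite_id": m,
             "lfc_recipient": truth.lfc_recipient.get(m, 0.0),
             "lfc_gvhd": truth.lfc_gvhd.get(m, 0.0),
             "loq": truth.loq_per_metabolite[m]}
            for m in table.metabolite_ids]).to_csv(d / "truth.csv", index=False)
        n_missing = int(table.data.isna().sum().sum())
        print(f"{name}: {table.n_samples} samples x {table.n_metabolites} "
              f"metabolites, {n_missing} censored cells "
              f"({n_missing / table.data.size:.1%}), "
              f"{len(truth.changed_ids)} truly changed metabolites")


if __name__ == "__main__":
    main()
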