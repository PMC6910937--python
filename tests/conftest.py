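import numpy as np
import pandas as pd
import pytest

from censomet.synthetic import SimConfig, generate_cohort
from censomet.tables import AbundanceTable


@pytest.fixture
def small_table():
    """3 samples x 3 metabolites with one missing cell."""
    df = pd.DataFrame(
        [[100.0, 200.0, 50.0],
         [110.0, np.nan, 60.0],
         [90.0, 220.0, 55.0]],
        index=["S1", "S2", "S3"], columns=["A", "B", "C"])
    return AbundanceTable(df, provenance="toy")


@pytest.fixture(scope="session")
def null_cohort():
    """Medium synthetic paired cohort with no group effects."""
    cfg = SimConfig(n_pairs=20, n_metabolites=60, frac_gvhd=0.5,
                    censor_quantile=0.1, seed=42)
    return generate_cohort(cfg)


def make_effect_cohort(n_pairs=30, n_metabolites=80, n_shifted=8,
                       lfc_low=1.5, lfc_high=2.5, censor_quantile=0.2,
                       frac_gvhd=0.0, seed=7):
    """Cohort with a known set of recipient-vs-donor shifts."""
    rng = np.random.default_rng(seed)
    met = [f"M{i:04d}" for i in range(n_metabolites)]
    shifted = rng.choice(n_metabolites, n_shifted, replace=False)
    effect_map = {met[j]: (float(rng.choice([-1, 1]) * rng.uniform(lfc_low, lfc_high)), 0.0)
                  for j in shifted}
    cfg = SimConfig(n_pairs=n_pairs, n_metabolites=n_metabolites,
                    frac_gvhd=frac_gvhd, censor_quantile=censor_quantile,
                    effect_map=effect_map, seed=seed)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    return make_effect_cohort()
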