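import numpy as np
import pandas as pd
import pytest

import bioaging_mixtures as bm
from bioaging_mixtures import synthdata


def score_clocks(table: pd.DataFrame) -> pd.DataFrame:
    """Append both aging outcomes to a generated cohort."""
    table = table.copy()
    panel = table[list(synthdata.KDM_BIOMARKERS)]
    training = bm.fit_kdm(panel, table["age"], names=list(synthdata.KDM_BIOMARKERS))
    table["kdm_biological_age"] = bm.kdm_biological_age(
        panel, table["age"], training)
    table["phenotypic_age"] = bm.phenoage_table(
        table, warn_implausible=False)["phenotypic_age"]
    return table


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort (no exposure effects), n=800, with scored outcomes."""
    config = bm.SimConfig(n_participants=800, seed=20250901)
    table, truth = bm.generate_cohort(config)
    return score_clocks(table), truth


@pytest.fixture(scope="session")
def small_exposed(small_cohort):
    table, _ = small_cohort
    return bm.build_exposures(
        table, synthdata.ANALYTES,
        standardize_covariates=["age", "sex", "race", "bmi_cat"],
    )
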