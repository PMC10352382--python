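import numpy as np
import pandas as pd
import pytest

from twinfam import datasets, simulate


@pytest.fixture(scope="session")
def mvn_table_small():
    """600 + 600 MVN families at the published dyad correlations."""
    return simulate.sample_families_mvn(
        n_mz=600,
        n_dz=600,
        corr_mz=datasets.family_correlation_matrix("MZ"),
        corr_dz=datasets.family_correlation_matrix("DZ"),
        seed=101,
    )


@pytest.fixture(scope="session")
def cohort_small():
    """Forward-simulated study-shaped cohort, 120 + 120 families."""
    cfg = simulate.default_config(seed=202, n_mz_families=120, n_dz_families=120)
    table, provenance = simulate.simulate_population(cfg)
    return table, provenance


def make_family_table(records):
    """Build a long-format family table from (family_id, role, zygosity, sex, age, ea) tuples."""
    return pd.DataFrame(
        records,
        columns=["family_id", "role", "zygosity", "sex", "age", "ea_years"],
    )
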