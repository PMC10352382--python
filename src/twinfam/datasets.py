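"""Packaged reference inputs.

Two kinds of published summary statistics ship with the package:

* the 13 twin-study subgroups (MZ/DZ correlations, pair counts, spousal
  correlations) re-analysed in the assortative-mating meta-analysis, and
* the dyadic educational-attainment correlations and descriptive statistics
  of the German twin-family cohort that calibrate the synthetic samplers.

Only published summary numbers are stored here; individual-level data are
always generated synthetically (see :mod:`twinfam.simulate`).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: canonical member ordering used by every 5-member family covariance matrix
ROLES = ("twin1", "twin2", "sibling", "mother", "father")

#: dyad label -> (Pearson r, number of complete pairs) for the twin-family cohort
DYAD_CORRELATIONS = {
    "mz_twins": (0.769, 498),
    "dz_twins": (0.595, 439),
    "sibling_twin": (0.453, 212),
    "mother_twin": (0.406, 884),
    "mother_sibling": (0.497, 201),
    "father_twin": (0.418, 525),
    "father_sibling": (0.388, 132),
    "parents": (0.597, 482),
}

#: per-role sample composition of the twin-family cohort:
#: n individuals, n female, n male, complete pairs, age range, mean EA (years), SD EA
ROLE_STATS = {
    "mz_twins": dict(n=1020, female=610, male=410, pairs=498, age=(22, 27), ea_mean=14.7, ea_sd=2.94),
    "dz_twins": dict(n=896, female=511, male=385, pairs=439, age=(22, 27), ea_mean=14.4, ea_sd=3.05),
    "siblings": dict(n=215, female=116, male=99, pairs=0, age=(21, 30), ea_mean=14.8, ea_sd=3.09),
    "mothers": dict(n=906, female=906, male=0, pairs=0, age=(41, 66), ea_mean=12.6, ea_sd=2.81),
    "fathers": dict(n=536, female=0, male=536, pairs=0, age=(44, 79), ea_mean=13.5, ea_sd=3.23),
}

#: observed missingness of the cohort relative to its 937 twin families
FATHER_MISSING_RATE = 1.0 - 525 / 937
SIBLING_MISSING_RATE = 1.0 - 212 / 937


def load_branigan_subgroups() -> pd.DataFrame:
    """Load the 13 study subgroups with published spousal correlations.

    Columns: study, sex, cohort, n_mz, n_dz, r_mz, r_dz, r_parents.
    """
    with resources.files("twinfam.data").joinpath("branigan_ea_subgroups.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def family_correlation_matrix(zygosity: str) -> np.ndarray:
    """Assemble the 5x5 member correlation matrix implied by the published dyads.

    Member order follows :data:`ROLES`.  The twin-twin entry depends on
    ``zygosity`` ("MZ" or "DZ"); all other dyads are zygosity-pooled as
    published.
    """
    d = {k: v[0] for k, v in DYAD_CORRELATIONS.items()}
    r_tt = d["mz_twins"] if zygosity.upper() == "MZ" else d["dz_twins"]
    m = np.eye(5)

    def put(i, j, r):
        m[i, j] = m[j, i] = r

    put(0, 1, r_tt)
    put(0, 2, d["sibling_twin"])
    put(1, 2, d["sibling_twin"])
    put(0, 3, d["mother_twin"])
    put(1, 3, d["mother_twin"])
    put(2, 3, d["mother_sibling"])
    put(0, 4, d["father_twin"])
    put(1, 4, d["father_twin"])
    put(2, 4, d["father_sibling"])
    put(3, 4, d["parents"])
    return m
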