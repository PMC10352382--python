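"""Phenotype construction and descriptive statistics for twin-family tables.

A *family table* is a long-format :class:`pandas.DataFrame` with one row per
person: ``family_id``, ``role`` (twin1, twin2, sibling, mother, father),
``zygosity`` (MZ/DZ, family-level), ``sex`` (female/male), ``age`` (years),
``ea_years`` (years of education) and, after :func:`residualize`,
``ea_std`` (the age/sex-corrected z-standardized phenotype the models use).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import ROLES

OFFSPRING_ROLES = ("twin1", "twin2", "sibling")
PARENT_ROLES = ("mother", "father")

#: default German qualification ladder (highest qualification -> years of
#: education).  Spans compulsory schooling (Hauptschule) to a doctorate.
DEFAULT_GERMAN_MAP = {
    "hauptschule": 9,
    "realschule": 10,
    "berufsausbildung": 11,
    "fachhochschulreife": 12,
    "abitur": 13,
    "meister": 14,
    "fachhochschulabschluss": 15,
    "bachelor": 16,
    "master": 17,
    "promotion": 18,
}


@dataclass(frozen=True)
class QualificationMap:
    """Ordered mapping from qualification labels to years of education."""

    years: dict

    def __post_init__(self):
        vals = list(self.years.values())
        if any(v <= 0 for v in vals):
            raise ValueError("years of education must be strictly positive")
        if sorted(vals) != vals:
            raise ValueError("mapping must be ordered by increasing years")

    def lookup(self, code: str) -> float:
        """Years for a qualification code; enrolled courses ('enrolled:<code>')
        use the completed qualification's entry."""
        key = str(code).strip().lower()
        if key.startswith("enrolled:"):
            key = key[len("enrolled:"):]
        if key not in self.years:
            raise KeyError(key)
        return float(self.years[key])


def default_qualification_map() -> QualificationMap:
    return QualificationMap(dict(DEFAULT_GERMAN_MAP))


def map_qualifications(records: pd.DataFrame, qmap: QualificationMap | None = None) -> pd.DataFrame:
    """Fill ``ea_years`` from a ``qualification`` column via the mapping.

    Unmapped codes abort with every offending code listed.
    """
    qmap = qmap or default_qualification_map()
    out = records.copy()
    missing = []
    years = []
    for code in out["qualification"]:
        try:
            years.append(qmap.lookup(code))
        except KeyError:
            missing.append(str(code))
            years.append(np.nan)
    if missing:
        raise KeyError(f"unmapped qualification codes: {sorted(set(missing))}")
    out["ea_years"] = years
    return out


def filter_siblings(table: pd.DataFrame, max_gap: float = 5.0) -> pd.DataFrame:
    """Drop siblings born ``max_gap`` or more years apart from their twins.

    'Less than five apart' is strict: a gap of exactly ``max_gap`` is removed.
    Siblings with a missing age (their own or the twins') are retained and
    flagged in the ``sibling_gap_unknown`` attribute of the result.
    """
    twins = table[table["role"].isin(("twin1", "twin2"))]
    twin_age = twins.groupby("family_id")["age"].mean()
    is_sib = table["role"] == "sibling"
    gap = (table.loc[is_sib, "age"] - table.loc[is_sib, "family_id"].map(twin_age)).abs()
    drop_idx = gap.index[gap >= max_gap]
    unknown = int(gap.isna().sum())
    out = table.drop(index=drop_idx).reset_index(drop=True)
    out.attrs["siblings_removed"] = len(drop_idx)
    out.attrs["sibling_gap_unknown"] = unknown
    return out


def residualize(table: pd.DataFrame, quadratic: bool = True) -> pd.DataFrame:
    """Regress EA on age and sex and z-standardize the residuals.

    The regression (intercept, age, sex, and — unless ``quadratic`` is off —
    age² and age×sex) is fitted separately within generation (offspring vs
    parents), since the two generations occupy disjoint age ranges.  Strata
    with fewer than 10 usable records fall back to plain centering/scaling
    with a warning.
    """
    out = table.copy()
    out["ea_std"] = np.nan
    for roles in (OFFSPRING_ROLES, PARENT_ROLES):
        idx = out["role"].isin(roles) & out["ea_years"].notna()
        sub = out.loc[idx]
        y = sub["ea_years"].to_numpy(float)
        if len(sub) < 10:
            if len(sub):
                warnings.warn(f"stratum {roles} has <10 records; falling back to centering")
                sd = y.std(ddof=1) if len(y) > 1 and y.std(ddof=1) > 0 else 1.0
                out.loc[idx, "ea_std"] = (y - y.mean()) / sd
            continue
        age = sub["age"].to_numpy(float)
        sex = (sub["sex"] == "male").to_numpy(float)
        cols = [age, sex]
        if quadratic:
            cols += [age**2, age * sex]
        X = sm.add_constant(np.column_stack(cols))
        resid = sm.OLS(y, X, missing="drop").fit().resid
        out.loc[idx, "ea_std"] = (resid - resid.mean()) / resid.std(ddof=1)
    return out


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh r ± z*/sqrt(n − 3))."""
    if n < 4:
        raise ValueError("n must be >= 4")
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


@dataclass(frozen=True)
class DyadCorrelationRow:
    dyad: str
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int


def to_wide(table: pd.DataFrame, value: str = "ea_std") -> pd.DataFrame:
    """Pivot the long table to one row per family with a column per role."""
    wide = table.pivot_table(index="family_id", columns="role", values=value, aggfunc="first")
    wide = wide.reindex(columns=list(ROLES))
    zyg = table.groupby("family_id")["zygosity"].first()
    wide["zygosity"] = zyg
    return wide


def dyad_correlations(table: pd.DataFrame, seed: int = 2023, value: str = "ea_std") -> pd.DataFrame:
    """Pearson correlations (with Fisher-z 95% CIs) for the standard dyads.

    Parent–twin and sibling–twin dyads use one *random* twin per family
    (seeded) rather than both, so families do not contribute twice.  Dyads
    with fewer than 4 complete pairs are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    wide = to_wide(table, value=value)

    has_t1 = wide["twin1"].notna()
    has_t2 = wide["twin2"].notna()
    pick_t1 = rng.random(len(wide)) < 0.5
    rand_twin = np.where(
        has_t1 & has_t2, np.where(pick_t1, wide["twin1"], wide["twin2"]),
        np.where(has_t1, wide["twin1"], wide["twin2"]),
    )
    wide = wide.assign(random_twin=rand_twin)

    mz = wide[wide["zygosity"] == "MZ"]
    dz = wide[wide["zygosity"] == "DZ"]
    dyads = [
        ("mz_twins", mz["twin1"], mz["twin2"]),
        ("dz_twins", dz["twin1"], dz["twin2"]),
        ("sibling_twin", wide["sibling"], wide["random_twin"]),
        ("mother_twin", wide["mother"], wide["random_twin"]),
        ("mother_sibling", wide["mother"], wide["sibling"]),
        ("father_twin", wide["father"], wide["random_twin"]),
        ("father_sibling", wide["father"], wide["sibling"]),
        ("parents", wide["mother"], wide["father"]),
    ]
    rows = []
    for name, x, y in dyads:
        x = pd.to_numeric(pd.Series(np.asarray(x, dtype=float)))
        y = pd.to_numeric(pd.Series(np.asarray(y, dtype=float)))
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 4:
            warnings.warn(f"dyad {name} has fewer than 4 complete pairs; omitted")
            continue
        r = float(stats.pearsonr(x[ok], y[ok]).statistic)
        lo, hi = fisher_ci(r, n)
        rows.append(DyadCorrelationRow(name, r, lo, hi, n))
    return pd.DataFrame([vars(r) for r in rows])


def run_preprocess(
    table: pd.DataFrame,
    qmap: QualificationMap | None = None,
    max_gap: float = 5.0,
    quadratic: bool = True,
) -> pd.DataFrame:
    """Full pipeline: qualification mapping (if needed), sibling filter, residualize.

    Idempotent: applying it to its own output changes nothing.
    """
    out = table
    if "ea_years" not in out.columns or out["ea_years"].isna().all():
        out = map_qualifications(out, qmap)
    out = filter_siblings(out, max_gap=max_gap)
    return residualize(out, quadratic=quadratic)
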