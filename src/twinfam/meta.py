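"""Falconer ACE decomposition, assortative-mating adjustment, and
fixed-effects meta-analysis of twin-study summaries.

The classical twin design attributes the excess resemblance of MZ over DZ
twins to additive genetics: A = 2(rMZ − rDZ), C = rMZ − A, E = 1 − rMZ.
Under positive phenotypic assortment with spousal correlation µ, DZ twins
share more than half their trait-relevant additive variance, so the Falconer
difference satisfies rMZ − rDZ = A(1 − µA)/2 instead.  Solving the quadratic
µA² − A + 2(rMZ − rDZ) = 0 for its smaller root yields the assortment-adjusted
heritability; whatever A gains, C loses, while E = 1 − rMZ is untouched.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TwinStudySummary:
    """One published study subgroup: twin correlations, pair counts, spousal r."""

    study_label: str
    sex: str
    cohort_label: str
    n_mz: int
    n_dz: int
    r_mz: float
    r_dz: float
    r_parents: float

    def __post_init__(self):
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("pair counts must be >= 1")
        for r in (self.r_mz, self.r_dz, self.r_parents):
            if not math.isfinite(r) or not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {r!r} outside [-1, 1]")


@dataclass(frozen=True)
class AceEstimate:
    """Standardized (A, C, E) variance proportions.

    ``truncated`` is set when the no-negative-C rule fired during the
    assortment adjustment (C floored at 0, A = rMZ).
    """

    A: float
    C: float
    E: float
    adjusted: bool = False
    truncated: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.A, self.C, self.E)


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance grand means with the per-study, per-component weights."""

    grand_mean: dict  # {"A": float, "C": float, "E": float}
    weights: pd.DataFrame  # columns A, C, E; one row per study
    n_studies: int


def round_percent(x: float) -> int:
    """Round a proportion to a whole percent, half away from zero (display rule)."""
    return int(
        decimal.Decimal(100 * x).quantize(decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP)
    )


def _check_corr(*rs: float) -> None:
    for r in rs:
        if not math.isfinite(r):
            raise ValueError("non-finite correlation")
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")


def _clamp01(value: float) -> tuple[float, bool]:
    if value < 0.0:
        return 0.0, True
    if value > 1.0:
        return 1.0, True
    return value, False


def falconer_decompose(r_mz: float, r_dz: float) -> AceEstimate:
    """Falconer ACE decomposition: A = 2(rMZ − rDZ), C = rMZ − A, E = 1 − rMZ.

    Components are clamped to [0, 1]; the ``truncated`` flag records whether
    clamping occurred.  Without clamping, A + C + E = 1 identically.
    """
    _check_corr(r_mz, r_dz)
    A = 2.0 * (r_mz - r_dz)
    C = r_mz - A
    E = 1.0 - r_mz
    A, ta = _clamp01(A)
    C, tc = _clamp01(C)
    E, te = _clamp01(E)
    return AceEstimate(A=A, C=C, E=E, adjusted=False, truncated=ta or tc or te)


def adjust_for_assortment(r_mz: float, r_dz: float, mu: float) -> AceEstimate:
    """ACE decomposition corrected for phenotypic assortment with spousal r = µ.

    Solves µA² − A + 2(rMZ − rDZ) = 0 for the smaller root
    A = [1 − sqrt(1 − 8µ(rMZ − rDZ))] / (2µ); C = rMZ − A; E = 1 − rMZ.
    If the discriminant is negative or the implied C is negative, C is floored
    at zero, A set to rMZ, and the ``truncated`` flag raised.  µ = 0 reduces
    exactly to :func:`falconer_decompose`.
    """
    _check_corr(r_mz, r_dz)
    if not math.isfinite(mu):
        raise ValueError("non-finite mu")
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu {mu} outside [0, 1]")

    E = 1.0 - r_mz
    if mu == 0.0:
        est = falconer_decompose(r_mz, r_dz)
        return AceEstimate(est.A, est.C, est.E, adjusted=True, truncated=est.truncated)

    disc = 1.0 - 8.0 * mu * (r_mz - r_dz)
    if disc < 0.0:
        A, _ = _clamp01(r_mz)
        return AceEstimate(A=A, C=0.0, E=E, adjusted=True, truncated=True)
    A = (1.0 - math.sqrt(disc)) / (2.0 * mu)
    C = r_mz - A
    if C < 0.0:
        A, _ = _clamp01(r_mz)
        return AceEstimate(A=A, C=0.0, E=E, adjusted=True, truncated=True)
    A, ta = _clamp01(A)
    return AceEstimate(A=A, C=C, E=E, adjusted=True, truncated=ta)


def component_sampling_variances(study: TwinStudySummary) -> dict:
    """Delta-method sampling variances of the Falconer components.

    Var(r) = (1 − r²)²/n per correlation, hence
    Var(A) = 4[Var(rMZ) + Var(rDZ)], Var(C) = Var(rMZ) + 4 Var(rDZ),
    Var(E) = Var(rMZ).
    """
    v_mz = (1.0 - study.r_mz**2) ** 2 / study.n_mz
    v_dz = (1.0 - study.r_dz**2) ** 2 / study.n_dz
    return {"A": 4.0 * (v_mz + v_dz), "C": v_mz + 4.0 * v_dz, "E": v_mz}


def fixed_effects_meta(studies: Iterable[TwinStudySummary], adjust: bool = False) -> MetaResult:
    """Fixed-effects (inverse-variance) grand means of per-study ACE estimates.

    When ``adjust`` is set, per-study estimates come from
    :func:`adjust_for_assortment` using each study's spousal correlation, but
    the weights remain those of the unadjusted estimates (adjusted sampling
    variances are not defined for the quadratic-root estimator).
    """
    studies = list(studies)
    if not studies:
        raise ValueError("at least one study is required")
    rows = []
    wrows = []
    for s in studies:
        est = adjust_for_assortment(s.r_mz, s.r_dz, s.r_parents) if adjust else falconer_decompose(s.r_mz, s.r_dz)
        var = component_sampling_variances(s)
        rows.append({"A": est.A, "C": est.C, "E": est.E})
        wrows.append({c: 1.0 / var[c] for c in ("A", "C", "E")})
    est_df = pd.DataFrame(rows)
    w_df = pd.DataFrame(wrows)
    grand = {c: float(np.average(est_df[c], weights=w_df[c])) for c in ("A", "C", "E")}
    return MetaResult(grand_mean=grand, weights=w_df, n_studies=len(studies))


def derive_rdz_from_ace(A: float, C: float) -> float:
    """Expected DZ correlation implied by ACE components: rDZ = 0.5·A + C."""
    if A < 0 or C < 0:
        raise ValueError("A and C must be non-negative")
    if A + C > 1 + 1e-12:
        raise ValueError("A + C must not exceed 1")
    return 0.5 * A + C


def pool_correlations(rs: Sequence[float], ns: Sequence[int]) -> dict:
    """Pool correlations across samples.

    Returns both the simple arithmetic mean and the inverse-variance weighted
    mean on the Fisher-z scale (weights n − 3, back-transformed).  The two
    agree when the inputs are equal.
    """
    if len(rs) != len(ns):
        raise ValueError("rs and ns must have equal length")
    if len(rs) == 0:
        raise ValueError("empty input")
    for n in ns:
        if n < 4:
            raise ValueError("each sample must have n >= 4")
    _check_corr(*rs)
    rs = np.asarray(rs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    zs = np.arctanh(rs)
    w = ns - 3.0
    return {
        "arithmetic": float(np.mean(rs)),
        "fisher_z_weighted": float(np.tanh(np.average(zs, weights=w))),
    }


# ---------------------------------------------------------------------------
# table-shaped output


def studies_from_frame(df: pd.DataFrame) -> list[TwinStudySummary]:
    """Build :class:`TwinStudySummary` records from a subgroup table.

    Expected columns: study, sex, cohort, n_mz, n_dz, r_mz, r_dz, r_parents.
    """
    return [
        TwinStudySummary(
            study_label=row["study"],
            sex=row["sex"],
            cohort_label=str(row["cohort"]),
            n_mz=int(row["n_mz"]),
            n_dz=int(row["n_dz"]),
            r_mz=float(row["r_mz"]),
            r_dz=float(row["r_dz"]),
            r_parents=float(row["r_parents"]),
        )
        for _, row in df.iterrows()
    ]


def meta_table(df: pd.DataFrame) -> pd.DataFrame:
    """Reproduce the re-analysis table: unadjusted and adjusted ACE per subgroup.

    Percentage columns hold whole percents (half-up); ``truncated`` flags the
    rows where the adjusted C hit its zero floor.
    """
    out = df.copy()
    studies = studies_from_frame(df)
    for prefix, adjust in (("", False), ("adj_", True)):
        A, C, E, trunc = [], [], [], []
        for s in studies:
            est = adjust_for_assortment(s.r_mz, s.r_dz, s.r_parents) if adjust else falconer_decompose(s.r_mz, s.r_dz)
            A.append(round_percent(est.A))
            C.append(round_percent(est.C))
            E.append(round_percent(est.E))
            trunc.append(est.truncated)
        out[f"{prefix}A_pct"] = A
        out[f"{prefix}C_pct"] = C
        out[f"{prefix}E_pct"] = E
        if adjust:
            out["truncated"] = trunc
    return out


def grand_mean_report(df: pd.DataFrame) -> dict:
    """Grand means (whole percents) for the unadjusted and adjusted meta-analysis."""
    studies = studies_from_frame(df)
    unadj = fixed_effects_meta(studies, adjust=False)
    adj = fixed_effects_meta(studies, adjust=True)
    return {
        "n_studies": unadj.n_studies,
        "unadjusted": {c: round_percent(unadj.grand_mean[c]) for c in ("A", "C", "E")},
        "adjusted": {c: round_percent(adj.grand_mean[c]) for c in ("A", "C", "E")},
    }
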