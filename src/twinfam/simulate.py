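"""Forward-time generative simulator of twin families.

The simulator is the package's independent oracle for the equilibrium
covariance algebra in :mod:`twinfam.model`, and the stand-in for the
restricted twin-family panel the real study analysed.  It iterates a
population of mating couples for a configurable number of generations so
that additive variance, transmitted-environment variance and passive
gene–environment covariance reach their stationary values *by simulation*
rather than by reusing the analytic fixed point.

Mating regimes
--------------
* phenotypic assortment — spouses are rank-matched on the phenotype itself
  (against a noisy copy whose noise is bisection-calibrated so the realized
  spousal correlation hits the target), inducing a spousal genetic
  correlation of roughly (broad heritability) × (spousal r);
* social homogamy — spouses are rank-matched on the *non-genetic* part of
  the phenotype, and phenotypic transmission flows from that same latent
  part, so spouses end up genetically uncorrelated;
* random — spouses are shuffled together.

The emitted cohort mimics the study sample: MZ/DZ twin pairs with at most
one near-in-age sibling and both parents, role-specific means, SDs and age
ranges, and fathers/siblings missing completely at random at the observed
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .model import ModelSpec, PathParams, calibrate_paths


class CalibrationError(RuntimeError):
    """Raised when the requested spousal correlation is unreachable."""


#: default equilibrium variance shares: the best-fitting phenotypic-assortment
#: model of the study (A=51%, S=10%, T=16%, E=23%) with its spousal r
DEFAULT_COMPONENTS = {"A": 0.51, "S": 0.10, "T": 0.16, "E": 0.23}
DEFAULT_SPOUSAL_R = datasets.DYAD_CORRELATIONS["parents"][0]

_ROLE_KEYS = {"twin1": None, "twin2": None}  # role stats resolved per zygosity


def _default_role_stats() -> dict:
    rs = datasets.ROLE_STATS
    return {
        "mz_twin": dict(mean=rs["mz_twins"]["ea_mean"], sd=rs["mz_twins"]["ea_sd"], age=rs["mz_twins"]["age"]),
        "dz_twin": dict(mean=rs["dz_twins"]["ea_mean"], sd=rs["dz_twins"]["ea_sd"], age=rs["dz_twins"]["age"]),
        "sibling": dict(mean=rs["siblings"]["ea_mean"], sd=rs["siblings"]["ea_sd"], age=rs["siblings"]["age"]),
        "mother": dict(mean=rs["mothers"]["ea_mean"], sd=rs["mothers"]["ea_sd"], age=rs["mothers"]["age"]),
        "father": dict(mean=rs["fathers"]["ea_mean"], sd=rs["fathers"]["ea_sd"], age=rs["fathers"]["age"]),
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated cohort.

    ``paths`` holds the raw structural paths (its ``mu`` entry is ignored:
    spousal resemblance is produced by the matching procedure, calibrated to
    ``target_spousal_r``).  Defaults reproduce the study conditions: 498 MZ
    and 439 DZ families, ten generations of phenotypic assortment at a
    spousal correlation of 0.597, paths calibrated so the equilibrium
    variance shares equal the best-fitting model's A/S/T/E decomposition,
    and fathers/siblings missing at the observed rates.
    """

    paths: PathParams
    n_mz_families: int = 498
    n_dz_families: int = 439
    generations: int = 10
    mating: str = "phenotypic_assortment"
    target_spousal_r: float = DEFAULT_SPOUSAL_R
    nonadditive_mode: str = "dominance"
    father_missing_rate: float = datasets.FATHER_MISSING_RATE
    sibling_missing_rate: float = datasets.SIBLING_MISSING_RATE
    role_stats: dict = field(default_factory=_default_role_stats)
    discretize: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mating not in ("phenotypic_assortment", "social_homogamy", "random"):
            raise ValueError(f"unknown mating regime {self.mating!r}")
        for rate in (self.father_missing_rate, self.sibling_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")
        if not 0.0 <= self.target_spousal_r < 1.0:
            raise ValueError("target_spousal_r must lie in [0, 1)")

    @property
    def r_n_sib(self) -> float:
        return 0.25 if self.nonadditive_mode == "dominance" else 0.0

    @classmethod
    def from_components(cls, components: dict | None = None, m: float = 0.0,
                        spousal_r: float = DEFAULT_SPOUSAL_R,
                        mating: str = "phenotypic_assortment", **kwargs) -> "SimConfig":
        """Build a config whose *equilibrium* variance shares match ``components``."""
        components = components or DEFAULT_COMPONENTS
        design = "NTFD_SH" if mating == "social_homogamy" else "NTFD_PA"
        free = tuple(p for p, share in (("a", "A"), ("n", "N"), ("s", "S"), ("t", "T"))
                     if components.get(share, 0) > 0) + ("e",)
        if m != 0:
            free += ("m",)
        if spousal_r > 0:
            free += ("mu",)
        spec = ModelSpec(design=design, free_paths=free)
        paths = calibrate_paths(spec, components, spousal_r=spousal_r, m=m)
        return cls(paths=replace(paths, mu=0.0), mating=mating,
                   target_spousal_r=spousal_r, **kwargs)


def default_config(seed: int = 0, **kwargs) -> SimConfig:
    """The study-condition default cohort (see :class:`SimConfig`)."""
    return SimConfig.from_components(DEFAULT_COMPONENTS, spousal_r=DEFAULT_SPOUSAL_R,
                                     seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# core forward simulation


def _phenotype(p: PathParams, A, N, S, T, P, E):
    return p.a * A + p.n * N + p.s * S + p.t * T + P + p.e * E


def _nongenetic(p: PathParams, S, T, P, E):
    return p.s * S + p.t * T + P + p.e * E


def _match_spouses(key_m, key_f, ph_m, ph_f, target_r, rng, tol=0.01, allow_clamp=False):
    """Pair males and females by rank-matching ``key`` with calibrated noise.

    Returns (order_m, order_f) index arrays such that couple i is
    (males[order_m[i]], females[order_f[i]]), with the realized *phenotype*
    correlation within ``tol`` of ``target_r``.  When the matching key cannot
    reach the target (e.g. matching on the non-genetic phenotype before the
    gene–environment covariance has equilibrated), ``allow_clamp`` accepts the
    strongest achievable pairing instead of raising — used for burn-in
    generations, where the achievable ceiling rises as covariance accrues.
    """
    n = len(key_m)
    order_m = np.argsort(key_m, kind="stable")
    noise = rng.standard_normal(n)
    key_sd = max(np.std(key_f), 1e-12)

    def realized(sd):
        order_f = np.argsort(key_f + sd * key_sd * noise, kind="stable")
        r = np.corrcoef(ph_m[order_m], ph_f[order_f])[0, 1]
        return r, order_f

    r0, order_f = realized(0.0)
    if r0 < target_r - tol:
        if allow_clamp:
            return order_m, order_f, r0
        raise CalibrationError(
            f"target spousal correlation {target_r:.3f} unreachable; "
            f"maximum achievable under this regime is {r0:.3f}"
        )
    lo, hi = 0.0, 4.0
    r_hi, _ = realized(hi)
    while r_hi > target_r and hi < 64:
        hi *= 2
        r_hi, _ = realized(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r_mid, order_mid = realized(mid)
        if abs(r_mid - target_r) <= tol * 0.5:
            return order_m, order_mid, r_mid
        if r_mid > target_r:
            lo = mid
        else:
            hi = mid
    r_fin, order_fin = realized(0.5 * (lo + hi))
    if abs(r_fin - target_r) > tol:
        raise CalibrationError("spousal-correlation bisection did not converge")
    return order_m, order_fin, r_fin


def _offspring_latents(p, rN, A_f, A_m, K_f, K_m, n_children, rng, mz=False):
    """Latent factors for ``n_children`` per couple (columns = children).

    ``K`` is the parental transmission source (always the observed parental
    phenotype).  MZ mode clones the genetic draws across the first two
    children.
    """
    n_fam = len(A_f)
    mid = 0.5 * (A_f + A_m)
    N_fam = rng.standard_normal(n_fam)
    S_fam = rng.standard_normal(n_fam)
    P_fam = p.m * (K_f + K_m)
    A = np.empty((n_children, n_fam))
    N = np.empty((n_children, n_fam))
    seg = np.sqrt(0.5)
    for c in range(n_children):
        if mz and c == 1:
            A[1] = A[0]
            N[1] = N[0]
            continue
        A[c] = mid + seg * rng.standard_normal(n_fam)
        N[c] = np.sqrt(rN) * N_fam + np.sqrt(1.0 - rN) * rng.standard_normal(n_fam)
    S = np.broadcast_to(S_fam, (n_children, n_fam))
    P = np.broadcast_to(P_fam, (n_children, n_fam))
    E = rng.standard_normal((n_children, n_fam))
    return A, N, S, P, E


def simulate_cohort_matrices(config: SimConfig, rng: np.random.Generator | None = None) -> dict:
    """Run the forward simulation and return raw phenotype matrices.

    Returns a dict with, per zygosity, an (n_families, 5) phenotype matrix in
    member order (twin1, twin2, sibling, mother, father) on the latent scale,
    plus diagnostics: realized spousal correlations per generation, the
    spousal additive-genetic correlation of the final parents, and the
    per-generation phenotypic variance.
    """
    rng = rng or np.random.default_rng(config.seed)
    p = config.paths
    rN = config.r_n_sib
    n_fam = config.n_mz_families + config.n_dz_families

    def key_of(Ph, S, T, P, E):
        if config.mating == "social_homogamy":
            return _nongenetic(p, S, T, P, E)
        return Ph

    # founders: one male and one female pool, unit latent variances
    lat = {}
    for sex in ("m", "f"):
        A = rng.standard_normal(n_fam)
        N = rng.standard_normal(n_fam)
        S = rng.standard_normal(n_fam)
        T = rng.standard_normal(n_fam)
        E = rng.standard_normal(n_fam)
        P = np.zeros(n_fam)
        lat[sex] = dict(A=A, N=N, S=S, T=T, P=P, E=E, Ph=_phenotype(p, A, N, S, T, P, E))

    spousal_r_history = []
    variance_history = []

    def pair(lat, allow_clamp=False):
        ph_m, ph_f = lat["m"]["Ph"], lat["f"]["Ph"]
        if config.mating == "random" or config.target_spousal_r == 0:
            om = rng.permutation(n_fam)
            of = rng.permutation(n_fam)
            r = float(np.corrcoef(ph_m[om], ph_f[of])[0, 1])
        else:
            km = key_of(ph_m, lat["m"]["S"], lat["m"]["T"], lat["m"]["P"], lat["m"]["E"])
            kf = key_of(ph_f, lat["f"]["S"], lat["f"]["T"], lat["f"]["P"], lat["f"]["E"])
            om, of, r = _match_spouses(km, kf, ph_m, ph_f, config.target_spousal_r, rng,
                                       allow_clamp=allow_clamp)
        return om, of, r

    for gen in range(config.generations - 1):
        om, of, r = pair(lat, allow_clamp=True)
        spousal_r_history.append(r)
        variance_history.append(float(np.var(np.concatenate([lat["m"]["Ph"], lat["f"]["Ph"]]))))
        father = {k: v[om] for k, v in lat["m"].items()}
        mother = {k: v[of] for k, v in lat["f"].items()}
        # phenotypic transmission always flows from the observed phenotype;
        # only the mate-matching key is latent under social homogamy
        A, N, S, P, E = _offspring_latents(
            p, rN, father["A"], mother["A"], father["Ph"], mother["Ph"], 2, rng
        )
        T = rng.standard_normal((2, n_fam))  # interior generations: ordinary sibs
        new = {}
        for c, sex in enumerate(("m", "f")):
            Ph = _phenotype(p, A[c], N[c], S[c], T[c], P[c], E[c])
            new[sex] = dict(A=A[c], N=N[c], S=S[c].copy(), T=T[c], P=P[c].copy(), E=E[c], Ph=Ph)
        lat = new

    # final generation: emit twin families.  Couples come out of the matcher
    # ordered by phenotype rank, so shuffle before splitting into MZ/DZ blocks.
    om, of, r = pair(lat)
    spousal_r_history.append(r)
    perm = rng.permutation(n_fam)
    om, of = om[perm], of[perm]
    father = {k: v[om] for k, v in lat["m"].items()}
    mother = {k: v[of] for k, v in lat["f"].items()}
    variance_history.append(float(np.var(np.concatenate([lat["m"]["Ph"], lat["f"]["Ph"]]))))
    spousal_genetic_r = float(np.corrcoef(father["A"], mother["A"])[0, 1])

    K_f, K_m = father["Ph"], mother["Ph"]

    out = {}
    start = 0
    for zyg, count in (("MZ", config.n_mz_families), ("DZ", config.n_dz_families)):
        sl = slice(start, start + count)
        start += count
        A_f, A_m = father["A"][sl], mother["A"][sl]
        A, N, S, P, E = _offspring_latents(
            p, rN, A_f, A_m, K_f[sl], K_m[sl], 3, rng, mz=(zyg == "MZ")
        )
        T_pair = rng.standard_normal(count)  # shared by the co-twins only
        T = np.vstack([T_pair, T_pair, rng.standard_normal(count)])
        Ph = _phenotype(p, A, N, S, T, P, E)
        mat = np.column_stack([Ph[0], Ph[1], Ph[2], mother["Ph"][sl], father["Ph"][sl]])
        out[zyg] = mat
        out[f"{zyg}_additive"] = np.column_stack([A[0], A[1], A[2], A_m, A_f])

    out["spousal_r_history"] = spousal_r_history
    out["variance_history"] = variance_history
    out["spousal_genetic_r"] = spousal_genetic_r
    return out


# ---------------------------------------------------------------------------
# emitting study-shaped tables


def _emit_family_table(config: SimConfig, mats: dict, rng: np.random.Generator) -> pd.DataFrame:
    pooled = np.concatenate([mats["MZ"].ravel(), mats["DZ"].ravel()])
    scale = max(float(np.std(pooled)), 1e-12)
    stats = config.role_stats

    rows = []
    fam_id = 0
    for zyg in ("MZ", "DZ"):
        mat = mats[zyg] / scale
        twin_key = "mz_twin" if zyg == "MZ" else "dz_twin"
        n = mat.shape[0]
        same_sex = rng.random(n) < 0.5  # MZ twins: one coin per pair
        t1_sex = np.where(same_sex, "female", "male")
        dz_t2 = np.where(rng.random(n) < 0.5, "female", "male")
        keep_sib = rng.random(n) >= config.sibling_missing_rate
        keep_fa = rng.random(n) >= config.father_missing_rate
        for i in range(n):
            fam_id += 1
            members = [
                ("twin1", twin_key, t1_sex[i], mat[i, 0]),
                ("twin2", twin_key, t1_sex[i] if zyg == "MZ" else dz_t2[i], mat[i, 1]),
            ]
            if keep_sib[i]:
                sib_sex = "female" if rng.random() < 0.5 else "male"
                members.append(("sibling", "sibling", sib_sex, mat[i, 2]))
            members.append(("mother", "mother", "female", mat[i, 3]))
            if keep_fa[i]:
                members.append(("father", "father", "male", mat[i, 4]))
            for role, key, sex, z in members:
                st = stats[key]
                ea = st["mean"] + st["sd"] * z
                if config.discretize:
                    ea = float(np.clip(np.round(ea), 9, 18))
                rows.append(
                    dict(
                        family_id=f"{zyg}{i:05d}",
                        role=role,
                        zygosity=zyg,
                        sex=sex,
                        age=float(rng.integers(st["age"][0], st["age"][1] + 1)),
                        ea_years=float(ea),
                    )
                )
    return pd.DataFrame(rows)


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a study-shaped cohort; returns (family table, provenance).

    The family table is long-format with role-specific EA means/SDs and age
    ranges applied and fathers/siblings missing at the configured rates.  The
    provenance dict records the seed and the realized spousal (phenotypic and
    additive-genetic) correlations.
    """
    rng = np.random.default_rng(config.seed)
    mats = simulate_cohort_matrices(config, rng)
    table = _emit_family_table(config, mats, rng)
    provenance = {
        "seed": config.seed,
        "mating": config.mating,
        "generations": config.generations,
        "target_spousal_r": config.target_spousal_r,
        "realized_spousal_r": mats["spousal_r_history"][-1],
        "spousal_r_history": mats["spousal_r_history"],
        "spousal_genetic_r": mats["spousal_genetic_r"],
        "variance_history": mats["variance_history"],
        "paths": config.paths.as_dict(),
    }
    return table, provenance


def sample_families_mvn(
    n_mz: int,
    n_dz: int,
    corr_mz: np.ndarray | None = None,
    corr_dz: np.ndarray | None = None,
    father_missing_rate: float = datasets.FATHER_MISSING_RATE,
    sibling_missing_rate: float = datasets.SIBLING_MISSING_RATE,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw families directly from a multivariate normal over the five members.

    Defaults to the member correlation matrices assembled from the published
    dyad correlations.  The phenotype is emitted on the standardized scale
    (column ``ea_std``), ready for model fitting.  Non-positive-semi-definite
    matrices are rejected with the smallest eigenvalue reported.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for zyg, n, corr in (("MZ", n_mz, corr_mz), ("DZ", n_dz, corr_dz)):
        if corr is None:
            corr = datasets.family_correlation_matrix(zyg)
        corr = np.asarray(corr, dtype=float)
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError(f"correlation matrix for {zyg} is not PSD (min eigenvalue {w.min():.3e})")
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
        vals = rng.standard_normal((n, 5)) @ chol.T
        keep_sib = rng.random(n) >= sibling_missing_rate
        keep_fa = rng.random(n) >= father_missing_rate
        sexes = {"twin1": None, "twin2": None, "sibling": None, "mother": "female", "father": "male"}
        for i in range(n):
            for j, role in enumerate(datasets.ROLES):
                if role == "sibling" and not keep_sib[i]:
                    continue
                if role == "father" and not keep_fa[i]:
                    continue
                sex = sexes[role] or ("female" if rng.random() < 0.5 else "male")
                rows.append(
                    dict(family_id=f"{zyg}{i:05d}", role=role, zygosity=zyg,
                         sex=sex, age=np.nan, ea_years=np.nan, ea_std=float(vals[i, j]))
                )
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: per-role counts, sex counts, pairs, age range, EA mean/SD."""
    if table.empty:
        raise ValueError("empty table")
    groups = [
        ("MZ twins", (table["role"].isin(("twin1", "twin2"))) & (table["zygosity"] == "MZ")),
        ("DZ twins", (table["role"].isin(("twin1", "twin2"))) & (table["zygosity"] == "DZ")),
        ("Siblings", table["role"] == "sibling"),
        ("Mothers", table["role"] == "mother"),
        ("Fathers", table["role"] == "father"),
        ("Total", pd.Series(True, index=table.index)),
    ]
    rows = []
    for label, mask in groups:
        sub = table[mask]
        if sub.empty:
            continue
        if label in ("MZ twins", "DZ twins"):
            per_fam = sub.groupby("family_id").size()
            pairs = int((per_fam == 2).sum())
        else:
            pairs = 0
        rows.append(
            dict(
                group=label,
                n=len(sub),
                female=int((sub["sex"] == "female").sum()),
                male=int((sub["sex"] == "male").sum()),
                pairs=pairs,
                age_min=float(sub["age"].min()) if sub["age"].notna().any() else np.nan,
                age_max=float(sub["age"].max()) if sub["age"].notna().any() else np.nan,
                ea_mean=float(sub["ea_years"].mean()),
                ea_sd=float(sub["ea_years"].std(ddof=1)),
            )
        )
    return pd.DataFrame(rows)
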