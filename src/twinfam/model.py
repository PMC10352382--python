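"""Model-implied covariance algebra for twin and nuclear-family designs.

A person's phenotype is built from six latent factors,

    F = a·A + n·N + s·S + t·T + p·P + e·E          (p fixed at 1),

where A is additive genetic, N non-additive genetic, S an environment shared
by all siblings, T an environment shared only by co-twins, P the familial
environment transmitted from the parents' phenotypes (path m from each
parent), and E the nonshared residual.  Spouses are connected by a copath µ.

Under sustained assortment and phenotypic transmission the additive variance
q = Var(A), the transmitted-environment variance x = Var(P), and the passive
gene–environment covariance w = Cov(A, P) are inflated relative to their
founder values.  Their stationary (intergenerational-equilibrium) values
solve a small fixed-point system; :func:`solve_equilibrium` computes it and
:func:`implied_covariance` assembles the expected covariance matrix of a
five-member family (twin1, twin2, sibling, mother, father).

Two mating regimes are supported.  Under *phenotypic assortment* (PA) the
copath attaches to the observed phenotype, so spouses' genotypes correlate.
Under *social homogamy* (SH) the copath attaches to a latent parental
phenotype whose genetic loadings are zero (a Cascade-style construction):
spousal resemblance is purely environmental and at equilibrium the passive
rGE covariance w is driven to zero, leaving spouses genetically uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ROLES

DESIGNS = ("CTD_ACE", "CTD_ANE", "NTFD_PA", "NTFD_SH")
PATH_NAMES = ("a", "n", "s", "t", "e", "m", "mu")


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium iteration fails or yields V <= 0."""


@dataclass(frozen=True)
class ModelSpec:
    """A model configuration: design, free paths, and the non-additive mode.

    ``free_paths`` lists the paths estimated from data; everything else is
    fixed at zero (``e`` must always be free — the nonshared residual is
    never dropped).  At most two of {n, s, m} may be free simultaneously:
    non-additive genetics, sibling-shared environment and phenotypic
    transmission are not jointly identified in this design.
    """

    design: str
    free_paths: tuple[str, ...]
    nonadditive_mode: str = "dominance"
    name: str | None = None

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.nonadditive_mode not in ("dominance", "epistasis"):
            raise ValueError(f"unknown nonadditive_mode {self.nonadditive_mode!r}")
        unknown = set(self.free_paths) - set(PATH_NAMES)
        if unknown:
            raise ValueError(f"unknown paths {sorted(unknown)}")
        if "e" not in self.free_paths:
            raise ValueError("the nonshared path e must always be free")
        if len({"n", "s", "m"} & set(self.free_paths)) > 2:
            raise ValueError("at most two of {n, s, m} may be free simultaneously")
        if self.design.startswith("CTD") and ({"m", "mu"} & set(self.free_paths)):
            raise ValueError("CTD designs assume random mating: m and mu are fixed at 0")

    @property
    def r_n_sib(self) -> float:
        """Non-additive genetic correlation for non-MZ siblings (MZ is always 1)."""
        return 0.25 if self.nonadditive_mode == "dominance" else 0.0

    @property
    def fixed_zero(self) -> tuple[str, ...]:
        return tuple(p for p in PATH_NAMES if p not in self.free_paths)

    @property
    def label(self) -> str:
        return self.name or f"{self.design}:{'+'.join(self.free_paths)}"


@dataclass(frozen=True)
class PathParams:
    """Numeric values of the seven structural paths (zero when fixed)."""

    a: float = 0.0
    n: float = 0.0
    s: float = 0.0
    t: float = 0.0
    e: float = 1.0
    m: float = 0.0
    mu: float = 0.0

    def check(self, spec: ModelSpec) -> None:
        for p in spec.fixed_zero:
            if getattr(self, p) != 0.0:
                raise ValueError(f"path {p} is fixed to zero under {spec.label}")
        if self.e <= 0:
            raise ValueError("e must be strictly positive")

    def as_dict(self) -> dict:
        return {p: getattr(self, p) for p in PATH_NAMES}


@dataclass(frozen=True)
class EquilibriumState:
    """Stationary latent moments under the given paths.

    q = Var(A); x = Var(P); w = Cov(A, P); V = total phenotypic variance;
    g = within-person Cov(A, F) = a·q + w.  ``c_af``, ``c_ff`` and
    ``v_latent`` are the moments of the (possibly latent) spousal phenotype
    F': Cov(A, F'), Cov(F, F') and Var(F').  Under PA, F' = F.
    """

    q: float
    x: float
    w: float
    V: float
    g: float
    c_af: float
    c_ff: float
    v_latent: float
    n_iter: int


def _latent_moments(design: str, params: PathParams, q: float, w: float, x: float, V: float):
    """Moments (Cov(A,F'), Var(F'), Cov(F,F')) of the spousal-copath phenotype."""
    if design in ("NTFD_SH",):
        v_lat = params.s**2 + params.t**2 + x + params.e**2
        return w, v_lat, v_lat + params.a * w
    # PA and CTD: the copath phenotype is the observed phenotype
    return params.a * q + w, V, V


def total_variance(params: PathParams, q: float, w: float, x: float) -> float:
    return (
        params.a**2 * q
        + params.n**2
        + params.s**2
        + params.t**2
        + x
        + 2.0 * params.a * w
        + params.e**2
    )


def solve_equilibrium(
    spec: ModelSpec,
    params: PathParams,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> EquilibriumState:
    """Solve the intergenerational equilibrium (q, w, x) by damped iteration.

    Founder additive variance is 1 (segregation variance ½), so under random
    mating with no transmission q = 1, w = x = 0.  Writing c_A = Cov(A, F')
    and c_F = Cov(F, F') for the copath phenotype F' (F' = F under PA; the
    a = n = 0 latent phenotype under SH) and g = a·q + w, the update maps are

        q  <- 1 + µ·c_A²                      (spousal additive covariance)
        w  <- m·(g + µ·c_A·c_F)               (transmission from each parent's
                                               observed phenotype, plus the
                                               assortative detour)
        x  <- 2m²·(V + µ·c_F²)

    which for PA reduce to q = 1 + µg², w = m·g·(1 + µV), x = 2m²V(1 + µV).
    Under SH, c_A = w, so spouses carry no first-order genetic covariance and
    passive rGE survives only through the transmission path itself.
    """
    params.check(spec)
    q, w, x = 1.0, 0.0, 0.0
    lam = damping
    for it in range(1, max_iter + 1):
        V = total_variance(params, q, w, x)
        if not np.isfinite(V) or V <= 0:
            raise EquilibriumError(f"non-positive phenotypic variance at iteration {it}")
        c_af, v_lat, c_ff = _latent_moments(spec.design, params, q, w, x, V)
        if abs(c_af) > 1e6 or q > 1e6 or abs(c_ff) > 1e6:
            raise EquilibriumError("divergent equilibrium (assortment too strong for these paths)")
        g = params.a * q + w
        q_new = 1.0 + params.mu * c_af**2
        w_new = params.m * (g + params.mu * c_af * c_ff)
        x_new = 2.0 * params.m**2 * (V + params.mu * c_ff**2)
        resid = abs(q_new - q) + abs(w_new - w) + abs(x_new - x)
        q = lam * q_new + (1 - lam) * q
        w = lam * w_new + (1 - lam) * w
        x = lam * x_new + (1 - lam) * x
        if resid < tol:
            break
    else:
        raise EquilibriumError(f"equilibrium not reached after {max_iter} iterations")
    V = total_variance(params, q, w, x)
    if V <= 0:
        raise EquilibriumError("non-positive phenotypic variance at the fixed point")
    c_af, v_lat, c_ff = _latent_moments(spec.design, params, q, w, x, V)
    return EquilibriumState(
        q=q, x=x, w=w, V=V, g=params.a * q + w,
        c_af=c_af, c_ff=c_ff, v_latent=v_lat, n_iter=it,
    )


@dataclass(frozen=True)
class FamilyCovariance:
    """Expected covariance matrix and mean vector of one family configuration."""

    zygosity: str
    members: tuple[str, ...]
    matrix: np.ndarray
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    def submatrix(self, idx):
        return self.matrix[np.ix_(idx, idx)]


def implied_covariance(
    spec: ModelSpec,
    params: PathParams,
    eq: EquilibriumState,
    zygosity: str,
    grand_mean: float = 0.0,
) -> FamilyCovariance:
    """Path-traced expected covariance of (twin1, twin2, sibling, mother, father).

    Diagonals all equal V: the twin-specific environment T is modelled as a
    variance component in every relative class (siblings and parents carry
    their own T variance, they just do not share it with the twins).
    """
    params.check(spec)
    a, n, s, t, m, mu = params.a, params.n, params.s, params.t, params.m, params.mu
    q, w, x, V = eq.q, eq.w, eq.x, eq.V
    r_n = spec.r_n_sib

    # sibling additive covariance: ½(q + spousal additive covariance)
    cov_a_sib = 0.5 * (q + mu * eq.c_af**2)
    shared_env = s**2 + x + 2.0 * a * w

    mz_tt = a**2 * q + n**2 + shared_env + t**2
    dz_tt = a**2 * cov_a_sib + r_n * n**2 + shared_env + t**2
    twin_sib = a**2 * cov_a_sib + r_n * n**2 + shared_env  # no shared T

    # parent-offspring: direct + assortative route into offspring A, plus the
    # transmitted-environment route into offspring P (source = observed phenotype)
    po_gen = a * 0.5 * (eq.g + mu * eq.c_ff * eq.c_af)
    po_env = m * (eq.V + mu * eq.c_ff**2)
    po = po_gen + po_env

    spousal = mu * eq.c_ff**2

    tt = mz_tt if zygosity.upper() == "MZ" else dz_tt
    mat = np.full((5, 5), np.nan)
    np.fill_diagonal(mat, V)
    mat[0, 1] = mat[1, 0] = tt
    for twin in (0, 1):
        mat[twin, 2] = mat[2, twin] = twin_sib
        mat[twin, 3] = mat[3, twin] = po
        mat[twin, 4] = mat[4, twin] = po
    mat[2, 3] = mat[3, 2] = po
    mat[2, 4] = mat[4, 2] = po
    mat[3, 4] = mat[4, 3] = spousal
    return FamilyCovariance(
        zygosity=zygosity.upper(),
        members=ROLES,
        matrix=mat,
        mean=np.full(5, grand_mean),
    )


def standardize_components(params: PathParams, eq: EquilibriumState) -> dict:
    """Standardized variance shares A, N, S, T, P, rGE, E (sum to 1; rGE may be < 0)."""
    V = eq.V
    if V <= 0:
        raise EquilibriumError("V must be positive")
    return {
        "A": params.a**2 * eq.q / V,
        "N": params.n**2 / V,
        "S": params.s**2 / V,
        "T": params.t**2 / V,
        "P": eq.x / V,
        "rGE": 2.0 * params.a * eq.w / V,
        "E": params.e**2 / V,
    }


def ctd_shared_environment(components: dict) -> float:
    """The CTD 'C' aggregate: everything siblings/twins share beyond additive genes."""
    return components["S"] + components["T"] + components["P"] + components["rGE"]


def decompose_parent_offspring(params: PathParams, eq: EquilibriumState) -> dict:
    """Split the implied parent–offspring covariance into genetic vs environmental routes.

    The genetic share flows through the offspring's A (including the
    assortative detour via the co-parent); the environmental share flows
    through the transmitted familial environment P.
    """
    genetic = params.a * 0.5 * (eq.g + params.mu * eq.c_ff * eq.c_af)
    environmental = params.m * (eq.V + params.mu * eq.c_ff**2)
    total = genetic + environmental
    if abs(total) < 1e-14:
        raise ValueError("parent-offspring covariance is zero; shares undefined")
    return {
        "covariance": total,
        "genetic_share": genetic / total,
        "environmental_share": environmental / total,
    }


def copath_for_spousal_r(
    spec: ModelSpec, params: PathParams, spousal_r: float, tol: float = 1e-10
) -> PathParams:
    """Find the copath µ at which the implied spousal *correlation* equals ``spousal_r``.

    The implied spousal correlation is µ·Cov(F, F')²/V, which depends on µ
    through the equilibrium; solved by simple substitution iteration.
    """
    from scipy import optimize as _opt

    if not 0 <= spousal_r < 1:
        raise ValueError("spousal_r must be in [0, 1)")
    if spousal_r == 0:
        return replace(params, mu=0.0)

    def implied_r(mu):
        eq = solve_equilibrium(spec, replace(params, mu=mu))
        return mu * eq.c_ff**2 / eq.V

    # expand µ upward until the implied correlation brackets the target;
    # too-strong assortment has no stable equilibrium, so back off on failure
    lo, step = 0.0, spousal_r
    hi = None
    for _ in range(200):
        cand = lo + step
        try:
            r_cand = implied_r(cand)
        except EquilibriumError:
            step *= 0.5
            continue
        if r_cand < spousal_r:
            lo = cand
        else:
            hi = cand
            break
        if step < 1e-12:
            break
    if hi is None:
        raise EquilibriumError(
            f"spousal correlation {spousal_r} unreachable under these paths"
        )
    mu = _opt.brentq(lambda u: implied_r(u) - spousal_r, lo, hi, xtol=tol)
    return replace(params, mu=mu)


def calibrate_paths(
    spec: ModelSpec,
    components: dict,
    spousal_r: float = 0.0,
    m: float = 0.0,
) -> PathParams:
    """Raw paths whose *equilibrium* standardized shares match ``components``.

    ``components`` maps a subset of {A, N, S, T, E} to target shares summing
    (with any transmission share) to 1.  The phenotypic-transmission path m,
    if nonzero, is taken as given rather than targeted.  Solved numerically;
    used to set up simulations that reproduce a fitted model's variance
    decomposition.
    """
    targets = {k: components.get(k, 0.0) for k in ("A", "N", "S", "T", "E")}
    active = [k for k, v in targets.items() if v > 0]
    path_of = {"A": "a", "N": "n", "S": "s", "T": "t", "E": "e"}

    def build(vals):
        kw = {path_of[k]: abs(v) for k, v in zip(active, vals)}
        kw["m"] = m
        return PathParams(**{**{"a": 0, "n": 0, "s": 0, "t": 0, "e": 1e-6}, **kw})

    def shares(vals):
        p = copath_for_spousal_r(spec, build(vals), spousal_r)
        return p, standardize_components(p, solve_equilibrium(spec, p))

    # each share scales as (path value)^2 / V, so multiplicative updates on
    # the path values converge rapidly; more robust here than a generic
    # root-finder, whose finite-difference steps can cross into parameter
    # regions without a stable equilibrium.  When m != 0 the emergent
    # transmission (P) and rGE shares occupy part of the variance, so the
    # targets are renormalized to the share left over — exact when the
    # targets sum to 1 and m = 0.
    target_sum = sum(targets[k] for k in active)
    vals = np.array([np.sqrt(targets[k]) for k in active])
    for _ in range(200):
        p, got = shares(vals)
        scale = (1.0 - got["P"] - got["rGE"]) / target_sum
        aims = {k: targets[k] * scale for k in active}
        err = np.array([got[k] - aims[k] for k in active])
        if np.max(np.abs(err)) < 1e-10:
            return p
        vals = vals * np.sqrt([aims[k] / max(got[k], 1e-12) for k in active])
    raise EquilibriumError(
        f"path calibration failed to converge (max error {np.max(np.abs(err)):.2e})"
    )


# ---------------------------------------------------------------------------
# named model presets (the PA/SH baseline ladder)

def _preset(design, paths, name, mode="dominance"):
    return ModelSpec(design=design, free_paths=tuple(paths), nonadditive_mode=mode, name=name)


def model_presets(nonadditive_mode: str = "dominance") -> dict:
    """The six NTFD baseline models (PA/SH x {N=0, S=0, P=0}) plus the CTD models.

    Baseline naming follows the component lists: e.g. ASTPE frees a, s, t, e
    and the transmission path m (with N fixed to zero).  µ is always free in
    NTFD models — the spousal block of the likelihood informs it.
    """
    mo = nonadditive_mode
    out = {
        "CTD-ACE": _preset("CTD_ACE", ("a", "s", "e"), "CTD-ACE", mo),
        "CTD-ANE": _preset("CTD_ANE", ("a", "n", "e"), "CTD-ANE", mo),
    }
    for kind, design in (("PA", "NTFD_PA"), ("SH", "NTFD_SH")):
        out[f"{kind}-ASTPE"] = _preset(design, ("a", "s", "t", "e", "m", "mu"), f"{kind}-ASTPE", mo)
        out[f"{kind}-ANTPE"] = _preset(design, ("a", "n", "t", "e", "m", "mu"), f"{kind}-ANTPE", mo)
        out[f"{kind}-ANSTE"] = _preset(design, ("a", "n", "s", "t", "e", "mu"), f"{kind}-ANSTE", mo)
        out[f"{kind}-ASTE"] = _preset(design, ("a", "s", "t", "e", "mu"), f"{kind}-ASTE", mo)
    return out
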