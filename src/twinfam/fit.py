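"""Full-information maximum likelihood for twin-family models.

Each family contributes the multivariate-normal log density of its *observed*
members, evaluated under the model-implied mean vector and the submatrix of
the implied five-member covariance matrix — so families with a missing
father or sibling (or a single twin) are retained rather than dropped.
Families are grouped by (zygosity, missingness pattern) and each group's
contribution is evaluated in one vectorized pass.

The module provides the saturated reference model, likelihood-ratio tests,
information criteria, profile-likelihood confidence intervals on the
standardized variance components, and the model-comparison ladder: six
baseline models (phenotypic assortment / social homogamy, each fixing one of
non-additive genetics, sibling environment, or phenotypic transmission to
zero) pruned by iteratively dropping non-significant paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .datasets import ROLES
from .model import (
    EquilibriumError,
    EquilibriumState,
    FamilyCovariance,
    ModelSpec,
    PathParams,
    implied_covariance,
    model_presets,
    solve_equilibrium,
    standardize_components,
)
from .preprocess import to_wide

LOG_2PI = math.log(2.0 * math.pi)
_BIG = 1e12

#: box constraints per path: variance-scale paths are non-negative, the
#: nonshared path is bounded away from zero, transmission and the copath may
#: take either sign but start positive
_BOUNDS = {
    "a": (0.0, 2.0),
    "n": (0.0, 2.0),
    "s": (0.0, 2.0),
    "t": (0.0, 2.0),
    "e": (1e-3, 2.0),
    "m": (-0.9, 0.9),
    "mu": (-0.95, 0.95),
    "mean": (-2.0, 2.0),
}
_START = {"a": 0.6, "n": 0.2, "s": 0.3, "t": 0.3, "e": 0.5, "m": 0.05, "mu": 0.3, "mean": 0.0}


class NonPSDError(RuntimeError):
    """Implied covariance not positive definite for some parameter set."""


# ---------------------------------------------------------------------------
# data container


@dataclass
class FamilyData:
    """Families grouped by (zygosity, missingness pattern) for fast FIML."""

    groups: list  # (zygosity, member index tuple, n_fam x k value array)
    n_obs: int
    n_families: int
    n_skipped: int

    @classmethod
    def from_table(cls, table: pd.DataFrame, value: str = "ea_std") -> "FamilyData":
        wide = to_wide(table, value=value)
        vals = wide[list(ROLES)].to_numpy(float)
        zyg = wide["zygosity"].to_numpy()
        present = ~np.isnan(vals)
        groups = []
        n_obs = 0
        n_skipped = 0
        for z in ("MZ", "DZ"):
            in_z = zyg == z
            if not in_z.any():
                continue
            pats, inverse = np.unique(present[in_z], axis=0, return_inverse=True)
            sub = vals[in_z]
            for pi, pat in enumerate(pats):
                idx = tuple(np.flatnonzero(pat))
                rows = sub[inverse == pi][:, list(idx)]
                if not idx:
                    n_skipped += int((inverse == pi).sum())
                    continue
                groups.append((z, idx, np.ascontiguousarray(rows)))
                n_obs += rows.size
        n_fam = int(len(wide)) - n_skipped
        return cls(groups=groups, n_obs=n_obs, n_families=n_fam, n_skipped=n_skipped)


def _as_data(data) -> FamilyData:
    return data if isinstance(data, FamilyData) else FamilyData.from_table(data)


# ---------------------------------------------------------------------------
# deviance


def _deviance_from_matrices(data: FamilyData, cov: dict, mean: dict) -> float:
    """-2 log likelihood given per-zygosity 5x5 covariance and 5-mean arrays."""
    total = 0.0
    for z, idx, rows in data.groups:
        sub = cov[z][np.ix_(idx, idx)]
        try:
            L = linalg.cholesky(sub, lower=True)
        except linalg.LinAlgError as err:
            raise NonPSDError(f"{z} pattern {idx}: {err}") from err
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        dev = rows - mean[z][list(idx)]
        u = linalg.solve_triangular(L, dev.T, lower=True)
        total += rows.shape[0] * (len(idx) * LOG_2PI + logdet) + float(np.sum(u * u))
    return total


def fiml_loglik(data, spec: ModelSpec, params: PathParams, grand_mean: float = 0.0) -> float:
    """-2 log likelihood of the family table under (spec, params).

    Raises :class:`NonPSDError` when the implied covariance fails a Cholesky
    factorization for some observed-member pattern.
    """
    data = _as_data(data)
    eq = solve_equilibrium(spec, params)
    cov = {z: implied_covariance(spec, params, eq, z).matrix for z in ("MZ", "DZ")}
    mean = {z: np.full(5, grand_mean) for z in ("MZ", "DZ")}
    return _deviance_from_matrices(data, cov, mean)


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """A converged maximum-likelihood fit."""

    name: str
    minus2LL: float
    n_params: int
    n_obs: int
    df: int
    AIC: float
    BIC: float
    spec: ModelSpec | None = None
    params: PathParams | None = None
    eq: EquilibriumState | None = None
    grand_mean: float = 0.0
    components: dict | None = None
    free_names: tuple = ()
    theta: np.ndarray | None = None
    se: dict | None = None
    component_ci: dict | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


def information_criteria(minus2LL: float, n_params: int, n_units: int) -> dict:
    """AIC = -2LL + 2k; BIC = -2LL + k log(n non-missing observations)."""
    return {
        "AIC": minus2LL + 2.0 * n_params,
        "BIC": minus2LL + n_params * math.log(n_units),
    }


def lrt(restricted: FitResult, general: FitResult, tol: float = 1e-6) -> dict:
    """Chi-squared likelihood-ratio test of a nested restriction."""
    ddf = general.n_params - restricted.n_params
    if ddf < 1:
        raise ValueError("restricted model must have fewer free parameters")
    delta = restricted.minus2LL - general.minus2LL
    if delta < -tol:
        raise RuntimeError(
            f"negative deviance difference ({delta:.4g}): optimizer failure in the general model"
        )
    delta = max(delta, 0.0)
    return {"delta_minus2LL": delta, "delta_df": ddf, "p": chi2_p(delta, ddf)}


def chi2_p(delta_minus2LL: float, delta_df: int) -> float:
    """Upper-tail chi-squared p-value for a deviance difference."""
    return float(stats.chi2.sf(delta_minus2LL, delta_df))


# ---------------------------------------------------------------------------
# structural-model fitting


def _theta_names(spec: ModelSpec) -> tuple:
    return tuple(p for p in ("a", "n", "s", "t", "e", "m", "mu") if p in spec.free_paths) + ("mean",)


def _params_from_theta(spec: ModelSpec, theta) -> tuple[PathParams, float]:
    names = _theta_names(spec)
    kw = dict(zip(names, theta))
    mean = kw.pop("mean")
    base = {p: 0.0 for p in ("a", "n", "s", "t", "m", "mu")}
    base["e"] = kw.get("e", 1.0)
    base.update(kw)
    return PathParams(**base), mean


def _objective(data: FamilyData, spec: ModelSpec):
    def fun(theta):
        params, mean = _params_from_theta(spec, theta)
        try:
            params.check(spec)
            eq = solve_equilibrium(spec, params)
            cov = {z: implied_covariance(spec, params, eq, z).matrix for z in ("MZ", "DZ")}
        except (EquilibriumError, ValueError):
            return _BIG
        means = {z: np.full(5, theta[-1]) for z in ("MZ", "DZ")}
        try:
            return _deviance_from_matrices(data, cov, means)
        except NonPSDError:
            return _BIG

    return fun


def _minimize(fun, x0, bounds, maxiter=4000):
    res = optimize.minimize(
        fun, x0, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-9, "adaptive": True},
    )
    polish = optimize.minimize(
        fun, res.x, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return polish if polish.fun <= res.fun else res


def fit_model(
    data,
    spec: ModelSpec,
    n_starts: int = 5,
    seeds: tuple = (1, 2, 3, 4, 5),
    compute_se: bool = False,
    compute_ci: bool = False,
    name: str | None = None,
) -> FitResult:
    """Fit a structural model by FIML with multi-start optimization.

    Deterministic: start points come from the fixed ``seeds``.  Standardized
    variance components are always reported; standard errors (numerical
    Hessian) and profile-likelihood 95% CIs on the components are optional.
    """
    data = _as_data(data)
    names = _theta_names(spec)
    bounds = [_BOUNDS[p] for p in names]
    fun = _objective(data, spec)

    starts = [np.array([_START[p] for p in names])]
    for k in range(1, n_starts):
        rng = np.random.default_rng(seeds[(k - 1) % len(seeds)])
        lo = np.array([b[0] for b in bounds])
        hi = np.array([min(b[1], 1.0) for b in bounds])
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best = None
    for x0 in starts:
        res = _minimize(fun, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _BIG:
        raise RuntimeError(f"no start converged for {spec.label}")

    params, mean = _params_from_theta(spec, best.x)
    eq = solve_equilibrium(spec, params)
    comps = standardize_components(params, eq)
    k = len(names)
    ic = information_criteria(best.fun, k, data.n_obs)
    fit = FitResult(
        name=name or spec.label,
        minus2LL=float(best.fun),
        n_params=k,
        n_obs=data.n_obs,
        df=data.n_obs - k,
        AIC=ic["AIC"],
        BIC=ic["BIC"],
        spec=spec,
        params=params,
        eq=eq,
        grand_mean=mean,
        components=comps,
        free_names=names,
        theta=np.asarray(best.x, dtype=float),
        converged=bool(best.fun < _BIG),
    )
    if compute_se:
        fit.se = _wald_se(fun, fit)
    if compute_ci:
        fit.component_ci = {
            c: profile_component_ci(data, spec, fit, c)
            for c, v in comps.items()
            if c != "rGE" and (c in ("A", "E") or v > 0 or _component_path(c) in spec.free_paths)
        }
    return fit


def _component_path(component: str) -> str:
    return {"A": "a", "N": "n", "S": "s", "T": "t", "E": "e", "P": "m", "rGE": "m"}[component]


def _wald_se(fun, fit: FitResult) -> dict:
    """Standard errors from the numerical Hessian of the deviance (0.5 H = observed information)."""
    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(fit.theta, fun)
    try:
        cov = 2.0 * np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return {}
    return dict(zip(fit.free_names, se))


def profile_component_ci(
    data,
    spec: ModelSpec,
    fit: FitResult,
    component: str,
    level: float = 0.95,
    penalty: float = 1e6,
    tol: float = 0.005,
) -> tuple[float, float]:
    """Profile-likelihood CI for one standardized variance component.

    The profile deviance at a candidate value c is the minimum of the FIML
    deviance over all parameters subject to component = c (imposed by a
    quadratic penalty); the CI collects the c whose profile deviance lies
    within the chi-squared(1) critical value of the optimum.  Variance-scale
    components are bounded below by zero.
    """
    data = _as_data(data)
    fun = _objective(data, spec)
    crit = fit.minus2LL + stats.chi2.ppf(level, 1)
    est = fit.components[component]
    bounds = [_BOUNDS[p] for p in fit.free_names]

    def make_profile():
        # warm-start each penalized fit from the previous optimum on the same
        # side of the estimate — consecutive bisection points are close, so
        # this cuts the simplex iterations by an order of magnitude
        state = {"theta": np.asarray(fit.theta, dtype=float)}

        def profile_dev(c):
            def pen(theta):
                base = fun(theta)
                if base >= _BIG:
                    return base
                params, _ = _params_from_theta(spec, theta)
                comp = standardize_components(params, solve_equilibrium(spec, params))[component]
                return base + penalty * (comp - c) ** 2

            res = optimize.minimize(
                pen, state["theta"], method="Nelder-Mead", bounds=bounds,
                options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-7, "adaptive": True},
            )
            state["theta"] = res.x
            return res.fun

        return profile_dev

    def search(direction, limit):
        # walk outward from the estimate in small steps (each penalized fit
        # warm-starts from its neighbour, so convergence is reliable), then
        # bisect inside the step that crosses the critical deviance
        profile_dev = make_profile()
        step = max(4 * tol, 0.02)
        inside = est
        while True:
            cand = inside + direction * step
            if (cand - limit) * direction >= 0:
                if profile_dev(limit) < crit:
                    return limit
                outside = limit
                break
            if profile_dev(cand) < crit:
                inside = cand
            else:
                outside = cand
                break
        lo, hi = inside, outside
        for _ in range(30):
            if abs(hi - lo) < tol:
                break
            mid = 0.5 * (lo + hi)
            if profile_dev(mid) < crit:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    floor = -1.0 if component == "rGE" else 0.0
    lower = search(-1.0, floor)
    upper = search(+1.0, 1.0)
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# saturated model


def _saturated_build(theta):
    mu = np.array([theta[0], theta[0], theta[1], theta[2], theta[3]])
    vt, vs, vm, vf = np.exp(theta[4:8])
    ctt, cts, cmt, cms, cft, cfs, cmf = theta[8:15]
    cov = np.array(
        [
            [vt, ctt, cts, cmt, cft],
            [ctt, vt, cts, cmt, cft],
            [cts, cts, vs, cms, cfs],
            [cmt, cmt, cms, vm, cmf],
            [cft, cft, cfs, cmf, vf],
        ]
    )
    return mu, cov


def _saturated_start(data: FamilyData, zyg: str):
    rows_by_idx = [(idx, r) for z, idx, r in data.groups if z == zyg]
    sums = np.zeros(5)
    sqs = np.zeros(5)
    cnt = np.zeros(5)
    cross = np.zeros((5, 5))
    ccnt = np.zeros((5, 5))
    for idx, r in rows_by_idx:
        for aj, j in enumerate(idx):
            col = r[:, aj]
            sums[j] += col.sum()
            sqs[j] += (col**2).sum()
            cnt[j] += len(col)
            for ak, kk in enumerate(idx):
                cross[j, kk] += float(col @ r[:, ak])
                ccnt[j, kk] += len(col)
    mean = sums / np.maximum(cnt, 1)
    var = np.maximum(sqs / np.maximum(cnt, 1) - mean**2, 1e-3)
    cov = cross / np.maximum(ccnt, 1) - np.outer(mean, mean)
    # symmetrize twins and clip correlations to keep the start PSD-ish
    vt = 0.5 * (var[0] + var[1])
    theta = np.array(
        [
            0.5 * (mean[0] + mean[1]), mean[2], mean[3], mean[4],
            math.log(vt), math.log(var[2]), math.log(var[3]), math.log(var[4]),
            cov[0, 1], 0.5 * (cov[0, 2] + cov[1, 2]),
            0.5 * (cov[0, 3] + cov[1, 3]), cov[2, 3],
            0.5 * (cov[0, 4] + cov[1, 4]), cov[2, 4], cov[3, 4],
        ]
    )
    return theta


def fit_saturated(data, name: str = "Saturated") -> FitResult:
    """Relative-class saturated model: free means, variances and covariances
    per zygosity, with co-twins treated as exchangeable.

    15 parameters per zygosity group present in the data; provides the
    reference deviance every structural model is tested against.
    """
    data = _as_data(data)
    total = 0.0
    k_total = 0
    extra = {}
    for zyg in ("MZ", "DZ"):
        groups = [g for g in data.groups if g[0] == zyg]
        if not groups:
            continue
        sub = FamilyData(groups=groups, n_obs=sum(r.size for _, _, r in groups),
                         n_families=sum(len(r) for _, _, r in groups), n_skipped=0)

        def fun(theta, sub=sub, zyg=zyg):
            mu, cov = _saturated_build(theta)
            try:
                return _deviance_from_matrices(sub, {zyg: cov}, {zyg: mu})
            except NonPSDError:
                return _BIG

        x0 = _saturated_start(data, zyg)
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"maxiter": 40000, "maxfev": 40000, "xatol": 1e-8, "fatol": 1e-10, "adaptive": True},
        )
        polish = optimize.minimize(fun, res.x, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-13})
        best = polish if polish.fun <= res.fun else res
        mu, cov = _saturated_build(best.x)
        extra[zyg] = {"mean": mu, "cov": cov, "minus2LL": float(best.fun)}
        total += float(best.fun)
        k_total += 15
    ic = information_criteria(total, k_total, data.n_obs)
    return FitResult(
        name=name, minus2LL=total, n_params=k_total, n_obs=data.n_obs,
        df=data.n_obs - k_total, AIC=ic["AIC"], BIC=ic["BIC"], extra=extra,
    )


# ---------------------------------------------------------------------------
# pruning and the model ladder


@dataclass
class PruneStep:
    dropped: tuple
    fit: FitResult
    p_vs_parent: float


@dataclass
class LadderReport:
    saturated: FitResult
    baselines: dict
    pruned: dict
    history: dict
    comparisons: pd.DataFrame
    best_name: str

    @property
    def best(self) -> FitResult:
        if self.best_name in self.pruned:
            return self.pruned[self.best_name]
        return self.baselines[self.best_name]


_DROPPABLE = ("n", "s", "t", "m", "a")


def prune_paths(data, baseline_spec: ModelSpec, alpha: float = 0.05,
                n_starts: int = 3, max_rounds: int = 6) -> dict:
    """Iteratively drop free paths whose 95% profile CI crosses zero.

    A path crosses zero when fixing it to zero worsens the deviance by less
    than the chi-squared(1) 95% critical value (the profile-likelihood test).
    All crossing paths are dropped together, the model refitted and tested
    against the baseline; pruning stops when nothing is droppable or the
    pooled drop degrades fit at level ``alpha``.  Dropping the transmission
    path m automatically zeroes the derived quantities x and w.
    """
    data = _as_data(data)
    crit = stats.chi2.ppf(1 - alpha, 1)
    baseline = fit_model(data, baseline_spec, n_starts=n_starts)
    current, current_spec = baseline, baseline_spec
    steps = []
    for _ in range(max_rounds):
        droppable = []
        for path in _DROPPABLE:
            if path not in current_spec.free_paths:
                continue
            trial_spec = ModelSpec(
                design=current_spec.design,
                free_paths=tuple(p for p in current_spec.free_paths if p != path),
                nonadditive_mode=current_spec.nonadditive_mode,
                name=f"{current_spec.label}-drop-{path}",
            )
            trial = fit_model(data, trial_spec, n_starts=n_starts)
            if trial.minus2LL - current.minus2LL < crit:
                droppable.append((path, trial))
        if not droppable:
            break
        if len(droppable) == 1:
            new_spec, new_fit = droppable[0][1].spec, droppable[0][1]
        else:
            dropped = tuple(p for p, _ in droppable)
            new_spec = ModelSpec(
                design=current_spec.design,
                free_paths=tuple(p for p in current_spec.free_paths if p not in dropped),
                nonadditive_mode=current_spec.nonadditive_mode,
                name=f"{current_spec.label}-drop-{'+'.join(dropped)}",
            )
            new_fit = fit_model(data, new_spec, n_starts=n_starts)
        test = lrt(new_fit, baseline)
        if test["p"] < alpha:
            break
        steps.append(PruneStep(dropped=tuple(set(current_spec.free_paths) - set(new_spec.free_paths)),
                               fit=new_fit, p_vs_parent=test["p"]))
        current, current_spec = new_fit, new_spec
    return {"baseline": baseline, "final": current, "steps": steps}


def run_ladder(data, nonadditive_mode: str = "dominance", n_starts: int = 3,
               alpha: float = 0.05) -> LadderReport:
    """Saturated model, six baselines, pruned submodels, and AIC selection."""
    data = _as_data(data)
    saturated = fit_saturated(data)
    presets = model_presets(nonadditive_mode)
    baseline_names = [f"{k}-{b}" for k in ("PA", "SH") for b in ("ASTPE", "ANTPE", "ANSTE")]
    baselines, pruned, history = {}, {}, {}
    rows = []
    for bn in baseline_names:
        res = prune_paths(data, presets[bn], alpha=alpha, n_starts=n_starts)
        baselines[bn] = res["baseline"]
        pruned[bn] = res["final"]
        history[bn] = res["steps"]
        t = lrt(res["baseline"], saturated)
        rows.append(dict(model=bn, minus2LL=res["baseline"].minus2LL,
                         n_params=res["baseline"].n_params, AIC=res["baseline"].AIC,
                         BIC=res["baseline"].BIC, against="Saturated",
                         delta_df=t["delta_df"], delta_minus2LL=t["delta_minus2LL"], p=t["p"]))
        if res["final"] is not res["baseline"]:
            t2 = lrt(res["final"], res["baseline"])
            rows.append(dict(model=res["final"].name, minus2LL=res["final"].minus2LL,
                             n_params=res["final"].n_params, AIC=res["final"].AIC,
                             BIC=res["final"].BIC, against=bn,
                             delta_df=t2["delta_df"], delta_minus2LL=t2["delta_minus2LL"], p=t2["p"]))
    comparisons = pd.DataFrame(rows)
    # select lowest AIC among baselines not significantly worse than saturated
    eligible = {bn: pruned[bn] for bn in baseline_names
                if lrt(baselines[bn], saturated)["p"] >= alpha}
    best_name = min(eligible or pruned, key=lambda k: (eligible or pruned)[k].AIC)
    return LadderReport(saturated=saturated, baselines=baselines, pruned=pruned,
                        history=history, comparisons=comparisons, best_name=best_name)
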