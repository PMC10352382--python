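# Methods

This note records the statistical models, the equilibrium algebra, and the
numerical choices implemented in `twinfam`. Notation: phenotypes are
standardized unless noted; `V` is the total phenotypic variance at
equilibrium.

## 1. Meta-analytic re-analysis

For a study subgroup with twin correlations `r_MZ` and `r_DZ`, the Falconer
decomposition under random mating is

```
A = 2 (r_MZ − r_DZ),   C = r_MZ − A,   E = 1 − r_MZ.
```

Assortative mating inflates the DZ (but not the MZ) genetic covariance. With
spousal phenotypic correlation `µ`, the DZ additive coefficient rises from ½
to ½(1 + µA), giving the quadratic `µA² − A + 2(r_MZ − r_DZ)·... = 0` whose
admissible root is

```
A_adj = [1 − sqrt(1 − 8 µ (r_MZ − r_DZ))] / (2µ),
C_adj = r_MZ − A_adj,   E = 1 − r_MZ.
```

As `µ → 0` this reduces to Falconer. Two truncation rules keep estimates in
the parameter space, applied per subgroup and flagged in the output table:

- if the discriminant `1 − 8µ(r_MZ − r_DZ)` is negative, or
- if `C_adj < 0`,

then `C` is set to 0 and `A` to `r_MZ` (five of the 13 packaged subgroups
truncate under `µ = 0.597`).

Fixed-effects pooling uses inverse-variance weights with the large-sample
variance of a correlation, `Var(r) = (1 − r²)² / n`, propagated linearly:

```
Var(A) = 4 [Var(r_MZ) + Var(r_DZ)],
Var(C) =    Var(r_MZ) + 4 Var(r_DZ),
Var(E) =    Var(r_MZ).
```

The adjusted estimates are pooled with the *unadjusted* weights, so that the
adjustment changes the estimates but not their relative influence; this keeps
the unadjusted and adjusted columns directly comparable and avoids the
degenerate zero-variance weights a truncated `C = 0` would otherwise produce.
Percentages are rounded half-up.

## 2. Nuclear twin family model

### Paths and components

Each phenotype is built from additive genes `A` (path `a`), non-additive
genes `N` (path `n`), sibling-shared environment `S` (path `s`),
twin-specific environment `T` (path `t`), unique environment `E` (path `e`),
and — when parents transmit environmentally — a familial environment `F`
received from the parents with path `m`. Reported variance components are the
standardized shares `A, N, S, T, P, rGE, E`, where `P = m²·(parental
phenotype variance term)/V` is the directly transmitted parental-phenotype
variance and `rGE` is the (doubled) covariance between transmitted genes and
transmitted environment induced jointly by parental transmission and
assortment.

### Equilibrium under assortment

Let `q` be the additive genetic variance inflation (`q = Var(A)/Var(A)_random
= 1` under random mating), `g = Cov(A, Ph)` the gene–phenotype covariance,
`w = Cov(A, F)` the gene–familial-environment covariance, and `x = Var(F)`.
With spousal copath `µ` (defined so that the spousal phenotypic covariance is
`µ · c_F²` on the matching key, see below), the stationary recursions are

```
q = 1 + µ c_A²
w = m (g + µ c_A c_F)
x = 2 m² (V + µ c_F²)
```

where `(c_A, c_F)` are the covariances of the *matching key* with `A` and
with the transmitted quantity:

- **Phenotypic assortment (PA)**: spouses match on the observed phenotype,
  so `c_A = g = a·q + w` and `c_F = V`.
- **Social homogamy (SH)**: spouses match on a latent social environment
  `L = F + unique-social` correlated with their own phenotype only through
  `F`; then `c_A = w` and `c_F = V_L + a·w` with
  `V_L = s² + t² + x + e²`-type terms on the latent scale.

The solver iterates these three equations to a fixed point (tolerance 1e-12)
and raises `EquilibriumError` on divergence. A useful internal identity,
checked in tests, is `q − ½ = ½ (q + µ c_A²)` rearranged for the DZ genetic
coefficient: DZ twins share `a²(q − ½ + ½µc_A²)`-equivalent additive variance
written as `a²(q − ½)` with `q` already at equilibrium.

### Transmission under social homogamy

A design decision with observable consequences: under SH, parents still
transmit their *observed phenotype* (`F_child = m (Ph_father + Ph_mother)` on
the path scale); only the *mate-matching key* is latent. Matching on a latent
environment leaves spousal genotypes essentially uncorrelated, while
phenotypic transmission generates passive gene–environment covariance
(`rGE ≈ 10%` of variance at the default calibration). The forward simulator
(Section 5) confirms both signatures: the spousal additive-genetic
correlation is ≈ `µ·h²` under PA and ≈ 0 under SH, and the SH-fit recovers a
substantial `rGE` share.

### Implied covariances

Standardized by `V`, the core entries are

```
r_MZ        = [a² q + n² + s² + t² + x + 2 a w] / V
r_DZ        = [a² (q − ½) + r_N n² + s² + t² + x + 2 a w] / V
r_twin-sib  = r_DZ − t² / V
r_parent-off= [½ a (g + µ c_F c_A) + m (V + µ c_F²)] / V
r_spousal   = µ c_F² / V
```

with `r_N = 0.25` for dominance and `0` for higher-order epistasis (a
configurable non-additive mode). The 5×5 family matrix (twin1, twin2,
sibling, mother, father) is assembled from these entries.

### Calibration

`calibrate_paths` finds path values whose standardized shares match requested
targets (e.g. `A = 0.51, S = 0.10, T = 0.16, E = 0.23`). Because `P` and
`rGE` are *emergent* under transmission and assortment, the requested shares
cannot in general sum to 1 of the total; the solver therefore renormalizes
the targets each iteration to the variance left over after the emergent
shares, and applies multiplicative fixed-point updates
`path ← path · sqrt(target/current)` (converges to 1e-10 in ~10 iterations).
`copath_for_spousal_r` inverts `r_spousal(µ)` for a requested spousal
correlation by bracketing (with step-halving where the equilibrium diverges)
followed by Brent root-finding.

## 3. FIML estimation

Raw family tables are grouped by zygosity × missingness pattern
(`FamilyData.from_table`); each group contributes
`Σ log N(y_i; 0, Σ_pattern)` with the implied covariance subset to the
observed roles, so families with missing fathers or siblings are retained
without imputation. The deviance `−2 log L` is minimized over the free paths
(plus `µ` where applicable) by multi-start L-BFGS-B on a bounded
parameterization; fits are deterministic given the data and start count.

The **saturated model** estimates one mean vector and unstructured covariance
per zygosity (15 covariance parameters per 5-role group), providing the
reference deviance for likelihood-ratio tests (`lrt`), with AIC/BIC reported
alongside. `run_ladder` fits the CTD and PA/SH model families, compares each
against the saturated model, prunes non-significant paths stepwise
(`prune_paths`), and reports the preferred model.

**Profile confidence intervals** for a variance component fix the component's
share via a quadratic penalty, re-optimize the remaining paths with a
warm-started Nelder–Mead (each profile point starts from the previous
solution), and locate the deviance crossing `−2ΔlogL = 3.84` by an outward
walk from the estimate followed by bisection. The walk-then-bisect order
matters: jumping straight to a distant candidate endpoint can leave the
penalized fit under-converged and collapse the interval.

## 4. Preprocessing

- **Qualification mapping**: ordered qualification codes map to years of
  education; an `enrolled:` prefix marks in-progress qualifications; unmapped
  codes are collected and reported rather than silently dropped.
- **Sibling filter**: siblings more than 5 years (strictly) from the twins'
  age are excluded; unknown ages are retained.
- **Residualization**: years of education are residualized on age and sex
  within role strata and standardized (`ea_std`); small strata fall back to
  the pooled model with a warning.
- **Dyad correlations**: Pearson correlations per dyad type with Fisher
  `tanh(atanh r ± 1.96/√(n−3))` confidence intervals.

## 5. Synthetic data

### Forward-time simulator

`simulate_population` evolves a population for a configurable number of
generations (default 10). Each generation: spouses are paired by rank-matching
on the mating key (observed phenotype under PA, latent social environment
under SH) with noise calibrated by bisection until the realized spousal
correlation hits the target within 0.01; offspring receive
`A = midparent + √½·N(0,1)` segregation, familial environment from the
parental phenotypes, and fresh `S/T/E` draws. MZ pairs clone `A` and `N`; the
non-additive correlation between DZ/sibs follows the configured mode. The
final cohort is shaped like the study sample: twin pairs plus one sibling,
mother, father, with role-specific age distributions, configurable
missingness, and optional discretization to 9–18 years of education.

Two numerical caveats, both verified empirically:

- **Burn-in clamp.** At generation 1 no gene–environment covariance exists
  yet, so under SH the target spousal correlation can exceed the maximum
  achievable; interior generations therefore accept the strongest achievable
  pairing, while the final generation must hit the target or raise
  `CalibrationError`.
- **Convergence transient.** The population approaches the analytic
  equilibrium geometrically; at the default 10 generations second moments sit
  ~0.3–1% below their equilibrium values. This is invisible at study scale
  but detectable as excess FIML deviance at ≥10⁴ families; by ~30 generations
  the gap is < 0.2%.

The simulator and the covariance algebra were developed as independent
implementations and agree (maximum dyad-correlation discrepancy ≈ 0.01–0.02
at 2×10⁴ families per zygosity) across PA, SH, and random-mating
configurations, including the spousal genetic-correlation contrast.

### Calibrated MVN sampler

`sample_families_mvn` draws family vectors directly from zygosity-specific
5×5 correlation matrices (rejecting non-PSD inputs), then applies study
missingness. It is the fast path for power analyses and for refitting models
to data generated at the observed dyad correlations.

## 6. Limitations

- The equilibrium algebra assumes a stationary population; cohort effects,
  secular trends in attainment, and age-varying heritability are out of
  scope.
- `P` and `rGE` are emergent quantities; target shares passed to
  `calibrate_paths` are renormalized accordingly and will not be hit exactly
  when `m ≠ 0`.
- Profile intervals use the χ²(1) calibration, which is approximate near the
  boundary of the parameter space (e.g. a component profiled at 0).
- The discretized education scale (9–18 years) mildly attenuates
  correlations; all fitting is done on the continuous standardized scale.
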