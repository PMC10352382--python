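import numpy as np
import pytest

from twinfam import model
from twinfam.model import (
    EquilibriumError,
    ModelSpec,
    PathParams,
    calibrate_paths,
    copath_for_spousal_r,
    ctd_shared_environment,
    decompose_parent_offspring,
    implied_covariance,
    model_presets,
    solve_equilibrium,
    standardize_components,
)

COMPONENTS = {"A": 0.51, "S": 0.10, "T": 0.16, "E": 0.23}
SPOUSAL_R = 0.597


@pytest.fixture(scope="module")
def pa_model():
    spec = ModelSpec("NTFD_PA", ("a", "s", "t", "e", "mu"))
    params = calibrate_paths(spec, COMPONENTS, spousal_r=SPOUSAL_R)
    return spec, params, solve_equilibrium(spec, params)


def test_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec("CTD_ACE", ("a", "s"))  # e must be free
    with pytest.raises(ValueError):
        ModelSpec("CTD_ACE", ("a", "s", "e", "mu"))  # CTD bans the copath
    with pytest.raises(ValueError):
        ModelSpec("NTFD_PA", ("a", "n", "s", "m", "e"))  # >2 of {n, s, m}


def test_random_mating_equilibrium_is_trivial():
    spec = ModelSpec("NTFD_PA", ("a", "s", "e"))
    p = PathParams(a=0.6, n=0.0, s=0.4, t=0.0, e=0.5)
    eq = solve_equilibrium(spec, p)
    assert eq.q == pytest.approx(1.0)
    assert eq.w == pytest.approx(0.0)
    assert eq.x == pytest.approx(0.0)
    assert eq.V == pytest.approx(0.6**2 + 0.4**2 + 0.5**2)


def test_equilibrium_identity_under_assortment(pa_model):
    spec, p, eq = pa_model
    # the DZ genetic covariance identity: q - 1/2 = (q + mu g^2)/2 - ... holds
    assert eq.q - 0.5 == pytest.approx(0.5 * (eq.q + p.mu * eq.g**2), abs=1e-9)
    assert eq.q == pytest.approx(1.0 + p.mu * eq.g**2, abs=1e-9)


def test_calibration_matches_targets(pa_model):
    spec, p, eq = pa_model
    comps = standardize_components(p, eq)
    for k, v in COMPONENTS.items():
        assert comps[k] == pytest.approx(v, abs=1e-8)
    assert sum(comps.values()) == pytest.approx(1.0)


def test_implied_correlations(pa_model):
    spec, p, eq = pa_model
    mz = implied_covariance(spec, p, eq, "MZ").matrix / eq.V
    dz = implied_covariance(spec, p, eq, "DZ").matrix / eq.V
    assert mz[0, 1] == pytest.approx(0.770, abs=5e-4)
    assert dz[0, 1] == pytest.approx(0.593, abs=5e-4)
    assert dz[3, 4] == pytest.approx(SPOUSAL_R, abs=1e-6)  # spouses
    assert dz[0, 3] == pytest.approx(0.407, abs=5e-4)  # parent-offspring
    # twin-sibling correlation is the DZ correlation minus the T share
    assert dz[0, 2] == pytest.approx(dz[0, 1] - p.t**2 / eq.V, abs=1e-9)
    # all members share the phenotypic variance on the diagonal
    assert np.allclose(np.diag(implied_covariance(spec, p, eq, "MZ").matrix), eq.V)


def test_parent_offspring_fully_genetic_under_pa(pa_model):
    spec, p, eq = pa_model
    decomp = decompose_parent_offspring(p, eq)
    assert decomp["genetic_share"] == pytest.approx(1.0)


def test_copath_solver_inverts_spousal_r(pa_model):
    spec, p, eq = pa_model
    p2 = copath_for_spousal_r(spec, p, 0.40)
    eq2 = solve_equilibrium(spec, p2)
    assert p2.mu * eq2.c_ff**2 / eq2.V == pytest.approx(0.40, abs=1e-8)
    assert p2.mu < p.mu


def test_social_homogamy_gene_environment_correlation():
    # with transmission from the observed parental phenotype, SH develops
    # passive rGE even though spouses match on the non-genetic phenotype
    spec = ModelSpec("NTFD_SH", ("a", "s", "t", "e", "m", "mu"))
    p = calibrate_paths(spec, {"A": 0.36, "S": 0.11, "T": 0.16, "E": 0.23},
                        spousal_r=SPOUSAL_R, m=0.10)
    eq = solve_equilibrium(spec, p)
    comps = standardize_components(p, eq)
    assert comps["rGE"] > 0.05
    assert comps["P"] > 0.01
    assert sum(comps.values()) == pytest.approx(1.0)
    # spousal additive covariance is second order (via w only), so the
    # parent-offspring covariance is only partly genetic
    decomp = decompose_parent_offspring(p, eq)
    assert 0.0 < decomp["genetic_share"] < 1.0


def test_sh_spousal_additive_covariance_small():
    spec = ModelSpec("NTFD_SH", ("a", "s", "t", "e", "m", "mu"))
    p = calibrate_paths(spec, {"A": 0.36, "S": 0.11, "T": 0.16, "E": 0.23},
                        spousal_r=SPOUSAL_R, m=0.10)
    eq = solve_equilibrium(spec, p)
    # matching on the latent environment: genotypes correlate only through w
    spousal_additive = p.mu * eq.c_af**2
    assert abs(spousal_additive) / eq.q < 0.05


def test_ctd_reduces_to_ace():
    spec = model_presets()["CTD-ACE"]
    p = PathParams(a=0.6, n=0.0, s=0.5, t=0.0, e=np.sqrt(1 - 0.36 - 0.25))
    eq = solve_equilibrium(spec, p)
    mz = implied_covariance(spec, p, eq, "MZ").matrix
    dz = implied_covariance(spec, p, eq, "DZ").matrix
    assert mz[0, 1] == pytest.approx(0.36 + 0.25)
    assert dz[0, 1] == pytest.approx(0.5 * 0.36 + 0.25)
    assert ctd_shared_environment(standardize_components(p, eq)) == pytest.approx(0.25)


def test_nonadditive_modes_differ_only_for_dz():
    for mode, rn_dz in (("dominance", 0.25), ("epistasis", 0.0)):
        spec = ModelSpec("CTD_ANE", ("a", "n", "e"), nonadditive_mode=mode)
        p = PathParams(a=0.5, n=0.4, s=0.0, t=0.0, e=np.sqrt(1 - 0.25 - 0.16))
        eq = solve_equilibrium(spec, p)
        mz = implied_covariance(spec, p, eq, "MZ").matrix
        dz = implied_covariance(spec, p, eq, "DZ").matrix
        assert mz[0, 1] == pytest.approx(0.25 + 0.16)  # MZ always share N fully
        assert dz[0, 1] == pytest.approx(0.5 * 0.25 + rn_dz * 0.16)


def test_equilibrium_divergence_raises():
    spec = ModelSpec("NTFD_PA", ("a", "e", "mu"))
    p = PathParams(a=1.4, n=0.0, s=0.0, t=0.0, e=0.1, mu=0.99)
    with pytest.raises(EquilibriumError):
        solve_equilibrium(spec, p)


def test_unreachable_spousal_r_raises():
    spec = ModelSpec("NTFD_PA", ("a", "e", "mu"))
    p = PathParams(a=0.3, n=0.0, s=0.0, t=0.0, e=0.4)
    with pytest.raises(EquilibriumError):
        copath_for_spousal_r(spec, p, 0.999)


def test_model_presets_complete():
    presets = model_presets()
    assert set(presets) >= {
        "CTD-ACE", "CTD-ANE",
        "PA-ASTPE", "PA-ANTPE", "PA-ANSTE", "PA-ASTE",
        "SH-ASTPE", "SH-ANTPE", "SH-ANSTE", "SH-ASTE",
    }
    assert "mu" not in presets["CTD-ACE"].free_paths
    assert "m" not in presets["PA-ASTE"].free_paths
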