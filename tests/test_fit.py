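import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinfam import datasets, simulate
from twinfam.fit import (
    FamilyData,
    chi2_p,
    fiml_loglik,
    fit_model,
    fit_saturated,
    information_criteria,
    lrt,
    profile_component_ci,
    prune_paths,
)
from twinfam.model import ModelSpec, PathParams, model_presets


@pytest.fixture(scope="module")
def twin_data(mvn_table_small):
    twins = mvn_table_small[mvn_table_small["role"].isin(("twin1", "twin2"))]
    return FamilyData.from_table(twins)


@pytest.fixture(scope="module")
def family_data(mvn_table_small):
    return FamilyData.from_table(mvn_table_small)


@pytest.fixture(scope="module")
def ctd_fit(twin_data):
    return fit_model(twin_data, model_presets()["CTD-ACE"], n_starts=2)


def test_family_data_grouping(mvn_table_small):
    data = FamilyData.from_table(mvn_table_small)
    n_rows = sum(rows.shape[0] for _, _, rows in data.groups)
    assert n_rows == data.n_families == mvn_table_small["family_id"].nunique()
    assert data.n_obs == int(mvn_table_small["ea_std"].notna().sum())
    zygosities = {z for z, _, _ in data.groups}
    assert zygosities == {"MZ", "DZ"}


def test_fiml_matches_closed_form_on_complete_twins():
    # two complete twin pairs: the FIML deviance must equal the sum of
    # bivariate-normal log densities
    table = pd.DataFrame({
        "family_id": ["f1", "f1", "f2", "f2"],
        "role": ["twin1", "twin2"] * 2,
        "zygosity": ["MZ", "MZ", "DZ", "DZ"],
        "sex": ["female"] * 4,
        "age": [24.0] * 4,
        "ea_std": [0.3, -0.2, 1.1, 0.4],
    })
    spec = model_presets()["CTD-ACE"]
    p = PathParams(a=0.6, n=0.0, s=0.5, t=0.0, e=np.sqrt(1 - 0.36 - 0.25))
    got = fiml_loglik(table, spec, p)
    mz_cov = np.array([[1.0, 0.61], [0.61, 1.0]])
    dz_cov = np.array([[1.0, 0.43], [0.43, 1.0]])
    expected = -2.0 * (
        stats.multivariate_normal(cov=mz_cov).logpdf([0.3, -0.2])
        + stats.multivariate_normal(cov=dz_cov).logpdf([1.1, 0.4])
    )
    assert got == pytest.approx(expected, rel=1e-10)


def test_information_criteria():
    ic = information_criteria(100.0, 3, 50)
    assert ic["AIC"] == pytest.approx(106.0)
    assert ic["BIC"] == pytest.approx(100.0 + 3 * np.log(50))


def test_chi2_p_values():
    assert chi2_p(0.0, 1) == pytest.approx(1.0)
    assert chi2_p(3.84, 1) == pytest.approx(0.05, abs=1e-3)


def test_ctd_fit_recovers_population_components(ctd_fit):
    c = ctd_fit.components
    C = c["S"] + c["T"] + c["P"] + c["rGE"]
    # population values from the sampled correlations: A = 0.348, C = 0.421
    assert c["A"] == pytest.approx(0.348, abs=0.12)
    assert C == pytest.approx(0.421, abs=0.12)
    assert c["E"] == pytest.approx(0.231, abs=0.05)
    assert c["A"] + C + c["E"] == pytest.approx(1.0, abs=1e-6)


def test_saturated_fits_no_worse_than_structured(twin_data, ctd_fit):
    sat = fit_saturated(twin_data)
    assert sat.minus2LL <= ctd_fit.minus2LL + 1e-6
    test = lrt(ctd_fit, sat)
    assert test["delta_df"] == sat.n_params - ctd_fit.n_params
    assert 0.0 <= test["p"] <= 1.0


def test_lrt_requires_nesting(ctd_fit):
    with pytest.raises(ValueError):
        lrt(ctd_fit, ctd_fit)


def test_ntfd_fit_recovers_components(family_data):
    fit = fit_model(family_data, model_presets()["PA-ASTE"], n_starts=2)
    c = fit.components
    # n = 1200 families: generous tolerances around the population solution
    assert c["A"] == pytest.approx(0.51, abs=0.12)
    assert c["E"] == pytest.approx(0.23, abs=0.06)
    assert c["S"] + c["T"] == pytest.approx(0.26, abs=0.12)
    assert fit.params.mu == pytest.approx(0.60, abs=0.12)
    assert fit.converged


def test_profile_ci_brackets_estimate(twin_data, ctd_fit):
    lo, hi = profile_component_ci(twin_data, model_presets()["CTD-ACE"], ctd_fit, "A")
    assert lo < ctd_fit.components["A"] < hi
    # CI width at n ~ 1000 pairs should be meaningful but not degenerate
    assert 0.03 < hi - lo < 0.5


def test_prune_drops_true_zero_path(family_data):
    # the sampled families carry no non-additive variance, so pruning the
    # ANSTE baseline must drop n
    res = prune_paths(family_data, model_presets()["PA-ANSTE"], n_starts=1)
    assert "n" not in res["final"].spec.free_paths
    assert res["final"].n_params <= res["baseline"].n_params


def test_fit_is_deterministic(twin_data):
    f1 = fit_model(twin_data, model_presets()["CTD-ACE"], n_starts=2)
    f2 = fit_model(twin_data, model_presets()["CTD-ACE"], n_starts=2)
    assert f1.minus2LL == f2.minus2LL
    assert np.array_equal(f1.theta, f2.theta)
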