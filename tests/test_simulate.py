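import dataclasses

import numpy as np
import pandas as pd
import pytest

from twinfam import datasets, model, simulate
from twinfam.simulate import (
    CalibrationError,
    SimConfig,
    default_config,
    sample_families_mvn,
    simulate_population,
    summarize,
)


def test_simulation_deterministic():
    cfg = default_config(seed=5, n_mz_families=60, n_dz_families=60)
    t1, p1 = simulate_population(cfg)
    t2, p2 = simulate_population(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert p1["realized_spousal_r"] == p2["realized_spousal_r"]


def test_simulation_seed_changes_output():
    t1, _ = simulate_population(default_config(seed=5, n_mz_families=60, n_dz_families=60))
    t2, _ = simulate_population(default_config(seed=6, n_mz_families=60, n_dz_families=60))
    assert not t1["ea_years"].equals(t2["ea_years"])


def test_study_shape(cohort_small):
    table, provenance = cohort_small
    assert set(table["role"]) == {"twin1", "twin2", "sibling", "mother", "father"}
    counts = table.groupby("zygosity")["family_id"].nunique()
    assert counts["MZ"] == 120 and counts["DZ"] == 120
    # every family has both twins and a mother
    per_fam = table.pivot_table(index="family_id", columns="role", values="ea_years", aggfunc="size")
    assert per_fam["twin1"].notna().all()
    assert per_fam["twin2"].notna().all()
    assert per_fam["mother"].notna().all()
    # fathers and siblings are missing at roughly the configured rates
    assert 0.3 < per_fam["father"].isna().mean() < 0.6
    assert 0.6 < per_fam["sibling"].isna().mean() < 0.9
    # target spousal correlation was reached
    assert provenance["realized_spousal_r"] == pytest.approx(0.597, abs=0.05)


def test_mz_twins_same_sex(cohort_small):
    table, _ = cohort_small
    mz = table[(table["zygosity"] == "MZ") & table["role"].isin(("twin1", "twin2"))]
    sexes = mz.pivot_table(index="family_id", columns="role", values="sex", aggfunc="first")
    assert (sexes["twin1"] == sexes["twin2"]).all()


def test_discretize_rounds_to_education_range():
    cfg = default_config(seed=11, n_mz_families=60, n_dz_families=60)
    cfg = dataclasses.replace(cfg, discretize=True)
    table, _ = simulate_population(cfg)
    assert table["ea_years"].between(9, 18).all()
    assert (table["ea_years"] == table["ea_years"].round()).all()


def test_ages_follow_role_ranges(cohort_small):
    table, _ = cohort_small
    twins = table[table["role"].isin(("twin1", "twin2"))]
    assert twins["age"].between(22, 27).all()
    mothers = table[table["role"] == "mother"]
    assert mothers["age"].between(41, 66).all()


def test_unreachable_spousal_target_raises():
    cfg = default_config(seed=0, n_mz_families=50, n_dz_families=50)
    cfg = dataclasses.replace(cfg, target_spousal_r=0.999)
    with pytest.raises(CalibrationError):
        simulate_population(cfg)


def test_mvn_sampler_recovers_dyad_correlations():
    table = sample_families_mvn(
        n_mz=3000, n_dz=3000,
        corr_mz=datasets.family_correlation_matrix("MZ"),
        corr_dz=datasets.family_correlation_matrix("DZ"),
        father_missing_rate=0.0, sibling_missing_rate=0.0, seed=17)
    wide = table.pivot_table(index="family_id", columns="role", values="ea_std", aggfunc="first")
    zyg = table.groupby("family_id")["zygosity"].first()
    mz = wide[zyg == "MZ"]
    assert np.corrcoef(mz["twin1"], mz["twin2"])[0, 1] == pytest.approx(0.769, abs=0.03)
    assert np.corrcoef(wide["mother"], wide["father"])[0, 1] == pytest.approx(0.597, abs=0.03)


def test_mvn_sampler_rejects_non_psd_matrix():
    bad = np.full((5, 5), 0.9)
    np.fill_diagonal(bad, 1.0)
    bad[0, 1] = bad[1, 0] = -0.9  # jointly infeasible
    with pytest.raises(ValueError, match="PSD"):
        sample_families_mvn(n_mz=10, n_dz=10, corr_mz=bad,
                            corr_dz=datasets.family_correlation_matrix("DZ"))


def test_summarize_shape(cohort_small):
    table, _ = cohort_small
    desc = summarize(table)
    assert "Total" in desc["group"].tolist()
    assert {"n", "ea_mean", "ea_sd"} <= set(desc.columns)


def test_forward_simulator_matches_model_oracle():
    # one PA configuration at moderate size; the dense grid is the
    # acceptance suite's job
    spec = model.ModelSpec("NTFD_PA", ("a", "s", "t", "e", "mu"))
    p = model.calibrate_paths(spec, {"A": 0.51, "S": 0.10, "T": 0.16, "E": 0.23},
                              spousal_r=0.597)
    eq = model.solve_equilibrium(spec, p)
    cfg = SimConfig(paths=p, n_mz_families=8000, n_dz_families=8000,
                    generations=12, mating="phenotypic_assortment",
                    target_spousal_r=0.597, seed=23, discretize=False,
                    father_missing_rate=0.0, sibling_missing_rate=0.0)
    mats = simulate.simulate_cohort_matrices(cfg)
    for zyg in ("MZ", "DZ"):
        emp = np.corrcoef(mats[zyg].T)
        imp = model.implied_covariance(spec, p, eq, zyg).matrix / eq.V
        se = 1.0 / np.sqrt(mats[zyg].shape[0])
        for i in range(5):
            for j in range(i + 1, 5):
                tol = 4 * se * (1 - imp[i, j] ** 2) + 0.01
                assert abs(emp[i, j] - imp[i, j]) < tol, (zyg, i, j)


def test_spousal_genetic_correlation_contrast():
    # phenotypic assortment induces a spousal genetic correlation ~ r * h2;
    # social homogamy leaves genotypes uncorrelated between spouses
    pa_spec = model.ModelSpec("NTFD_PA", ("a", "s", "t", "e", "mu"))
    pa = model.calibrate_paths(pa_spec, {"A": 0.51, "S": 0.10, "T": 0.16, "E": 0.23},
                               spousal_r=0.597)
    sh_spec = model.ModelSpec("NTFD_SH", ("a", "s", "t", "e", "m", "mu"))
    sh = model.calibrate_paths(sh_spec, {"A": 0.36, "S": 0.11, "T": 0.16, "E": 0.23},
                               spousal_r=0.597, m=0.10)
    out = {}
    for name, paths, mating in (("PA", pa, "phenotypic_assortment"),
                                ("SH", sh, "social_homogamy")):
        cfg = SimConfig(paths=paths, n_mz_families=5000, n_dz_families=5000,
                        generations=12, mating=mating, target_spousal_r=0.597,
                        seed=29, discretize=False,
                        father_missing_rate=0.0, sibling_missing_rate=0.0)
        out[name] = simulate.simulate_cohort_matrices(cfg)["spousal_genetic_r"]
    assert out["PA"] == pytest.approx(0.597 * 0.51, abs=0.05)
    assert abs(out["SH"]) < 0.05
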