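import numpy as np
import pandas as pd
import pytest

from twinfam import preprocess
from twinfam.preprocess import (
    QualificationMap,
    default_qualification_map,
    dyad_correlations,
    filter_siblings,
    fisher_ci,
    map_qualifications,
    residualize,
    run_preprocess,
    to_wide,
)

from conftest import make_family_table


def _family(fid, zyg="MZ", sib_age=24.0, twin_age=24.0):
    rows = [
        (fid, "twin1", zyg, "female", twin_age, 15.0),
        (fid, "twin2", zyg, "female", twin_age, 14.0),
        (fid, "sibling", zyg, "male", sib_age, 13.0),
        (fid, "mother", zyg, "female", 52.0, 12.0),
        (fid, "father", zyg, "male", 55.0, 13.0),
    ]
    return rows


def test_qualification_map_ordering_enforced():
    with pytest.raises(ValueError):
        QualificationMap({"a": 10, "b": 9})
    with pytest.raises(ValueError):
        QualificationMap({"a": 0})


def test_qualification_lookup_enrolled_prefix():
    qmap = default_qualification_map()
    assert qmap.lookup("abitur") == 13
    assert qmap.lookup("ENROLLED:Master") == 17
    with pytest.raises(KeyError):
        qmap.lookup("unknown-degree")


def test_map_qualifications_lists_all_unmapped_codes():
    df = pd.DataFrame({"qualification": ["abitur", "bogus1", "bogus2"]})
    with pytest.raises(KeyError) as err:
        map_qualifications(df)
    assert "bogus1" in str(err.value) and "bogus2" in str(err.value)


def test_map_qualifications_fills_years():
    df = pd.DataFrame({"qualification": ["hauptschule", "promotion"]})
    out = map_qualifications(df)
    assert list(out["ea_years"]) == [9.0, 18.0]


def test_sibling_filter_strict_boundary():
    table = make_family_table(
        _family("f1", sib_age=28.9)  # gap 4.9 -> kept
        + _family("f2", sib_age=29.0)  # gap exactly 5 -> removed
        + _family("f3", sib_age=30.0)  # gap 6 -> removed
    )
    out = filter_siblings(table)
    kept = out[out["role"] == "sibling"]["family_id"].tolist()
    assert kept == ["f1"]
    assert out.attrs["siblings_removed"] == 2


def test_sibling_filter_retains_unknown_ages():
    rows = _family("f1")
    table = make_family_table(rows)
    table.loc[table["role"] == "sibling", "age"] = np.nan
    out = filter_siblings(table)
    assert (out["role"] == "sibling").sum() == 1
    assert out.attrs["sibling_gap_unknown"] == 1


def test_residualize_removes_age_and_sex_effects():
    rng = np.random.default_rng(5)
    n = 400
    age = rng.uniform(22, 30, n)
    sex = rng.integers(0, 2, n)
    ea = 10 + 0.3 * age + 1.2 * sex + rng.normal(0, 1, n)
    table = pd.DataFrame({
        "family_id": [f"f{i}" for i in range(n)],
        "role": ["twin1"] * n,
        "zygosity": ["MZ"] * n,
        "sex": np.where(sex == 1, "male", "female"),
        "age": age,
        "ea_years": ea,
    })
    out = residualize(table)
    z = out["ea_std"].to_numpy()
    assert abs(np.corrcoef(z, age)[0, 1]) < 0.02
    assert abs(np.corrcoef(z, sex)[0, 1]) < 0.02
    assert np.mean(z) == pytest.approx(0.0, abs=1e-10)
    assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_residualize_small_stratum_falls_back_to_centering():
    table = make_family_table(_family("f1"))
    with pytest.warns(UserWarning, match="fewer|<10|centering"):
        out = residualize(table)
    assert out["ea_std"].notna().all()


def test_fisher_ci_known_values():
    lo, hi = fisher_ci(0.597, 482)
    assert lo == pytest.approx(0.5358, abs=5e-4)
    assert hi == pytest.approx(0.6517, abs=5e-4)
    with pytest.raises(ValueError):
        fisher_ci(0.5, 3)


def test_to_wide_one_row_per_family():
    table = make_family_table(_family("f1") + _family("f2", zyg="DZ"))
    table["ea_std"] = 1.0
    wide = to_wide(table)
    assert len(wide) == 2
    assert list(wide.loc["f1", ["twin1", "twin2"]]) == [1.0, 1.0]
    assert wide.loc["f2", "zygosity"] == "DZ"


def test_dyad_correlations_deterministic_and_complete(mvn_table_small):
    d1 = dyad_correlations(mvn_table_small, seed=7)
    d2 = dyad_correlations(mvn_table_small, seed=7)
    pd.testing.assert_frame_equal(d1, d2)
    assert set(d1["dyad"]) == {
        "mz_twins", "dz_twins", "sibling_twin", "mother_twin",
        "mother_sibling", "father_twin", "father_sibling", "parents",
    }
    assert ((d1["ci_low"] < d1["r"]) & (d1["r"] < d1["ci_high"])).all()


def test_dyad_correlations_recover_population_values(mvn_table_small):
    d = dyad_correlations(mvn_table_small, seed=7).set_index("dyad")
    # n = 600 per zygosity: sampling SE ~ 0.02-0.04 per dyad
    assert d.loc["mz_twins", "r"] == pytest.approx(0.769, abs=0.08)
    assert d.loc["dz_twins", "r"] == pytest.approx(0.595, abs=0.10)
    assert d.loc["parents", "r"] == pytest.approx(0.597, abs=0.10)


def test_run_preprocess_idempotent(cohort_small):
    table, _ = cohort_small
    once = run_preprocess(table)
    twice = run_preprocess(once)
    pd.testing.assert_series_equal(once["ea_std"], twice["ea_std"])
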