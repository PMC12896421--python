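"""Synthetic cohort generator: determinism, structure, CSV round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from albigrid import (
    CohortParseError,
    InvalidInputError,
    SyntheticCohortConfig,
    Zone,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from albigrid.zones import zones_of


def test_same_seed_gives_identical_cohorts(tmp_path):
    cfg = SyntheticCohortConfig(n_patients=400, seed=123)
    r1, t1 = generate_cohort(cfg)
    r2, t2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(r1, r2)
    pd.testing.assert_frame_equal(t1, t2)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(r1, p1, seed=cfg.seed)
    write_cohort_csv(r2, p2, seed=cfg.seed)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ():
    r1, _ = generate_cohort(SyntheticCohortConfig(n_patients=200, seed=1))
    r2, _ = generate_cohort(SyntheticCohortConfig(n_patients=200, seed=2))
    assert not r1.equals(r2)


def test_degenerate_mixture_maps_every_patient_to_one_zone():
    cfg = SyntheticCohortConfig(
        n_patients=300,
        zone_weights={Zone.AL_HIGH_1: 1.0},
        p_out_of_cpa=0.0,
        p_low_bilirubin_extreme=0.0,
        p_high_albumin_extreme=0.0,
        subgroup_zone_weights=None,
        seed=3,
    )
    records, truth = generate_cohort(cfg)
    final = records.merge(
        truth[["patient_id", "retained_date"]], on="patient_id"
    ).query("date == retained_date")
    zones = zones_of(final["albumin"], final["bilirubin"])
    assert all(z is Zone.AL_HIGH_1 for z in zones)
    assert (truth["zone"] == Zone.AL_HIGH_1.label).all()


def test_cpa_filter_survival_matches_contamination_rate():
    """~80% of patients carry in-CP-A final values (the 19.6% out-of-range
    contamination), within 3 binomial standard errors."""
    cfg = SyntheticCohortConfig(n_patients=4000, seed=9)
    _, truth = generate_cohort(cfg)
    survive = (truth["category"] != "out_of_cpa").mean()
    tol = 3 * math.sqrt(0.196 * 0.804 / cfg.n_patients)
    assert abs(survive - 0.804) < tol


def test_visit_counts_poisson_distributed(small_cohort):
    cfg, records, _ = small_cohort
    visits = records.groupby("patient_id").size()
    assert len(visits) == cfg.n_patients
    assert (visits >= 1).all()
    # mean of 1 + Poisson(1) is 2
    assert abs(visits.mean() - 2.0) < 3 * 1.0 / math.sqrt(cfg.n_patients)


def test_wide_csv_round_trip(tmp_path, small_cohort):
    _, records, _ = small_cohort
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path, seed=11)
    back = read_cohort_csv(path)
    pd.testing.assert_frame_equal(back, records)
    assert path.read_text().startswith("# albigrid cohort")


def test_long_csv_round_trip_through_pairing(tmp_path, small_cohort):
    from albigrid import pair_same_day

    _, records, _ = small_cohort
    path = tmp_path / "cohort_long.csv"
    write_cohort_csv(records, path, long_format=True)
    back = read_cohort_csv(path)
    assert {"analyte", "value"} <= set(back.columns)
    paired = pair_same_day(back)
    merged = paired.merge(
        records, on=["patient_id", "date"], suffixes=("", "_orig")
    )
    assert len(merged) == len(records)
    assert np.allclose(merged["albumin"], merged["albumin_orig"])
    assert np.allclose(merged["bilirubin"], merged["bilirubin_orig"])


def test_empty_cohort_file_reads_empty(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("patient_id,date,albumin,bilirubin,icd10_codes\n")
    assert len(read_cohort_csv(path)) == 0


def test_malformed_numeric_names_the_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# meta\n"
        "patient_id,date,albumin,bilirubin,icd10_codes\n"
        "P1,2024-01-01,4.2,0.8,\n"
        "P2,2024-01-02,four,0.9,\n"
    )
    with pytest.raises(CohortParseError) as exc:
        read_cohort_csv(path)
    assert exc.value.line == 4


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 0},
        {"p_out_of_cpa": 1.5},
        {"zone_weights": {Zone.AL_HIGH_1: 0.0}},
        {"visit_rate": -1.0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(InvalidInputError):
        SyntheticCohortConfig(**kwargs)


def test_inconsistent_subgroup_weights_rejected():
    """Subgroup mixtures must difference out of the total (HCC in CLD in
    total); an impossible combination is caught at sampling setup."""
    cfg = SyntheticCohortConfig(
        zone_weights={Zone.AL_HIGH_1: 1.0, Zone.AL_LOW_2: 1.0},
        subgroup_zone_weights={
            "cld": {Zone.AL_LOW_2: 1.0},
            "hcc": {Zone.AL_HIGH_1: 1.0},
        },
        p_cld=0.9,
        p_hcc_given_cld=0.5,
    )
    with pytest.raises(InvalidInputError):
        cfg.stratum_zone_probs()


def test_disease_codes_match_strata(small_cohort):
    _, records, truth = small_cohort
    codes = records.drop_duplicates("patient_id").merge(truth, on="patient_id")
    hcc = codes[codes["stratum"] == "hcc"]
    assert hcc["icd10_codes"].str.contains("C22").all()
    none = codes[codes["stratum"] == "none"]
    assert not none["icd10_codes"].str.contains(
        "B18|B19|K70|K73|K74|C22", regex=True
    ).any()
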