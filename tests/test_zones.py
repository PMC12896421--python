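"""Seven-zone partition, three-step classifier and concordance auditing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from albigrid import (
    LabPair,
    NotApplicableError,
    NotClassifiableError,
    RuleOutcome,
    Zone,
    ZoneRuleSet,
    classify,
    classify_zone,
    concordance_analysis,
    rule_outcome,
    three_step_classify,
)
from albigrid.zones import NONMIXED_ZONES, zone_lattice_cells, zones_of


@pytest.mark.parametrize(
    "albumin, bilirubin, zone",
    [
        (4.5, 2.9, Zone.AL_HIGH_1),  # high albumin dominates any bilirubin
        (4.4, 0.3, Zone.AL_HIGH_1),  # boundary inclusive
        (3.3, 2.5, Zone.EXCLUDED_CPB),
        (3.5, 2.0, Zone.EXCLUDED_CPB),  # both combination edges inclusive
        (3.5, 1.9, Zone.AL_LOW_2),  # albumin exactly 3.5 is Al-Low, not Int
        (3.0, 1.0, Zone.AL_LOW_2),  # cohort box admits albumin 3.0
        (4.1, 2.4, Zone.BI_HIGH_2),
        (4.3, 0.5, Zone.INT_BETTER_1),
        (4.0, 1.0, Zone.INT_WORSE_2),  # refinement corner itself
        (4.2, 1.5, Zone.INT_HIGH_X),
        (3.8, 0.5, Zone.INT_LOW_X),
        (2.5, 1.0, Zone.OUT_OF_RANGE),
        (4.0, 3.5, Zone.OUT_OF_RANGE),
        (5.6, 1.0, Zone.OUT_OF_RANGE),
        (4.0, 0.2, Zone.OUT_OF_RANGE),
    ],
)
def test_classify_zone_boundary_conventions(albumin, bilirubin, zone):
    assert classify_zone(LabPair(albumin, bilirubin)) is zone


@given(
    albumin=st.floats(min_value=0.5, max_value=8.0),
    bilirubin=st.floats(min_value=0.05, max_value=8.0),
)
@settings(max_examples=300, derandomize=True)
def test_classify_zone_total_and_vectorization_consistent(albumin, bilirubin):
    """Every positive pair gets exactly one zone, identically scalar and
    vectorised."""
    zone = classify_zone(LabPair(albumin, bilirubin))
    assert isinstance(zone, Zone)
    assert zones_of(np.array([albumin]), np.array([bilirubin]))[0] is zone


@pytest.mark.parametrize(
    "zone, outcome",
    [
        (Zone.AL_HIGH_1, RuleOutcome.GRADE1),
        (Zone.INT_BETTER_1, RuleOutcome.GRADE1),
        (Zone.AL_LOW_2, RuleOutcome.GRADE2),
        (Zone.BI_HIGH_2, RuleOutcome.GRADE2),
        (Zone.INT_WORSE_2, RuleOutcome.GRADE2),
        (Zone.INT_HIGH_X, RuleOutcome.NEEDS_FORMULA),
        (Zone.INT_LOW_X, RuleOutcome.NEEDS_FORMULA),
    ],
)
def test_rule_outcome_follows_zone_suffix(zone, outcome):
    assert rule_outcome(zone) is outcome


@pytest.mark.parametrize("zone", [Zone.EXCLUDED_CPB, Zone.OUT_OF_RANGE])
def test_sentinel_zones_have_no_outcome(zone):
    with pytest.raises(NotClassifiableError):
        rule_outcome(zone)


def test_three_step_examples():
    r1 = three_step_classify(LabPair(4.8, 0.5))
    assert (r1.grade, r1.used_formula) == (1, False)
    r2 = three_step_classify(LabPair(3.9, 1.2))
    assert (r2.grade, r2.used_formula) == (2, False)
    r3 = three_step_classify(LabPair(3.9, 0.5))
    assert r3.used_formula and r3.zone is Zone.INT_LOW_X
    assert r3.grade == classify(LabPair(3.9, 0.5)).grade


@pytest.mark.parametrize("albumin, bilirubin", [(2.5, 1.0), (3.2, 2.5), (4.0, 3.5)])
def test_three_step_rejects_non_cpa_values(albumin, bilirubin):
    with pytest.raises(NotClassifiableError):
        three_step_classify(LabPair(albumin, bilirubin))


def test_invalid_rule_cutoffs_rejected():
    with pytest.raises(Exception):
        ZoneRuleSet(albumin_low=4.0, albumin_mid=3.5)


def test_zone_lattice_cells_partition_the_grid():
    cells = [c for z in Zone if z.is_analytic for c in zone_lattice_cells(z)]
    assert len(cells) == len(set(cells)) == 645


@pytest.mark.parametrize("zone", NONMIXED_ZONES)
def test_lattice_concordance_is_exact_in_decided_zones(zone):
    """On the 0.1 reporting lattice every decided zone is pure."""
    report = concordance_analysis(zone, 4000, seed=5, precision_mode="deci")
    assert report.agreement == 1.0
    assert report.discordant_examples == []


def test_continuous_concordance_int_worse_exact():
    """The worst corner of Int-Worse-2 is (4.0, 1.0) with score -2.586,
    above the grade-1 bound, so no continuous point disagrees."""
    report = concordance_analysis(
        Zone.INT_WORSE_2, 50_000, seed=6, precision_mode="continuous"
    )
    assert report.agreement == 1.0


def test_continuous_concordance_int_better_boundary_sliver():
    """A sliver hugging the (4.0, 1.0) corner of Int-Better-1 is formula
    grade 2; agreement stays >= 99% and discordant samples sit in it."""
    report = concordance_analysis(
        Zone.INT_BETTER_1, 200_000, seed=7, precision_mode="continuous"
    )
    assert 0.99 <= report.agreement < 1.0
    for pair in report.discordant_examples:
        assert pair.albumin < 4.05 and pair.bilirubin > 0.9


def test_concordance_rejects_mixed_zone():
    with pytest.raises(NotApplicableError):
        concordance_analysis(Zone.INT_LOW_X, 100, seed=0)
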