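"""Seven-zone cutoff partition of the Child-Pugh A plane and bedside rules.

The Child-Pugh A (CP-A) analytic box -- albumin 3.0-5.5 g/dL, bilirubin
0.3-3.0 mg/dL, minus the low-albumin/high-bilirubin combination that
corresponds to CP-B -- is partitioned into seven axis-aligned rectangles
by three albumin cutoffs (3.5, 4.0, 4.4 g/dL) and two bilirubin cutoffs
(1.0, 2.4 mg/dL):

* ``Al-High-1`` (albumin >= 4.4) and ``Int-Better-1`` are always ALBI
  grade 1 on the reporting lattice;
* ``Al-Low-2`` (albumin <= 3.5), ``Bi-High-2`` (bilirubin >= 2.4) and
  ``Int-Worse-2`` are always grade 2;
* the two mixed zones ``Int-High-x`` and ``Int-Low-x`` contain both
  grades, so the ALBI formula must be evaluated there.

``three_step_classify`` implements the resulting bedside flowchart:
albumin thresholds first, then the bilirubin threshold, then the
refinement corner at (albumin 4.0, bilirubin 1.0), falling back to the
formula only inside a mixed zone.  ``concordance_analysis`` audits how
often the rule grade agrees with the formula grade under uniform
sampling inside a zone, either at continuous precision or snapped to
the 0.1 laboratory reporting lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import AlbiParameters, DEFAULT_PARAMS, LabPair, albi_grade, albi_score
from .errors import InvalidInputError, NotApplicableError, NotClassifiableError

__all__ = [
    "Zone",
    "RuleOutcome",
    "ZoneRuleSet",
    "DEFAULT_RULES",
    "ConcordanceReport",
    "ThreeStepResult",
    "classify_zone",
    "zones_of",
    "rule_outcome",
    "three_step_classify",
    "concordance_analysis",
    "overall_nonmixed_concordance",
    "zone_rectangle",
    "zone_lattice_cells",
    "formula_grades",
]

# CP-A analytic box for cohort data (g/dL, mg/dL); the derivation grid
# starts at albumin 3.1 but measured cohorts admit 3.0.
CPA_ALBUMIN_MIN = 3.0
CPA_ALBUMIN_MAX = 5.5
CPA_BILIRUBIN_MIN = 0.3
CPA_BILIRUBIN_MAX = 3.0


class Zone(Enum):
    """Seven analytic zones plus the two non-analytic sentinels."""

    AL_HIGH_1 = "Al-High-1"
    AL_LOW_2 = "Al-Low-2"
    BI_HIGH_2 = "Bi-High-2"
    INT_BETTER_1 = "Int-Better-1"
    INT_WORSE_2 = "Int-Worse-2"
    INT_HIGH_X = "Int-High-x"
    INT_LOW_X = "Int-Low-x"
    EXCLUDED_CPB = "CP-B"
    OUT_OF_RANGE = "out-of-range"

    @property
    def label(self) -> str:
        return self.value

    @property
    def is_analytic(self) -> bool:
        return self not in (Zone.EXCLUDED_CPB, Zone.OUT_OF_RANGE)

    @property
    def is_mixed(self) -> bool:
        return self in (Zone.INT_HIGH_X, Zone.INT_LOW_X)


ANALYTIC_ZONES = tuple(z for z in Zone if z.is_analytic)
NONMIXED_ZONES = tuple(z for z in ANALYTIC_ZONES if not z.is_mixed)


class RuleOutcome(Enum):
    """What the zone rules alone say about a patient."""

    GRADE1 = 1
    GRADE2 = 2
    NEEDS_FORMULA = 0


@dataclass(frozen=True)
class ZoneRuleSet:
    """The five cutoff values defining the seven-zone partition."""

    albumin_low: float = 3.5
    albumin_mid: float = 4.0
    albumin_high: float = 4.4
    bilirubin_low: float = 1.0
    bilirubin_high: float = 2.4

    def __post_init__(self) -> None:
        if not self.albumin_low < self.albumin_mid < self.albumin_high:
            raise InvalidInputError("albumin cutoffs must be strictly increasing")
        if not self.bilirubin_low < self.bilirubin_high:
            raise InvalidInputError("bilirubin cutoffs must be strictly increasing")


DEFAULT_RULES = ZoneRuleSet()


def classify_zone(pair: LabPair, rules: ZoneRuleSet = DEFAULT_RULES) -> Zone:
    """Assign a lab pair to exactly one zone (total on the positive quadrant).

    Boundary conventions follow the published rule text: albumin exactly
    at 4.4 is ``Al-High-1``, exactly at 3.5 is ``Al-Low-2`` (the low rule
    takes precedence over the intermediate band), bilirubin thresholds
    are inclusive from above (>= 1.0, >= 2.4), and the CP-B combination
    (albumin <= 3.5 with bilirubin >= 2.0) is a sentinel, not a zone.
    """
    a, b = pair.albumin, pair.bilirubin
    if (
        a < CPA_ALBUMIN_MIN
        or a > CPA_ALBUMIN_MAX
        or b < CPA_BILIRUBIN_MIN
        or b > CPA_BILIRUBIN_MAX
    ):
        return Zone.OUT_OF_RANGE
    if a <= rules.albumin_low and b >= 2.0:
        return Zone.EXCLUDED_CPB
    if a >= rules.albumin_high:
        return Zone.AL_HIGH_1
    if a <= rules.albumin_low:
        return Zone.AL_LOW_2
    # intermediate albumin band
    if b >= rules.bilirubin_high:
        return Zone.BI_HIGH_2
    if a > rules.albumin_mid:
        return Zone.INT_BETTER_1 if b < rules.bilirubin_low else Zone.INT_HIGH_X
    return Zone.INT_WORSE_2 if b >= rules.bilirubin_low else Zone.INT_LOW_X


def zones_of(
    albumin: np.ndarray,
    bilirubin: np.ndarray,
    rules: ZoneRuleSet = DEFAULT_RULES,
) -> np.ndarray:
    """Vectorised :func:`classify_zone` over parallel value arrays.

    Returns an object array of :class:`Zone` members; used by the cohort
    pipeline where row-by-row construction of ``LabPair`` would dominate.
    """
    a = np.asarray(albumin, dtype=float)
    b = np.asarray(bilirubin, dtype=float)
    out_of_range = (
        (a < CPA_ALBUMIN_MIN)
        | (a > CPA_ALBUMIN_MAX)
        | (b < CPA_BILIRUBIN_MIN)
        | (b > CPA_BILIRUBIN_MAX)
    )
    conditions = [
        out_of_range,
        (a <= rules.albumin_low) & (b >= 2.0),
        a >= rules.albumin_high,
        a <= rules.albumin_low,
        b >= rules.bilirubin_high,
        (a > rules.albumin_mid) & (b < rules.bilirubin_low),
        (a <= rules.albumin_mid) & (b >= rules.bilirubin_low),
        a > rules.albumin_mid,
    ]
    choices = [
        Zone.OUT_OF_RANGE,
        Zone.EXCLUDED_CPB,
        Zone.AL_HIGH_1,
        Zone.AL_LOW_2,
        Zone.BI_HIGH_2,
        Zone.INT_BETTER_1,
        Zone.INT_WORSE_2,
        Zone.INT_HIGH_X,
    ]
    result = np.select(conditions, choices, default=Zone.INT_LOW_X)
    return result.astype(object)


def rule_outcome(zone: Zone) -> RuleOutcome:
    """Grade claim carried by a zone's label suffix (-1, -2 or x)."""
    if not zone.is_analytic:
        raise NotClassifiableError(f"zone {zone.label} carries no grade claim")
    if zone in (Zone.AL_HIGH_1, Zone.INT_BETTER_1):
        return RuleOutcome.GRADE1
    if zone in (Zone.AL_LOW_2, Zone.BI_HIGH_2, Zone.INT_WORSE_2):
        return RuleOutcome.GRADE2
    return RuleOutcome.NEEDS_FORMULA


@dataclass(frozen=True)
class ThreeStepResult:
    grade: int
    used_formula: bool
    zone: Zone


def three_step_classify(
    pair: LabPair,
    rules: ZoneRuleSet = DEFAULT_RULES,
    params: AlbiParameters = DEFAULT_PARAMS,
) -> ThreeStepResult:
    """Bedside three-step ALBI grading.

    Step 1: albumin >= 4.4 -> grade 1; albumin <= 3.5 -> grade 2.
    Step 2: bilirubin >= 2.4 -> grade 2.
    Step 3: refinement at (4.0, 1.0): the concordant quadrants are decided
    (grade 1 favorable, grade 2 unfavorable); the two discordant quadrants
    are the mixed zones, where the ALBI formula is evaluated.

    Raises :class:`NotClassifiableError` outside the CP-A analytic range.
    """
    zone = classify_zone(pair, rules)
    if not zone.is_analytic:
        raise NotClassifiableError(
            f"({pair.albumin}, {pair.bilirubin}) is {zone.label}; "
            "the three-step algorithm applies to CP-A values only"
        )
    outcome = rule_outcome(zone)
    if outcome is RuleOutcome.NEEDS_FORMULA:
        grade = albi_grade(albi_score(pair, params), params)
        return ThreeStepResult(grade=grade, used_formula=True, zone=zone)
    return ThreeStepResult(grade=outcome.value, used_formula=False, zone=zone)


def zone_rectangle(
    zone: Zone, rules: ZoneRuleSet = DEFAULT_RULES
) -> tuple[float, float, float, float]:
    """Bounding rectangle (alb_lo, alb_hi, bili_lo, bili_hi) of an analytic zone.

    Bounds are the closure of the zone; which edges belong to the zone
    follows the inequalities in :func:`classify_zone` (interior sampling
    is unaffected since edges have measure zero).
    """
    r = rules
    boxes = {
        Zone.AL_HIGH_1: (r.albumin_high, CPA_ALBUMIN_MAX, CPA_BILIRUBIN_MIN, CPA_BILIRUBIN_MAX),
        Zone.AL_LOW_2: (CPA_ALBUMIN_MIN, r.albumin_low, CPA_BILIRUBIN_MIN, 2.0),
        Zone.BI_HIGH_2: (r.albumin_low, r.albumin_high, r.bilirubin_high, CPA_BILIRUBIN_MAX),
        Zone.INT_BETTER_1: (r.albumin_mid, r.albumin_high, CPA_BILIRUBIN_MIN, r.bilirubin_low),
        Zone.INT_WORSE_2: (r.albumin_low, r.albumin_mid, r.bilirubin_low, r.bilirubin_high),
        Zone.INT_HIGH_X: (r.albumin_mid, r.albumin_high, r.bilirubin_low, r.bilirubin_high),
        Zone.INT_LOW_X: (r.albumin_low, r.albumin_mid, CPA_BILIRUBIN_MIN, r.bilirubin_low),
    }
    try:
        return boxes[zone]
    except KeyError:
        raise NotApplicableError(f"{zone.label} has no analytic rectangle") from None


def zone_lattice_cells(
    zone: Zone,
    rules: ZoneRuleSet = DEFAULT_RULES,
    albumin_min_deci: int = 31,
) -> list[tuple[int, int]]:
    """All 0.1-lattice cells (deci-units) of an analytic zone.

    The derivation grid starts at albumin 3.1 g/dL (``albumin_min_deci=31``);
    pass 30 for the cohort box, which admits albumin 3.0.
    """
    if not zone.is_analytic:
        raise NotApplicableError(f"{zone.label} has no lattice cells")
    cells = []
    for a in range(albumin_min_deci, 56):
        for b in range(3, 31):
            if classify_zone(LabPair(a / 10, b / 10), rules) is zone:
                cells.append((a, b))
    return cells


@dataclass
class ConcordanceReport:
    """Rule-vs-formula agreement under uniform sampling inside a zone."""

    zone: Zone | None
    n_samples: int
    n_agree: int
    discordant_examples: list[LabPair] = field(default_factory=list)

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_samples


_MAX_DISCORDANT_EXAMPLES = 20


def _sample_zone(
    zone: Zone,
    n: int,
    rng: np.random.Generator,
    rules: ZoneRuleSet,
    precision_mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    if precision_mode == "deci":
        cells = zone_lattice_cells(zone, rules)
        idx = rng.integers(0, len(cells), size=n)
        arr = np.array(cells, dtype=float)[idx] / 10.0
        return arr[:, 0], arr[:, 1]
    if precision_mode == "continuous":
        alo, ahi, blo, bhi = zone_rectangle(zone, rules)
        return rng.uniform(alo, ahi, size=n), rng.uniform(blo, bhi, size=n)
    raise InvalidInputError(f"unknown precision_mode {precision_mode!r}")


def formula_grades(
    albumin: np.ndarray, bilirubin: np.ndarray, params: AlbiParameters
) -> np.ndarray:
    scores = params.bilirubin_coefficient * np.log10(
        bilirubin * params.bilirubin_mgdl_to_umol
    ) + params.albumin_coefficient * (albumin * params.albumin_gdl_to_gl)
    if params.score_decimals is not None:
        scores = np.round(scores, params.score_decimals)
    grades = np.full(scores.shape, 3, dtype=int)
    grades[scores <= params.grade2_max_score] = 2
    grades[scores <= params.grade1_max_score] = 1
    return grades


def concordance_analysis(
    zone: Zone,
    n_samples: int,
    seed: int,
    rules: ZoneRuleSet = DEFAULT_RULES,
    params: AlbiParameters = DEFAULT_PARAMS,
    precision_mode: str = "continuous",
) -> ConcordanceReport:
    """Agreement of a zone's grade claim with the ALBI formula.

    Samples uniformly inside the zone (continuous, or snapped to the 0.1
    reporting lattice in ``deci`` mode) and compares the suffix grade with
    the formula grade.  Mixed zones make no claim, so requesting one
    raises :class:`NotApplicableError`.
    """
    if zone.is_mixed or not zone.is_analytic:
        raise NotApplicableError(f"{zone.label} makes no rule-only grade claim")
    if n_samples <= 0:
        raise InvalidInputError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    alb, bili = _sample_zone(zone, n_samples, rng, rules, precision_mode)
    claimed = rule_outcome(zone).value
    grades = formula_grades(alb, bili, params)
    agree = grades == claimed
    discordant = np.flatnonzero(~agree)[:_MAX_DISCORDANT_EXAMPLES]
    examples = [LabPair(float(alb[i]), float(bili[i])) for i in discordant]
    return ConcordanceReport(
        zone=zone,
        n_samples=n_samples,
        n_agree=int(agree.sum()),
        discordant_examples=examples,
    )


def overall_nonmixed_concordance(
    n_samples: int,
    seed: int,
    rules: ZoneRuleSet = DEFAULT_RULES,
    params: AlbiParameters = DEFAULT_PARAMS,
    precision_mode: str = "continuous",
) -> ConcordanceReport:
    """Area-weighted rule-vs-formula agreement across the five non-mixed zones.

    Zones are sampled proportionally to their rectangle areas, i.e. the
    result is the agreement under a uniform draw from the union of the
    directly-classifiable region.
    """
    areas = {}
    for zone in NONMIXED_ZONES:
        alo, ahi, blo, bhi = zone_rectangle(zone, rules)
        areas[zone] = (ahi - alo) * (bhi - blo)
    total_area = sum(areas.values())
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(
        n_samples, [areas[z] / total_area for z in NONMIXED_ZONES]
    )
    n_agree = 0
    examples: list[LabPair] = []
    for zone, n_zone in zip(NONMIXED_ZONES, counts):
        if n_zone == 0:
            continue
        sub_seed = int(rng.integers(0, 2**31))
        report = concordance_analysis(
            zone, int(n_zone), sub_seed, rules, params, precision_mode
        )
        n_agree += report.n_agree
        examples.extend(report.discordant_examples)
    return ConcordanceReport(
        zone=None,
        n_samples=n_samples,
        n_agree=n_agree,
        discordant_examples=examples[:_MAX_DISCORDANT_EXAMPLES],
    )
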