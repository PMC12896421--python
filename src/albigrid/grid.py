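"""Exhaustive enumeration of the Child-Pugh A albumin x bilirubin matrix.

Laboratory values are reported in 0.1 increments, so the CP-A plane
(albumin 3.1-5.5 g/dL, bilirubin 0.3-3.0 mg/dL) contains finitely many
distinct value pairs: 25 x 28 = 700, of which 55 (albumin 3.1-3.5 with
bilirubin 2.0-3.0, the CP-B combination) are excluded, leaving 645
eligible pairs.  Every eligible pair is scored with the ALBI formula and
assigned to one of the seven cutoff zones, which is how the cutoffs were
derived and is the reference distribution for cohort validation.

Lattice coordinates are integers in tenths throughout: 0.1 is not
exactly representable in binary floating point and a naive float range
drops or duplicates endpoints.  Step sizes other than multiples of 0.1
are rejected; for a coarser step the lattice consists of the integer
multiples of the step inside the bounds (e.g. step 0.2 gives albumin
3.2-5.4 and bilirubin 0.4-3.0, the even tenths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import AlbiParameters, DEFAULT_PARAMS, LabPair, classify
from .errors import InvalidInputError, UnsupportedStepError
from .zones import (
    DEFAULT_RULES,
    RuleOutcome,
    Zone,
    ZoneRuleSet,
    classify_zone,
    rule_outcome,
)

__all__ = [
    "GridSpec",
    "GridCell",
    "SimulationSummary",
    "enumerate_grid",
    "annotate_grid",
    "run_simulation",
    "zone_purity_report",
    "grid_to_dataframe",
    "render_matrix",
]


def _to_deci(value: float, name: str) -> int:
    deci = round(value * 10)
    if abs(deci - value * 10) > 1e-9:
        raise InvalidInputError(f"{name}={value} is not a multiple of 0.1")
    return deci


@dataclass(frozen=True)
class GridSpec:
    """Bounds, step and CP-B exclusion box of the derivation lattice."""

    albumin_min: float = 3.1
    albumin_max: float = 5.5
    bilirubin_min: float = 0.3
    bilirubin_max: float = 3.0
    step: float = 0.1
    cpb_albumin_max: float = 3.5
    cpb_bilirubin_min: float = 2.0

    def __post_init__(self) -> None:
        if self.albumin_min >= self.albumin_max:
            raise InvalidInputError("albumin_min must be below albumin_max")
        if self.bilirubin_min >= self.bilirubin_max:
            raise InvalidInputError("bilirubin_min must be below bilirubin_max")
        if self.step <= 0:
            raise UnsupportedStepError(f"step must be positive, got {self.step}")
        step_deci = round(self.step * 10)
        if step_deci < 1 or abs(step_deci - self.step * 10) > 1e-9:
            raise UnsupportedStepError(
                f"step={self.step} is not a multiple of the 0.1 reporting increment"
            )
        for name in (
            "albumin_min",
            "albumin_max",
            "bilirubin_min",
            "bilirubin_max",
            "cpb_albumin_max",
            "cpb_bilirubin_min",
        ):
            _to_deci(getattr(self, name), name)

    @property
    def step_deci(self) -> int:
        return round(self.step * 10)

    def axis_deci(self, lo: float, hi: float) -> list[int]:
        """Lattice coordinates: multiples of the step inside [lo, hi]."""
        lo_d, hi_d, s = _to_deci(lo, "lo"), _to_deci(hi, "hi"), self.step_deci
        start = -(-lo_d // s) * s  # smallest multiple of s >= lo_d
        return list(range(start, hi_d + 1, s))

    @property
    def albumin_deci(self) -> list[int]:
        return self.axis_deci(self.albumin_min, self.albumin_max)

    @property
    def bilirubin_deci(self) -> list[int]:
        return self.axis_deci(self.bilirubin_min, self.bilirubin_max)

    def in_cpb_box(self, albumin_deci: int, bilirubin_deci: int) -> bool:
        return (
            albumin_deci <= _to_deci(self.cpb_albumin_max, "cpb_albumin_max")
            and bilirubin_deci >= _to_deci(self.cpb_bilirubin_min, "cpb_bilirubin_min")
        )


@dataclass
class GridCell:
    """One lattice point; annotation fields are filled by :func:`annotate_grid`."""

    albumin_deci: int
    bilirubin_deci: int
    score: float | None = None
    formula_grade: int | None = None
    zone: Zone | None = None
    rule_outcome: RuleOutcome | None = None

    @property
    def albumin(self) -> float:
        return self.albumin_deci / 10.0

    @property
    def bilirubin(self) -> float:
        return self.bilirubin_deci / 10.0


@dataclass
class SimulationSummary:
    """Counts and zone distribution of one grid simulation."""

    n_total_pairs: int
    n_excluded_cpb: int
    n_eligible: int
    n_grade1: int
    n_grade2: int
    zone_counts: dict[Zone, int]
    n_directly_classifiable: int
    cells: list[GridCell] = field(repr=False, default_factory=list)

    @property
    def fraction_directly_classifiable(self) -> float:
        return self.n_directly_classifiable / self.n_eligible

    @property
    def n_coarse_classifiable(self) -> int:
        """Pairs decided by the three coarse thresholds alone
        (albumin 3.5 / 4.4, bilirubin 2.4), before the refinement corner."""
        return sum(
            self.zone_counts.get(z, 0)
            for z in (Zone.AL_HIGH_1, Zone.AL_LOW_2, Zone.BI_HIGH_2)
        )


def enumerate_grid(spec: GridSpec = GridSpec()) -> list[GridCell]:
    """All eligible lattice points (CP-B combination box removed)."""
    return [
        GridCell(a, b)
        for a in spec.albumin_deci
        for b in spec.bilirubin_deci
        if not spec.in_cpb_box(a, b)
    ]


def annotate_grid(
    cells: list[GridCell],
    params: AlbiParameters = DEFAULT_PARAMS,
    rules: ZoneRuleSet = DEFAULT_RULES,
) -> list[GridCell]:
    """Fill score, formula grade, zone and rule outcome in place."""
    for cell in cells:
        pair = LabPair(cell.albumin, cell.bilirubin)
        result = classify(pair, params)
        cell.score = result.score
        cell.formula_grade = result.grade
        cell.zone = classify_zone(pair, rules)
        cell.rule_outcome = rule_outcome(cell.zone)
    return cells


def run_simulation(
    spec: GridSpec = GridSpec(),
    params: AlbiParameters = DEFAULT_PARAMS,
    rules: ZoneRuleSet = DEFAULT_RULES,
) -> SimulationSummary:
    """Enumerate, annotate and summarise the CP-A lattice."""
    n_total = len(spec.albumin_deci) * len(spec.bilirubin_deci)
    cells = annotate_grid(enumerate_grid(spec), params, rules)
    zone_counts: dict[Zone, int] = {}
    n_grade1 = 0
    for cell in cells:
        zone_counts[cell.zone] = zone_counts.get(cell.zone, 0) + 1
        if cell.formula_grade == 1:
            n_grade1 += 1
    n_mixed = zone_counts.get(Zone.INT_HIGH_X, 0) + zone_counts.get(Zone.INT_LOW_X, 0)
    return SimulationSummary(
        n_total_pairs=n_total,
        n_excluded_cpb=n_total - len(cells),
        n_eligible=len(cells),
        n_grade1=n_grade1,
        n_grade2=len(cells) - n_grade1,
        zone_counts=zone_counts,
        n_directly_classifiable=len(cells) - n_mixed,
        cells=cells,
    )


def zone_purity_report(cells: list[GridCell]) -> dict[Zone, set[int]]:
    """Set of formula grades observed in each zone (purity audit)."""
    report: dict[Zone, set[int]] = {}
    for cell in cells:
        report.setdefault(cell.zone, set()).add(cell.formula_grade)
    return report


def grid_to_dataframe(cells: list[GridCell]) -> pd.DataFrame:
    """Annotated grid as a tidy DataFrame (CSV-export schema)."""
    return pd.DataFrame(
        {
            "albumin": [c.albumin for c in cells],
            "bilirubin": [c.bilirubin for c in cells],
            "score": [c.score for c in cells],
            "grade": [c.formula_grade for c in cells],
            "zone": [c.zone.label if c.zone else None for c in cells],
            "rule_outcome": [
                c.rule_outcome.name if c.rule_outcome else None for c in cells
            ],
        }
    )


_ZONE_GLYPHS = {
    Zone.AL_HIGH_1: "A",
    Zone.INT_BETTER_1: "B",
    Zone.INT_HIGH_X: "h",
    Zone.INT_LOW_X: "l",
    Zone.INT_WORSE_2: "W",
    Zone.AL_LOW_2: "L",
    Zone.BI_HIGH_2: "H",
}


def render_matrix(summary: SimulationSummary, spec: GridSpec = GridSpec()) -> str:
    """Text rendering of the zone matrix.

    Albumin rows run top-down from high to low, bilirubin columns left to
    right from low to high; ``#`` marks the excluded CP-B combination box.
    One glyph per cell, uppercase for directly-classifiable zones,
    lowercase for the mixed zones where the formula is required.
    """
    by_coord = {(c.albumin_deci, c.bilirubin_deci): c for c in summary.cells}
    bili_axis = spec.bilirubin_deci
    lines = ["alb\\bil " + " ".join(f"{b/10:>3.1f}" for b in bili_axis)]
    for a in reversed(spec.albumin_deci):
        glyphs = []
        for b in bili_axis:
            cell = by_coord.get((a, b))
            glyphs.append(_ZONE_GLYPHS[cell.zone] if cell else "#")
        lines.append(f"{a/10:>7.1f} " + "   ".join(glyphs))
    legend = ", ".join(f"{g}={z.label}" for z, g in _ZONE_GLYPHS.items())
    lines.append(f"legend: {legend}, #=excluded CP-B combination")
    return "\n".join(lines)
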