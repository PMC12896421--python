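"""Albumin-bilirubin (ALBI) score and grade.

The ALBI score is a linear index of hepatic reserve introduced as an
objective alternative to the Child-Pugh classification:

    score = 0.66 * log10(bilirubin [umol/L]) - 0.085 * albumin [g/L]

with grade 1 for score <= -2.60, grade 2 for -2.60 < score <= -1.39 and
grade 3 above that.  Clinical laboratories in much of the world report
albumin in g/dL and total bilirubin in mg/dL, so inputs here are taken in
those conventional units and converted internally (x10 and x17.1).

Grading convention: the score is rounded to ``score_decimals`` decimal
places (default 2, the precision at which ALBI scores are conventionally
reported) before comparison with the thresholds, and the grade-1 boundary
is inclusive (-2.60 -> grade 1).  On the 0.1-increment Child-Pugh A
lattice this convention is the one that reproduces the published
grade-1/grade-2 partition; set ``score_decimals=None`` for raw
double-precision thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "AlbiParameters",
    "LabPair",
    "AlbiResult",
    "DEFAULT_PARAMS",
    "albi_score",
    "albi_grade",
    "classify",
]


@dataclass(frozen=True)
class AlbiParameters:
    """Coefficients, unit conversions and grade thresholds of the ALBI model.

    Attributes
    ----------
    bilirubin_coefficient
        Weight on log10(bilirubin in umol/L); dimensionless.
    albumin_coefficient
        Weight on albumin in g/L; dimensionless (negative: higher albumin
        means better reserve, i.e. a lower score).
    grade1_max_score, grade2_max_score
        Inclusive upper score bounds of grades 1 and 2.
    bilirubin_mgdl_to_umol, albumin_gdl_to_gl
        Unit-conversion factors applied to the conventional-unit inputs.
    score_decimals
        Decimal places the score is rounded to before grading; ``None``
        disables rounding.
    """

    bilirubin_coefficient: float = 0.66
    albumin_coefficient: float = -0.085
    grade1_max_score: float = -2.60
    grade2_max_score: float = -1.39
    bilirubin_mgdl_to_umol: float = 17.1
    albumin_gdl_to_gl: float = 10.0
    score_decimals: int | None = 2

    def __post_init__(self) -> None:
        if not self.grade1_max_score < self.grade2_max_score:
            raise InvalidInputError("grade1_max_score must be below grade2_max_score")
        if self.bilirubin_mgdl_to_umol <= 0 or self.albumin_gdl_to_gl <= 0:
            raise InvalidInputError("unit-conversion factors must be positive")
        if self.bilirubin_coefficient == 0 or self.albumin_coefficient == 0:
            raise InvalidInputError("coefficients must be nonzero")


DEFAULT_PARAMS = AlbiParameters()


@dataclass(frozen=True)
class LabPair:
    """A same-day albumin (g/dL) / total bilirubin (mg/dL) measurement."""

    albumin: float
    bilirubin: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.albumin) and math.isfinite(self.bilirubin)):
            raise InvalidInputError("albumin and bilirubin must be finite")
        if self.albumin <= 0 or self.bilirubin <= 0:
            raise InvalidInputError(
                f"albumin and bilirubin must be positive, got "
                f"({self.albumin}, {self.bilirubin})"
            )


@dataclass(frozen=True)
class AlbiResult:
    """ALBI score together with the grade it implies."""

    score: float
    grade: int


def albi_score(pair: LabPair, params: AlbiParameters = DEFAULT_PARAMS) -> float:
    """Return the (unrounded) ALBI score for a lab pair.

    The score is linear in albumin and in log10 bilirubin, so it is
    strictly increasing in bilirubin and strictly decreasing in albumin.
    """
    bili_umol = pair.bilirubin * params.bilirubin_mgdl_to_umol
    alb_gl = pair.albumin * params.albumin_gdl_to_gl
    return (
        params.bilirubin_coefficient * math.log10(bili_umol)
        + params.albumin_coefficient * alb_gl
    )


def albi_grade(score: float, params: AlbiParameters = DEFAULT_PARAMS) -> int:
    """Map an ALBI score to grade 1, 2 or 3 (upper bounds inclusive)."""
    if not math.isfinite(score):
        raise InvalidInputError(f"score must be finite, got {score}")
    if params.score_decimals is not None:
        score = round(score, params.score_decimals)
    if score <= params.grade1_max_score:
        return 1
    if score <= params.grade2_max_score:
        return 2
    return 3


def classify(pair: LabPair, params: AlbiParameters = DEFAULT_PARAMS) -> AlbiResult:
    """Compute score and grade for a lab pair in one call."""
    score = albi_score(pair, params)
    return AlbiResult(score=score, grade=albi_grade(score, params))
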