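"""Seeded synthetic patient-level laboratory cohorts.

The validation cohort this generator emulates is a multi-hospital
electronic-health-record extract: patients with same-day serum albumin
and total bilirubin measurements in a calendar year, possibly several
such dates per patient, with chronic-liver-disease (CLD) and
hepatocellular-carcinoma (HCC) status carried as ICD-10 codes.  The
generator reproduces the statistical structure the validation pipeline
is sensitive to:

* a configurable zone mixture for the final (most recent, in-range)
  record of each patient, defaulting to the zone frequencies observed
  in a large real-world Child-Pugh A cohort;
* contamination exercising every pipeline filter -- values outside the
  CP-A range, near-zero bilirubin (0.1-0.2 mg/dL), and supra-physiologic
  albumin (> 5.5 g/dL);
* extra earlier lab dates per patient (Poisson-distributed decoys) so
  that per-patient deduplication has real work to do;
* overlapping disease strata (HCC inside CLD inside the total cohort)
  with stratum-specific zone mixtures.

Each cohort comes with a ground-truth table (intended zone, stratum and
retained record per patient) so that pipeline recovery can be asserted
exactly, not just statistically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CohortParseError, InvalidInputError
from .zones import (
    ANALYTIC_ZONES,
    DEFAULT_RULES,
    Zone,
    ZoneRuleSet,
    zone_lattice_cells,
    zone_rectangle,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortConfig",
    "PatientRecord",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "TOTAL_COHORT_ZONE_COUNTS",
    "CLD_COHORT_ZONE_COUNTS",
    "HCC_COHORT_ZONE_COUNTS",
]

CLD_ICD10_CODES = ("B18", "B19", "K70", "K73", "K74")
HCC_ICD10_CODE = "C22"

# Zone frequencies of a 7583-patient real-world CP-A cohort and its CLD
# (n=2325) and HCC (n=1130) subgroups; the generator's default mixture.
TOTAL_COHORT_ZONE_COUNTS: dict[Zone, int] = {
    Zone.AL_HIGH_1: 3625,
    Zone.AL_LOW_2: 992,
    Zone.BI_HIGH_2: 39,
    Zone.INT_BETTER_1: 1278,
    Zone.INT_WORSE_2: 282,
    Zone.INT_HIGH_X: 255,
    Zone.INT_LOW_X: 1112,
}
CLD_COHORT_ZONE_COUNTS: dict[Zone, int] = {
    Zone.AL_HIGH_1: 1083,
    Zone.AL_LOW_2: 262,
    Zone.BI_HIGH_2: 26,
    Zone.INT_BETTER_1: 366,
    Zone.INT_WORSE_2: 148,
    Zone.INT_HIGH_X: 111,
    Zone.INT_LOW_X: 329,
}
HCC_COHORT_ZONE_COUNTS: dict[Zone, int] = {
    Zone.AL_HIGH_1: 434,
    Zone.AL_LOW_2: 144,
    Zone.BI_HIGH_2: 13,
    Zone.INT_BETTER_1: 213,
    Zone.INT_WORSE_2: 95,
    Zone.INT_HIGH_X: 53,
    Zone.INT_LOW_X: 178,
}

ANALYTIC_ZONE_ORDER = tuple(z for z in ANALYTIC_ZONES)


@dataclass(frozen=True)
class PatientRecord:
    """One laboratory row: same-day albumin/bilirubin plus diagnosis codes."""

    patient_id: str
    date: str  # ISO-8601
    albumin: float
    bilirubin: float
    icd10_codes: tuple[str, ...] = ()


@dataclass
class SyntheticCohortConfig:
    """Generative parameters of the synthetic cohort.

    Contamination proportions are applied sequentially per patient:
    ``p_out_of_cpa`` first (values failing the CP-A range restriction),
    then ``p_low_bilirubin_extreme`` and ``p_high_albumin_extreme``
    among the remaining in-range patients, so that the expected
    filtering funnel of a 10,000-patient draw is 10,000 -> ~8,040
    in-range -> ~7,580 analysable.
    """

    n_patients: int = 10_000
    zone_weights: Mapping[Zone, float] = field(
        default_factory=lambda: dict(TOTAL_COHORT_ZONE_COUNTS)
    )
    p_out_of_cpa: float = 0.196
    p_low_bilirubin_extreme: float = 0.057
    p_high_albumin_extreme: float = 0.0001
    visit_rate: float = 1.0
    p_cld: float = 2325 / 7583
    p_hcc_given_cld: float = 1130 / 2325
    subgroup_zone_weights: Mapping[str, Mapping[Zone, float]] | None = field(
        default_factory=lambda: {
            "cld": dict(CLD_COHORT_ZONE_COUNTS),
            "hcc": dict(HCC_COHORT_ZONE_COUNTS),
        }
    )
    seed: int = 0
    year: int = 2024
    continuous_values: bool = False

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise InvalidInputError("n_patients must be positive")
        for name in (
            "p_out_of_cpa",
            "p_low_bilirubin_extreme",
            "p_high_albumin_extreme",
            "p_cld",
            "p_hcc_given_cld",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name}={v} outside [0, 1]")
        if self.visit_rate < 0:
            raise InvalidInputError("visit_rate must be nonnegative")
        w = self.zone_weights
        if any(x < 0 for x in w.values()) or sum(w.values()) <= 0:
            raise InvalidInputError(
                "zone_weights must be nonnegative with a positive sum"
            )

    def stratum_zone_probs(self) -> dict[str, np.ndarray]:
        """Zone mixtures of the three disjoint strata (none / CLD-only / HCC).

        The configured subgroup weights describe *overlapping* cohorts
        (HCC inside CLD inside total), so the disjoint strata are obtained
        by differencing: non-CLD = total - CLD, CLD-only = CLD - HCC.
        When no subgroup weights are given every stratum uses the total
        mixture.
        """
        total = np.array(
            [self.zone_weights.get(z, 0.0) for z in ANALYTIC_ZONE_ORDER], float
        )
        total_p = total / total.sum()
        if not self.subgroup_zone_weights:
            return {"none": total_p, "cld": total_p, "hcc": total_p}
        cld = np.array(
            [self.subgroup_zone_weights["cld"].get(z, 0.0) for z in ANALYTIC_ZONE_ORDER],
            float,
        )
        hcc = np.array(
            [self.subgroup_zone_weights["hcc"].get(z, 0.0) for z in ANALYTIC_ZONE_ORDER],
            float,
        )
        # scale overlapping counts to the configured stratum prevalences
        n_cld = self.p_cld * total.sum()
        n_hcc = self.p_hcc_given_cld * n_cld
        cld_scaled = cld / cld.sum() * n_cld
        hcc_scaled = hcc / hcc.sum() * n_hcc
        none_w = total - cld_scaled
        cld_only_w = cld_scaled - hcc_scaled
        if (none_w < -1e-9).any() or (cld_only_w < -1e-9).any():
            raise InvalidInputError(
                "subgroup zone weights are inconsistent with the total mixture "
                "(differencing total - CLD or CLD - HCC went negative)"
            )
        none_w = np.clip(none_w, 0.0, None)
        cld_only_w = np.clip(cld_only_w, 0.0, None)
        return {
            "none": none_w / none_w.sum(),
            "cld": cld_only_w / cld_only_w.sum(),
            "hcc": hcc_scaled / hcc_scaled.sum(),
        }


def _zone_cells(rules: ZoneRuleSet) -> dict[Zone, np.ndarray]:
    # cohort box admits albumin 3.0 (deci 30), unlike the derivation grid
    return {
        z: np.array(zone_lattice_cells(z, rules, albumin_min_deci=30), dtype=int)
        for z in ANALYTIC_ZONE_ORDER
    }


def _draw_zone_value(
    zone_idx: int,
    cells: dict[Zone, np.ndarray],
    rng: np.random.Generator,
    continuous: bool,
) -> tuple[float, float]:
    zone = ANALYTIC_ZONE_ORDER[zone_idx]
    if continuous:
        # uniform over the zone's rectangle, so the value stays in-zone
        alo, ahi, blo, bhi = zone_rectangle(zone)
        return float(rng.uniform(alo, ahi)), float(rng.uniform(blo, bhi))
    zcells = cells[zone]
    a_deci, b_deci = zcells[rng.integers(0, len(zcells))]
    return a_deci / 10.0, b_deci / 10.0


def _draw_codes(stratum: str, rng: np.random.Generator) -> tuple[str, ...]:
    if stratum == "hcc":
        codes = [HCC_ICD10_CODE]
        if rng.random() < 0.6:  # HCC mostly arises on chronic liver disease
            codes.append(CLD_ICD10_CODES[rng.integers(0, len(CLD_ICD10_CODES))])
        return tuple(codes)
    if stratum == "cld":
        n = 1 + int(rng.random() < 0.3)
        idx = rng.choice(len(CLD_ICD10_CODES), size=n, replace=False)
        return tuple(CLD_ICD10_CODES[i] for i in sorted(idx))
    # unrelated comorbidity codes should not trip the CLD matcher
    return ("I10",) if rng.random() < 0.3 else ()


def generate_cohort(
    config: SyntheticCohortConfig,
    rules: ZoneRuleSet = DEFAULT_RULES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate laboratory records and the matching ground truth.

    Returns
    -------
    records : DataFrame
        Wide schema, one row per patient-date: ``patient_id``, ``date``
        (ISO-8601), ``albumin``, ``bilirubin``, ``icd10_codes``
        (semicolon-separated, possibly empty).  Row order is by patient
        then date.
    truth : DataFrame
        One row per patient: ``patient_id``, ``category`` (clean /
        out_of_cpa / bilirubin_extreme / albumin_extreme), ``zone``
        (label, empty for contaminated patients), ``stratum`` (none /
        cld / hcc), ``retained_date``, ``albumin``, ``bilirubin`` of the
        record the pipeline should retain.
    """
    rng = np.random.default_rng(config.seed)
    cells = _zone_cells(rules)
    stratum_probs = config.stratum_zone_probs()
    total_w = np.array(
        [config.zone_weights.get(z, 0.0) for z in ANALYTIC_ZONE_ORDER], float
    )
    total_probs = total_w / total_w.sum()
    dates = pd.date_range(f"{config.year}-01-01", f"{config.year}-12-31", freq="D")
    n_days = len(dates)

    rec_rows: list[tuple[str, str, float, float, str]] = []
    truth_rows: list[tuple[str, str, str, str, str, float, float]] = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        if rng.random() < config.p_cld:
            stratum = "hcc" if rng.random() < config.p_hcc_given_cld else "cld"
        else:
            stratum = "none"
        codes = ";".join(_draw_codes(stratum, rng))

        if rng.random() < config.p_out_of_cpa:
            category = "out_of_cpa"
        elif rng.random() < config.p_low_bilirubin_extreme:
            category = "bilirubin_extreme"
        elif rng.random() < config.p_high_albumin_extreme:
            category = "albumin_extreme"
        else:
            category = "clean"

        zone_label = ""
        if category == "clean":
            zone_idx = rng.choice(len(ANALYTIC_ZONE_ORDER), p=stratum_probs[stratum])
            zone_label = ANALYTIC_ZONE_ORDER[zone_idx].label
            alb, bili = _draw_zone_value(
                zone_idx, cells, rng, config.continuous_values
            )
        elif category == "out_of_cpa":
            kind = rng.choice(3, p=[0.5, 0.3, 0.2])
            if kind == 0:  # hypoalbuminemia below the CP-A floor
                alb = rng.integers(20, 30) / 10.0
                bili = rng.integers(3, 31) / 10.0
            elif kind == 1:  # hyperbilirubinemia above the CP-A ceiling
                alb = rng.integers(30, 56) / 10.0
                bili = rng.integers(31, 61) / 10.0
            else:  # CP-B combination box
                alb = rng.integers(30, 36) / 10.0
                bili = rng.integers(20, 31) / 10.0
        elif category == "bilirubin_extreme":
            alb = rng.integers(30, 56) / 10.0  # in-range albumin
            bili = rng.integers(1, 3) / 10.0
        else:  # albumin_extreme
            alb = rng.integers(56, 61) / 10.0
            bili = rng.integers(3, 31) / 10.0

        n_extra = int(rng.poisson(config.visit_rate))
        n_extra = min(n_extra, n_days - 1)
        day_idx = np.sort(rng.choice(n_days, size=n_extra + 1, replace=False))
        visit_dates = [dates[j].date().isoformat() for j in day_idx]
        for d in visit_dates[:-1]:  # earlier decoy visits, overall clean mixture
            zi = rng.choice(len(ANALYTIC_ZONE_ORDER), p=total_probs)
            da, db = _draw_zone_value(zi, cells, rng, config.continuous_values)
            rec_rows.append((pid, d, da, db, codes))
        retained = visit_dates[-1]
        rec_rows.append((pid, retained, alb, bili, codes))
        truth_rows.append(
            (pid, category, zone_label, stratum, retained, alb, bili)
        )

    records = pd.DataFrame(
        rec_rows, columns=["patient_id", "date", "albumin", "bilirubin", "icd10_codes"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "category",
            "zone",
            "stratum",
            "retained_date",
            "albumin",
            "bilirubin",
        ],
    )
    logger.info(
        "generated %d records for %d patients (seed=%d)",
        len(records),
        config.n_patients,
        config.seed,
    )
    return records, truth


def write_cohort_csv(
    records: pd.DataFrame,
    path,
    seed: int | None = None,
    long_format: bool = False,
) -> None:
    """Write a cohort to CSV with a metadata comment header.

    ``long_format`` melts each row into two analyte rows
    (``analyte`` in {albumin, bilirubin}, ``value``), the schema some
    laboratory exports use; the wide schema is the default.
    """
    df = records
    if long_format:
        df = records.melt(
            id_vars=["patient_id", "date", "icd10_codes"],
            value_vars=["albumin", "bilirubin"],
            var_name="analyte",
            value_name="value",
        ).sort_values(["patient_id", "date", "analyte"], kind="stable")
        df = df[["patient_id", "date", "analyte", "value", "icd10_codes"]]
    with open(path, "w", newline="") as fh:
        fh.write("# albigrid cohort v0.1.0\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


_WIDE_COLUMNS = {"patient_id", "date", "albumin", "bilirubin"}
_LONG_COLUMNS = {"patient_id", "date", "analyte", "value"}


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a wide- or long-schema cohort CSV (``#`` comment lines skipped).

    Malformed numeric fields raise :class:`CohortParseError` carrying the
    offending 1-based physical line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_offset = 0
    while header_offset < len(lines) and lines[header_offset].startswith("#"):
        header_offset += 1
    try:
        df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise CohortParseError("cohort file has no header row") from None
    cols = set(df.columns)
    if _WIDE_COLUMNS <= cols:
        numeric_cols = ["albumin", "bilirubin"]
    elif _LONG_COLUMNS <= cols:
        numeric_cols = ["value"]
    else:
        raise CohortParseError(
            f"unrecognised cohort schema: columns {sorted(cols)}"
        )
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric {col} value {df[col].iloc[row]!r}",
                line=header_offset + 1 + row + 1,
            )
        df[col] = coerced
    if "icd10_codes" in df.columns:
        df["icd10_codes"] = df["icd10_codes"].fillna("")
    else:
        df["icd10_codes"] = ""
    return df
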