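"""Cohort validation pipeline: pair, deduplicate, filter, tabulate, test.

Mirrors how a real-world laboratory extract is reduced to one analysable
observation per patient:

1. same-day pairing -- keep patient-dates where both albumin and
   bilirubin were measured;
2. per-patient deduplication -- retain the most recent paired record
   of the year (ties broken by file order, last wins);
3. CP-A range restriction -- drop albumin < 3.0 g/dL, bilirubin >
   3.0 mg/dL and (by default) the CP-B combination box;
4. extreme-value exclusion -- drop albumin > 5.5 g/dL and bilirubin
   below 0.3 mg/dL (the 0.1-0.2 near-zero readings);
5. zone mapping and tabulation for the total cohort and the CLD / HCC
   subgroups, with a Pearson chi-square goodness-of-fit test of each
   subgroup's zone distribution against the overall cohort's.

The subgroups overlap the total cohort (HCC inside CLD inside total);
the goodness-of-fit test nevertheless uses the total cohort as the
reference distribution, which is the convention this pipeline validates
(the non-independence is a documented caveat, not corrected for).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlbiParameters, DEFAULT_PARAMS
from .errors import InvalidInputError
from .zones import (
    ANALYTIC_ZONES,
    DEFAULT_RULES,
    Zone,
    ZoneRuleSet,
    formula_grades,
    rule_outcome,
    zones_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "CohortSummary",
    "GofResult",
    "pair_same_day",
    "dedupe_latest",
    "apply_filters",
    "summarize",
    "gof_test",
    "subgroup_gof",
    "run_pipeline",
]

ZONE_LABELS = [z.label for z in ANALYTIC_ZONES]


@dataclass(frozen=True)
class FilterConfig:
    """Range restrictions and diagnosis-code definitions of the pipeline."""

    albumin_min: float = 3.0
    albumin_max: float = 5.5
    bilirubin_min: float = 0.3
    bilirubin_max: float = 3.0
    apply_cpb_combo_exclusion: bool = True
    cpb_albumin_max: float = 3.5
    cpb_bilirubin_min: float = 2.0
    cld_codes: frozenset[str] = frozenset({"B18", "B19", "K70", "K73", "K74", "C22"})
    hcc_code: str = "C22"

    def __post_init__(self) -> None:
        if self.albumin_min >= self.albumin_max:
            raise InvalidInputError("albumin_min must be below albumin_max")
        if self.bilirubin_min >= self.bilirubin_max:
            raise InvalidInputError("bilirubin_min must be below bilirubin_max")


@dataclass
class GofResult:
    """Pearson chi-square goodness-of-fit result."""

    statistic: float
    df: int
    p_value: float


@dataclass
class CohortSummary:
    """Tabulated zone/grade distributions plus the filtering funnel."""

    n_final: int
    zone_counts: pd.DataFrame  # index: zone label; columns: total/cld/hcc
    grade_counts: pd.DataFrame  # index: grade 1/2/3; columns: total/cld/hcc
    n_directly_classifiable: pd.Series
    n_needs_formula: pd.Series
    funnel: dict[str, int] = field(default_factory=dict)
    removal_log: dict[str, int] = field(default_factory=dict)

    @property
    def zone_proportions(self) -> pd.DataFrame:
        return self.zone_counts / self.zone_counts.sum(axis=0)


def _ensure_order_column(df: pd.DataFrame) -> pd.DataFrame:
    out = df.reset_index(drop=True).copy()
    if "_ord" not in out.columns:
        out["_ord"] = np.arange(len(out))
    return out


def pair_same_day(records: pd.DataFrame) -> pd.DataFrame:
    """One candidate observation per patient-date with both analytes.

    Accepts the wide schema (albumin/bilirubin columns; rows missing
    either analyte are dropped) or the long schema (analyte/value rows,
    pivoted per patient-date).  A duplicated analyte on the same
    patient-date keeps the last row in file order, with a warning.
    """
    cols = set(records.columns)
    if {"albumin", "bilirubin"} <= cols:
        out = _ensure_order_column(records)
        keep = out["albumin"].notna() & out["bilirubin"].notna()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropped %d rows missing an analyte", n_dropped)
        return out[keep].reset_index(drop=True)
    if not {"analyte", "value"} <= cols:
        raise InvalidInputError(
            f"records have neither wide nor long schema: {sorted(cols)}"
        )
    out = _ensure_order_column(records)
    dup = out.duplicated(["patient_id", "date", "analyte"], keep=False)
    if dup.any():
        logger.warning(
            "%d duplicated analyte rows on the same patient-date; keeping last",
            int(dup.sum()),
        )
        out = out.drop_duplicates(["patient_id", "date", "analyte"], keep="last")
    wide = out.pivot(
        index=["patient_id", "date"], columns="analyte", values="value"
    ).reset_index()
    wide.columns.name = None
    agg = {"_ord": ("_ord", "max")}
    if "icd10_codes" in out.columns:
        agg["icd10_codes"] = ("icd10_codes", "last")
    meta = out.groupby(["patient_id", "date"], sort=False).agg(**agg).reset_index()
    wide = wide.merge(meta, on=["patient_id", "date"], how="left")
    for analyte in ("albumin", "bilirubin"):
        if analyte not in wide.columns:
            wide[analyte] = np.nan
    keep = wide["albumin"].notna() & wide["bilirubin"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d patient-dates missing an analyte", n_dropped)
    wide = wide[keep].sort_values("_ord", kind="stable").reset_index(drop=True)
    return wide


def dedupe_latest(paired: pd.DataFrame) -> pd.DataFrame:
    """Keep each patient's most recent observation (date ties: last in file).

    Output preserves the retained rows' original file order.
    """
    out = _ensure_order_column(paired)
    ranked = out.sort_values(["date", "_ord"], kind="stable")
    kept = ranked.groupby("patient_id", sort=False).tail(1)
    ties = (
        ranked.groupby("patient_id")["date"].transform("max") == ranked["date"]
    ).groupby(ranked["patient_id"]).sum()
    n_tied = int((ties > 1).sum())
    if n_tied:
        logger.warning(
            "%d patients had tied most-recent dates; kept last in file order",
            n_tied,
        )
    return kept.sort_values("_ord", kind="stable").reset_index(drop=True)


def apply_filters(
    observations: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """CP-A range restriction then extreme-value exclusion.

    Each removed record is attributed to the first rule it fails, in the
    order below, so the removal log decomposes the funnel exactly.
    """
    a = observations["albumin"].to_numpy(dtype=float)
    b = observations["bilirubin"].to_numpy(dtype=float)
    rules: list[tuple[str, np.ndarray]] = [
        ("albumin_below_min", a < config.albumin_min),
        ("bilirubin_above_max", b > config.bilirubin_max),
    ]
    if config.apply_cpb_combo_exclusion:
        rules.append(
            (
                "cpb_combination",
                (a <= config.cpb_albumin_max) & (b >= config.cpb_bilirubin_min),
            )
        )
    rules += [
        ("albumin_above_max", a > config.albumin_max),
        ("bilirubin_below_min", b < config.bilirubin_min),
    ]
    removal: dict[str, int] = {}
    removed = np.zeros(len(observations), dtype=bool)
    for name, mask in rules:
        newly = mask & ~removed
        removal[name] = int(newly.sum())
        removed |= newly
    survivors = observations[~removed].reset_index(drop=True)
    logger.info("filters removed %d of %d observations: %s",
                int(removed.sum()), len(observations), removal)
    return survivors, removal


def _has_code(codes: pd.Series, wanted: frozenset[str] | set[str]) -> np.ndarray:
    split = codes.fillna("").astype(str).str.split(";")
    return np.array([bool(set(c) & set(wanted) - {""}) for c in split])


def summarize(
    survivors: pd.DataFrame,
    rules: ZoneRuleSet = DEFAULT_RULES,
    params: AlbiParameters = DEFAULT_PARAMS,
    config: FilterConfig = FilterConfig(),
) -> CohortSummary:
    """Zone and grade tabulations for the total cohort and CLD/HCC subgroups.

    Grades are resolved from the zone rules where the zone is decisive
    and from the ALBI formula inside the two mixed zones, so the grade
    table is exactly what the bedside three-step algorithm would produce.
    """
    if len(survivors) == 0:
        raise InvalidInputError("no observations survive filtering")
    a = survivors["albumin"].to_numpy(dtype=float)
    b = survivors["bilirubin"].to_numpy(dtype=float)
    zones = zones_of(a, b, rules)
    if any(not z.is_analytic for z in zones):
        raise InvalidInputError(
            "survivors contain out-of-range or CP-B values; run apply_filters first"
        )
    grades = np.empty(len(survivors), dtype=int)
    needs_formula = np.zeros(len(survivors), dtype=bool)
    for zone in ANALYTIC_ZONES:
        mask = zones == zone
        if not mask.any():
            continue
        outcome = rule_outcome(zone)
        if zone.is_mixed:
            needs_formula[mask] = True
            grades[mask] = formula_grades(a[mask], b[mask], params)
        else:
            grades[mask] = outcome.value

    codes = survivors.get("icd10_codes", pd.Series([""] * len(survivors)))
    masks = {
        "total": np.ones(len(survivors), dtype=bool),
        "cld": _has_code(codes, config.cld_codes),
        "hcc": _has_code(codes, {config.hcc_code}),
    }
    zone_labels = np.array([z.label for z in zones])
    zone_counts = pd.DataFrame(
        {
            name: pd.Series(zone_labels[m]).value_counts().reindex(ZONE_LABELS, fill_value=0)
            for name, m in masks.items()
        }
    )
    grade_counts = pd.DataFrame(
        {
            name: pd.Series(grades[m]).value_counts().reindex([1, 2, 3], fill_value=0)
            for name, m in masks.items()
        }
    )
    n_formula = pd.Series(
        {name: int(needs_formula[m].sum()) for name, m in masks.items()}
    )
    n_direct = pd.Series({name: int(m.sum()) for name, m in masks.items()}) - n_formula
    return CohortSummary(
        n_final=len(survivors),
        zone_counts=zone_counts,
        grade_counts=grade_counts,
        n_directly_classifiable=n_direct,
        n_needs_formula=n_formula,
    )


def gof_test(observed, reference) -> GofResult:
    """Pearson chi-square goodness-of-fit of counts against proportions.

    ``reference`` may be any positive weights; it is normalised first,
    so the statistic is invariant to rescaling.  A reference category
    with nonpositive weight has no defined expected count and raises.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape:
        raise InvalidInputError("observed and reference must have equal length")
    if (obs < 0).any() or obs.sum() <= 0:
        raise InvalidInputError("observed counts must be nonnegative, positive total")
    if (ref <= 0).any():
        raise InvalidInputError(
            "reference proportions must all be positive (expected counts undefined)"
        )
    expected = ref / ref.sum() * obs.sum()
    statistic, p_value = stats.chisquare(obs, f_exp=expected)
    return GofResult(statistic=float(statistic), df=len(obs) - 1, p_value=float(p_value))


def subgroup_gof(summary: CohortSummary) -> dict[str, GofResult]:
    """Test each subgroup's zone distribution against the total cohort's.

    A zone empty in the total cohort is necessarily empty in every
    subgroup (subgroups are subsets), so such categories are dropped
    before testing, reducing the degrees of freedom accordingly.
    """
    reference = summary.zone_counts["total"].to_numpy()
    populated = reference > 0
    out = {}
    for name in ("cld", "hcc"):
        observed = summary.zone_counts[name].to_numpy()
        if observed.sum() > 0:
            out[name] = gof_test(observed[populated], reference[populated])
    return out


def run_pipeline(
    records: pd.DataFrame,
    rules: ZoneRuleSet = DEFAULT_RULES,
    params: AlbiParameters = DEFAULT_PARAMS,
    config: FilterConfig = FilterConfig(),
) -> tuple[CohortSummary, pd.DataFrame]:
    """Full pairing -> dedup -> filter -> summarise chain.

    Returns the summary (funnel and removal log attached) and the
    surviving observations.
    """
    paired = pair_same_day(records)
    deduped = dedupe_latest(paired)
    survivors, removal = apply_filters(deduped, config)
    n_stage1 = len(survivors) + removal["albumin_above_max"] + removal["bilirubin_below_min"]
    summary = summarize(survivors, rules, params, config)
    summary.funnel = {
        "n_input": len(records),
        "n_after_pairing": len(paired),
        "n_after_dedup": len(deduped),
        "n_after_cpa": n_stage1,
        "n_after_extremes": len(survivors),
    }
    summary.removal_log = removal
    return summary, survivors
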