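"""Resolve each patient's record set to a single ethnic category.

Patients accumulate many ethnicity records across primary and secondary
care, and the records can disagree.  The resolution cascade applies, in
order: (1) a first ranking criterion (record frequency or recency per
category), (2) the other criterion to break ties, (3) care-tier priority
(primary or secondary), (4) a census-distribution ordering, which always
resolves because it is a strict total order, and (5) optionally a
"non-Other" rewrite — if the winner is Other but the patient has evidence
of another known category, the cascade is rerun with the Other records
removed.  Records of unknown ethnicity are discarded first; a patient with
no usable record is Unknown.

Four preset configurations cover the variants evaluated against each other:

========== ============== =============== ====================
preset     first criterion tier priority   non-Other rewrite
========== ============== =============== ====================
algorithm1 frequency       secondary       yes
algorithm2 frequency       primary         yes
algorithm3 recency         primary         yes
algorithm4 frequency       primary         no
========== ============== =============== ====================

Algorithm 2 is the basis of the CPRD Ethnicity Records product;
algorithm 1 is the earlier public-health variant that preferred hospital
records.

``derive_patient`` is the per-patient implementation,
``brute_force_derive`` an independent record-filtering oracle used by the
test suite, and ``derive_cohort`` a vectorised pandas implementation for
whole cohorts; the three are cross-checked on randomised inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .code_mapping import CANONICAL_ORDER, KNOWN_CATEGORIES, EthnicCategory
from .ehr_ingest import EthnicityRecord, SourceSet, care_tier_of, select_sources

logger = logging.getLogger(__name__)

__all__ = [
    "ENGLAND_CENSUS_2021",
    "CensusDistribution",
    "AlgorithmConfig",
    "DerivedEthnicity",
    "PRESETS",
    "preset",
    "derive_patient",
    "brute_force_derive",
    "derive_cohort",
]

#: Sentinel ordering date for records with a missing date: they sort
#: strictly older than any real date.
_DATE_FLOOR = date.min
_TS_FLOOR = pd.Timestamp.min


@dataclass(frozen=True)
class CensusDistribution:
    """Percentage distribution over the five known categories.

    The derived rank order (descending percentage) is used as the census
    tie-break; the default is the England 2021 Census distribution.
    """

    proportions: dict
    label: str = ""

    def __post_init__(self) -> None:
        cats = {EthnicCategory.parse(c) for c in self.proportions}
        if cats != set(KNOWN_CATEGORIES):
            raise ValueError(
                "census distribution must cover exactly the five known "
                f"categories; got {sorted(c.value for c in cats)}"
            )
        total = sum(self.proportions.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"census percentages sum to {total}, expected 100±0.1")
        object.__setattr__(
            self,
            "proportions",
            {EthnicCategory.parse(c): float(v) for c, v in self.proportions.items()},
        )

    @property
    def rank_order(self) -> tuple:
        """Categories from most to least common; ties broken by canonical
        order so the result is always a strict total order."""
        return tuple(
            sorted(
                self.proportions,
                key=lambda c: (-self.proportions[c], CANONICAL_ORDER.index(c)),
            )
        )


#: England, 2021 Census: White 81.05, Asian 9.61, Black 4.22,
#: Mixed/Multiple 2.96, Other 2.18 (percent of the population with a known
#: category).  Rank order White > Asian > Black > Mixed/Multiple > Other.
ENGLAND_CENSUS_2021 = CensusDistribution(
    proportions={
        EthnicCategory.WHITE: 81.05,
        EthnicCategory.ASIAN: 9.61,
        EthnicCategory.BLACK: 4.22,
        EthnicCategory.MIXED: 2.96,
        EthnicCategory.OTHER: 2.18,
    },
    label="England Census 2021",
)


@dataclass(frozen=True)
class AlgorithmConfig:
    """Ordered prioritisation rules for the resolution cascade.

    ``step_order_first`` selects which of frequency/recency ranks first;
    the other is applied second.  ``census_order`` must be a strict total
    order over exactly the five known categories.
    """

    step_order_first: str = "frequency"  # frequency | recency
    source_priority: str = "primary"     # primary | secondary
    census_order: tuple = ENGLAND_CENSUS_2021.rank_order
    prioritise_non_other: bool = True
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.step_order_first not in ("frequency", "recency"):
            raise ValueError(
                f"step_order_first must be 'frequency' or 'recency', "
                f"got {self.step_order_first!r}"
            )
        if self.source_priority not in ("primary", "secondary"):
            raise ValueError(
                f"source_priority must be 'primary' or 'secondary', "
                f"got {self.source_priority!r}"
            )
        order = tuple(EthnicCategory.parse(c) for c in self.census_order)
        if not order:
            raise ValueError("census_order must not be empty")
        if set(order) != set(KNOWN_CATEGORIES) or len(order) != len(KNOWN_CATEGORIES):
            raise ValueError(
                "census_order must be a strict total order over exactly the "
                "five known categories"
            )
        object.__setattr__(self, "census_order", order)

    @property
    def step_order(self) -> tuple:
        second = "recency" if self.step_order_first == "frequency" else "frequency"
        return (self.step_order_first, second)

    def census_rank(self, category: EthnicCategory) -> int:
        return self.census_order.index(category)


PRESETS = {
    "algorithm1": AlgorithmConfig(
        step_order_first="frequency",
        source_priority="secondary",
        prioritise_non_other=True,
        preset_name="algorithm1",
    ),
    "algorithm2": AlgorithmConfig(
        step_order_first="frequency",
        source_priority="primary",
        prioritise_non_other=True,
        preset_name="algorithm2",
    ),
    "algorithm3": AlgorithmConfig(
        step_order_first="recency",
        source_priority="primary",
        prioritise_non_other=True,
        preset_name="algorithm3",
    ),
    "algorithm4": AlgorithmConfig(
        step_order_first="frequency",
        source_priority="primary",
        prioritise_non_other=False,
        preset_name="algorithm4",
    ),
}


def preset(name: str) -> AlgorithmConfig:
    """Return one of the four frozen preset configurations."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: " + ", ".join(sorted(PRESETS))
        ) from None


@dataclass(frozen=True)
class DerivedEthnicity:
    """The single per-patient category with an audit trail."""

    patient_id: str
    category: EthnicCategory
    deciding_step: str
    n_usable_records: int

    def __post_init__(self) -> None:
        unknown = self.category is EthnicCategory.UNKNOWN
        no_records = self.deciding_step == "no_usable_records"
        empty = self.n_usable_records == 0
        if not (unknown == no_records == empty):
            raise ValueError(
                "Unknown category, no_usable_records step and zero usable "
                "records must coincide"
            )


def _as_records(records: Union[pd.DataFrame, Iterable]) -> list:
    if isinstance(records, pd.DataFrame):
        out = []
        for row in records.itertuples(index=False):
            record_date = row.record_date
            if pd.isna(record_date):
                record_date = None
            elif isinstance(record_date, pd.Timestamp):
                record_date = record_date.date()
            out.append(
                EthnicityRecord(
                    patient_id=str(row.patient_id),
                    source=str(row.source),
                    category=EthnicCategory.parse(row.category),
                    record_date=record_date,
                    raw_code=str(getattr(row, "raw_code", "")),
                )
            )
        return out
    return list(records)


def _check_single_patient(records: Sequence[EthnicityRecord]) -> None:
    ids = {r.patient_id for r in records}
    if len(ids) > 1:
        raise ValueError(
            f"derive_patient expects records for a single patient; got ids {sorted(ids)}"
        )


def _sort_date(record: EthnicityRecord):
    return record.record_date if record.record_date is not None else _DATE_FLOOR


def _resolve(
    usable: Sequence[EthnicityRecord], config: AlgorithmConfig
) -> tuple:
    """Run cascade steps (b)-(f) over already-usable records.

    Returns (category, deciding_step).  Aggregates per category, then
    filters survivors stage by stage; a stage that leaves all survivors
    (e.g. tier priority where all or none have prioritised-tier evidence)
    is non-discriminating and simply passes through.
    """
    categories = sorted({r.category for r in usable}, key=CANONICAL_ORDER.index)
    if len(categories) == 1:
        return categories[0], "unanimous"

    counts = {c: sum(1 for r in usable if r.category is c) for c in categories}
    latest = {
        c: max(_sort_date(r) for r in usable if r.category is c) for c in categories
    }
    prioritised_tier = config.source_priority
    tier_evidence = {
        c: any(
            r.care_tier == prioritised_tier for r in usable if r.category is c
        )
        for c in categories
    }

    def criterion_key(name: str):
        if name == "frequency":
            return counts.__getitem__
        if name == "recency":
            return latest.__getitem__
        if name == "source_priority":
            return tier_evidence.__getitem__
        raise AssertionError(name)

    survivors = categories
    stages = list(config.step_order) + ["source_priority"]
    for stage in stages:
        key = criterion_key(stage)
        top = max(key(c) for c in survivors)
        filtered = [c for c in survivors if key(c) == top]
        if len(filtered) < len(survivors):
            survivors = filtered
        if len(survivors) == 1:
            return survivors[0], stage
    # census ordering is a strict total order: always resolves
    winner = min(survivors, key=config.census_rank)
    return winner, "census"


def derive_patient(
    records: Union[pd.DataFrame, Iterable],
    config: AlgorithmConfig,
) -> DerivedEthnicity:
    """Resolve one patient's records to a single category.

    Deterministic: no step ever breaks ties by record order, so same-day
    duplicate records cannot change the result between runs.
    """
    records = _as_records(records)
    _check_single_patient(records)
    patient_id = records[0].patient_id if records else ""
    usable = [r for r in records if r.category is not EthnicCategory.UNKNOWN]
    if not usable:
        return DerivedEthnicity(
            patient_id=patient_id,
            category=EthnicCategory.UNKNOWN,
            deciding_step="no_usable_records",
            n_usable_records=0,
        )
    category, step = _resolve(usable, config)
    if (
        config.prioritise_non_other
        and category is EthnicCategory.OTHER
        and any(r.category is not EthnicCategory.OTHER for r in usable)
    ):
        non_other = [r for r in usable if r.category is not EthnicCategory.OTHER]
        category, _ = _resolve(non_other, config)
        step = "non_other_rewrite"
    return DerivedEthnicity(
        patient_id=patient_id,
        category=category,
        deciding_step=step,
        n_usable_records=len(usable),
    )


def brute_force_derive(
    records: Union[pd.DataFrame, Iterable],
    config: AlgorithmConfig,
) -> DerivedEthnicity:
    """Oracle implementation: literal successive filtering of the record set.

    Instead of aggregating per category, each cascade step discards the
    records of eliminated categories from the working set and recomputes
    every quantity from the records that remain.  Intended for testing
    ``derive_patient``; quadratic and unvectorised by design.
    """
    records = _as_records(records)
    _check_single_patient(records)
    patient_id = records[0].patient_id if records else ""
    usable = [r for r in records if r.category is not EthnicCategory.UNKNOWN]
    if not usable:
        return DerivedEthnicity(
            patient_id=patient_id,
            category=EthnicCategory.UNKNOWN,
            deciding_step="no_usable_records",
            n_usable_records=0,
        )

    def filter_records(pool: list) -> tuple:
        if len({r.category for r in pool}) == 1:
            return pool[0].category, "unanimous"
        working = list(pool)
        for stage in list(config.step_order) + ["source_priority", "census"]:
            if stage == "frequency":
                def value(r, w=working):
                    return sum(1 for s in w if s.category is r.category)
            elif stage == "recency":
                def value(r, w=working):
                    return max(_sort_date(s) for s in w if s.category is r.category)
            elif stage == "source_priority":
                def value(r, w=working):
                    return any(
                        s.care_tier == config.source_priority
                        for s in w
                        if s.category is r.category
                    )
            else:  # census
                def value(r):
                    return -config.census_rank(r.category)
            top = max(value(r) for r in working)
            survivors = [r for r in working if value(r) == top]
            if len({r.category for r in survivors}) < len(
                {r.category for r in working}
            ):
                working = survivors
            if len({r.category for r in working}) == 1:
                return working[0].category, stage
        raise AssertionError("census stage must resolve")

    category, step = filter_records(usable)
    if (
        config.prioritise_non_other
        and category is EthnicCategory.OTHER
        and any(r.category is not EthnicCategory.OTHER for r in usable)
    ):
        remaining = [r for r in usable if r.category is not EthnicCategory.OTHER]
        category, _ = filter_records(remaining)
        step = "non_other_rewrite"
    return DerivedEthnicity(
        patient_id=patient_id,
        category=category,
        deciding_step=step,
        n_usable_records=len(usable),
    )


# ---------------------------------------------------------------------------
# Vectorised cohort derivation
# ---------------------------------------------------------------------------

def _staged_filter(agg: pd.DataFrame, config: AlgorithmConfig) -> pd.DataFrame:
    """Filter the per-(patient, category) table stage by stage.

    ``agg`` columns: patient_id, category, n, latest, tier_flag,
    census_key.  Returns one row per patient: category + deciding_step.
    """
    stage_columns = {
        "frequency": "n",
        "recency": "latest",
        "source_priority": "tier_flag",
        "census": "census_key",
    }
    current = agg
    sizes = current.groupby("patient_id")["category"].transform("size")
    deciding = pd.Series("unanimous", index=current.index)
    undecided = sizes > 1
    for stage in list(config.step_order) + ["source_priority", "census"]:
        if not undecided.any():
            break
        column = stage_columns[stage]
        top = current.groupby("patient_id")[column].transform("max")
        keep = (current[column] == top) | ~undecided
        current = current[keep]
        deciding = deciding[keep]
        undecided = undecided[keep]
        sizes = current.groupby("patient_id")["category"].transform("size")
        newly = undecided & (sizes == 1)
        deciding[newly] = stage
        undecided = undecided & ~newly
    assert not undecided.any()
    out = current[["patient_id", "category"]].copy()
    out["deciding_step"] = deciding
    return out


def _aggregate(usable: pd.DataFrame, config: AlgorithmConfig) -> pd.DataFrame:
    latest = usable["record_date"].fillna(_TS_FLOOR)
    prioritised = usable["care_tier"] == config.source_priority
    agg = (
        usable.assign(_latest=latest, _tier=prioritised)
        .groupby(["patient_id", "category"], sort=True, observed=True)
        .agg(n=("category", "size"), latest=("_latest", "max"), tier_flag=("_tier", "any"))
        .reset_index()
    )
    rank = {c.value: config.census_rank(c) for c in KNOWN_CATEGORIES}
    agg["census_key"] = -agg["category"].map(rank)
    return agg


def derive_cohort(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    config: AlgorithmConfig,
    source_set: Optional[Union[SourceSet, str]] = None,
    restrict_hes_to_linkage_eligible: bool = True,
) -> pd.DataFrame:
    """Derive one category per patient in ``meta``, vectorised.

    Applies source selection first when ``source_set`` is given.  Patients
    without records appear with category Unknown; records referencing
    patients absent from ``meta`` are excluded with a warning.  The output
    (one row per patient, sorted by patient id) is independent of input
    row order and equals ``derive_patient`` applied per patient.
    """
    records = records.copy()
    if source_set is not None:
        records = select_sources(
            records, source_set, restrict_hes_to_linkage_eligible, meta
        )
    known_patients = set(meta["patient_id"])
    orphan = ~records["patient_id"].isin(known_patients)
    if orphan.any():
        logger.warning(
            "%d record(s) reference patients absent from metadata; excluded",
            int(orphan.sum()),
        )
        records = records[~orphan]
    if "care_tier" not in records.columns:
        records["care_tier"] = records["source"].map(care_tier_of)
    if not np.issubdtype(records["record_date"].dtype, np.datetime64):
        records["record_date"] = pd.to_datetime(records["record_date"])

    usable = records[records["category"] != EthnicCategory.UNKNOWN.value]
    n_usable = usable.groupby("patient_id")["category"].size()

    if usable.empty:
        resolved = pd.DataFrame(columns=["patient_id", "category", "deciding_step"])
    else:
        agg = _aggregate(usable, config)
        resolved = _staged_filter(agg, config)
        if config.prioritise_non_other:
            n_categories = agg.groupby("patient_id")["category"].size()
            other_winners = resolved.loc[
                resolved["category"] == EthnicCategory.OTHER.value, "patient_id"
            ]
            # rewrite only applies when another known category is on record
            rewrite_ids = [
                p for p in other_winners if n_categories.get(p, 0) > 1
            ]
            if rewrite_ids:
                subset = usable[
                    usable["patient_id"].isin(rewrite_ids)
                    & (usable["category"] != EthnicCategory.OTHER.value)
                ]
                redo = _staged_filter(_aggregate(subset, config), config)
                redo["deciding_step"] = "non_other_rewrite"
                resolved = pd.concat(
                    [resolved[~resolved["patient_id"].isin(rewrite_ids)], redo],
                    ignore_index=True,
                )

    out = pd.DataFrame({"patient_id": sorted(set(meta["patient_id"]))})
    out = out.merge(resolved, on="patient_id", how="left")
    out["n_usable_records"] = (
        out["patient_id"].map(n_usable).fillna(0).astype(int)
    )
    missing = out["category"].isna()
    out.loc[missing, "category"] = EthnicCategory.UNKNOWN.value
    out.loc[missing, "deciding_step"] = "no_usable_records"
    return out.rename(columns={"category": "ethnicity"}).reset_index(drop=True)
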