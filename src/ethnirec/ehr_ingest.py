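"""Read source flat files, deduplicate practices, filter populations.

The real CPRD GOLD/Aurum and HES table schemas are licensed, so this module
defines minimal analogous flat-file contracts (documented per reader) and
leaves the mapping from licensed extracts to these shapes to the user:

* primary-care file: ``patient_id,practice_id,code,coding_system,obs_date``
* HES file:          ``patient_id,ethnos_code,episode_date,dataset``
* patient metadata:  ``patient_id,database,practice_id,acceptable,
  linkage_eligible,currently_registered,sex`` (booleans as 0/1)
* bridging file:     ``practice_id_gold,practice_id_aurum``

All readers return :class:`pandas.DataFrame` tables; record tables are
normalised to ``patient_id, source, coding_system, code, record_date`` so a
single code-mapping and derivation path serves every source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .code_mapping import CodingSystem, EthnicCategory

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCES",
    "SOURCE_SET_PRESETS",
    "COVERAGE_CUTOFFS",
    "SourceSet",
    "EthnicityRecord",
    "PatientMeta",
    "IngestFormatError",
    "care_tier_of",
    "read_primary_care",
    "read_hes",
    "read_patient_meta",
    "read_bridging",
    "apply_bridging",
    "filter_population",
    "select_sources",
]

#: The six record sources; cprd_* are primary care, hes_* secondary care.
SOURCES = ("cprd_gold", "cprd_aurum", "hes_apc", "hes_op", "hes_ae", "hes_did")

_HES_DATASETS = ("apc", "op", "ae", "did")

#: Linked-data coverage cut-offs per HES dataset.  Used for validation
#: warnings only — synthetic data controls its own dates, and real extracts
#: should be windowed upstream.
COVERAGE_CUTOFFS = {
    "hes_apc": date(2021, 3, 31),
    "hes_op": date(2020, 10, 31),
    "hes_did": date(2020, 10, 31),
    "hes_ae": date(2020, 3, 31),
}


class IngestFormatError(ValueError):
    """An input file does not match its documented column contract."""


def care_tier_of(source: str) -> str:
    """primary for cprd_*, secondary for hes_*; pure function of source."""
    if source.startswith("cprd_"):
        return "primary"
    if source.startswith("hes_"):
        return "secondary"
    raise ValueError(f"unknown source {source!r}")


@dataclass(frozen=True)
class EthnicityRecord:
    """One dated, source-attributed, category-mapped ethnicity observation."""

    patient_id: str
    source: str
    category: EthnicCategory
    record_date: Optional[date] = None
    raw_code: str = ""

    @property
    def care_tier(self) -> str:
        return care_tier_of(self.source)


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    database: str  # gold | aurum
    practice_id: str
    acceptable: bool
    linkage_eligible: bool
    currently_registered: bool
    sex: str = "indeterminate"


@dataclass(frozen=True)
class SourceSet:
    """Which of the six record sources contribute to derivation."""

    included: frozenset
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        bad = set(self.included) - set(SOURCES)
        if bad:
            raise ValueError(f"unknown sources in source set: {sorted(bad)}")

    @classmethod
    def preset(cls, name: str) -> "SourceSet":
        try:
            members = SOURCE_SET_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown source-set preset {name!r}; valid presets: "
                + ", ".join(sorted(SOURCE_SET_PRESETS))
            ) from None
        return cls(included=frozenset(members), preset_name=name)


#: The four source-set variants assessed: everything, primary care plus the
#: admitted-patient-care dataset only, primary care only, APC only.
SOURCE_SET_PRESETS = {
    "all_sources": frozenset(SOURCES),
    "cprd_hes_apc": frozenset({"cprd_gold", "cprd_aurum", "hes_apc"}),
    "cprd_only": frozenset({"cprd_gold", "cprd_aurum"}),
    "hes_apc_only": frozenset({"hes_apc"}),
}


def _read_table(path: Union[str, Path], required: tuple) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(required) - set(frame.columns)
    if missing:
        raise IngestFormatError(
            f"{path}: missing column(s) {sorted(missing)} (found {list(frame.columns)})"
        )
    return frame


def _parse_iso_dates(
    raw: pd.Series, path: Union[str, Path], column: str
) -> pd.Series:
    """Strict ISO-8601 date parsing; empty cells become missing dates."""
    stripped = raw.astype(str).str.strip()
    parsed = pd.to_datetime(stripped, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (stripped != "")
    if bad.any():
        # header is line 1, first data row line 2
        lines = [int(i) + 2 for i in raw.index[bad][:5]]
        raise IngestFormatError(
            f"{path}: malformed {column} value(s) at line(s) {lines} "
            f"(first bad value: {stripped[bad].iloc[0]!r}); expected YYYY-MM-DD"
        )
    n_missing = int((stripped == "").sum())
    if n_missing:
        logger.warning("%s: %d record(s) with missing %s", path, n_missing, column)
    return parsed


def read_primary_care(path: Union[str, Path], dialect: str) -> pd.DataFrame:
    """Read a GOLD- or Aurum-shaped observation table.

    Returns the normalised raw-record frame with ``source`` set to
    ``cprd_gold`` or ``cprd_aurum`` and ``coding_system`` taken from the
    file (``read`` for GOLD, ``snomed`` for Aurum, validated).
    """
    if dialect not in ("gold", "aurum"):
        raise ValueError(f"dialect must be 'gold' or 'aurum', got {dialect!r}")
    frame = _read_table(
        path, ("patient_id", "practice_id", "code", "coding_system", "obs_date")
    )
    expected_system = CodingSystem.READ if dialect == "gold" else CodingSystem.SNOMED
    systems = frame["coding_system"].str.strip().str.lower()
    if not frame.empty and not (systems == expected_system.value).all():
        offending = sorted(set(systems) - {expected_system.value})
        raise IngestFormatError(
            f"{path}: {dialect} files must use coding_system "
            f"{expected_system.value!r}; found {offending}"
        )
    dates = _parse_iso_dates(frame["obs_date"], path, "obs_date")
    return pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "source": f"cprd_{dialect}",
            "coding_system": expected_system.value,
            "code": frame["code"],
            "record_date": dates,
        }
    )


def read_hes(path: Union[str, Path], dataset: Optional[str] = None) -> pd.DataFrame:
    """Read a HES-like episode table (one ethnos code per row).

    ``dataset`` (apc|op|ae|did), when given, asserts that every row belongs
    to that dataset; otherwise the file's ``dataset`` column is used as is.
    Identical duplicate rows are retained — repeated episodes are real data.
    Records dated after the dataset's linked-data coverage cut-off trigger a
    warning, never a drop.
    """
    if dataset is not None and dataset not in _HES_DATASETS:
        raise ValueError(
            f"dataset must be one of {_HES_DATASETS}, got {dataset!r}"
        )
    frame = _read_table(path, ("patient_id", "ethnos_code", "episode_date", "dataset"))
    datasets = frame["dataset"].str.strip().str.lower()
    bad = sorted(set(datasets) - set(_HES_DATASETS)) if not frame.empty else []
    if bad:
        raise IngestFormatError(f"{path}: unknown HES dataset label(s) {bad}")
    if dataset is not None and not frame.empty and not (datasets == dataset).all():
        raise IngestFormatError(
            f"{path}: expected all rows to be dataset {dataset!r}; found "
            f"{sorted(set(datasets))}"
        )
    dates = _parse_iso_dates(frame["episode_date"], path, "episode_date")
    sources = ("hes_" + datasets) if not frame.empty else pd.Series(dtype=object)
    out = pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "source": sources,
            "coding_system": CodingSystem.HES_ETHNOS.value,
            "code": frame["ethnos_code"],
            "record_date": dates,
        }
    )
    for source, cutoff in COVERAGE_CUTOFFS.items():
        late = (out["source"] == source) & (out["record_date"] > pd.Timestamp(cutoff))
        if late.any():
            logger.warning(
                "%s: %d %s record(s) dated after the coverage cut-off %s",
                path,
                int(late.sum()),
                source,
                cutoff,
            )
    return out


_BOOL_VALUES = {"0": False, "1": True}


def read_patient_meta(path: Union[str, Path]) -> pd.DataFrame:
    frame = _read_table(
        path,
        (
            "patient_id",
            "database",
            "practice_id",
            "acceptable",
            "linkage_eligible",
            "currently_registered",
            "sex",
        ),
    )
    for column in ("acceptable", "linkage_eligible", "currently_registered"):
        values = frame[column].str.strip()
        bad = sorted(set(values) - set(_BOOL_VALUES)) if not frame.empty else []
        if bad:
            raise IngestFormatError(
                f"{path}: column {column!r} must be 0/1; found {bad}"
            )
        frame[column] = values.map(_BOOL_VALUES)
    databases = frame["database"].str.strip().str.lower()
    bad_db = sorted(set(databases) - {"gold", "aurum"}) if not frame.empty else []
    if bad_db:
        raise IngestFormatError(f"{path}: unknown database label(s) {bad_db}")
    frame["database"] = databases
    return frame


def read_bridging(path: Union[str, Path]) -> pd.DataFrame:
    frame = _read_table(path, ("practice_id_gold", "practice_id_aurum"))
    if frame.duplicated().any():
        frame = frame.drop_duplicates(ignore_index=True)
    return frame


def apply_bridging(
    meta_gold: pd.DataFrame,
    meta_aurum: pd.DataFrame,
    bridging: pd.DataFrame,
) -> pd.DataFrame:
    """Deduplicate practices present in both databases (Aurum records kept).

    Drops every GOLD patient whose practice appears in the bridging file's
    GOLD column; Aurum patients are never dropped.  Idempotent.  Bridging
    practice ids found in neither database produce a warning, not an error.
    """
    bridged_gold = set(bridging["practice_id_gold"]) if len(bridging) else set()
    known_practices = set(meta_gold["practice_id"]) | set(meta_aurum["practice_id"])
    orphans = (
        set(bridging["practice_id_gold"]) | set(bridging["practice_id_aurum"])
        if len(bridging)
        else set()
    ) - known_practices
    if orphans:
        logger.warning(
            "bridging file names %d practice id(s) absent from both databases: %s",
            len(orphans),
            sorted(orphans)[:5],
        )
    kept_gold = meta_gold[~meta_gold["practice_id"].isin(bridged_gold)]
    out = pd.concat([meta_aurum, kept_gold], ignore_index=True)
    duplicated = out.duplicated(subset=["database", "patient_id"])
    if duplicated.any():
        raise IngestFormatError(
            f"{int(duplicated.sum())} duplicate (database, patient_id) pair(s) "
            "after bridging deduplication"
        )
    return out


def filter_population(
    meta: pd.DataFrame,
    acceptable_only: bool = False,
    currently_registered_only: bool = False,
    linkage_eligible_only: bool = False,
) -> pd.DataFrame:
    """Conjunctive population filter; each flag independently applicable."""
    mask = pd.Series(True, index=meta.index)
    if acceptable_only:
        mask &= meta["acceptable"].astype(bool)
    if currently_registered_only:
        mask &= meta["currently_registered"].astype(bool)
    if linkage_eligible_only:
        mask &= meta["linkage_eligible"].astype(bool)
    return meta[mask].reset_index(drop=True)


def select_sources(
    records: pd.DataFrame,
    source_set: Union[SourceSet, str],
    restrict_hes_to_linkage_eligible: bool = True,
    meta: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Keep records whose source is in the source set.

    With ``restrict_hes_to_linkage_eligible`` (the default — linked hospital
    data only exists for linkage-eligible patients), hes_* records of
    patients not flagged ``linkage_eligible`` in ``meta`` are dropped.
    Idempotent; output is always a subset of the input rows.
    """
    if isinstance(source_set, str):
        source_set = SourceSet.preset(source_set)
    out = records[records["source"].isin(source_set.included)]
    if restrict_hes_to_linkage_eligible:
        if meta is None:
            raise ValueError(
                "meta is required when restrict_hes_to_linkage_eligible is set"
            )
        eligible = set(meta.loc[meta["linkage_eligible"].astype(bool), "patient_id"])
        is_hes = out["source"].str.startswith("hes_")
        out = out[~is_hes | out["patient_id"].isin(eligible)]
    return out
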