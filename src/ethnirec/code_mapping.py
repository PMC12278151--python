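"""Map source-specific ethnicity codes to the six high-level categories.

Primary-care ethnicity is recorded with Read codes (CPRD GOLD dialect) or
SNOMED-CT concepts (CPRD Aurum dialect); hospital episodes carry the NHS
"ethnos" field.  A code list maps each (code, coding system) pair to one of
six high-level ethnic groups commonly used in UK healthcare research:
Asian, Black, Mixed/Multiple, White, Other and Unknown.

The code lists shipped under :mod:`ethnirec.data` are small synthetic
examples in the documented format; any list with the same header can be
dropped in, so full published lists can be used where licensing allows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EthnicCategory",
    "CodingSystem",
    "CodeListEntry",
    "CodeList",
    "CodeListError",
    "CodeListFormatError",
    "CodeListValidationError",
    "DuplicateCodeError",
    "UnmappedCodeError",
    "KNOWN_CATEGORIES",
    "CANONICAL_ORDER",
    "load_codelist",
    "bundled_codelist_path",
    "map_code",
    "map_raw_records",
]


class EthnicCategory(str, Enum):
    """High-level ethnic category.

    Exactly six admissible values.  Parsing is case-insensitive; the
    canonical printed labels are used on all output.  ``Unknown`` must be
    explicit in a code list — an absent category is a format error, never a
    silent Unknown.
    """

    ASIAN = "Asian"
    BLACK = "Black"
    MIXED = "Mixed/Multiple"
    WHITE = "White"
    OTHER = "Other"
    UNKNOWN = "Unknown"

    @classmethod
    def parse(cls, label: Union[str, "EthnicCategory"]) -> "EthnicCategory":
        if isinstance(label, EthnicCategory):
            return label
        if not isinstance(label, str):
            raise CodeListValidationError(f"category must be a string, got {label!r}")
        key = label.strip().lower()
        try:
            return _CATEGORY_ALIASES[key]
        except KeyError:
            raise CodeListValidationError(
                f"unknown ethnic category {label!r}; admissible values are "
                + ", ".join(c.value for c in EthnicCategory)
            ) from None

    def __str__(self) -> str:  # canonical label on output
        return self.value


_CATEGORY_ALIASES = {c.value.lower(): c for c in EthnicCategory}
_CATEGORY_ALIASES["mixed"] = EthnicCategory.MIXED
_CATEGORY_ALIASES["mixed/multiple"] = EthnicCategory.MIXED
_CATEGORY_ALIASES["mixed or multiple"] = EthnicCategory.MIXED

#: The five known categories (Unknown excluded), census-table order.
KNOWN_CATEGORIES = (
    EthnicCategory.WHITE,
    EthnicCategory.ASIAN,
    EthnicCategory.BLACK,
    EthnicCategory.MIXED,
    EthnicCategory.OTHER,
)

#: Canonical reporting order for tables and confusion matrices.
CANONICAL_ORDER = (
    EthnicCategory.ASIAN,
    EthnicCategory.BLACK,
    EthnicCategory.MIXED,
    EthnicCategory.WHITE,
    EthnicCategory.OTHER,
    EthnicCategory.UNKNOWN,
)


class CodingSystem(str, Enum):
    READ = "read"          # CPRD GOLD (Vision)
    SNOMED = "snomed"      # CPRD Aurum (EMIS Web)
    HES_ETHNOS = "hes_ethnos"  # HES bespoke ethnos field

    @classmethod
    def parse(cls, label: Union[str, "CodingSystem"]) -> "CodingSystem":
        if isinstance(label, CodingSystem):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise CodeListValidationError(
                f"unknown coding system {label!r}; expected one of "
                + ", ".join(s.value for s in CodingSystem)
            ) from None

    def __str__(self) -> str:
        return self.value


class CodeListError(ValueError):
    """Base class for code-list problems."""


class CodeListFormatError(CodeListError):
    """The file does not match the documented header/format."""


class CodeListValidationError(CodeListError):
    """A row carries an inadmissible category or coding system."""


class DuplicateCodeError(CodeListError):
    """The same (code, coding_system) pair appears more than once."""


class UnmappedCodeError(KeyError):
    """Strict-mode lookup of a code absent from the list."""


@dataclass(frozen=True)
class CodeListEntry:
    code: str
    coding_system: CodingSystem
    description: str
    category: EthnicCategory


@dataclass
class CodeList:
    """An in-memory code list with total, loud lookup.

    Lookup is keyed on ``(code, coding_system)``; both are opaque strings as
    far as this module is concerned (no Read-code hierarchy logic).
    """

    entries: list[CodeListEntry]
    provenance: str = ""
    _index: dict[tuple[str, CodingSystem], CodeListEntry] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for entry in self.entries:
            key = (entry.code, entry.coding_system)
            if key in self._index:
                raise DuplicateCodeError(
                    f"duplicate code list entry for code={entry.code!r} "
                    f"coding_system={entry.coding_system.value!r}"
                )
            self._index[key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, Union[str, CodingSystem]]) -> bool:
        code, system = key
        return (str(code), CodingSystem.parse(system)) in self._index

    def lookup(self, code: str, coding_system: Union[str, CodingSystem]) -> CodeListEntry:
        key = (str(code), CodingSystem.parse(coding_system))
        try:
            return self._index[key]
        except KeyError:
            raise UnmappedCodeError(
                f"code {code!r} ({key[1].value}) is not in code list "
                f"{self.provenance or '<unnamed>'}"
            ) from None

    def codes_for(
        self, category: EthnicCategory, coding_system: Union[str, CodingSystem]
    ) -> list[str]:
        """All codes in one system mapping to ``category`` (list order)."""
        system = CodingSystem.parse(coding_system)
        return [
            e.code
            for e in self.entries
            if e.coding_system is system and e.category is category
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [e.code for e in self.entries],
                "coding_system": [e.coding_system.value for e in self.entries],
                "description": [e.description for e in self.entries],
                "category": [e.category.value for e in self.entries],
            }
        )

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


_REQUIRED_COLUMNS = ("code", "coding_system", "description", "category")


def load_codelist(
    path: Union[str, Path],
    expected_system: Optional[Union[str, CodingSystem]] = None,
    provenance: Optional[str] = None,
) -> CodeList:
    """Load a code list from delimiter-separated text.

    The file must have a header naming ``code, coding_system, description,
    category``.  Every category must be one of the six admissible values and
    (code, coding_system) pairs must be unique.  ``expected_system``
    restricts the file to a single coding system.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise CodeListFormatError(
                f"{path}: missing required column {column!r} "
                f"(found {list(frame.columns)})"
            )
    expected = CodingSystem.parse(expected_system) if expected_system else None
    entries: list[CodeListEntry] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        if not str(row.category).strip():
            raise CodeListFormatError(
                f"{path}: row {row_number}: category is empty — Unknown must "
                "be written explicitly"
            )
        try:
            system = CodingSystem.parse(row.coding_system)
            category = EthnicCategory.parse(row.category)
        except CodeListValidationError as exc:
            raise CodeListValidationError(f"{path}: row {row_number}: {exc}") from None
        if expected is not None and system is not expected:
            raise CodeListValidationError(
                f"{path}: row {row_number}: coding system {system.value!r} "
                f"does not match expected {expected.value!r}"
            )
        entries.append(
            CodeListEntry(
                code=str(row.code),
                coding_system=system,
                description=str(row.description),
                category=category,
            )
        )
    return CodeList(entries=entries, provenance=provenance or str(path))


def bundled_codelist_path(coding_system: Union[str, CodingSystem]) -> Path:
    """Path to the synthetic example code list shipped for one system."""
    system = CodingSystem.parse(coding_system)
    root = resources.files("ethnirec.data") / "codelists"
    return Path(str(root / f"{system.value}.csv"))


def load_bundled_codelists() -> CodeList:
    """One merged CodeList over all three bundled example lists."""
    entries: list[CodeListEntry] = []
    for system in CodingSystem:
        entries.extend(load_codelist(bundled_codelist_path(system), system).entries)
    return CodeList(entries=entries, provenance="bundled synthetic example lists")


def map_code(
    code: str,
    coding_system: Union[str, CodingSystem],
    codelist: CodeList,
    mode: str = "strict",
) -> EthnicCategory:
    """Map one raw code to its high-level category.

    ``mode='strict'`` (default) raises :class:`UnmappedCodeError` for codes
    absent from the list; ``mode='lenient'`` returns ``Unknown`` and logs.
    Strict is the default because published lists are presumed exhaustive
    and silent coercion hides data errors.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    try:
        return codelist.lookup(code, coding_system).category
    except UnmappedCodeError:
        if mode == "strict":
            raise
        logger.warning(
            "unlisted code %r (%s) mapped to Unknown (lenient mode)",
            code,
            CodingSystem.parse(coding_system).value,
        )
        return EthnicCategory.UNKNOWN


def map_raw_records(
    raw_rows: pd.DataFrame,
    codelist: CodeList,
    mode: str = "strict",
) -> pd.DataFrame:
    """Vectorised mapping of a raw record table to an ethnicity-record table.

    ``raw_rows`` must carry ``patient_id, source, coding_system, code,
    record_date`` (the normalised shape the ingest readers emit).  Returns
    one row per input row, order preserved, with ``category`` and
    ``care_tier`` columns added.  In strict mode an unlisted code raises
    with the offending row index; in lenient mode the row maps to Unknown
    and the count is conserved.
    """
    from .ehr_ingest import care_tier_of  # local import to avoid a cycle

    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    required = {"patient_id", "source", "coding_system", "code", "record_date"}
    missing = required - set(raw_rows.columns)
    if missing:
        raise CodeListFormatError(f"raw rows missing columns: {sorted(missing)}")

    out = raw_rows.copy()
    if out.empty:
        out["category"] = pd.Series(dtype=object)
        out["care_tier"] = pd.Series(dtype=object)
        return out

    mapping = {
        (e.code, e.coding_system.value): e.category.value for e in codelist.entries
    }
    keys = list(zip(out["code"].astype(str), out["coding_system"].astype(str)))
    categories = [mapping.get(k) for k in keys]
    if mode == "strict":
        for position, mapped in enumerate(categories):
            if mapped is None:
                code, system = keys[position]
                raise UnmappedCodeError(
                    f"row {out.index[position]}: code {code!r} ({system}) is "
                    f"not in code list {codelist.provenance or '<unnamed>'}"
                )
    else:
        n_unlisted = sum(1 for c in categories if c is None)
        if n_unlisted:
            logger.warning(
                "%d unlisted code(s) mapped to Unknown (lenient mode)", n_unlisted
            )
        categories = [
            EthnicCategory.UNKNOWN.value if c is None else c for c in categories
        ]
    out["category"] = categories
    out["care_tier"] = out["source"].map(care_tier_of)
    out = out.rename(columns={"code": "raw_code"})
    return out
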