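"""Generate multi-source synthetic EHR cohorts with known ground truth.

Real linked primary/secondary-care extracts are access-controlled, so this
module fabricates cohorts in exactly the flat-file shapes
:mod:`ethnirec.ehr_ingest` reads, with a truth table alongside.  The
generator emulates the statistical structure of the real data landscape:

* two primary-care databases (Aurum holding ~76% of patients, per the
  published database split) with practice-level overlap captured in a
  bridging file;
* ~82% of patients eligible for linkage to hospital datasets, which is
  the only way secondary-care records exist;
* per-source recording completeness tuned so that, at the defaults,
  roughly 64% of patients end up with at least one usable (known-category)
  record — the completeness level reported for the real linked cohort;
* per-record noise: a configurable misclassification rate (uniform over
  the other four known categories unless a confusion matrix is supplied)
  and a rate of unknown-category codes;
* record multiplicity via a shifted Poisson (at least one record given any)
  and record dates uniform over a configurable window.

It does **not** attempt realistic clinical vocabulary usage, consultation
patterns, practice-level clustering of ethnicity, or deprivation/geography
structure; see the methods note for what that implies about test evidence.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .code_mapping import (
    CodeList,
    CodingSystem,
    EthnicCategory,
    KNOWN_CATEGORIES,
    load_bundled_codelists,
)
from .derivation import ENGLAND_CENSUS_2021

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "cohort_raw_records",
    "truth_accuracy",
]

#: Share of secondary-care records allocated to each hospital dataset.
#: Admitted-patient care dominates, which is what makes "primary + APC"
#: agree far better with "all sources" than either single-source variant.
HES_DATASET_WEIGHTS = {"apc": 0.50, "op": 0.30, "ae": 0.15, "did": 0.05}


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic cohort generator.

    Defaults encode the documented study conditions: Aurum fraction 0.7604,
    linkage eligibility 0.8218, truth distribution equal to the England
    2021 Census, and per-source completeness chosen so the overall
    usable-record fraction lands near 64%.
    """

    n_patients: int = 10_000
    true_distribution: dict = field(
        default_factory=lambda: {
            c: ENGLAND_CENSUS_2021.proportions[c] for c in KNOWN_CATEGORIES
        }
    )
    aurum_fraction: float = 0.7604
    acceptable_fraction: float = 0.95
    currently_registered_fraction: float = 0.50
    linkage_eligible_fraction: float = 0.8218
    p_record_primary: float = 0.40
    p_record_secondary: float = 0.52
    #: odds multiplier for secondary presence given primary presence;
    #: 1.0 keeps the two independent.
    secondary_given_primary_odds: float = 1.0
    records_per_patient_mean: float = 5.0
    misclassification_rate: float = 0.05
    p_unknown_code: float = 0.05
    #: optional row-stochastic confusion override {true_cat: {obs_cat: p}};
    #: when set, misclassification_rate/p_unknown_code are ignored.
    confusion_matrix: Optional[dict] = None
    date_window: tuple = (date(2004, 1, 1), date(2021, 3, 31))
    #: 0 = dates uniform over the window; larger values skew record dates
    #: toward the end of the window (recent-recording trend).
    recency_trend: float = 0.0
    n_practices_per_db: int = 20
    n_bridged_practices: int = 2
    p_missing_date: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        proportions = {EthnicCategory.parse(c): v for c, v in self.true_distribution.items()}
        if set(proportions) != set(KNOWN_CATEGORIES):
            raise ValueError(
                "true_distribution must cover exactly the five known categories"
            )
        total = sum(proportions.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(
                f"true_distribution sums to {total}, expected 100±0.1"
            )
        for name in (
            "aurum_fraction",
            "acceptable_fraction",
            "currently_registered_fraction",
            "linkage_eligible_fraction",
            "p_record_primary",
            "p_record_secondary",
            "misclassification_rate",
            "p_unknown_code",
            "p_missing_date",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.misclassification_rate + self.p_unknown_code > 1.0:
            raise ValueError(
                "misclassification_rate + p_unknown_code must not exceed 1"
            )
        if self.records_per_patient_mean < 1.0:
            raise ValueError("records_per_patient_mean must be >= 1")
        if self.secondary_given_primary_odds <= 0:
            raise ValueError("secondary_given_primary_odds must be positive")
        if self.recency_trend < 0:
            raise ValueError("recency_trend must be >= 0")
        start, end = self.date_window
        if start >= end:
            raise ValueError("date_window must be a non-empty interval")
        if self.n_bridged_practices > self.n_practices_per_db:
            raise ValueError("n_bridged_practices cannot exceed n_practices_per_db")

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    def to_jsonable(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["true_distribution"] = {
            EthnicCategory.parse(c).value: v for c, v in self.true_distribution.items()
        }
        payload["date_window"] = [d.isoformat() for d in self.date_window]
        if self.confusion_matrix is not None:
            payload["confusion_matrix"] = {
                EthnicCategory.parse(a).value: {
                    EthnicCategory.parse(b).value: p for b, p in row.items()
                }
                for a, row in self.confusion_matrix.items()
            }
        return payload


@dataclass
class SyntheticCohort:
    """In-memory result of one generator run."""

    truth: pd.DataFrame          # patient_id, true_category
    meta: pd.DataFrame           # ehr_ingest patient-metadata shape
    primary_gold: pd.DataFrame   # primary-care file shape (GOLD)
    primary_aurum: pd.DataFrame  # primary-care file shape (Aurum)
    hes: dict                    # dataset -> HES file shape
    bridging: pd.DataFrame       # practice_id_gold, practice_id_aurum
    params: SimulationParams


def _sample_categories(
    rng: np.random.Generator, truth: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """Observed category per record given each record's true category."""
    categories = np.array([c.value for c in KNOWN_CATEGORIES] + ["Unknown"])
    index_of = {c: i for i, c in enumerate(categories)}
    n = len(truth)
    if params.confusion_matrix is not None:
        matrix = np.zeros((len(KNOWN_CATEGORIES), len(categories)))
        for a, row in params.confusion_matrix.items():
            ai = index_of[EthnicCategory.parse(a).value]
            for b, p in row.items():
                matrix[ai, index_of[EthnicCategory.parse(b).value]] = p
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("confusion_matrix rows must sum to 1")
        truth_idx = np.array([index_of[t] for t in truth])
        u = rng.random(n)
        cum = matrix.cumsum(axis=1)
        picks = (u[:, None] > cum[truth_idx]).sum(axis=1)
        return categories[picks]
    out = truth.copy()
    u = rng.random(n)
    unknown_mask = u < params.p_unknown_code
    mis_mask = (~unknown_mask) & (
        u < params.p_unknown_code + params.misclassification_rate
    )
    out[unknown_mask] = "Unknown"
    if mis_mask.any():
        known = np.array([c.value for c in KNOWN_CATEGORIES])
        truth_idx = np.array([index_of[t] for t in truth[mis_mask]])
        # uniform over the other four known categories
        shift = rng.integers(1, len(known), size=int(mis_mask.sum()))
        out[mis_mask] = known[(truth_idx + shift) % len(known)]
    return out


def _sample_dates(
    rng: np.random.Generator, n: int, params: SimulationParams
) -> np.ndarray:
    start, end = params.date_window
    span = (end - start).days
    u = rng.random(n)
    if params.recency_trend > 0:
        u = u ** (1.0 / (1.0 + params.recency_trend))
    offsets = (u * span).astype(int)
    return np.datetime64(start) + offsets.astype("timedelta64[D]")


def _codes_for(
    codelist: CodeList, system: CodingSystem
) -> dict:
    table = {}
    for category in list(KNOWN_CATEGORIES) + [EthnicCategory.UNKNOWN]:
        codes = codelist.codes_for(category, system)
        if not codes:
            raise ValueError(
                f"code list has no {category.value} codes for {system.value}"
            )
        table[category.value] = np.array(codes)
    return table


def _pick_codes(
    rng: np.random.Generator, observed: np.ndarray, code_table: dict
) -> np.ndarray:
    out = np.empty(len(observed), dtype=object)
    for category, codes in code_table.items():
        mask = observed == category
        if mask.any():
            out[mask] = codes[rng.integers(0, len(codes), size=int(mask.sum()))]
    return out


def generate_cohort(
    params: SimulationParams,
    codelist: Optional[CodeList] = None,
) -> SyntheticCohort:
    """Generate one cohort; reproducible given ``params.seed``.

    Validation runs before anything is produced.  Secondary-care records
    are generated only for linkage-eligible patients.  Record categories
    equal the patient's true category unless the record is unknown-coded or
    misclassified; codes are drawn from the code list's entries for the
    observed category in the source's coding system.
    """
    params.validate()
    codelist = codelist or load_bundled_codelists()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    patient_ids = np.array([f"p{i:08d}" for i in range(1, n + 1)])
    proportions = {
        EthnicCategory.parse(c): v for c, v in params.true_distribution.items()
    }
    known = np.array([c.value for c in KNOWN_CATEGORIES])
    probs = np.array([proportions[c] for c in KNOWN_CATEGORIES]) / 100.0
    probs = probs / probs.sum()
    truth = known[rng.choice(len(known), size=n, p=probs)]

    is_aurum = rng.random(n) < params.aurum_fraction
    acceptable = rng.random(n) < params.acceptable_fraction
    registered = rng.random(n) < params.currently_registered_fraction
    eligible = rng.random(n) < params.linkage_eligible_fraction
    sex = np.where(rng.random(n) < 0.5, "female", "male")

    # practices: gold practices g001.., aurum practices a001..; the first
    # n_bridged gold practices also appear in the bridging file
    n_prac = params.n_practices_per_db
    gold_practices = np.array([f"g{i:03d}" for i in range(1, n_prac + 1)])
    aurum_practices = np.array([f"a{i:03d}" for i in range(1, n_prac + 1)])
    practice = np.where(
        is_aurum,
        aurum_practices[rng.integers(0, n_prac, size=n)],
        gold_practices[rng.integers(0, n_prac, size=n)],
    )
    bridging = pd.DataFrame(
        {
            "practice_id_gold": gold_practices[: params.n_bridged_practices],
            "practice_id_aurum": aurum_practices[: params.n_bridged_practices],
        }
    )

    has_primary = rng.random(n) < params.p_record_primary
    p_sec = np.full(n, params.p_record_secondary)
    if params.secondary_given_primary_odds != 1.0:
        odds = (
            p_sec / (1 - p_sec) * params.secondary_given_primary_odds
        )
        p_sec = np.where(has_primary, odds / (1 + odds), p_sec)
    has_secondary = (rng.random(n) < p_sec) & eligible

    def record_counts(mask: np.ndarray) -> np.ndarray:
        counts = np.zeros(n, dtype=int)
        size = int(mask.sum())
        counts[mask] = 1 + rng.poisson(params.records_per_patient_mean - 1.0, size)
        return counts

    primary_counts = record_counts(has_primary)
    secondary_counts = record_counts(has_secondary)

    code_tables = {
        system: _codes_for(codelist, system) for system in CodingSystem
    }

    def build_records(counts: np.ndarray) -> pd.DataFrame:
        idx = np.repeat(np.arange(n), counts)
        observed = _sample_categories(rng, truth[idx], params)
        dates = _sample_dates(rng, len(idx), params)
        date_strings = np.datetime_as_string(dates, unit="D")
        if params.p_missing_date > 0:
            missing = rng.random(len(idx)) < params.p_missing_date
            date_strings = np.where(missing, "", date_strings)
        return pd.DataFrame(
            {
                "_idx": idx,
                "patient_id": patient_ids[idx],
                "_observed": observed,
                "_date": date_strings,
            }
        )

    primary = build_records(primary_counts)
    primary["_aurum"] = is_aurum[primary["_idx"]]
    primary["practice_id"] = practice[primary["_idx"]]

    def primary_frame(rows: pd.DataFrame, system: CodingSystem) -> pd.DataFrame:
        codes = _pick_codes(rng, rows["_observed"].to_numpy(), code_tables[system])
        return pd.DataFrame(
            {
                "patient_id": rows["patient_id"].to_numpy(),
                "practice_id": rows["practice_id"].to_numpy(),
                "code": codes,
                "coding_system": system.value,
                "obs_date": rows["_date"].to_numpy(),
            }
        )

    primary_gold = primary_frame(primary[~primary["_aurum"]], CodingSystem.READ)
    primary_aurum = primary_frame(primary[primary["_aurum"]], CodingSystem.SNOMED)

    secondary = build_records(secondary_counts)
    dataset_names = np.array(list(HES_DATASET_WEIGHTS))
    weights = np.array(list(HES_DATASET_WEIGHTS.values()))
    assignment = dataset_names[
        rng.choice(len(dataset_names), size=len(secondary), p=weights / weights.sum())
    ]
    secondary_codes = _pick_codes(
        rng, secondary["_observed"].to_numpy(), code_tables[CodingSystem.HES_ETHNOS]
    )
    hes = {}
    for name in HES_DATASET_WEIGHTS:
        mask = assignment == name
        hes[name] = pd.DataFrame(
            {
                "patient_id": secondary["patient_id"].to_numpy()[mask],
                "ethnos_code": secondary_codes[mask],
                "episode_date": secondary["_date"].to_numpy()[mask],
                "dataset": name,
            }
        )

    meta = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "database": np.where(is_aurum, "aurum", "gold"),
            "practice_id": practice,
            "acceptable": acceptable.astype(int),
            "linkage_eligible": eligible.astype(int),
            "currently_registered": registered.astype(int),
            "sex": sex,
        }
    )
    truth_table = pd.DataFrame({"patient_id": patient_ids, "true_category": truth})
    return SyntheticCohort(
        truth=truth_table,
        meta=meta,
        primary_gold=primary_gold,
        primary_aurum=primary_aurum,
        hes=hes,
        bridging=bridging,
        params=params,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict:
    """Write a cohort in the ingest file formats plus truth and manifest.

    Returns a name -> path mapping.  Files: ``gold.csv``, ``aurum.csv``,
    ``hes_apc.csv``/``hes_op.csv``/``hes_ae.csv``/``hes_did.csv``,
    ``patients.csv``, ``bridging.csv``, ``truth.csv``, ``params.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path

    emit("gold", cohort.primary_gold)
    emit("aurum", cohort.primary_aurum)
    for dataset, frame in cohort.hes.items():
        emit(f"hes_{dataset}", frame)
    emit("patients", cohort.meta)
    emit("bridging", cohort.bridging)
    emit("truth", cohort.truth)
    manifest = out_dir / "params.json"
    manifest.write_text(
        json.dumps(cohort.params.to_jsonable(), indent=2, sort_keys=True) + "\n"
    )
    paths["params"] = manifest
    return paths


def cohort_raw_records(cohort: SyntheticCohort) -> pd.DataFrame:
    """Normalised raw-record frame for a cohort, without a file round-trip.

    Produces the same shape the ingest readers emit (``patient_id, source,
    coding_system, code, record_date``), ready for
    :func:`ethnirec.code_mapping.map_raw_records`.
    """
    def dates(raw: pd.Series) -> pd.Series:
        return pd.to_datetime(raw.replace("", pd.NaT), format="%Y-%m-%d")

    frames = [
        pd.DataFrame(
            {
                "patient_id": cohort.primary_gold["patient_id"],
                "source": "cprd_gold",
                "coding_system": CodingSystem.READ.value,
                "code": cohort.primary_gold["code"],
                "record_date": dates(cohort.primary_gold["obs_date"]),
            }
        ),
        pd.DataFrame(
            {
                "patient_id": cohort.primary_aurum["patient_id"],
                "source": "cprd_aurum",
                "coding_system": CodingSystem.SNOMED.value,
                "code": cohort.primary_aurum["code"],
                "record_date": dates(cohort.primary_aurum["obs_date"]),
            }
        ),
    ]
    for dataset, frame in cohort.hes.items():
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": frame["patient_id"],
                    "source": f"hes_{dataset}",
                    "coding_system": CodingSystem.HES_ETHNOS.value,
                    "code": frame["ethnos_code"],
                    "record_date": dates(frame["episode_date"]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_accuracy(derived: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Accuracy of non-Unknown derivations against the truth table.

    Returns overall accuracy plus per-category accuracy (recall of each
    true category among patients derived to a known category).
    """
    column = "ethnicity" if "ethnicity" in derived.columns else "category"
    merged = derived[["patient_id", column]].merge(
        truth[["patient_id", "true_category"]], on="patient_id", how="inner"
    )
    known = merged[merged[column] != EthnicCategory.UNKNOWN.value]
    if known.empty:
        raise ValueError("no known derivations: accuracy is undefined")
    correct = known[column].astype(str) == known["true_category"].astype(str)
    per_category = {}
    for category in KNOWN_CATEGORIES:
        subset = known[known["true_category"] == category.value]
        if len(subset):
            per_category[category.value] = float(
                (subset[column].astype(str) == category.value).mean()
            )
    return {
        "overall": float(correct.mean()),
        "n_known": int(len(known)),
        "per_category": per_category,
    }
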