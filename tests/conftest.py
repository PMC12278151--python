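"""Shared fixtures: tiny file-based cohorts and random record-set factories."""

from __future__ import annotations

import itertools
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from ethnirec import (
    EthnicCategory,
    EthnicityRecord,
    SOURCES,
    load_bundled_codelists,
)

CATEGORIES = list(EthnicCategory)
KNOWN = [c for c in CATEGORIES if c is not EthnicCategory.UNKNOWN]


@pytest.fixture(scope="session")
def codelist():
    return load_bundled_codelists()


def make_record(
    category,
    source="cprd_aurum",
    record_date=None,
    patient_id="p1",
    raw_code="x",
):
    return EthnicityRecord(
        patient_id=patient_id,
        source=source,
        category=EthnicCategory.parse(category),
        record_date=record_date,
        raw_code=raw_code,
    )


def random_record_set(rng: np.random.Generator, patient_id="p1", max_records=6):
    """Randomised small record set: categories over all six values,
    sources over all six, dates over a 3-year window with occasional
    missing dates and deliberate duplicates."""
    n = int(rng.integers(0, max_records + 1))
    start = date(2019, 1, 1)
    records = []
    for _ in range(n):
        category = CATEGORIES[rng.integers(0, len(CATEGORIES))]
        source = SOURCES[rng.integers(0, len(SOURCES))]
        if rng.random() < 0.1:
            record_date = None
        else:
            record_date = start + timedelta(days=int(rng.integers(0, 3 * 365)))
        records.append(
            make_record(category, source, record_date, patient_id=patient_id)
        )
    # occasionally duplicate a record exactly (same-day repeat episodes)
    if records and rng.random() < 0.3:
        records.append(records[int(rng.integers(0, len(records)))])
    return records


def records_to_frame(records):
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "source": [r.source for r in records],
            "care_tier": [r.care_tier for r in records],
            "record_date": pd.to_datetime(
                [r.record_date for r in records], errors="coerce"
            ),
            "category": [r.category.value for r in records],
            "raw_code": [r.raw_code for r in records],
        }
    )


@pytest.fixture
def primary_care_file(tmp_path):
    """5-row GOLD-shaped observation file using bundled Read codes."""
    path = tmp_path / "gold.csv"
    path.write_text(
        "patient_id,practice_id,code,coding_system,obs_date\n"
        "p1,g001,9S1..,read,2019-05-01\n"
        "p1,g001,9S6..,read,2020-07-14\n"
        "p2,g001,9S1..,read,2018-01-02\n"
        "p3,g002,9SZ..,read,2021-03-31\n"
        "p4,g002,9S2..,read,\n"
    )
    return path


@pytest.fixture
def hes_file(tmp_path):
    path = tmp_path / "hes_apc.csv"
    path.write_text(
        "patient_id,ethnos_code,episode_date,dataset\n"
        "p1,A,2020-02-02,apc\n"
        "p2,H,2019-11-30,apc\n"
        "p2,H,2019-11-30,apc\n"
    )
    return path


@pytest.fixture
def meta_frame():
    rows = []
    for i, (acceptable, registered, eligible, db) in enumerate(
        [
            (1, 1, 1, "aurum"),
            (1, 1, 0, "aurum"),
            (1, 0, 1, "gold"),
            (0, 0, 1, "gold"),
            (0, 0, 0, "aurum"),
            (0, 1, 1, "gold"),
        ],
        start=1,
    ):
        rows.append(
            {
                "patient_id": f"p{i}",
                "database": db,
                "practice_id": "a001" if db == "aurum" else "g001",
                "acceptable": bool(acceptable),
                "linkage_eligible": bool(eligible),
                "currently_registered": bool(registered),
                "sex": "female",
            }
        )
    return pd.DataFrame(rows)
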