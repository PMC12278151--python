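"""Distribution tables, Cohen's kappa, agreement bands, census comparison.

The evaluation framework mirrors how competing derivation configurations
are compared in practice: per-configuration category distributions (counts
and percentages, half-up rounded to two decimals), pairwise inter-rater
reliability via Cohen's kappa with its large-sample standard error,
qualitative agreement bands, and a representativeness comparison of the
known-category distribution against a census reference.

Kappa is computed from the confusion matrix ``M`` of two categorisations of
the same ``n`` patients::

    p_o   = trace(M) / n
    p_e   = sum_i (row_i / n) (col_i / n)
    kappa = (p_o - p_e) / (1 - p_e)
    se    = sqrt( p_o (1 - p_o) / ( n (1 - p_e)^2 ) )

The standard error is Cohen's large-sample approximation; the exact
Fleiss-Cohen-Everitt variance is deliberately not the default (see the
methods note).  When both categorisations are constant and identical,
``p_e = 1`` and kappa is undefined: this raises, never silently returns
0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .code_mapping import CANONICAL_ORDER, KNOWN_CATEGORIES, EthnicCategory
from .derivation import (
    AlgorithmConfig,
    CensusDistribution,
    ENGLAND_CENSUS_2021,
    derive_cohort,
)
from .ehr_ingest import SourceSet

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionTable",
    "KappaResult",
    "BandScheme",
    "DEFAULT_BANDS",
    "LANDIS_KOCH_BANDS",
    "MCHUGH_BANDS",
    "BAND_SCHEMES",
    "UndefinedKappaError",
    "round_half_up",
    "distribution",
    "crosstab",
    "cohens_kappa",
    "agreement_band",
    "compare_to_reference",
    "run_comparison_suite",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 dp), as tables print."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


class UndefinedKappaError(ValueError):
    """Both raters are constant (p_e = 1); kappa has no defined value."""


@dataclass(frozen=True)
class DistributionTable:
    """Counts and half-up-rounded percentages per category."""

    counts: dict
    percentages: dict
    include_unknown: bool
    population_label: str = ""

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.value for c in self.counts],
                "count": list(self.counts.values()),
                "percentage": [self.percentages[c] for c in self.counts],
            }
        )


def distribution(
    derived: pd.DataFrame,
    include_unknown: bool = True,
    population_label: str = "",
) -> DistributionTable:
    """Category distribution of a derived-ethnicity table.

    With ``include_unknown=False`` the Unknown patients are excluded before
    percentaging, i.e. percentages renormalise over the known categories.
    """
    if len(derived) == 0:
        raise ValueError("empty population: distribution is undefined")
    column = "ethnicity" if "ethnicity" in derived.columns else "category"
    labels = derived[column].astype(str)
    if not include_unknown:
        labels = labels[labels != EthnicCategory.UNKNOWN.value]
        if len(labels) == 0:
            raise ValueError(
                "empty population after excluding Unknown: distribution is undefined"
            )
    raw_counts = labels.value_counts()
    order = CANONICAL_ORDER if include_unknown else tuple(
        c for c in CANONICAL_ORDER if c is not EthnicCategory.UNKNOWN
    )
    counts = {c: int(raw_counts.get(c.value, 0)) for c in order}
    total = sum(counts.values())
    percentages = {c: round_half_up(100.0 * k / total, 2) for c, k in counts.items()}
    return DistributionTable(
        counts=counts,
        percentages=percentages,
        include_unknown=include_unknown,
        population_label=population_label,
    )


def crosstab(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix of two derived tables, joined on patient id.

    The matrix covers the union of categories present in either table, in
    canonical order.  Patients present in only one table are dropped with a
    warning; disjoint id sets are an error.
    """
    col_a = "ethnicity" if "ethnicity" in a.columns else "category"
    col_b = "ethnicity" if "ethnicity" in b.columns else "category"
    merged = a[["patient_id", col_a]].merge(
        b[["patient_id", col_b]],
        on="patient_id",
        how="inner",
        suffixes=("_a", "_b"),
    )
    name_a, name_b = f"{col_a}_a", f"{col_b}_b"
    if merged.empty:
        raise ValueError(
            "no overlapping patient ids between the two derived tables "
            f"(|A|={len(a)}, |B|={len(b)})"
        )
    if len(merged) < len(a) or len(merged) < len(b):
        logger.warning(
            "patient id mismatch: |A|=%d, |B|=%d, paired=%d",
            len(a),
            len(b),
            len(merged),
        )
    present = set(merged[name_a].astype(str)) | set(merged[name_b].astype(str))
    order = [c.value for c in CANONICAL_ORDER if c.value in present]
    table = pd.crosstab(merged[name_a].astype(str), merged[name_b].astype(str))
    table = table.reindex(index=order, columns=order, fill_value=0)
    table.index.name = "a"
    table.columns.name = "b"
    return table


@dataclass(frozen=True)
class BandScheme:
    """Ordered half-open intervals (lo, hi] mapping kappa to a label."""

    name: str
    breakpoints: tuple  # ((upper_bound, label), ...) ascending

    def __post_init__(self) -> None:
        uppers = [u for u, _ in self.breakpoints]
        if uppers != sorted(uppers) or len(set(uppers)) != len(uppers):
            raise ValueError("band breakpoints must be strictly increasing")
        if not math.isclose(uppers[-1], 1.0):
            raise ValueError("band breakpoints must cover (-1, 1]")

    def label(self, kappa: float) -> str:
        if not (-1.0 <= kappa <= 1.0):
            raise ValueError(f"kappa {kappa} outside [-1, 1]")
        for upper, name in self.breakpoints:
            if kappa <= upper:
                return name
        raise AssertionError("breakpoints cover (-1, 1]")


#: Default scheme: the only banding consistent with the labels used for
#: the reported statistics (fair at 0.36, moderate at 0.55, strong at 0.89,
#: almost perfect above 0.90).
DEFAULT_BANDS = BandScheme(
    name="default",
    breakpoints=(
        (0.0, "none"),
        (0.20, "none/slight"),
        (0.40, "fair"),
        (0.60, "moderate"),
        (0.80, "good"),
        (0.90, "strong"),
        (1.00, "almost perfect"),
    ),
)

LANDIS_KOCH_BANDS = BandScheme(
    name="landis_koch",
    breakpoints=(
        (0.0, "poor"),
        (0.20, "slight"),
        (0.40, "fair"),
        (0.60, "moderate"),
        (0.80, "substantial"),
        (1.00, "almost perfect"),
    ),
)

MCHUGH_BANDS = BandScheme(
    name="mchugh",
    breakpoints=(
        (0.20, "none"),
        (0.39, "minimal"),
        (0.59, "weak"),
        (0.79, "moderate"),
        (0.90, "strong"),
        (1.00, "almost perfect"),
    ),
)

BAND_SCHEMES = {s.name: s for s in (DEFAULT_BANDS, LANDIS_KOCH_BANDS, MCHUGH_BANDS)}


def agreement_band(kappa: float, scheme: BandScheme = DEFAULT_BANDS) -> str:
    """Qualitative label of the half-open band containing ``kappa``."""
    return scheme.label(kappa)


@dataclass(frozen=True)
class KappaResult:
    confusion: pd.DataFrame
    n: int
    p_o: float
    p_e: float
    kappa: float
    se: float
    band: str


def cohens_kappa(
    confusion: pd.DataFrame,
    drop_unknown_pairs: bool = False,
    scheme: BandScheme = DEFAULT_BANDS,
) -> KappaResult:
    """Cohen's kappa with large-sample standard error from a square matrix.

    ``drop_unknown_pairs`` removes the Unknown row and column before
    computing marginals, i.e. restricts to pairs where both categorisations
    are known (the unknown-removal sensitivity analysis).
    """
    table = confusion.copy()
    if drop_unknown_pairs:
        unknown = EthnicCategory.UNKNOWN.value
        table = table.drop(index=unknown, columns=unknown, errors="ignore")
    matrix = table.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {matrix.shape}")
    if (matrix < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    n = float(matrix.sum())
    if n < 2:
        raise ValueError(f"kappa needs at least 2 paired observations, got {int(n)}")
    p_o = float(np.trace(matrix)) / n
    row = matrix.sum(axis=1) / n
    col = matrix.sum(axis=0) / n
    p_e = float(row @ col)
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        raise UndefinedKappaError(
            "both categorisations are constant (p_e = 1); kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    return KappaResult(
        confusion=table,
        n=int(n),
        p_o=p_o,
        p_e=p_e,
        kappa=kappa,
        se=se,
        band=scheme.label(kappa),
    )


def compare_to_reference(
    dist: DistributionTable,
    reference: CensusDistribution = ENGLAND_CENSUS_2021,
) -> pd.DataFrame:
    """Observed minus reference percentage, per known category.

    ``dist`` must exclude Unknown (renormalised over known categories), as
    census references only cover stated ethnic groups.
    """
    if dist.include_unknown or EthnicCategory.UNKNOWN in dist.counts:
        raise ValueError(
            "representativeness comparison requires a distribution with "
            "Unknown excluded (include_unknown=False)"
        )
    rows = []
    for category in KNOWN_CATEGORIES:
        observed = dist.percentages.get(category, 0.0)
        expected = reference.proportions[category]
        rows.append(
            {
                "category": category.value,
                "observed_pct": observed,
                "reference_pct": expected,
                "difference_pp": round_half_up(observed - expected, 2),
            }
        )
    frame = pd.DataFrame(rows)
    order = [c.value for c in CANONICAL_ORDER if c is not EthnicCategory.UNKNOWN]
    return frame.set_index("category").loc[order].reset_index()


def _format_pct(x: float) -> str:
    return f"{x:.2f}"


def run_comparison_suite(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    configs: Sequence[AlgorithmConfig],
    source_sets: Sequence[Union[SourceSet, str]],
    out_dir: Union[str, Path],
    reference: CensusDistribution = ENGLAND_CENSUS_2021,
    include_currently_registered: bool = True,
    band_scheme: BandScheme = DEFAULT_BANDS,
) -> dict:
    """Full comparison report for a cohort.

    For every (config, source set): a distribution table.  Kappa pairs
    follow the reporting layout of the underlying evaluation: the first
    config is the base compared against every other config on the first
    source set, and the first source set is the base compared against every
    other source set under the first config — each with and without
    unknown pairs, for the full population and (optionally) the
    currently-registered restriction.  Writes one CSV per distribution,
    ``kappa_pairs.csv``, ``representativeness.csv`` and a plain-text
    summary; returns the results as a dict.  Deterministic: identical
    inputs yield byte-identical files.
    """
    from .ehr_ingest import filter_population

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    source_sets = [
        SourceSet.preset(s) if isinstance(s, str) else s for s in source_sets
    ]
    populations = [("all", meta)]
    if include_currently_registered:
        populations.append(
            ("currently_registered", filter_population(meta, currently_registered_only=True))
        )

    def config_label(config: AlgorithmConfig, position: int) -> str:
        return config.preset_name or f"config{position + 1}"

    def set_label(source_set: SourceSet, position: int) -> str:
        return source_set.preset_name or f"sourceset{position + 1}"

    derived: dict = {}
    results: dict = {"distributions": {}, "kappa_pairs": [], "representativeness": {}}
    summary_lines = []
    for pop_name, pop_meta in populations:
        for ci, config in enumerate(configs):
            for si, source_set in enumerate(source_sets):
                key = (pop_name, config_label(config, ci), set_label(source_set, si))
                table = derive_cohort(records, pop_meta, config, source_set)
                derived[key] = table
                dist = distribution(table, include_unknown=True, population_label=pop_name)
                results["distributions"][key] = dist
                if pop_name == "all":
                    dist.to_frame().to_csv(
                        out_dir / f"distribution_{key[1]}_{key[2]}.csv", index=False
                    )

    for pop_name, _ in populations:
        base_cfg = config_label(configs[0], 0)
        base_set = set_label(source_sets[0], 0)
        pairs = [
            (base_cfg, base_set, config_label(c, i), base_set)
            for i, c in enumerate(configs)
            if i > 0
        ] + [
            (base_cfg, base_set, base_cfg, set_label(s, i))
            for i, s in enumerate(source_sets)
            if i > 0
        ]
        for cfg_a, set_a, cfg_b, set_b in pairs:
            a = derived[(pop_name, cfg_a, set_a)]
            b = derived[(pop_name, cfg_b, set_b)]
            table = crosstab(a, b)
            for drop_unknown in (False, True):
                try:
                    res = cohens_kappa(table, drop_unknown, band_scheme)
                except UndefinedKappaError:
                    continue
                results["kappa_pairs"].append(
                    {
                        "population": pop_name,
                        "base": f"{cfg_a}/{set_a}",
                        "comparator": f"{cfg_b}/{set_b}",
                        "drop_unknown_pairs": drop_unknown,
                        "n": res.n,
                        "kappa": res.kappa,
                        "se": res.se,
                        "band": res.band,
                    }
                )
                summary_lines.append(
                    f"[{pop_name}] {cfg_a}/{set_a} vs {cfg_b}/{set_b}"
                    f"{' (known only)' if drop_unknown else ''}: "
                    f"kappa={res.kappa:.4f} SE={res.se:.4f} ({res.band}, n={res.n})"
                )

    kappa_frame = pd.DataFrame(results["kappa_pairs"])
    if not kappa_frame.empty:
        kappa_frame = kappa_frame.assign(
            kappa=kappa_frame["kappa"].map(lambda x: f"{x:.6f}"),
            se=kappa_frame["se"].map(lambda x: f"{x:.6f}"),
        )
    kappa_frame.to_csv(out_dir / "kappa_pairs.csv", index=False)

    repr_rows = []
    for ci, config in enumerate(configs):
        key = ("all", config_label(config, ci), set_label(source_sets[0], 0))
        dist_known = distribution(derived[key], include_unknown=False)
        diff = compare_to_reference(dist_known, reference)
        results["representativeness"][key[1]] = diff
        for row in diff.itertuples(index=False):
            repr_rows.append(
                {
                    "config": key[1],
                    "category": row.category,
                    "observed_pct": _format_pct(row.observed_pct),
                    "reference_pct": _format_pct(row.reference_pct),
                    "difference_pp": _format_pct(row.difference_pp),
                }
            )
    pd.DataFrame(repr_rows).to_csv(out_dir / "representativeness.csv", index=False)

    (out_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return results
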