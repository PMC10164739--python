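"""Activity-data curation: confidence filters and potency aggregation.

Raw activity records (one Ki measurement each) are filtered to direct binding
assays ("D") at the highest assay confidence level (score 9), grouped into
target-based activity classes, and consolidated to one pKi value per compound
per class. Multiple measurements for a compound are combined by the geometric
mean on the Ki scale — equivalently the arithmetic mean of the individual pKi
values — provided all measurements fall within the same order of magnitude;
otherwise the compound is disregarded for that class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import canonical_smiles

log = logging.getLogger(__name__)

#: Sentinel returned by :func:`aggregate_potency` for inconsistent measurements.
REJECTED = object()

#: Measurements spanning more than one order of magnitude are inconsistent.
MAX_KI_RATIO = 10.0


@dataclass(frozen=True)
class ActivityRecord:
    """A single raw activity measurement for one compound against one target."""

    smiles: str
    class_id: str
    relationship_type: str
    confidence_score: int
    ki_molar: float


@dataclass(frozen=True)
class Compound:
    """A curated molecule with one consolidated pKi within an activity class."""

    smiles: str  # canonical
    class_id: str
    pki: float

    def __post_init__(self):
        if not math.isfinite(self.pki):
            raise ValueError(f"pKi must be finite, got {self.pki!r}")


def filter_records(records: list[ActivityRecord]) -> list[ActivityRecord]:
    """Keep records with relationship type "D", confidence score 9 and a
    positive numeric Ki; unparsable SMILES are dropped with a warning.

    Order is preserved and the function is idempotent.
    """
    kept: list[ActivityRecord] = []
    for rec in records:
        if rec.relationship_type != "D" or rec.confidence_score != 9:
            continue
        try:
            ki = float(rec.ki_molar)
        except (TypeError, ValueError):
            continue
        if not math.isfinite(ki) or ki <= 0:
            continue
        if canonical_smiles(rec.smiles) is None:
            log.warning("dropping record with unparsable SMILES: %r", rec.smiles)
            continue
        kept.append(rec)
    return kept


def aggregate_potency(measurements: list[float]):
    """Consolidate Ki measurements (molar) for one compound–class combination.

    Returns −log10(geometric mean Ki) when max(Ki)/min(Ki) ≤ 10 (a ratio of
    exactly 10 is accepted), else the module-level ``REJECTED`` sentinel.
    The geometric mean on the Ki scale equals the arithmetic mean of pKi.
    """
    if not measurements:
        raise ValueError("no measurements to aggregate")
    for ki in measurements:
        if not (isinstance(ki, (int, float)) and math.isfinite(ki) and ki > 0):
            raise ValueError(f"Ki values must be positive and finite, got {ki!r}")
    if max(measurements) / min(measurements) > MAX_KI_RATIO:
        return REJECTED
    pkis = [-math.log10(ki) for ki in measurements]
    return sum(pkis) / len(pkis)


def build_activity_classes(
    records: list[ActivityRecord],
) -> dict[str, list[Compound]]:
    """Group filtered records into activity classes with one Compound per
    (canonical SMILES, class). Duplicate rows are pooled into one measurement
    list before aggregation; compounds failing aggregation are omitted.
    """
    pools: dict[tuple[str, str], list[float]] = {}
    class_order: dict[str, None] = {}
    for rec in records:
        smi = canonical_smiles(rec.smiles)
        if smi is None:
            log.warning("dropping record with unparsable SMILES: %r", rec.smiles)
            continue
        pools.setdefault((rec.class_id, smi), []).append(float(rec.ki_molar))
        class_order.setdefault(rec.class_id)
    classes: dict[str, list[Compound]] = {cid: [] for cid in class_order}
    n_rejected = 0
    for (class_id, smi), kis in pools.items():
        pki = aggregate_potency(kis)
        if pki is REJECTED:
            n_rejected += 1
            continue
        classes[class_id].append(Compound(smiles=smi, class_id=class_id, pki=pki))
    if n_rejected:
        log.info("disregarded %d compounds with inconsistent measurements", n_rejected)
    return classes


# ---------------------------------------------------------------------------
# delimited-text interfaces

DEFAULT_COLUMNS = {
    "smiles": "smiles",
    "class_id": "class_id",
    "relationship_type": "relationship_type",
    "confidence_score": "confidence_score",
    "ki_molar": "ki_molar",
}


def read_activity_records(
    path: str | Path, columns: dict[str, str] | None = None, sep: str = ","
) -> list[ActivityRecord]:
    """Read raw activity records from delimited text (CSV/TSV).

    ``columns`` maps the five canonical field names to the file's column names.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"input {path} lacks columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        records.append(
            ActivityRecord(
                smiles=str(row[cols["smiles"]]),
                class_id=str(row[cols["class_id"]]),
                relationship_type=str(row[cols["relationship_type"]]),
                confidence_score=int(row[cols["confidence_score"]]),
                ki_molar=float(row[cols["ki_molar"]]),
            )
        )
    return records


def write_compound_tables(
    classes: dict[str, list[Compound]], path: str | Path
) -> None:
    """Write the curated per-class compound table as CSV."""
    rows = [
        {"class_id": c.class_id, "smiles": c.smiles, "pki": c.pki}
        for compounds in classes.values()
        for c in compounds
    ]
    pd.DataFrame(rows, columns=["class_id", "smiles", "pki"]).to_csv(path, index=False)


def read_compound_tables(path: str | Path) -> dict[str, list[Compound]]:
    """Read a curated compound table written by :func:`write_compound_tables`."""
    df = pd.read_csv(path)
    classes: dict[str, list[Compound]] = {}
    for row in df.itertuples(index=False):
        classes.setdefault(str(row.class_id), []).append(
            Compound(smiles=str(row.smiles), class_id=str(row.class_id), pki=float(row.pki))
        )
    return classes
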