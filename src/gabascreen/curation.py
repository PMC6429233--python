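"""Activity curation: active/inactive labelling, pIC50 conversion, deduplication.

Actives are defined by strict potency thresholds per assay type
(IC50 < 4100 nM, Ki < 1500 nM, EC50 < 25 uM by default) or by a
pre-labelled fold-change flag. Ki values convert to IC50 assuming
IC50 = 2 * Ki; EC50 values are not convertible to pIC50 unless
explicitly overridden. Duplicate structures are removed
stereochemistry-aware, so enantiomers remain distinct entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .chemio import Compound
from .errors import ClassificationError, ConversionError

Measure = Literal["IC50", "Ki", "EC50"]

#: Default activity thresholds, all in nM (strict '<' inequalities).
DEFAULT_THRESHOLDS_NM: dict[str, float] = {
    "IC50": 4100.0,
    "Ki": 1500.0,
    "EC50": 25_000.0,
}

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental potency measure for a compound."""

    compound_id: str
    measure: Measure
    value: float  # in `unit`
    unit: str = "nM"
    source_note: str = ""
    fold_change_active: bool = False

    def __post_init__(self):
        if self.value <= 0:
            raise ClassificationError(
                f"activity value must be > 0 (got {self.value} for {self.compound_id!r})"
            )
        if self.unit not in _UNIT_TO_NM:
            raise ClassificationError(f"unknown concentration unit {self.unit!r}")

    @property
    def value_nm(self) -> float:
        """The measured value in nM regardless of the stored unit."""
        return self.value * _UNIT_TO_NM[self.unit]


def classify_activity(
    r: ActivityRecord, thresholds: Mapping[str, float] | None = None
) -> Literal["active", "inactive"]:
    """Label a record active iff its strict threshold inequality holds.

    ``thresholds`` maps measure name to the nM cut-off; boundary values are
    inactive (strict '<'). A true ``fold_change_active`` flag marks the
    record active regardless of the numeric value.
    """
    thr = dict(DEFAULT_THRESHOLDS_NM if thresholds is None else thresholds)
    if r.fold_change_active:
        return "active"
    if r.measure not in thr:
        raise ClassificationError(f"unknown measure {r.measure!r}")
    if thr[r.measure] <= 0:
        raise ClassificationError("thresholds must be positive")
    return "active" if r.value_nm < thr[r.measure] else "inactive"


def to_pic50(r: ActivityRecord, ec50_as_ic50: bool = False) -> float:
    """Convert a record to pIC50 = -log10(IC50 in mol/L).

    Ki records are first converted assuming IC50 = 2 * Ki. EC50 records are
    not convertible: functional potency and inhibitory potency are not
    interchangeable, so an EC50 raises :class:`ConversionError` unless
    ``ec50_as_ic50`` explicitly requests that the value be treated as an
    IC50 anyway.
    """
    if r.measure == "IC50":
        ic50_nm = r.value_nm
    elif r.measure == "Ki":
        ic50_nm = 2.0 * r.value_nm
    elif r.measure == "EC50":
        if not ec50_as_ic50:
            raise ConversionError(
                f"EC50 record for {r.compound_id!r} is not convertible to pIC50 "
                "(set ec50_as_ic50=True to override)"
            )
        ic50_nm = r.value_nm
    else:  # pragma: no cover
        raise ConversionError(f"unknown measure {r.measure!r}")
    return -math.log10(ic50_nm * 1e-9)


def deduplicate(compounds: Sequence[Compound]) -> list[Compound]:
    """Drop duplicate structures, keeping the first occurrence of each.

    Identity is the canonical isomeric SMILES, so enantiomers (and other
    stereoisomers) are distinct and are kept.
    """
    seen: set[str] = set()
    out: list[Compound] = []
    for c in compounds:
        key = c.smiles
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


@dataclass
class CuratedSet:
    """Curation result: disjoint active/inactive compound lists with provenance."""

    actives: list[Compound]
    inactives: list[Compound]
    provenance: dict[str, str] = field(default_factory=dict)
    rejected: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        overlap = {c.id for c in self.actives} & {c.id for c in self.inactives}
        if overlap:
            raise ClassificationError(f"compounds in both classes: {sorted(overlap)}")


def curate(
    compounds: Sequence[Compound],
    records: Iterable[ActivityRecord],
    thresholds: Mapping[str, float] | None = None,
) -> CuratedSet:
    """Deduplicate and label a library from its activity records.

    A compound with several records is active if ANY record passes its
    threshold (permissive OR across assay types). Compounds with no record
    are rejected with a reason rather than silently classified.
    """
    by_cid: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_cid.setdefault(r.compound_id, []).append(r)
    unique = deduplicate(compounds)
    actives, inactives = [], []
    provenance: dict[str, str] = {}
    rejected: dict[str, str] = {}
    for c in unique:
        recs = by_cid.get(c.id)
        if not recs:
            rejected[c.id] = "no activity record"
            continue
        hits = [r for r in recs if classify_activity(r, thresholds) == "active"]
        if hits:
            r = hits[0]
            rule = (
                "fold-change flag"
                if r.fold_change_active
                else f"{r.measure} {r.value} {r.unit} < threshold"
            )
            actives.append(c)
            provenance[c.id] = rule
        else:
            inactives.append(c)
            provenance[c.id] = "no record below threshold"
    return CuratedSet(actives=actives, inactives=inactives, provenance=provenance, rejected=rejected)


def best_pic50(records: Sequence[ActivityRecord], ec50_as_ic50: bool = False) -> float:
    """The pIC50 to use when a compound has several records.

    IC50 records are preferred over Ki (avoiding the x2 assumption when
    unnecessary); within a measure the most potent (lowest) value wins.
    """
    ic50s = [r for r in records if r.measure == "IC50"]
    kis = [r for r in records if r.measure == "Ki"]
    pool = ic50s or kis or list(records)
    if not pool:
        raise ConversionError("no records")
    best = min(pool, key=lambda r: r.value_nm)
    return to_pic50(best, ec50_as_ic50=ec50_as_ic50)


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read the activity table (compound_id, measure, value, unit[, role, fold_change_active])."""
    df = pd.read_csv(path)
    required = {"compound_id", "measure", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ClassificationError(f"activity CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                measure=str(row.measure),  # type: ignore[arg-type]
                value=float(row.value),
                unit=str(row.unit),
                fold_change_active=bool(getattr(row, "fold_change_active", False)),
            )
        )
    return records
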