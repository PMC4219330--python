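"""Training-corpus curation: class assignment, filtering rules and balancing.

Four location classes are modelled: nuclear (N), nucleocytoplasmic (Y,
annotated in both nucleus and cytoplasm), cytoplasmic (C) and extracellular
(E). Proteins annotated in any other compartment are excluded so that each
class is location-exclusive.

The selection filters mirror a curated sequence/structure corpus: reviewed
records only, experimentally verified location (no "by similarity",
"probable" or "potential" qualifiers), length >= 150 residues (shorter
chains give unstable range-restricted composition estimates), glycosylated
extracellular proteins removed (glycans change surface properties), and at
least one structure segment so residue exposure is observable.

One-vs-rest training requires a negative set the same size as the positive
class, drawn as evenly as possible from the other three classes; a class
too small to meet its quota contributes all its members and the deficit is
split over the remaining classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exposure import ExposlocError

__all__ = [
    "CLASS_ORDER",
    "LOCATION_LABELS",
    "AnnotationRecord",
    "BalancedTrainingSet",
    "InsufficientDataError",
    "assign_location_class",
    "filter_annotations",
    "select_longest_structure",
    "balance_dataset",
    "negative_quota",
    "load_reference_class_counts",
    "read_annotation_table",
]

#: Fixed class order used for score vectors, tie-breaking and serialization.
CLASS_ORDER = ("N", "Y", "C", "E")

#: Annotation labels recognised as the three base locations.
LOCATION_LABELS = {"nuclear": "N", "cytoplasmic": "C", "extracellular": "E"}

#: Evidence qualifiers marking a location annotation as not experimentally
#: verified.
UNVERIFIED_QUALIFIERS = ("by similarity", "probable", "potential")

MIN_LENGTH = 150


class InsufficientDataError(ExposlocError):
    """Not enough negatives (or class members) to build the requested set."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One curated annotation row (stands in for a sequence-database record)."""

    protein_id: str
    length: int
    locations: frozenset
    evidence: frozenset = frozenset()
    reviewed: bool = True
    glycosylated: bool = False
    structures: tuple = ()  # (structure_id, covered-residue count) pairs

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")
        for sid, count in self.structures:
            if count > self.length:
                raise ValueError(
                    f"{self.protein_id}: structure {sid} covers {count} residues "
                    f"but the sequence has only {self.length}")


def assign_location_class(record: AnnotationRecord) -> Optional[str]:
    """Map a record's location labels to N/Y/C/E, or ``None`` if rejected.

    N, C or E require that single location exclusively; Y requires exactly
    {nuclear, cytoplasmic}. Any unrecognised label, or an empty label set,
    rejects the record (location-exclusivity rule).
    """
    labels = {str(l).strip().lower() for l in record.locations}
    if not labels or not labels.issubset(LOCATION_LABELS):
        return None
    if labels == {"nuclear", "cytoplasmic"}:
        return "Y"
    if len(labels) == 1:
        return LOCATION_LABELS[next(iter(labels))]
    return None


def filter_annotations(
    records: Sequence[AnnotationRecord],
    *,
    min_length: int = MIN_LENGTH,
    qualifiers: Sequence[str] = UNVERIFIED_QUALIFIERS,
    require_structure: bool = True,
) -> Tuple[list, list]:
    """Apply the curation rules; return (kept records, rejection log).

    The log lists ``(protein_id, rule)`` for every removal, where rule is
    the first failing filter among: ``unreviewed``, ``unverified-evidence``,
    ``location-class``, ``min-length``, ``glycosylated-extracellular``,
    ``no-structure``. Idempotent: running the survivors through again
    removes nothing.
    """
    kept, log = [], []
    qualifiers = tuple(q.lower() for q in qualifiers)
    for rec in records:
        if not rec.reviewed:
            log.append((rec.protein_id, "unreviewed"))
            continue
        evidence = {str(e).strip().lower() for e in rec.evidence}
        if evidence.intersection(qualifiers):
            log.append((rec.protein_id, "unverified-evidence"))
            continue
        cls = assign_location_class(rec)
        if cls is None:
            log.append((rec.protein_id, "location-class"))
            continue
        if rec.length < min_length:
            log.append((rec.protein_id, "min-length"))
            continue
        if cls == "E" and rec.glycosylated:
            log.append((rec.protein_id, "glycosylated-extracellular"))
            continue
        if require_structure and not rec.structures:
            log.append((rec.protein_id, "no-structure"))
            continue
        kept.append(rec)
    return kept, log


def select_longest_structure(record: AnnotationRecord) -> str:
    """Structure id covering the most residues; ties by lexicographic id."""
    if not record.structures:
        raise InsufficientDataError(f"{record.protein_id}: no structure segments")
    return min(record.structures, key=lambda sc: (-sc[1], sc[0]))[0]


def negative_quota(n_positive: int, available: Mapping[str, int]) -> dict:
    """Per-class negative draw counts summing exactly to ``n_positive``.

    ``available`` maps the three negative classes (in fixed class order) to
    their sizes. Quotas are as equal as possible (remainders distributed
    one-by-one in class order); a class smaller than its quota contributes
    everything and the deficit is re-split over the remaining classes.
    """
    total = sum(available.values())
    if total < n_positive:
        raise InsufficientDataError(
            f"need {n_positive} negatives but only {total} are available")
    alloc = {c: 0 for c in available}
    active = [c for c in available]
    remaining = n_positive
    while remaining > 0:
        base, rem = divmod(remaining, len(active))
        quota = {c: base + (1 if i < rem else 0) for i, c in enumerate(active)}
        deficits = [c for c in active if available[c] < quota[c]]
        if not deficits:
            for c in active:
                alloc[c] += quota[c]
            break
        for c in deficits:
            alloc[c] = available[c]
            remaining -= available[c]
            active.remove(c)
    return alloc


@dataclass
class BalancedTrainingSet:
    """Equal-sized positive and negative example sets for one binary task."""

    positive_class: str
    positives: list
    negatives: list  # (example, origin class) pairs
    seed: int
    per_class_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.negatives) != len(self.positives):
            raise ValueError("negative set must equal positive set in size")


def balance_dataset(
    class_members: Mapping[str, Sequence],
    positive: str,
    seed: int = 0,
) -> BalancedTrainingSet:
    """Draw a seeded, class-balanced negative set for one-vs-rest training.

    ``class_members`` maps each class to its example list (ids or indices).
    Negatives are sampled without replacement from the other classes under
    :func:`negative_quota`; the draw is reproducible for a given
    (members, positive, seed).
    """
    if positive not in class_members:
        raise KeyError(f"positive class {positive!r} not in class_members")
    positives = list(class_members[positive])
    others = {c: list(class_members.get(c, ()))
              for c in CLASS_ORDER if c != positive and c in class_members}
    quota = negative_quota(len(positives), {c: len(m) for c, m in others.items()})
    rng = np.random.default_rng(seed)
    negatives = []
    for cls in others:
        members = others[cls]
        take = quota[cls]
        idx = rng.choice(len(members), size=take, replace=False) if take else []
        negatives.extend((members[i], cls) for i in sorted(idx))
    return BalancedTrainingSet(positive, positives, negatives, seed, quota)


def load_reference_class_counts() -> dict:
    """Packaged per-class sizes of the reference structure-resolved corpus."""
    ref = resources.files("exposloc.data") / "class_counts.json"
    return dict(json.loads(ref.read_text())["counts"])


def read_annotation_table(path) -> list:
    """Read an annotation TSV into :class:`AnnotationRecord` objects.

    Columns: ``protein_id  length  locations  evidence  reviewed
    glycosylated  structures`` — multi-valued fields comma-separated,
    structures as ``id:count`` pairs, booleans as 0/1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        structures = tuple(
            (part.split(":")[0], int(part.split(":")[1]))
            for part in str(row.get("structures", "")).split(",") if ":" in part
        )
        records.append(AnnotationRecord(
            protein_id=row["protein_id"],
            length=int(row["length"]),
            locations=frozenset(s for s in str(row["locations"]).split(",") if s),
            evidence=frozenset(s for s in str(row.get("evidence", "")).split(",") if s),
            reviewed=str(row.get("reviewed", "1")) in ("1", "true", "True"),
            glycosylated=str(row.get("glycosylated", "0")) in ("1", "true", "True"),
            structures=structures,
        ))
    return records
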