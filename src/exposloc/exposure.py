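"""Per-residue solvent exposure: relative accessibility, range binning and parsers.

A residue's *relative solvent accessibility* (RSA) is its absolute
solvent-accessible surface area (the DSSP ``ACC`` column, in squared
angstroms) divided by the maximum attainable area for that amino-acid type.
RSA is unitless in [0, 1]: 0 means fully buried, 1 fully exposed.

RSA values are discretised into six *exposure ranges* (1 = most buried,
6 = most exposed) whose default boundaries were chosen so that each range
holds a near-equal share of residues in a large structure-derived corpus::

    range 1  [0.00, 0.01)      range 4  [0.21, 0.37)
    range 2  [0.01, 0.08)      range 5  [0.37, 0.57)
    range 3  [0.08, 0.21)      range 6  [0.57, 1.00]

For sequences without a solved structure, per-residue exposure predicted on
the SABLE integer scale (0 = buried .. 9 = exposed) is mapped onto the same
six ranges: scores 0-4 map to ranges 1-5 and the sparsely populated scores
5-9 collapse into range 6.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Optional, Sequence, Union

__all__ = [
    "AMINO_ACIDS",
    "AA_INDEX",
    "DEFAULT_RANGE_BOUNDARIES",
    "DEFAULT_SABLE_MAP",
    "RangeBoundaries",
    "SableMap",
    "ResidueRecord",
    "ExposureProfile",
    "ExposlocError",
    "ParseError",
    "ProfileConsistencyError",
    "DegeneratePartitionError",
    "load_max_accessibility",
    "relative_accessibility",
    "assign_range",
    "derive_ranges",
    "map_sable_to_range",
    "parse_dssp",
    "parse_sable",
    "read_sable_file",
    "read_fasta",
    "build_profile",
]

#: The 20 canonical one-letter codes in fixed alphabetical order. This order
#: indexes every composition vector and is recorded in model manifests.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ExposlocError(Exception):
    """Base class for errors raised by this package."""


class ParseError(ExposlocError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ProfileConsistencyError(ExposlocError):
    """Residue records disagree with the protein sequence."""


class DegeneratePartitionError(ExposlocError):
    """Too few distinct values to cut the requested number of ranges."""


# ---------------------------------------------------------------------------
# Maximum accessibility table
# ---------------------------------------------------------------------------

def load_max_accessibility(path: Union[str, Path, None] = None) -> dict:
    """Load a per-amino-acid maximum accessibility table (A^2).

    With no argument the packaged Rose et al. (1985) mean maximum ASA table
    is returned. A custom table may be supplied as a JSON file with either a
    top-level ``values`` mapping or a bare ``{code: max_asa}`` mapping; all
    20 canonical codes must be present with positive values.
    """
    if path is None:
        ref = resources.files("exposloc.data") / "max_accessibility_rose1985.json"
        raw = json.loads(ref.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    values = raw.get("values", raw) if isinstance(raw, dict) else raw
    table = {str(k): float(v) for k, v in values.items()}
    missing = [aa for aa in AMINO_ACIDS if aa not in table]
    if missing:
        raise ValueError(f"max-accessibility table missing codes: {missing}")
    bad = [aa for aa in AMINO_ACIDS if table[aa] <= 0]
    if bad:
        raise ValueError(f"max-accessibility values must be positive: {bad}")
    return {aa: table[aa] for aa in AMINO_ACIDS}


_DEFAULT_MAX_ACC: Optional[dict] = None


def _default_max_acc() -> dict:
    global _DEFAULT_MAX_ACC
    if _DEFAULT_MAX_ACC is None:
        _DEFAULT_MAX_ACC = load_max_accessibility()
    return _DEFAULT_MAX_ACC


def relative_accessibility(acc: float, aa: str, table: Optional[dict] = None) -> Optional[float]:
    """Absolute accessibility (A^2) -> RSA in [0, 1].

    Values above the tabulated maximum (terminal or distorted residues) are
    clamped to 1.0 so the most-exposed range keeps a meaningful upper bound.
    Returns ``None`` for a non-canonical residue code — the caller's signal
    to skip the residue rather than fail.
    """
    if acc < 0:
        raise ValueError(f"negative accessibility {acc!r}")
    if table is None:
        table = _default_max_acc()
    aa = aa.upper()
    if aa not in table:
        return None
    return min(acc / table[aa], 1.0)


# ---------------------------------------------------------------------------
# Exposure ranges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeBoundaries:
    """Contiguous partition of [0, 1] into exposure ranges.

    ``cuts`` holds k+1 ascending cut points starting at 0 and ending at 1.
    Interval *i* (1-based) is [cuts[i-1], cuts[i]), left-closed/right-open;
    the last interval is closed so RSA = 1 belongs to range k.
    """

    cuts: tuple = (0.0, 0.01, 0.08, 0.21, 0.37, 0.57, 1.0)

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        object.__setattr__(self, "cuts", cuts)
        if len(cuts) < 2 or cuts[0] != 0.0 or cuts[-1] != 1.0:
            raise ValueError("cuts must start at 0 and end at 1")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cuts must be strictly increasing")

    @property
    def n_ranges(self) -> int:
        return len(self.cuts) - 1

    def interval(self, index: int) -> tuple:
        """(low, high) of 1-based range ``index``."""
        if not 1 <= index <= self.n_ranges:
            raise ValueError(f"range index {index} out of 1..{self.n_ranges}")
        return self.cuts[index - 1], self.cuts[index]


DEFAULT_RANGE_BOUNDARIES = RangeBoundaries()


def assign_range(rsa: float, bounds: RangeBoundaries = DEFAULT_RANGE_BOUNDARIES) -> int:
    """Return the 1-based exposure range containing ``rsa``."""
    if not 0.0 <= rsa <= 1.0:
        raise ValueError(f"rsa {rsa!r} outside [0, 1]")
    if rsa == 1.0:
        return bounds.n_ranges
    return bisect_right(bounds.cuts, rsa, 1, len(bounds.cuts) - 1)


def derive_ranges(rsa_values: Sequence[float], k: int = 6) -> RangeBoundaries:
    """Derive k equal-count (percentile) range boundaries from a value sample.

    Cut points are placed at the i*n/k order statistics, so with distinct
    values the per-range counts differ by at most one. The default pipeline
    uses the packaged boundaries; this exists to recalibrate them on a new
    structure corpus.
    """
    values = sorted(float(v) for v in rsa_values)
    if not values:
        raise ValueError("rsa_values is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    if any(v < 0 or v > 1 for v in (values[0], values[-1])):
        raise ValueError("rsa values must lie in [0, 1]")
    if k == 1:
        return RangeBoundaries((0.0, 1.0))
    n = len(values)
    if len(set(values)) < k:
        raise DegeneratePartitionError(
            f"cannot cut {k} ranges from {len(set(values))} distinct values"
        )
    inner = [values[(i * n) // k] for i in range(1, k)]
    cuts = (0.0, *inner, 1.0)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise DegeneratePartitionError(
            f"tied order statistics prevent a {k}-range partition"
        )
    return RangeBoundaries(cuts)


@dataclass(frozen=True)
class SableMap:
    """Total, monotone, surjective map from SABLE scores 0-9 to ranges 1..k."""

    targets: tuple = (1, 2, 3, 4, 5, 6, 6, 6, 6, 6)

    def __post_init__(self):
        targets = tuple(int(t) for t in self.targets)
        object.__setattr__(self, "targets", targets)
        if len(targets) != 10:
            raise ValueError("SableMap must map all 10 scores 0..9")
        if any(b < a for a, b in zip(targets, targets[1:])):
            raise ValueError("SableMap must be monotone non-decreasing")
        k = max(targets)
        if targets[0] != 1 or set(targets) != set(range(1, k + 1)):
            raise ValueError("SableMap must be surjective onto 1..k")

    @property
    def n_ranges(self) -> int:
        return max(self.targets)

    def inverse(self, range_index: int) -> tuple:
        """All scores mapping to ``range_index`` (used by the mock writer)."""
        scores = tuple(s for s, t in enumerate(self.targets) if t == range_index)
        if not scores:
            raise ValueError(f"no score maps to range {range_index}")
        return scores


DEFAULT_SABLE_MAP = SableMap()


def map_sable_to_range(score: int, sable_map: SableMap = DEFAULT_SABLE_MAP) -> int:
    """Map a predicted exposure score (0-9) to its exposure range."""
    if not 0 <= score <= 9:
        raise ValueError(f"SABLE score {score!r} outside 0..9")
    return sable_map.targets[score]


# ---------------------------------------------------------------------------
# Residues and profiles
# ---------------------------------------------------------------------------

class ResidueRecord(NamedTuple):
    """One covered residue of a protein.

    ``acc`` (absolute accessibility, A^2) and ``rsa`` are present for
    structure-derived records; predicted records carry only the mapped
    exposure range. ``position`` is 1-based into the protein sequence.
    """

    position: int
    aa: str
    acc: Optional[float]
    rsa: Optional[float]
    range_index: int
    source: str


@dataclass
class ExposureProfile:
    """A protein sequence with per-residue exposure for its covered residues.

    ``residues`` lists only residues with exposure information and a
    canonical amino-acid code; the full sequence (which may contain X/B/Z/U
    or gaps) is kept for length-based filters.
    """

    protein_id: str
    sequence: str
    residues: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        n = len(self.sequence)
        for rec in self.residues:
            if not 1 <= rec.position <= n:
                raise ProfileConsistencyError(
                    f"{self.protein_id}: residue position {rec.position} outside "
                    f"sequence of length {n}"
                )
            if rec.position in seen:
                raise ProfileConsistencyError(
                    f"{self.protein_id}: duplicate residue position {rec.position}"
                )
            seen.add(rec.position)
            if self.sequence[rec.position - 1].upper() != rec.aa:
                raise ProfileConsistencyError(
                    f"{self.protein_id}: residue {rec.aa} at position {rec.position} "
                    f"does not match sequence letter "
                    f"{self.sequence[rec.position - 1]!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_covered(self) -> int:
        return len(self.residues)

    @property
    def source(self) -> Optional[str]:
        return self.residues[0].source if self.residues else None


def build_profile(
    protein_id: str,
    sequence: str,
    records: Iterable[tuple],
    *,
    source: str = "structure",
    bounds: RangeBoundaries = DEFAULT_RANGE_BOUNDARIES,
    sable_map: SableMap = DEFAULT_SABLE_MAP,
    max_acc: Optional[dict] = None,
) -> ExposureProfile:
    """Assemble an :class:`ExposureProfile` from parsed residue records.

    ``records`` are ``(position, aa, acc)`` triples when ``source`` is
    ``"structure"`` (acc in A^2, converted to RSA then binned) or
    ``(position, aa, score)`` when ``source`` is ``"predicted"`` (SABLE
    score mapped directly to a range). Residues with non-canonical codes are
    silently excluded from the profile but remain part of the sequence.
    """
    if source not in ("structure", "predicted"):
        raise ValueError(f"unknown exposure source {source!r}")
    sequence = str(sequence).upper()
    residues = []
    for position, aa, value in records:
        aa = str(aa).upper()
        if aa not in AA_INDEX:
            continue
        if source == "structure":
            rsa = relative_accessibility(float(value), aa, table=max_acc)
            if rsa is None:
                continue
            rec = ResidueRecord(int(position), aa, float(value), rsa,
                                assign_range(rsa, bounds), source)
        else:
            rng = map_sable_to_range(int(value), sable_map)
            rec = ResidueRecord(int(position), aa, None, None, rng, source)
        residues.append(rec)
    return ExposureProfile(protein_id, sequence, residues)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def _as_lines(stream: Union[str, Path, IO, Iterable[str]]) -> list:
    if isinstance(stream, (str, Path)):
        return Path(stream).read_text().splitlines()
    if hasattr(stream, "read"):
        return stream.read().splitlines()
    return [line.rstrip("\n") for line in stream]


def parse_dssp(stream) -> list:
    """Parse per-residue accessibility into ``(position, aa, acc)`` triples.

    Accepts either genuine DSSP output (fixed columns; the residue code at
    column 14 and the ACC field at columns 35-38) or the simplified
    3-column TSV dialect ``position<TAB>aa<TAB>acc`` used for fixtures.
    Chain breaks ('!') and unresolved residues are absent from the output;
    lowercase codes (DSSP's half-cystine bridge labels) are reported as 'C'.
    """
    lines = _as_lines(stream)
    is_dssp = any(line.lstrip().startswith("#  RESIDUE") for line in lines)
    records = []
    if is_dssp:
        in_body = False
        for lineno, line in enumerate(lines, 1):
            if not in_body:
                in_body = line.lstrip().startswith("#  RESIDUE")
                continue
            if len(line) < 38 or line[13] == "!":
                continue
            aa = line[13]
            if aa.islower():
                aa = "C"
            try:
                position = int(line[5:10])
                acc = float(line[34:38])
            except ValueError as exc:
                raise ParseError(f"bad DSSP residue row: {exc}", lineno) from None
            records.append((position, aa, acc))
        return records
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"expected 3 tab-separated fields, got {len(parts)}", lineno)
        try:
            position, aa, acc = int(parts[0]), parts[1], float(parts[2])
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
        aa = "C" if aa.islower() else aa
        records.append((position, aa, acc))
    return records


def _parse_sable_block(name, seq_parts, score_parts, lineno) -> list:
    sequence = "".join(seq_parts)
    scores = "".join(score_parts)
    if not sequence or not scores:
        raise ParseError(f"record {name or '<anonymous>'}: missing sequence or scores",
                         lineno)
    if len(scores) != len(sequence):
        raise ParseError(
            f"record {name or '<anonymous>'}: {len(scores)} scores for "
            f"{len(sequence)} residues", lineno)
    return [(i + 1, aa, int(s)) for i, (aa, s) in enumerate(zip(sequence, scores))]


def _iter_sable_records(lines):
    name, seq_parts, score_parts = None, [], []
    started = False
    last_line = 0
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if started:
                yield name, _parse_sable_block(name, seq_parts, score_parts, last_line)
            name, seq_parts, score_parts = line[1:].split()[0] if line[1:].split() else "", [], []
            started = True
            continue
        started = True
        if all(ch in "0123456789" for ch in line):
            score_parts.append(line)
        elif line.isalpha():
            seq_parts.append(line)
        else:
            raise ParseError(f"line is neither sequence nor digit scores: {line!r}",
                             lineno)
        last_line = lineno
    if started:
        yield name, _parse_sable_block(name, seq_parts, score_parts, last_line)


def parse_sable(stream) -> list:
    """Parse one predicted-exposure record into ``(position, aa, score)`` triples.

    Format: an optional ``>id`` header, the sequence (alphabetic lines, may
    wrap) and the per-residue scores as digit-string lines of equal total
    length. Raises :class:`ParseError` when lengths disagree or a score line
    contains non-digits.
    """
    records = list(_iter_sable_records(_as_lines(stream)))
    if not records:
        return []
    if len(records) > 1:
        raise ParseError(
            f"stream holds {len(records)} records; use read_sable_file()")
    return records[0][1]


def read_sable_file(stream) -> dict:
    """Parse a multi-record predicted-exposure file into ``{id: triples}``."""
    out = {}
    for name, triples in _iter_sable_records(_as_lines(stream)):
        out[name] = triples
    return out


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    from Bio import SeqIO

    handle = path if hasattr(path, "read") else str(path)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
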