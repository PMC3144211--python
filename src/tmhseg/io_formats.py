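"""Text I/O for protein sequences, helix-interval annotations and predictions.

Coordinate convention
---------------------
Intervals are 1-based and inclusive on both ends throughout the library
(residue numbering as printed in structure databases).  BED-style input
(0-based, half-open) is converted at the read/write boundary and never
stored internally.

Non-standard residues
---------------------
FASTA files for membrane-protein benchmarks routinely contain ``X`` (and
occasionally ``B``, ``Z``, ``U``, ``J``, ``O`` or ``*``).  Two policies are
offered:

* ``"mask"`` (default): such positions are kept in the sequence as ``X``;
  they are excluded from composition counts and receive a compositional
  index of 0.
* ``"strict"``: any character outside the 20-letter alphabet is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
"""The 20 standard residues, in the conventional one-letter order."""

MASK_CHAR = "X"
_AMBIGUOUS = set("XBZJUO*")

Interval = Tuple[int, int]


class FormatError(ValueError):
    """An input file or in-memory object violates its format contract."""


def sanitize_sequence(sequence: str, policy: str = "mask") -> str:
    """Uppercase a raw sequence and apply the non-standard-residue policy.

    Under ``mask``, ambiguous codes are replaced by ``X``; under ``strict``
    they raise :class:`FormatError`.  Characters that are neither standard
    residues nor recognized ambiguity codes always raise.
    """
    if policy not in ("mask", "strict"):
        raise ValueError(f"unknown residue policy {policy!r}")
    out = []
    for ch in sequence.upper():
        if ch in AMINO_ACIDS:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            if policy == "strict":
                raise FormatError(f"non-standard residue {ch!r} under strict policy")
            out.append(MASK_CHAR)
        else:
            raise FormatError(f"invalid sequence character {ch!r}")
    return "".join(out)


def validate_intervals(intervals: Sequence[Interval], length: int) -> Tuple[Interval, ...]:
    """Sort intervals, then check 1 <= start <= end <= length and no overlap."""
    ordered = tuple(sorted((int(s), int(e)) for s, e in intervals))
    prev_end = 0
    for start, end in ordered:
        if start < 1 or end < start or end > length:
            raise FormatError(f"invalid interval ({start}, {end}) for length {length}")
        if start <= prev_end:
            raise FormatError(f"overlapping interval ({start}, {end})")
        prev_end = end
    return ordered


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with optional reference helix spans."""

    id: str
    sequence: str
    reference_segments: Optional[Tuple[Interval, ...]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("empty record id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = set(AMINO_ACIDS) | {MASK_CHAR}
        bad = set(self.sequence) - allowed
        if bad:
            raise FormatError(f"record {self.id!r}: unsanitized characters {sorted(bad)}")
        if self.reference_segments is not None:
            object.__setattr__(
                self,
                "reference_segments",
                validate_intervals(self.reference_segments, len(self.sequence)),
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_segments(self, segments: Sequence[Interval]) -> "ProteinRecord":
        return replace(self, reference_segments=tuple(segments))


@dataclass
class Dataset:
    """An ordered collection of :class:`ProteinRecord` with unique ids."""

    records: List[ProteinRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def ids(self) -> List[str]:
        return [rec.id for rec in self.records]


def read_fasta(path, policy: str = "mask", name: str = "") -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    The header token before the first whitespace becomes the record id.
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=entry.id, sequence=sanitize_sequence(str(entry.seq), policy)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Dataset(records=records, name=name or path.stem)


def write_fasta(dataset: Dataset, path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _from_bed(start: int, end: int) -> Interval:
    # BED is 0-based half-open; internal is 1-based inclusive.
    return start + 1, end


def _to_bed(interval: Interval) -> Tuple[int, int]:
    return interval[0] - 1, interval[1]


def read_intervals(path, bed: bool = False) -> Dict[str, List[Interval]]:
    """Read a 3-column interval file (``id<TAB>start<TAB>end``) into a dict.

    Lines with ``.`` in both coordinate columns register the id with an
    empty interval list; blank lines and ``#`` comments are skipped.
    No per-record validation is done here (lengths are unknown).
    """
    path = Path(path)
    out: Dict[str, List[Interval]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            rid, s, e = parts
            out.setdefault(rid, [])
            if s == "." and e == ".":
                continue
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if bed:
                start, end = _from_bed(start, end)
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            out[rid].append((start, end))
    return out


def read_annotations(path, dataset: Dataset, bed: bool = False) -> Dataset:
    """Attach reference helix intervals from a TSV/BED file to a dataset.

    Returns a new :class:`Dataset`; records not mentioned in the file keep
    their previous annotations.  Unknown ids and out-of-range intervals are
    errors.
    """
    raw = read_intervals(path, bed=bed)
    known = set(dataset.ids())
    for rid in raw:
        if rid not in known:
            raise FormatError(f"{path}: unknown record id {rid!r}")
    new_records = []
    for rec in dataset:
        if rec.id in raw:
            try:
                segments = validate_intervals(raw[rec.id], len(rec))
            except FormatError as exc:
                raise FormatError(f"{path}: record {rec.id!r}: {exc}") from None
            new_records.append(rec.with_segments(segments))
        else:
            new_records.append(rec)
    return Dataset(records=new_records, name=dataset.name)


def write_predictions(
    dataset: Dataset,
    predictions: Mapping[str, Sequence[Interval]],
    path,
    bed: bool = False,
) -> None:
    """Write per-record intervals as 3-column TSV in dataset order.

    A record with an empty interval list is written as a single
    ``id<TAB>.<TAB>.`` sentinel line so the id round-trips.
    """
    path = Path(path)
    lines = []
    for rec in dataset:
        intervals = validate_intervals(predictions.get(rec.id, ()), len(rec))
        if not intervals:
            lines.append(f"{rec.id}\t.\t.")
        for iv in intervals:
            s, e = _to_bed(iv) if bed else iv
            lines.append(f"{rec.id}\t{s}\t{e}")
    path.write_text("\n".join(lines) + "\n")
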