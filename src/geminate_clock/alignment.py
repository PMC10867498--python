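"""Aligned multi-FASTA ingestion, trimming and sample-to-group tables.

Alignments are read with Biopython and validated into a light immutable
container. Residues are uppercased on read, RNA ``U`` is mapped to ``T``
and the two common gap dialects ``-`` and ``.`` are normalized to ``-``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import AlignmentError, PartitionError

#: residues accepted after normalization: bases, gap, N and IUPAC ambiguity
VALID_RESIDUES = frozenset("ACGT-NRYSWKMBDHV")

_NORMALIZE = str.maketrans({"U": "T", ".": "-"})


def normalize_residues(residues: str) -> str:
    """Uppercase, map U->T and '.'->'-'; reject unknown characters."""
    out = residues.upper().translate(_NORMALIZE)
    bad = set(out) - VALID_RESIDUES
    if bad:
        raise AlignmentError(f"invalid residue characters: {sorted(bad)!r}")
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its sample identifier."""

    sample_id: str
    residues: str

    def __post_init__(self):
        if not self.sample_id:
            raise AlignmentError("empty sample_id")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Equal-length set of sequences for one locus."""

    locus: str
    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise AlignmentError(f"{self.locus}: alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            ref = len(self.records[0])
            bad = [r.sample_id for r in self.records if len(r) != ref]
            raise AlignmentError(
                f"{self.locus}: unequal sequence lengths; offending IDs "
                f"(differ from first record's {ref} columns): {bad}"
            )
        if lengths == {0}:
            raise AlignmentError(f"{self.locus}: zero-length alignment")
        ids = [r.sample_id for r in self.records]
        seen: set[str] = set()
        dup: list[str] = []
        for i in ids:
            if i in seen:
                dup.append(i)
            seen.add(i)
        if dup:
            raise AlignmentError(f"{self.locus}: duplicate sample IDs {sorted(set(dup))}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> str:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.residues
        raise KeyError(sample_id)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Alignment restricted to ``ids``, preserving record order."""
        keep = set(ids)
        recs = [r for r in self.records if r.sample_id in keep]
        missing = keep - {r.sample_id for r in recs}
        if missing:
            raise AlignmentError(f"{self.locus}: unknown sample IDs {sorted(missing)}")
        return Alignment(self.locus, recs)


def read_alignment(path: str | Path, locus: str) -> Alignment:
    """Read an aligned FASTA file; IDs are the first header token.

    Raises :class:`AlignmentError` for empty files, duplicate IDs or
    unequal row lengths (naming the offending records).
    """
    path = Path(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    return Alignment(locus, records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write unwrapped FASTA preserving record order."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.sample_id}\n{rec.residues}\n")


def trim_alignment(aln: Alignment, start: int, end: int) -> Alignment:
    """Columns ``start``..``end`` (1-based, inclusive) of every record."""
    if not (1 <= start <= end <= aln.length):
        raise AlignmentError(
            f"{aln.locus}: trim window [{start}, {end}] outside 1..{aln.length}"
        )
    recs = [
        SequenceRecord(r.sample_id, r.residues[start - 1 : end]) for r in aln.records
    ]
    return Alignment(aln.locus, recs)


@dataclass(frozen=True)
class GroupPartition:
    """Sample -> (group, region) labels, e.g. western_Atlantic / Florida."""

    assignments: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.assignments:
            raise PartitionError("partition has no assignments")
        object.__setattr__(self, "assignments", dict(self.assignments))

    def group(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id][0]
        except KeyError:
            raise PartitionError(f"sample {sample_id!r} has no group assignment")

    def region(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id][1]
        except KeyError:
            raise PartitionError(f"sample {sample_id!r} has no group assignment")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _ in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [s for s, (g, _) in self.assignments.items() if g == group]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


def read_partition(path: str | Path) -> GroupPartition:
    """Read a TSV with header ``sample_id  group  region``.

    ``region`` may be omitted per-row or as a column; it then defaults
    to the group label.
    """
    path = Path(path)
    assignments: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PartitionError(f"{path}: empty partition file")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["sample_id", "group"]:
            raise PartitionError(
                f"{path}: expected header 'sample_id\\tgroup[\\tregion]', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise PartitionError(f"{path}: malformed row at line {lineno}: {row}")
            sample, group = row[0].strip(), row[1].strip()
            region = row[2].strip() if len(row) > 2 and row[2].strip() else group
            if sample in assignments:
                raise PartitionError(f"{path}: duplicate sample_id {sample!r} at line {lineno}")
            assignments[sample] = (group, region)
    return GroupPartition(assignments)


def write_partition(part: GroupPartition, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "group", "region"])
        for sample, (group, region) in part.assignments.items():
            writer.writerow([sample, group, region])
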