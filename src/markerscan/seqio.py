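"""Sequence I/O: FASTA reading/writing, alphabet validation, region extraction.

All user-facing coordinates are 1-based inclusive (the convention of the
alignment viewers and population-genetics tools this package interoperates
with); conversion to Python's 0-based half-open slices happens at the module
boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide codes -> set of concrete bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Characters accepted in a stored sequence (post-normalisation).
SEQUENCE_ALPHABET = frozenset(IUPAC_CODES) | {"-"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

#: Default: taxon label = first two whitespace-separated words of the
#: description after the id (genus + species epithet).
DEFAULT_TAXON_REGEX = r"^\s*(\S+\s+\S+)"


class SequenceError(ValueError):
    """Raised for malformed sequence data (bad alphabet, bad coordinates...)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, *, record_id: str = "?") -> str:
    """Upper-case, map U->T and '.'->'-', and validate the alphabet.

    Raises :class:`SequenceError` naming the record and the first offending
    character if the sequence contains anything outside the IUPAC nucleotide
    alphabet plus gaps.
    """
    s = seq.upper().replace("U", "T").replace(".", "-")
    bad = set(s) - SEQUENCE_ALPHABET
    if bad:
        ch = sorted(bad)[0]
        raise SequenceError(
            f"record {record_id!r}: illegal character {ch!r} in sequence"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (a genome, a gene, or an amplicon)."""

    id: str
    seq: str
    description: str = ""
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        object.__setattr__(self, "seq", normalize_sequence(self.seq, record_id=self.id))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")

    def with_seq(self, seq: str) -> "SequenceRecord":
        return replace(self, seq=seq)


@dataclass
class SequenceCollection:
    """Ordered set of records; ``aligned=True`` guarantees equal lengths."""

    records: list[SequenceRecord] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceError(f"duplicate record id {dup!r} in collection")
        if self.aligned and len({len(r) for r in self.records}) > 1:
            raise SequenceError("aligned collection has unequal sequence lengths")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def alignment_length(self) -> int:
        if not self.aligned:
            raise SequenceError("collection is not aligned")
        if not self.records:
            raise SequenceError("empty collection has no alignment length")
        return len(self.records[0])


@dataclass(frozen=True)
class ManifestRow:
    accession: str
    species: str
    path: str | None = None


@dataclass
class AccessionManifest:
    """Accession -> species table standing in for a genome download list."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.rows]
        if any(not a for a in accs):
            raise SequenceError("manifest accession must be non-empty")
        if len(accs) != len(set(accs)):
            raise SequenceError("duplicate accession in manifest")


def parse_taxon_label(description: str, pattern: str = DEFAULT_TAXON_REGEX) -> str | None:
    """Extract a species label from a FASTA description line."""
    if not description:
        return None
    m = re.search(pattern, description)
    return m.group(1) if m else None


def read_fasta(
    path: str | Path,
    *,
    taxon_regex: str | None = DEFAULT_TAXON_REGEX,
) -> SequenceCollection:
    """Read a FASTA file into a :class:`SequenceCollection`.

    Sequences are upper-cased, U is converted to T and '.' gaps to '-'.
    The collection is flagged aligned iff all sequences share one length and
    at least one contains a gap character. The taxon label of each record is
    parsed from its description with ``taxon_regex`` (None disables parsing).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                description=desc,
                taxon_label=parse_taxon_label(desc, taxon_regex) if taxon_regex else None,
            )
        )
    if not records:
        raise SequenceError(f"no records in {path}")
    lengths = {len(r) for r in records}
    has_gap = any("-" in r.seq for r in records)
    return SequenceCollection(records=records, aligned=(len(lengths) == 1 and has_gap))


def write_fasta(collection: SequenceCollection | Iterable[SequenceRecord],
                path: str | Path, *, wrap: int = 70) -> None:
    """Write records to FASTA (wrapped at ``wrap`` columns)."""
    records = list(collection)
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def extract_region(collection: SequenceCollection, start: int, end: int) -> SequenceCollection:
    """Trim every record of an aligned collection to columns [start, end].

    Coordinates are 1-based inclusive alignment columns; the output region
    length is ``end - start + 1`` for every record.
    """
    if not collection.aligned:
        raise SequenceError("extract_region requires an aligned collection")
    length = collection.alignment_length
    if not (1 <= start <= end <= length):
        raise SequenceError(
            f"region {start}-{end} out of range for alignment of length {length}"
        )
    records = [r.with_seq(r.seq[start - 1:end]) for r in collection]
    return SequenceCollection(records=records, aligned=True)


def read_manifest(path: str | Path) -> AccessionManifest:
    """Read a TSV manifest with header ``accession<TAB>species<TAB>path``."""
    rows: list[ManifestRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["accession", "species"]:
            raise SequenceError(f"bad manifest header in {path}: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            rows.append(ManifestRow(
                accession=parts[0],
                species=parts[1] if len(parts) > 1 else "",
                path=parts[2] if len(parts) > 2 and parts[2] else None,
            ))
    return AccessionManifest(rows=rows)


def write_tsv_report(
    rows: Sequence[Sequence[object]],
    path: str | Path,
    *,
    header: Sequence[str],
    float_precision: int = 6,
) -> None:
    """Write a TSV report: header row, given row order, fixed float precision."""
    def fmt(cell: object) -> str:
        if isinstance(cell, float):
            return f"{cell:.{float_precision}f}"
        return str(cell)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(c) for c in row) + "\n")


def read_tsv_report(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read back a TSV report as (header, rows of strings)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise SequenceError(f"empty report {path}")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:] if ln]
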