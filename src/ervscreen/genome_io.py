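"""Sequence and annotation I/O plus the codon-level primitives.

Coordinates are 1-based inclusive throughout (GFF3 convention). Soft-masked
(lowercase) input is uppercased on read; masking is not tracked.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

__all__ = [
    "SeqRecord",
    "Genome",
    "Feature",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "translate",
    "revcomp",
    "STOP_CODONS",
]


class FormatError(ValueError):
    """Malformed input file (message carries the offending line number)."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence: either nucleotide over {A,C,G,T,N} or protein."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Genome:
    """An ordered set of contigs belonging to one species."""

    contigs: list[SeqRecord]
    species_label: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids in genome")
        if sum(len(c) for c in self.contigs) == 0:
            raise ValueError("genome has zero total length")
        self._by_id = {c.id: c for c in self.contigs}

    def __getitem__(self, contig_id: str) -> SeqRecord:
        return self._by_id[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def __iter__(self):
        return iter(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 1-based inclusive on the forward strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str  # gene, exon, ERV, marker, other
    name: str
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature span {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "Feature") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.end
            and other.start <= self.end
        )

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path | io.TextIOBase) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, preserving order and uppercasing.

    Raises FormatError (with a line number) for a sequence line before any
    header or for a header with no sequence.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    records: list[SeqRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: header {header!r} has no sequence")
        records.append(SeqRecord(id=header, seq=seq.upper()))

    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if len(line) > 1 else ""
            if not header:
                raise FormatError(f"line {lineno}: empty FASTA header")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FormatError(f"line {lineno}: sequence before any FASTA header")
            chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_GFF_KINDS = {"gene", "exon", "ERV", "marker"}


def read_gff(path: str | Path) -> list[Feature]:
    """Parse a 9-column GFF3 file into Features sorted by (contig, start).

    The feature-type column maps onto the Feature.kind vocabulary; unknown
    types become "other". Name= (or ID=) in column 9 becomes the name.
    """
    features: list[Feature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"line {lineno}: expected 9 tab-separated columns")
        contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinates") from exc
        if start > end:
            raise FormatError(f"line {lineno}: start {start} > end {end}")
        attrs = {}
        for item in attrs_s.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
        name = attrs.get("Name", attrs.get("ID", ""))
        kind = ftype if ftype in _GFF_KINDS else "other"
        features.append(
            Feature(
                contig_id=contig,
                start=start,
                end=end,
                strand=strand if strand in {"+", "-"} else "+",
                kind=kind,
                name=name,
                attributes=attrs,
            )
        )
    features.sort(key=lambda f: (f.contig_id, f.start, f.end, f.name))
    return features


def write_gff(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("Name", f.name)
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items() if v != "")
            fh.write(
                f"{f.contig_id}\t.\t{f.kind}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attr_s}\n"
            )


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Codons containing N translate to 'X'; stop codons to '*'.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    bad = set(nt) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return str(Seq(nt).translate())


def revcomp(nt: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    bad = set(nt) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return str(Seq(nt).reverse_complement())
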