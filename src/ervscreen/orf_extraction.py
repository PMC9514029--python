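"""Six-frame harvest of stop-flanked open reading frames.

An ORF here is a maximal run of non-stop codons between two stop codons
(or a contig end) in one of the six reading frames, at least `min_len_nt`
nucleotides long. The flanking stops are not part of the reported span.
This reproduces the stop-to-stop mode of getorf-style extraction used as
the first stage of the screen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_io import Genome, SeqRecord, STOP_CODONS, revcomp, translate

__all__ = ["OrfRecord", "extract_orfs", "orf_to_fasta", "parse_orf_id", "orf_table"]

# a run of >MAX_AMBIGUOUS_CODONS consecutive all-N codons splits an ORF so
# assembly gaps cannot stitch together giant artificial frames
MAX_AMBIGUOUS_CODONS = 10


@dataclass(frozen=True)
class OrfRecord:
    """A stop-flanked ORF with forward-strand genomic coordinates."""

    orf_id: str
    contig_id: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str
    frame: int  # 0,1,2: offset of the first codon base within its strand
    nt_seq: str  # as read (minus-strand ORFs are already reverse-complemented)
    aa_seq: str

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) != len(self.nt_seq):
            raise ValueError("span/sequence length mismatch")
        if len(self.nt_seq) % 3 != 0:
            raise ValueError("ORF length not a codon multiple")
        if "*" in self.aa_seq:
            raise ValueError("internal stop codon in ORF")

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)


def _codon_runs(codons: list[str], min_codons: int, require_both_stops: bool):
    """Yield (start_codon_index, n_codons) for reportable ORF runs.

    A run is a maximal stretch of non-stop codons. A stretch of more than
    MAX_AMBIGUOUS_CODONS consecutive N-containing codons splits a run; the
    ambiguous stretch itself belongs to neither side, and a gap boundary
    does not count as a stop for `require_both_stops`.
    """
    n = len(codons)
    # maximal non-stop runs as half-open [a, b) codon index intervals
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if codons[i] in STOP_CODONS:
            i += 1
            continue
        j = i
        while j < n and codons[j] not in STOP_CODONS:
            j += 1
        runs.append((i, j))
        i = j
    for a, b in runs:
        stop_left = a > 0
        stop_right = b < n
        # split on long ambiguous stretches
        pieces: list[tuple[int, int, bool, bool]] = []  # (a, b, stopL, stopR)
        seg_start = a
        k = a
        while k < b:
            if "N" in codons[k]:
                g = k
                while g < b and "N" in codons[g]:
                    g += 1
                if g - k > MAX_AMBIGUOUS_CODONS:
                    if k > seg_start:
                        pieces.append((seg_start, k, seg_start == a and stop_left, False))
                    seg_start = g
                k = g
            else:
                k += 1
        if b > seg_start:
            pieces.append((seg_start, b, seg_start == a and stop_left, stop_right))
        for pa, pb, sl, sr in pieces:
            if pb - pa >= min_codons and (not require_both_stops or (sl and sr)):
                yield pa, pb - pa


def extract_orfs(
    genome: Genome,
    min_len_nt: int = 240,
    require_both_stops: bool = False,
) -> list[OrfRecord]:
    """Return every stop-flanked ORF of length >= min_len_nt in six frames.

    Minus-strand ORFs carry forward-strand coordinates; their nt_seq is the
    reading-direction (reverse-complemented) sequence. Output is sorted by
    (contig, start, strand, frame) and deterministic.
    """
    if min_len_nt <= 0 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be positive and divisible by 3")
    if genome.total_length == 0 or not genome.contigs:
        raise ValueError("empty genome")
    min_codons = min_len_nt // 3
    out: list[OrfRecord] = []
    for contig in genome:
        L = len(contig.seq)
        for strand in "+-":
            seq = contig.seq if strand == "+" else revcomp(contig.seq)
            for frame in range(3):
                usable = (L - frame) // 3
                codons = [seq[frame + 3 * k : frame + 3 * k + 3] for k in range(usable)]
                for ci, ncod in _codon_runs(codons, min_codons, require_both_stops):
                    nt = "".join(codons[ci : ci + ncod])
                    # offset of the run within the strand-oriented sequence
                    s_off = frame + 3 * ci
                    e_off = s_off + 3 * ncod - 1
                    if strand == "+":
                        start, end = s_off + 1, e_off + 1
                    else:
                        start, end = L - e_off, L - s_off
                    aa = translate(nt)
                    orf_id = f"{contig.id}:{start}-{end}({strand})f{frame}"
                    out.append(
                        OrfRecord(
                            orf_id=orf_id,
                            contig_id=contig.id,
                            start=start,
                            end=end,
                            strand=strand,
                            frame=frame,
                            nt_seq=nt,
                            aa_seq=aa,
                        )
                    )
    out.sort(key=lambda o: (o.contig_id, o.start, o.strand, o.frame))
    return out


_ID_RE = re.compile(r"^(?P<contig>.+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)f(?P<frame>[012])$")


def parse_orf_id(orf_id: str) -> tuple[str, int, int, str, int]:
    """Recover (contig, start, end, strand, frame) from an ORF id."""
    m = _ID_RE.match(orf_id)
    if m is None:
        raise ValueError(f"unparseable ORF id {orf_id!r}")
    return (
        m.group("contig"),
        int(m.group("start")),
        int(m.group("end")),
        m.group("strand"),
        int(m.group("frame")),
    )


def orf_to_fasta(orfs: Iterable[OrfRecord], which: str = "aa") -> list[SeqRecord]:
    """Render ORFs as FASTA records (ids encode contig/strand/coordinates)."""
    if which not in {"nt", "aa"}:
        raise ValueError("which must be 'nt' or 'aa'")
    return [
        SeqRecord(id=o.orf_id, seq=o.nt_seq if which == "nt" else o.aa_seq)
        for o in orfs
    ]


def orf_table(orfs: Iterable[OrfRecord]):
    """Tabulate ORFs (orf_id, contig, start, end, strand, frame, length_nt)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "orf_id": o.orf_id,
                "contig": o.contig_id,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "frame": o.frame,
                "length_nt": o.length_nt,
            }
            for o in orfs
        ]
    )
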