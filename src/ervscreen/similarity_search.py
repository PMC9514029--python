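"""Local protein alignment with BLAST-style statistics, translated search,
and k-mer self-dotplots.

Smith-Waterman alignment (BLOSUM62, affine gaps, open 11 / extend 1) is
executed by Biopython's PairwiseAligner; bitscores and E-values follow the
Karlin-Altschul formulae with the published gapped BLOSUM62 constants
(lambda = 0.267 nats, K = 0.041). The translated search aligns a protein
query against all six-frame stop-split translated segments of a genome
and maps hits back to forward-strand genomic coordinates, playing the
role tBLASTn plays in the screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, revcomp, translate

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "SearchHit",
    "smith_waterman",
    "bit_and_evalue",
    "translated_search",
    "self_dotplot",
    "DEFAULT_SCHEME",
]


@dataclass(frozen=True)
class ScoringScheme:
    """BLOSUM62 affine-gap scoring with Karlin-Altschul constants."""

    gap_open: int = 11  # BLAST convention: a k-long gap costs open + k*extend
    gap_extend: int = 1
    lam: float = 0.267  # nats per raw score unit (gapped BLOSUM62 11/1)
    K: float = 0.041
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_SCHEME = ScoringScheme()


@lru_cache(maxsize=4)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass
class LocalAlignment:
    query_id: str
    subject_id: str
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    raw_score: float
    n_identical: int
    aln_len: int
    bitscore: float = float("nan")
    evalue: float = float("nan")

    def __post_init__(self) -> None:
        if self.raw_score <= 0:
            raise ValueError("local alignment must have positive score")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("inverted alignment span")
        if self.n_identical > self.aln_len:
            raise ValueError("n_identical > aln_len")


@dataclass
class SearchHit:
    """A translated-search hit located on the genome."""

    alignment: LocalAlignment
    contig_id: str
    genomic_start: int  # 1-based inclusive, forward strand
    genomic_end: int
    strand: str
    frame: int
    query_cover: float

    def __post_init__(self) -> None:
        if not (0 < self.query_cover <= 1):
            raise ValueError("query_cover must lie in (0, 1]")


def smith_waterman(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalAlignment | None:
    """Optimal local alignment, or None when no positive-scoring cell exists."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(scheme)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    q_blocks, s_blocks = aln.aligned
    ident = 0
    aln_len = 0
    prev_q_end = prev_s_end = None
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            aln_len += (qa - prev_q_end) + (sa - prev_s_end)  # gap columns
        aln_len += qb - qa
        for off in range(qb - qa):
            if query[qa + off] == subject[sa + off]:
                ident += 1
        prev_q_end, prev_s_end = qb, sb
    return LocalAlignment(
        query_id=query_id,
        subject_id=subject_id,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
        raw_score=float(score),
        n_identical=ident,
        aln_len=aln_len,
    )


def bit_and_evalue(
    raw_score: float, query_len: int, db_len: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[float, float]:
    """Karlin-Altschul bitscore and E-value for a raw alignment score."""
    if raw_score <= 0:
        raise ValueError("raw_score must be positive")
    bits = (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)
    evalue = scheme.K * query_len * db_len * math.exp(-scheme.lam * raw_score)
    return bits, evalue


def _six_frame_segments(genome: Genome):
    """Yield (contig_id, strand, frame, aa_offset, peptide) stop-split segments.

    aa_offset is the 0-based index of the segment's first residue within the
    full frame translation of the strand-oriented sequence.
    """
    for contig in genome:
        L = len(contig.seq)
        for strand in "+-":
            seq = contig.seq if strand == "+" else revcomp(contig.seq)
            for frame in range(3):
                usable = (L - frame) // 3
                if usable == 0:
                    continue
                aa = translate(seq[frame : frame + 3 * usable])
                pos = 0
                for seg in aa.split("*"):
                    if seg:
                        yield contig.id, strand, frame, pos, seg
                    pos += len(seg) + 1


def _map_to_genome(contig_len: int, strand: str, frame: int, aa_from: int, aa_to: int):
    """Map a 0-based half-open aa span in a frame translation to 1-based
    inclusive forward-strand nucleotide coordinates."""
    s_off = frame + 3 * aa_from
    e_off = frame + 3 * aa_to - 1
    if strand == "+":
        return s_off + 1, e_off + 1
    return contig_len - e_off, contig_len - s_off


def translated_search(
    protein: str,
    genome: Genome,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_threshold: float = 1e-5,
    query_id: str = "query",
) -> list[SearchHit]:
    """Align a protein against the six-frame translation of a genome.

    One optimal alignment is reported per stop-split segment (a coarse
    analogue of BLAST HSP culling: one hit per locus); hits with
    E < threshold are returned sorted by bitscore descending.
    """
    if not protein:
        raise ValueError("empty protein query")
    segments = list(_six_frame_segments(genome))
    db_len = sum(len(s[4]) for s in segments)
    if db_len == 0:
        return []
    contig_lens = {c.id: len(c.seq) for c in genome}
    hits: list[SearchHit] = []
    for contig_id, strand, frame, aa_off, seg in segments:
        if len(seg) < 5:  # tiny inter-stop slivers cannot score
            continue
        aln = smith_waterman(protein, seg, scheme, query_id=query_id, subject_id=f"{contig_id}({strand})f{frame}")
        if aln is None:
            continue
        aln.bitscore, aln.evalue = bit_and_evalue(aln.raw_score, len(protein), db_len, scheme)
        if aln.evalue >= evalue_threshold:
            continue
        g_start, g_end = _map_to_genome(
            contig_lens[contig_id],
            strand,
            frame,
            aa_off + aln.s_start - 1,
            aa_off + aln.s_end,
        )
        hits.append(
            SearchHit(
                alignment=aln,
                contig_id=contig_id,
                genomic_start=g_start,
                genomic_end=g_end,
                strand=strand,
                frame=frame,
                query_cover=aln.aln_len / len(protein),
            )
        )
    hits.sort(key=lambda h: (-h.alignment.bitscore, h.contig_id, h.genomic_start))
    return hits


def self_dotplot(seq: str, k: int = 12) -> list[tuple[int, int, str]]:
    """All off-diagonal k-mer self-matches of a nucleotide sequence.

    Returns (i, j, strand) with 1-based start positions and i < j; '+' for
    direct repeats and '-' for inverted (reverse-complement) matches.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    seq = seq.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    out: list[tuple[int, int, str]] = []
    for kmer, positions in index.items():
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                out.append((positions[a] + 1, positions[b] + 1, "+"))
        rc = revcomp(kmer)
        if rc in index and rc != kmer:
            if kmer < rc:  # visit each unordered kmer pair once
                for i in positions:
                    for j in index[rc]:
                        lo, hi = (i, j) if i < j else (j, i)
                        if lo != hi:
                            out.append((lo + 1, hi + 1, "-"))
        elif rc == kmer:
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    out.append((positions[a] + 1, positions[b] + 1, "-"))
    out.sort()
    return out
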