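"""Greedy incremental peptide clustering at an identity threshold.

This reproduces the CD-HIT stage of the screen: peptides are sorted
longest-first, each joins the first cluster whose representative it
matches at >= the identity threshold (identity = identical aligned
residues / length of the shorter sequence, under a free-end-gap global
alignment), otherwise it founds a new cluster. Clusters with more than
`max_size` members are then discarded wholesale — the mutual similarity
of young, high-copy ERV families puts them in exactly such clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import SeqRecord

__all__ = ["Cluster", "pairwise_identity", "greedy_cluster", "filter_large_clusters", "cluster_table"]


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]  # includes the representative, in joining order

    def __len__(self) -> int:
        return len(self.member_ids)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style 11/1 affine costs; end gaps free so a fragment can match
    # its region of a longer representative at full identity
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.end_insertion_score = 0  # free end gaps in both sequences
    aligner.end_deletion_score = 0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues over the shorter length."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    ident = 0
    for (a_blk, b_blk) in zip(*aln.aligned):
        for off in range(a_blk[1] - a_blk[0]):
            if a[a_blk[0] + off] == b[b_blk[0] + off]:
                ident += 1
    return ident / min(len(a), len(b))


def greedy_cluster(seqs: list[SeqRecord], threshold: float = 0.5) -> list[Cluster]:
    """CD-HIT-style greedy clustering against cluster representatives.

    Deterministic: sequences are processed longest-first (ties by id), and
    membership is tested against representatives in cluster-creation order.
    """
    ids = [r.id for r in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    order = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    clusters: list[Cluster] = []
    reps: list[SeqRecord] = []
    for rec in order:
        placed = False
        for cl, rep in zip(clusters, reps):
            if pairwise_identity(rec.seq, rep.seq) >= threshold:
                cl.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=rec.id, member_ids=[rec.id]))
            reps.append(rec)
    return clusters


def filter_large_clusters(clusters: list[Cluster], max_size: int = 10) -> set[str]:
    """Ids of all members of clusters with at most `max_size` members.

    Members of clusters of more than `max_size` sequences (young ERV
    families) are removed.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    keep: set[str] = set()
    for cl in clusters:
        if len(cl) <= max_size:
            keep.update(cl.member_ids)
    return keep


def cluster_table(clusters: list[Cluster], seqs: list[SeqRecord]):
    """Tabulate cluster membership with identity to the representative."""
    import pandas as pd

    by_id = {r.id: r.seq for r in seqs}
    rows = []
    for ci, cl in enumerate(clusters):
        rep = by_id[cl.representative_id]
        for m in cl.member_ids:
            ident = 1.0 if m == cl.representative_id else pairwise_identity(by_id[m], rep)
            rows.append(
                {
                    "cluster_id": ci,
                    "representative": cl.representative_id,
                    "member": m,
                    "identity": round(ident, 4),
                }
            )
    return pd.DataFrame(rows)
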