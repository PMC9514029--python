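"""Decision logic of the screen: cross-species pairing and the filters.

After ORF extraction, domain scanning and cluster-size filtering, the
surviving ORFs of species A are paired with their best-scoring partners
in species B (high-stringency E-value and bitscore cuts), pairs that
correspond to already-annotated genes are removed, and the remainder are
tested for lineage specificity: a candidate counts as having an ortholog
in an outgroup genome only if a translated hit with sufficient query
cover lies close to the conserved marker gene on the same contig.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome_io import Feature, Genome, SeqRecord
from .orf_extraction import OrfRecord
from .similarity_search import (
    DEFAULT_SCHEME,
    LocalAlignment,
    ScoringScheme,
    bit_and_evalue,
    smith_waterman,
    translated_search,
)

__all__ = [
    "CandidatePair",
    "SpecificityVerdict",
    "pair_cross_species",
    "exclude_annotated",
    "lineage_specificity",
    "motif_check",
    "auto_bitscore_cutoff",
]


@dataclass
class CandidatePair:
    orf_a: OrfRecord
    orf_b: OrfRecord
    alignment: LocalAlignment
    passed_filters: list = field(default_factory=list)  # (filter, verdict, detail)

    @property
    def candidate_id(self) -> str:
        return f"{self.orf_a.orf_id}|{self.orf_b.orf_id}"

    def log(self, filter_name: str, verdict: str, detail: str = "") -> None:
        self.passed_filters.append((filter_name, verdict, detail))


@dataclass
class SpecificityVerdict:
    candidate_id: str
    outgroup_genome_id: str
    n_cover_hits: int
    min_marker_distance: Optional[int]  # bp; None when on a different contig
    verdict: str  # lineage_specific | ortholog_found | marker_absent


def pair_cross_species(
    orfs_a: Sequence[OrfRecord],
    orfs_b: Sequence[OrfRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_max: float = 1e-50,
    bitscore_min: float = 200.0,
) -> list[CandidatePair]:
    """Best cross-species partner per A-ORF under stringent cuts.

    Candidate (a, b) alignments passing E < evalue_max and
    bitscore >= bitscore_min are ranked by bitscore; each A-ORF and each
    B-ORF is used at most once (greedy assignment by descending bitscore,
    ties broken by ORF ids for determinism).
    """
    db_len = sum(len(o.aa_seq) for o in orfs_b)
    scored: list[tuple[float, str, str, OrfRecord, OrfRecord, LocalAlignment]] = []
    for a in orfs_a:
        for b in orfs_b:
            aln = smith_waterman(
                a.aa_seq, b.aa_seq, scheme, query_id=a.orf_id, subject_id=b.orf_id
            )
            if aln is None:
                continue
            aln.bitscore, aln.evalue = bit_and_evalue(
                aln.raw_score, len(a.aa_seq), db_len, scheme
            )
            if aln.evalue < evalue_max and aln.bitscore >= bitscore_min:
                scored.append((aln.bitscore, a.orf_id, b.orf_id, a, b, aln))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[CandidatePair] = []
    for _, aid, bid, a, b, aln in scored:
        if aid in used_a or bid in used_b:
            continue
        used_a.add(aid)
        used_b.add(bid)
        pair = CandidatePair(orf_a=a, orf_b=b, alignment=aln)
        pair.log("pairing", "pass", f"bitscore={aln.bitscore:.1f} evalue={aln.evalue:.3g}")
        pairs.append(pair)
    pairs.sort(key=lambda p: p.orf_a.orf_id)
    return pairs


def auto_bitscore_cutoff(bitscores: Sequence[float]) -> float:
    """Data-driven bitscore cut: midpoint of the largest gap in the sorted
    bitscore distribution (the screen's 'distribution of the bitscore' rule).

    With fewer than 3 scores there is no distribution to split: returns 0.
    """
    xs = sorted(bitscores)
    if len(xs) < 3:
        return 0.0
    gaps = [(xs[i + 1] - xs[i], i) for i in range(len(xs) - 1)]
    best_gap, i = max(gaps)
    if best_gap <= 0:
        return 0.0
    return (xs[i] + xs[i + 1]) / 2.0


def _overlaps_named_gene(
    orf: OrfRecord, features: Sequence[Feature], exclusion: set[str]
) -> Optional[str]:
    for f in features:
        if f.kind != "gene" or f.name not in exclusion:
            continue
        if f.contig_id == orf.contig_id and f.start <= orf.end and orf.start <= f.end:
            return f.name
    return None


def exclude_annotated(
    pairs: Sequence[CandidatePair],
    features_a: Sequence[Feature],
    features_b: Sequence[Feature],
    exclusion_names: Iterable[str] = (),
    known_protein_db: Sequence[SeqRecord] = (),
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_max: float = 1e-5,
) -> list[CandidatePair]:
    """Drop pairs that correspond to already-annotated known genes.

    A pair is removed if either ORF overlaps (>= 1 bp, either strand) an
    annotated gene whose name is on the exclusion list, or if either
    peptide hits the known-protein database below `evalue_max`.
    """
    exclusion = set(exclusion_names)
    known = list(known_protein_db)
    db_len = sum(len(r.seq) for r in known)
    kept: list[CandidatePair] = []
    for pair in pairs:
        trigger = None
        for orf, feats in ((pair.orf_a, features_a), (pair.orf_b, features_b)):
            name = _overlaps_named_gene(orf, feats, exclusion)
            if name is not None:
                trigger = f"{orf.orf_id} overlaps annotated gene {name}"
                break
        if trigger is None and known:
            for orf in (pair.orf_a, pair.orf_b):
                for rec in known:
                    aln = smith_waterman(orf.aa_seq, rec.seq, scheme)
                    if aln is None:
                        continue
                    _, ev = bit_and_evalue(aln.raw_score, len(orf.aa_seq), db_len, scheme)
                    if ev < evalue_max:
                        trigger = f"{orf.orf_id} hits known protein {rec.id} (E={ev:.3g})"
                        break
                if trigger:
                    break
        if trigger is None:
            pair.log("known_gene_exclusion", "pass", "")
            kept.append(pair)
        else:
            pair.log("known_gene_exclusion", "removed", trigger)
    return kept


def lineage_specificity(
    candidate: CandidatePair,
    outgroups: Sequence[tuple[Genome, object]],
    marker_protein: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    cover_min: float = 0.6,
    proximity_max: int = 1_000_000,
    evalue_max: float = 1e-5,
) -> list[SpecificityVerdict]:
    """Translated search of the candidate against each outgroup genome.

    The marker locus in each outgroup is the highest-scoring translated
    hit of `marker_protein`; the candidate has an ortholog there only if
    one of its own hits with query cover >= cover_min lies within
    `proximity_max` bp of the marker on the same contig.
    """
    if not candidate.orf_a.aa_seq:
        raise ValueError("empty candidate peptide")
    verdicts: list[SpecificityVerdict] = []
    for genome, _marker_hint in outgroups:
        marker_hits = translated_search(
            marker_protein, genome, scheme, evalue_threshold=evalue_max, query_id="marker"
        )
        if not marker_hits:
            verdicts.append(
                SpecificityVerdict(
                    candidate_id=candidate.candidate_id,
                    outgroup_genome_id=genome.species_label,
                    n_cover_hits=0,
                    min_marker_distance=None,
                    verdict="marker_absent",
                )
            )
            continue
        marker = marker_hits[0]
        hits = translated_search(
            candidate.orf_a.aa_seq,
            genome,
            scheme,
            evalue_threshold=evalue_max,
            query_id=candidate.candidate_id,
        )
        cover_hits = [h for h in hits if h.query_cover >= cover_min]
        min_dist: Optional[int] = None
        found = False
        for h in cover_hits:
            if h.contig_id != marker.contig_id:
                continue
            dist = max(
                0,
                max(h.genomic_start, marker.genomic_start)
                - min(h.genomic_end, marker.genomic_end),
            )
            min_dist = dist if min_dist is None else min(min_dist, dist)
            if dist <= proximity_max:
                found = True
        verdicts.append(
            SpecificityVerdict(
                candidate_id=candidate.candidate_id,
                outgroup_genome_id=genome.species_label,
                n_cover_hits=len(cover_hits),
                min_marker_distance=min_dist,
                verdict="ortholog_found" if found else "lineage_specific",
            )
        )
    return verdicts


def motif_check(peptide: str, motifs: Sequence[tuple[str, str]]) -> dict:
    """Presence and positions of each motif pattern in a peptide.

    Patterns are regular expressions over the amino-acid alphabet; 'X' is
    shorthand for any residue. Returns {name: (present, [1-based starts])}.
    """
    out: dict[str, tuple[bool, list[int]]] = {}
    for name, pattern in motifs:
        try:
            rx = re.compile(pattern.replace("X", "."))
        except re.error as exc:
            raise ValueError(f"malformed motif pattern {pattern!r}: {exc}") from exc
        starts = [m.start() + 1 for m in rx.finditer(peptide)]
        out[name] = (len(starts) > 0, starts)
    return out
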