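"""Seeded generator of a two-species genome pair with planted ERV content.

The generator emulates the genomic situation the screen is designed for:

* a high-copy *young* ERV family whose copies are nearly identical within
  a species (they must co-cluster and be discarded by the cluster-size
  filter);
* a *domesticated* tandem triplet of ERV-derived ORFs sitting on the
  opposite strand inside the intron of a conserved marker gene, evolving
  under purifying selection (omega << 1) in both species;
* a *decoy* conserved ERV-derived gene that is already annotated (it must
  be caught by the known-gene exclusion, the way an ASPRV1-like gene is);
* abundant neutral background ORFs arising by chance in random sequence;
* an optional outgroup genome carrying the marker gene but (by default)
  no ortholog of the domesticated genes, only a distant RT-like relic on
  another contig.

Divergence is indel-free: a species pair is produced by evolving the
ancestor down two independent branches, neutrally outside coding regions
and codon-wise inside them (synonymous changes accepted, nonsynonymous
accepted with probability omega, stop-creating changes rejected). Young
ERV ORFs evolve with omega = 1 but still reject stops: the screen's young
class is by construction the set of chance ORFs that have *not yet* been
disrupted by nonsense mutations. The stop codons flanking planted ORFs
are held fixed so that truth-table coordinates remain exact.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .genome_io import Feature, Genome, SeqRecord, STOP_CODONS, revcomp, translate

__all__ = [
    "SimConfig",
    "YoungFamilyConfig",
    "DomesticatedConfig",
    "DivergenceConfig",
    "OutgroupConfig",
    "TruthEntry",
    "TruthTable",
    "RTSeedProfileSet",
    "AncestorBundle",
    "SpeciesPair",
    "simulate_ancestor",
    "speciate",
    "make_outgroup",
    "simulate_pair",
    "simulate_rt_tree_replicate",
    "evolve_coding",
    "mutate_neutral",
    "random_coding",
    "CATALYTIC_MOTIF",
    "ABLATED_MOTIF",
]

_BASES = "ACGT"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# canonical RT catalytic motif and its ablated (domesticated) form
CATALYTIC_MOTIF = "YVDD"
ABLATED_MOTIF = "YVNN"

_CODONS_FOR: dict[str, list[str]] = {}
for _c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
    if _c not in STOP_CODONS:
        _CODONS_FOR.setdefault(translate(_c), []).append(_c)


@dataclass
class YoungFamilyConfig:
    copy_number: int = 30
    intra_identity: float = 0.98
    element_length: int = 2000
    orf_fraction: float = 0.45  # fraction of the element occupied by the ORF


@dataclass
class DomesticatedConfig:
    n_copies: int = 3
    orf_length_nt: int = 1800
    omega: float = 0.1
    tandem_spacing: int = 400
    marker_gene_length: int = 10_000
    rt_length_aa: int = 200  # RT-derived tail of each domesticated peptide
    paralog_divergence: float = 0.25  # per-copy proposal rate from the prototype
    domestication_divergence: float = 0.15  # aa divergence from the RT seed consensus
    ablate_catalytic_motif: bool = True


@dataclass
class DivergenceConfig:
    branch_length_syn: float = 0.15  # pairwise dS between the two species
    ts_tv: float = 2.0


@dataclass
class OutgroupConfig:
    present: bool = True
    has_ortholog: bool = False
    has_marker: bool = True
    ortholog_distance_bp: int = 5000  # marker-to-ortholog distance when planted
    neutral_rate: float = 0.5
    coding_rate: float = 0.3


@dataclass
class SimConfig:
    seed: int = 0
    contig_lengths: tuple = (40_000, 75_000)  # minimum lengths after planting
    young_family: YoungFamilyConfig = field(default_factory=YoungFamilyConfig)
    domesticated: DomesticatedConfig = field(default_factory=DomesticatedConfig)
    decoy_known_gene: bool = True
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    outgroup: OutgroupConfig = field(default_factory=OutgroupConfig)

    def __post_init__(self) -> None:
        if not (0 < self.young_family.intra_identity <= 1):
            raise ValueError("intra_identity must be in (0, 1]")
        if self.domesticated.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.domesticated.orf_length_nt % 3:
            raise ValueError("orf_length_nt must be a codon multiple")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthEntry:
    species: str
    contig: str
    start: int
    end: int
    strand: str
    element_class: str  # young_erv, domesticated, decoy_known, marker_gene
    name: str
    omega: Optional[float] = None
    catalytic_motif_present: Optional[bool] = None
    ortholog_of: Optional[str] = None


@dataclass
class TruthTable:
    entries: list

    def of_class(self, cls: str, species: str | None = None) -> list[TruthEntry]:
        return [
            e
            for e in self.entries
            if e.element_class == cls and (species is None or e.species == species)
        ]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([asdict(e) for e in self.entries])


@dataclass
class RTSeedProfileSet:
    """Synthetic retroviral-domain seed alignments (the scan's profile input)."""

    alignments: dict  # name -> list[SeqRecord] (aligned, equal length)
    consensus: dict  # name -> consensus peptide


# ---------------------------------------------------------------------------
# low-level evolution primitives


def _alt_base_probs(kappa: float) -> dict[str, tuple[str, np.ndarray]]:
    table = {}
    for b in _BASES:
        alts = [x for x in _BASES if x != b]
        w = np.array([kappa if x == _TRANSITION[b] else 1.0 for x in alts])
        table[b] = ("".join(alts), w / w.sum())
    return table


def mutate_neutral(rng: np.random.Generator, seq: str, rate: float, kappa: float = 2.0) -> str:
    """Per-site substitutions at probability `rate` with ts/tv bias kappa."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    probs = _alt_base_probs(kappa)
    for i in hit:
        b = arr[i].decode()
        if b not in probs:
            continue
        alts, w = probs[b]
        arr[i] = alts[rng.choice(3, p=w)].encode()
    return arr.tobytes().decode()


def evolve_coding(
    rng: np.random.Generator,
    cds: str,
    rate: float,
    omega: float,
    kappa: float = 2.0,
    frozen_aa: tuple[int, int] | None = None,
) -> str:
    """Evolve an in-frame CDS by rejection sampling of point mutations.

    Proposals arrive as Poisson(rate * length) events at random positions;
    at each position the replacement base is drawn (with ts/tv bias kappa)
    from the alternatives that do not create a stop codon — the
    substitution process is conditioned on the sequence staying sense,
    which is exactly the process whose synonymous-site fractions the
    Nei-Gojobori counting assumes. Synonymous changes are always accepted,
    nonsynonymous ones with probability omega. `frozen_aa` protects a
    half-open codon range (e.g. a catalytic motif) from any
    nonsynonymous change.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be a codon multiple")
    seq = list(cds)
    n_events = rng.poisson(rate * len(cds))
    for _ in range(n_events):
        pos = int(rng.integers(0, len(seq)))
        b = seq[pos]
        c0 = pos - pos % 3
        off = pos % 3
        codon_old = "".join(seq[c0 : c0 + 3])
        alts = []
        weights = []
        for x in _BASES:
            if x == b:
                continue
            codon_new = codon_old[:off] + x + codon_old[off + 1 :]
            if codon_new in STOP_CODONS:
                continue
            alts.append((x, codon_new))
            weights.append(kappa if x == _TRANSITION[b] else 1.0)
        if not alts:
            continue
        w = np.asarray(weights)
        new, codon_new = alts[rng.choice(len(alts), p=w / w.sum())]
        syn = translate(codon_old) == translate(codon_new)
        if not syn:
            if frozen_aa is not None and frozen_aa[0] <= c0 // 3 < frozen_aa[1]:
                continue
            if rng.random() >= omega:
                continue
        seq[pos] = new
    return "".join(seq)


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_AA20))[rng.integers(0, 20, size=length)])


def mutate_peptide(rng: np.random.Generator, pep: str, rate: float, keep: set[int] = frozenset()) -> str:
    out = list(pep)
    for i in range(len(out)):
        if i in keep:
            continue
        if rng.random() < rate:
            out[i] = _AA20[rng.integers(0, 20)]
    return "".join(out)


def random_coding(rng: np.random.Generator, peptide: str) -> str:
    """Reverse-translate a peptide, drawing synonymous codons uniformly."""
    return "".join(
        _CODONS_FOR[a][rng.integers(0, len(_CODONS_FOR[a]))] for a in peptide
    )


# ---------------------------------------------------------------------------
# ancestor construction


@dataclass
class _Segment:
    kind: str  # bg | stop | cds
    seq: str  # forward-strand sequence
    strand: str = "+"
    omega: float | None = None
    name: str = ""
    element_class: str = ""


@dataclass
class AncestorBundle:
    genome: Genome
    features: list
    truth: TruthTable
    seeds: RTSeedProfileSet
    segments: dict  # contig_id -> list[_Segment]
    cfg: SimConfig
    prototypes: dict  # name -> reading-orientation CDS of each planted element


@dataclass
class SpeciesPair:
    genome_a: Genome
    genome_b: Genome
    features_a: list
    features_b: list
    truth: TruthTable


def _make_seed_alignment(rng, consensus: str, n: int = 5, rate: float = 0.15, keep=frozenset()):
    recs = [SeqRecord(id="consensus", seq=consensus)]
    for k in range(1, n):
        recs.append(SeqRecord(id=f"seed{k}", seq=mutate_peptide(rng, consensus, rate, keep)))
    return recs


def _make_seeds(rng: np.random.Generator, cfg: SimConfig) -> RTSeedProfileSet:
    rt_len = cfg.domesticated.rt_length_aa
    motif_at = rt_len // 2
    rt_cons = random_peptide(rng, rt_len)
    rt_cons = rt_cons[:motif_at] + CATALYTIC_MOTIF + rt_cons[motif_at + len(CATALYTIC_MOTIF) :]
    keep = set(range(motif_at, motif_at + len(CATALYTIC_MOTIF)))
    gag_cons = random_peptide(rng, 250)
    pro_cons = random_peptide(rng, 220)
    alignments = {
        "RT_spuma_like": _make_seed_alignment(rng, rt_cons, keep=keep),
        "gag_like": _make_seed_alignment(rng, gag_cons),
        "pro_like": _make_seed_alignment(rng, pro_cons),
    }
    return RTSeedProfileSet(
        alignments=alignments,
        consensus={"RT_spuma_like": rt_cons, "gag_like": gag_cons, "pro_like": pro_cons},
    )


def _domesticated_prototype(rng, cfg: SimConfig, rt_consensus: str) -> tuple[str, bool]:
    """Build the pre-duplication coding sequence: non-RT head + RT-derived tail."""
    dom = cfg.domesticated
    rt_len = dom.rt_length_aa
    motif_at = rt_len // 2
    rt_pep = mutate_peptide(
        rng,
        rt_consensus,
        dom.domestication_divergence,
        keep=set(range(motif_at, motif_at + len(CATALYTIC_MOTIF))),
    )
    motif_present = True
    if dom.ablate_catalytic_motif:
        rt_pep = rt_pep[:motif_at] + ABLATED_MOTIF + rt_pep[motif_at + len(ABLATED_MOTIF) :]
        motif_present = False
    head_len = dom.orf_length_nt // 3 - rt_len
    if head_len < 0:
        raise ValueError("orf_length_nt too short for the RT region")
    pep = random_peptide(rng, head_len) + rt_pep
    return random_coding(rng, pep), motif_present


def simulate_ancestor(cfg: SimConfig) -> AncestorBundle:
    """Build the ancestral genome with all planted elements and the truth table."""
    rng = np.random.default_rng(cfg.seed + 100)
    seeds = _make_seeds(rng, cfg)
    dom = cfg.domesticated
    yng = cfg.young_family
    prototypes: dict[str, str] = {}

    # --- chr1: marker gene with the domesticated triplet in its intron, decoy
    segs1: list[_Segment] = [_Segment("bg", random_nt(rng, 8000))]
    exon1 = random_coding(rng, random_peptide(rng, 200))
    exon2 = random_coding(rng, random_peptide(rng, 200))
    prototypes["GRIP2_exon1"], prototypes["GRIP2_exon2"] = exon1, exon2

    # tandem units, minus strand: reading (TAA + CDS + TAA) -> forward revcomp
    proto_cds, motif_present = _domesticated_prototype(rng, cfg, seeds.consensus["RT_spuma_like"])
    prototypes["RTOM_prototype"] = proto_cds
    rt_lo = dom.orf_length_nt // 3 - dom.rt_length_aa
    motif_lo = rt_lo + dom.rt_length_aa // 2
    spacer_proto = random_nt(rng, dom.tandem_spacing)
    triplet_segs: list[_Segment] = []
    for k in range(dom.n_copies):
        cds_k = evolve_coding(
            rng,
            proto_cds,
            dom.paralog_divergence,
            dom.omega,
            cfg.divergence.ts_tv,
            frozen_aa=(motif_lo, motif_lo + len(CATALYTIC_MOTIF)),
        )
        name = f"RTOM{k + 1}"
        prototypes[name] = cds_k
        triplet_segs.append(_Segment("stop", revcomp("TAA")))
        triplet_segs.append(
            _Segment("cds", revcomp(cds_k), "-", dom.omega, name, "domesticated")
        )
        triplet_segs.append(_Segment("stop", revcomp("TAA")))
        triplet_segs.append(
            _Segment("bg", mutate_neutral(rng, spacer_proto, dom.paralog_divergence, cfg.divergence.ts_tv))
        )
    triplet_len = sum(len(s.seq) for s in triplet_segs)
    pad = max((dom.marker_gene_length - 1200 - triplet_len) // 2, 500)

    segs1.append(_Segment("cds", exon1, "+", 0.05, "GRIP2_exon1", "marker_gene"))
    segs1.append(_Segment("bg", random_nt(rng, pad)))
    segs1.extend(triplet_segs)
    segs1.append(_Segment("bg", random_nt(rng, pad)))
    segs1.append(_Segment("cds", exon2, "+", 0.05, "GRIP2_exon2", "marker_gene"))
    segs1.append(_Segment("bg", random_nt(rng, 6000)))

    if cfg.decoy_known_gene:
        decoy_cds = random_coding(rng, mutate_peptide(rng, seeds.consensus["pro_like"], 0.15))
        prototypes["ASPRV1"] = decoy_cds
        segs1.append(_Segment("stop", "TAA"))
        segs1.append(_Segment("cds", decoy_cds, "+", 0.1, "ASPRV1", "decoy_known"))
        segs1.append(_Segment("stop", "TAA"))
    tail = cfg.contig_lengths[0] - sum(len(s.seq) for s in segs1)
    segs1.append(_Segment("bg", random_nt(rng, max(tail, 2000))))

    # --- chr2: scattered young family copies
    orf_codons = int(yng.element_length * yng.orf_fraction) // 3
    young_pep = seeds.consensus["gag_like"]
    if orf_codons > len(young_pep):
        young_pep = young_pep + random_peptide(rng, orf_codons - len(young_pep))
    young_cds_proto = random_coding(rng, mutate_peptide(rng, young_pep[:orf_codons], 0.10))
    prototypes["young_prototype"] = young_cds_proto
    flank_total = yng.element_length - len(young_cds_proto) - 6
    f5 = flank_total // 2
    f3 = flank_total - f5
    flank5_proto = random_nt(rng, f5)
    flank3_proto = random_nt(rng, f3)
    per_copy_rate = (1.0 - yng.intra_identity) / 2.0
    segs2: list[_Segment] = []
    for k in range(yng.copy_number):
        segs2.append(_Segment("bg", random_nt(rng, int(rng.integers(300, 1200)))))
        segs2.append(_Segment("bg", mutate_neutral(rng, flank5_proto, per_copy_rate, cfg.divergence.ts_tv)))
        segs2.append(_Segment("stop", "TAA"))
        cds_k = evolve_coding(rng, young_cds_proto, per_copy_rate, 1.0, cfg.divergence.ts_tv)
        segs2.append(_Segment("cds", cds_k, "+", 1.0, f"young_{k + 1:02d}", "young_erv"))
        segs2.append(_Segment("stop", "TAA"))
        segs2.append(_Segment("bg", mutate_neutral(rng, flank3_proto, per_copy_rate, cfg.divergence.ts_tv)))
    tail2 = cfg.contig_lengths[1] - sum(len(s.seq) for s in segs2)
    segs2.append(_Segment("bg", random_nt(rng, max(tail2, 1000))))

    segments = {"chr1": segs1, "chr2": segs2}
    genome, features, truth = _assemble(segments, "ancestor", motif_present)
    return AncestorBundle(
        genome=genome,
        features=features,
        truth=truth,
        seeds=seeds,
        segments=segments,
        cfg=cfg,
        prototypes=prototypes,
    )


def _assemble(segments: dict, species: str, motif_present: bool):
    contigs = []
    features: list[Feature] = []
    entries: list[TruthEntry] = []
    for contig_id, segs in segments.items():
        pos = 1
        marker_span: list[int] = []
        for seg in segs:
            start, end = pos, pos + len(seg.seq) - 1
            if seg.kind == "cds":
                cls = seg.element_class
                if cls == "marker_gene":
                    marker_span.extend([start, end])
                    features.append(
                        Feature(contig_id, start, end, seg.strand, "exon", seg.name)
                    )
                else:
                    kind = "gene" if cls == "decoy_known" else "ERV"
                    features.append(
                        Feature(contig_id, start, end, seg.strand, kind, seg.name)
                    )
                entries.append(
                    TruthEntry(
                        species=species,
                        contig=contig_id,
                        start=start,
                        end=end,
                        strand=seg.strand,
                        element_class=cls,
                        name=seg.name,
                        omega=seg.omega if cls != "marker_gene" else None,
                        catalytic_motif_present=(
                            motif_present if cls == "domesticated" else None
                        ),
                    )
                )
            pos = end + 1
        if marker_span:
            g_start, g_end = min(marker_span), max(marker_span)
            features.append(Feature(contig_id, g_start, g_end, "+", "gene", "GRIP2"))
            entries.append(
                TruthEntry(
                    species=species,
                    contig=contig_id,
                    start=g_start,
                    end=g_end,
                    strand="+",
                    element_class="marker_gene",
                    name="GRIP2",
                )
            )
        contigs.append(SeqRecord(id=contig_id, seq="".join(s.seq for s in segs)))
    features.sort(key=lambda f: (f.contig_id, f.start, f.end, f.name))
    return Genome(contigs, species_label=species), features, TruthTable(entries)


def _evolve_segments(
    segments: dict,
    rng: np.random.Generator,
    neutral_rate: float,
    kappa: float,
    omega_scale: float = 1.0,
    coding_rate: float | None = None,
    drop_classes: frozenset = frozenset(),
    destroy_marker: bool = False,
) -> dict:
    """One descendant branch: mutate every segment according to its kind."""
    out: dict[str, list[_Segment]] = {}
    for contig_id, segs in segments.items():
        new_segs = []
        for seg in segs:
            if seg.kind == "stop":
                new_segs.append(seg)
                continue
            if seg.kind == "bg":
                new_segs.append(
                    _Segment("bg", mutate_neutral(rng, seg.seq, neutral_rate, kappa))
                )
                continue
            # cds
            if seg.element_class in drop_classes or (
                destroy_marker and seg.element_class == "marker_gene"
            ):
                new_segs.append(_Segment("bg", random_nt(rng, len(seg.seq))))
                continue
            reading = seg.seq if seg.strand == "+" else revcomp(seg.seq)
            rate = coding_rate if coding_rate is not None else neutral_rate
            evolved = evolve_coding(
                rng, reading, rate, min(seg.omega * omega_scale, 1.0), kappa
            )
            fwd = evolved if seg.strand == "+" else revcomp(evolved)
            new_segs.append(
                _Segment("cds", fwd, seg.strand, seg.omega, seg.name, seg.element_class)
            )
        out[contig_id] = new_segs
    return out


def speciate(ancestor: AncestorBundle, cfg: SimConfig | None = None) -> SpeciesPair:
    """Evolve the ancestor down two independent branches into species A and B."""
    cfg = cfg or ancestor.cfg
    kappa = cfg.divergence.ts_tv
    branch = cfg.divergence.branch_length_syn / 2.0
    motif_present = not cfg.domesticated.ablate_catalytic_motif
    out = {}
    for label, offset in (("species_A", 101), ("species_B", 102)):
        rng = np.random.default_rng(cfg.seed + offset)
        segs = _evolve_segments(ancestor.segments, rng, branch, kappa)
        out[label] = _assemble({k: v for k, v in segs.items()}, label, motif_present)
    genome_a, features_a, truth_a = out["species_A"]
    genome_b, features_b, truth_b = out["species_B"]
    entries = []
    for e in truth_a.entries + truth_b.entries:
        other = "species_B" if e.species == "species_A" else "species_A"
        link = None
        if e.element_class in {"domesticated", "decoy_known", "marker_gene"}:
            link = f"{other}:{e.name}"
        entries.append(
            TruthEntry(
                **{**asdict(e), "ortholog_of": link}
            )
        )
    return SpeciesPair(
        genome_a=genome_a,
        genome_b=genome_b,
        features_a=features_a,
        features_b=features_b,
        truth=TruthTable(entries),
    )


def make_outgroup(ancestor: AncestorBundle, cfg: SimConfig | None = None):
    """A deeply diverged genome for the lineage-specificity test.

    Carries the marker gene (unless has_marker is off). When has_ortholog
    is set, a diverged copy of the first domesticated gene is planted
    `ortholog_distance_bp` downstream of the marker; otherwise the only
    RT-related sequence is a partial relic on the other contig.
    Returns (genome, marker_locus Feature or None).
    """
    cfg = cfg or ancestor.cfg
    og = cfg.outgroup
    kappa = cfg.divergence.ts_tv
    rng = np.random.default_rng(cfg.seed + 103)
    segs = _evolve_segments(
        ancestor.segments,
        rng,
        og.neutral_rate,
        kappa,
        coding_rate=og.coding_rate,
        drop_classes=frozenset({"domesticated", "decoy_known"}),
        destroy_marker=not og.has_marker,
    )
    # a partial RT relic far from the marker (different contig)
    rt_cds = random_coding(
        rng, mutate_peptide(rng, ancestor.seeds.consensus["RT_spuma_like"], 0.10)
    )
    segs["chr2"].append(_Segment("bg", random_nt(rng, 1500)))
    segs["chr2"].append(_Segment("stop", "TAA"))
    segs["chr2"].append(_Segment("cds", rt_cds, "+", None, "outgroup_rt_relic", ""))
    segs["chr2"].append(_Segment("stop", "TAA"))
    segs["chr2"].append(_Segment("bg", random_nt(rng, 1000)))
    if og.has_ortholog:
        ortho = evolve_coding(
            rng, ancestor.prototypes["RTOM1"], og.coding_rate, cfg.domesticated.omega, kappa
        )
        insert = [
            _Segment("bg", random_nt(rng, max(og.ortholog_distance_bp, 100))),
            _Segment("stop", revcomp("TAA")),
            _Segment("cds", revcomp(ortho), "-", None, "outgroup_ortholog", ""),
            _Segment("stop", revcomp("TAA")),
        ]
        # place right after the last marker exon on chr1
        idx = max(
            i for i, s in enumerate(segs["chr1"]) if s.element_class == "marker_gene"
        )
        segs["chr1"] = segs["chr1"][: idx + 1] + insert + segs["chr1"][idx + 1 :]
    genome, features, _truth = _assemble(segs, "outgroup", False)
    marker = next((f for f in features if f.kind == "gene" and f.name == "GRIP2"), None)
    return genome, marker


def simulate_rt_tree_replicate(cfg: SimConfig, seed: int) -> tuple[dict, str]:
    """One duplication-before-speciation replicate at the RT-peptide level.

    Returns ({label: RT peptide}, outgroup_label): the domesticated
    prototype is duplicated into n_copies paralogs (deep divergence), each
    paralog then speciates into _A/_B copies (shallow divergence); the RT
    seed consensus serves as the tree outgroup. All peptides are the same
    length (indel-free), so they are trivially aligned.
    """
    rng = np.random.default_rng(seed)
    seeds = _make_seeds(rng, cfg)
    dom = cfg.domesticated
    proto, _ = _domesticated_prototype(rng, cfg, seeds.consensus["RT_spuma_like"])
    rt_lo = dom.orf_length_nt // 3 - dom.rt_length_aa
    branch = cfg.divergence.branch_length_syn / 2.0
    kappa = cfg.divergence.ts_tv
    peps: dict[str, str] = {}
    for k in range(dom.n_copies):
        cds_k = evolve_coding(rng, proto, dom.paralog_divergence, dom.omega, kappa)
        for sp in ("A", "B"):
            cds = evolve_coding(rng, cds_k, branch, dom.omega, kappa)
            peps[f"RTOM{k + 1}_{sp}"] = translate(cds)[rt_lo:]
    outgroup_label = "RT_seed_consensus"
    peps[outgroup_label] = seeds.consensus["RT_spuma_like"]
    return peps, outgroup_label


def simulate_pair(cfg: SimConfig):
    """Convenience wrapper: ancestor -> (pair, outgroup or None, bundle)."""
    bundle = simulate_ancestor(cfg)
    pair = speciate(bundle, cfg)
    outgroup = make_outgroup(bundle, cfg) if cfg.outgroup.present else None
    return pair, outgroup, bundle
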