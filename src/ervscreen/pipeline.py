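"""One-call orchestration of the full screen and downstream analyses.

Stage order: ORF extraction -> profile-HMM domain scan -> identity
clustering / cluster-size filter -> cross-species pairing -> known-gene
exclusion -> lineage specificity -> selection statistics -> tree ->
self-dotplot. Every stage only removes candidates, every threshold lives
in PipelineConfig, and the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    conservation_screen as screen_mod,
    identity_clustering,
    orf_extraction,
    phylo,
    profile_hmm,
    selection_stats,
    similarity_search,
    synthetic_data,
)
from .genome_io import Feature, Genome, SeqRecord, write_fasta, write_gff

__all__ = ["PipelineConfig", "RunReport", "ScreenInputs", "run_screen", "run_validation_mode", "pairwise_poisson_matrix"]


@dataclass
class PipelineConfig:
    """Every tunable of the screen, with the standard defaults."""

    min_len_nt: int = 240  # minimum stop-flanked ORF length
    hmm_evalue: float = 1e-5  # domain scan threshold
    cluster_identity: float = 0.5  # greedy clustering identity
    max_cluster_size: int = 10  # clusters larger than this are discarded
    pair_evalue: float = 1e-50  # cross-species pairing E-value
    pair_bitscore_min: float = 200.0  # fixed bitscore cut
    pair_bitscore_auto: bool = False  # largest-gap rule instead of the fixed cut
    known_evalue: float = 1e-5  # known-protein exclusion threshold
    outgroup_evalue: float = 1e-5  # translated search threshold
    cover_min: float = 0.6  # query cover for an outgroup ortholog
    proximity_max: int = 1_000_000  # bp between hit and marker locus
    dotplot_k: int = 12
    calib_n_random: int = 1000
    calib_len: int = 400
    n_boot: int = 1000  # Z-test bootstrap replicates
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cluster_identity <= 1 and 0 < self.cover_min <= 1):
            raise ValueError("identity/cover thresholds must lie in (0, 1]")
        if self.min_len_nt <= 0 or self.min_len_nt % 3:
            raise ValueError("min_len_nt must be positive and divisible by 3")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ScreenInputs:
    genome_a: Genome
    genome_b: Genome
    features_a: list
    features_b: list
    seed_alignments: dict  # profile name -> list[SeqRecord]
    exclusion_names: list
    known_protein_db: list  # SeqRecord peptides of known genes
    outgroups: list  # (Genome, marker Feature or None)
    marker_protein: str
    tree_outgroup_seq: Optional[SeqRecord] = None  # roots the candidate tree

    @classmethod
    def from_simulation(cls, cfg: synthetic_data.SimConfig) -> tuple["ScreenInputs", object]:
        """Build screen inputs from the synthetic generator; returns
        (inputs, SpeciesPair) so the truth table stays available."""
        pair, outgroup, bundle = synthetic_data.simulate_pair(cfg)
        marker_protein = (
            synthetic_data.translate(bundle.prototypes["GRIP2_exon1"])
            + synthetic_data.translate(bundle.prototypes["GRIP2_exon2"])
        )
        known_db = []
        if cfg.decoy_known_gene:
            known_db.append(
                SeqRecord(
                    id="ASPRV1_known",
                    seq=synthetic_data.translate(bundle.prototypes["ASPRV1"]),
                )
            )
        rt_cons = bundle.seeds.consensus["RT_spuma_like"]
        inputs = cls(
            genome_a=pair.genome_a,
            genome_b=pair.genome_b,
            features_a=pair.features_a,
            features_b=pair.features_b,
            seed_alignments=bundle.seeds.alignments,
            exclusion_names=["ASPRV1"],
            known_protein_db=known_db,
            outgroups=[outgroup] if outgroup is not None else [],
            marker_protein=marker_protein,
            tree_outgroup_seq=SeqRecord(id="RT_seed_consensus", seq=rt_cons),
        )
        return inputs, pair


@dataclass
class RunReport:
    stage_counts: dict
    candidates: list  # final CandidatePair list
    verdicts: list  # SpecificityVerdict per candidate x outgroup
    selection: pd.DataFrame
    tree: Optional[phylo.Tree]
    gene_pair_monophyly: dict  # candidate_id -> bool
    dotplot: list
    motif_table: dict
    log: list = field(default_factory=list)

    def candidate_table(self) -> pd.DataFrame:
        rows = []
        for pair in self.candidates:
            rows.append(
                {
                    "candidate_id": pair.candidate_id,
                    "orf_a": pair.orf_a.orf_id,
                    "orf_b": pair.orf_b.orf_id,
                    "bitscore": round(pair.alignment.bitscore, 1),
                    "evalue": pair.alignment.evalue,
                    "filters": ";".join(f"{f}:{v}" for f, v, _ in pair.passed_filters),
                    "verdicts": ";".join(
                        v.verdict for v in self.verdicts if v.candidate_id == pair.candidate_id
                    ),
                }
            )
        return pd.DataFrame(rows)


def pairwise_poisson_matrix(seqs: dict[str, str]) -> phylo.DistanceMatrix:
    """Poisson distances from pairwise global alignments (free end gaps).

    Used when no multiple alignment is available: p is the mismatch
    fraction over pairwise-aligned residue columns.
    """
    labels = sorted(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            if len(a) == len(b):
                p_cols = [(x, y) for x, y in zip(a, b)]
            else:
                aln = identity_clustering._aligner().align(a, b)[0]
                p_cols = []
                for (ab, bb) in zip(*aln.aligned):
                    for off in range(ab[1] - ab[0]):
                        p_cols.append((a[ab[0] + off], b[bb[0] + off]))
            if not p_cols:
                raise ValueError(f"unalignable pair {labels[i]}, {labels[j]}")
            p = sum(1 for x, y in p_cols if x != y) / len(p_cols)
            p = min(p, 0.95)  # saturation guard
            d[i, j] = d[j, i] = -math.log1p(-p)
    return phylo.DistanceMatrix(labels, d)


def _scan_stage(inputs: ScreenInputs, cfg: PipelineConfig, orfs, log):
    profiles = []
    for name, aln in sorted(inputs.seed_alignments.items()):
        p = profile_hmm.build_profile(aln, name=name)
        profile_hmm.calibrate(p, cfg.calib_n_random, cfg.calib_len, seed=cfg.seed)
        profiles.append(p)
    survivors = {}
    for species, orf_list in orfs.items():
        records = orf_extraction.orf_to_fasta(orf_list, "aa")
        hits = profile_hmm.scan(profiles, records, cfg.hmm_evalue)
        hit_ids = {h.seq_id for h in hits}
        survivors[species] = [o for o in orf_list if o.orf_id in hit_ids]
        log.append(f"scan[{species}]: {len(orf_list)} ORFs -> {len(survivors[species])} with domain hits")
    return profiles, survivors


def _cluster_stage(survivors, cfg: PipelineConfig, log):
    out = {}
    for species, orf_list in survivors.items():
        records = orf_extraction.orf_to_fasta(orf_list, "aa")
        clusters = identity_clustering.greedy_cluster(records, cfg.cluster_identity)
        keep = identity_clustering.filter_large_clusters(clusters, cfg.max_cluster_size)
        out[species] = [o for o in orf_list if o.orf_id in keep]
        log.append(
            f"cluster[{species}]: {len(clusters)} clusters; "
            f"{len(orf_list) - len(out[species])} ORFs removed in clusters > {cfg.max_cluster_size}"
        )
    return out


def run_screen(
    inputs: ScreenInputs, cfg: PipelineConfig | None = None, outdir: str | Path | None = None
) -> RunReport:
    """Execute the full screen; optionally write all intermediates."""
    cfg = cfg or PipelineConfig()
    log: list[str] = []
    counts: dict[str, int] = {}
    scheme = similarity_search.DEFAULT_SCHEME

    orfs = {
        "A": orf_extraction.extract_orfs(inputs.genome_a, cfg.min_len_nt),
        "B": orf_extraction.extract_orfs(inputs.genome_b, cfg.min_len_nt),
    }
    counts["orfs_A"], counts["orfs_B"] = len(orfs["A"]), len(orfs["B"])

    profiles, survivors = _scan_stage(inputs, cfg, orfs, log)
    counts["domain_A"], counts["domain_B"] = len(survivors["A"]), len(survivors["B"])

    clustered = _cluster_stage(survivors, cfg, log)
    counts["clustered_A"], counts["clustered_B"] = len(clustered["A"]), len(clustered["B"])

    bitscore_min = cfg.pair_bitscore_min
    if cfg.pair_bitscore_auto:
        pre = screen_mod.pair_cross_species(
            clustered["A"], clustered["B"], scheme, cfg.pair_evalue, bitscore_min=0.0
        )
        bitscore_min = screen_mod.auto_bitscore_cutoff([p.alignment.bitscore for p in pre])
        log.append(f"auto bitscore cutoff: {bitscore_min:.1f}")
    pairs = screen_mod.pair_cross_species(
        clustered["A"], clustered["B"], scheme, cfg.pair_evalue, bitscore_min
    )
    counts["paired"] = len(pairs)

    pairs = screen_mod.exclude_annotated(
        pairs,
        inputs.features_a,
        inputs.features_b,
        inputs.exclusion_names,
        inputs.known_protein_db,
        scheme,
        cfg.known_evalue,
    )
    counts["after_known_gene_exclusion"] = len(pairs)

    verdicts = []
    for pair in pairs:
        vs = screen_mod.lineage_specificity(
            pair,
            inputs.outgroups,
            inputs.marker_protein,
            scheme,
            cfg.cover_min,
            cfg.proximity_max,
            cfg.outgroup_evalue,
        )
        verdicts.extend(vs)
        if vs and all(v.verdict == "lineage_specific" for v in vs):
            pair.log("lineage_specificity", "lineage_specific", "")
        elif not vs:
            pair.log("lineage_specificity", "untested", "no outgroups supplied")
        else:
            pair.log("lineage_specificity", ";".join(v.verdict for v in vs), "")
    counts["final_candidates"] = len(pairs)

    sel_rows = []
    for i, pair in enumerate(pairs):
        res = selection_stats.analyze_pair(
            pair.orf_a.nt_seq, pair.orf_b.nt_seq, n_boot=cfg.n_boot, seed=cfg.seed + i
        )
        sel_rows.append(
            {
                "candidate_id": pair.candidate_id,
                "L_codons": res.n_codons,
                "dN": res.dN,
                "dS": res.dS,
                "dNdS": res.dnds,
                "var_dN": res.var_dN,
                "var_dS": res.var_dS,
                "Z": res.Z,
                "p": res.p_value,
                "percent_identity": res.percent_identity,
            }
        )
    selection = pd.DataFrame(sel_rows)

    tree = None
    mono: dict[str, bool] = {}
    if len(pairs) >= 1 and inputs.tree_outgroup_seq is not None and len(pairs) * 2 + 1 >= 3:
        seqs = {}
        for pair in pairs:
            seqs[f"A|{pair.orf_a.orf_id}"] = pair.orf_a.aa_seq
            seqs[f"B|{pair.orf_b.orf_id}"] = pair.orf_b.aa_seq
        seqs[inputs.tree_outgroup_seq.id] = inputs.tree_outgroup_seq.seq
        dm = pairwise_poisson_matrix(seqs)
        tree = phylo.nj_tree(dm)
        for pair in pairs:
            mono[pair.candidate_id] = phylo.is_monophyletic(
                tree,
                {f"A|{pair.orf_a.orf_id}", f"B|{pair.orf_b.orf_id}"},
                inputs.tree_outgroup_seq.id,
            )

    dotplot: list = []
    if pairs:
        contig = pairs[0].orf_a.contig_id
        lo = min(p.orf_a.start for p in pairs if p.orf_a.contig_id == contig)
        hi = max(p.orf_a.end for p in pairs if p.orf_a.contig_id == contig)
        margin = 500
        lo = max(1, lo - margin)
        hi = min(len(inputs.genome_a[contig].seq), hi + margin)
        locus = inputs.genome_a[contig].seq[lo - 1 : hi]
        dotplot = similarity_search.self_dotplot(locus, cfg.dotplot_k)
        log.append(f"dotplot: locus {contig}:{lo}-{hi}, {len(dotplot)} k-mer matches")

    motifs = [("RT_catalytic", synthetic_data.CATALYTIC_MOTIF)]
    motif_table = {
        pair.candidate_id: screen_mod.motif_check(pair.orf_a.aa_seq, motifs)
        for pair in pairs
    }

    report = RunReport(
        stage_counts=counts,
        candidates=pairs,
        verdicts=verdicts,
        selection=selection,
        tree=tree,
        gene_pair_monophyly=mono,
        dotplot=dotplot,
        motif_table=motif_table,
        log=log,
    )
    if outdir is not None:
        _write_report(report, inputs, cfg, orfs, Path(outdir))
    return report


def _write_report(report: RunReport, inputs: ScreenInputs, cfg: PipelineConfig, orfs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    for sp, orf_list in orfs.items():
        write_fasta(orf_extraction.orf_to_fasta(orf_list, "aa"), outdir / f"orfs_{sp}.faa")
        orf_extraction.orf_table(orf_list).to_csv(outdir / f"orfs_{sp}.tsv", sep="\t", index=False)
    report.candidate_table().to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    report.selection.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    if report.tree is not None:
        (outdir / "candidates.nwk").write_text(report.tree.newick + "\n")
    pd.DataFrame(
        report.dotplot, columns=["i", "j", "strand"] if report.dotplot else None
    ).to_csv(outdir / "dotplot.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "candidate_id": v.candidate_id,
                "outgroup": v.outgroup_genome_id,
                "n_cover_hits": v.n_cover_hits,
                "min_marker_distance": v.min_marker_distance,
                "verdict": v.verdict,
            }
            for v in report.verdicts
        ]
    ).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    (outdir / "stage_counts.tsv").write_text(
        "\n".join(f"{k}\t{v}" for k, v in report.stage_counts.items()) + "\n"
    )
    (outdir / "screen.log").write_text("\n".join(report.log) + "\n")


def run_validation_mode(report: RunReport, truth: synthetic_data.TruthTable) -> pd.DataFrame:
    """Compare the final report against a truth table of planted genes.

    A planted gene is recovered when a final candidate ORF (species A)
    overlaps its coordinates; the decoy is correctly excluded when no
    final candidate overlaps it.
    """
    rows = []
    for entry in truth.of_class("domesticated", "species_A"):
        hit = any(
            p.orf_a.contig_id == entry.contig
            and p.orf_a.start <= entry.end
            and entry.start <= p.orf_a.end
            for p in report.candidates
        )
        rows.append({"name": entry.name, "class": entry.element_class, "recovered": hit})
    for entry in truth.of_class("decoy_known", "species_A"):
        hit = any(
            p.orf_a.contig_id == entry.contig
            and p.orf_a.start <= entry.end
            and entry.start <= p.orf_a.end
            for p in report.candidates
        )
        rows.append({"name": entry.name, "class": entry.element_class, "recovered": hit})
    for entry in truth.of_class("young_erv", "species_A"):
        hit = any(
            p.orf_a.contig_id == entry.contig
            and p.orf_a.start <= entry.end
            and entry.start <= p.orf_a.end
            for p in report.candidates
        )
        rows.append({"name": entry.name, "class": entry.element_class, "recovered": hit})
    return pd.DataFrame(rows)
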