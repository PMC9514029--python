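import dataclasses

import numpy as np
import pytest

from ervscreen.genome_io import Feature, SeqRecord
from ervscreen.orf_extraction import OrfRecord
from ervscreen import conservation_screen as cs
from ervscreen import synthetic_data as sd
from ervscreen.pipeline import PipelineConfig, ScreenInputs, run_screen


def _orf(orf_id, contig="c1", start=100, seq=None, strand="+"):
    nt = seq
    from ervscreen.genome_io import translate

    return OrfRecord(
        orf_id=orf_id,
        contig_id=contig,
        start=start,
        end=start + len(nt) - 1,
        strand=strand,
        frame=0,
        nt_seq=nt,
        aa_seq=translate(nt),
    )


@pytest.fixture(scope="module")
def conserved_orf_sets():
    """Three diverged ortholog pairs plus one unpaired ORF per species."""
    rng = np.random.default_rng(0)
    orfs_a, orfs_b = [], []
    for k in range(3):
        anc = sd.random_coding(rng, sd.random_peptide(rng, 200))
        orfs_a.append(_orf(f"a{k}", start=1000 * (k + 1), seq=sd.evolve_coding(rng, anc, 0.08, 0.1, 2.0)))
        orfs_b.append(_orf(f"b{k}", start=1000 * (k + 1), seq=sd.evolve_coding(rng, anc, 0.08, 0.1, 2.0)))
    orfs_a.append(_orf("a_solo", start=9000, seq=sd.random_coding(rng, sd.random_peptide(rng, 150))))
    orfs_b.append(_orf("b_solo", start=9000, seq=sd.random_coding(rng, sd.random_peptide(rng, 150))))
    return orfs_a, orfs_b


class TestPairing:
    def test_planted_triple_yields_three_pairs(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        pairs = cs.pair_cross_species(orfs_a, orfs_b)
        assert len(pairs) == 3
        assert {(p.orf_a.orf_id, p.orf_b.orf_id) for p in pairs} == {
            ("a0", "b0"), ("a1", "b1"), ("a2", "b2"),
        }

    def test_empty_inputs_propagate(self):
        assert cs.pair_cross_species([], []) == []

    def test_bitscore_filter_monotone(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        loose = {p.candidate_id for p in cs.pair_cross_species(orfs_a, orfs_b, bitscore_min=0)}
        strict = {p.candidate_id for p in cs.pair_cross_species(orfs_a, orfs_b, bitscore_min=200)}
        assert strict <= loose

    def test_each_subject_used_once(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        # duplicate a query: both cannot claim the same subject
        pairs = cs.pair_cross_species(orfs_a + [dataclasses.replace(orfs_a[0], orf_id="a0bis")], orfs_b)
        used_b = [p.orf_b.orf_id for p in pairs]
        assert len(used_b) == len(set(used_b))

    def test_auto_bitscore_cutoff_splits_largest_gap(self):
        assert cs.auto_bitscore_cutoff([10, 12, 11, 300, 310]) == pytest.approx(156.0)
        assert cs.auto_bitscore_cutoff([1.0]) == 0.0


class TestExcludeAnnotated:
    def test_overlapping_excluded_gene_removed(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        pairs = cs.pair_cross_species(orfs_a, orfs_b)
        feats = [Feature("c1", 900, 1500, "+", "gene", "ASPRV1")]
        kept = cs.exclude_annotated(pairs, feats, [], exclusion_names=["ASPRV1"])
        assert {p.orf_a.orf_id for p in kept} == {"a1", "a2"}
        removed = next(p for p in pairs if p.orf_a.orf_id == "a0")
        assert any(v == "removed" for _, v, _ in removed.passed_filters)

    def test_intron_of_unlisted_gene_retained(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        pairs = cs.pair_cross_species(orfs_a, orfs_b)
        feats = [Feature("c1", 1, 50_000, "+", "gene", "GRIP2")]
        kept = cs.exclude_annotated(pairs, feats, [], exclusion_names=["ASPRV1"])
        assert len(kept) == len(pairs)

    def test_known_protein_hit_removed(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        pairs = cs.pair_cross_species(orfs_a, orfs_b)
        db = [SeqRecord("known", pairs[0].orf_a.aa_seq)]
        kept = cs.exclude_annotated(pairs, [], [], known_protein_db=db)
        assert len(kept) == len(pairs) - 1

    def test_empty_exclusions_identity(self, conserved_orf_sets):
        orfs_a, orfs_b = conserved_orf_sets
        pairs = cs.pair_cross_species(orfs_a, orfs_b)
        assert cs.exclude_annotated(pairs, [], []) == pairs


@pytest.fixture(scope="module")
def sim():
    cfg = sd.SimConfig(seed=21)
    bundle = sd.simulate_ancestor(cfg)
    pair = sd.speciate(bundle, cfg)
    return cfg, bundle, pair


class TestLineageSpecificity:
    def _candidate(self, bundle, pair):
        entry = pair.truth.of_class("domesticated", "species_A")[0]
        seq = pair.genome_a[entry.contig].seq[entry.start - 1 : entry.end]
        from ervscreen.genome_io import revcomp, translate

        nt = revcomp(seq)
        orf = OrfRecord(
            orf_id="cand", contig_id=entry.contig, start=entry.start, end=entry.end,
            strand="-", frame=0, nt_seq=nt, aa_seq=translate(nt),
        )
        import ervscreen.similarity_search as sim_mod

        aln = sim_mod.smith_waterman(orf.aa_seq, orf.aa_seq)
        aln.bitscore, aln.evalue = sim_mod.bit_and_evalue(aln.raw_score, len(orf.aa_seq), 10_000)
        return cs.CandidatePair(orf_a=orf, orf_b=orf, alignment=aln)

    def _marker_protein(self, bundle):
        from ervscreen.genome_io import translate

        return translate(bundle.prototypes["GRIP2_exon1"]) + translate(
            bundle.prototypes["GRIP2_exon2"]
        )

    def test_outgroup_without_ortholog_is_lineage_specific(self, sim):
        cfg, bundle, pair = sim
        outgroup = sd.make_outgroup(bundle, cfg)
        (v,) = cs.lineage_specificity(
            self._candidate(bundle, pair), [outgroup], self._marker_protein(bundle)
        )
        assert v.verdict == "lineage_specific"

    def test_outgroup_with_ortholog_found(self, sim):
        cfg, bundle, pair = sim
        cfg2 = sd.SimConfig(seed=21)
        cfg2.outgroup = dataclasses.replace(cfg2.outgroup, has_ortholog=True)
        outgroup = sd.make_outgroup(bundle, cfg2)
        (v,) = cs.lineage_specificity(
            self._candidate(bundle, pair), [outgroup], self._marker_protein(bundle)
        )
        assert v.verdict == "ortholog_found"

    def test_outgroup_without_marker(self, sim):
        cfg, bundle, pair = sim
        cfg2 = sd.SimConfig(seed=21)
        cfg2.outgroup = dataclasses.replace(cfg2.outgroup, has_marker=False)
        outgroup = sd.make_outgroup(bundle, cfg2)
        (v,) = cs.lineage_specificity(
            self._candidate(bundle, pair), [outgroup], self._marker_protein(bundle)
        )
        assert v.verdict == "marker_absent"

    def test_no_outgroups_gives_no_verdicts(self, sim):
        cfg, bundle, pair = sim
        assert cs.lineage_specificity(
            self._candidate(bundle, pair), [], self._marker_protein(bundle)
        ) == []


class TestMotifCheck:
    def test_canonical_rt_motif_present(self):
        table = cs.motif_check("GGYVDDGG", [("rt", "YXDD")])
        assert table["rt"] == (True, [3])

    def test_absent_when_no_aspartates(self):
        table = cs.motif_check("GGGYVNNGG", [("rt", "YXDD")])
        assert table["rt"][0] is False

    def test_ablated_domesticated_peptides_lack_motif(self):
        bundle = sd.simulate_ancestor(sd.SimConfig(seed=2))
        from ervscreen.genome_io import revcomp, translate

        for entry in bundle.truth.of_class("domesticated"):
            seq = bundle.genome[entry.contig].seq[entry.start - 1 : entry.end]
            aa = translate(revcomp(seq))
            present, _ = cs.motif_check(aa, [("rt", sd.CATALYTIC_MOTIF)])["rt"]
            assert present is entry.catalytic_motif_present

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError):
            cs.motif_check("MKV", [("bad", "((")])
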