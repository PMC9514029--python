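import dataclasses

import numpy as np
import pytest

from ervscreen.genome_io import STOP_CODONS, revcomp, translate
from ervscreen import synthetic_data as sd


@pytest.fixture(scope="module")
def bundle():
    return sd.simulate_ancestor(sd.SimConfig(seed=3))


@pytest.fixture(scope="module")
def species_pair(bundle):
    return sd.speciate(bundle)


def _planted_cds(genome, entry):
    fwd = genome[entry.contig].seq[entry.start - 1 : entry.end]
    return fwd if entry.strand == "+" else revcomp(fwd)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a1, _, _ = sd.simulate_pair(sd.SimConfig(seed=5))
        a2, _, _ = sd.simulate_pair(sd.SimConfig(seed=5))
        for g1, g2 in ((a1.genome_a, a2.genome_a), (a1.genome_b, a2.genome_b)):
            assert [c.seq for c in g1] == [c.seq for c in g2]
        assert a1.truth.to_dataframe().equals(a2.truth.to_dataframe())

    def test_different_seed_differs(self):
        a1, _, _ = sd.simulate_pair(sd.SimConfig(seed=5))
        a2, _, _ = sd.simulate_pair(sd.SimConfig(seed=6))
        assert a1.genome_a["chr1"].seq != a2.genome_a["chr1"].seq


class TestAncestor:
    def test_truth_table_bookkeeping(self, bundle):
        cfg = bundle.cfg
        assert len(bundle.truth.of_class("young_erv")) == cfg.young_family.copy_number
        assert len(bundle.truth.of_class("domesticated")) == cfg.domesticated.n_copies
        assert len(bundle.truth.of_class("decoy_known")) == 1

    def test_coordinates_index_planted_sequences(self, bundle):
        for entry in bundle.truth.of_class("domesticated"):
            cds = _planted_cds(bundle.genome, entry)
            assert cds == bundle.prototypes[entry.name]
            aa = translate(cds)
            assert "*" not in aa

    def test_planted_orfs_are_stop_flanked(self, bundle):
        for cls in ("domesticated", "young_erv", "decoy_known"):
            for entry in bundle.truth.of_class(cls):
                seq = bundle.genome[entry.contig].seq
                if entry.strand == "+":
                    left = seq[entry.start - 4 : entry.start - 1]
                    right = seq[entry.end : entry.end + 3]
                else:
                    left = revcomp(seq[entry.end : entry.end + 3])
                    right = revcomp(seq[entry.start - 4 : entry.start - 1])
                assert left in STOP_CODONS and right in STOP_CODONS

    def test_young_family_ancestral_identity(self, bundle):
        cfg = bundle.cfg
        entries = bundle.truth.of_class("young_erv")
        seqs = [_planted_cds(bundle.genome, e) for e in entries]
        rng = np.random.default_rng(0)
        for _ in range(30):
            i, j = rng.choice(len(seqs), 2, replace=False)
            ident = np.mean([x == y for x, y in zip(seqs[i], seqs[j])])
            assert ident >= cfg.young_family.intra_identity - 0.01

    def test_domesticated_inside_marker_intron_opposite_strand(self, bundle):
        marker = bundle.truth.of_class("marker_gene")
        gene = next(e for e in marker if e.name == "GRIP2")
        exons = [e for e in marker if e.name != "GRIP2"]
        for entry in bundle.truth.of_class("domesticated"):
            assert entry.strand == "-"
            assert gene.start <= entry.start and entry.end <= gene.end
            assert not any(
                entry.start <= ex.end and ex.start <= entry.end for ex in exons
            )

    def test_catalytic_motif_ablated_by_default(self, bundle):
        for entry in bundle.truth.of_class("domesticated"):
            assert entry.catalytic_motif_present is False
            aa = translate(_planted_cds(bundle.genome, entry))
            assert sd.ABLATED_MOTIF in aa


class TestSpeciation:
    def test_coordinates_lift_over_and_stay_coding(self, species_pair):
        for genome, species in (
            (species_pair.genome_a, "species_A"),
            (species_pair.genome_b, "species_B"),
        ):
            for entry in species_pair.truth.of_class("domesticated", species):
                aa = translate(_planted_cds(genome, entry))
                assert "*" not in aa

    def test_species_diverged_but_related(self, species_pair, bundle):
        a = species_pair.genome_a["chr1"].seq
        b = species_pair.genome_b["chr1"].seq
        assert a != b
        p = np.mean([x != y for x, y in zip(a, b)])
        ds = bundle.cfg.divergence.branch_length_syn
        assert 0.3 * ds < p < 2.0 * ds  # neutral divergence near the configured dS

    def test_ortholog_links_cross_species(self, species_pair):
        for entry in species_pair.truth.of_class("domesticated", "species_A"):
            assert entry.ortholog_of == f"species_B:{entry.name}"

    def test_omega_zero_keeps_peptides_identical(self):
        cfg = sd.SimConfig(seed=11)
        cfg.domesticated = dataclasses.replace(cfg.domesticated, omega=1e-12)
        pair = sd.speciate(sd.simulate_ancestor(cfg), cfg)
        a_entry = pair.truth.of_class("domesticated", "species_A")[0]
        b_entry = next(
            e for e in pair.truth.of_class("domesticated", "species_B") if e.name == a_entry.name
        )
        aa_a = translate(_planted_cds(pair.genome_a, a_entry))
        aa_b = translate(_planted_cds(pair.genome_b, b_entry))
        assert aa_a == aa_b
        nt_a = _planted_cds(pair.genome_a, a_entry)
        nt_b = _planted_cds(pair.genome_b, b_entry)
        assert nt_a != nt_b  # synonymous divergence still happened

    def test_zero_branch_length_returns_ancestor(self):
        cfg = sd.SimConfig(seed=12)
        cfg.divergence = dataclasses.replace(cfg.divergence, branch_length_syn=0.0)
        bundle = sd.simulate_ancestor(cfg)
        pair = sd.speciate(bundle, cfg)
        assert pair.genome_a["chr1"].seq == bundle.genome["chr1"].seq
        assert pair.genome_b["chr2"].seq == bundle.genome["chr2"].seq


class TestOutgroup:
    def test_marker_present_domesticated_absent(self, bundle):
        genome, marker = sd.make_outgroup(bundle)
        assert marker is not None and marker.name == "GRIP2"
        # the domesticated prototype must not survive anywhere in the outgroup
        for entry in bundle.truth.of_class("domesticated"):
            assert bundle.prototypes[entry.name] not in genome["chr1"].seq

    def test_no_marker_variant(self, bundle):
        cfg = sd.SimConfig(seed=3)
        cfg.outgroup = dataclasses.replace(cfg.outgroup, has_marker=False)
        genome, marker = sd.make_outgroup(bundle, cfg)
        assert marker is None


class TestEvolutionPrimitives:
    def test_evolve_coding_never_creates_stops(self):
        rng = np.random.default_rng(1)
        cds = sd.random_coding(rng, sd.random_peptide(rng, 200))
        out = sd.evolve_coding(rng, cds, 0.5, 1.0, 2.0)
        assert "*" not in translate(out)

    def test_evolve_coding_omega_limits_nonsynonymous(self):
        rng = np.random.default_rng(2)
        pep = sd.random_peptide(rng, 500)
        cds = sd.random_coding(rng, pep)
        out = sd.evolve_coding(rng, cds, 0.2, 0.01, 2.0)
        aa_changes = sum(1 for x, y in zip(pep, translate(out)) if x != y)
        nt_changes = sum(1 for x, y in zip(cds, out) if x != y)
        assert nt_changes > 50  # synonymous divergence accumulated
        assert aa_changes <= 5

    def test_frozen_range_protected(self):
        rng = np.random.default_rng(3)
        pep = sd.random_peptide(rng, 100)
        cds = sd.random_coding(rng, pep)
        out = sd.evolve_coding(rng, cds, 1.0, 1.0, 2.0, frozen_aa=(40, 50))
        assert translate(out)[40:50] == pep[40:50]

    def test_mutate_neutral_rate(self):
        rng = np.random.default_rng(4)
        seq = sd.random_nt(rng, 20_000)
        out = sd.mutate_neutral(rng, seq, 0.1, 2.0)
        p = np.mean([x != y for x, y in zip(seq, out)])
        assert 0.08 < p < 0.12

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.SimConfig(young_family=sd.YoungFamilyConfig(intra_identity=1.5))
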