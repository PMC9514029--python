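import itertools
import math

import numpy as np
import pytest

from ervscreen.genome_io import SeqRecord
from ervscreen import profile_hmm as ph
from ervscreen import synthetic_data as sd

from oracles import viterbi_bruteforce


def toy_profile(M, seed=0, n_seqs=4, alphabet="ACDE"):
    rng = np.random.default_rng(seed)
    recs = [
        SeqRecord(id=f"s{k}", seq="".join(rng.choice(list(alphabet), M)))
        for k in range(n_seqs)
    ]
    return ph.build_profile(recs, name=f"toy{M}")


class TestBuildProfile:
    def test_single_sequence_max_mass_on_observed(self):
        p = ph.build_profile([SeqRecord("s", "ACDEF")])
        assert p.M == 5
        for k, aa in enumerate("ACDEF"):
            assert np.argmax(p.match_emissions[k]) == ph._AA_INDEX[aa]

    def test_duplicate_sequence_idempotent(self):
        p1 = ph.build_profile([SeqRecord("s", "ACDEF")])
        p2 = ph.build_profile([SeqRecord("a", "ACDEF"), SeqRecord("b", "ACDEF")])
        assert p1.M == p2.M
        # same argmax structure; emission mass only sharpens
        assert (
            np.argmax(p1.match_emissions, axis=1) == np.argmax(p2.match_emissions, axis=1)
        ).all()

    def test_gappy_column_becomes_insert(self):
        recs = [
            SeqRecord("a", "AC-DF"),
            SeqRecord("b", "AC-DF"),
            SeqRecord("c", "ACWDF"),
        ]
        p = ph.build_profile(recs)
        assert p.M == 4  # the 1/3-occupancy column is not a match state

    def test_half_occupancy_is_match(self):
        recs = [SeqRecord("a", "A-C"), SeqRecord("b", "AWC")]
        assert ph.build_profile(recs).M == 3

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            ph.build_profile([])

    def test_probability_rows_normalized(self):
        p = toy_profile(6, seed=3)
        assert np.allclose(p.match_emissions.sum(axis=1), 1.0)
        assert math.isclose(p.background.sum(), 1.0)


class TestViterbi:
    def test_self_hit_is_maximal_over_alternatives(self):
        p = ph.build_profile([SeqRecord("s", "ACDEF")])
        self_score = ph.viterbi_local(p, "ACDEF")
        assert ph.viterbi_local(p, "PPPPP") <= self_score

    @pytest.mark.parametrize("M", [1, 2, 3, 4])
    def test_equals_bruteforce_enumeration(self, M):
        p = toy_profile(M, seed=M)
        rng = np.random.default_rng(100 + M)
        peptides = ["".join(t) for t in itertools.product("ACDE", repeat=2)]
        peptides += ["".join(rng.choice(list("ACDE"), int(rng.integers(3, 7)))) for _ in range(40)]
        for pep in peptides:
            assert ph.viterbi_local(p, pep) == pytest.approx(
                viterbi_bruteforce(p, pep), abs=1e-9
            )

    def test_unknown_residue_scores_background(self):
        p = toy_profile(3)
        s1 = ph.viterbi_local(p, "XXX")
        # all-unknown peptide: emissions 0 bits, best is entry + single match
        assert s1 == pytest.approx(-math.log2(p.M), abs=1e-9)

    def test_span_covers_planted_consensus(self):
        rng = np.random.default_rng(5)
        cons = sd.random_peptide(rng, 30)
        p = ph.build_profile(
            [SeqRecord("c", cons)]
            + [SeqRecord(f"v{k}", sd.mutate_peptide(rng, cons, 0.15)) for k in range(4)]
        )
        pep = sd.random_peptide(rng, 40) + cons + sd.random_peptide(rng, 40)
        score, (s, e) = ph.viterbi_local(p, pep, with_span=True)
        assert score > 20
        assert s >= 35 and e <= 115  # span stays in the planted neighborhood

    def test_batch_scores_match_single(self):
        p = toy_profile(5, seed=9, alphabet="ACDEFGHIK")
        rng = np.random.default_rng(2)
        peps = ["".join(rng.choice(list("ACDEFGHIK"), 12)) for _ in range(8)]
        enc = np.array([[ph._AA_INDEX[a] for a in pep] for pep in peps])
        batch = ph._viterbi_scores_batch(p, enc)
        singles = [ph.viterbi_local(p, pep) for pep in peps]
        assert np.allclose(batch, singles, atol=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ph.viterbi_local(toy_profile(2), "")


class TestCalibration:
    def test_gumbel_shift_equivariance(self):
        rng = np.random.default_rng(0)
        scores = rng.gumbel(5.0, 1.0 / 0.7, size=2000)
        lam1, mu1 = ph.fit_gumbel(scores)
        lam2, mu2 = ph.fit_gumbel(scores + 3.0)
        assert lam2 == pytest.approx(lam1, rel=1e-12)
        assert mu2 == pytest.approx(mu1 + 3.0, abs=1e-9)

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(1)
        scores = rng.gumbel(5.0, 1.0 / 0.7, size=1000)
        lam, mu = ph.fit_gumbel(scores)
        assert lam == pytest.approx(0.7, rel=0.10)
        assert mu == pytest.approx(5.0, abs=0.2)

    def test_monte_carlo_stability(self):
        p = toy_profile(8, seed=4, alphabet="ACDEFGHIKLMNP")
        lam1, _ = ph.calibrate(p, 300, 100, seed=0)
        lam2, _ = ph.calibrate(p, 600, 100, seed=0)
        assert abs(lam2 - lam1) / lam1 < 0.2

    def test_degenerate_variance_raises(self):
        with pytest.raises(ph.CalibrationError):
            ph.fit_gumbel(np.ones(100))

    def test_tail_probability_monotone_in_score(self):
        ps = [ph.gumbel_tail(s, 0.5, 3.0) for s in np.linspace(-5, 2000, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(p >= 0 for p in ps)


@pytest.fixture(scope="module")
def rt_setup():
    rng = np.random.default_rng(11)
    cons = sd.random_peptide(rng, 60)
    aln = [SeqRecord("c", cons)] + [
        SeqRecord(f"v{k}", sd.mutate_peptide(rng, cons, 0.15)) for k in range(4)
    ]
    p = ph.build_profile(aln, name="rt")
    ph.calibrate(p, 500, 150, seed=0)
    return p, cons, rng


class TestScan:
    def test_empty_sequence_collection(self, rt_setup):
        p, _, _ = rt_setup
        assert ph.scan([p], [], 1e-5) == []

    def test_planted_domain_recovered(self, rt_setup):
        p, cons, rng = rt_setup
        seqs = [SeqRecord("planted", sd.random_peptide(rng, 50) + cons)]
        seqs += [SeqRecord(f"bg{k}", sd.random_peptide(rng, 110)) for k in range(20)]
        hits = ph.scan([p], seqs, 1e-5)
        assert "planted" in {h.seq_id for h in hits}

    def test_threshold_monotonicity(self, rt_setup):
        p, cons, rng = rt_setup
        seqs = [SeqRecord(f"s{k}", sd.random_peptide(rng, 80)) for k in range(10)]
        seqs.append(SeqRecord("pl", cons))
        loose = {(h.profile_name, h.seq_id) for h in ph.scan([p], seqs, math.inf)}
        strict = {(h.profile_name, h.seq_id) for h in ph.scan([p], seqs, 1e-5)}
        assert strict <= loose

    def test_uncalibrated_profile_rejected(self):
        p = toy_profile(3)
        with pytest.raises(RuntimeError):
            ph.scan([p], [SeqRecord("a", "ACD")], 1e-5)

    def test_consensus_outscores_shuffled(self, rt_setup):
        p, cons, _ = rt_setup
        rng = np.random.default_rng(77)
        wins = 0
        n = 50
        for k in range(n):
            flank = sd.random_peptide(rng, 30)
            with_cons = flank + cons
            shuffled = flank + "".join(rng.permutation(list(cons)))
            wins += ph.viterbi_local(p, with_cons) >= ph.viterbi_local(p, shuffled)
        assert wins >= 0.95 * n


class TestSerialization:
    def test_round_trip(self, tmp_path):
        p = toy_profile(5, seed=6)
        ph.calibrate(p, 200, 80, seed=0)
        path = tmp_path / "profiles.txt"
        ph.save_profiles([p], path)
        (q,) = ph.load_profiles(path)
        assert q.name == p.name and q.M == p.M
        assert np.allclose(q.match_emissions, p.match_emissions, atol=1e-7)
        assert q.calibration == pytest.approx(p.calibration, rel=1e-6)
        pep = "ACDEACDE"
        assert ph.viterbi_local(q, pep) == pytest.approx(ph.viterbi_local(p, pep), abs=1e-5)
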