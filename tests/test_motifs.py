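"""End-motif, breakpoint-motif, background and N-index behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plasmafrag as pf

from conftest import make_fragments, make_genome, random_instance
import oracles


class TestEndMotifs:
    def test_both_ends_contribute(self):
        # plus end CCCA at start; minus end revcomp of the 4-mer ending at `end`
        seq = "CCCA" + "G" * 20 + "ACGT" + "A" * 10
        genome = make_genome(chr1=seq)
        frags = make_fragments([("chr1", 0, 28, "+")])
        prof = pf.end_motif_profile(frags, genome, k=4)
        assert prof.freq("CCCA") == pytest.approx(0.5)
        assert prof.freq(oracles.revcomp(seq[24:28])) == pytest.approx(0.5)

    def test_palindromic_fragment_single_motif(self):
        genome = make_genome(chr1="ACGTACGT")
        frags = make_fragments([("chr1", 0, 8, "+")])
        prof = pf.end_motif_profile(frags, genome, k=4)
        # revcomp("ACGT") == "ACGT": both ends give the same motif
        assert prof.freq("ACGT") == pytest.approx(1.0)

    def test_edge_and_n_windows_skipped(self):
        genome = make_genome(chr1="NNNN" + "ACGTAGGC" * 4 + "AC")
        frags = make_fragments([("chr1", 0, 20, "+"), ("chr1", 4, 34, "+")])
        prof = pf.end_motif_profile(frags, genome, k=4)
        # first fragment's plus end starts in the N run -> skipped;
        # second fragment's minus end runs off usable sequence edge
        assert prof.n_sites == 3

    def test_uniform_cleavage_near_uniform_profile(self):
        genome = pf.generate_genome(1, 200_000, 0.5, seed=2)
        prof_cls = pf.ClassProfile(length_mix=((167.0, 0.0001, 1.0),))
        frags = pf.simulate_sample(genome, None, prof_cls, 100_000, seed=9)
        prof = pf.end_motif_profile(frags, genome, k=4)
        # 200k ends; binomial SD at p=1/256 is ~1.4e-4, allow generous bound
        assert np.abs(prof.freqs - 1 / 256).max() < 0.003

    def test_strand_symmetry(self, toy_genome):
        frags = pf.simulate_sample(
            toy_genome, None, pf.ClassProfile(), 2000, seed=4
        )
        prof = pf.end_motif_profile(frags, toy_genome, k=4)
        rc_genome = toy_genome.reverse_complemented()
        flipped = frags.data.copy()
        L = {name: toy_genome[name].length for name in toy_genome}
        starts = flipped["start"].copy()
        flipped["start"] = flipped["chrom"].map(L) - flipped["end"]
        flipped["end"] = flipped["chrom"].map(L) - starts
        flipped["strand"] = flipped["strand"].map({"+": "-", "-": "+"})
        prof_rc = pf.end_motif_profile(
            pf.FragmentSet("t", flipped), rc_genome, k=4
        )
        np.testing.assert_allclose(prof.freqs, prof_rc.freqs, atol=1e-12)


class TestBreakpointMotifs:
    def test_windows_straddle_breakpoints(self):
        seq = "TTACGTCAGGTTGCAATCCG"
        genome = make_genome(chr1=seq)
        frags = make_fragments([("chr1", 5, 15, "+")])
        prof = pf.breakpoint_motif_profile(frags, genome, flank=3)
        assert prof.freq(seq[2:8]) == pytest.approx(0.5)  # plus breakpoint at 5
        assert prof.freq(oracles.revcomp(seq[12:18])) == pytest.approx(0.5)

    def test_edge_breakpoint_skipped(self):
        genome = make_genome(chr1="ACGTACGTACGTACGT")
        frags = make_fragments([("chr1", 1, 9, "+")])
        prof = pf.breakpoint_motif_profile(frags, genome, flank=3)
        assert prof.n_sites == 1  # start=1 is within flank of the edge


class TestBackground:
    def test_both_strands_counted(self):
        genome = make_genome(chr1="AAAA")
        prof = pf.background_motif_freq(genome, 4)
        assert prof.freq("AAAA") == pytest.approx(0.5)
        assert prof.freq("TTTT") == pytest.approx(0.5)

    def test_matches_bruteforce_on_repeat_genome(self):
        seq = "ACGT" * 1000
        genome = make_genome(chr1=seq)
        prof = pf.background_motif_freq(genome, 4)
        expected = oracles.background_motif_counts({"chr1": seq}, 4)
        total = sum(expected.values())
        for motif, count in expected.items():
            assert prof.freq(motif) == pytest.approx(count / total)

    def test_genome_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            pf.background_motif_freq(make_genome(chr1="ACG"), 6)


@pytest.mark.parametrize("kind", ["end", "breakpoint", "background"])
def test_bruteforce_oracle_equivalence(kind):
    """Vectorised motif counts match direct string scanning exactly."""
    rng = np.random.default_rng(123)
    for _ in range(12):
        sequences, frags = random_instance(rng)
        genome = make_genome(**sequences)
        fragset = make_fragments(frags)
        if kind == "end":
            prof = pf.end_motif_profile(fragset, genome, k=4)
            expected = oracles.end_motif_counts(frags, sequences, 4)
        elif kind == "breakpoint":
            prof = pf.breakpoint_motif_profile(fragset, genome, flank=3)
            expected = oracles.breakpoint_motif_counts(frags, sequences, 3)
        else:
            prof = pf.background_motif_freq(genome, 4)
            expected = oracles.background_motif_counts(sequences, 4)
        total = sum(expected.values())
        assert prof.n_sites == total
        counts = np.rint(prof.freqs * total).astype(int)
        got = {m: int(c) for m, c in zip(pf.all_motifs(prof.k), counts) if c}
        assert got == expected


class TestNIndex:
    def test_analytic_values(self):
        uniform = pf.MotifProfile(4, "end", np.full(256, 1 / 256))
        assert float(pf.n_index(uniform)) == pytest.approx(1.0)
        point = np.zeros(256)
        point[5] = 1.0
        assert float(pf.n_index(pf.MotifProfile(4, "end", point))) == pytest.approx(0.0)
        two = np.zeros(256)
        two[[3, 77]] = 0.5
        assert float(pf.n_index(pf.MotifProfile(4, "end", two))) == pytest.approx(
            math.log(2) / math.log(256)
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=16, max_size=16), st.permutations(range(16)))
    def test_relabel_invariance_and_uniform_maximum(self, weights, perm):
        freqs = np.zeros(256)
        w = np.asarray(weights)
        freqs[:16] = w / w.sum()
        permuted = freqs.copy()
        permuted[:16] = freqs[list(perm)]
        a = float(pf.n_index(pf.MotifProfile(4, "end", freqs)))
        b = float(pf.n_index(pf.MotifProfile(4, "end", permuted)))
        assert a == pytest.approx(b)
        assert a <= 1.0 + 1e-12


def test_profiles_normalised_with_full_key_set(toy_genome):
    frags = pf.simulate_sample(toy_genome, None, pf.ClassProfile(), 500, seed=1)
    for prof in [
        pf.end_motif_profile(frags, toy_genome, 4),
        pf.end_motif_profile(frags, toy_genome, 6),
        pf.breakpoint_motif_profile(frags, toy_genome, 3),
        pf.background_motif_freq(toy_genome, 4),
    ]:
        assert len(prof.freqs) == 4**prof.k
        assert abs(prof.freqs.sum() - 1.0) < 1e-9
        assert len(prof.as_dict()) == 4**prof.k


def test_enrichment_near_one_under_uniform_cleavage(toy_genome):
    frags = pf.simulate_sample(toy_genome, None, pf.ClassProfile(), 60_000, seed=8)
    obs = pf.breakpoint_motif_profile(frags, toy_genome, 3)
    bg = pf.background_motif_freq(toy_genome, 6)
    ratio = pf.motif_enrichment(obs, bg)
    n = obs.n_sites
    p = bg.freqs
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(p * (1 - p) / n) / p  # 1 SD of the ratio
    ok = np.abs(ratio.to_numpy() - 1.0) <= 3 * sd
    ok = ok[np.isfinite(ratio.to_numpy())]
    assert ok.mean() >= 0.95
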