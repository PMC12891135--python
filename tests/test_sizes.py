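"""Length histogram, E-index, genome binning, and S/L ratio behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

import plasmafrag as pf

from conftest import make_fragments, make_genome
import oracles


class TestLengthHistogram:
    def test_exact_counts(self):
        frags = make_fragments(
            [("chr1", 0, 167, "+"), ("chr1", 10, 177, "+"), ("chr1", 5, 305, "-")]
        )
        hist = pf.length_histogram(frags)
        assert hist.count(167) == 2
        assert hist.count(300) == 1
        assert hist.total_in_range == 3

    def test_empty_set_all_zero(self):
        frags = pf.FragmentSet(
            "e", pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        )
        hist = pf.length_histogram(frags)
        assert hist.total_in_range == 0
        assert hist.n_below == 0 and hist.n_above == 0

    def test_out_of_range_tallied_separately(self):
        frags = make_fragments([("chr1", 0, 10, "+"), ("chr1", 0, 500, "+")])
        hist = pf.length_histogram(frags, range=(30, 400))
        assert hist.n_below == 1 and hist.n_above == 1

    def test_mixture_recovered_at_scale(self, toy_genome):
        mix = ((145.0, 8.0, 0.5), (167.0, 8.0, 0.5))
        frags = pf.simulate_sample(
            toy_genome, None, pf.ClassProfile(length_mix=mix), 100_000, seed=21
        )
        hist = pf.length_histogram(frags)
        lengths = np.arange(30, 401)
        truth = 0.5 * np.exp(-((lengths - 145.0) ** 2) / (2 * 64)) / math.sqrt(
            2 * math.pi * 64
        ) + 0.5 * np.exp(-((lengths - 167.0) ** 2) / (2 * 64)) / math.sqrt(2 * math.pi * 64)
        truth = truth / truth.sum()
        emp = hist.counts / hist.counts.sum()
        assert 0.5 * np.abs(emp - truth).sum() < 0.02  # total variation


class TestEIndex:
    def test_point_mass_zero(self):
        frags = make_fragments([("chr1", 0, 167, "+")] * 5)
        assert pf.e_index(pf.length_histogram(frags)) == pytest.approx(0.0)

    def test_uniform_one(self):
        hist = pf.LengthHistogram((30, 400), np.ones(371, dtype=np.int64))
        assert pf.e_index(hist) == pytest.approx(1.0)

    def test_two_class_analytic(self):
        counts = np.zeros(371, dtype=np.int64)
        counts[[100, 200]] = 7
        hist = pf.LengthHistogram((30, 400), counts)
        assert pf.e_index(hist) == pytest.approx(math.log(2) / math.log(371))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pf.e_index(pf.LengthHistogram((30, 400), np.zeros(371, dtype=np.int64)))

    def test_majorization_monotonicity(self):
        # moving mass from a heavier to a lighter class increases evenness
        counts = np.zeros(371, dtype=np.int64)
        counts[0], counts[1] = 90, 10
        low = pf.e_index(pf.LengthHistogram((30, 400), counts))
        counts[0], counts[1] = 80, 20
        high = pf.e_index(pf.LengthHistogram((30, 400), counts))
        assert high > low


class TestBins:
    def test_tiling_and_tail_rule(self):
        genome = pf.generate_genome(1, 20_000, 0.5, seed=1)
        bins = pf.build_bins(genome, 5000)
        assert len(bins) == 4
        # 12.4 kb chromosome: tail of 2.4 kb < 2.5 kb is dropped
        g2 = pf.Genome([pf.GenomeSequence("c", genome["chr1"].sequence[:12_400])])
        assert len(pf.build_bins(g2, 5000).data) == 2

    def test_gc_threshold(self):
        seq = "AT" * 5000 + "GC" * 5000
        genome = make_genome(chr1=seq)
        bins = pf.build_bins(genome, 10_000, gc_min=0.3)
        assert list(bins.data["pass"]) == [False, True]

    def test_blacklist_any_overlap_fails(self):
        genome = pf.generate_genome(1, 20_000, 0.5, seed=2)
        black = pf.IntervalTrack(
            pd.DataFrame(
                [("chr1", 4999, 5001, "bl", "", "+")], columns=pf.IntervalTrack.COLUMNS
            )
        )
        bins = pf.build_bins(genome, 5000, blacklist=black)
        assert list(bins.data["pass"]) == [False, False, True, True]

    def test_mappability_from_masked_track(self):
        genome = pf.generate_genome(1, 20_000, 0.5, seed=3)
        masked = pf.IntervalTrack(
            pd.DataFrame(
                [("chr1", 0, 1000, "m", "", "+")], columns=pf.IntervalTrack.COLUMNS
            )
        )
        bins = pf.build_bins(genome, 5000, mappability=masked, map_min=0.9)
        assert bins.data["mappability"].iloc[0] == pytest.approx(0.8)
        assert not bins.data["pass"].iloc[0]
        assert bins.data["pass"].iloc[1:].all()

    def test_pass_flags_match_bruteforce(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            L = 30_000
            seq = "".join(rng.choice(list("ACGTN"), size=L, p=[0.3, 0.2, 0.1, 0.3, 0.1]))
            genome = make_genome(chr1=seq)
            intervals = []
            for _ in range(int(rng.integers(0, 5))):
                s = int(rng.integers(0, L - 100))
                intervals.append(("chr1", s, s + int(rng.integers(10, 100)), "b", "", "+"))
            black = (
                pf.IntervalTrack(pd.DataFrame(intervals, columns=pf.IntervalTrack.COLUMNS))
                if intervals
                else None
            )
            bins = pf.build_bins(genome, 5000, blacklist=black)
            pairs = [(s, e) for _c, s, e, *_ in intervals]
            for row in bins.data.itertuples(index=False):
                expected = oracles.bin_pass_bruteforce(seq, row.start, row.end, 0.3, pairs)
                assert row[5] == expected, (trial, row)


class TestSLProfile:
    def _bins(self, length=100_000):
        genome = pf.generate_genome(1, length, 0.5, seed=7)
        return genome, pf.build_bins(genome, 10_000, gc_min=0.0)

    def test_ratio_and_missing_convention(self):
        genome, bins = self._bins()
        frags = make_fragments(
            [("chr1", 100, 220, "+")] * 100  # short, bin 0
            + [("chr1", 300, 460, "+")] * 50  # long, bin 0
            + [("chr1", 15_000, 15_120, "+")] * 3  # short only, bin 1
        )
        prof = pf.sl_profile(frags, bins)
        assert prof.bins.loc[0, "ratio"] == pytest.approx(2.0)
        assert np.isnan(prof.bins.loc[1, "ratio"])

    def test_conservation(self, toy_genome):
        frags = pf.simulate_sample(toy_genome, None, pf.ClassProfile(), 20_000, seed=3)
        bins = pf.build_bins(toy_genome, 10_000)
        prof = pf.sl_profile(frags, bins)
        counted = int(prof.bins["short"].sum() + prof.bins["long"].sum())
        assert counted + prof.n_out_of_class + prof.n_failed_bin == prof.n_total == len(frags)

    def test_mixture_ratio_within_binomial_error(self):
        genome, bins = self._bins(200_000)
        # uniform placement, 60/40 short/long mixture
        rng = np.random.default_rng(11)
        n = 60_000
        short = rng.random(n) < 0.6
        lengths = np.where(short, 125, 180)
        starts = rng.integers(0, 199_000, size=n)
        frags = pf.FragmentSet(
            "t",
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": starts,
                    "end": starts + lengths,
                    "strand": "+",
                }
            ),
        )
        prof = pf.sl_profile(frags, bins)
        ok = 0
        for row in prof.bins.itertuples(index=False):
            tot = row.short + row.long
            if tot == 0:
                continue
            se = math.sqrt(0.6 * 0.4 / tot)  # SE of the short fraction
            p_hat = row.short / tot
            lo, hi = 0.6 - 3 * se, 0.6 + 3 * se
            ok += lo <= p_hat <= hi
        assert ok / len(prof.bins) >= 0.95

    def test_zscored_ratios_named_and_standardised(self, toy_genome):
        frags = pf.simulate_sample(toy_genome, None, pf.ClassProfile(), 20_000, seed=5)
        bins = pf.build_bins(toy_genome, 10_000)
        z = pf.sl_profile(frags, bins).zscored_ratios()
        assert all(name.startswith("SL_chr") for name in z.index)
        vals = z.dropna()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-6)
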