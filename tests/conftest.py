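import numpy as np
import pandas as pd
import pytest

import plasmafrag as pf


def make_genome(**named_sequences) -> pf.Genome:
    """Tiny explicit genome from keyword sequences."""
    return pf.Genome(pf.GenomeSequence(n, s) for n, s in named_sequences.items())


def make_fragments(frags, sample_id="t") -> pf.FragmentSet:
    """FragmentSet from (chrom, start, end, strand) tuples."""
    df = pd.DataFrame(frags, columns=["chrom", "start", "end", "strand"])
    return pf.FragmentSet(sample_id, df)


def random_instance(rng, max_genome=2000, max_frags=200, k_margin=8):
    """A random toy genome (with occasional N) plus in-bounds fragments."""
    L = int(rng.integers(200, max_genome))
    bases = rng.choice(list("ACGT"), size=L, p=[0.3, 0.2, 0.2, 0.3])
    if rng.random() < 0.5:  # sprinkle N runs
        for _ in range(int(rng.integers(1, 4))):
            p = int(rng.integers(0, L - 5))
            bases[p : p + int(rng.integers(1, 5))] = "N"
    seq = "".join(bases)
    n = int(rng.integers(1, max_frags))
    starts = rng.integers(0, max(L - k_margin - 60, 1), size=n)
    lengths = rng.integers(20, 60, size=n)
    ends = np.minimum(starts + lengths, L)
    strands = rng.choice(["+", "-"], size=n)
    frags = [
        ("chr1", int(s), int(e), str(st))
        for s, e, st in zip(starts, ends, strands)
        if e > s
    ]
    return {"chr1": seq}, frags


@pytest.fixture(scope="session")
def toy_genome():
    return pf.generate_genome(2, 120_000, 0.41, seed=11)


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    return pf.generate_annotation(toy_genome, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort reused by classifier/pipeline tests."""
    spec = pf.CohortSpec(
        n_benign=8, n_malignant=8, fragments_per_sample=5000, seed=17, chrom_length=300_000
    )
    return pf.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    bins = pf.build_bins(small_cohort.genome, 100_000)
    feats = pf.extract_cohort_features(
        small_cohort.fragment_sets,
        small_cohort.genome,
        bins=bins,
        annotation=small_cohort.annotation,
        sites=small_cohort.dip_sites,
    )
    return pf.assemble_features(feats, small_cohort.metadata)
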