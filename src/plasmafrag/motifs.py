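"""5' end-motif and breakpoint-motif profiles, genome background, N-index.

Every fragment is a double-stranded template with two 5' termini: the
plus-strand 5' end at ``start`` and the minus-strand 5' end at ``end``.  Both
contribute one motif, read from the *reference* genome (not read bases) and
oriented 5'->3' on the respective strand, i.e. the minus-strand end
contributes a reverse-complemented reference k-mer.  Windows containing N or
falling off a chromosome edge are skipped (and counted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, all_motifs, motif_code, revcomp_code_table
from .io import FragmentSet

logger = logging.getLogger(__name__)


@dataclass
class MotifProfile:
    """A normalised frequency vector over all 4**k motifs.

    ``freqs`` is indexed by the integer motif code (lexicographic order over
    A<C<G<T); ``n_sites`` is the number of motif observations behind it.
    """

    k: int
    kind: str  # 'end' | 'breakpoint' | 'background'
    freqs: np.ndarray
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.freqs) != 4**self.k:
            raise ValueError(f"profile for k={self.k} needs {4**self.k} entries")
        if (self.freqs < 0).any():
            raise ValueError("negative motif frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("motif profile does not sum to 1")

    def freq(self, motif: str) -> float:
        return float(self.freqs[motif_code(motif)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(all_motifs(self.k), self.freqs))

    def to_series(self, prefix: str = "") -> pd.Series:
        return pd.Series(self.freqs, index=[f"{prefix}{m}" for m in all_motifs(self.k)])


@dataclass
class NIndex:
    """Normalised Shannon entropy of an end-motif profile, in [0, 1]."""

    value: float
    k: int

    def __float__(self) -> float:
        return self.value


def _end_motif_codes(fragments: FragmentSet, genome: Genome, k: int):
    """Integer codes of both 5'-end motifs of every fragment; yields per-chrom
    arrays with invalid (-1 / out-of-range) entries removed, plus skip count."""
    rc = revcomp_code_table(k)
    skipped = 0
    for chrom, starts, ends, _strands in fragments.by_chrom():
        if chrom not in genome:
            raise KeyError(f"fragment chromosome {chrom!r} absent from genome")
        kmers = genome[chrom].kmer_codes(k)
        n_pos = len(kmers)
        # plus-strand 5' end: k-mer starting at `start`
        ok_p = starts < n_pos
        plus = kmers[starts[ok_p]]
        # minus-strand 5' end: revcomp of k-mer ending at `end`
        mstart = ends - k
        ok_m = (mstart >= 0) & (mstart < n_pos)
        minus = kmers[mstart[ok_m]]
        minus = rc[minus[minus >= 0]]  # drop N windows before the rc lookup
        n_valid_plus = int((plus >= 0).sum())
        skipped += int((~ok_p).sum() + (~ok_m).sum()) + (len(plus) - n_valid_plus)
        skipped += int(ok_m.sum()) - len(minus)
        yield np.concatenate([plus[plus >= 0], minus])
    if skipped:
        logger.info("end motifs: skipped %d ends (edge or N)", skipped)


def end_motif_profile(fragments: FragmentSet, genome: Genome, k: int = 4) -> MotifProfile:
    """Oriented 5' end-motif frequencies (two motifs per fragment)."""
    counts = np.zeros(4**k, dtype=np.int64)
    for codes in _end_motif_codes(fragments, genome, k):
        counts += np.bincount(codes, minlength=4**k)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid fragment ends for end-motif profile")
    return MotifProfile(k, "end", counts / total, n_sites=int(total))


def breakpoint_motif_profile(
    fragments: FragmentSet, genome: Genome, flank: int = 3
) -> MotifProfile:
    """Breakpoint-context motifs: ``flank`` bp each side of each 5' cleavage
    point, oriented on the end's strand (2*flank-mers, total frequency 1)."""
    k = 2 * flank
    rc = revcomp_code_table(k)
    counts = np.zeros(4**k, dtype=np.int64)
    skipped = 0
    for chrom, starts, ends, _strands in fragments.by_chrom():
        if chrom not in genome:
            raise KeyError(f"fragment chromosome {chrom!r} absent from genome")
        kmers = genome[chrom].kmer_codes(k)
        n_pos = len(kmers)
        # plus end breakpoint at `start`: window [start-flank, start+flank)
        ps = starts - flank
        ok_p = (ps >= 0) & (ps < n_pos)
        plus = kmers[ps[ok_p]]
        plus = plus[plus >= 0]
        # minus end breakpoint at `end`: revcomp of window [end-flank, end+flank)
        ms = ends - flank
        ok_m = (ms >= 0) & (ms < n_pos)
        minus = kmers[ms[ok_m]]
        minus = rc[minus[minus >= 0]]  # drop N windows before the rc lookup
        skipped += 2 * len(starts) - len(plus) - len(minus)
        counts += np.bincount(np.concatenate([plus, minus]), minlength=4**k)
    if skipped:
        logger.info("breakpoint motifs: skipped %d breakpoints (edge or N)", skipped)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid breakpoints for breakpoint-motif profile")
    return MotifProfile(k, "breakpoint", counts / total, n_sites=int(total))


def background_motif_freq(genome: Genome, k: int) -> MotifProfile:
    """k-mer frequency over all windows of both genome strands (N skipped)."""
    if all(c.length < k for c in genome.values()):
        raise ValueError(f"genome shorter than k={k}")
    rc = revcomp_code_table(k)
    counts = np.zeros(4**k, dtype=np.int64)
    for chrom in genome.values():
        kmers = chrom.kmer_codes(k)
        valid = kmers[kmers >= 0]
        counts += np.bincount(valid, minlength=4**k)
        counts += np.bincount(rc[valid], minlength=4**k)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid k-mer windows in genome")
    return MotifProfile(k, "background", counts / total, n_sites=int(total))


def motif_enrichment(observed: MotifProfile, background: MotifProfile) -> pd.Series:
    """Element-wise observed/background frequency ratio (NaN where background 0).

    Exposed separately from the raw-normalised profiles so callers can choose
    either representation for modelling.
    """
    if observed.k != background.k:
        raise ValueError("profiles have different k")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(background.freqs > 0, observed.freqs / background.freqs, np.nan)
    return pd.Series(ratio, index=list(all_motifs(observed.k)))


def n_index(profile: MotifProfile) -> NIndex:
    """Motif-diversity score: Shannon entropy (nats) of the end-motif
    frequencies divided by log(4**k); 1 at uniformity, 0 for a point mass."""
    p = profile.freqs
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("profile is not normalised")
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return NIndex(entropy / math.log(4**profile.k), profile.k)
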