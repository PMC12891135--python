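"""Fragment-size features: length histogram, E-index, genome bins, S/L ratios.

Short fragments are 100-150 bp and long fragments 151-220 bp (inclusive);
per-bin short/long count ratios on a 100 kb tiling capture regional
fragmentation, while the E-index summarises global size-distribution evenness
as a normalised entropy over a fixed 30-400 bp support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from .io import FragmentSet, IntervalTrack

logger = logging.getLogger(__name__)

SHORT_RANGE = (100, 150)
LONG_RANGE = (151, 220)


@dataclass
class LengthHistogram:
    """Per-1-bp length counts over an inclusive [min, max] support.

    Lengths outside the support are tallied separately in n_below/n_above.
    """

    range: tuple[int, int]
    counts: np.ndarray
    n_below: int = 0
    n_above: int = 0

    @property
    def total_in_range(self) -> int:
        return int(self.counts.sum())

    def count(self, length: int) -> int:
        lo, hi = self.range
        if not lo <= length <= hi:
            return 0
        return int(self.counts[length - lo])


def length_histogram(fragments: FragmentSet, range: tuple[int, int] = (30, 400)) -> LengthHistogram:
    lo, hi = range
    if hi < lo:
        raise ValueError("histogram range inverted")
    lengths = fragments.lengths
    below = int((lengths < lo).sum())
    above = int((lengths > hi).sum())
    inside = lengths[(lengths >= lo) & (lengths <= hi)]
    counts = np.bincount(inside - lo, minlength=hi - lo + 1)
    return LengthHistogram((lo, hi), counts.astype(np.int64), below, above)


def e_index(hist: LengthHistogram) -> float:
    """Evenness of the fragment-size distribution: Shannon entropy of the
    normalised in-range histogram divided by log(number of length classes)."""
    total = hist.counts.sum()
    if total == 0:
        raise ValueError("e_index undefined for an empty histogram")
    p = hist.counts / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    n_classes = len(hist.counts)
    if n_classes < 2:
        return 0.0
    return entropy / math.log(n_classes)


@dataclass
class GenomeBins:
    """Non-overlapping fixed-width tiling with per-bin GC, mappability and a
    pass flag; the trailing partial bin of a chromosome is dropped when
    shorter than half the bin size."""

    bin_size: int
    data: pd.DataFrame  # chrom, start, end, gc, mappability, pass

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_pass(self) -> int:
        return int(self.data["pass"].sum())


def build_bins(
    genome: Genome,
    bin_size: int,
    gc_min: float = 0.3,
    map_min: float = 0.9,
    mappability: IntervalTrack | float = 1.0,
    blacklist: IntervalTrack | None = None,
) -> GenomeBins:
    """Tile the genome and flag bins failing GC, mappability or blacklist rules.

    ``mappability`` is either a constant or a track of *masked* (unmappable)
    intervals, in which case bin mappability = 1 - masked overlap fraction.
    Any blacklist overlap at all fails a bin.
    """
    if bin_size < 1000:
        raise ValueError("bin_size must be >= 1000")
    rows = []
    for name, chrom in genome.items():
        pos = 0
        while pos < chrom.length:
            end = min(pos + bin_size, chrom.length)
            if end - pos < bin_size / 2:
                break  # drop short tail bin
            gc = chrom.gc_fraction(pos, end)
            if isinstance(mappability, IntervalTrack):
                masked = mappability.overlap_bases(name, pos, end)
                mapp = 1.0 - masked / (end - pos)
            else:
                mapp = float(mappability)
            black = blacklist.overlap_bases(name, pos, end) if blacklist is not None else 0
            ok = (not math.isnan(gc)) and gc >= gc_min and mapp >= map_min and black == 0
            rows.append((name, pos, end, gc, mapp, ok))
            pos += bin_size
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "mappability", "pass"])
    logger.info("build_bins: %d bins, %d pass", len(df), int(df["pass"].sum()))
    return GenomeBins(bin_size, df)


@dataclass
class SLProfile:
    """Per-pass-bin short/long fragment counts and their ratio.

    ``ratio`` is NaN where long_count == 0 (mean-imputed later at the matrix
    stage).  Bookkeeping fields allow exact conservation checks:
    n_total = sum(short+long over pass bins) + n_out_of_class + n_failed_bin.
    """

    bins: pd.DataFrame  # chrom, start, end, short, long, ratio
    n_total: int
    n_out_of_class: int
    n_failed_bin: int

    def zscored_ratios(self) -> pd.Series:
        """Ratios z-scaled across bins within the sample (depth invariance);
        NaN ratios stay NaN."""
        r = self.bins["ratio"]
        mu, sd = r.mean(), r.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            z = r - mu
        else:
            z = (r - mu) / sd
        z.index = [
            f"SL_{c}_{s}" for c, s in zip(self.bins["chrom"], self.bins["start"])
        ]
        return z


def sl_profile(
    fragments: FragmentSet,
    bins: GenomeBins,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> SLProfile:
    """Assign each fragment to the bin containing its midpoint and count
    short/long fragments per passing bin."""
    df = bins.data
    n_total = len(fragments)
    short = np.zeros(len(df), dtype=np.int64)
    long_ = np.zeros(len(df), dtype=np.int64)
    n_out = n_failed = 0
    by_chrom = {c: sub for c, sub in df.groupby("chrom", sort=False)}
    for chrom, starts, ends, _strands in fragments.by_chrom():
        mids = (starts + ends) // 2
        lengths = ends - starts
        sub = by_chrom.get(chrom)
        if sub is None:
            n_failed += len(mids)
            continue
        bstarts = sub["start"].to_numpy()
        bends = sub["end"].to_numpy()
        bpass = sub["pass"].to_numpy()
        rows = sub.index.to_numpy()
        idx = np.searchsorted(bstarts, mids, side="right") - 1
        ok = (idx >= 0) & (mids < bends[np.clip(idx, 0, None)])
        ok &= np.where(ok, bpass[np.clip(idx, 0, None)], False)
        n_failed += int((~ok).sum())
        idx, lengths = rows[idx[ok]], lengths[ok]
        is_s = (lengths >= short_range[0]) & (lengths <= short_range[1])
        is_l = (lengths >= long_range[0]) & (lengths <= long_range[1])
        n_out += int((~(is_s | is_l)).sum())
        short += np.bincount(idx[is_s], minlength=len(df))
        long_ += np.bincount(idx[is_l], minlength=len(df))
    out = df[df["pass"]][["chrom", "start", "end"]].copy()
    out["short"] = short[df["pass"].to_numpy()]
    out["long"] = long_[df["pass"].to_numpy()]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out["long"] > 0, out["short"] / out["long"], np.nan)
    out["ratio"] = ratio
    return SLProfile(out.reset_index(drop=True), n_total, n_out, n_failed)
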