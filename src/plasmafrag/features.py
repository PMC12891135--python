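"""Per-sample feature extraction and matrix assembly.

One sample's fragments are reduced to a named feature vector:

==============  ==========================================================
prefix          meaning
==============  ==========================================================
``EM4_/EM6_``   5' end-motif frequencies (k = 4 / 6)
``BP6_``        breakpoint-context 6-mer frequencies (3 bp each side)
``N_INDEX``     end-motif diversity (normalised entropy, k = 4)
``E_INDEX``     fragment-size evenness (normalised entropy, 30-400 bp)
``SL_*``        per-100 kb-bin short/long ratios, z-scaled within sample
``REP_/REPC_``  repeat subfamily / category overlap frequencies
``GRF_*``       nucleosome coverage summaries (central, +-1 kb mean,
                190 bp amplitude)
==============  ==========================================================

``assemble_features`` unions the per-sample vectors with optional external
columns (e.g. tumour-fraction estimates keyed by sample_id), mean-imputes
missing values from the assembled samples, and drops zero-variance columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .coverage import midpoint_coverage, profile_summary
from .genome import Genome
from .io import FeatureMatrix, FragmentSet, IntervalTrack
from .motifs import breakpoint_motif_profile, end_motif_profile, n_index
from .repeats import repeat_feature_vector
from .sizes import GenomeBins, e_index, length_histogram, sl_profile

logger = logging.getLogger(__name__)


def extract_sample_features(
    fragments: FragmentSet,
    genome: Genome,
    bins: GenomeBins | None = None,
    annotation: IntervalTrack | None = None,
    sites: IntervalTrack | None = None,
    end_motif_k: tuple[int, ...] = (4,),
    include_breakpoint: bool = False,
    flank: int = 3,
    coverage_window: int = 4995,
) -> pd.Series:
    """Compute the configured feature families for one sample."""
    parts: list[pd.Series] = []
    em4 = None
    for k in end_motif_k:
        prof = end_motif_profile(fragments, genome, k)
        if k == 4:
            em4 = prof
        parts.append(prof.to_series(prefix=f"EM{k}_"))
    if include_breakpoint:
        bp = breakpoint_motif_profile(fragments, genome, flank)
        parts.append(bp.to_series(prefix=f"BP{2 * flank}_"))
    if em4 is None:
        em4 = end_motif_profile(fragments, genome, 4)
    hist = length_histogram(fragments)
    parts.append(
        pd.Series(
            {"N_INDEX": float(n_index(em4)), "E_INDEX": e_index(hist)}
        )
    )
    if bins is not None:
        parts.append(sl_profile(fragments, bins).zscored_ratios())
    if annotation is not None:
        parts.append(repeat_feature_vector(fragments, annotation))
    if sites is not None:
        profile = midpoint_coverage(fragments, sites, window=coverage_window)
        central, mean1kb, amp = profile_summary(profile)
        parts.append(
            pd.Series(
                {"GRF_central": central, "GRF_mean1kb": mean1kb, "GRF_amp": amp}
            )
        )
    return pd.concat(parts)


def extract_cohort_features(
    fragment_sets,
    genome: Genome,
    bins: GenomeBins | None = None,
    annotation: IntervalTrack | None = None,
    sites: IntervalTrack | None = None,
    **kwargs,
) -> dict[str, pd.Series]:
    """Feature vectors for each sample, keyed by sample_id."""
    return {
        fs.sample_id: extract_sample_features(
            fs, genome, bins=bins, annotation=annotation, sites=sites, **kwargs
        )
        for fs in fragment_sets
    }


def assemble_features(
    sample_features: dict[str, pd.Series],
    metadata: pd.DataFrame,
    external: pd.DataFrame | None = None,
    impute: bool = True,
    drop_zero_variance: bool = True,
) -> FeatureMatrix:
    """Union the per-sample vectors into a FeatureMatrix.

    Samples must appear in ``metadata`` (with a ``label`` column); missing
    values are imputed with the column mean over the assembled samples (these
    are the training-split statistics at training time — CV refits re-impute
    split-confined), and columns constant across samples are dropped.
    """
    for sid in sample_features:
        if sid not in metadata.index:
            raise ValueError(f"sample {sid!r} has fragments but no metadata")
    values = pd.DataFrame(sample_features).T
    values.index.name = "sample_id"
    if external is not None:
        ext = external.reindex(values.index)
        overlap = set(ext.columns) & set(values.columns)
        if overlap:
            raise ValueError(f"external columns collide with features: {sorted(overlap)}")
        values = pd.concat([values, ext], axis=1)
    values = values.astype(float)
    if impute:
        means = values.mean(axis=0)
        n_missing = int(values.isna().sum().sum())
        if n_missing:
            logger.info("assemble_features: mean-imputed %d missing values", n_missing)
        values = values.fillna(means)
        # columns that were all-NaN have no mean; drop them
        all_nan = values.columns[values.isna().all()]
        if len(all_nan):
            logger.info("assemble_features: dropped all-missing columns %s", list(all_nan))
            values = values.drop(columns=all_nan)
    if drop_zero_variance:
        variances = values.var(axis=0, ddof=0)
        dead = variances[variances == 0].index
        if len(dead):
            logger.info(
                "assemble_features: dropped %d zero-variance columns", len(dead)
            )
            values = values.drop(columns=dead)
    meta = metadata.loc[values.index]
    labels = meta["label"].astype(int)
    return FeatureMatrix(values, labels, meta.drop(columns=["label"]))
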