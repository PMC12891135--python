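"""Repeat-element features: family taxonomy and fragment-overlap frequencies.

Six feature categories are used: LINE, SINE, LTR, Satellite, plus two grouped
ones — TransposableElement (DNA, Retroposon and Rolling-Circle families) and
RNAElement (tRNA, srpRNA, snRNA, scRNA, rRNA).  A fragment belongs to the
repeat whose interval contains its midpoint; nested annotations resolve to the
smallest containing interval (most specific label wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FragmentSet, IntervalTrack

logger = logging.getLogger(__name__)

CATEGORIES = (
    "LINE",
    "SINE",
    "LTR",
    "Satellite",
    "TransposableElement",
    "RNAElement",
)

# family-name -> category for RepeatMasker-style "Family_Subfamily" names
_FAMILY_TO_CATEGORY = {
    "LINE": "LINE",
    "SINE": "SINE",
    "LTR": "LTR",
    "SATELLITE": "Satellite",
    "DNA": "TransposableElement",
    "RETROPOSON": "TransposableElement",
    "RC": "TransposableElement",
    "TRNA": "RNAElement",
    "SRPRNA": "RNAElement",
    "SNRNA": "RNAElement",
    "SCRNA": "RNAElement",
    "RRNA": "RNAElement",
}

# direct subfamily -> category table for the bundled synthetic annotation
SUBFAMILY_TO_CATEGORY = {
    "AluY": "SINE",
    "AluS": "SINE",
    "AluJ": "SINE",
    "L1": "LINE",
    "L2": "LINE",
    "ERVL": "LTR",
    "ERV1": "LTR",
    "Gypsy": "LTR",
    "centr": "Satellite",
    "hAT_Charlie": "TransposableElement",
    "hAT_Tip100": "TransposableElement",
    "TcMar_Tigger": "TransposableElement",
    "tRNA": "RNAElement",
    "rRNA": "RNAElement",
    "srpRNA": "RNAElement",
}


@dataclass(frozen=True)
class RepeatTaxonomy:
    category: str
    subfamily: str


def classify_family(family_name: str) -> RepeatTaxonomy:
    """Map a repeat family/subfamily name to its feature category.

    Accepts bare category names ("SINE"), RNA family names ("tRNA"),
    RepeatMasker-style compound names ("DNA_hAT_Charlie" -> family "DNA"),
    and known subfamilies ("AluY" -> SINE).  Unknown names classify as
    "Unclassified" and are excluded from features.
    """
    name = family_name.strip()
    upper = name.upper()
    if upper in _FAMILY_TO_CATEGORY:
        return RepeatTaxonomy(_FAMILY_TO_CATEGORY[upper], name)
    head = upper.split("_", 1)[0]
    if head in _FAMILY_TO_CATEGORY:
        sub = name.split("_", 1)[1] if "_" in name else name
        return RepeatTaxonomy(_FAMILY_TO_CATEGORY[head], sub)
    if name in SUBFAMILY_TO_CATEGORY:
        return RepeatTaxonomy(SUBFAMILY_TO_CATEGORY[name], name)
    logger.debug("repeat family %r unclassified", family_name)
    return RepeatTaxonomy("Unclassified", name)


def _annotation_categories(annotation: IntervalTrack) -> pd.Series:
    """Category per interval, from the category column when set, else derived
    from the interval name."""
    cats = annotation.data["category"].astype(str)
    names = annotation.data["name"].astype(str)
    derived = [
        c if c in CATEGORIES else classify_family(n).category
        for c, n in zip(cats, names)
    ]
    return pd.Series(derived, index=annotation.data.index)


def repeat_frequencies(
    fragments: FragmentSet,
    annotation: IntervalTrack,
    level: str = "subfamily",
) -> pd.Series:
    """Fraction of fragments whose midpoint lies inside each repeat
    subfamily (or category) interval; keys are the fixed taxonomy with zeros
    for absent entries, so category values equal the sum of their
    subfamilies exactly."""
    if level not in {"subfamily", "category"}:
        raise ValueError("level must be 'subfamily' or 'category'")
    n_total = len(fragments)
    sub_counts: dict[str, int] = {s: 0 for s in SUBFAMILY_TO_CATEGORY}
    sub_category: dict[str, str] = dict(SUBFAMILY_TO_CATEGORY)
    if n_total and len(annotation):
        categories = _annotation_categories(annotation)
        names = annotation.data["name"].astype(str)
        for chrom, starts, ends, _strands in fragments.by_chrom():
            mids = (starts + ends) // 2
            hit = annotation.locate_points(chrom, mids)
            hit = hit[hit >= 0]
            if len(hit) == 0:
                continue
            for row, n in zip(*np.unique(hit, return_counts=True)):
                cat = categories.loc[row]
                if cat == "Unclassified":
                    continue
                sub = names.loc[row]
                sub_counts[sub] = sub_counts.get(sub, 0) + int(n)
                sub_category[sub] = cat
    denom = max(n_total, 1)
    sub_freqs = pd.Series(
        {k: v / denom for k, v in sorted(sub_counts.items())}, dtype=float
    )
    if level == "subfamily":
        return sub_freqs
    # category frequency is, by construction, the sum of its subfamily
    # frequencies (exact, including float rounding)
    return pd.Series(
        {
            c: sub_freqs[[s for s in sub_freqs.index if sub_category.get(s) == c]].sum()
            for c in CATEGORIES
        },
        dtype=float,
    )


def repeat_feature_vector(fragments: FragmentSet, annotation: IntervalTrack) -> pd.Series:
    """Both levels as named features: REP_<subfamily> and REPC_<category>."""
    sub = repeat_frequencies(fragments, annotation, "subfamily")
    cat = repeat_frequencies(fragments, annotation, "category")
    sub.index = [f"REP_{k}" for k in sub.index]
    cat.index = [f"REPC_{k}" for k in cat.index]
    return pd.concat([sub, cat])
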