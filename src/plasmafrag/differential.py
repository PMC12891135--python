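"""Two-group differential feature analysis.

Feature-wise Wilcoxon rank-sum (Mann-Whitney U) tests between benign and
malignant samples: exact-distribution p-values for small tie-free groups
(combined n <= 20), otherwise the normal approximation with tie and
continuity corrections; Benjamini-Hochberg q-values across the tested
features.  ``top_k`` exports the most differential features with a per-feature
z-scored submatrix for heatmap display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import FeatureMatrix

EXACT_MAX_N = 20


def wilcoxon_differential(
    matrix: FeatureMatrix, families: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature rank-sum test, benign vs malignant.

    Returns a table with group medians, direction ('benign' or 'malignant'
    depending on which median is higher, 'none' when equal), the U statistic
    (malignant as the first sample), two-sided p, BH q, and a ``constant``
    flag (p set to 1 by convention for features identical in all samples).
    ``families`` optionally restricts testing to features starting with any of
    the given prefixes.
    """
    if matrix.labels is None:
        raise ValueError("differential analysis requires labels")
    y = matrix.labels.to_numpy()
    if (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise ValueError("need >= 3 samples per class")
    cols = list(matrix.feature_names)
    if families is not None:
        cols = [c for c in cols if any(c.startswith(f) for f in families)]
    X = matrix.values[cols].to_numpy(dtype=float)
    ben = X[y == 0]
    mal = X[y == 1]
    n_comb = len(ben) + len(mal)
    rows = []
    for j, name in enumerate(cols):
        b, m = ben[:, j], mal[:, j]
        med_b, med_m = float(np.median(b)), float(np.median(m))
        constant = bool(np.all(X[:, j] == X[0, j]))
        if constant:
            rows.append((name, med_b, med_m, "none", np.nan, 1.0, True))
            continue
        has_ties = len(np.unique(np.concatenate([b, m]))) < n_comb
        method = "exact" if (n_comb <= EXACT_MAX_N and not has_ties) else "asymptotic"
        res = mannwhitneyu(m, b, alternative="two-sided", method=method, use_continuity=True)
        if med_m > med_b:
            direction = "malignant"
        elif med_b > med_m:
            direction = "benign"
        else:
            direction = "none"
        rows.append((name, med_b, med_m, direction, float(res.statistic), float(res.pvalue), False))
    table = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "median_benign",
            "median_malignant",
            "direction",
            "statistic",
            "p_value",
            "constant",
        ],
    ).set_index("feature")
    tested = ~table["constant"]
    q = np.full(len(table), 1.0)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            table.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    table["q_value"] = q
    return table


def top_k(
    table: pd.DataFrame,
    matrix: FeatureMatrix,
    k: int = 30,
    families: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """The k most differential features and their per-feature z-scored
    submatrix (samples x features), for heatmap display.

    Ordering: ascending p, ties broken by |median difference| descending, then
    feature name.  ``families`` optionally restricts to given name prefixes.
    """
    sub = table
    if families is not None:
        keep = [f for f in sub.index if any(f.startswith(p) for p in families)]
        sub = sub.loc[keep]
    if k > len(sub):
        raise ValueError(f"k={k} exceeds the {len(sub)} available features")
    order = sub.assign(
        _absdiff=(sub["median_malignant"] - sub["median_benign"]).abs()
    ).sort_values(
        by=["p_value", "_absdiff", "feature"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    features = list(order.index[:k])
    vals = matrix.values[features]
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0).replace(0, 1.0)
    z = (vals - mu) / sd
    return features, z
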