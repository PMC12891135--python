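"""Cancer-score classification: repeated stratified 10-fold CV around an
L2-penalised logistic GLM, plus ROC / fixed-specificity operating points and
subgroup evaluation.

The "cancer score" is the model's predicted probability of malignancy in
[0, 1].  Training runs ``repeats`` independent stratified k-fold splits with
re-drawn fold assignments; within every training split the features are
mean-imputed, z-standardised and fitted with a penalty strength chosen by
inner cross-validation, and the held-out fold is scored.  A sample's
out-of-fold (oof) score is its held-out probability averaged over repeats.
A final locked model refit on all training data (same recipe) scores external
samples.  One master seed derives all per-repeat streams, so results are
reproducible and invariant to sample/feature order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .io import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_CS = (0.01, 0.1, 1.0)
SPEC_TARGETS = (0.90, 0.95, 0.99)


@dataclass
class FittedGLM:
    """A locked imputation + standardisation + logistic model."""

    feature_names: list
    impute_means: np.ndarray
    scale_mean: np.ndarray
    scale_std: np.ndarray
    coef: np.ndarray
    intercept: float
    C: float

    def predict(self, values: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in values.columns]
        if missing:
            raise ValueError(f"matrix is missing model column {missing[0]!r}")
        X = values[self.feature_names].to_numpy(dtype=float)
        X = np.where(np.isnan(X), self.impute_means, X)
        Z = (X - self.scale_mean) / self.scale_std
        lin = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-lin))


@dataclass
class ModelResult:
    """Out-of-fold cancer scores, the locked model, and the CV configuration."""

    oof_scores: pd.Series
    model: FittedGLM
    cv_config: dict
    coefficients: pd.Series  # mean coefficient across all CV refits
    insample_scores: pd.Series | None = None

    def to_json(self, path) -> None:
        payload = {
            "glm": "logistic regression, L2 penalty, C by inner CV",
            "cv_config": self.cv_config,
            "feature_names": list(self.model.feature_names),
            "impute_means": self.model.impute_means.tolist(),
            "scale_mean": self.model.scale_mean.tolist(),
            "scale_std": self.model.scale_std.tolist(),
            "coef": self.model.coef.tolist(),
            "intercept": self.model.intercept,
            "C": self.model.C,
            "cv_mean_coefficients": self.coefficients.tolist(),
            "oof_scores": {k: float(v) for k, v in self.oof_scores.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelResult":
        with open(path) as fh:
            payload = json.load(fh)
        model = FittedGLM(
            feature_names=payload["feature_names"],
            impute_means=np.asarray(payload["impute_means"]),
            scale_mean=np.asarray(payload["scale_mean"]),
            scale_std=np.asarray(payload["scale_std"]),
            coef=np.asarray(payload["coef"]),
            intercept=payload["intercept"],
            C=payload["C"],
        )
        oof = pd.Series(payload["oof_scores"])
        coeffs = pd.Series(payload["cv_mean_coefficients"], index=payload["feature_names"])
        return cls(oof, model, payload["cv_config"], coeffs)


def _fit_split(X: np.ndarray, y: np.ndarray, Cs, inner_folds: int, seed: int):
    """Impute/standardise on the given training rows and fit the penalised
    logistic model, with the L2 strength chosen by inner stratified CV over
    the C grid (mean held-out log-loss); returns the FittedGLM arrays."""
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    X = np.where(np.isnan(X), means, X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    best_C = float(Cs[len(Cs) // 2])
    # inner CV needs >= 2 members per class per fold pool
    inner_folds = min(inner_folds, int(np.bincount(y).min()))
    if len(Cs) > 1 and inner_folds >= 2:
        inner = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
        losses = np.zeros(len(Cs))
        for tr, te in inner.split(Z, y):
            for ic, C in enumerate(Cs):
                clf = LogisticRegression(C=C, max_iter=3000)
                clf.fit(Z[tr], y[tr])
                p = np.clip(clf.predict_proba(Z[te])[:, 1], 1e-12, 1 - 1e-12)
                losses[ic] -= float(
                    np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
                )
        best_C = float(Cs[int(np.argmin(losses))])
    clf = LogisticRegression(C=best_C, max_iter=3000)
    clf.fit(Z, y)
    return means, mu, sd, clf.coef_[0].copy(), float(clf.intercept_[0]), best_C


def train_glm_cv(
    matrix: FeatureMatrix,
    folds: int = 10,
    repeats: int = 200,
    seed: int = 0,
    Cs=DEFAULT_CS,
    inner_folds: int = 5,
) -> ModelResult:
    """Repeated stratified k-fold CV producing oof cancer scores and a locked
    refit-on-all model."""
    if matrix.labels is None:
        raise ValueError("feature matrix has no labels")
    y = matrix.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both classes")
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} samples per class for {folds}-fold stratified CV"
        )
    # canonical ordering makes results invariant to input sample/column order
    order = np.argsort(np.asarray(matrix.sample_ids, dtype=object))
    ids = [matrix.sample_ids[i] for i in order]
    cols = sorted(matrix.feature_names)
    X = matrix.values.loc[ids, cols].to_numpy(dtype=float)
    y = matrix.labels.loc[ids].to_numpy()

    ss = np.random.SeedSequence([int(seed), 0x61A0])
    repeat_seeds = ss.generate_state(repeats * 2) % (2**31)
    score_sum = np.zeros(len(y))
    coef_sum = np.zeros(X.shape[1])
    n_fits = 0
    for r in range(repeats):
        skf = StratifiedKFold(folds, shuffle=True, random_state=int(repeat_seeds[2 * r]))
        for train_idx, test_idx in skf.split(X, y):
            means, mu, sd, coef, intercept, _C = _fit_split(
                X[train_idx], y[train_idx], Cs, inner_folds, int(repeat_seeds[2 * r + 1])
            )
            Xt = X[test_idx]
            Xt = np.where(np.isnan(Xt), means, Xt)
            Z = (Xt - mu) / sd
            score_sum[test_idx] += 1.0 / (1.0 + np.exp(-(Z @ coef + intercept)))
            coef_sum += coef
            n_fits += 1
    oof = pd.Series(score_sum / repeats, index=ids, name="oof_score")

    means, mu, sd, coef, intercept, best_C = _fit_split(
        X, y, Cs, inner_folds, int(ss.generate_state(1)[0] % (2**31))
    )
    model = FittedGLM(cols, means, mu, sd, coef, intercept, best_C)
    insample = pd.Series(model.predict(matrix.values.loc[ids]), index=ids, name="insample_score")
    logger.info(
        "train_glm_cv: %d samples x %d features, %d fits, locked C=%g",
        len(y),
        X.shape[1],
        n_fits,
        best_C,
    )
    return ModelResult(
        oof_scores=oof,
        model=model,
        cv_config={"folds": folds, "repeats": repeats, "seed": int(seed), "Cs": list(Cs)},
        coefficients=pd.Series(coef_sum / max(n_fits, 1), index=cols),
        insample_scores=insample,
    )


def predict_scores(result: ModelResult, matrix: FeatureMatrix) -> pd.Series:
    """Score samples with the locked model (stored imputation/scaling)."""
    return pd.Series(
        result.model.predict(matrix.values), index=matrix.values.index, name="cancer_score"
    )


def roc_metrics(scores, labels) -> dict:
    """AUC (rank/trapezoid; ties handled by midranks via the ROC curve) and
    the full curve points at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return {
        "auc": float(sk_auc(fpr, tpr)),
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
    }


def operating_point(scores, labels, spec_target: float = 0.95) -> dict:
    """Choose the smallest score threshold whose specificity meets the target
    (call positive when score >= threshold) and report the confusion metrics.

    Among qualifying thresholds the smallest maximises sensitivity; with
    spec_target <= 0 the threshold is -inf (everything positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("operating point requires both classes")
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    threshold = np.inf
    for t in candidates:  # ascending; first qualifying = max sensitivity
        specificity = float((neg < t).mean())
        if specificity >= spec_target:
            threshold = float(t)
            break
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "spec_target": spec_target,
        "threshold": threshold,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "accuracy": (tp + tn) / len(labels),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


def evaluate(
    scores,
    labels,
    metadata: pd.DataFrame | None = None,
    spec_targets=SPEC_TARGETS,
    primary_spec: float = 0.95,
    threshold: float | None = None,
) -> dict:
    """Full evaluation report: AUC, operating point (at a fixed threshold if
    given, else chosen at ``primary_spec`` specificity on these scores),
    sensitivity at each fixed specificity, and subgroup breakdowns."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    roc = roc_metrics(scores, labels)
    if threshold is None:
        op = operating_point(scores, labels, primary_spec)
    else:
        op = _metrics_at_threshold(scores, labels, threshold)
    report = {
        "n": int(len(labels)),
        "n_benign": int((labels == 0).sum()),
        "n_malignant": int((labels == 1).sum()),
        "auc": roc["auc"],
        "threshold": op["threshold"],
        "accuracy": op["accuracy"],
        "sensitivity": op["sensitivity"],
        "specificity": op["specificity"],
        "ppv": op["ppv"],
        "npv": op["npv"],
        "confusion": op["confusion"],
        "sensitivity_at_spec": {
            f"{t:.2f}": operating_point(scores, labels, t)["sensitivity"]
            for t in spec_targets
        },
    }
    if metadata is not None:
        report["subgroups"] = subgroup_eval(scores, labels, metadata)
    return report


def _metrics_at_threshold(scores, labels, threshold: float) -> dict:
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    return {
        "threshold": float(threshold),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "accuracy": (tp + tn) / len(labels),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


EARLY_STAGES = {"I", "II"}
LATE_STAGES = {"III", "IV"}


def subgroup_eval(scores, labels, metadata: pd.DataFrame) -> dict:
    """Per-subgroup ROC/operating metrics.

    Stage subgroups compare the full benign set against the malignant subset
    of that stage band; sex and age subgroups restrict both classes.  Empty
    subgroups are reported as absent.  Malignant-only score contrasts across
    paired subgroups use a Wilcoxon rank-sum test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    meta = metadata.reset_index(drop=True)
    out: dict = {}

    def _eval(mask) -> dict | None:
        mask = np.asarray(mask)
        if len(np.unique(labels[mask])) < 2:
            return None
        sub_roc = roc_metrics(scores[mask], labels[mask])
        op = operating_point(scores[mask], labels[mask], 0.95)
        return {
            "n": int(mask.sum()),
            "auc": sub_roc["auc"],
            "sensitivity": op["sensitivity"],
            "specificity": op["specificity"],
        }

    stage = meta["stage"].fillna("").astype(str) if "stage" in meta else pd.Series("", index=meta.index)
    benign = labels == 0
    early_mask = benign | (stage.isin(EARLY_STAGES).to_numpy() & (labels == 1))
    late_mask = benign | (stage.isin(LATE_STAGES).to_numpy() & (labels == 1))
    for key, mask in [("stage_early", early_mask), ("stage_late", late_mask)]:
        r = _eval(mask & ((labels == 0) | mask))
        if r is not None and (mask & (labels == 1)).sum() > 0:
            out[key] = r
    mal_early = (labels == 1) & stage.isin(EARLY_STAGES).to_numpy()
    mal_late = (labels == 1) & stage.isin(LATE_STAGES).to_numpy()
    if mal_early.sum() >= 2 and mal_late.sum() >= 2:
        stat = mannwhitneyu(scores[mal_late], scores[mal_early], alternative="two-sided")
        out["stage_score_ranksum_p"] = float(stat.pvalue)

    if "sex" in meta:
        for key, val in [("sex_female", "F"), ("sex_male", "M")]:
            mask = (meta["sex"] == val).to_numpy()
            r = _eval(mask)
            if r is not None:
                out[key] = r
    if "age" in meta:
        age = pd.to_numeric(meta["age"], errors="coerce")
        for key, mask in [
            ("age_lt65", (age < 65).to_numpy()),
            ("age_ge65", (age >= 65).to_numpy()),
        ]:
            r = _eval(mask)
            if r is not None:
                out[key] = r
    return out
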