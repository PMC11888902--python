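"""Validation schemes and binary-classification metrics.

All metrics are computed from the confusion-matrix cells with hypertensive=1
as the positive class: accuracy, precision, sensitivity (recall),
specificity, F1, Jaccard, Cohen's kappa, ROC-AUC (trapezoidal, equal to the
Mann-Whitney rank statistic with ties counted half) and McNemar's paired
chi-square test. Splits are stratified and, by default, group-aware: all
segments of one source recording stay on the same side, preventing
twin-segment leakage that would otherwise inflate scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, train_test_split

from bcgkit.features import standardize_features

__all__ = [
    "ConfusionMatrix",
    "PairedErrorTable",
    "EvaluationReport",
    "confusion",
    "basic_metrics",
    "cohens_kappa",
    "mcnemar_test",
    "roc_auc",
    "holdout_split",
    "kfold_cv",
    "evaluate_model",
    "compare_models",
    "parse_scheme",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity",
                "f1", "jaccard", "kappa", "auc")


def _check_binary(*label_vectors) -> list[np.ndarray]:
    out = []
    n = None
    for v in label_vectors:
        v = np.asarray(v, dtype=int).ravel()
        if n is None:
            n = v.shape[0]
        elif v.shape[0] != n:
            raise ValueError("label vectors have different lengths")
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("labels must lie in {0, 1}")
        out.append(v)
    return out


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PairedErrorTable:
    """Discordant/concordant counts for two classifiers on the same samples."""

    both_correct: int
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    both_wrong: int

    @property
    def total(self) -> int:
        return self.both_correct + self.b + self.c + self.both_wrong


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Confusion counts with class 1 (hypertensive) positive."""
    y_true, y_pred = _check_binary(y_true, y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float, warn_label: str) -> float:
    if den == 0:
        warnings.warn(f"{warn_label}: 0/0 encountered, returning 0", stacklevel=3)
        return 0.0
    return num / den


def basic_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, sensitivity, specificity, F1 and Jaccard.

    Degenerate 0/0 ratios (e.g. precision with no positive predictions)
    return 0 with a warning rather than raising, so cross-validation loops
    survive degenerate folds.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    precision = _safe_ratio(tp, tp + fp, "precision")
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity")
    specificity = _safe_ratio(tn, tn + fp, "specificity")
    f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity, "f1")
    jaccard = _safe_ratio(tp, tp + fp + fn, "jaccard")
    return {
        "accuracy": (tp + tn) / cm.total,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "jaccard": jaccard,
    }


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (P_o - P_e) / (1 - P_e).

    P_e is the agreement expected from the marginal label frequencies. When
    both raters use a single identical category (P_e = 1), kappa is defined
    as 1 for perfect agreement and 0 otherwise, with a warning.
    """
    y_true, y_pred = _check_binary(y_true, y_pred)
    n = y_true.shape[0]
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = float(np.mean(y_true == y_pred))
    p_e = 0.0
    for k in (0, 1):
        p_e += float(np.mean(y_true == k)) * float(np.mean(y_pred == k))
    if p_e >= 1.0 - 1e-15:
        warnings.warn("kappa degenerate: both raters constant", stacklevel=2)
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def paired_error_table(y_true, pred_a, pred_b) -> PairedErrorTable:
    y_true, pred_a, pred_b = _check_binary(y_true, pred_a, pred_b)
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    return PairedErrorTable(
        both_correct=int(np.sum(a_ok & b_ok)),
        b=int(np.sum(a_ok & ~b_ok)),
        c=int(np.sum(~a_ok & b_ok)),
        both_wrong=int(np.sum(~a_ok & ~b_ok)),
    )


def mcnemar_test(y_true, pred_a, pred_b, correction: bool = False) -> tuple[float, float]:
    """McNemar chi-square on the discordant counts of two classifiers.

    chi2 = (b - c)^2 / (b + c); with the optional continuity correction the
    numerator becomes (|b - c| - 1)^2. When the models never disagree
    (b + c = 0) the statistic is 0 and p = 1. p-value from the chi-square
    distribution with one degree of freedom.
    """
    table = paired_error_table(y_true, pred_a, pred_b)
    b, c = table.b, table.c
    if b + c == 0:
        return 0.0, 1.0
    if correction:
        chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    else:
        chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def roc_auc(y_true, scores) -> tuple[float, np.ndarray]:
    """ROC curve and trapezoidal AUC for scores of the positive class.

    The curve sweeps every distinct score as a threshold, from (0, 0) to
    (1, 1) with FPR = 1 - specificity on the abscissa. Trapezoidal
    integration over this curve equals the Mann-Whitney rank statistic with
    tied pairs counted one half.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if y_true.shape[0] != scores.shape[0]:
        raise ValueError("length mismatch")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_true = y_true[order]
    # cumulative counts at each distinct-score cut
    distinct = np.where(np.diff(sorted_scores))[0]
    cuts = np.r_[distinct, sorted_true.shape[0] - 1]
    tps = np.cumsum(sorted_true)[cuts]
    fps = (cuts + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return auc, points


# ------------------------------------------------------------------- splits


def holdout_split(labels, groups=None, test_fraction: float = 0.25,
                  stratified: bool = True, group_aware: bool = True,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified train/test partition at the given test fraction.

    With ``group_aware`` (default) the split operates on source recordings,
    so sibling segments never straddle the boundary; stratification then
    applies to recording labels. Raises if either side ends up single-class.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    idx = np.arange(labels.shape[0])
    if group_aware:
        if groups is None:
            raise ValueError("group_aware split requires groups")
        groups = np.asarray(groups)
        uniq, first = np.unique(groups, return_index=True)
        group_labels = labels[first]
        train_g, test_g = train_test_split(
            uniq, test_size=test_fraction, random_state=seed,
            stratify=group_labels if stratified else None,
        )
        train_idx = idx[np.isin(groups, train_g)]
        test_idx = idx[np.isin(groups, test_g)]
    else:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=seed,
            stratify=labels if stratified else None,
        )
    for side, name in ((train_idx, "train"), (test_idx, "test")):
        if len(np.unique(labels[side])) < 2:
            raise ValueError(f"{name} side is single-class; adjust the split")
    return np.sort(train_idx), np.sort(test_idx)


def kfold_cv(labels, groups=None, k: int = 5, stratified: bool = True,
             group_aware: bool = True, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint stratified folds; group-aware by default."""
    labels = np.asarray(labels, dtype=int).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if group_aware:
        if groups is None:
            raise ValueError("group_aware CV requires groups")
        groups = np.asarray(groups)
        if k > len(np.unique(groups)):
            raise ValueError("k exceeds the number of groups")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(np.sort(tr), np.sort(te))
                for tr, te in splitter.split(labels[:, None], labels, groups)]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(np.sort(tr), np.sort(te))
            for tr, te in splitter.split(labels[:, None], labels)]


def parse_scheme(scheme: str) -> tuple[str, float | int]:
    """Parse ``"holdout:0.25"`` / ``"holdout:0.5"`` / ``"cv:5"`` / ``"cv:10"``."""
    kind, _, value = scheme.partition(":")
    if kind == "holdout":
        frac = float(value)
        return "holdout", frac
    if kind == "cv":
        return "cv", int(value)
    raise ValueError(f"unknown scheme {scheme!r}; use 'holdout:<frac>' or 'cv:<k>'")


# ------------------------------------------------------------------ reports


@dataclass
class EvaluationReport:
    """Per-split metric bundle plus the unweighted mean across splits."""

    scheme: str
    seed: int
    splits: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    mcnemar_p: float | None = None

    def to_json(self, path=None) -> str:
        def convert(obj):
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        text = json.dumps(convert(asdict(self)), indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        """Flat metric table: one row per split plus a 'mean' row."""
        rows = []
        for i, split in enumerate(self.splits):
            rows.append({"split": i, **{m: split[m] for m in METRIC_NAMES}})
        if self.mean:
            rows.append({"split": "mean", **{m: self.mean[m] for m in METRIC_NAMES}})
        return pd.DataFrame(rows)


def _evaluate_split(model_factory, X, y, train_idx, test_idx) -> dict:
    (X_train_s, X_test_s), _ = standardize_features(X[train_idx], X[test_idx])
    model = model_factory()
    model.fit(X_train_s, y[train_idx])
    proba = model.predict_proba(X_test_s)
    y_pred = np.argmax(proba, axis=1)
    y_test = y[test_idx]
    cm = confusion(y_test, y_pred)
    metrics = basic_metrics(cm)
    metrics["kappa"] = cohens_kappa(y_test, y_pred)
    auc, points = roc_auc(y_test, proba[:, 1])
    metrics["auc"] = auc
    metrics["roc_points"] = points
    metrics["confusion"] = asdict(cm)
    metrics["n_test"] = int(len(test_idx))
    metrics["predictions"] = y_pred
    metrics["test_indices"] = test_idx
    return metrics


def evaluate_model(model_factory, X, y, groups=None, scheme: str = "holdout:0.25",
                   seed: int = 0, group_aware: bool = True) -> EvaluationReport:
    """Train and evaluate a model under a named validation scheme.

    ``model_factory`` is a zero-argument callable returning an unfitted
    estimator with ``fit`` / ``predict_proba`` (see
    :func:`bcgkit.models.make_model`). Features are standardized with
    train-side statistics inside each split. For CV schemes the report
    carries per-fold metrics and their unweighted mean; for hold-out there
    is a single split (its metrics repeated as the mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    kind, value = parse_scheme(scheme)
    if kind == "holdout":
        partitions = [holdout_split(y, groups, test_fraction=value,
                                    group_aware=group_aware, seed=seed)]
    else:
        partitions = kfold_cv(y, groups, k=value, group_aware=group_aware, seed=seed)
    report = EvaluationReport(scheme=scheme, seed=seed)
    for train_idx, test_idx in partitions:
        report.splits.append(_evaluate_split(model_factory, X, y, train_idx, test_idx))
    report.mean = {
        m: float(np.mean([s[m] for s in report.splits])) for m in METRIC_NAMES
    }
    return report


def compare_models(y_true, pred_a, pred_b, correction: bool = False) -> dict:
    """Pairwise McNemar comparison of two prediction vectors."""
    table = paired_error_table(y_true, pred_a, pred_b)
    chi2, p = mcnemar_test(y_true, pred_a, pred_b, correction=correction)
    return {"chi2": chi2, "p": p, "b": table.b, "c": table.c,
            "both_correct": table.both_correct, "both_wrong": table.both_wrong}


def plot_roc(points: np.ndarray, path, label: str = "model") -> None:
    """Optional ROC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(points[:, 0], points[:, 1], label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("False positive rate (1 - specificity)")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
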