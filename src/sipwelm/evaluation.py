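"""Evaluation protocol: confusion metrics, ROC/AUC, holdout and 5-fold CV.

The positive class (+1) is "self-interacting". Reported metrics are
accuracy (Ac), sensitivity (Sn = TP/(TP+FN)), specificity (Sp), precision
(Pe) and Matthews correlation coefficient (MCC), plus the trapezoid AUC of
the score-threshold ROC. Cross-validation is stratified by default and the
aggregate row reports mean +/- population standard deviation per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, KFold

from sipwelm.features import (
    DEFAULT_PCA_DIM,
    FeatureMatrix,
    minmax_apply,
    minmax_fit,
    pca_apply,
    pca_fit,
)
from sipwelm.welm import TrainingConfig, welm_predict, welm_score, welm_train

METRIC_NAMES = ("Ac", "Sn", "Sp", "Pe", "MCC", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Derived metrics; ``zero_denominator`` lists metrics whose denominator
    was zero and which are therefore reported as 0 by convention."""

    Ac: float
    Sn: float
    Sp: float
    Pe: float
    MCC: float
    counts: ConfusionCounts
    AUC: float = float("nan")
    zero_denominator: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class CVReport:
    """Per-fold metric reports plus mean / population-std aggregates."""

    per_fold: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]
    seed: int
    fold_assignments: np.ndarray  # fold index of every sample

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per fold plus mean and std rows."""
        rows = [
            {"fold": i + 1, **r.as_dict()} for i, r in enumerate(self.per_fold)
        ]
        rows.append({"fold": "mean", **self.mean})
        rows.append({"fold": "std", **self.std})
        return pd.DataFrame(rows)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count the four confusion cells for +1/-1 labels (+1 = SIP)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(np.unique(arr)) - {-1, 1}
        if bad:
            raise ValueError(f"{name} labels must be +1/-1, found {sorted(bad)}")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Ac/Sn/Sp/Pe/MCC from confusion counts.

    A metric whose denominator is zero is reported as 0 and named in
    ``zero_denominator`` instead of raising.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated samples")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    flagged: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    ac = (tp + tn) / counts.total
    sn = ratio(tp, tp + fn, "Sn")
    sp = ratio(tn, tn + fp, "Sp")
    pe = ratio(tp, tp + fp, "Pe")
    mcc_den = np.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return MetricsReport(
        Ac=ac, Sn=sn, Sp=sp, Pe=pe, MCC=mcc,
        counts=counts, zero_denominator=tuple(flagged),
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR arrays) and trapezoid AUC from decision scores.

    The trapezoid AUC over the threshold sweep equals the Mann-Whitney
    pairwise statistic P(score_pos > score_neg) + 0.5 P(tie).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = set(np.unique(y_true))
    if classes != {-1, 1}:
        raise ValueError(
            f"ROC needs both classes present with +1/-1 labels, got {sorted(classes)}"
        )
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def holdout_split(
    dataset: FeatureMatrix,
    fraction: float = 1.0 / 6.0,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded (train, test) split with round(fraction * n) test samples.

    Stratified by default: per-class test counts follow a largest-remainder
    apportionment of the overall test size, so the test class ratio is
    within one sample of the global ratio.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = dataset.n
    n_test = int(round(fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"fraction {fraction} yields an empty split for n={n}"
        )
    rng = np.random.default_rng(seed)
    if stratify and dataset.y is not None:
        test_idx: list[int] = []
        quotas = {}
        rema = []
        for cls in (-1, 1):
            members = np.flatnonzero(dataset.y == cls)
            exact = fraction * len(members)
            quotas[cls] = int(np.floor(exact))
            rema.append((exact - np.floor(exact), cls))
        short = n_test - sum(quotas.values())
        for _, cls in sorted(rema, reverse=True)[:short]:
            quotas[cls] += 1
        for cls in (-1, 1):
            members = rng.permutation(np.flatnonzero(dataset.y == cls))
            test_idx.extend(members[: quotas[cls]])
        test_idx = np.sort(np.array(test_idx))
    else:
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return dataset.subset(np.flatnonzero(~mask)), dataset.subset(test_idx)


def five_fold_cv(
    dataset: FeatureMatrix,
    cfg: TrainingConfig | None = None,
    pca_dim: int | None = DEFAULT_PCA_DIM,
    seed: int = 0,
    n_folds: int = 5,
    stratify: bool = True,
    pca_fit_scope: str = "train",
    scale_inputs: bool = True,
) -> CVReport:
    """Stratified k-fold cross-validation of the PCA + WELM pipeline.

    Per fold: optionally fit PCA on the training folds only (``pca_fit_scope
    = 'train'``, the leakage-free default; ``'all'`` fits once on the full
    dataset), rescale classifier inputs to the training folds' [-1, 1] range
    (``scale_inputs``), train a WELM, and evaluate on the held-out fold.
    ``pca_dim = None`` skips PCA. Aggregates are the mean and population
    standard deviation over folds.
    """
    if dataset.y is None:
        raise ValueError("cross-validation requires labels")
    y = dataset.y
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    if stratify and n_min < n_folds:
        raise ValueError(
            f"minority class has {n_min} members; needs >= {n_folds} for "
            f"{n_folds} stratified folds"
        )
    if pca_fit_scope not in ("train", "all"):
        raise ValueError("pca_fit_scope must be 'train' or 'all'")
    cfg = cfg or TrainingConfig()

    splitter = (
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        if stratify
        else KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    )
    global_pca = (
        pca_fit(dataset, pca_dim)
        if (pca_dim is not None and pca_fit_scope == "all")
        else None
    )

    per_fold: list[MetricsReport] = []
    assignments = np.full(dataset.n, -1, dtype=int)
    for fold, (tr, te) in enumerate(splitter.split(dataset.X, y)):
        assignments[te] = fold
        train, test = dataset.subset(tr), dataset.subset(te)
        if pca_dim is not None:
            model_pca = global_pca or pca_fit(train, pca_dim)
            train = pca_apply(model_pca, train)
            test = pca_apply(model_pca, test)
        if scale_inputs:
            scaler = minmax_fit(train)
            train = minmax_apply(scaler, train)
            test = minmax_apply(scaler, test)
        model = welm_train(train.X, train.y, cfg)
        pred = welm_predict(model, test.X)
        report = compute_metrics(confusion_counts(test.y, pred))
        _, _, report.AUC = roc_auc(test.y, welm_score(model, test.X))
        per_fold.append(report)

    mean = {
        m: float(np.mean([getattr(r, m) for r in per_fold])) for m in METRIC_NAMES
    }
    std = {
        m: float(np.std([getattr(r, m) for r in per_fold])) for m in METRIC_NAMES
    }
    return CVReport(
        per_fold=per_fold, mean=mean, std=std, seed=seed,
        fold_assignments=assignments,
    )
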