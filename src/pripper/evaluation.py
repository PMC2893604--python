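"""Quality measures, leave-one-out protocol, ROC curves, bootstrap comparison.

The quality measures are the standard confusion-matrix summaries:
ACC = (TP+TN)/N, PRC = TP/(TP+FP), FDR = FP/(TP+FP) = 1−PRC,
SPC = TN/(TN+FP), and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Leave-one-out retrains the classifier N times, once per held-out
sample, and aggregates the N single-sample predictions into one
confusion matrix — the protocol used both for hyperparameter selection
and for the headline quality measures.

The bootstrap comparison resamples the evaluated site set with
replacement (default 10 000 replicates), classifies each replicate with
every classifier at its fixed native threshold, and reports the mean
and standard deviation of (FPR, TPR) per classifier — a point cloud,
not a curve, because thresholds are not swept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from sklearn import metrics as _skm

from .classifiers import ClassifierConfig, SiteClassifier, VoteClassifier, train
from .dataset import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == -1) & (yp == 1))),
            tn=int(np.sum((yt == -1) & (yp == -1))),
            fn=int(np.sum((yt == 1) & (yp == -1))),
        )


@dataclass(frozen=True)
class QualityMeasures:
    """ACC/PRC/FDR/SPC/MCC with explicit undefined-value flags.

    When TP+FP = 0 precision and the false discovery rate are undefined
    and reported as NaN with ``undefined_precision`` set; a zero MCC
    denominator yields MCC = 0 by the usual convention.
    """

    acc: float
    prc: float
    fdr: float
    spc: float
    mcc: float
    undefined_precision: bool = False
    undefined_specificity: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "prc": self.prc,
            "fdr": self.fdr,
            "spc": self.spc,
            "mcc": self.mcc,
        }


def quality_measures(c: ConfusionCounts) -> QualityMeasures:
    """Compute the five quality measures from confusion counts."""
    n = c.total
    if n == 0:
        raise ValueError("confusion counts are all zero")
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    acc = (tp + tn) / n
    if tp + fp > 0:
        prc = tp / (tp + fp)
        fdr = fp / (tp + fp)
        undef_prc = False
    else:
        prc = math.nan
        fdr = math.nan
        undef_prc = True
    if tn + fp > 0:
        spc = tn / (tn + fp)
        undef_spc = False
    else:
        spc = math.nan
        undef_spc = True
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return QualityMeasures(acc, prc, fdr, spc, mcc, undef_prc, undef_spc)


@dataclass
class LooResult:
    """Per-sample leave-one-out predictions and decision scores."""

    predictions: np.ndarray
    scores: np.ndarray
    y_true: np.ndarray
    n_degenerate_folds: int = 0

    @property
    def counts(self) -> ConfusionCounts:
        return ConfusionCounts.from_labels(self.y_true, self.predictions)


def loo_predict(
    ds: LabeledDataset,
    config: ClassifierConfig,
    *,
    on_degenerate: str = "majority",
) -> LooResult:
    """Leave-one-out predictions: N refits, each tested on its held-out sample.

    A fold whose training part loses a class entirely (possible only in
    tiny datasets) is handled per ``on_degenerate``: ``"majority"``
    predicts the training fold's remaining class with a warning;
    ``"error"`` raises.
    """
    n = len(ds)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    if set(np.unique(ds.y)) != {-1, 1}:
        raise ValueError("leave-one-out needs both classes present")
    preds = np.zeros(n, dtype=np.int64)
    scores = np.zeros(n, dtype=np.float64)
    degenerate = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_tr = ds.y[mask]
        classes = set(np.unique(y_tr))
        if classes != {-1, 1}:
            if on_degenerate == "error":
                raise ValueError(f"fold {i}: training set lost a class")
            only = int(next(iter(classes)))
            warnings.warn(
                f"fold {i}: single-class training fold, predicting {only}"
            )
            preds[i] = only
            scores[i] = math.inf if only == 1 else -math.inf
            degenerate += 1
            mask[i] = True
            continue
        fold = LabeledDataset(
            X=ds.X[mask], y=y_tr, geometry=ds.geometry, provenance="loo-fold"
        )
        clf = train(fold, config)
        x = ds.X[i : i + 1]
        preds[i] = int(clf.classify(x)[0])
        scores[i] = float(clf.decision_scores(x)[0])
        mask[i] = True
    return LooResult(preds, scores, ds.y.copy(), degenerate)


def leave_one_out(
    ds: LabeledDataset, config: ClassifierConfig, **kwargs
) -> ConfusionCounts:
    """Aggregate confusion counts from the leave-one-out protocol."""
    return loo_predict(ds, config, **kwargs).counts


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered by increasing FPR, with trapezoidal AUC.

    Endpoints (0,0) and (1,1) are always included; ``thresholds`` holds
    the decision-score threshold generating each point (the endpoints
    carry ±inf).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_scores(y_true: Sequence[int], scores: Sequence[float]) -> RocCurve:
    """Build an ROC curve from ±1 labels and continuous decision scores."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(y, s, pos_label=1, drop_intermediate=False)
    # guarantee the (1,1) endpoint; sklearn already anchors (0,0)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    thr = thr.astype(np.float64)
    thr[0] = np.inf
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def roc_curve(
    clf: SiteClassifier, ds: LabeledDataset
) -> RocCurve:
    """ROC of a fitted classifier's decision scores on a dataset.

    Thresholds are taken at every distinct score.  Note the Vote
    ensemble is threshold-free (binary votes) and has no curve; it is
    compared as a single (FPR, TPR) point via :func:`bootstrap_compare`.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    return roc_from_scores(ds.y, clf.decision_scores(ds.X))


@dataclass(frozen=True)
class BootstrapPoint:
    """Mean ± sd of (FPR, TPR) over bootstrap replicates."""

    mean_fpr: float
    mean_tpr: float
    sd_fpr: float
    sd_tpr: float
    n_replicates: int
    n_skipped: int


def bootstrap_compare(
    classifiers: Mapping[str, Union[SiteClassifier, VoteClassifier, None]],
    ds: LabeledDataset,
    *,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    predictions: Optional[Mapping[str, Sequence[int]]] = None,
) -> dict[str, BootstrapPoint]:
    """Fixed-threshold bootstrap comparison of classifiers.

    Each replicate resamples the evaluated sites with replacement (same
    resample for every classifier, so the comparison is paired) and
    records each classifier's (FPR, TPR) at its native threshold.
    Replicates lacking either class are skipped and tallied.

    By default each classifier's ±1 predictions on ``ds`` come from
    ``predictions[name]`` (e.g. leave-one-out predictions); when absent
    the classifier is applied to ``ds.X`` directly (Vote members then
    share the dataset's geometry, so per-member windows require
    precomputed predictions).
    """
    n = len(ds)
    if n == 0:
        raise ValueError("empty dataset")
    pred_matrix: dict[str, np.ndarray] = {}
    for name, clf in classifiers.items():
        if predictions is not None and name in predictions:
            p = np.asarray(predictions[name], dtype=np.int64)
            if p.shape[0] != n:
                raise ValueError(f"predictions for {name!r} have wrong length")
        elif isinstance(clf, SiteClassifier):
            p = clf.classify(ds.X)
        else:
            raise ValueError(
                f"classifier {name!r} needs precomputed predictions"
            )
        pred_matrix[name] = p

    rng = np.random.default_rng(seed)
    y = ds.y
    out: dict[str, BootstrapPoint] = {}
    # draw all replicate index sets once so every classifier sees the
    # same resamples (paired comparison), chunked to bound memory
    stats = {name: ([], []) for name in pred_matrix}
    skipped = 0
    chunk = 1000
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        yb = y[idx]
        pos = yb == 1
        npos = pos.sum(axis=1)
        nneg = n - npos
        valid = (npos > 0) & (nneg > 0)
        skipped += int(np.sum(~valid))
        for name, p in pred_matrix.items():
            pb = p[idx]
            tp = ((pb == 1) & pos).sum(axis=1)
            fp = ((pb == 1) & ~pos).sum(axis=1)
            with np.errstate(invalid="ignore"):
                tprs = tp[valid] / npos[valid]
                fprs = fp[valid] / nneg[valid]
            stats[name][0].append(fprs)
            stats[name][1].append(tprs)
        done += m
    for name in pred_matrix:
        fprs = np.concatenate(stats[name][0]) if stats[name][0] else np.array([])
        tprs = np.concatenate(stats[name][1]) if stats[name][1] else np.array([])
        if fprs.size == 0:
            raise ValueError("all bootstrap replicates were single-class")
        out[name] = BootstrapPoint(
            mean_fpr=float(fprs.mean()),
            mean_tpr=float(tprs.mean()),
            sd_fpr=float(fprs.std(ddof=1)) if fprs.size > 1 else 0.0,
            sd_tpr=float(tprs.std(ddof=1)) if tprs.size > 1 else 0.0,
            n_replicates=int(fprs.size),
            n_skipped=skipped,
        )
    return out


def evaluation_report(
    measures: Mapping[str, QualityMeasures], *, percent: bool = True
) -> str:
    """TSV report of quality measures per classifier (ACC PRC FDR SPC MCC)."""
    cols = ("acc", "prc", "fdr", "spc", "mcc")
    lines = ["classifier\t" + "\t".join(c.upper() for c in cols)]
    for name, qm in measures.items():
        vals = qm.as_dict()
        scale = 100.0 if percent else 1.0
        lines.append(
            name
            + "\t"
            + "\t".join(
                f"{vals[c] * scale:.1f}" if not math.isnan(vals[c]) else "NA"
                for c in cols
            )
        )
    return "\n".join(lines) + "\n"
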