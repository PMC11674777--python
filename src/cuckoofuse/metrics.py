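"""Evaluation suite: accuracy, one-vs-rest precision/recall/F1 with
micro-averages, micro ROC-AUC, and Scott's Pi chance-corrected agreement.

Accuracy for the single-label multi-class task is correct/total; the pooled
(micro) precision, recall and F1 all coincide with it, which is why a single
micro row summarizes a model. Scott's Pi corrects observed agreement for the
chance agreement implied by the *pooled* marginal distribution of both label
streams (unlike Cohen's kappa, which uses each rater's own marginals); an
ordinal task can opt into linear or quadratic disagreement weights so that
near-misses between adjacent severity stages count less than distant errors.

Zero-denominator precision/recall are reported as 0 and flagged undefined
rather than raising, so batch evaluation never aborts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import multilabel_confusion_matrix, roc_auc_score

from .errors import UndefinedMetricError, ValidationError

WEIGHTINGS = ("none", "linear", "quadratic")


def _check_labels(truth, pred, K: Optional[int] = None):
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValidationError(
            f"label sequences must be equal-length 1-D, got {truth.shape} and {pred.shape}"
        )
    if truth.size < 1:
        raise ValidationError("need at least one sample")
    if K is not None:
        for name, arr in (("first", truth), ("second", pred)):
            if arr.min() < 0 or arr.max() >= K:
                raise ValidationError(f"{name} sequence has labels outside [0, {K})")
    return truth, pred


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts (TP/FP/FN/TN), each summing to N."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def confusion_counts(truth: Sequence[int], pred: Sequence[int], K: int) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class."""
    truth, pred = _check_labels(truth, pred, K)
    m = multilabel_confusion_matrix(truth, pred, labels=np.arange(K))
    return ConfusionCounts(
        tp=m[:, 1, 1].astype(np.int64),
        fp=m[:, 0, 1].astype(np.int64),
        fn=m[:, 1, 0].astype(np.int64),
        tn=m[:, 0, 0].astype(np.int64),
    )


def _prf(tp, fp, fn):
    """Precision/recall/F1 from pooled or per-class counts, with undefined flags."""
    tp = np.asarray(tp, dtype=np.float64)
    fp = np.asarray(fp, dtype=np.float64)
    fn = np.asarray(fn, dtype=np.float64)
    p_den = tp + fp
    r_den = tp + fn
    precision = np.divide(tp, p_den, out=np.zeros_like(tp), where=p_den > 0)
    recall = np.divide(tp, r_den, out=np.zeros_like(tp), where=r_den > 0)
    f_den = precision + recall
    f1 = np.divide(2 * precision * recall, f_den,
                   out=np.zeros_like(precision), where=f_den > 0)
    return (precision, p_den == 0), (recall, r_den == 0), (f1, f_den == 0)


def per_class_prf(counts: ConfusionCounts):
    """Per-class precision, recall and F1 (harmonic mean), with undefined flags.

    Returns three ``(values, undefined_mask)`` pairs in class order.
    """
    return _prf(counts.tp, counts.fp, counts.fn)


def micro_average(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Micro precision/recall/F1: pool TP/FP/FN over classes, then apply the
    binary formulas. Equal to accuracy for single-label multi-class input."""
    (p, _), (r, _), (f, _) = _prf(counts.tp.sum(), counts.fp.sum(), counts.fn.sum())
    return float(p), float(r), float(f)


def accuracy(truth: Sequence[int], pred: Sequence[int]) -> float:
    """Fraction of positions where prediction equals truth."""
    truth, pred = _check_labels(truth, pred)
    return float(np.mean(truth == pred))


def roc_auc_micro(truth: Sequence[int], probs: np.ndarray) -> float:
    """Micro-averaged ROC-AUC over the flattened one-vs-rest expansion.

    The N x K one-hot truth and score matrices are flattened into N*K binary
    decisions; the AUC is the probability that a positive outscores a
    negative, ties counted 1/2. Scores need not be normalized (fused weighted
    sums are accepted as-is).
    """
    truth = np.asarray(truth, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != truth.shape[0]:
        raise ValidationError(
            f"scores must be N x K with N == len(truth); got {probs.shape} for N={truth.size}"
        )
    if truth.size < 2:
        raise ValidationError("micro ROC-AUC needs at least 2 samples")
    K = probs.shape[1]
    onehot = np.zeros_like(probs)
    onehot[np.arange(truth.size), truth] = 1.0
    y = onehot.ravel()
    if y.min() == y.max():
        raise UndefinedMetricError("flattened one-vs-rest truth is single-class")
    return float(roc_auc_score(y, probs.ravel()))


def per_class_auc(truth: Sequence[int], probs: np.ndarray) -> list[Optional[float]]:
    """One-vs-rest AUC per class; ``None`` where a class never occurs (or
    always occurs) in the truth."""
    truth = np.asarray(truth, dtype=np.int64)
    out: list[Optional[float]] = []
    for k in range(probs.shape[1]):
        y = (truth == k).astype(int)
        if y.min() == y.max():
            out.append(None)
        else:
            out.append(float(roc_auc_score(y, probs[:, k])))
    return out


@dataclass
class AgreementResult:
    """Scott's Pi decomposition: observed agreement, chance agreement, pi."""

    po: float
    pe: float
    pi: Optional[float]

    @property
    def defined(self) -> bool:
        return self.pi is not None


def _agreement_weights(K: int, weighting: str) -> np.ndarray:
    if weighting not in WEIGHTINGS:
        raise ValidationError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")
    i, j = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    if weighting == "none":
        return (i == j).astype(np.float64)
    d = np.abs(i - j) / (K - 1)
    return 1.0 - (d if weighting == "linear" else d**2)


def scotts_pi(a: Sequence[int], b: Sequence[int], K: int,
              weighting: str = "none") -> AgreementResult:
    """Scott's Pi between two label streams.

    pi = (Po - Pe) / (1 - Pe), where Po is the (weighted) observed agreement
    and Pe the chance agreement under the pooled marginals
    m_k = (count_a(k) + count_b(k)) / (2N). Ordinal weighting replaces the
    exact-match indicator by 1 - |i-j|/(K-1) (linear) or 1 - ((i-j)/(K-1))^2
    (quadratic) in both Po and Pe. Symmetric in its arguments.

    When both streams are degenerate on one class, Pe = 1 and pi is
    undefined: the result carries ``pi=None`` rather than raising.
    """
    a, b = _check_labels(a, b, K)
    W = _agreement_weights(K, weighting)
    n = a.size
    po = float(np.mean(W[a, b]))
    m = (np.bincount(a, minlength=K) + np.bincount(b, minlength=K)) / (2.0 * n)
    pe = float(m @ W @ m)
    if pe >= 1.0 - 1e-12:
        return AgreementResult(po=po, pe=pe, pi=None)
    return AgreementResult(po=po, pe=pe, pi=float((po - pe) / (1.0 - pe)))


def agreement_matrix(label_streams: Sequence[np.ndarray], K: int,
                     weighting: str = "none") -> np.ndarray:
    """Symmetric matrix of pairwise Scott's Pi between argmax label streams.

    Diagonal cells are 1 except when a stream is degenerate on a single class
    (undefined agreement), where NaN is stored.
    """
    M = len(label_streams)
    out = np.full((M, M), np.nan)
    for i in range(M):
        for j in range(i, M):
            res = scotts_pi(label_streams[i], label_streams[j], K, weighting)
            val = np.nan if res.pi is None else res.pi
            out[i, j] = out[j, i] = val
    return out


@dataclass
class MetricsReport:
    """Full evaluation of one prediction stream against truth labels."""

    class_names: list[str]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    undefined: dict = field(default_factory=dict)   # metric -> list of flagged classes
    micro_precision: float = 0.0
    micro_recall: float = 0.0
    micro_f1: float = 0.0
    accuracy: float = 0.0
    roc_auc_micro: Optional[float] = None
    roc_auc_per_class: Optional[list] = None
    scotts_pi_vs_truth: Optional[float] = None
    scotts_pi_weighting: str = "none"

    def to_dict(self) -> dict:
        per_class = {
            name: {"precision": self.precision[k], "recall": self.recall[k],
                   "f1": self.f1[k],
                   "roc_auc": None if self.roc_auc_per_class is None
                   else self.roc_auc_per_class[k]}
            for k, name in enumerate(self.class_names)
        }
        return {
            "per_class": per_class,
            "micro_average": {"precision": self.micro_precision,
                              "recall": self.micro_recall, "f1": self.micro_f1},
            "accuracy": self.accuracy,
            "roc_auc_micro": self.roc_auc_micro,
            "scotts_pi_vs_truth": self.scotts_pi_vs_truth,
            "scotts_pi_weighting": self.scotts_pi_weighting,
            "undefined": self.undefined,
        }


def evaluate(truth: Sequence[int], probs: np.ndarray, class_names: Sequence[str],
             weighting: str = "none") -> MetricsReport:
    """Compute the full metric suite for one probability stream.

    ``probs`` may be raw weighted sums (fused output): labels come from the
    row argmax and ROC-AUC ranks raw scores, so no renormalization is needed.
    """
    from .fusion import argmax_labels

    truth = np.asarray(truth, dtype=np.int64)
    K = len(class_names)
    pred = argmax_labels(probs)
    counts = confusion_counts(truth, pred, K)
    (p, p_und), (r, r_und), (f, f_und) = per_class_prf(counts)
    mp, mr, mf = micro_average(counts)
    try:
        auc = roc_auc_micro(truth, probs)
    except (UndefinedMetricError, ValidationError):
        auc = None
    pi = scotts_pi(truth, pred, K, weighting)
    return MetricsReport(
        class_names=list(class_names),
        precision=[float(x) for x in p],
        recall=[float(x) for x in r],
        f1=[float(x) for x in f],
        undefined={
            "precision": [class_names[k] for k in np.nonzero(p_und)[0]],
            "recall": [class_names[k] for k in np.nonzero(r_und)[0]],
            "f1": [class_names[k] for k in np.nonzero(f_und)[0]],
        },
        micro_precision=mp, micro_recall=mr, micro_f1=mf,
        accuracy=accuracy(truth, pred),
        roc_auc_micro=auc,
        roc_auc_per_class=per_class_auc(truth, probs),
        scotts_pi_vs_truth=pi.pi,
        scotts_pi_weighting=weighting,
    )
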