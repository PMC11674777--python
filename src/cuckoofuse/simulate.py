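"""Synthetic label manifests and probabilistic classifier outputs.

Stands in for trained image classifiers: each simulated model has a *skill*
(the probability that the modal class of its emitted probability row equals
the true class) and a *concentration* (how sharply the row peaks on the modal
class). Errors can be biased toward adjacent severity stages, mirroring the
way real dementia-stage classifiers confuse neighbouring grades far more
often than distant ones. Pairs of models can share "hard cases" through an
error-event correlation ``rho``, which controls the inter-model agreement
that pairwise Scott's Pi measures.

Probability rows are Dirichlet draws with a single concentrated component
moved onto the modal class, then the largest component is swapped into the
modal slot — so the row argmax *equals* the modal class by construction and
empirical argmax accuracy is exactly Binomial(n, skill).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ClassScheme, DatasetManifest, PredictionSet
from .errors import ValidationError


@dataclass(frozen=True)
class SimModelSpec:
    """One simulated probabilistic classifier.

    skill
        Probability the emitted row's modal class is the true class.
    concentration
        Dirichlet mass added to the modal component; higher means nearer
        one-hot. Default 20: sharp but not saturated, so ROC-AUC stays
        informative.
    confusion_bias
        Decay factor in (0, 1] for error placement: a wrong class at ordinal
        distance d is chosen with weight ``confusion_bias**(d-1)``, so
        adjacent stages absorb most errors. ``None`` for uniform errors.
    """

    skill: float
    concentration: float = 20.0
    confusion_bias: Optional[float] = 0.5

    def __post_init__(self):
        if not (0.0 <= self.skill <= 1.0):
            raise ValidationError(f"skill must be in [0, 1], got {self.skill}")
        if self.concentration <= 0:
            raise ValidationError(f"concentration must be positive, got {self.concentration}")
        if self.confusion_bias is not None and not (0.0 < self.confusion_bias <= 1.0):
            raise ValidationError(
                f"confusion_bias must be in (0, 1] or None, got {self.confusion_bias}")


@dataclass(frozen=True)
class SimPairSpec:
    """Two simulated models whose error events correlate with strength rho.

    Per sample, with probability ``rho`` both models' error events are driven
    by one shared uniform draw (a common "hard case"); otherwise they are
    independent. rho=1 with equal skills makes the two error sets identical;
    rho=0 makes the joint-error rate the product of the marginal error rates.
    """

    spec_a: SimModelSpec
    spec_b: SimModelSpec
    rho: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValidationError(f"rho must be in [0, 1], got {self.rho}")


def generate_manifest(class_counts: Sequence[int], scheme: ClassScheme,
                      rng: np.random.Generator) -> DatasetManifest:
    """Manifest with exactly the requested per-class counts, shuffled order."""
    counts = np.asarray(class_counts, dtype=np.int64)
    if counts.shape != (scheme.K,):
        raise ValidationError(
            f"{counts.size} class counts for a {scheme.K}-class scheme")
    if np.any(counts < 0):
        raise ValidationError("class counts must be non-negative")
    if np.count_nonzero(counts) < 2:
        raise ValidationError("need at least two non-empty classes")
    labels = np.repeat(np.arange(scheme.K), counts)
    labels = labels[rng.permutation(labels.size)]
    ids = [f"s{i:07d}" for i in range(labels.size)]
    return DatasetManifest(ids, labels, scheme)


def _wrong_class(truth: np.ndarray, K: int, bias: Optional[float],
                 rng: np.random.Generator) -> np.ndarray:
    """Sample one wrong class per entry, adjacent-biased if requested."""
    out = np.empty(truth.size, dtype=np.int64)
    classes = np.arange(K)
    for i, t in enumerate(truth):
        others = classes[classes != t]
        if bias is None:
            out[i] = rng.choice(others)
        else:
            w = bias ** (np.abs(others - t) - 1.0)
            out[i] = rng.choice(others, p=w / w.sum())
    return out


def _concentrated_rows(modal: np.ndarray, K: int, concentration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Dirichlet rows peaked on — and argmax-guaranteed at — the modal class."""
    n = modal.size
    alpha = np.ones(K)
    alpha[0] += concentration
    rows = rng.dirichlet(alpha, size=n)
    idx = np.arange(n)
    jmax = np.argmax(rows, axis=1)
    tmp = rows[idx, modal].copy()
    rows[idx, modal] = rows[idx, jmax]
    rows[idx, jmax] = tmp
    return rows


def simulate_model_predictions(labels: Sequence[int], spec: SimModelSpec,
                               scheme: ClassScheme, rng: np.random.Generator,
                               model_id: str = "sim_model",
                               sample_ids: Optional[Sequence[str]] = None,
                               errors: Optional[np.ndarray] = None) -> PredictionSet:
    """Simulate one model's probability table over the given true labels.

    ``errors`` optionally fixes which samples the model gets wrong (used by
    the correlated-pair generator); otherwise each sample errs independently
    with probability ``1 - skill``.
    """
    truth = np.asarray(labels, dtype=np.int64)
    if truth.ndim != 1 or truth.size < 1:
        raise ValidationError("labels must be a non-empty 1-D sequence")
    if errors is None:
        errors = rng.random(truth.size) >= spec.skill
    modal = truth.copy()
    if errors.any():
        modal[errors] = _wrong_class(truth[errors], scheme.K, spec.confusion_bias, rng)
    probs = _concentrated_rows(modal, scheme.K, spec.concentration, rng)
    if sample_ids is None:
        sample_ids = [f"s{i:07d}" for i in range(truth.size)]
    return PredictionSet(model_id, list(sample_ids), probs, scheme, truth)


def simulate_correlated_pair(labels: Sequence[int], pair: SimPairSpec,
                             scheme: ClassScheme, rng: np.random.Generator,
                             model_ids: tuple[str, str] = ("sim_model_a", "sim_model_b"),
                             sample_ids: Optional[Sequence[str]] = None
                             ) -> tuple[PredictionSet, PredictionSet]:
    """Simulate two models whose error events share hard cases with strength rho."""
    truth = np.asarray(labels, dtype=np.int64)
    n = truth.size
    shared = rng.random(n) < pair.rho
    u = rng.random(n)
    u_a = np.where(shared, u, rng.random(n))
    u_b = np.where(shared, u, rng.random(n))
    err_a = u_a >= pair.spec_a.skill
    err_b = u_b >= pair.spec_b.skill
    if sample_ids is None:
        sample_ids = [f"s{i:07d}" for i in range(n)]
    ps_a = simulate_model_predictions(truth, pair.spec_a, scheme, rng,
                                      model_ids[0], sample_ids, errors=err_a)
    ps_b = simulate_model_predictions(truth, pair.spec_b, scheme, rng,
                                      model_ids[1], sample_ids, errors=err_b)
    return ps_a, ps_b
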