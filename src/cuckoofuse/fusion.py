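"""Probability-level (soft-voting) fusion of aligned prediction sets.

Two rules are provided: plain averaging, P = (P_A + P_B + ...)/M, and the
weighted sum P = sum_m w_m * P_m. Weights live in [0, 1] per model with **no**
sum-to-one constraint — weight pairs such as (0.5, 0.45) are legal and the
fused rows then sum to 0.95. Fused probabilities are never renormalized; the
decision rule is the row argmax, which is invariant to the weight scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import FusedPredictions, PredictionSet, validate_alignment
from .errors import DimensionError, ValidationError


@dataclass(frozen=True)
class WeightVector:
    """Per-model fusion weights, each in [0, 1], at least one positive."""

    weights: tuple[float, ...]

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if len(w) < 2:
            raise ValidationError(f"need at least 2 weights, got {len(w)}")
        for i, x in enumerate(w):
            if not (0.0 <= x <= 1.0):
                raise ValidationError(f"weight {i} is {x}, outside [0, 1]")
        if not any(x > 0 for x in w):
            raise ValidationError("all weights are zero")

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Row-wise argmax with ties broken toward the lowest class index.

    The lowest index is the least-severe stage under the scheme's ordering,
    so ties resolve conservatively and deterministically.
    """
    probs = np.asarray(probs)
    if probs.ndim != 2 or probs.size == 0:
        raise DimensionError(f"need a non-empty N x K matrix, got shape {probs.shape}")
    if np.any(probs < 0):
        raise ValidationError("scores must be non-negative")
    return np.argmax(probs, axis=1).astype(np.int64)


def weighted_fuse(models: Sequence[PredictionSet], w: WeightVector) -> FusedPredictions:
    """Fuse aligned models by the weighted sum of their probability matrices.

    ``probs[i, k] = sum_m w_m * probs_m[i, k]``; each fused row sums to the
    weight total when every input row sums to 1. Labels are the tie-broken
    argmax of the fused rows.
    """
    models = list(models)
    if len(models) < 2:
        raise DimensionError(f"fusion needs at least 2 models, got {len(models)}")
    if len(w) != len(models):
        raise DimensionError(
            f"{len(w)} weights for {len(models)} models"
        )
    validate_alignment(models)
    weights = w.as_array()
    probs = np.zeros_like(models[0].probs)
    for wm, m in zip(weights, models):
        probs += wm * m.probs
    truth = next((m.truth for m in models if m.truth is not None), None)
    return FusedPredictions(
        probs=probs,
        labels=argmax_labels(probs),
        weights_used=weights,
        source_model_ids=[m.model_id for m in models],
        sample_ids=list(models[0].sample_ids),
        scheme=models[0].scheme,
        truth=None if truth is None else truth.copy(),
    )


def average_fuse(models: Sequence[PredictionSet]) -> FusedPredictions:
    """Equal-weight fusion: the element-wise mean of the model matrices.

    Identical (bit-for-bit) to ``weighted_fuse`` with all weights 1/M.
    """
    models = list(models)
    if len(models) < 2:
        raise DimensionError(f"fusion needs at least 2 models, got {len(models)}")
    return weighted_fuse(models, WeightVector((1.0 / len(models),) * len(models)))
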