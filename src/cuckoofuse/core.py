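"""Core data types: class schemes, prediction sets, manifests, fused outputs.

The ordering of class labels is significant throughout: severity stages are
ordinal (none < very mild < mild < moderate for the dementia screening task
this package was built around), and both the ordinal agreement weights and the
argmax tie rule depend on it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: Row-probability sum tolerance: rows must sum to 1 within this bound.
ROW_SUM_TOL = 1e-6

#: The closed set of split tags a manifest entry may carry.
SPLIT_TAGS = ("unassigned", "test", "train", "validation")


@dataclass(frozen=True)
class ClassScheme:
    """An ordered, fixed set of class labels.

    Parameters
    ----------
    names
        Class labels in increasing severity order. Order is significant:
        ordinal metrics and the argmax tie rule both depend on it.
    """

    names: tuple[str, ...]

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 2:
            raise ValidationError(f"a class scheme needs at least 2 classes, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValidationError(f"class names must be unique, got {names}")

    @property
    def K(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown class name {name!r}; scheme has {self.names}") from None


#: Default scheme for the four-stage dementia severity task.
DEMENTIA_SCHEME = ClassScheme(("none", "very_mild", "mild", "moderate"))

#: Published per-class scan counts for the OASIS-derived severity dataset,
#: in scheme order (none, very_mild, mild, moderate).
OASIS_CLASS_COUNTS = (67_222, 13_725, 5_002, 488)


def _as_prob_matrix(probs, n_classes: int) -> np.ndarray:
    arr = np.asarray(probs, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"probability matrix must be 2-D, got shape {arr.shape}")
    if arr.shape[1] != n_classes:
        raise ValidationError(
            f"probability matrix has {arr.shape[1]} columns but the scheme has {n_classes} classes"
        )
    return arr


@dataclass
class PredictionSet:
    """One model's per-sample class-probability output.

    ``probs`` is an N x K matrix; every row is a probability distribution over
    the scheme's classes (sum within ``ROW_SUM_TOL`` of 1). ``truth`` holds
    class *indices* in memory; files store class names.
    """

    model_id: str
    sample_ids: list[str]
    probs: np.ndarray
    scheme: ClassScheme
    truth: Optional[np.ndarray] = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probs = _as_prob_matrix(self.probs, self.scheme.K)
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=np.int64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    def validate(self) -> None:
        n = self.probs.shape[0]
        if n < 1:
            raise ValidationError("a prediction set needs at least one sample")
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} probability rows"
            )
        if len(set(self.sample_ids)) != n:
            seen, dup = set(), None
            for s in self.sample_ids:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise ValidationError(f"duplicate sample id {dup!r}")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            i, k = np.argwhere((self.probs < 0) | (self.probs > 1))[0]
            raise ValidationError(
                f"probability out of [0, 1] for sample {self.sample_ids[i]!r}, "
                f"class {self.scheme.names[k]!r}: {self.probs[i, k]!r}"
            )
        sums = self.probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(
                f"probabilities for sample {self.sample_ids[i]!r} sum to {sums[i]!r}, "
                f"outside 1 +/- {ROW_SUM_TOL}"
            )
        if self.truth is not None:
            if self.truth.shape != (n,):
                raise ValidationError(
                    f"truth has shape {self.truth.shape}, expected ({n},)"
                )
            if np.any((self.truth < 0) | (self.truth >= self.scheme.K)):
                i = int(np.argmax((self.truth < 0) | (self.truth >= self.scheme.K)))
                raise ValidationError(
                    f"truth label {self.truth[i]} for sample {self.sample_ids[i]!r} "
                    f"outside [0, {self.scheme.K})"
                )

    def renormalized(self) -> "PredictionSet":
        """Return a copy with each row rescaled to sum to exactly 1.

        Explicit opt-in; validation never renormalizes silently.
        """
        probs = self.probs / self.probs.sum(axis=1, keepdims=True)
        return PredictionSet(self.model_id, list(self.sample_ids), probs,
                             self.scheme, None if self.truth is None else self.truth.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PredictionSet):
            return NotImplemented
        same_truth = (
            (self.truth is None and other.truth is None)
            or (self.truth is not None and other.truth is not None
                and np.array_equal(self.truth, other.truth))
        )
        return (
            self.model_id == other.model_id
            and self.sample_ids == other.sample_ids
            and self.scheme == other.scheme
            and self.probs.shape == other.probs.shape
            and np.array_equal(self.probs, other.probs)
            and same_truth
        )


@dataclass
class DatasetManifest:
    """Sample-id -> ordinal class label table with split tags.

    ``labels`` are class indices into ``scheme``; ``splits`` come from the
    closed tag set ``SPLIT_TAGS``.
    """

    sample_ids: list[str]
    labels: np.ndarray
    scheme: ClassScheme
    splits: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.splits:
            self.splits = ["unassigned"] * len(self.sample_ids)
        if len(self.sample_ids) != len(self.labels) or len(self.sample_ids) != len(self.splits):
            raise ValidationError(
                f"manifest columns disagree in length: {len(self.sample_ids)} ids, "
                f"{len(self.labels)} labels, {len(self.splits)} splits"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("manifest sample ids must be unique")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.scheme.K):
            raise ValidationError(
                f"manifest labels outside [0, {self.scheme.K})"
            )
        for s in self.splits:
            if s not in SPLIT_TAGS:
                raise ValidationError(f"unknown split tag {s!r}; allowed: {SPLIT_TAGS}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def class_counts(self) -> np.ndarray:
        """Per-class entry counts, in scheme order."""
        return np.bincount(self.labels, minlength=self.scheme.K)

    def subset(self, mask: np.ndarray, split: Optional[str] = None) -> "DatasetManifest":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        splits = [split if split is not None else s
                  for s, m in zip(self.splits, mask) if m]
        return DatasetManifest(ids, self.labels[mask], self.scheme, splits)


@dataclass
class FusedPredictions:
    """Weighted-sum fusion output.

    ``probs`` rows sum to the weight total (not necessarily 1: no
    renormalization is applied); only ``labels`` — the tie-broken row argmax —
    is consumed by the agreement metrics.
    """

    probs: np.ndarray
    labels: np.ndarray
    weights_used: np.ndarray
    source_model_ids: list[str]
    sample_ids: list[str]
    scheme: ClassScheme
    truth: Optional[np.ndarray] = None


@dataclass
class Mismatch:
    """One alignment discrepancy between two prediction sets."""

    kind: str           # 'n_samples' | 'n_classes' | 'sample_id' | 'truth'
    position: Optional[int]
    detail: str


@dataclass
class AlignmentReport:
    """Outcome of comparing two prediction sets for fusability."""

    model_a: str
    model_b: str
    mismatches: list[Mismatch]

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def summary(self) -> str:
        if self.ok:
            return f"{self.model_a} and {self.model_b} are aligned"
        first = self.mismatches[0]
        return (
            f"{len(self.mismatches)} mismatch(es) between {self.model_a} and "
            f"{self.model_b}; first: {first.detail}"
        )


def validate_prediction_pair(a: PredictionSet, b: PredictionSet) -> AlignmentReport:
    """Check that two prediction sets describe the same samples in the same order.

    Returns a report listing every mismatch (never raises); fusion rejects
    unaligned pairs by raising :class:`AlignmentError` carrying this report.
    """
    mismatches: list[Mismatch] = []
    if a.scheme.K != b.scheme.K:
        mismatches.append(Mismatch(
            "n_classes", None,
            f"class counts differ: {a.scheme.K} vs {b.scheme.K}"))
    if a.n_samples != b.n_samples:
        mismatches.append(Mismatch(
            "n_samples", None,
            f"sample counts differ: {a.n_samples} vs {b.n_samples}"))
    else:
        for i, (sa, sb) in enumerate(zip(a.sample_ids, b.sample_ids)):
            if sa != sb:
                mismatches.append(Mismatch(
                    "sample_id", i,
                    f"sample ids differ at position {i}: {sa!r} vs {sb!r}"))
        if a.truth is not None and b.truth is not None:
            for i in np.nonzero(a.truth != b.truth)[0]:
                i = int(i)
                mismatches.append(Mismatch(
                    "truth", i,
                    f"truth labels differ for sample {a.sample_ids[i]!r}: "
                    f"{a.truth[i]} vs {b.truth[i]}"))
    return AlignmentReport(a.model_id, b.model_id, mismatches)


def validate_alignment(models: Sequence[PredictionSet]) -> None:
    """Raise :class:`AlignmentError` on the first unaligned pair."""
    from .errors import AlignmentError

    for i in range(1, len(models)):
        report = validate_prediction_pair(models[0], models[i])
        if not report.ok:
            raise AlignmentError(report)
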