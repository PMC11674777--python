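"""Class-imbalance handling: test reservation, re-balancing, stratified split.

The protocol is reservation-first: a test set is drawn per class *before* any
resampling, so no duplicated sample can leak into evaluation. The remaining
pool is then balanced to a fixed per-class target by subsampling majority
classes without replacement and duplicating minority samples (no synthetic
augmentation — duplicates carry ``#r<k>`` replica suffixes so leakage checks
can spot them). Finally the balanced pool is split into train/validation with
per-class proportional allocation, preserving the balance just created.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .core import DatasetManifest
from .errors import InfeasibilityError, ValidationError

ROUNDING_MODES = ("half_up", "half_even", "floor", "ceil")


def _round(x: float, mode: str) -> int:
    if mode == "half_up":
        return int(math.floor(x + 0.5))
    if mode == "half_even":
        return int(round(x))
    if mode == "floor":
        return int(math.floor(x))
    if mode == "ceil":
        return int(math.ceil(x))
    raise ValidationError(f"rounding mode must be one of {ROUNDING_MODES}, got {mode!r}")


@dataclass(frozen=True)
class ReservationRules:
    """Per-class test-set reservation: a fraction in (0, 1) or an absolute count.

    ``rules`` maps class name -> ``("fraction", f)`` or ``("count", n)``.
    Fractions are rounded per ``rounding`` (default half-up).
    """

    rules: dict
    rounding: str = "half_up"

    def __post_init__(self):
        if self.rounding not in ROUNDING_MODES:
            raise ValidationError(
                f"rounding mode must be one of {ROUNDING_MODES}, got {self.rounding!r}")
        for cls, (kind, value) in self.rules.items():
            if kind == "fraction":
                if not (0.0 < value < 1.0):
                    raise ValidationError(
                        f"reservation fraction for {cls!r} must be in (0, 1), got {value}")
            elif kind == "count":
                if value < 0 or value != int(value):
                    raise ValidationError(
                        f"reservation count for {cls!r} must be a non-negative "
                        f"integer, got {value}")
            else:
                raise ValidationError(
                    f"reservation rule for {cls!r} must be 'fraction' or 'count', "
                    f"got {kind!r}")

    def resolve(self, class_name: str, class_size: int) -> int:
        """Number of samples to reserve from a class of the given size."""
        if class_name not in self.rules:
            return 0
        kind, value = self.rules[class_name]
        if kind == "count":
            return int(value)
        return _round(value * class_size, self.rounding)


@dataclass(frozen=True)
class BalanceSpec:
    """Target per-class size; duplication-only oversampling,
    without-replacement undersampling."""

    target_per_class: int
    oversample_mode: str = "duplicate"
    undersample_mode: str = "without-replacement"

    def __post_init__(self):
        if self.target_per_class < 1:
            raise ValidationError(
                f"target_per_class must be >= 1, got {self.target_per_class}")
        if self.oversample_mode != "duplicate":
            raise ValidationError(f"unsupported oversample mode {self.oversample_mode!r}")
        if self.undersample_mode != "without-replacement":
            raise ValidationError(f"unsupported undersample mode {self.undersample_mode!r}")


def reserve_test_split(manifest: DatasetManifest, rules: ReservationRules,
                       rng: np.random.Generator
                       ) -> tuple[DatasetManifest, DatasetManifest]:
    """Reserve a per-class test set uniformly without replacement.

    Returns ``(test, pool)``: disjoint, exhaustive, with the test entries
    tagged ``test``. Raises if a class cannot supply its reservation.
    """
    n = len(manifest)
    counts = manifest.class_counts()
    test_mask = np.zeros(n, dtype=bool)
    for k, name in enumerate(manifest.scheme.names):
        want = rules.resolve(name, int(counts[k]))
        if want > counts[k]:
            raise InfeasibilityError(
                f"class {name!r} has {counts[k]} samples but {want} were "
                f"requested for the test set")
        if want:
            idx = np.nonzero(manifest.labels == k)[0]
            test_mask[rng.choice(idx, size=want, replace=False)] = True
    return manifest.subset(test_mask, split="test"), manifest.subset(~test_mask)


def rebalance(pool: DatasetManifest, spec: BalanceSpec,
              rng: np.random.Generator) -> DatasetManifest:
    """Bring every class to exactly ``target_per_class`` entries.

    Classes above target are subsampled without replacement; classes below
    keep every original once plus duplicates drawn with replacement, each
    given a ``#r<k>`` replica suffix. Output order is shuffled.
    """
    target = spec.target_per_class
    ids: list[str] = []
    labels: list[int] = []
    for k, name in enumerate(pool.scheme.names):
        idx = np.nonzero(pool.labels == k)[0]
        if idx.size == 0:
            raise InfeasibilityError(f"class {name!r} is empty; cannot rebalance")
        if idx.size >= target:
            keep = rng.choice(idx, size=target, replace=False)
            ids.extend(pool.sample_ids[i] for i in keep)
        else:
            ids.extend(pool.sample_ids[i] for i in idx)
            extra = rng.choice(idx, size=target - idx.size, replace=True)
            replica_count: dict[str, int] = {}
            for i in extra:
                src = pool.sample_ids[i]
                replica_count[src] = replica_count.get(src, 0) + 1
                ids.append(f"{src}#r{replica_count[src]}")
        labels.extend([k] * target)
    order = rng.permutation(len(ids))
    return DatasetManifest([ids[i] for i in order],
                           np.asarray(labels, dtype=np.int64)[order],
                           pool.scheme)


def _proportional_allocation(class_sizes: np.ndarray, total_take: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total_take`` across classes."""
    exact = class_sizes * total_take / class_sizes.sum()
    base = np.floor(exact).astype(np.int64)
    remainder = exact - base
    short = total_take - int(base.sum())
    # hand the leftover units to the largest remainders (ties: lower class first)
    for k in np.argsort(-remainder, kind="stable")[:short]:
        base[k] += 1
    return base


def stratified_split(balanced: DatasetManifest, train_count: int, val_count: int,
                     rng: np.random.Generator
                     ) -> tuple[DatasetManifest, DatasetManifest]:
    """Split into train/validation with per-class proportional allocation.

    ``train_count + val_count`` must equal the manifest size; equal class
    sizes yield equal per-class contributions (24,000 at 19,000/5,000 gives
    4,750/1,250 per class for four balanced classes).
    """
    n = len(balanced)
    if train_count < 0 or val_count < 0 or train_count + val_count != n:
        raise ValidationError(
            f"train + validation must equal {n}, got {train_count} + {val_count}")
    counts = balanced.class_counts()
    take = _proportional_allocation(counts[counts > 0],
                                    train_count) if train_count else None
    train_mask = np.zeros(n, dtype=bool)
    if train_count:
        present = np.nonzero(counts > 0)[0]
        for k, t in zip(present, take):
            if t > counts[k]:
                raise ValidationError(
                    f"class {balanced.scheme.names[k]!r} cannot supply {t} "
                    f"training samples from {counts[k]}")
            idx = np.nonzero(balanced.labels == k)[0]
            train_mask[rng.choice(idx, size=int(t), replace=False)] = True
    return (balanced.subset(train_mask, split="train"),
            balanced.subset(~train_mask, split="validation"))
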