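"""Delimited-text I/O for prediction tables and dataset manifests.

One dialect only: comma-delimited UTF-8 with a mandatory header and "."
decimal point. Probabilities are written as shortest round-trip decimal
representations, so ``read(write(ps)) == ps`` bit-for-bit. Class column order
is fixed by the :class:`~cuckoofuse.core.ClassScheme`, never inferred from the
file.

Prediction table header: ``sample_id,true_label,<class 1>,...,<class K>``
(``true_label`` optional). Manifest header: ``sample_id,label,split``.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import ClassScheme, DatasetManifest, FusedPredictions, PredictionSet
from .errors import FormatError

PathLike = Union[str, Path]


def read_prediction_table(path: PathLike, scheme: ClassScheme,
                          renormalize: bool = False) -> PredictionSet:
    """Read one model's prediction table.

    The header must name ``sample_id``, optionally ``true_label``, then one
    column per class in scheme order. Rows whose probabilities sum outside
    1 +/- 1e-6 raise a validation error naming the sample, unless
    ``renormalize=True`` explicitly opts in to rescaling.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "true_label": str},
                     float_precision="round_trip")
    cols = list(df.columns)
    if not cols or cols[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id', got {cols[:1]}")
    rest = cols[1:]
    has_truth = bool(rest) and rest[0] == "true_label"
    class_cols = rest[1:] if has_truth else rest
    expected = list(scheme.names)
    if class_cols != expected:
        for got, want in zip(class_cols, expected):
            if got != want:
                raise FormatError(
                    f"{path}: expected class column {want!r}, found {got!r}"
                )
        missing = expected[len(class_cols):]
        extra = class_cols[len(expected):]
        if missing:
            raise FormatError(f"{path}: missing class column {missing[0]!r}")
        raise FormatError(f"{path}: unexpected trailing column {extra[0]!r}")

    probs = df[expected].to_numpy(dtype=np.float64)
    truth = None
    if has_truth:
        truth = np.array([scheme.index(t) for t in df["true_label"]], dtype=np.int64)
    ps = PredictionSet(
        model_id=path.stem,
        sample_ids=list(df["sample_id"]),
        probs=probs if not renormalize else probs / probs.sum(axis=1, keepdims=True),
        scheme=scheme,
        truth=truth,
    )
    return ps


def write_prediction_table(ps: PredictionSet, path: PathLike) -> None:
    """Write a prediction table such that ``read_prediction_table`` inverts it.

    Probabilities are serialized with full round-trip precision; the
    ``true_label`` column is present only when truth labels are attached.
    """
    path = Path(path)
    data: dict = {"sample_id": ps.sample_ids}
    if ps.truth is not None:
        data["true_label"] = [ps.scheme.names[t] for t in ps.truth]
    for k, name in enumerate(ps.scheme.names):
        data[name] = ps.probs[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def read_manifest(path: PathLike, scheme: ClassScheme) -> DatasetManifest:
    """Read a ``sample_id,label,split`` manifest; labels are class names on disk."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["sample_id", "label", "split"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: manifest header must be {','.join(expected)}, "
            f"got {','.join(df.columns)}"
        )
    labels = np.array([scheme.index(t) for t in df["label"]], dtype=np.int64)
    return DatasetManifest(list(df["sample_id"]), labels, scheme, list(df["split"]))


def write_manifest(manifest: DatasetManifest, path: PathLike) -> None:
    pd.DataFrame({
        "sample_id": manifest.sample_ids,
        "label": [manifest.scheme.names[t] for t in manifest.labels],
        "split": manifest.splits,
    }).to_csv(path, index=False)


def write_fused(fused: FusedPredictions, path: PathLike) -> None:
    """Write fused output as a prediction table plus a ``.meta.json`` sidecar.

    Fused rows sum to the weight total, not 1, so the table is written with
    raw weighted sums and the sidecar records the weights and source models
    needed to interpret them.
    """
    path = Path(path)
    data: dict = {"sample_id": fused.sample_ids}
    if fused.truth is not None:
        data["true_label"] = [fused.scheme.names[t] for t in fused.truth]
    for k, name in enumerate(fused.scheme.names):
        data[name] = fused.probs[:, k]
    data["predicted_label"] = [fused.scheme.names[t] for t in fused.labels]
    pd.DataFrame(data).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({
        "weights_used": [float(w) for w in fused.weights_used],
        "source_model_ids": list(fused.source_model_ids),
        "classes": list(fused.scheme.names),
    }, indent=2) + "\n", encoding="utf-8")
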