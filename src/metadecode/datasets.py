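"""Labeled feature datasets and their on-disk representations.

A :class:`LabeledDataset` is the package's common currency: a trials-by-features
matrix with binary labels, optionally carrying the pre-corruption ("clean")
labels and the boolean mislabel mask that the noise-injection step produces.
Two serializations are supported: delimited text (one row per sample, feature
columns ``f0..f{d-1}`` followed by ``label``, ``clean_label``, ``mislabeled``)
and an ``.npz`` array container with a JSON metadata block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "save_dataset", "load_dataset"]


@dataclass
class LabeledDataset:
    """Feature matrix with (possibly noisy) binary labels.

    Parameters
    ----------
    features : ndarray, shape (n_samples, n_features)
        Real-valued features (e.g. per-neuron firing rates, or a trial
        trajectory over timepoints).
    labels : ndarray of {0, 1}, shape (n_samples,)
        The labels the decoder trains on; may be corrupted.
    clean_labels : ndarray of {0, 1} or None
        Ground-truth labels before any corruption.
    mislabel_mask : ndarray of bool or None
        True where ``labels != clean_labels``. Must be consistent with the
        two label vectors when all three are present.
    meta : dict
        Free-form provenance (seed, noise portion, realized noise level, ...).
    """

    features: np.ndarray
    labels: np.ndarray
    clean_labels: np.ndarray | None = None
    mislabel_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length must match the number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        if self.clean_labels is not None:
            self.clean_labels = np.asarray(self.clean_labels, dtype=int)
            if self.clean_labels.shape != (n,):
                raise ValueError("clean_labels length mismatch")
        if self.mislabel_mask is not None:
            self.mislabel_mask = np.asarray(self.mislabel_mask, dtype=bool)
            if self.mislabel_mask.shape != (n,):
                raise ValueError("mislabel_mask length mismatch")
            if self.clean_labels is not None and not np.array_equal(
                self.mislabel_mask, self.labels != self.clean_labels
            ):
                raise ValueError(
                    "mislabel_mask inconsistent with labels != clean_labels"
                )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row-subset the dataset (copies, keeps masks aligned)."""
        idx = np.asarray(idx)
        return LabeledDataset(
            features=self.features[idx].copy(),
            labels=self.labels[idx].copy(),
            clean_labels=None if self.clean_labels is None else self.clean_labels[idx].copy(),
            mislabel_mask=None if self.mislabel_mask is None else self.mislabel_mask[idx].copy(),
            meta=dict(self.meta, subset_of=self.meta.get("seed")),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f{j}": self.features[:, j] for j in range(self.n_features)}
        cols["label"] = self.labels
        if self.clean_labels is not None:
            cols["clean_label"] = self.clean_labels
        if self.mislabel_mask is not None:
            cols["mislabeled"] = self.mislabel_mask.astype(int)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "LabeledDataset":
        feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        feat_cols.sort(key=lambda c: int(c[1:]))
        if not feat_cols or "label" not in df.columns:
            raise ValueError("expected feature columns f0..fK and a 'label' column")
        return cls(
            features=df[feat_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            clean_labels=df["clean_label"].to_numpy(dtype=int)
            if "clean_label" in df.columns
            else None,
            mislabel_mask=df["mislabeled"].to_numpy(dtype=bool)
            if "mislabeled" in df.columns
            else None,
            meta=meta or {},
        )


def save_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset to ``.csv`` (delimited text) or ``.npz`` (array container)."""
    path = Path(path)
    if path.suffix == ".npz":
        arrays = {"features": dataset.features, "labels": dataset.labels}
        if dataset.clean_labels is not None:
            arrays["clean_labels"] = dataset.clean_labels
        if dataset.mislabel_mask is not None:
            arrays["mislabel_mask"] = dataset.mislabel_mask
        arrays["meta_json"] = np.array(json.dumps(dataset.meta, default=str))
        np.savez(path, **arrays)
    else:
        dataset.to_frame().to_csv(path, index=False)


def load_dataset(path: str | Path) -> LabeledDataset:
    """Read a dataset written by :func:`save_dataset`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"])) if "meta_json" in z else {}
            return LabeledDataset(
                features=z["features"],
                labels=z["labels"],
                clean_labels=z["clean_labels"] if "clean_labels" in z else None,
                mislabel_mask=z["mislabel_mask"] if "mislabel_mask" in z else None,
                meta=meta,
            )
    return LabeledDataset.from_frame(pd.read_csv(path))
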