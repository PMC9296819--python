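"""Label-noise injection by random shuffling, and pooling of noisy datasets.

Corruption picks a portion of samples uniformly at random and applies a
uniform random permutation to *their labels only*. Shuffling (as opposed to
independent resampling) preserves the total class counts, so an imbalanced
dataset stays imbalanced at every noise portion; the realized noise level —
the fraction of labels actually changed — is below the portion because a
shuffled label can land back on its own class. For binary labels with class
counts (n0, n1) out of n, the expected realized level at portion p is
``p * 2 * n0 * n1 / n**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset

__all__ = ["NoiseSpec", "shuffle_labels", "realized_noise_level", "mix_datasets"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise portion (fraction of labels entered into the shuffle) and seed."""

    portion: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.portion <= 1.0:
            raise ValueError("portion must lie in [0, 1]")


def shuffle_labels(dataset: LabeledDataset, spec: NoiseSpec) -> LabeledDataset:
    """Randomly shuffle a portion of the labels.

    ``round(portion * n)`` sample indices are drawn without replacement
    (round-half-to-even); the labels at those indices are permuted uniformly.
    Features are untouched. The returned dataset records the input labels as
    ``clean_labels`` and the elementwise disagreement as ``mislabel_mask``.
    Deterministic given ``spec.seed``.
    """
    n = dataset.n_samples
    k = int(np.round(spec.portion * n))
    rng = np.random.default_rng(spec.seed)
    new_labels = dataset.labels.copy()
    if k > 0:
        idx = rng.choice(n, size=k, replace=False)
        new_labels[idx] = dataset.labels[idx][rng.permutation(k)]
    mask = new_labels != dataset.labels
    return LabeledDataset(
        features=dataset.features,
        labels=new_labels,
        clean_labels=dataset.labels.copy(),
        mislabel_mask=mask,
        meta=dict(
            dataset.meta,
            noise_portion=spec.portion,
            noise_seed=spec.seed,
            realized_noise_level=float(mask.mean()),
        ),
    )


def realized_noise_level(dataset: LabeledDataset) -> float:
    """Fraction of samples whose label differs from the clean label."""
    if dataset.mislabel_mask is None:
        raise ValueError("dataset carries no mislabel mask; corrupt it first")
    return float(dataset.mislabel_mask.mean())


def mix_datasets(datasets: list[LabeledDataset]) -> LabeledDataset:
    """Row-concatenate datasets of equal feature dimension.

    Emulates pooling training data from annotators of different quality.
    Either every input carries a mislabel mask (and clean labels) or none
    does. The pooled realized noise level is the sample-size-weighted mean
    of the inputs' levels.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    dims = {d.n_features for d in datasets}
    if len(dims) != 1:
        raise ValueError(f"feature dimension mismatch: {sorted(dims)}")
    has_mask = [d.mislabel_mask is not None for d in datasets]
    if any(has_mask) and not all(has_mask):
        raise ValueError("either all or none of the datasets may carry masks")
    has_clean = all(d.clean_labels is not None for d in datasets)
    return LabeledDataset(
        features=np.concatenate([d.features for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        clean_labels=np.concatenate([d.clean_labels for d in datasets])
        if has_clean
        else None,
        mislabel_mask=np.concatenate([d.mislabel_mask for d in datasets])
        if all(has_mask)
        else None,
        meta={
            "source": "mixture",
            "component_sizes": [d.n_samples for d in datasets],
            "component_noise_levels": [
                d.meta.get("realized_noise_level") for d in datasets
            ],
        },
    )
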