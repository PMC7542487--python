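"""Synthetic style-grouped binary classification data.

Each style group applies one common affine distortion (a rotation drawn at a
controllable angle plus a bounded shift) to class-conditional base
distributions: two isotropic Gaussian clusters separated along the first
axis.  ``style_strength`` scales both the rotation angle (radians) and the
shift, so strength 0 collapses every distortion to the identity and all
groups are i.i.d. from the same mixture.  Affine distortions are exactly the
family a linear-kernel style matrix can in principle undo, which makes the
generator a faithful stress test for the style-regularized trainer.

Splits mirror the two experimental designs for grouped data: a within-group
split (every test style also appears in training, the Rule-2 regime) and a
style-holdout split (whole groups excluded from training, the Rule-3 regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import InputError
from .style_transform import StyleGroupedDataset

#: shift magnitude per unit of style_strength, relative to the cluster spread
_SHIFT_SCALE = 0.3


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the generator.

    Defaults: 3 groups of 40 four-dimensional samples, class means 2.0 apart,
    unit within-class spread, distortion angle equal to ``style_strength``
    radians.
    """

    n_groups: int = 3
    per_group: int = 40
    dim: int = 4
    class_sep: float = 2.0
    style_strength: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.per_group < 1 or self.dim < 1:
            raise InputError("counts must be positive")
        if self.style_strength < 0:
            raise InputError("style_strength must be >= 0")
        if not self.noise_sd > 0:
            raise InputError("noise_sd must be > 0")


def _random_rotation(rng: np.random.Generator, dim: int, angle: float) -> np.ndarray:
    """Rotation exp(angle * S) for a random unit-Frobenius skew-symmetric S."""
    if dim == 1 or angle == 0.0:
        return np.eye(dim)
    A = rng.standard_normal((dim, dim))
    S = (A - A.T) / 2.0
    nrm = np.linalg.norm(S)
    if nrm == 0.0:  # pragma: no cover - probability zero
        return np.eye(dim)
    return expm(angle * S / nrm)


def generate(config: SynthConfig) -> StyleGroupedDataset:
    """Draw a style-grouped dataset; identical configs give identical data."""
    rng = np.random.default_rng(config.seed)
    mean = np.zeros(config.dim)
    mean[0] = config.class_sep / 2.0
    X_parts, y_parts, g_parts = [], [], []
    for j in range(1, config.n_groups + 1):
        n_pos = (config.per_group + 1) // 2
        yj = np.concatenate([np.ones(n_pos), -np.ones(config.per_group - n_pos)])
        base = yj[:, None] * mean + config.noise_sd * rng.standard_normal(
            (config.per_group, config.dim))
        R = _random_rotation(rng, config.dim, config.style_strength)
        shift = _SHIFT_SCALE * config.style_strength * rng.standard_normal(config.dim)
        X_parts.append(base @ R.T + shift)
        y_parts.append(yj)
        g_parts.append(np.full(config.per_group, j))
    return StyleGroupedDataset(np.vstack(X_parts), np.concatenate(y_parts),
                               np.concatenate(g_parts))


@dataclass(frozen=True)
class SplitPlan:
    """How to carve a style-grouped dataset into train and test.

    ``train_fraction`` applies within every group not named in
    ``held_out_styles``; held-out groups go entirely to the test set
    (the unseen-style design).
    """

    train_fraction: float = 0.5
    held_out_styles: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise InputError("train_fraction must be in (0, 1)")


def make_splits(dataset: StyleGroupedDataset, plan: SplitPlan,
                seed: int) -> tuple[StyleGroupedDataset, StyleGroupedDataset]:
    """Label-stratified within-group split; held-out styles appear only in test."""
    held = set(plan.held_out_styles)
    unknown = held - set(dataset.group_ids.tolist())
    if unknown:
        raise InputError(f"held-out styles {sorted(unknown)} not present in the dataset")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for g in dataset.group_ids:
        idx = np.flatnonzero(dataset.group == g)
        if int(g) in held:
            test_idx.append(idx)
            continue
        if idx.size < 2:
            raise InputError(f"group {g} has fewer than 2 samples; cannot split it")
        for label in (-1.0, 1.0):
            sub = idx[dataset.y[idx] == label]
            perm = rng.permutation(sub)
            k = int(np.floor(plan.train_fraction * sub.size + 0.5))
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
    tr = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], dtype=int)
    te = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    if tr.size == 0 or te.size == 0:
        raise InputError("split produced an empty train or test set")
    return dataset.subset(tr), dataset.subset(te)
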