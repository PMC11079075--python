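"""Training objective: weighted cross-entropy plus soft Dice loss.

The combined loss is

    Loss = w_CE * Loss_CE + w_Dice * Loss_Dice            (both weights 1)

with a class-averaged cross-entropy

    Loss_CE = -(1/C) sum_j sum_i w_j G_ij log(P_ij)

and a class-averaged soft Dice loss

    Loss_Dice = 1 - (2/C) sum_j [ sum_i P_ij G_ij /
                                  (sum_i P_ij^2 + sum_i G_ij^2) ]

where ``P`` is the predicted per-voxel class probability map, ``G`` the
one-hot encoded ground truth, ``C`` the number of classes and ``N`` the
number of voxels.  Note the cross-entropy carries no 1/N factor, so its
value scales with patch size; a per-voxel-mean variant is available behind
``LossConfig.per_voxel_mean`` for callers who want a size-free number.

Probabilities and one-hot labels are plain ``(N, C)`` float arrays (any
leading spatial shape is flattened); a small epsilon guards both the log and
Dice terms of classes absent from prediction and truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CbctError, LabelVolume

__all__ = [
    "LossConfig",
    "one_hot_encode",
    "ce_loss",
    "dice_loss",
    "combined_loss",
    "as_prob_map",
]


@dataclass(frozen=True)
class LossConfig:
    """Weights and smoothing for the combined objective."""

    w_ce: float = 1.0
    w_dice: float = 1.0
    class_weights: np.ndarray | None = None  # per-class w_j, default all 1
    epsilon: float = 1e-5
    per_voxel_mean: bool = False  # divide the CE sum by N as well

    def __post_init__(self) -> None:
        if self.w_ce < 0 or self.w_dice < 0:
            raise CbctError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise CbctError("epsilon must be positive")
        if self.class_weights is not None:
            cw = np.asarray(self.class_weights, float)
            if np.any(cw < 0):
                raise CbctError("class weights must be non-negative")
            object.__setattr__(self, "class_weights", cw)


def as_prob_map(values: np.ndarray, num_classes: int | None = None) -> np.ndarray:
    """Validate and flatten a probability map to ``(N, C)``.

    Accepts ``(..., C)`` arrays; checks entries lie in [0, 1] and per-voxel
    class sums equal 1 within 1e-6.
    """
    arr = np.asarray(values, float)
    if arr.ndim < 2:
        raise CbctError("probability map needs a trailing class axis")
    arr = arr.reshape(-1, arr.shape[-1])
    if num_classes is not None and arr.shape[1] != num_classes:
        raise CbctError(f"expected {num_classes} classes, got {arr.shape[1]}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise CbctError("probabilities must lie in [0, 1]")
    sums = arr.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise CbctError("per-voxel class probabilities must sum to 1")
    return arr


def one_hot_encode(labels: LabelVolume | np.ndarray, class_list) -> np.ndarray:
    """One-hot encode labels to ``(N, C)`` with columns in ``class_list`` order.

    Raises on any label not present in ``class_list``, naming it.
    """
    arr = labels.values if isinstance(labels, LabelVolume) else np.asarray(labels)
    flat = arr.reshape(-1)
    classes = np.asarray(list(class_list))
    if len(np.unique(classes)) != len(classes):
        raise CbctError("class_list contains duplicates")
    lookup = {int(c): i for i, c in enumerate(classes)}
    unknown = sorted(set(int(v) for v in np.unique(flat)) - set(lookup))
    if unknown:
        raise CbctError(f"labels not in class_list: {unknown}")
    onehot = np.zeros((flat.size, len(classes)), dtype=float)
    idx = np.vectorize(lookup.__getitem__, otypes=[np.int64])(flat)
    onehot[np.arange(flat.size), idx] = 1.0
    return onehot


def _check_shapes(P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, float)
    G = np.asarray(G, float)
    if P.shape != G.shape:
        raise CbctError(f"shape mismatch: P {P.shape} vs G {G.shape}")
    P = P.reshape(-1, P.shape[-1])
    G = G.reshape(-1, G.shape[-1])
    return P, G


def _class_weights(config: LossConfig, C: int) -> np.ndarray:
    if config.class_weights is None:
        return np.ones(C)
    cw = np.asarray(config.class_weights, float)
    if cw.shape != (C,):
        raise CbctError(f"class_weights shape {cw.shape} != ({C},)")
    return cw


def ce_loss(P: np.ndarray, G: np.ndarray, config: LossConfig | None = None) -> float:
    """Class-averaged cross-entropy, exactly as stated (no 1/N factor).

    ``P`` is clamped at ``epsilon`` before the log so empty predictions do
    not yield -inf.  ``per_voxel_mean`` additionally divides by N.
    """
    config = config or LossConfig()
    P, G = _check_shapes(P, G)
    N, C = P.shape
    w = _class_weights(config, C)
    logP = np.log(np.clip(P, config.epsilon, None))
    total = -np.sum(w[None, :] * G * logP) / C
    if config.per_voxel_mean:
        total /= N
    return float(total)


def dice_loss(P: np.ndarray, G: np.ndarray, config: LossConfig | None = None) -> float:
    """Class-averaged soft Dice loss.

    Per class: ``sum(P G) / (sum(P^2) + sum(G^2) + eps)``; the epsilon keeps
    classes absent from both prediction and truth at a zero (not 0/0) term.
    """
    config = config or LossConfig()
    P, G = _check_shapes(P, G)
    C = P.shape[1]
    inter = np.sum(P * G, axis=0)
    denom = np.sum(P * P, axis=0) + np.sum(G * G, axis=0) + config.epsilon
    return float(1.0 - (2.0 / C) * np.sum(inter / denom))


def combined_loss(P: np.ndarray, G: np.ndarray, config: LossConfig | None = None) -> float:
    """``w_CE * CE + w_Dice * Dice`` with the configured weights."""
    config = config or LossConfig()
    return config.w_ce * ce_loss(P, G, config) + config.w_dice * dice_loss(P, G, config)
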