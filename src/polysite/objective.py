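"""Imbalance-aware compound loss.

total = CE + lambda1 * center + lambda2 * inter

* class-weighted cross entropy (weighted-mean convention: sum of weighted
  negative log-likelihoods divided by the sum of the weights of the valid
  residues);
* center loss (1 / 2B) sum_i |F_i - c_{y_i}|^2 pulling residue features
  toward their class centers, with centers updated iteratively by
  c_k <- c_k + alpha * (mean_k(F) - c_k) on detached features;
* inter-center hinge sum_{i != j} max(0, m - |c_i - c_j|) over ordered
  pairs, exactly as printed (each unordered pair counts twice).

Centers are state, not optimizer parameters: the center update rule is the
only thing that moves them, so the inter term contributes to the reported
total but not to network gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .constants import CLASS_WEIGHTS
from .errors import ConsistencyError

__all__ = ["CenterState", "LossConfig", "LossBreakdown", "weighted_cross_entropy",
           "center_loss", "update_centers", "inter_loss", "total_loss",
           "compound_loss"]


@dataclass
class CenterState:
    centers: np.ndarray  # (K, d_final)
    alpha: float = 0.5

    @classmethod
    def initialize(cls, n_classes: int, dim: int, seed: int = 0,
                   alpha: float = 0.5) -> "CenterState":
        rng = np.random.default_rng(seed)
        return cls(0.01 * rng.standard_normal((n_classes, dim)), alpha)


@dataclass
class LossConfig:
    lambda1: float = 0.1
    lambda2: float = 0.001
    margin: float = 0.1
    class_weights: tuple[float, ...] = CLASS_WEIGHTS
    inter_pairs: str = "ordered"  # "unordered" halves the printed double count

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConsistencyError("lambda1 and lambda2 must be >= 0")
        if self.margin <= 0:
            raise ConsistencyError("margin must be > 0")
        if any(w <= 0 for w in self.class_weights):
            raise ConsistencyError("class weights must be > 0")


@dataclass
class LossBreakdown:
    ce: float
    center: float
    inter: float
    total: float = field(init=False)
    lambda1: float = 0.1
    lambda2: float = 0.001

    def __post_init__(self):
        self.total = self.ce + self.lambda1 * self.center + self.lambda2 * self.inter


def _validate(labels: np.ndarray, n_classes: int, mask: np.ndarray | None,
              n_rows: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != n_rows:
        raise ConsistencyError("labels length mismatch")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= n_classes:
        raise ConsistencyError(f"labels outside [0, {n_classes})")
    if mask is None:
        mask = np.ones(n_rows, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConsistencyError("all residues masked out of the loss")
    return mask


def _log_softmax(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    return shifted - shifted.exp().sum(axis=1, keepdims=True).log()


def weighted_cross_entropy(logits, labels, weights=None, mask=None) -> Tensor:
    """Weighted-mean cross entropy over valid residues."""
    logits = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, float))
    B, K = logits.shape
    if weights is None:
        weights = np.ones(K)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != K:
        raise ConsistencyError(f"{weights.shape[0]} weights for {K} classes")
    labels = np.asarray(labels, dtype=int)
    mask = _validate(labels, K, mask, B)
    idx = np.flatnonzero(mask)
    lp = _log_softmax(logits).take_rows(idx)
    onehot = np.zeros((len(idx), K))
    onehot[np.arange(len(idx)), labels[idx]] = 1.0
    w = weights[labels[idx]]
    weighted_nll = (lp * Tensor(-onehot * w[:, None])).sum()
    return weighted_nll * (1.0 / w.sum())


def center_loss(features, labels, centers: np.ndarray, mask=None) -> Tensor:
    """(1 / 2B) sum over valid residues of squared distance to the class
    center; B is the valid-residue count. Centers are constants here."""
    features = features if isinstance(features, Tensor) else Tensor(np.asarray(features, float))
    labels = np.asarray(labels, dtype=int)
    mask = _validate(labels, centers.shape[0], mask, features.shape[0])
    idx = np.flatnonzero(mask)
    f = features.take_rows(idx)
    c = Tensor(centers[labels[idx]])
    return ((f - c) ** 2).sum() * (1.0 / (2.0 * len(idx)))


def update_centers(state: CenterState, features: np.ndarray, labels,
                   mask=None) -> CenterState:
    """c_k <- c_k + alpha * (batch mean of class-k features - c_k) for each
    class present among valid residues; absent classes are untouched.
    Features are treated as constants (no gradient flows)."""
    features = features.data if isinstance(features, Tensor) else np.asarray(features, float)
    labels = np.asarray(labels, dtype=int)
    mask = _validate(labels, state.centers.shape[0], mask, features.shape[0])
    centers = state.centers.copy()
    for k in np.unique(labels[mask]):
        sel = mask & (labels == k)
        delta = features[sel].mean(axis=0) - centers[k]
        centers[k] = centers[k] + state.alpha * delta
    return CenterState(centers, state.alpha)


def inter_loss(centers: np.ndarray, margin: float, pairs: str = "ordered") -> float:
    """Hinge on pairwise center distances, summed over ordered pairs i != j
    as printed (each unordered pair contributes twice)."""
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    hinge = np.maximum(0.0, margin - dist)
    np.fill_diagonal(hinge, 0.0)
    total = float(hinge.sum())
    return total / 2.0 if pairs == "unordered" else total


def total_loss(ce: float, center: float, inter: float,
               config: LossConfig | None = None) -> LossBreakdown:
    config = config or LossConfig()
    return LossBreakdown(ce=float(ce), center=float(center), inter=float(inter),
                         lambda1=config.lambda1, lambda2=config.lambda2)


def compound_loss(f_final: Tensor, logits: Tensor, labels, centers: CenterState,
                  config: LossConfig, mask=None) -> tuple[Tensor, LossBreakdown]:
    """Differentiable total loss plus its scalar decomposition."""
    ce = weighted_cross_entropy(logits, labels, config.class_weights, mask)
    cent = center_loss(f_final, labels, centers.centers, mask)
    inter = inter_loss(centers.centers, config.margin, config.inter_pairs)
    total = ce + cent * config.lambda1 + inter * config.lambda2
    breakdown = total_loss(float(ce.data), float(cent.data), inter, config)
    return total, breakdown
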