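"""Contrastive regression losses with age-aware weighting and adaptive neighbourhoods.

Classification-style contrastive learning defines positives by class
identity; for a continuous label like age the attraction/repulsion between
two samples is instead graded by their age difference through a Gaussian
kernel ``w_ik = exp(-(y_i - y_k)^2 / (2 sigma^2))``.

Three losses are provided, in increasing order of structure:

* ``loss_yaware``       — kernel-weighted InfoNCE over all pairs,
* ``loss_exponential``  — same, with denominator exponents scaled by
  ``(1 - w_it)`` so age-dissimilar samples are repelled harder,
* ``loss_adaptive``     — the exponential form restricted, per anchor, to a
  nearest-neighbour set in embedding space whose size shrinks over training,
  with kernel weights normalised per anchor.

Self-pairs are excluded everywhere: the denominator for anchor i and
positive k sums over t not in {i, k}, and an anchor is never a member of
its own neighbour set (self-similarity terms are constant and would only
flatten the softmax).

All losses accept features as either a plain array or an autodiff
:class:`~elastoage._tensor.Tensor` and return a scalar Tensor, so the same
code path serves both training and the closed-form checks in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._tensor import Tensor

__all__ = [
    "EmbeddingBatch",
    "NeighbourhoodSchedule",
    "age_kernel_weights",
    "similarity_matrix",
    "select_neighbours",
    "loss_yaware",
    "loss_exponential",
    "loss_adaptive",
]


@dataclass
class EmbeddingBatch:
    """Unit-norm feature vectors with their chronological ages (years)."""

    features: object  # (n, d) ndarray or Tensor
    ages: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        data = self.features.data if isinstance(self.features, Tensor) else np.asarray(self.features)
        if data.ndim != 2 or data.shape[0] != self.ages.shape[0]:
            raise ValueError("features must be (n, d) matching ages")
        if data.shape[0] < 2:
            raise ValueError("a contrastive batch needs n >= 2 samples")
        norms = np.linalg.norm(data, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("feature vectors must be unit-norm (|norm - 1| <= 1e-6)")

    @property
    def n(self) -> int:
        return self.ages.shape[0]


@dataclass
class NeighbourhoodSchedule:
    """Linear shrink of the per-anchor neighbour count over epochs.

    The size at a given epoch is ``clamp(start - step*epoch, end, start)``;
    ``start_count=None`` means "all other samples in the batch" (n - 1).
    """

    step: int
    end_count: int
    metric: str = "euclidean"
    start_count: int | None = None

    def __post_init__(self):
        if self.end_count < 1:
            raise ValueError("end_count must be >= 1")
        if self.step < 0:
            raise ValueError("step must be >= 0")
        if self.metric not in ("manhattan", "euclidean", "similarity"):
            raise ValueError(f"unknown neighbourhood metric {self.metric!r}")

    def size(self, epoch: int, n: int) -> int:
        start = (n - 1) if self.start_count is None else min(self.start_count, n - 1)
        return int(np.clip(start - self.step * epoch, self.end_count, start))


def age_kernel_weights(ages, sigma: float) -> np.ndarray:
    """Gaussian age-similarity kernel, symmetric, zero diagonal."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ages = np.asarray(ages, dtype=float)
    d = ages[:, None] - ages[None, :]
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    return w


def similarity_matrix(features) -> np.ndarray:
    """Pairwise cosine similarity of (assumed unit-norm) embeddings."""
    f = features.data if isinstance(features, Tensor) else np.asarray(features, dtype=float)
    norms = np.linalg.norm(f, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        warnings.warn("features are not unit-norm; normalizing", stacklevel=2)
        f = f / norms[:, None]
    return f @ f.T


def select_neighbours(features, epoch: int, schedule: NeighbourhoodSchedule) -> list:
    """Per-sample nearest-neighbour index sets at the scheduled size.

    'similarity' ranks by descending cosine similarity; 'manhattan' and
    'euclidean' by ascending distance. Self is always excluded.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    f = features.data if isinstance(features, Tensor) else np.asarray(features, dtype=float)
    n = f.shape[0]
    if schedule.end_count >= n:
        raise ValueError(f"end_count ({schedule.end_count}) must be < batch size ({n})")
    m = schedule.size(epoch, n)
    if schedule.metric == "similarity":
        d = -(f @ f.T)
    elif schedule.metric == "manhattan":
        d = cdist(f, f, metric="cityblock")
    else:
        d = cdist(f, f, metric="euclidean")
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return [order[i, :m].copy() for i in range(n)]


def _as_tensor(features) -> Tensor:
    return features if isinstance(features, Tensor) else Tensor(np.asarray(features, dtype=float))


def _pair_terms(batch: EmbeddingBatch, sigma: float):
    """Common pieces: similarity Tensor S, kernel weights w, off-diag mask."""
    if batch.n < 3:
        raise ValueError("contrastive losses need n >= 3 (non-empty denominators)")
    f = _as_tensor(batch.features)
    S = f @ f.transpose((1, 0))
    w = age_kernel_weights(batch.ages, sigma)
    off = 1.0 - np.eye(batch.n)
    return f, S, w, off


def _diag_part(E: Tensor, n: int) -> Tensor:
    return (E * np.eye(n)).sum(axis=1, keepdims=True)


def loss_yaware(batch: EmbeddingBatch, sigma: float) -> Tensor:
    """Kernel-weighted contrastive regression loss.

    ``L = -sum_i sum_{k != i} w_ik log[ exp(s_ik) / sum_{t not in {i,k}} exp(s_it) ]``
    """
    _, S, w, off = _pair_terms(batch, sigma)
    n = batch.n
    E = S.exp()
    row = E.sum(axis=1, keepdims=True) - _diag_part(E, n)  # sum over t != i
    denom = row - E * Tensor(off)  # additionally drop t = k (diagonal untouched: kept positive)
    terms = S - denom.log()
    return -(Tensor(w * off) * terms * Tensor(off)).sum()


def loss_exponential(batch: EmbeddingBatch, sigma: float) -> Tensor:
    """Contrastive loss with repulsion-scaled denominator exponents.

    Denominator terms are ``exp(s_it (1 - w_it))``: pairs with very different
    ages (w near 0) keep full repulsion, near-age pairs are barely repelled.
    """
    _, S, w, off = _pair_terms(batch, sigma)
    n = batch.n
    A = (S * Tensor(1.0 - w)).exp()
    rowA = (A * Tensor(off)).sum(axis=1, keepdims=True)  # t != i
    denom = rowA - A * Tensor(off)  # t not in {i, k}
    terms = S - denom.log()
    return -(Tensor(w * off) * terms * Tensor(off)).sum()


def loss_adaptive(batch: EmbeddingBatch, sigma: float, neighbour_sets) -> Tensor:
    """Adaptive-neighbourhood contrastive regression loss.

    ``L = -sum_i sum_{k != i} (w_ik / sum_t w_it)
          log[ exp(s_ik) / sum_{t in NN(i) \\ {k}} exp(s_it (1 - w_it)) ]``

    `neighbour_sets[i]` are the indices of anchor i's current nearest
    neighbours (self excluded). A pair whose effective denominator set is
    empty (the neighbour set was exactly {k}) is skipped with a warning.
    """
    _, S, w, off = _pair_terms(batch, sigma)
    n = batch.n
    nmask = np.zeros((n, n))
    for i, idx in enumerate(neighbour_sets):
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"neighbour set of sample {i} is empty")
        if i in idx:
            raise ValueError(f"sample {i} appears in its own neighbour set")
        nmask[i, idx] = 1.0

    wn = w / w.sum(axis=1, keepdims=True)  # per-anchor weight normalisation
    A = (S * Tensor(1.0 - w)).exp()
    rowA = (A * Tensor(nmask)).sum(axis=1, keepdims=True)
    denom = rowA - A * Tensor(nmask)  # drop t = k when k is a neighbour

    empty = (denom.data <= 0) & (off > 0) & (wn > 0)
    pair_mask = off.copy()
    if np.any(empty):
        warnings.warn(f"{int(empty.sum())} pair(s) skipped: empty denominator", stacklevel=2)
        pair_mask[empty] = 0.0
    # keep log finite on masked-out entries
    denom = denom + Tensor(1.0 - np.minimum(pair_mask, (denom.data > 0).astype(float)))
    terms = S - denom.log()
    return -(Tensor(wn * pair_mask) * terms * Tensor(pair_mask)).sum()
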