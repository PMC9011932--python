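"""Spectral graph-convolution primitives shared by the drug and bio branches.

The propagation rule is the renormalized first-order filter

    H' = ReLU( D_tilde^{-1/2} (A + I) D_tilde^{-1/2} H W )

with ``D_tilde[k,k] = sum_m (A + I)[k,m]``. Padded (masked-out) nodes are
excluded from batch-normalization statistics and from pooling, so a graph
embedded in a larger zero-padded template produces the same output as the
graph at its native size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


class ShapeError(ValueError):
    """Operand dimensions are inconsistent."""


@dataclass
class GCNLayerParams:
    """Weights and regularization switches for one graph-convolution layer."""

    W: np.ndarray
    use_batchnorm: bool = False
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or min(self.W.shape) < 1:
            raise ShapeError(f"weight matrix must be 2-D, got shape {self.W.shape}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency with self-loops, entries in [0, 1]."""

    A_hat: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.A_hat.shape[0]


def normalize_adjacency(A: np.ndarray) -> NormalizedAdjacency:
    """Compute ``D_tilde^{-1/2} (A + I) D_tilde^{-1/2}``.

    Parameters
    ----------
    A
        Binary symmetric adjacency with zero diagonal. Isolated nodes come
        out with a unit self-loop entry, the limit of the formula at degree 0.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return NormalizedAdjacency(A_hat=A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :])


def gcn_layer(H: np.ndarray, A_hat: NormalizedAdjacency | np.ndarray,
              params: GCNLayerParams, node_mask: np.ndarray | None = None,
              training: bool = False,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """One propagation step: aggregate, (batch-normalize), ReLU, (dropout).

    Batch-norm statistics, when enabled, are taken over masked-in nodes only
    (affine-free, batch statistics — the trainable path lives in
    :mod:`dualgcn.model`). Masked-out rows are zero on output.
    """
    H = np.asarray(H, dtype=float)
    Ah = A_hat.A_hat if isinstance(A_hat, NormalizedAdjacency) else np.asarray(A_hat, float)
    n = Ah.shape[0]
    if H.shape[0] != n:
        raise ShapeError(f"H has {H.shape[0]} rows but adjacency has {n} nodes")
    if H.shape[1] != params.W.shape[0]:
        raise ShapeError(
            f"H has {H.shape[1]} features but W expects {params.W.shape[0]}")
    mask = np.ones(n) if node_mask is None else np.asarray(node_mask, float)
    if mask.shape != (n,):
        raise ShapeError(f"node_mask must have length {n}, got {mask.shape}")

    Z = Ah @ H @ params.W
    if params.use_batchnorm:
        m = mask[:, None]
        count = m.sum()
        mean = (Z * m).sum(axis=0) / count
        var = (((Z - mean) ** 2) * m).sum(axis=0) / count
        Z = (Z - mean) / np.sqrt(var + 1e-5)
    Z = np.maximum(Z, 0.0)
    if training and params.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training with dropout requires an rng")
        keep = rng.random(Z.shape) >= params.dropout_rate
        Z = Z * keep / (1.0 - params.dropout_rate)
    return Z * mask[:, None]


def graph_pool(H: np.ndarray, node_mask: np.ndarray | None = None,
               how: str = "max") -> np.ndarray:
    """Masked global pooling over nodes; padded rows can never contribute."""
    H = np.asarray(H, dtype=float)
    mask = np.ones(H.shape[0]) if node_mask is None else np.asarray(node_mask, float)
    keep = mask.astype(bool)
    if not keep.any():
        raise ValueError("graph_pool requires at least one masked-in node")
    if how == "max":
        return H[keep].max(axis=0)
    if how == "mean":
        return H[keep].mean(axis=0)
    raise ValueError(f"unknown pooling '{how}' (expected 'max' or 'mean')")
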