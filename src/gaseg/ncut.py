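"""Pairwise pixel affinities and the differentiable soft normalized-cut loss.

The soft-N-cut criterion scores a soft K-way partition of an image graph:

    J(V, K) = K - sum_k  [ sum_{u,v} w(u,v) p_k(u) p_k(v) ]
                        / [ sum_{u,t} w(u,t) p_k(u) ]

where ``p_k(u)`` is the probability that pixel ``u`` belongs to class ``k``
and ``w(u,v)`` is an affinity combining intensity similarity and spatial
proximity.  Minimising J maximises the normalized within-class association,
i.e. it rewards partitions whose classes are coherent in both intensity and
space.  J is bounded by [0, K] and is 0 for the trivial K=1 partition.

Because w couples every pair of pixels within a radius, the loss on a full
256x256 image is memory-heavy; the networks therefore evaluate it on an
average-pooled image/probability grid (256 -> 128 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AffinitySpec",
    "pixel_weights",
    "soft_ncut_loss",
    "soft_ncut_loss_grad",
    "pooled_soft_ncut_loss",
    "average_pool",
]

_EPS = 1e-8  # guard for a class with vanishing total probability


@dataclass(frozen=True)
class AffinitySpec:
    """Parameters of the pairwise weight w(u,v).

    ``w(u,v) = exp(-(I_u-I_v)^2/sigma_i^2) * exp(-||X_u-X_v||^2/sigma_x^2)``
    for pixels closer than ``radius`` (Euclidean), else 0.
    """

    sigma_i: float = 0.1
    sigma_x: float = 4.0
    radius: int = 5

    def __post_init__(self):
        if self.sigma_i <= 0 or self.sigma_x <= 0:
            raise ValueError("sigma_i and sigma_x must be positive")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


def pixel_weights(image: np.ndarray, spec: AffinitySpec = AffinitySpec()) -> sp.csr_matrix:
    """Sparse symmetric affinity matrix over the pixels of a 2-D image.

    Pixels are flattened in row-major order.  The diagonal is 1
    (zero intensity difference at zero distance); entries beyond
    ``spec.radius`` are structurally zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    h, w = image.shape
    n = h * w
    flat = image.ravel()
    rows_list, cols_list, vals_list = [], [], []
    r = spec.radius
    idx = np.arange(n).reshape(h, w)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if np.sqrt(d2) >= r:
                if d2 > 0:  # keep the diagonal; drop out-of-radius offsets
                    continue
            ys = slice(max(0, dy), min(h, h + dy))
            xs = slice(max(0, dx), min(w, w + dx))
            ys0 = slice(max(0, -dy), min(h, h - dy))
            xs0 = slice(max(0, -dx), min(w, w - dx))
            u = idx[ys0, xs0].ravel()
            v = idx[ys, xs].ravel()
            di = flat[u] - flat[v]
            wv = np.exp(-(di * di) / spec.sigma_i ** 2) * np.exp(-d2 / spec.sigma_x ** 2)
            rows_list.append(u)
            cols_list.append(v)
            vals_list.append(wv)
    mat = sp.coo_matrix(
        (np.concatenate(vals_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(n, n),
    )
    return mat.tocsr()


def _as_prob_matrix(probabilities: np.ndarray) -> np.ndarray:
    """(K,H,W) or (N,K) -> (N,K) float64."""
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim == 3:
        p = p.reshape(p.shape[0], -1).T
    if p.ndim != 2:
        raise ValueError("probabilities must be (K,H,W) or (N,K)")
    return p


def soft_ncut_loss(probabilities: np.ndarray, weights: sp.spmatrix) -> float:
    """J = K - sum_k assoc_k / denom_k (see module docstring)."""
    p = _as_prob_matrix(probabilities)
    n, k = p.shape
    if weights.shape != (n, n):
        raise ValueError("weights shape does not match pixel count")
    d = np.asarray(weights.sum(axis=1)).ravel()  # degree: sum_t w(u,t)
    wp = weights @ p  # (N,K)
    assoc = np.einsum("nk,nk->k", p, wp)
    denom = p.T @ d + _EPS
    return float(k - np.sum(assoc / denom))


def soft_ncut_loss_grad(probabilities: np.ndarray, weights: sp.spmatrix):
    """Loss and its gradient with respect to the per-pixel probabilities.

    Returns ``(J, grad)`` with ``grad`` shaped (N, K):
    dJ/dp_k(u) = -[2 (W p_k)_u denom_k - assoc_k d_u] / denom_k^2.
    """
    p = _as_prob_matrix(probabilities)
    n, k = p.shape
    d = np.asarray(weights.sum(axis=1)).ravel()
    wp = weights @ p
    assoc = np.einsum("nk,nk->k", p, wp)
    denom = p.T @ d + _EPS
    j = float(k - np.sum(assoc / denom))
    grad = -(2.0 * wp * denom[None, :] - d[:, None] * assoc[None, :]) / (denom ** 2)[None, :]
    return j, grad


def average_pool(arr: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool the trailing two axes by ``factor`` (must divide evenly)."""
    if factor == 1:
        return arr
    *lead, h, w = arr.shape
    if h % factor or w % factor:
        raise ValueError("pool factor must divide both image sides")
    new = arr.reshape(*lead, h // factor, factor, w // factor, factor)
    return new.mean(axis=(-3, -1))


def pooled_soft_ncut_loss(image: np.ndarray, probabilities: np.ndarray,
                          spec: AffinitySpec = AffinitySpec(),
                          pool_factor: int = 2) -> float:
    """Soft-N-cut loss on the average-pooled image and probability map.

    Both the image (used for the affinities) and the probability map are
    pooled to the same coarser grid; pooled per-pixel distributions are
    renormalized (average pooling already preserves the simplex up to
    float error).
    """
    image = np.asarray(image, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 3:
        raise ValueError("probabilities must be (K,H,W)")
    img_p = average_pool(image, pool_factor)
    pp = average_pool(p, pool_factor)
    pp = pp / np.maximum(pp.sum(axis=0, keepdims=True), _EPS)
    w = pixel_weights(img_p, spec)
    return soft_ncut_loss(pp, w)
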