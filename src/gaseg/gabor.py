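"""Texture baseline: Gabor filter-bank features clustered per pixel.

A Gabor filter is a Gaussian envelope modulated by a sinusoid,

    h(x, y) = 1/(2 pi sx sy) * exp(-1/2 (x'^2/sx^2 + y'^2/sy^2))
              * cos(2 pi u0 x'),

with (x', y') the pixel coordinates rotated by the filter orientation
theta and u0 the radial frequency in cycles/pixel.  Each filter response
passes through a saturating nonlinearity tanh(alpha * r) and is smoothed
into a local texture energy; the per-pixel feature vector is completed
with the (normalized) pixel coordinates and clustered with k-means.
When per-pixel class probabilities are needed (e.g. for ROC analysis),
fuzzy c-means replaces k-means; its memberships argmax to the same hard
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

__all__ = ["GaborBank", "gabor_kernel", "extract_features", "fuzzy_cmeans",
           "cluster_pixels", "GaborKMeans", "GaborKMeansResults"]


@dataclass(frozen=True)
class GaborBank:
    """Filter bank: all (frequency, orientation) pairs.

    Per-filter envelope defaults to sigma_x = sigma_y = 1/(2 u0) so the
    envelope scales with wavelength.  ``smooth_factor`` sets the texture
    energy smoothing to sigma = smooth_factor/u0.
    """

    frequencies: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3)
    orientations: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    sigma_x: float | None = None   # None -> 1/(2 u0) per filter
    sigma_y: float | None = None
    sigmoid_alpha: float = 0.25
    smooth_factor: float = 3.0
    spatial_weight: float = 1.0

    def __post_init__(self):
        if len(self.orientations) == 0:
            raise ValueError("need at least one orientation")
        if len(self.frequencies) == 0:
            raise ValueError("need at least one frequency (empty bank)")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")

    @property
    def n_features(self) -> int:
        return len(self.frequencies) * len(self.orientations) + 2


def gabor_kernel(u0: float, theta: float = 0.0, sigma_x: float = 2.0,
                 sigma_y: float = 2.0, half_size: int | None = None) -> np.ndarray:
    """Evaluate the Gabor function on a centered grid rotated by theta."""
    if u0 <= 0:
        raise ValueError("frequency u0 must be positive")
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("sigmas must be positive")
    if half_size is None:
        half_size = int(np.ceil(3.0 * max(sigma_x, sigma_y)))
    ax = np.arange(-half_size, half_size + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)   # xx: column offset, yy: row offset
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    env = np.exp(-0.5 * (xr ** 2 / sigma_x ** 2 + yr ** 2 / sigma_y ** 2))
    return env * np.cos(2 * np.pi * u0 * xr) / (2 * np.pi * sigma_x * sigma_y)


def extract_features(image: np.ndarray, bank: GaborBank = GaborBank()) -> np.ndarray:
    """Per-pixel feature table (n_pixels, n_filters + 2).

    For each (u0, theta): convolve, tanh(alpha r) nonlinearity, Gaussian
    smoothing (sigma = smooth_factor/u0) into texture energy.  The last two
    columns are the row/column coordinates normalized to [0, 1] and scaled
    by ``spatial_weight``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    h, w = img.shape
    cols = []
    for u0 in bank.frequencies:
        sx = bank.sigma_x if bank.sigma_x is not None else 1.0 / (2.0 * u0)
        sy = bank.sigma_y if bank.sigma_y is not None else 1.0 / (2.0 * u0)
        for theta in bank.orientations:
            k = gabor_kernel(u0, theta, sx, sy)
            resp = ndimage.convolve(img, k, mode="reflect")
            energy = ndimage.gaussian_filter(
                np.abs(np.tanh(bank.sigmoid_alpha * resp)),
                sigma=bank.smooth_factor / u0, mode="reflect")
            cols.append(energy.ravel())
    yy, xx = np.mgrid[0:h, 0:w]
    cols.append(bank.spatial_weight * yy.ravel() / max(h - 1, 1))
    cols.append(bank.spatial_weight * xx.ravel() / max(w - 1, 1))
    return np.stack(cols, axis=1)


def _standardize(features: np.ndarray) -> np.ndarray:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (features - mu) / sd


def fuzzy_cmeans(x: np.ndarray, n_clusters: int, m: float = 2.0,
                 max_iter: int = 100, tol: float = 1e-5,
                 init_centers: np.ndarray | None = None,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means: returns (memberships (n, c), centers (c, d)).

    Memberships u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)); centers are the
    u^m-weighted means.  Initialised from k-means centers unless given.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if init_centers is None:
        km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed).fit(x)
        centers = km.cluster_centers_.copy()
    else:
        centers = np.asarray(init_centers, dtype=np.float64).copy()
    expo = 2.0 / (m - 1.0)
    u = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-expo / 2.0 * 1.0)  # d^{-2/(m-1)} since d2 = d^2
        u_new = inv / inv.sum(axis=1, keepdims=True)
        um = u_new ** m
        centers = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-12)
        if u is not None and np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return u, centers


def cluster_pixels(features: np.ndarray, n_clusters: int, soft: bool = False,
                   seed: int = 0, standardized: bool = False):
    """Cluster the per-pixel feature table.

    Hard mode returns integer labels (k-means); soft mode returns the fuzzy
    c-means membership matrix (rows sum to 1), whose argmax reproduces a
    hard k-means-style clustering.
    """
    feats = np.asarray(features, dtype=np.float64)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > feats.shape[0]:
        raise ValueError("more clusters than pixels")
    if not standardized:
        feats = _standardize(feats)
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed).fit(feats)
    if not soft:
        return km.labels_
    u, _ = fuzzy_cmeans(feats, n_clusters, init_centers=km.cluster_centers_,
                        seed=seed)
    return u


class GaborKMeans:
    """Estimator wrapper: texture features + per-pixel clustering."""

    def __init__(self, bank: GaborBank = GaborBank(), n_clusters: int = 2,
                 soft: bool = False, seed: int = 0):
        self.bank = bank
        self.n_clusters = n_clusters
        self.soft = soft
        self.seed = seed

    def fit(self, image: np.ndarray) -> "GaborKMeansResults":
        img = np.asarray(image, dtype=np.float64)
        feats = extract_features(img, self.bank)
        out = cluster_pixels(feats, self.n_clusters, soft=self.soft,
                             seed=self.seed)
        if self.soft:
            memberships = out.reshape(img.shape + (self.n_clusters,))
            labels = memberships.argmax(axis=2)
        else:
            memberships = None
            labels = out.reshape(img.shape)
        return GaborKMeansResults(image=img, labels_=labels,
                                  memberships_=memberships,
                                  n_clusters=self.n_clusters)


@dataclass
class GaborKMeansResults:
    image: np.ndarray
    labels_: np.ndarray
    memberships_: np.ndarray | None
    n_clusters: int

    def lesion_mask(self) -> np.ndarray:
        """Binary mask of the cluster with the brightest mean intensity."""
        means = [self.image[self.labels_ == c].mean() if (self.labels_ == c).any()
                 else -np.inf for c in range(self.n_clusters)]
        return (self.labels_ == int(np.argmax(means))).astype(np.uint8)

    def lesion_probability(self) -> np.ndarray:
        """Soft lesion-membership channel (requires soft=True)."""
        if self.memberships_ is None:
            raise ValueError("fit with soft=True to get memberships")
        means = [self.image[self.labels_ == c].mean() if (self.labels_ == c).any()
                 else -np.inf for c in range(self.n_clusters)]
        return self.memberships_[..., int(np.argmax(means))]

    def summary(self) -> str:
        sizes = np.bincount(self.labels_.ravel(), minlength=self.n_clusters)
        lines = ["Gabor filter bank + k-means segmentation",
                 "=" * 44,
                 f"{'clusters':<20} {self.n_clusters}",
                 f"{'soft memberships':<20} {self.memberships_ is not None}"]
        for c, s in enumerate(sizes):
            lines.append(f"{'cluster %d pixels' % c:<20} {s}")
        return "\n".join(lines) + "\n"
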