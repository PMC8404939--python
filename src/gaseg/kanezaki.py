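"""Per-image unsupervised CNN segmentation with superpixel refinement.

One small CNN is initialised and trained from scratch *for each image*
(nothing transfers between images).  Three desiderata drive the design:
pixels with similar features share a label; spatially continuous pixels
share a label; and the number of distinct labels should stay large enough
to avoid the trivial one-cluster solution.

Each iteration alternates a forward process — compute a q-channel response
map ``y_n = W_c x_n + b_c`` over learned 3x3 conv features, whiten every
channel to zero mean / unit variance over the image (this is what props up
the cluster count), take the per-pixel argmax label, then force every SLIC
superpixel to its modal label — and a backward process: the cross-entropy
between the (whitened) responses and the refined labels is
back-propagated.  The output cluster count q' satisfies 1 <= q' <= q and
tends to shrink as training merges clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic as _sk_slic

from . import nn

__all__ = ["KanezakiConfig", "extract_features", "classify", "whiten",
           "compute_superpixels", "superpixel_refine", "KanezakiNet",
           "KanezakiResults"]


@dataclass(frozen=True)
class KanezakiConfig:
    p: int = 64              # feature dimension
    q: int = 64              # maximum number of clusters
    n_superpixels: int = 1000
    n_iterations: int = 64
    lr: float = 0.1
    momentum: float = 0.9
    stop_at_binary: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.p < 1 or self.q < 1 or self.n_superpixels < 1:
            raise ValueError("p, q and n_superpixels must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def whiten(response: np.ndarray) -> np.ndarray:
    """Per-channel standardisation of a (q,H,W) response map over the image."""
    mu = response.mean(axis=(1, 2), keepdims=True)
    sd = response.std(axis=(1, 2), keepdims=True)
    return (response - mu) / (sd + 1e-8)


def classify(response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whitened response map and per-pixel argmax labels (ties -> lowest)."""
    yw = whiten(response)
    return yw, yw.argmax(axis=0)


def compute_superpixels(image: np.ndarray, n_superpixels: int) -> np.ndarray:
    """SLIC partition of the image into ~n_superpixels connected regions."""
    img = np.asarray(image, dtype=np.float64)
    if n_superpixels > img.size:
        raise ValueError("more superpixels than pixels")
    if n_superpixels == 1:
        return np.zeros(img.shape, dtype=np.intp)
    seg = _sk_slic(img, n_segments=n_superpixels, compactness=0.1,
                   channel_axis=None, start_label=0, enforce_connectivity=True)
    return seg.astype(np.intp)


def superpixel_refine(labels: np.ndarray, superpixels: np.ndarray) -> np.ndarray:
    """Force every superpixel to its modal label (ties -> lowest label).

    Idempotent, and never increases the number of distinct labels.
    """
    labels = np.asarray(labels)
    sp = np.asarray(superpixels)
    if labels.shape != sp.shape:
        raise ValueError("labels and superpixels must share a shape")
    out = np.empty_like(labels)
    sp_flat = sp.ravel()
    lab_flat = labels.ravel()
    order = np.argsort(sp_flat, kind="stable")
    sorted_sp = sp_flat[order]
    bounds = np.flatnonzero(np.r_[True, sorted_sp[1:] != sorted_sp[:-1], True])
    out_flat = out.ravel()
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a == b:
            raise ValueError("empty superpixel")
        members = order[a:b]
        counts = np.bincount(lab_flat[members])
        out_flat[members] = counts.argmax()  # argmax -> lowest label on ties
    return out


class _PerImageCNN:
    """3 conv layers (2 feature layers of width p + a 1x1 classifier to q)."""

    def __init__(self, p: int, q: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(1, p, 3, rng)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(p, p, 3, rng)
        self.r2 = nn.ReLU()
        self.head = nn.Conv2d(p, q, 1, rng)

    def features(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        h = self.r1.forward(self.c1.forward(x, store), store)
        return self.r2.forward(self.c2.forward(h, store), store)

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        return self.head.forward(self.features(x, store), store)

    def backward(self, dy: np.ndarray) -> None:
        dh = self.head.backward(dy)
        self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dh))))

    @property
    def params(self):
        return self.c1.params + self.c2.params + self.head.params

    @property
    def grads(self):
        return self.c1.grads + self.c2.grads + self.head.grads


def extract_features(image: np.ndarray, p: int = 64, seed: int = 0) -> np.ndarray:
    """Per-pixel p-dimensional conv features (3x3 kernels + ReLU), (p,H,W)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    img = np.asarray(image, dtype=np.float32)
    net = _PerImageCNN(p, 1, np.random.default_rng(seed))
    return net.features(img[None, None], store=False)[0]


def _whiten_backward(y: np.ndarray, yw: np.ndarray, dyw: np.ndarray) -> np.ndarray:
    """Backprop through per-channel standardisation (q,H,W)."""
    n = y.shape[1] * y.shape[2]
    sd = y.std(axis=(1, 2), keepdims=True) + 1e-8
    dmean = dyw.mean(axis=(1, 2), keepdims=True)
    dvar = (dyw * yw).mean(axis=(1, 2), keepdims=True)
    return (dyw - dmean - yw * dvar) / sd


class KanezakiNet:
    """Per-image alternating CNN/superpixel segmenter; ``fit`` trains it."""

    def __init__(self, config: KanezakiConfig = KanezakiConfig()):
        self.config = config

    def fit(self, image: np.ndarray) -> "KanezakiResults":
        cfg = self.config
        img = np.asarray(image, dtype=np.float32)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        rng = np.random.default_rng(cfg.seed)
        net = _PerImageCNN(cfg.p, cfg.q, rng)
        opt = nn.SGD(net.params, net.grads, lr=cfg.lr, momentum=cfg.momentum)
        sp = compute_superpixels(img, min(cfg.n_superpixels, img.size))
        x = img[None, None]
        history: list[int] = []
        labels = None
        for _ in range(cfg.n_iterations):
            y = net.forward(x)[0]                     # (q,H,W)
            yw, raw_labels = classify(y)
            labels = superpixel_refine(raw_labels, sp)
            qprime = int(np.unique(labels).size)
            history.append(qprime)
            if cfg.stop_at_binary and qprime <= 2:
                break
            # cross-entropy between softmax(whitened responses) and refined labels
            p = nn.channel_softmax(yw[None])[0]
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, labels[None], 1.0, axis=0)
            n_pix = img.size
            dp = (-onehot / np.maximum(p, 1e-12)) / n_pix
            dz = nn.channel_softmax_backward(p, dp)   # grad wrt whitened y
            dy = _whiten_backward(y, yw, dz)
            net.backward(dy[None].astype(np.float32))
            opt.step()
        return KanezakiResults(image=np.asarray(image, dtype=np.float64),
                               labels_=labels, n_clusters_=history[-1],
                               cluster_history_=history, config=cfg)


@dataclass
class KanezakiResults:
    image: np.ndarray
    labels_: np.ndarray
    n_clusters_: int
    cluster_history_: list[int]
    config: KanezakiConfig

    def lesion_mask(self) -> np.ndarray:
        """Binary mask of the brightest-mean-intensity cluster."""
        labs = np.unique(self.labels_)
        means = [self.image[self.labels_ == c].mean() for c in labs]
        return (self.labels_ == labs[int(np.argmax(means))]).astype(np.uint8)

    def summary(self) -> str:
        lines = [
            "Per-image CNN + SLIC superpixel refinement",
            "=" * 44,
            f"{'max clusters q':<22} {self.config.q}",
            f"{'initial q-prime':<22} {self.cluster_history_[0]}",
            f"{'final q-prime':<22} {self.n_clusters_}",
            f"{'iterations run':<22} {len(self.cluster_history_)}",
        ]
        return "\n".join(lines) + "\n"
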