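"""W-net: fully convolutional autoencoder for unsupervised segmentation.

Both the encoder and the decoder are U-nets.  The encoder ends in a K-way
channel softmax, so its output is a per-pixel probability map over K latent
classes; the decoder reconstructs the input image from that map.  Training
is fully unsupervised and alternates, per batch,

1. a reconstruction step: mean-squared error between input and
   reconstruction, back-propagated through the *whole* W-net, and
2. a partition step: the soft normalized-cut loss of the probability map
   (evaluated on an average-pooled grid for tractability), back-propagated
   through the *encoder only*,

each with its own Adam optimizer.  After training, ``argmax`` over the
probability map yields a K-class segmentation; a (one-time) mapping of
latent classes onto {lesion, background} produces the binary lesion mask.
With K=3 the network typically learns bright-lesion / background / vessel
classes, and the lesion class is the brightest one.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import nn
from .ncut import AffinitySpec, average_pool, pixel_weights, soft_ncut_loss_grad

__all__ = [
    "WNetConfig",
    "WNet",
    "WNetResults",
    "reconstruction_loss",
    "argmax_segment",
    "map_classes_to_lesion",
    "auto_map_classes",
]

_EPS = 1e-8


@dataclass(frozen=True)
class WNetConfig:
    """Hyper-parameters of the W-net.

    The default geometry (depth 5, 64 base features) yields 1024 features
    at the bottleneck of each U-net, kernel size 3, K=3 classes and 250
    epochs with two Adam optimizers — the configuration used on real
    256x256 cSLO series.  ``depth`` and ``base_features`` scale the network
    down for CPU-sized experiments.
    """

    n_classes: int = 3
    kernel_size: int = 3
    depth: int = 5
    base_features: int = 64
    epochs: int = 250
    lr_reconstruction: float = 1e-3
    lr_ncut: float = 1e-3
    batch_size: int = 8
    pool_factor: int = 2
    ncut_warmup_epochs: int = 0
    affinity: AffinitySpec = field(default_factory=AffinitySpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.ncut_warmup_epochs < 0:
            raise ValueError("ncut_warmup_epochs must be >= 0")

    @property
    def bottleneck_features(self) -> int:
        return self.base_features * 2 ** (self.depth - 1)


def reconstruction_loss(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean squared error (1/n) sum (Y - Yhat)^2 over the n pixels."""
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(reconstructed, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between original and reconstruction")
    return float(np.mean((a - b) ** 2))


def argmax_segment(probabilities: np.ndarray) -> np.ndarray:
    """Per-pixel label of the most probable class; ties -> lowest index."""
    p = np.asarray(probabilities)
    if p.ndim != 3:
        raise ValueError("probabilities must be (K,H,W)")
    return p.argmax(axis=0)


def map_classes_to_lesion(mask: np.ndarray, lesion_classes: set[int] | frozenset[int]) -> np.ndarray:
    """Binary lesion mask: 1 where the label belongs to ``lesion_classes``."""
    m = np.asarray(mask)
    out = np.zeros(m.shape, dtype=np.uint8)
    for c in lesion_classes:
        out[m == c] = 1
    return out


def _f1_from_masks(preds, truths) -> float:
    tp = fp = fn = 0
    for p, t in zip(preds, truths):
        p = np.asarray(p).astype(bool)
        t = np.asarray(t).astype(bool)
        tp += int(np.sum(p & t))
        fp += int(np.sum(p & ~t))
        fn += int(np.sum(~p & t))
    denom = tp + 0.5 * (fp + fn)
    return 1.0 if denom == 0 else tp / denom


def auto_map_classes(label_masks, images, n_classes: int,
                     reference_masks=None) -> set[int]:
    """Map latent classes to the lesion automatically.

    Without reference masks, the lesion is taken to be the class with the
    highest mean image intensity (geographic atrophy appears as the
    brightest region in IR cSLO; the W-net's classes are intensity-driven).
    With reference masks, every non-empty subset of classes is scored by
    pooled F1 against the references and the best subset is returned.
    """
    label_masks = [np.asarray(m) for m in label_masks]
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if not label_masks:
        raise ValueError("need at least one frame")
    if reference_masks is not None:
        best, best_f1 = None, -1.0
        classes = range(n_classes)
        for r in range(1, n_classes + 1):
            for subset in combinations(classes, r):
                preds = [map_classes_to_lesion(m, set(subset)) for m in label_masks]
                f1 = _f1_from_masks(preds, reference_masks)
                if f1 > best_f1:
                    best, best_f1 = set(subset), f1
        return best
    sums = np.zeros(n_classes)
    counts = np.zeros(n_classes)
    for m, im in zip(label_masks, images):
        for c in range(n_classes):
            sel = m == c
            sums[c] += im[sel].sum()
            counts[c] += sel.sum()
    means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    return {int(np.argmax(means))}


class WNet:
    """Unsupervised W-net segmenter (build with a config, then ``fit``)."""

    def __init__(self, config: WNetConfig = WNetConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = nn.UNet(1, config.n_classes, config.depth,
                               config.base_features, config.kernel_size,
                               rng, final="softmax")
        self.decoder = nn.UNet(config.n_classes, 1, config.depth,
                               config.base_features, config.kernel_size,
                               rng, final="linear")
        self._side: int | None = None

    # ------------------------------------------------------------------
    def _check_side(self, side: int) -> None:
        if side % 2 ** (self.config.depth - 1) != 0:
            raise ValueError(
                f"image side {side} must be divisible by 2**(depth-1)")
        if side % self.config.pool_factor != 0:
            raise ValueError("pool_factor must divide the image side")

    @staticmethod
    def _validate_images(images) -> np.ndarray:
        if len(images) == 0:
            raise ValueError("need at least one training image")
        arrs = []
        for im in images:
            a = np.asarray(im)
            if a.dtype == bool or np.issubdtype(a.dtype, np.integer):
                raise TypeError(
                    "training consumes grayscale images only (float in [0,1]); "
                    "got an integer/boolean array — masks are not accepted")
            if a.ndim != 2:
                raise ValueError("images must be 2-D single channel")
            if a.min() < -1e-6 or a.max() > 1 + 1e-6:
                raise ValueError("image intensities must lie in [0,1]")
            arrs.append(a.astype(np.float32))
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError("all training images must share one shape")
        h, w = arrs[0].shape
        if h != w:
            raise ValueError("images must be square")
        return np.stack(arrs)[:, None]  # (M,1,H,W)

    # ------------------------------------------------------------------
    def _ncut_grad_batch(self, probs: np.ndarray, weights_list) -> tuple[float, np.ndarray]:
        """Pooled soft-N-cut loss (batch mean) and gradient wrt probs."""
        cfg = self.config
        f = cfg.pool_factor
        bsz, k, h, w = probs.shape
        grad = np.zeros_like(probs, dtype=np.float64)
        total = 0.0
        for i in range(bsz):
            p_pool = average_pool(probs[i].astype(np.float64), f)  # (K,h/f,w/f)
            s = np.maximum(p_pool.sum(axis=0, keepdims=True), _EPS)
            q = p_pool / s
            j, g_q = soft_ncut_loss_grad(q, weights_list[i])
            g_q = g_q.T.reshape(k, h // f, w // f)
            # renormalization backward: dP = (gQ - sum_j gQ_j Q_j) / s
            g_pool = (g_q - (g_q * q).sum(axis=0, keepdims=True)) / s
            # average-pool backward
            g_full = g_pool.repeat(f, axis=1).repeat(f, axis=2) / (f * f)
            grad[i] = g_full
            total += j
        return total / bsz, (grad / bsz).astype(np.float32)

    def fit(self, images, verbose: bool = False) -> "WNetResults":
        """Train on unlabeled images; returns results with loss history."""
        cfg = self.config
        x_all = self._validate_images(images)
        m, _, h, w = x_all.shape
        self._check_side(h)
        self._side = h
        f = cfg.pool_factor
        weights = [
            pixel_weights(average_pool(x_all[i, 0].astype(np.float64), f),
                          cfg.affinity)
            for i in range(m)
        ]
        params_all = self.encoder.params + self.decoder.params
        grads_all = self.encoder.grads + self.decoder.grads
        opt_recon = nn.Adam(params_all, grads_all, lr=cfg.lr_reconstruction)
        opt_ncut = nn.Adam(self.encoder.params, self.encoder.grads, lr=cfg.lr_ncut)
        rng = np.random.default_rng(cfg.seed + 1)
        history = []
        n_mse_steps = n_ncut_steps = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(m)
            mse_vals, ncut_vals = [], []
            for start in range(0, m, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x = x_all[idx]
                ncut_active = epoch >= cfg.ncut_warmup_epochs
                # one forward, then two successive optimization steps
                p = self.encoder.forward(x)
                recon = self.decoder.forward(p)
                diff = recon - x
                mse = float(np.mean(diff ** 2))
                dmse = (2.0 * diff / diff.size).astype(np.float32)
                # -- step 1: reconstruction error, full W-net -----------
                dp = self.decoder.backward(dmse)
                self.encoder.backward(dp, retain=ncut_active)
                opt_recon.step()
                n_mse_steps += 1
                # -- step 2: soft-N-cut, encoder only -------------------
                jval, dj = self._ncut_grad_batch(p, [weights[i] for i in idx])
                if ncut_active:
                    self.encoder.backward(dj)
                    opt_ncut.step()
                    n_ncut_steps += 1
                mse_vals.append(mse)
                ncut_vals.append(jval)
            history.append({"epoch": epoch,
                            "mse": float(np.mean(mse_vals)),
                            "soft_ncut": float(np.mean(ncut_vals))})
            if verbose:
                print(f"epoch {epoch:4d}  mse={history[-1]['mse']:.5f}  "
                      f"J={history[-1]['soft_ncut']:.4f}")
        return WNetResults(model=self,
                           history=pd.DataFrame(history),
                           n_mse_steps=n_mse_steps,
                           n_ncut_steps=n_ncut_steps)

    @classmethod
    def fit_restarts(cls, images, config: WNetConfig, n_init: int = 2,
                     verbose: bool = False) -> "WNetResults":
        """Train ``n_init`` models from different initializations and keep
        the one with the lowest final soft-N-cut loss.

        The alternating objective is non-convex and can settle either on a
        partition locked to the lesion boundaries or on a coarser
        intensity-stratum partition; the final soft-N-cut value separates
        the two, so restart selection is fully unsupervised (the same
        rationale as k-means' ``n_init``).  Restart i uses ``config.seed + i``.
        """
        if n_init < 1:
            raise ValueError("n_init must be >= 1")
        from dataclasses import replace as _replace

        best: WNetResults | None = None
        for i in range(n_init):
            model = cls(_replace(config, seed=config.seed + i))
            res = model.fit(images, verbose=verbose)
            j = float(res.history["soft_ncut"].iloc[-1])
            if verbose:
                print(f"restart {i}: final soft-N-cut J = {j:.4f}")
            if best is None or j < float(best.history["soft_ncut"].iloc[-1]):
                best = res
        return best

    # ------------------------------------------------------------------
    def predict(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class probability map (K,H,W) for one image."""
        a = np.asarray(image, dtype=np.float32)
        if a.ndim != 2:
            raise ValueError("image must be 2-D")
        if self._side is not None and a.shape != (self._side, self._side):
            raise ValueError(
                f"image side {a.shape} does not match training side {self._side}")
        self._check_side(a.shape[0])
        p = self.encoder.forward(a[None, None], store=False)
        return p[0].astype(np.float64)

    def reconstruct(self, image: np.ndarray) -> np.ndarray:
        p = self.predict(image)
        out = self.decoder.forward(p[None].astype(np.float32), store=False)
        return out[0, 0].astype(np.float64)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["affinity"] = asdict(self.config.affinity)
        state = {f"enc_{k}": v for k, v in self.encoder.state_dict().items()}
        state.update({f"dec_{k}": v for k, v in self.decoder.state_dict().items()})
        np.savez_compressed(path, __config__=json.dumps(cfg),
                            __side__=np.array(self._side or -1), **state)

    @classmethod
    def load(cls, path) -> "WNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg["affinity"] = AffinitySpec(**cfg["affinity"])
            model = cls(WNetConfig(**cfg))
            side = int(data["__side__"])
            model._side = None if side < 0 else side
            enc = {k[4:]: data[k] for k in data.files if k.startswith("enc_")}
            dec = {k[4:]: data[k] for k in data.files if k.startswith("dec_")}
        model.encoder.load_state_dict(enc)
        model.decoder.load_state_dict(dec)
        return model


@dataclass
class WNetResults:
    """Trained W-net with its loss history and segmentation helpers."""

    model: WNet
    history: pd.DataFrame
    n_mse_steps: int
    n_ncut_steps: int

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        return self.model.predict(image)

    def segment(self, image: np.ndarray) -> np.ndarray:
        """K-class label map by argmax over the probability map."""
        return argmax_segment(self.model.predict(image))

    def lesion_mask(self, image: np.ndarray, lesion_classes: set[int]) -> np.ndarray:
        return map_classes_to_lesion(self.segment(image), lesion_classes)

    def map_lesion_classes(self, images, reference_masks=None) -> set[int]:
        masks = [self.segment(im) for im in images]
        return auto_map_classes(masks, images, self.model.config.n_classes,
                                reference_masks=reference_masks)

    def summary(self) -> str:
        cfg = self.model.config
        buf = io.StringIO()
        buf.write("W-net unsupervised segmentation\n")
        buf.write("=" * 47 + "\n")
        n_par = self.model.encoder.n_params + self.model.decoder.n_params
        rows = [
            ("classes K", cfg.n_classes),
            ("depth / base features", f"{cfg.depth} / {cfg.base_features}"),
            ("bottleneck features", cfg.bottleneck_features),
            ("parameters", n_par),
            ("epochs", len(self.history)),
            ("optimizer steps (mse/ncut)", f"{self.n_mse_steps}/{self.n_ncut_steps}"),
        ]
        if len(self.history):
            rows.append(("final MSE", f"{self.history['mse'].iloc[-1]:.5f}"))
            rows.append(("final soft-N-cut J", f"{self.history['soft_ncut'].iloc[-1]:.4f}"))
        for k, v in rows:
            buf.write(f"{k:<30} {v}\n")
        return buf.getvalue()
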