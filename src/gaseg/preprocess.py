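"""Preprocessing chain for registered cSLO IR fundus frames.

Registered exports carry near-black borders from the spatial alignment step;
frames of one eye are acquired months apart under different gain and
illumination.  The chain is: crop the black frame, resize to a common
working resolution (256x256 by default), then jointly homogenize the
gray-level statistics of all frames of a series so that any two processed
images have comparable intensities.

Homogenization is an affine standardisation of every frame to the
statistics of the series' median frame, followed by one series-wide affine
map onto [0, 1].  It equalises global mean/std only — low-frequency shading
inside a frame is deliberately left untouched (the residual defect is then
identical across the series, which is what downstream comparison needs).
The transform is monotone per frame and idempotent.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import Frame, SeriesDataset

__all__ = [
    "crop_black_borders",
    "resize_to_working",
    "resize_mask",
    "homogenize_series",
    "preprocess_series",
]


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    return img


def crop_black_borders(image: np.ndarray, threshold: float = 0.02) -> np.ndarray:
    """Largest sub-rectangle whose boundary rows/columns carry signal.

    A row/column belongs to the border while every pixel in it is
    <= ``threshold``.  Never removes a pixel above threshold.  Raises on a
    fully black frame (unusable registration artefact).
    """
    img = _validate_image(image)
    keep = img > threshold
    if not keep.any():
        raise ValueError("image is entirely black at this threshold; unusable frame")
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    return img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def resize_to_working(image: np.ndarray, side: int = 256) -> np.ndarray:
    """Bilinear resize to ``side`` x ``side``, intensities kept in [0, 1]."""
    if side < 16:
        raise ValueError("side must be >= 16")
    img = _validate_image(image)
    if img.shape == (side, side):
        return img.copy()
    out = _sk_resize(img, (side, side), order=1, mode="reflect",
                     anti_aliasing=img.shape[0] > side, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def resize_mask(mask: np.ndarray, side: int = 256) -> np.ndarray:
    """Nearest-neighbour resize for label masks (stays integer/binary)."""
    if side < 16:
        raise ValueError("side must be >= 16")
    m = np.asarray(mask)
    if m.shape == (side, side):
        return m.copy()
    out = _sk_resize(m.astype(np.float64), (side, side), order=0,
                     anti_aliasing=False, preserve_range=True)
    return np.rint(out).astype(m.dtype)


def homogenize_series(series: SeriesDataset) -> SeriesDataset:
    """Equalise global mean/std of every frame of a series (see module doc).

    After correction all frames share the same global mean and std (within
    1e-6) and the series occupies exactly [0, 1].  Monotone per frame,
    idempotent.  A constant-valued frame (zero variance) is rejected.
    """
    if len(series) < 1:
        raise ValueError("series must contain at least one frame")
    imgs = [_validate_image(f.image) for f in series]
    means = np.array([im.mean() for im in imgs])
    stds = np.array([im.std() for im in imgs])
    if np.any(stds < 1e-12):
        raise ValueError("constant-valued frame: cannot homogenize zero variance")
    ref = int(np.argsort(means)[len(means) // 2])  # median-mean frame
    m_t, s_t = means[ref], stds[ref]
    out = [(im - means[i]) / stds[i] * s_t + m_t for i, im in enumerate(imgs)]
    lo = min(im.min() for im in out)
    hi = max(im.max() for im in out)
    span = hi - lo
    out = [(im - lo) / span for im in out]
    frames = [Frame(image=im, mask=f.mask, time_index=f.time_index)
              for im, f in zip(out, series.frames)]
    return SeriesDataset(frames=frames, name=series.name)


def preprocess_series(series: SeriesDataset, side: int = 256,
                      border_threshold: float = 0.02) -> SeriesDataset:
    """Full chain: crop black borders, resize, joint homogenization."""
    frames = []
    for f in series.frames:
        img = crop_black_borders(f.image, border_threshold)
        mask = f.mask
        if mask is not None:
            # crop the mask with the same bounding box
            keep = _validate_image(f.image) > border_threshold
            rows = np.flatnonzero(keep.any(axis=1))
            cols = np.flatnonzero(keep.any(axis=0))
            mask = np.asarray(mask)[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
            mask = resize_mask(mask, side)
        frames.append(Frame(image=resize_to_working(img, side), mask=mask,
                            time_index=f.time_index))
    return homogenize_series(SeriesDataset(frames=frames, name=series.name))
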