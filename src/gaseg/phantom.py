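"""Synthetic cSLO-like fundus phantoms with ground-truth lesion masks.

Real infrared cSLO images of dry-ARMD eyes show bright, irregularly shaped
atrophic patches (geographic atrophy, GA) on a textured retinal background
crossed by dark vessels, under smooth uneven illumination, and lesions only
ever grow over a longitudinal series.  The generator emulates exactly those
statistical features so every method in the package can be exercised and
scored without clinical data:

* lesions: star-convex regions — a circle whose radius is perturbed by a
  random low-order Fourier series (amplitude = ``boundary_irregularity``),
  brightened over the background by ``lesion_contrast`` and optionally
  blurred at the boundary;
* vessels: dark curvilinear random-walk strokes with a Gaussian profile,
  applied multiplicatively;
* illumination: a smooth low-order polynomial shading field shared by all
  frames of a series;
* noise: additive Gaussian, then clipping to [0, 1].

Everything is a pure function of (config, seed): identical configs give
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomConfig", "Frame", "SeriesDataset", "generate_phantom", "generate_series"]


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 256
    n_lesions: int = 2
    lesion_contrast: float = 0.5
    boundary_irregularity: float = 0.25
    blur_sigma: float = 0.0
    vessel_count: int = 4
    illumination_gradient: float = 0.15
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if not (0.0 <= self.lesion_contrast <= 1.0):
            raise ValueError("lesion_contrast must lie in [0, 1]")
        if self.boundary_irregularity < 0 or self.blur_sigma < 0:
            raise ValueError("irregularity and blur_sigma must be >= 0")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if not (0.0 <= self.illumination_gradient < 1.0):
            raise ValueError("illumination_gradient must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Frame:
    image: np.ndarray
    mask: np.ndarray
    time_index: int


@dataclass
class SeriesDataset:
    """Ordered longitudinal frames for one eye."""

    frames: list[Frame] = field(default_factory=list)
    name: str = "series"

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def _star_mask(size: int, center: tuple[float, float], radius: float,
               irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Star-convex region: r(theta) = radius * (1 + irregularity * fourier)."""
    n_harm = 6
    amp = rng.standard_normal(n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    pert = np.zeros_like(theta)
    for h in range(n_harm):
        pert += amp[h] / (h + 1) * np.cos((h + 2) * theta + phase[h])
    r_theta = radius * np.clip(1.0 + irregularity * pert, 0.2, 3.0)
    return rad <= r_theta


def _vessel_field(size: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative attenuation field with dark curvilinear strokes."""
    canvas = np.zeros((size, size))
    for _ in range(count):
        edge = rng.integers(0, 4)
        if edge == 0:
            y, x = 0.0, rng.uniform(0, size)
            ang = rng.uniform(0.25 * np.pi, 0.75 * np.pi)
        elif edge == 1:
            y, x = float(size - 1), rng.uniform(0, size)
            ang = rng.uniform(-0.75 * np.pi, -0.25 * np.pi)
        elif edge == 2:
            y, x = rng.uniform(0, size), 0.0
            ang = rng.uniform(-0.25 * np.pi, 0.25 * np.pi)
        else:
            y, x = rng.uniform(0, size), float(size - 1)
            ang = rng.uniform(0.75 * np.pi, 1.25 * np.pi)
        for _ in range(3 * size):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < size and 0 <= ix < size:
                canvas[iy, ix] = 1.0
            elif canvas.any():
                break
            ang += rng.normal(0.0, 0.12)
            y += np.sin(ang)
            x += np.cos(ang)
    profile = ndimage.gaussian_filter(canvas, sigma=max(size / 256.0, 0.8))
    if profile.max() > 0:
        profile = profile / profile.max()
    return 1.0 - 0.45 * profile


def _illumination_field(size: int, gradient: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth polynomial shading in [1 - gradient, 1]."""
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    c = rng.uniform(-1.0, 1.0, size=6)
    fld = (c[0] * yy + c[1] * xx + c[2] * yy * xx
           + c[3] * yy ** 2 + c[4] * xx ** 2 + c[5])
    lo, hi = fld.min(), fld.max()
    if hi - lo < 1e-12:
        return np.ones((size, size))
    fld = (fld - lo) / (hi - lo)  # [0,1]
    return 1.0 - gradient * (1.0 - fld)


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    base = 0.35
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
    texture *= 0.04 / max(texture.std(), 1e-12)
    return base + texture


def _lesion_geometry(config: PhantomConfig, rng: np.random.Generator):
    """Sample lesion centers and radii; deterministic given the rng state."""
    size = config.image_size
    lesions = []
    for _ in range(config.n_lesions):
        center = (rng.uniform(0.25 * size, 0.75 * size),
                  rng.uniform(0.25 * size, 0.75 * size))
        radius = rng.uniform(0.08, 0.16) * size
        lesions.append((center, radius))
    return lesions


def _render(config: PhantomConfig, mask: np.ndarray, background: np.ndarray,
            vessels: np.ndarray, illum: np.ndarray,
            noise_rng: np.random.Generator) -> np.ndarray:
    lesion_field = mask.astype(np.float64)
    if config.blur_sigma > 0:
        lesion_field = ndimage.gaussian_filter(lesion_field, config.blur_sigma)
    img = background + config.lesion_contrast * lesion_field
    img = img * vessels * illum
    if config.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, config.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic fundus image plus its binary ground-truth lesion mask."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    background = _background(size, rng)
    vessels = _vessel_field(size, config.vessel_count, rng)
    illum = _illumination_field(size, config.illumination_gradient, rng)
    mask = np.zeros((size, size), dtype=bool)
    for center, radius in _lesion_geometry(config, rng):
        mask |= _star_mask(size, center, radius, config.boundary_irregularity, rng)
    img = _render(config, mask, background, vessels, illum, rng)
    return img, mask.astype(np.uint8)


def generate_series(config: PhantomConfig, n_frames: int, growth_rate: float,
                    new_lesion_at: int | None = None,
                    name: str = "series") -> SeriesDataset:
    """Longitudinal series with monotonically growing lesions.

    Frame t's mask is frame t-1's mask dilated by ``round(growth_rate *
    image_size / 50)`` pixels (at least 1 when growth_rate > 0), so the
    pixel-wise subset relation mask_{t-1} <= mask_t holds exactly.  An
    optional new lesion component appears at frame ``new_lesion_at``,
    emulating de-novo atrophy.  All frames share one background, vessel map
    and illumination field; only sensor noise is resampled per frame.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if growth_rate < 0:
        raise ValueError("growth_rate must be >= 0")
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    background = _background(size, rng)
    vessels = _vessel_field(size, config.vessel_count, rng)
    illum = _illumination_field(size, config.illumination_gradient, rng)
    mask = np.zeros((size, size), dtype=bool)
    for center, radius in _lesion_geometry(config, rng):
        mask |= _star_mask(size, center, 0.7 * radius,
                           config.boundary_irregularity, rng)
    step = 0
    if growth_rate > 0:
        step = max(1, int(round(growth_rate * size / 50.0)))
    struct = ndimage.generate_binary_structure(2, 2)
    frames = []
    for t in range(n_frames):
        if t > 0 and step > 0 and mask.any():
            mask = ndimage.binary_dilation(mask, structure=struct, iterations=step)
        if new_lesion_at is not None and t == new_lesion_at:
            center = (rng.uniform(0.15 * size, 0.85 * size),
                      rng.uniform(0.15 * size, 0.85 * size))
            mask = mask | _star_mask(size, center, 0.05 * size,
                                     config.boundary_irregularity, rng)
        frames.append(Frame(
            image=_render(config, mask, background, vessels, illum, rng),
            mask=mask.astype(np.uint8),
            time_index=t,
        ))
    return SeriesDataset(frames=frames, name=name)
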