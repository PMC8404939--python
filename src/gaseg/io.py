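"""Dataset layout and PNG round-tripping.

On disk a dataset is one directory per series::

    root/
      series_000/
        frame_000.png  frame_001.png ...
        masks/frame_000.png ...        (optional, 0/255 binary)
        series.json                    (generator config + seed, if synthetic)

Images are 8-bit grayscale PNG, normalized to [0, 1] on load; masks are
paired by filename and binarised.  Frames sort by their zero-padded index
regardless of on-disk order.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import Frame, PhantomConfig, SeriesDataset

__all__ = ["save_image", "load_image", "save_series", "load_series",
           "load_dataset"]

_FRAME_RE = re.compile(r"frame_(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def save_image(path, image: np.ndarray) -> None:
    """Write a [0,1] float image (or 0/1 mask) as 8-bit grayscale PNG."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    if arr.max() <= 1.0 + 1e-9:
        arr = arr * 255.0
    Image.fromarray(np.clip(np.rint(arr), 0, 255).astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale image, normalized to [0, 1]."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"unreadable image file: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def save_series(series: SeriesDataset, root, config: PhantomConfig | None = None) -> Path:
    """Write one series directory (frames, masks subdir, JSON sidecar)."""
    root = Path(root)
    sdir = root / series.name
    (sdir / "masks").mkdir(parents=True, exist_ok=True)
    for f in series.frames:
        name = f"frame_{f.time_index:03d}.png"
        save_image(sdir / name, f.image)
        if f.mask is not None:
            save_image(sdir / "masks" / name, f.mask.astype(np.float64))
    if config is not None:
        (sdir / "series.json").write_text(json.dumps(asdict(config), indent=2))
    return sdir


def load_series(sdir) -> SeriesDataset:
    sdir = Path(sdir)
    entries = []
    for p in sdir.iterdir():
        m = _FRAME_RE.match(p.name)
        if p.is_file() and m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise ValueError(f"no frames found in series directory {sdir}")
    entries.sort(key=lambda t: t[0])
    mask_dir = sdir / "masks"
    frames = []
    for idx, p in entries:
        mask = None
        mp = mask_dir / p.name
        if mask_dir.is_dir():
            if not mp.is_file():
                candidates = list(mask_dir.glob("frame_*"))
                if candidates:
                    raise ValueError(f"unpaired mask set: no mask for frame {p.name} in {mask_dir}")
            else:
                mask = (load_image(mp) > 0.5).astype(np.uint8)
        frames.append(Frame(image=load_image(p), mask=mask, time_index=idx))
    return SeriesDataset(frames=frames, name=sdir.name)


def load_dataset(root) -> list[SeriesDataset]:
    """Load every series directory under ``root`` (sorted by name)."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    sdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not sdirs:
        raise ValueError(f"empty dataset directory: {root}")
    return [load_series(d) for d in sdirs]
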