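"""End-to-end orchestration: preprocess, segment, map, evaluate, compare.

The W-net trains once on the training series and is then applied to every
frame; the three baselines are fitted per frame.  Each method's multi-class
output is mapped to a binary lesion mask by the brightest-class rule
(the W-net optionally by reference-guided mapping on the training split),
then scored with the shared pixel-wise protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chanvese import ChanVese, ChanVeseConfig
from .evaluate import EvalReport, evaluate_series
from .gabor import GaborBank, GaborKMeans
from .kanezaki import KanezakiConfig, KanezakiNet
from .phantom import SeriesDataset
from .wnet import WNet, WNetConfig, argmax_segment

__all__ = ["segment_dataset", "compare_methods", "train_and_eval_wnet"]


def train_and_eval_wnet(train_series: list[SeriesDataset],
                        test_series: list[SeriesDataset],
                        config: WNetConfig,
                        fusion: bool = False) -> tuple[EvalReport, EvalReport]:
    """Train a W-net on the training series, evaluate on both splits."""
    train_imgs = [f.image for s in train_series for f in s.frames]
    model = WNet(config)
    results = model.fit(train_imgs)
    lesion_classes = results.map_lesion_classes(train_imgs)
    reports = []
    for split, sets in (("train", train_series), ("test", test_series)):
        preds = {s.name: [results.lesion_mask(f.image, lesion_classes)
                          for f in s.frames] for s in sets}
        reports.append(evaluate_series(preds, sets, method="wnet",
                                       split=split, fusion=fusion))
    return tuple(reports)


def segment_dataset(series_list: list[SeriesDataset], method: str,
                    seed: int = 0, epochs: int = 60,
                    wnet_config: WNetConfig | None = None) -> dict[str, list[np.ndarray]]:
    """Binary lesion masks for every frame, per method name."""
    if method == "wnet":
        cfg = wnet_config or WNetConfig(depth=3, base_features=16,
                                        epochs=epochs, seed=seed)
        imgs = [f.image for s in series_list for f in s.frames]
        model = WNet(cfg)
        res = model.fit(imgs)
        lc = res.map_lesion_classes(imgs)
        return {s.name: [res.lesion_mask(f.image, lc) for f in s.frames]
                for s in series_list}
    if method == "gabor":
        est = GaborKMeans(GaborBank(), n_clusters=2, seed=seed)
        return {s.name: [est.fit(f.image).lesion_mask() for f in s.frames]
                for s in series_list}
    if method == "chanvese":
        est = ChanVese(ChanVeseConfig())
        return {s.name: [est.fit(f.image).mask_ for f in s.frames]
                for s in series_list}
    if method == "kanezaki":
        out = {}
        for s in series_list:
            masks = []
            for f in s.frames:
                cfg = KanezakiConfig(p=32, q=32, n_superpixels=200,
                                     n_iterations=32, seed=seed)
                masks.append(KanezakiNet(cfg).fit(f.image).lesion_mask())
            out[s.name] = masks
        return out
    raise ValueError(f"unknown method {method!r}")


def compare_methods(series_list: list[SeriesDataset], epochs: int = 60,
                    seed: int = 0, fusion_for_wnet: bool = True) -> pd.DataFrame:
    """Table of mean +/- std F1/precision/recall for all four methods."""
    rows = []
    for method in ("chanvese", "kanezaki", "gabor", "wnet"):
        preds = segment_dataset(series_list, method, seed=seed, epochs=epochs)
        variants = [(method, False)]
        if method == "wnet" and fusion_for_wnet:
            variants.append(("wnet+seg_t-1", True))
        for name, fuse in variants:
            rep = evaluate_series(preds, series_list, method=name, fusion=fuse)
            agg = rep.aggregate()
            rows.append({"method": name, **{k: round(v, 4) for k, v in agg.items()}})
    return pd.DataFrame(rows)
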