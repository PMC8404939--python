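"""Pixel-wise evaluation protocol shared by every segmentation method.

Lesion pixels are the positive class.  From the confusion counts,

    precision = TP / (TP + FP),   recall = TP / (TP + FN),
    F1 = 2 precision recall / (precision + recall)
       = TP / (TP + 0.5 (FP + FN)),

the two F1 forms being algebraically identical.  Degenerate conventions
(documented and tested): empty truth with empty prediction scores 1 on all
three; empty truth with a non-empty prediction scores precision 0,
recall 1, F1 0; an empty prediction against non-empty truth scores
precision 0.

ROC curves require per-pixel lesion probabilities (soft memberships, e.g.
fuzzy c-means or the W-net softmax); AUC is the trapezoid integral and
equals the probability that a random lesion pixel outranks a random
background pixel (ties counted half).

Temporal fusion exploits that geographic atrophy only grows: the lesion
mask at time t is merged (pixel-wise union) with the mask predicted at
t-1, trading precision for a guaranteed non-decrease in recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import SeriesDataset

__all__ = ["ConfusionCounts", "confusion", "scores", "f1_score", "roc_curve",
           "temporal_fusion", "evaluate_series", "EvalReport", "make_splits"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    u = np.unique(m)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    return m.astype(bool)


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts, lesion = positive class."""
    p = _as_binary(predicted)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("predicted and truth masks must share a shape")
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)))


def scores(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) with the documented degenerate conventions."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 1.0 if fn == 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    denom = tp + 0.5 * (fp + fn)
    f1 = tp / denom if denom > 0 else 1.0
    return precision, recall, f1


def f1_score(predicted: np.ndarray, truth: np.ndarray) -> float:
    return scores(confusion(predicted, truth))[2]


def roc_curve(probabilities: np.ndarray, truth: np.ndarray,
              thresholds: np.ndarray | None = None):
    """ROC sweep of a per-pixel lesion-probability map.

    Returns ``(fpr, tpr, auc)``; the curve includes the (0,0) and (1,1)
    endpoints and AUC is computed by the trapezoid rule.  Raises if the
    truth contains a single class (ROC undefined).
    """
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    t = _as_binary(truth).ravel()
    if p.shape != t.shape:
        raise ValueError("probabilities and truth must share a shape")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC is undefined when truth has a single class")
    if thresholds is None:
        thresholds = np.unique(p)
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        pred = p >= th
        tpr.append(np.sum(pred & t) / n_pos)
        fpr.append(np.sum(pred & ~t) / n_neg)
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_a = np.asarray(fpr)
    tpr_a = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return fpr_a, tpr_a, auc


def temporal_fusion(mask_t: np.ndarray, mask_prev: np.ndarray) -> np.ndarray:
    """Pixel-wise union of the current and previous lesion masks."""
    a = _as_binary(mask_t)
    b = _as_binary(mask_prev)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    return (a | b).astype(np.uint8)


@dataclass
class EvalReport:
    """Per-frame scores plus aggregate mean +/- std for one method."""

    method: str
    split: str
    frame_scores: pd.DataFrame  # columns: series, frame, precision, recall, f1
    fusion: bool = False
    series_means: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.series_means is None and len(self.frame_scores):
            self.series_means = (self.frame_scores
                                 .groupby("series")[["precision", "recall", "f1"]]
                                 .mean().reset_index())

    def aggregate(self, over: str = "frames") -> pd.Series:
        """Mean +/- std over 'frames' (pooled) or over 'series' means."""
        src = self.frame_scores if over == "frames" else self.series_means
        cols = src[["precision", "recall", "f1"]]
        out = {}
        for c in cols:
            out[f"{c}_mean"] = float(cols[c].mean())
            out[f"{c}_std"] = float(cols[c].std(ddof=0))
        return pd.Series(out)

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"Evaluation report — method: {self.method}"
            + (" + Seg_(t-1) fusion" if self.fusion else ""),
            "=" * 52,
            f"{'split':<14} {self.split}",
            f"{'frames':<14} {len(self.frame_scores)}",
            f"{'F1':<14} {agg['f1_mean']:.3f} ± {agg['f1_std']:.3f}",
            f"{'precision':<14} {agg['precision_mean']:.3f} ± {agg['precision_std']:.3f}",
            f"{'recall':<14} {agg['recall_mean']:.3f} ± {agg['recall_std']:.3f}",
        ]
        return "\n".join(lines) + "\n"


def evaluate_series(predictions: dict[str, list[np.ndarray]],
                    truth: list[SeriesDataset] | dict[str, list[np.ndarray]],
                    method: str = "", split: str = "test",
                    fusion: bool = False) -> EvalReport:
    """Score predicted lesion masks against ground truth, series by series.

    ``predictions`` maps series name -> ordered list of binary masks.
    ``truth`` is either a list of SeriesDataset (masks taken from frames)
    or a dict of mask lists keyed like predictions.  With ``fusion``,
    frame t >= 1 is replaced by its union with frame t-1's prediction
    before scoring.  Frames without a truth mask are skipped with a
    warning.
    """
    if isinstance(truth, dict):
        truth_map = truth
    else:
        truth_map = {s.name: [f.mask for f in s.frames] for s in truth}
    rows = []
    for name, preds in predictions.items():
        if name not in truth_map:
            raise KeyError(f"no ground truth for series {name!r}")
        tmasks = truth_map[name]
        fused_prev = None
        for i, pred in enumerate(preds):
            use = pred
            if fusion and fused_prev is not None:
                use = temporal_fusion(pred, fused_prev)
            fused_prev = pred
            if i >= len(tmasks) or tmasks[i] is None:
                warnings.warn(f"series {name!r} frame {i}: missing truth mask, skipped")
                continue
            prec, rec, f1 = scores(confusion(use, tmasks[i]))
            rows.append({"series": name, "frame": i, "precision": prec,
                         "recall": rec, "f1": f1})
    return EvalReport(method=method, split=split,
                      frame_scores=pd.DataFrame(rows,
                                                columns=["series", "frame",
                                                         "precision", "recall", "f1"]),
                      fusion=fusion)


def make_splits(n_series: int = 18, n_train: int = 12, n_repeats: int = 8,
                seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """Seeded random train/test series splits (12 train / 6 test by default,
    8 repetitions), the protocol used in place of k-fold when series counts
    are small and their lengths uneven."""
    if not (0 < n_train < n_series):
        raise ValueError("need 0 < n_train < n_series")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n_series)
        splits.append((sorted(perm[:n_train].tolist()),
                       sorted(perm[n_train:].tolist())))
    return splits
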