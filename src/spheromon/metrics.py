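"""Quantitative validation: per-feature relative error, pixel-level
sensitivity (TPR) and precision (PPV), per-set summaries, and qualitative
red-mask overlays.

Degenerate denominators (reference value 0, empty masks) yield NaN and are
excluded from set means; the exclusion count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def relative_error(ms: float, as_: float) -> float:
    """|MS - AS| / |MS| * 100, NaN when the reference MS is zero."""
    if ms == 0 or not math.isfinite(ms) or not math.isfinite(as_):
        return math.nan
    return abs(ms - as_) / abs(ms) * 100.0


@dataclass
class Confusion:
    tp: int
    fp: int
    fn: int
    tpr: float
    ppv: float


def pixel_confusion(truth_mask: np.ndarray, pred_mask: np.ndarray) -> Confusion:
    """Pixel counts and rates of a predicted mask against a reference mask.

    TPR = TP / (TP + FN), PPV = TP / (TP + FP); NaN when the respective
    denominator is zero (empty truth or empty prediction).
    """
    truth = np.asarray(truth_mask, dtype=bool)
    pred = np.asarray(pred_mask, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    tp = int((truth & pred).sum())
    fp = int((pred & ~truth).sum())
    fn = int((truth & ~pred).sum())
    tpr = tp / (tp + fn) if tp + fn > 0 else math.nan
    ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
    return Confusion(tp, fp, fn, tpr, ppv)


def iou(truth_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Intersection over union; NaN when both masks are empty."""
    c = pixel_confusion(truth_mask, pred_mask)
    union = c.tp + c.fp + c.fn
    return c.tp / union if union > 0 else math.nan


def set_summary(results: pd.DataFrame, set_column: str = "set") -> pd.DataFrame:
    """Mean +/- sample SD of every numeric metric, per set and pooled.

    ``results`` holds one row per spheroid with a set label column and one
    column per metric.  The pooled column ("Set 1-4") is computed over all
    spheroids, not as a mean of set means; NaN entries are excluded with
    their count reported in an ``n_excluded`` block.
    """
    metrics = [c for c in results.columns if c != set_column]
    sets = sorted(results[set_column].unique())
    rows = []
    for metric in metrics:
        row: dict[str, object] = {"metric": metric}
        for label in sets:
            vals = results.loc[results[set_column] == label, metric].astype(float)
            row[f"{label}_mean"] = vals.mean()
            row[f"{label}_sd"] = vals.std(ddof=1)
        pooled = results[metric].astype(float)
        row["pooled_mean"] = pooled.mean()
        row["pooled_sd"] = pooled.std(ddof=1)
        row["n_excluded"] = int(pooled.isna().sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def overlay(
    frame,
    masks,
    alpha: float = 0.4,
    color: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Render semi-transparent coloured masks on top of a grayscale frame.

    Returns an RGB float array in [0, 1]; with no masks the output is the
    gray-to-RGB conversion of the input.
    """
    from .segment import SpheroidMask
    from .well_detect import Frame

    img = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, float)
    combined = np.zeros(img.shape, dtype=bool)
    for m in masks:
        if isinstance(m, SpheroidMask):
            combined |= m.to_frame(img.shape)
        else:
            m = np.asarray(m, dtype=bool)
            if m.shape != img.shape:
                raise ValueError(f"mask shape {m.shape} != frame shape {img.shape}")
            combined |= m
    rgb = np.repeat(img[..., None], 3, axis=2)
    tint = np.asarray(color, dtype=float)
    rgb[combined] = (1.0 - alpha) * rgb[combined] + alpha * tint
    return np.clip(rgb, 0.0, 1.0)
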