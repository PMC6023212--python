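"""Microwell detection: Roberts gradient, fixed threshold, two-stage circular
Hough transform, and false-positive removal.

The detector votes for circle centers with ring kernels over the configured
radius range (stage one), then assigns each accepted center the radius with
maximal radial edge support (stage two).  Circle "strength" is the normalised
accumulator support, i.e. the fraction of the circle circumference covered by
edge pixels, and is the quantity used for false-positive filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .config import ConfigurationError, DetectionParams

#: Rec.601 luma weights, applied when converting colour frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class Frame:
    """A single grayscale time-lapse frame with intensities in [0, 1].

    ``pixels`` is indexed ``[row, col]`` with the origin at the top-left;
    x denotes the column coordinate and y the row coordinate (0-based).
    """

    pixels: np.ndarray
    frame_index: int = 0
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Frame.pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame.pixels must be finite")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("Frame.pixels must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(
        cls, arr: np.ndarray, frame_index: int = 0, time_min: float = 0.0
    ) -> "Frame":
        """Build a frame from a raw image array.

        Integer arrays are rescaled by their dtype range; RGB(A) input is
        converted to grayscale with Rec.601 luma weights.
        """
        arr = np.asarray(arr)
        if arr.ndim == 3:
            arr = arr[..., :3] @ _LUMA if arr.shape[-1] >= 3 else arr[..., 0]
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        arr = np.clip(arr.astype(float), 0.0, 1.0)
        return cls(arr, frame_index=frame_index, time_min=time_min)


@dataclass
class WellDetection:
    """One detected microwell: sub-pixel center, radius and accumulator strength."""

    center: tuple[float, float]  # (x, y) sub-pixel
    radius: float
    strength: float

    @property
    def cx(self) -> float:
        return self.center[0]

    @property
    def cy(self) -> float:
        return self.center[1]


def roberts_gradient(frame: Frame | np.ndarray) -> np.ndarray:
    """Un-normalised Roberts gradient magnitude.

    Gx(r, c) = I(r, c) - I(r+1, c+1) and Gy(r, c) = I(r+1, c) - I(r, c+1).
    Out-of-range samples in the last row/column are edge-replicated so a flat
    field maps to an all-zero gradient; the choice only affects the outermost
    row/column, far outside any accepted well.
    """
    img = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, float)
    padded = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    gx = padded[:-1, :-1] - padded[1:, 1:]
    gy = padded[1:, :-1] - padded[:-1, 1:]
    return np.hypot(gx, gy)


def threshold_gradient(gradient: np.ndarray, tau: float = 0.015) -> np.ndarray:
    """Binary edge map: true where gradient strictly exceeds ``tau``."""
    if tau < 0:
        raise ConfigurationError("gradient threshold must be >= 0")
    return np.asarray(gradient) > tau


def _ring_kernel(radius: float) -> np.ndarray:
    """Annulus of unit width at the given radius, used as a voting kernel."""
    r_out = int(np.ceil(radius + 0.5))
    yy, xx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
    dist = np.hypot(yy, xx)
    return (np.abs(dist - radius) <= 0.5).astype(float)


def detect_circles(
    edges: np.ndarray,
    r_min: float,
    r_max: float,
    sensitivity: float = 0.975,
    edge_threshold: float = 0.030,
) -> list[WellDetection]:
    """Two-stage circular Hough transform on a (binary or graded) edge map.

    Stage one accumulates center votes from edge pixels over the whole radius
    range; peaks whose summed support exceeds ``(1 - sensitivity)`` times the
    accumulator maximum are accepted.  Stage two assigns each center the
    radius maximising the per-radius edge support.  Detections are returned
    sorted by descending strength.
    """
    if r_min > r_max:
        raise ConfigurationError(f"r_min ({r_min}) > r_max ({r_max})")
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.isfinite(edges)):
        raise ValueError("edge map must be finite")
    edge_mask = (edges > edge_threshold).astype(float)
    if not edge_mask.any():
        return []

    radii = np.arange(int(np.floor(r_min)), int(np.ceil(r_max)) + 1)
    # per-radius support normalised by circumference -> comparable across radii
    support = np.empty((len(radii), *edge_mask.shape))
    for i, r in enumerate(radii):
        kern = _ring_kernel(r)
        conv = fftconvolve(edge_mask, kern, mode="same")
        support[i] = conv / kern.sum()
    acc = support.mean(axis=0)
    acc_smooth = ndimage.gaussian_filter(acc, sigma=2.0)

    peak_thresh = max((1.0 - sensitivity) * acc_smooth.max(), 1e-9)
    min_dist = max(8, int(round(0.5 * r_min)))
    local_max = acc_smooth == ndimage.maximum_filter(
        acc_smooth, size=2 * min_dist + 1, mode="constant"
    )
    peaks = np.argwhere(local_max & (acc_smooth > peak_thresh))

    detections: list[WellDetection] = []
    h, w = edge_mask.shape
    for row, col in peaks:
        # sub-pixel center: accumulator center-of-mass in a 5x5 window
        r0, r1 = max(row - 2, 0), min(row + 3, h)
        c0, c1 = max(col - 2, 0), min(col + 3, w)
        win = acc_smooth[r0:r1, c0:c1]
        tot = win.sum()
        if tot <= 0:
            cy, cx = float(row), float(col)
        else:
            ys, xs = np.mgrid[r0:r1, c0:c1]
            cy = float((ys * win).sum() / tot)
            cx = float((xs * win).sum() / tot)
        # stage two: radius with maximal support at the (integer) peak
        prof = support[:, row, col]
        best = int(np.argmax(prof))
        radius = float(radii[best])
        # parabolic sub-pixel refinement of the radius profile
        if 0 < best < len(radii) - 1:
            denom = prof[best - 1] - 2 * prof[best] + prof[best + 1]
            if denom < 0:
                radius += float(0.5 * (prof[best - 1] - prof[best + 1]) / denom)
        radius = float(np.clip(radius, r_min, r_max))
        strength = float(prof[best])
        if strength > 0:
            detections.append(WellDetection((cx, cy), radius, strength))

    detections.sort(key=lambda d: (-d.strength, d.cy, d.cx))
    return detections


def _filter_once(
    detections: list[WellDetection],
    frame_shape: tuple[int, int],
    pitch: float,
    strength_fraction: float,
) -> list[WellDetection]:
    kept = list(detections)
    # (a) relative circle strength, iterated to a fixpoint so the operation
    # is idempotent (the median shifts when weak detections are removed)
    while kept:
        med = float(np.median([d.strength for d in kept]))
        survivors = [d for d in kept if d.strength >= strength_fraction * med]
        if len(survivors) == len(kept):
            break
        kept = survivors
    # (b) spacing: greedy strongest-first suppression below 0.8 x pitch
    kept.sort(key=lambda d: (-d.strength, d.cy, d.cx))
    spaced: list[WellDetection] = []
    min_sep = 0.8 * pitch
    for d in kept:
        if all(np.hypot(d.cx - k.cx, d.cy - k.cy) >= min_sep for k in spaced):
            spaced.append(d)
    # (c) only wells completely inside the field of view
    h, w = frame_shape[:2]
    return [
        d
        for d in spaced
        if min(d.cx, d.cy, (w - 1) - d.cx, (h - 1) - d.cy) >= d.radius
    ]


def filter_detections(
    detections: list[WellDetection],
    frame_shape: tuple[int, int],
    pitch: float = 225.0,
    strength_fraction: float = 0.5,
) -> list[WellDetection]:
    """Remove false positives by relative circle strength and well spacing,
    then drop wells not completely inside the field of view.

    The whole criterion chain is iterated until stable, making the filter
    idempotent.
    """
    if pitch <= 0:
        raise ConfigurationError("pitch must be positive")
    if not 0 < strength_fraction <= 1:
        raise ConfigurationError("strength_fraction must be in (0, 1]")
    kept = list(detections)
    while True:
        nxt = _filter_once(kept, frame_shape, pitch, strength_fraction)
        if len(nxt) == len(kept):
            return nxt
        kept = nxt


def detect_wells(frame: Frame, params: DetectionParams | None = None) -> list[WellDetection]:
    """Full detection chain for one frame: gradient, threshold, Hough, filter."""
    params = params or DetectionParams()
    params.validate()
    grad = roberts_gradient(frame)
    edges = threshold_gradient(grad, params.gradient_threshold)
    raw = detect_circles(
        edges, params.r_min, params.r_max, params.sensitivity, params.edge_threshold
    )
    return filter_detections(
        raw, frame.shape, params.pitch_px, params.strength_fraction
    )
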