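"""Per-well spheroid segmentation.

Chain: circular inner-disk mask, adaptive Otsu threshold on the in-well
intensities, fixed threshold on the gradient image, OR-combination, AND with
the well mask, then a four-step morphological cleanup (keep-largest with
small-object retention, bridge + diagonal fill, bounded hole fill with
opening, second bridge/diagonal fill and final hole fill).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .config import SegmentationParams
from .well_detect import Frame, WellDetection

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)

# 8-neighbour offsets in bit order used by the bridge lookup table
_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SpheroidMask:
    """Binary foreground mask of one well, stored as a local crop.

    ``offset`` is the (row, col) of the crop's top-left pixel in full-frame
    coordinates, so full-frame positions are exact.
    """

    pixels: np.ndarray
    offset: tuple[int, int] = (0, 0)
    well_id: int = -1
    frame_index: int = 0
    empty_flag: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not self.pixels.any():
            self.empty_flag = True

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def to_frame(self, shape: tuple[int, int]) -> np.ndarray:
        """Paste the crop into a full-frame boolean array."""
        full = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.pixels.shape
        full[r0 : r0 + h, c0 : c0 + w] = self.pixels
        return full


def crop_bounds(
    center: tuple[float, float], radius: float, shape: tuple[int, int], pad: int = 2
) -> tuple[int, int, int, int]:
    """(r0, r1, c0, c1) of the square working crop around a well center,
    clipped to the frame.  Side is 2*ceil(radius) + 2*pad + 1."""
    cx, cy = center
    half = int(np.ceil(radius)) + pad
    r0 = max(int(round(cy)) - half, 0)
    r1 = min(int(round(cy)) + half + 1, shape[0])
    c0 = max(int(round(cx)) - half, 0)
    c1 = min(int(round(cx)) + half + 1, shape[1])
    return r0, r1, c0, c1


def well_mask(
    center: tuple[float, float], inner_radius: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean disk: true iff (x - cx)^2 + (y - cy)^2 <= inner_radius^2."""
    if inner_radius <= 0:
        raise ValueError("inner_radius must be positive")
    cx, cy = center
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= inner_radius**2


class OtsuResult(NamedTuple):
    threshold: float
    degenerate: bool


def otsu_threshold(intensities: np.ndarray, bins: int = 256) -> OtsuResult:
    """Otsu threshold of a value collection via between-class variance.

    The histogram spans the data range with ``bins`` bins; ties are broken
    toward the lowest maximizing bin and the returned threshold is that bin's
    center.  A constant input is degenerate and returns the constant.
    """
    vals = np.asarray(intensities, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("otsu_threshold requires a non-empty collection")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return OtsuResult(lo, True)
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)
    k = int(np.argmax(sigma_b))  # argmax returns the lowest maximizing bin
    return OtsuResult(float(centers[k]), False)


# ---------------------------------------------------------------------------
# morphological primitives
# ---------------------------------------------------------------------------


def _build_bridge_lut() -> np.ndarray:
    """For each 8-neighbour bit pattern: 1 if the foreground neighbours form
    two or more mutually 8-disconnected groups (center excluded)."""
    lut = np.zeros(256, dtype=bool)
    # adjacency between the 8 neighbour positions (Chebyshev distance <= 1,
    # never through the excluded center)
    adj = [
        [
            j
            for j in range(8)
            if j != i
            and max(
                abs(_NEIGHBOURS[i][0] - _NEIGHBOURS[j][0]),
                abs(_NEIGHBOURS[i][1] - _NEIGHBOURS[j][1]),
            )
            <= 1
        ]
        for i in range(8)
    ]
    for pattern in range(256):
        on = [i for i in range(8) if pattern >> i & 1]
        if len(on) < 2:
            continue
        seen: set[int] = set()
        comps = 0
        for i in on:
            if i in seen:
                continue
            comps += 1
            stack = [i]
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                stack.extend(j for j in adj[k] if pattern >> j & 1 and j not in seen)
        lut[pattern] = comps >= 2
    return lut


_BRIDGE_LUT = _build_bridge_lut()
_BIT_KERNEL = np.zeros((3, 3), dtype=int)
for _i, (_dr, _dc) in enumerate(_NEIGHBOURS):
    _BIT_KERNEL[1 + _dr, 1 + _dc] = 1 << _i


def bridge_pixels(mask: np.ndarray) -> np.ndarray:
    """Bridge unconnected pixels: a background pixel becomes foreground iff
    its 8-neighbourhood holds >= 2 foreground pixels that are not 8-connected
    to each other within that neighbourhood.  Single simultaneous pass."""
    mask = np.asarray(mask, dtype=bool)
    pattern = ndimage.correlate(
        mask.astype(int), _BIT_KERNEL, mode="constant", cval=0
    )
    return mask | (~mask & _BRIDGE_LUT[pattern])


def diagonal_fill(mask: np.ndarray) -> np.ndarray:
    """Fill diagonal-only 2x2 blocks: where the foreground of a 2x2 block is
    exactly one diagonal pair, both background pixels of the block are set.
    Single simultaneous pass."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    a = mask[:-1, :-1]
    b = mask[:-1, 1:]
    c = mask[1:, :-1]
    d = mask[1:, 1:]
    main_diag = a & d & ~b & ~c
    anti_diag = b & c & ~a & ~d
    out[:-1, 1:] |= main_diag
    out[1:, :-1] |= main_diag
    out[:-1, :-1] |= anti_diag
    out[1:, 1:] |= anti_diag
    return out


def fill_holes(mask: np.ndarray, max_area: int | None = None) -> np.ndarray:
    """Fill interior holes (4-connected background components not touching
    the border) with area <= ``max_area``; all of them when ``max_area`` is
    None."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(~mask, structure=_STRUCT4)
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = np.unique(labels[border & ~mask])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        if max_area is None or counts[lab] <= max_area:
            fill[lab] = True
    return mask | fill[labels]


def disk_element(radius: int) -> np.ndarray:
    """Disk structuring element {(dx, dy): dx^2 + dy^2 <= radius^2}."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return xx**2 + yy**2 <= radius**2


def erode(mask: np.ndarray, disk_r: int) -> np.ndarray:
    """Minkowski erosion with a disk element (outside the grid is background)."""
    return ndimage.binary_erosion(
        np.asarray(mask, bool), structure=disk_element(disk_r), border_value=0
    )


def dilate(mask: np.ndarray, disk_r: int) -> np.ndarray:
    """Minkowski dilation with a disk element."""
    return ndimage.binary_dilation(
        np.asarray(mask, bool), structure=disk_element(disk_r), border_value=0
    )


def largest_component(mask: np.ndarray) -> np.ndarray:
    """The largest 8-connected component; ties broken by the lowest
    (row, col) first pixel of the component."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda lab: int(np.argmax(flat == lab)))
    return labels == keep


def morph_cleanup(
    mask: np.ndarray,
    small_keep: int = 25,
    hole_fill: int = 150,
    disk_r: int = 2,
) -> np.ndarray:
    """Four-step cleanup producing a single hole-free object (or nothing).

    (i) keep the largest object plus every object with area <= ``small_keep``;
    (ii) bridge, then diagonal fill;
    (iii) fill holes <= ``hole_fill``, erode with a disk of radius ``disk_r``,
    keep the largest object, dilate with the same disk;
    (iv) bridge and diagonal fill a second time, then fill the remaining holes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    # (i)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = largest_component(mask)
    small = (counts[labels] <= small_keep) & mask
    step1 = largest | small
    # (ii)
    step2 = diagonal_fill(bridge_pixels(step1))
    # (iii)
    step3 = fill_holes(step2, hole_fill)
    step3 = erode(step3, disk_r)
    if not step3.any():
        return step3
    step3 = dilate(largest_component(step3), disk_r)
    # (iv)
    step4 = diagonal_fill(bridge_pixels(step3))
    return fill_holes(step4, None)


# ---------------------------------------------------------------------------
# per-well segmentation
# ---------------------------------------------------------------------------


def segment_spheroid(
    frame: Frame,
    gradient: np.ndarray,
    well: WellDetection,
    params: SegmentationParams | None = None,
    well_id: int = -1,
) -> SpheroidMask:
    """Segment the spheroid inside one detected well.

    Works on a square crop of side 2*inner_radius + 5 around the well center;
    the crop offset is recorded so full-frame coordinates stay exact.  The
    result is confined to the well's inner disk and holds at most one
    8-connected component.
    """
    params = params or SegmentationParams()
    params.validate()
    img = frame.pixels
    gradient = np.asarray(gradient, dtype=float)
    if gradient.shape != img.shape:
        raise ValueError("gradient must match the frame shape")
    cx, cy = well.center
    rad = params.inner_radius_px
    r0, r1, c0, c1 = crop_bounds(well.center, rad, img.shape)
    crop = img[r0:r1, c0:c1]
    grad_crop = gradient[r0:r1, c0:c1]
    disk = well_mask((cx - c0, cy - r0), rad, crop.shape)

    in_well = crop[disk]
    if in_well.size == 0:
        return SpheroidMask(
            np.zeros(crop.shape, bool), (r0, c0), well_id, frame.frame_index, True
        )
    otsu = otsu_threshold(in_well, params.otsu_bins)
    if params.polarity == "dark":
        intensity_fg = crop < otsu.threshold
    else:
        intensity_fg = crop > otsu.threshold
    # degenerate-threshold guard: in a cell-free well Otsu merely splits the
    # noise; require a minimum separation between the two class means
    lo_cls = in_well[in_well < otsu.threshold]
    hi_cls = in_well[in_well >= otsu.threshold]
    degenerate = (
        otsu.degenerate
        or lo_cls.size == 0
        or hi_cls.size == 0
        or float(hi_cls.mean() - lo_cls.mean()) < params.min_contrast
    )
    if degenerate:
        intensity_fg = np.zeros_like(intensity_fg)
    grad_fg = grad_crop > params.gradient_threshold
    combined = (intensity_fg | grad_fg) & disk
    cleaned = morph_cleanup(
        combined, params.small_keep, params.hole_fill, params.disk_r
    )
    # bridge/dilate in the cleanup may push single pixels past the disk rim;
    # re-clip and re-select so the containment and single-object contracts hold
    cleaned &= disk
    if cleaned.any():
        cleaned = fill_holes(largest_component(cleaned), None)
    return SpheroidMask(
        cleaned, (r0, c0), well_id, frame.frame_index, not cleaned.any()
    )
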