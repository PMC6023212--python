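"""Morphological descriptors of a spheroid mask.

Definitions are fixed here so results are environment independent: axis
lengths come from the ellipse with the same normalized second central moments
(including the +1/12 per-pixel variance term), circularity is
4*pi*area/perimeter^2, roundness is 4*area/(pi*major_axis^2) and the
perimeter is a weighted boundary-chain length (orthogonal steps 1, diagonal
steps sqrt(2), +1 per 180-degree chain reversal; an isolated pixel counts 4
by the unit-square convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .segment import SpheroidMask

_STRUCT8 = np.ones((3, 3), dtype=bool)

# clockwise Moore neighbourhood, starting west (row, col offsets)
_CW = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass
class FeatureRecord:
    area_px: float = math.nan
    perimeter_px: float = math.nan
    minor_axis_px: float = math.nan
    major_axis_px: float = math.nan
    roundness: float = math.nan
    circularity: float = math.nan
    centroid: tuple[float, float] = (math.nan, math.nan)  # (x, y)
    equivalent_diameter_px: float = math.nan
    eccentricity: float = math.nan
    solidity: float = math.nan
    empty_flag: bool = False
    pixel_size_um: float = 1.333

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def perimeter_um(self) -> float:
        return self.perimeter_px * self.pixel_size_um

    def as_dict(self) -> dict:
        return {
            "area_px": self.area_px,
            "area_um2": self.area_um2,
            "perimeter_px": self.perimeter_px,
            "perimeter_um": self.perimeter_um,
            "minor_px": self.minor_axis_px,
            "major_px": self.major_axis_px,
            "roundness": self.roundness,
            "circularity": self.circularity,
            "cx": self.centroid[0],
            "cy": self.centroid[1],
            "eq_diam_px": self.equivalent_diameter_px,
            "eccentricity": self.eccentricity,
            "solidity": self.solidity,
            "empty_flag": self.empty_flag,
        }


def _trace_component(mask: np.ndarray, start: tuple[int, int]) -> float:
    """Chain length of one component's outer boundary via Moore tracing
    with Jacob's stopping criterion."""
    h, w = mask.shape

    def fg(q: tuple[int, int]) -> bool:
        return 0 <= q[0] < h and 0 <= q[1] < w and bool(mask[q])

    # start is the component's row-major first pixel, so its west neighbour
    # is guaranteed background and serves as the initial backtrack
    start_b = (start[0], start[1] - 1)
    p, b = start, start_b
    all_steps: list[tuple[int, int]] = []
    # the tracing map (pixel, backtrack) -> next state is deterministic, so
    # the walk enters a cycle; the closed boundary chain is that cycle (the
    # very first state can be a transient not on it)
    seen: dict[tuple, int] = {(p, b): 0}
    while True:
        bi = _CW.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            idx = (bi + k) % 8
            q = (p[0] + _CW[idx][0], p[1] + _CW[idx][1])
            if fg(q):
                prev = (bi + k - 1) % 8
                nxt = q
                new_b = (p[0] + _CW[prev][0], p[1] + _CW[prev][1])
                break
        if nxt is None:  # isolated pixel
            return 4.0
        all_steps.append((nxt[0] - p[0], nxt[1] - p[1]))
        p, b = nxt, new_b
        state = (p, b)
        if state in seen:
            steps = all_steps[seen[state] :]
            break
        seen[state] = len(all_steps)
    length = 0.0
    for dr, dc in steps:
        length += math.sqrt(2.0) if dr != 0 and dc != 0 else 1.0
    # cap correction: +1 per 180-degree reversal, cyclically
    for i in range(len(steps)):
        dr0, dc0 = steps[i]
        dr1, dc1 = steps[(i + 1) % len(steps)]
        if dr0 == -dr1 and dc0 == -dc1:
            length += 1.0
    return length


def perimeter_length(mask: np.ndarray | SpheroidMask) -> float:
    """Weighted boundary-chain length of the mask's outer boundary.

    Orthogonal steps count 1, diagonal steps sqrt(2); each 180-degree chain
    reversal adds 1 (unit-square caps); an isolated pixel has perimeter 4 and
    the empty mask 0.  Components are summed; interior hole boundaries are
    not counted (final masks are hole-free by contract).
    """
    if isinstance(mask, SpheroidMask):
        mask = mask.pixels
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    total = 0.0
    for lab in range(1, n + 1):
        comp = labels == lab
        flat = int(np.argmax(comp))
        start = (flat // mask.shape[1], flat % mask.shape[1])
        total += _trace_component(comp, start)
    return total


def _convex_area(rows: np.ndarray, cols: np.ndarray) -> float:
    """Pixel count of the filled convex hull of the pixel centers."""
    pts = np.column_stack([cols, rows]).astype(float)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return float(len(uniq))
    try:
        hull = ConvexHull(uniq)
    except QhullError:  # collinear points
        return float(len(uniq))
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    inside = np.ones(len(grid), dtype=bool)
    for a, b, c in hull.equations:
        inside &= grid @ np.array([a, b]) + c <= 1e-9
    return float(inside.sum())


def extract_features(
    mask: SpheroidMask | np.ndarray, pixel_size_um: float = 1.333
) -> FeatureRecord:
    """Compute the morphological descriptors of a (cleaned) spheroid mask.

    An empty mask yields a record with ``empty_flag`` set and NaN in every
    numeric field.  When a :class:`SpheroidMask` is given, the centroid is
    reported in full-frame coordinates via the crop offset.
    """
    offset = (0, 0)
    if isinstance(mask, SpheroidMask):
        offset = mask.offset
        mask = mask.pixels
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return FeatureRecord(empty_flag=True, pixel_size_um=pixel_size_um)

    rows, cols = np.nonzero(mask)
    area = float(len(rows))
    cy = float(rows.mean()) + offset[0]
    cx = float(cols.mean()) + offset[1]

    # normalized second central moments with the +1/12 per-pixel variance term
    r = rows - rows.mean()
    c = cols - cols.mean()
    mrr = float((r * r).mean()) + 1.0 / 12.0
    mcc = float((c * c).mean()) + 1.0 / 12.0
    mrc = float((r * c).mean())
    common = math.sqrt((mrr - mcc) ** 2 + 4.0 * mrc**2)
    lam1 = (mrr + mcc + common) / 2.0
    lam2 = (mrr + mcc - common) / 2.0
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    eccentricity = math.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0

    perim = perimeter_length(mask)
    circularity = 4.0 * math.pi * area / perim**2 if perim > 0 else math.nan
    roundness = 4.0 * area / (math.pi * major**2) if major > 0 else math.nan
    eq_diam = math.sqrt(4.0 * area / math.pi)
    solidity = area / _convex_area(rows, cols)

    return FeatureRecord(
        area_px=area,
        perimeter_px=perim,
        minor_axis_px=minor,
        major_axis_px=major,
        roundness=roundness,
        circularity=circularity,
        centroid=(cx, cy),
        equivalent_diameter_px=eq_diam,
        eccentricity=eccentricity,
        solidity=solidity,
        empty_flag=False,
        pixel_size_um=pixel_size_um,
    )
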