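"""Independent brute-force reference implementations used by the test suite.

Everything here is written as plain Python loops over pixels, sharing no code
with the package, so it can serve as an oracle for the vectorised
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def roberts_slow(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, float)
    h, w = img.shape
    out = np.zeros((h, w))

    def at(r, c):  # edge replication for out-of-range samples
        return img[min(r, h - 1), min(c, w - 1)]

    for r in range(h):
        for c in range(w):
            gx = at(r, c) - at(r + 1, c + 1)
            gy = at(r + 1, c) - at(r, c + 1)
            out[r, c] = math.hypot(gx, gy)
    return out


def otsu_slow(values, bins: int = 256) -> float:
    """Exhaustive between-class-variance search over a 256-bin histogram."""
    vals = np.asarray(values, float).ravel()
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        return float(lo)
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_var, best_k = -1.0, 0
    for k in range(bins - 1):
        n0 = hist[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:  # strict: lowest maximizing bin wins
            best_var, best_k = var, k
    return float(centers[best_k])


def _neighbour_groups(block: np.ndarray) -> int:
    """Number of mutually 8-disconnected foreground groups among the 8
    neighbours of the centre of a 3x3 block (centre excluded)."""
    cells = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1) and block[r, c]]
    groups = 0
    seen = set()
    for cell in cells:
        if cell in seen:
            continue
        groups += 1
        stack = [cell]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            for other in cells:
                if other not in seen and max(
                    abs(cur[0] - other[0]), abs(cur[1] - other[1])
                ) <= 1:
                    stack.append(other)
    return groups


def bridge_slow(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, bool)
    padded = np.pad(mask, 1)
    out = mask.copy()
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                continue
            block = padded[r : r + 3, c : c + 3]
            if _neighbour_groups(block) >= 2:
                out[r, c] = True
    return out


def diagonal_fill_slow(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, bool)
    out = mask.copy()
    h, w = mask.shape
    for r in range(h - 1):
        for c in range(w - 1):
            a, b = mask[r, c], mask[r, c + 1]
            d, e = mask[r + 1, c], mask[r + 1, c + 1]
            if a and e and not b and not d:
                out[r, c + 1] = out[r + 1, c] = True
            if b and d and not a and not e:
                out[r, c] = out[r + 1, c + 1] = True
    return out


def fill_holes_slow(mask: np.ndarray, max_area=None) -> np.ndarray:
    """Flood-fill based hole filling (4-connected background components)."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    out = mask.copy()
    visited = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if mask[r, c] or visited[r, c]:
                continue
            comp, stack, border = [], [(r, c)], False
            visited[r, c] = True
            while stack:
                cr, cc = stack.pop()
                comp.append((cr, cc))
                if cr in (0, h - 1) or cc in (0, w - 1):
                    border = True
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc] and not visited[nr, nc]:
                        visited[nr, nc] = True
                        stack.append((nr, nc))
            if not border and (max_area is None or len(comp) <= max_area):
                for cr, cc in comp:
                    out[cr, cc] = True
    return out


def _disk_offsets(radius: int):
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def erode_slow(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    offs = _disk_offsets(radius)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w and mask[nr, nc]):
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilate_slow(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    offs = _disk_offsets(radius)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w:
                    out[nr, nc] = True
    return out


def axes_slow(mask: np.ndarray) -> tuple[float, float]:
    """(major, minor) axis lengths from the pixel list: eigenvalues of the
    coordinate covariance with the +1/12 per-pixel variance correction."""
    rows, cols = np.nonzero(np.asarray(mask, bool))
    n = len(rows)
    rbar, cbar = rows.mean(), cols.mean()
    srr = sum((r - rbar) ** 2 for r in rows) / n + 1.0 / 12.0
    scc = sum((c - cbar) ** 2 for c in cols) / n + 1.0 / 12.0
    src = sum((r - rbar) * (c - cbar) for r, c in zip(rows, cols)) / n
    disc = math.sqrt((srr - scc) ** 2 + 4 * src * src)
    lam1 = (srr + scc + disc) / 2
    lam2 = (srr + scc - disc) / 2
    return 4 * math.sqrt(lam1), 4 * math.sqrt(lam2)


_CCW8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def perimeter_slow(mask: np.ndarray) -> float:
    """Boundary chain length via an independently written Moore walk:
    orthogonal 1, diagonal sqrt(2), +1 per 180-degree reversal (cyclic);
    isolated pixel 4; summed over 8-connected components."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    if not mask.any():
        return 0.0

    # label components with simple flood fill (8-connectivity)
    labels = np.zeros((h, w), int)
    nlab = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                nlab += 1
                stack = [(r, c)]
                labels[r, c] = nlab
                while stack:
                    cr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = cr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                                labels[nr, nc] = nlab
                                stack.append((nr, nc))

    total = 0.0
    for lab in range(1, nlab + 1):
        comp = labels == lab
        pts = list(zip(*np.nonzero(comp)))
        if len(pts) == 1:
            total += 4.0
            continue
        total += _chain_length_cyclic(comp, min(pts))
    return total


def _chain_length_cyclic(comp: np.ndarray, start) -> float:
    """State-repeat version identical in spirit to perimeter_slow's walk but
    robust: follows (pixel, incoming-direction) states until a repeat, then
    measures the cycle."""
    h, w = comp.shape

    def fg(q):
        return 0 <= q[0] < h and 0 <= q[1] < w and comp[q]

    state = (start, None)
    seen = {}
    steps = []
    idx = 0
    while state not in seen:
        seen[state] = idx
        p, d_in = state
        base = 6 if d_in is None else (d_in + 6) % 8
        nxt = None
        for k in range(8):
            nd = (base + k) % 8
            q = (p[0] + _CCW8[nd][0], p[1] + _CCW8[nd][1])
            if fg(q):
                nxt = (q, nd)
                break
        if nxt is None:
            return 4.0
        steps.append(nxt[1])
        state = nxt
        idx += 1
    cycle = steps[seen[state] :]
    length = 0.0
    for d in cycle:
        dr, dc = _CCW8[d]
        length += math.sqrt(2) if dr and dc else 1.0
    m = len(cycle)
    for i in range(m):
        if (cycle[i] + 4) % 8 == cycle[(i + 1) % m]:
            length += 1.0
    return length


def random_blob(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random single-component, hole-free test mask built from smoothed
    noise (independent of the package's generators)."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.standard_normal((size, size)), 4.0)
    mask = field > np.quantile(field, 0.75)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        mask = np.zeros((size, size), bool)
        mask[size // 2, size // 2] = True
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    return ndi.binary_fill_holes(mask)
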