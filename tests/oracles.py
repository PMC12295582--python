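"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, flood fill, all-pairs half-plane
tests, exact integer arithmetic) so they share no code path with the
package; the frame-removal pipeline is checked against these
pixel-exactly.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bf_whites_to_black(image: np.ndarray, wth: float) -> np.ndarray:
    out = image.copy()
    h, w, _ = image.shape
    for i in range(h):
        for j in range(w):
            if int(image[i, j, 0]) + int(image[i, j, 1]) + int(image[i, j, 2]) >= 3 * 256 * wth:
                out[i, j] = (0, 0, 0)
    return out


def bf_grayscale_max(image: np.ndarray) -> np.ndarray:
    h, w, _ = image.shape
    out = np.zeros((h, w), dtype=image.dtype)
    for i in range(h):
        for j in range(w):
            out[i, j] = max(image[i, j, 0], image[i, j, 1], image[i, j, 2])
    return out


def bf_normalize(gray: np.ndarray) -> np.ndarray:
    lo = float(gray.min())
    hi = float(gray.max())
    if hi == lo:
        return np.zeros(gray.shape, dtype=float)
    return (gray.astype(float) - lo) / (hi - lo)


def bf_binarize(normed: np.ndarray, bth: float) -> np.ndarray:
    return np.array([[v >= bth for v in row] for row in normed], dtype=bool)


def bf_remove_small_objects(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Flood-fill 8-connected labelling, then drop components below min_area."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    out = mask.copy()
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = []
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    r, c = queue.popleft()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                if len(comp) < min_area:
                    for r, c in comp:
                        out[r, c] = False
    return out


def bf_remove_small_holes(mask: np.ndarray, min_area: int) -> np.ndarray:
    return ~bf_remove_small_objects(~mask, min_area)


def bf_convex_hull(mask: np.ndarray) -> np.ndarray:
    """All-pairs half-plane hull of the foreground pixel centers (exact ints)."""
    pts = [tuple(p) for p in np.argwhere(mask)]
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    if not pts:
        return out
    if len(pts) == 1:
        out[pts[0]] = True
        return out

    arr = np.array(pts, dtype=np.int64)
    # collinearity check against the first two distinct points
    a0, d0 = arr[0], None
    for p in arr[1:]:
        if not np.array_equal(p, a0):
            d0 = p - a0
            break
    collinear = all((d0[0] * (p[1] - a0[1]) - d0[1] * (p[0] - a0[0])) == 0 for p in arr)
    if collinear:
        ts = [int(d0 @ (p - a0)) for p in arr]
        tmin, tmax = min(ts), max(ts)
        for i in range(h):
            for j in range(w):
                v = np.array([i, j]) - a0
                if d0[0] * v[1] - d0[1] * v[0] == 0 and tmin <= int(d0 @ v) <= tmax:
                    out[i, j] = True
        return out

    # supporting half-planes: ordered pairs (a, b) with every point on the left
    edges = []
    n = len(arr)
    for ia in range(n):
        for ib in range(n):
            if ia == ib:
                continue
            a, b = arr[ia], arr[ib]
            crosses = (b[0] - a[0]) * (arr[:, 1] - a[1]) - (b[1] - a[1]) * (arr[:, 0] - a[0])
            if (crosses >= 0).all():
                edges.append((a, b))
    for i in range(h):
        for j in range(w):
            inside = True
            for a, b in edges:
                if (b[0] - a[0]) * (j - a[1]) - (b[1] - a[1]) * (i - a[0]) < 0:
                    inside = False
                    break
            out[i, j] = inside
    return out


def bf_kendall_tau(a: np.ndarray, d: np.ndarray) -> float:
    k = len(a)
    total = 0
    for i in range(k):
        for j in range(i + 1, k):
            total += 1 if (a[i] - a[j]) * (d[i] - d[j]) > 0 else -1
    return total / (k * (k - 1) / 2)


def bf_spearman_rho(a: np.ndarray, d: np.ndarray) -> float:
    k = len(a)
    s = sum((int(ai) - int(di)) ** 2 for ai, di in zip(a, d))
    return 1.0 - 6.0 * s / (k * (k * k - 1))


def bf_ndcg(gold_scores_by_item: dict, detected_items, actual_items) -> float:
    dcg = 0.0
    idcg = 0.0
    for i, item in enumerate(detected_items, start=1):
        dcg += (2.0 ** gold_scores_by_item[item] - 1.0) / np.log2(i + 1)
    for i, item in enumerate(actual_items, start=1):
        idcg += (2.0 ** gold_scores_by_item[item] - 1.0) / np.log2(i + 1)
    return dcg / idcg
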