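"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: labeling is checked
against a breadth-first flood fill, boundary tracing against a direct
neighbor-scan characterization of the outer contour, and NTC fitting
against an exhaustive scan over all candidate threshold triples.
"""

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected components by repeated BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                q = deque([(r0, c0)])
                labels[r0, c0] = nxt
                while q:
                    r, c = q.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and labels[rr, cc] == 0):
                            labels[rr, cc] = nxt
                            q.append((rr, cc))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label images induce the same partition of the foreground."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or ((a > 0) != (b > 0)).any():
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return (len(pairs) == len({p[0] for p in pairs})
            and len(pairs) == len({p[1] for p in pairs}))


def outer_edge_set(region: np.ndarray) -> set[tuple[int, int]]:
    """Outer-contour pixels of one region, by direct definition.

    The exterior is the border-connected component of the 4-connected
    background; the outer contour is every foreground pixel 4-adjacent to
    it (off-image counts as exterior).  Returned as a set of (x, y).
    """
    region = np.asarray(region, dtype=bool)
    h, w = region.shape
    ext = np.zeros((h + 2, w + 2), dtype=bool)
    bg = np.pad(~region, 1, constant_values=True)
    q = deque([(0, 0)])
    ext[0, 0] = True
    while q:
        r, c = q.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h + 2 and 0 <= cc < w + 2 and bg[rr, cc] and not ext[rr, cc]:
                ext[rr, cc] = True
                q.append((rr, cc))
    edge = set()
    for r in range(h):
        for c in range(w):
            if region[r, c]:
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    if ext[r + 1 + dr, c + 1 + dc]:
                        edge.add((c, r))
                        break
    return edge


def ntc_min_errors_exhaustive(s: np.ndarray, y: np.ndarray) -> int:
    """Minimum training misclassifications over every threshold triple.

    Candidates are all cut positions in the descending-sorted values
    (equivalently: midpoints of adjacent sorted values plus sentinels
    beyond the extremes).  Checks all c1 <= c2 <= c3 by brute force.
    """
    order = np.argsort(-np.asarray(s, dtype=float), kind="stable")
    yy = np.asarray(y, dtype=int)[order]
    n = len(yy)
    # correct-prediction counts per class for every prefix length
    p = np.zeros((5, n + 1), dtype=int)
    for k in (1, 2, 3, 4):
        p[k, 1:] = np.cumsum(yy == k)
    best = -1
    for c1 in range(n + 1):
        for c2 in range(c1, n + 1):
            for c3 in range(c2, n + 1):
                correct = (p[1, c1] + (p[2, c2] - p[2, c1])
                           + (p[3, c3] - p[3, c2]) + (p[4, n] - p[4, c3]))
                if correct > best:
                    best = correct
    return n - best


def rasterize_truth(truth, shape: tuple[int, int]) -> np.ndarray:
    """Independently rasterize a ground-truth table to a boolean mask."""
    from skimage.draw import ellipse

    mask = np.zeros(shape, dtype=bool)
    for rec in truth:
        rr, cc = ellipse(rec.cy, rec.cx, rec.ry, rec.rx,
                         rotation=np.deg2rad(rec.angle_deg), shape=shape)
        mask[rr, cc] = True
    return mask
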