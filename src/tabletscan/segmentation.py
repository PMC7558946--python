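"""Locate tablets in a sheet: binarize, label, trace boundaries, crop.

The segmentation contract mirrors the classic binary-image toolchain:
threshold to a foreground mask, label connected components, trace each
component's outer boundary by Moore-neighbor tracing with Jacob's stopping
criterion, filter out debris and border-touching objects, and emit one
rectangular RGB crop per surviving region.  Only outer boundaries are
traced; holes inside a tablet are neither filled nor re-labelled.

Coordinates are pixel units, origin top-left, x rightward, y downward,
0-based; bounding boxes ``(x_min, y_min, x_max, y_max)`` are inclusive at
both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core import SheetImage, TabletImage

__all__ = [
    "TabletRegion",
    "binarize",
    "label_components",
    "trace_boundary",
    "extract_regions",
    "filter_regions",
    "crop_tablets",
    "segment_sheet",
    "default_min_area",
    "write_regions_csv",
    "write_crops",
]

# BT.601 luma weights; rounded half-up to an integer intensity.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class TabletRegion:
    """One segmented connected component.

    ``boundary`` is the ordered outer boundary walk as an (N, 2) array of
    (x, y) pixel coordinates; consecutive pixels (cyclically) are
    8-adjacent.  ``pixel_count`` is the region area in pixels, ``bbox`` the
    tight inclusive bounding box, ``centroid`` the unweighted mean pixel
    position (x, y).
    """

    region_id: int
    boundary: np.ndarray
    pixel_count: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    sheet_id: str = ""


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Integer luminance image: round(0.299 R + 0.587 G + 0.114 B)."""
    return np.floor(pixels[..., 0] * _LUMA[0] + pixels[..., 1] * _LUMA[1]
                    + pixels[..., 2] * _LUMA[2] + 0.5).astype(np.uint8)


def binarize(
    sheet: SheetImage | np.ndarray,
    method: str = "otsu_luminance",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a sheet to a boolean foreground (tablet) mask.

    The threshold is applied to integer luminance.  Whichever side of the
    threshold covers less than half the sheet is taken as foreground —
    tablets are sparser than background regardless of whether the scan is
    light-on-dark or dark-on-light.  A constant sheet yields an empty mask.
    """
    pixels = sheet.pixels if isinstance(sheet, SheetImage) else np.asarray(sheet)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
        raise ValueError("binarize expects an 8-bit RGB sheet")
    lum = luminance(pixels)
    if method == "otsu_luminance":
        if int(lum.min()) == int(lum.max()):
            return np.zeros(lum.shape, dtype=bool)
        thr = float(threshold_otsu(lum))
    elif method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    above = lum > thr
    frac_above = above.mean()
    mask = above if frac_above <= 0.5 else ~above
    return mask


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected foreground components, ids dense from 1.

    Two foreground pixels share an id iff they are connected under the
    chosen adjacency (4 = edge neighbors, 8 = edge + diagonal).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndi.label(mask, structure=structure)
    return labels


# Moore neighborhood in clockwise order (dy, dx) starting from West, for an
# image with y increasing downward: W, NW, N, NE, E, SE, S, SW.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(labels: np.ndarray, region_id: int = 1) -> np.ndarray:
    """Trace the outer boundary of one region by Moore-neighbor tracing.

    Starts at the topmost-leftmost region pixel (entered from the West) and
    walks the Moore neighborhood clockwise.  Termination generalizes
    Jacob's stopping criterion — re-entering the start pixel from the
    original direction — to a repeat of any (pixel, entry-direction)
    state, which provably terminates and stays correct on the rare spur
    shapes where the start state itself is never revisited.  Returns an
    (N, 2) array of (x, y) coordinates forming a closed walk: consecutive
    pixels, including last-to-first, are 8-adjacent.  A single-pixel
    region yields a length-1 boundary.
    """
    labels = np.asarray(labels)
    if labels.dtype == bool:
        region = labels
        if region_id != 1:
            raise KeyError(f"boolean mask has only region 1, got {region_id}")
    else:
        region = labels == region_id
    if not region.any():
        raise KeyError(f"region_id {region_id} not present")

    rows, cols = np.nonzero(region)
    start = (int(rows[0]), int(cols[0]))  # row-major scan: topmost, then leftmost
    h, w = region.shape

    def fg(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < h and 0 <= c < w and region[r, c]

    # Entered the start pixel from the West (its West neighbor cannot be
    # foreground by choice of start).
    walk = [start]
    current = start
    backtrack_dir = 0  # index into _MOORE pointing at the previous (background) pixel
    seen = {(start, backtrack_dir): 0}

    cycle_start = 0
    while True:
        found = False
        for k in range(1, 9):
            d = (backtrack_dir + k) % 8
            nb = (current[0] + _MOORE[d][0], current[1] + _MOORE[d][1])
            if fg(nb):
                # New backtrack: the neighbor checked just before nb, seen
                # from nb's frame.
                prev_d = (backtrack_dir + k - 1) % 8
                prev = (current[0] + _MOORE[prev_d][0], current[1] + _MOORE[prev_d][1])
                dr, dc = prev[0] - nb[0], prev[1] - nb[1]
                backtrack_dir = _MOORE.index((dr, dc))
                current = nb
                found = True
                break
        if not found:
            break  # isolated pixel
        state = (current, backtrack_dir)
        if state in seen:
            cycle_start = seen[state]
            break
        seen[state] = len(walk)
        walk.append(current)
    boundary = walk[cycle_start:]
    arr = np.array([(c, r) for r, c in boundary], dtype=int)
    return arr


def extract_regions(labels: np.ndarray, sheet_id: str = "") -> list[TabletRegion]:
    """Build :class:`TabletRegion` records (with boundaries) from a label image."""
    labels = np.asarray(labels)
    n = int(labels.max())
    regions: list[TabletRegion] = []
    if n == 0:
        return regions
    slices = ndi.find_objects(labels)
    for rid in range(1, n + 1):
        sl = slices[rid - 1]
        if sl is None:
            continue
        sub = labels[sl] == rid
        rr, cc = np.nonzero(sub)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        bbox = (int(cc.min()), int(rr.min()), int(cc.max()), int(rr.max()))
        centroid = (float(cc.mean()), float(rr.mean()))
        boundary = trace_boundary(labels, rid)
        regions.append(
            TabletRegion(
                region_id=rid,
                boundary=boundary,
                pixel_count=int(sub.sum()),
                bbox=bbox,
                centroid=centroid,
                sheet_id=sheet_id,
            )
        )
    return regions


def default_min_area(radius_min: float) -> int:
    """Debris threshold: a quarter of the smallest configured tablet area."""
    return int(round(0.25 * np.pi * radius_min**2))


def filter_regions(
    regions: Sequence[TabletRegion],
    min_area: int,
    sheet_shape: tuple[int, int],
    border_policy: str = "drop",
) -> list[TabletRegion]:
    """Drop debris (area < min_area) and, optionally, border-touching regions.

    ``sheet_shape`` is (height, width).  ``border_policy='drop'`` removes
    any region whose bounding box touches the sheet edge (a partially
    scanned tablet); ``'keep'`` retains them.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if border_policy not in ("drop", "keep"):
        raise ValueError(f"unknown border_policy {border_policy!r}")
    h, w = sheet_shape
    out = []
    for r in regions:
        if r.pixel_count < min_area:
            continue
        if border_policy == "drop":
            x0, y0, x1, y1 = r.bbox
            if x0 == 0 or y0 == 0 or x1 == w - 1 or y1 == h - 1:
                continue
        out.append(r)
    return out


def crop_tablets(
    sheet: SheetImage,
    regions: Sequence[TabletRegion],
    padding: int = 0,
) -> list[TabletImage]:
    """Cut one rectangular RGB crop per region from the sheet.

    The bounding box is expanded by ``padding`` on all sides and clipped to
    the sheet; pixels inside the rectangle but outside the region (the
    corners around an ellipse) are retained as-is, matching a plain
    bounding-box crop of a traced object.
    """
    crops: list[TabletImage] = []
    for r in regions:
        x0, y0, x1, y1 = r.bbox
        x0 = max(0, x0 - padding)
        y0 = max(0, y0 - padding)
        x1 = min(sheet.width - 1, x1 + padding)
        y1 = min(sheet.height - 1, y1 + padding)
        crops.append(
            TabletImage(
                pixels=sheet.pixels[y0 : y1 + 1, x0 : x1 + 1].copy(),
                sheet_id=sheet.sheet_id,
                region_id=r.region_id,
                bbox=(x0, y0, x1, y1),
            )
        )
    return crops


def segment_sheet(
    sheet: SheetImage,
    min_area: int | None = None,
    border_policy: str = "drop",
    connectivity: int = 8,
    padding: int = 0,
    method: str = "otsu_luminance",
    threshold: float | None = None,
) -> tuple[list[TabletRegion], list[TabletImage], dict]:
    """Full per-sheet segmentation: binarize -> label -> trace -> filter -> crop.

    ``min_area`` defaults to a quarter of the area of a radius-10 disc when
    not given (callers that know their generator's radius should pass
    :func:`default_min_area` of it).  Returns the surviving regions, their
    crops, and a small bookkeeping dict including the number of rejected
    regions.
    """
    if min_area is None:
        min_area = default_min_area(10.0)
    mask = binarize(sheet, method=method, threshold=threshold)
    labels = label_components(mask, connectivity=connectivity)
    regions = extract_regions(labels, sheet_id=sheet.sheet_id)
    kept = filter_regions(regions, min_area, (sheet.height, sheet.width),
                          border_policy)
    crops = crop_tablets(sheet, kept, padding=padding)
    info = {
        "n_candidates": len(regions),
        "n_kept": len(kept),
        "n_rejected": len(regions) - len(kept),
    }
    return kept, crops, info


def write_regions_csv(regions: Sequence[TabletRegion], path: str | Path) -> Path:
    """Regions table: region_id, area, inclusive bbox, centroid (0-based px)."""
    path = Path(path)
    rows = [
        {
            "sheet_id": r.sheet_id,
            "region_id": r.region_id,
            "area_px": r.pixel_count,
            "x_min": r.bbox[0], "y_min": r.bbox[1],
            "x_max": r.bbox[2], "y_max": r.bbox[3],
            "cx": r.centroid[0], "cy": r.centroid[1],
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_crops(crops: Sequence[TabletImage], outdir: str | Path) -> list[Path]:
    """Write per-tablet PNGs named {sheet_id}_{region_id}.png."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in crops:
        p = outdir / f"{c.tablet_id}.png"
        iio.imwrite(p, c.pixels)
        paths.append(p)
    return paths
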