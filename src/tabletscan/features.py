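"""Per-tablet feature extraction: downsampling, padding, summed intensities.

Two representations feed the classifiers.  The multivariate models
(PLS-DA, SVM, CNN) consume the downsampled crop itself, flattened to a
fixed-length vector once all crops are padded to a common canonical size.
The numerical threshold classifier consumes a single scalar per tablet:
the intensity of one color channel summed over all spatial pixel
positions of the downsampled crop.  For a yellow coat the blue channel is
the informative one — the more coating, the less blue — so summed blue is
the default statistic.

Sums are taken over the whole rectangular crop, background corners
included; padding uses value 0, so padding to the canonical size leaves
every summed intensity unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import TabletImage

__all__ = [
    "downsample",
    "pad_to_canonical",
    "canonical_size",
    "sum_intensity",
    "flatten",
    "unflatten",
    "FeatureTable",
    "build_features",
]

_CHANNELS = {"R": 0, "G": 1, "B": 2}


def _pixels(img: TabletImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, TabletImage) else np.asarray(img)


def _rewrap(img: TabletImage | np.ndarray, pixels: np.ndarray):
    if isinstance(img, TabletImage):
        return TabletImage(pixels=pixels, sheet_id=img.sheet_id,
                           region_id=img.region_id, bbox=img.bbox,
                           class_true=img.class_true)
    return pixels


def downsample(
    img: TabletImage | np.ndarray, factor: int = 50, mode: str = "decimate"
):
    """Reduce a crop by an integer factor.

    ``decimate`` keeps every ``factor``-th pixel starting at index 0 (a
    plain subsampling, the default).  ``block_mean`` averages each
    factor x factor block — partial blocks at the right/bottom edge are
    averaged over the pixels they actually contain — and rounds half-up to
    8 bits.  Output dimensions are ``ceil(in / factor)`` in both modes.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    a = _pixels(img)
    if mode == "decimate":
        out = np.ascontiguousarray(a[::factor, ::factor])
    elif mode == "block_mean":
        h, w = a.shape[:2]
        ridx = np.arange(0, h, factor)
        cidx = np.arange(0, w, factor)
        sums = np.add.reduceat(
            np.add.reduceat(a.astype(np.float64), ridx, axis=0), cidx, axis=1
        )
        rcounts = np.diff(np.append(ridx, h))
        ccounts = np.diff(np.append(cidx, w))
        counts = np.outer(rcounts, ccounts)[..., None]
        out = np.floor(sums / counts + 0.5).astype(np.uint8)
    else:
        raise ValueError(f"unknown downsample mode {mode!r}")
    return _rewrap(img, out)


def canonical_size(images: Iterable[TabletImage | np.ndarray]) -> tuple[int, int]:
    """Smallest (h, w) canvas that fits every crop: the per-axis maxima."""
    hmax = wmax = 0
    for img in images:
        a = _pixels(img)
        hmax = max(hmax, a.shape[0])
        wmax = max(wmax, a.shape[1])
    if hmax == 0:
        raise ValueError("no images given")
    return hmax, wmax


def pad_to_canonical(
    img: TabletImage | np.ndarray, size: tuple[int, int], fill: int = 0
):
    """Center a crop on a ``size`` = (h, w) canvas of constant ``fill`` value.

    With the default fill of 0, padding conserves every per-channel summed
    intensity.  Offsets are floor((canvas - crop) / 2).
    """
    a = _pixels(img)
    h, w = a.shape[:2]
    H, W = size
    if h > H or w > W:
        raise ValueError(
            f"crop {h}x{w} exceeds canonical size {H}x{W}; "
            "recompute the canonical size over the full dataset"
        )
    canvas = np.full((H, W, 3), fill, dtype=np.uint8)
    oy, ox = (H - h) // 2, (W - w) // 2
    canvas[oy : oy + h, ox : ox + w] = a
    return _rewrap(img, canvas)


def sum_intensity(img: TabletImage | np.ndarray, channel: str = "B") -> float:
    """Sum one color channel over all spatial pixel positions of the crop."""
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")
    a = _pixels(img)
    return float(a[..., _CHANNELS[channel]].sum(dtype=np.float64))


def flatten(img: TabletImage | np.ndarray, size: tuple[int, int] | None = None) -> np.ndarray:
    """Flatten a crop to a 1-D vector, row-major within each channel plane,
    planes ordered R, G, B.  Length is ``3 * h * w``.

    When ``size`` is given the crop must already be at that canonical size.
    Round-trips with :func:`unflatten`.
    """
    a = _pixels(img)
    if size is not None and a.shape[:2] != tuple(size):
        raise ValueError(f"crop shape {a.shape[:2]} != canonical {tuple(size)}")
    return np.concatenate([a[..., c].ravel() for c in range(3)]).astype(np.float64)


def unflatten(vec: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten` for a known (h, w)."""
    h, w = size
    vec = np.asarray(vec)
    if vec.size != 3 * h * w:
        raise ValueError(f"vector length {vec.size} != 3*{h}*{w}")
    planes = vec.reshape(3, h, w)
    return np.moveaxis(planes, 0, -1).astype(np.uint8)


@dataclass
class FeatureTable:
    """Aligned per-tablet features.

    ``table`` holds one row per tablet (tablet_id, sheet_id, region_id,
    class_true, s_red, s_green, s_blue); ``X`` the flattened canonical RGB
    vectors, row-aligned with the table; ``images`` the padded canonical
    crops themselves (CNN input); ``size`` the canonical (h, w).
    """

    table: pd.DataFrame
    X: np.ndarray
    images: list[TabletImage]
    size: tuple[int, int]

    def s(self, channel: str = "B") -> np.ndarray:
        col = {"R": "s_red", "G": "s_green", "B": "s_blue"}[channel]
        return self.table[col].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["class_true"].to_numpy()

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_features(
    tablets: Sequence[TabletImage],
    factor: int = 50,
    mode: str = "decimate",
    size: tuple[int, int] | None = None,
) -> FeatureTable:
    """Downsample, pad to a common canonical size, and tabulate features.

    The canonical size defaults to the per-axis maximum over the
    downsampled crops of this dataset (first pass), so no crop is ever
    truncated.  Summed intensities are computed on the padded crops;
    zero-padding makes them identical to sums on the raw downsampled crops.
    """
    if not tablets:
        raise ValueError("no tablet crops given")
    small = [downsample(t, factor=factor, mode=mode) for t in tablets]
    if size is None:
        size = canonical_size(small)
    padded = [pad_to_canonical(s, size) for s in small]
    rows = []
    vecs = []
    for p in padded:
        rows.append(
            {
                "tablet_id": p.tablet_id,
                "sheet_id": p.sheet_id,
                "region_id": p.region_id,
                "class_true": p.class_true,
                "s_red": sum_intensity(p, "R"),
                "s_green": sum_intensity(p, "G"),
                "s_blue": sum_intensity(p, "B"),
            }
        )
        vecs.append(flatten(p, size))
    return FeatureTable(
        table=pd.DataFrame(rows), X=np.vstack(vecs), images=padded, size=size
    )
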