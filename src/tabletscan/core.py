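"""Core raster containers shared by every pipeline stage.

Coordinate convention used throughout the package: pixel units, origin at
the top-left corner, x increasing rightward (columns), y increasing
downward (rows), 0-based indexing.  Bounding boxes are inclusive at both
ends: ``(x_min, y_min, x_max, y_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SheetImage", "TabletImage", "as_rgb8"]


def as_rgb8(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit RGB raster of shape (H, W, 3)."""
    a = np.asarray(pixels)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {a.shape}")
    if a.dtype != np.uint8:
        raise ValueError(f"expected dtype uint8, got {a.dtype}")
    return a


@dataclass
class SheetImage:
    """One scanned (or simulated) sheet of tablets.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``(H, W, 3)`` uint8 RGB raster.
    sheet_id : str
        Stable identifier used for provenance in every downstream record.
    dpi : int
        Scan resolution; metadata only, never used in computation.
    meta : dict
        Free-form provenance (generator spec echo, seed, source path).
    """

    pixels: np.ndarray
    sheet_id: str
    dpi: int = 600
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = as_rgb8(self.pixels)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class TabletImage:
    """A per-tablet RGB crop with provenance back to its sheet and region.

    ``class_true`` is the ground-truth coating class (1 = uncoated ...
    4 = fully coated) when known, else ``None``.
    """

    pixels: np.ndarray
    sheet_id: str = ""
    region_id: int = 0
    bbox: tuple[int, int, int, int] | None = None
    class_true: int | None = None

    def __post_init__(self) -> None:
        self.pixels = as_rgb8(self.pixels)

    @property
    def tablet_id(self) -> str:
        return f"{self.sheet_id}_{self.region_id}"

    @property
    def shape_hw(self) -> tuple[int, int]:
        return int(self.pixels.shape[0]), int(self.pixels.shape[1])
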