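"""Seeded synthetic scanner: sheets of coated tablets with ground truth.

The generator emulates the statistical structure the downstream analysis
relies on, not scanner optics.  A yellow film coat absorbs blue light, so
the blue channel of a scanned tablet declines monotonically with coating
amount; white uncoated tablets sit highest.  Four coating classes are
modelled (1 = uncoated, 2 = slightly, 3 = moderately, 4 = fully coated),
each with its own RGB mean and spread.  Color variation is modelled at two
levels: a per-tablet base color drawn once from the class distribution
(between-tablet spread, e.g. uneven spray deposition) and i.i.d. per-pixel
Gaussian scanner noise on top (within-tablet spread).

Tablets are rendered as filled ellipses on a dark neutral background,
placed with a minimum pairwise gap and never touching the sheet border,
mirroring how tablets are laid out on a flatbed scanner for segmentation.
Everything is deterministic for a fixed (spec, seed) pair: one
``numpy.random.Generator`` (PCG64) is consumed in a documented order
(placement draws per tablet, then base colors per tablet, then one noise
field), so fixtures are regenerable from their metadata alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .core import SheetImage

__all__ = [
    "CoatingClassSpec",
    "SheetSpec",
    "TabletTruth",
    "GroundTruth",
    "SheetTooCrowdedError",
    "generate_sheet",
    "batch_fixture",
    "scaled_batch_counts",
    "default_classes",
    "overlap_classes",
    "DEFAULT_BATCH_COUNTS",
    "write_sheet",
]

#: Per-class tablet counts of the reference scanned dataset the generator
#: emulates (uncoated, slightly, moderately, fully coated); total 2318.
DEFAULT_BATCH_COUNTS: tuple[int, int, int, int] = (623, 596, 595, 504)

_PRESETS: dict[str, dict] = {
    # Defaults emulate white cores under an increasingly yellow film: blue
    # declines strongly and strictly (gaps ~50), while red and green decay
    # at an accelerating rate as the film builds up.  The acceleration
    # makes the four class means non-collinear in RGB space, as real
    # coated-tablet colors are — a purely proportional decline would make
    # the classes indistinguishable to any model beyond a single linear
    # direction.
    # Tablet radii vary ~+/-2%: pressed tablet cores are dimensionally very
    # uniform, and that uniformity is what makes a raw (area-weighted)
    # intensity sum a usable class statistic.
    # Channel means follow saturating absorption kinetics: blue drops
    # steeply at first and the decrements shrink (57, 50, 42) as the film
    # builds, green and red barely move early and fall faster late.  The
    # kinetics curve the class-mean path in RGB space, as real dye
    # deposition does.
    "default": {
        "means": ((242, 240, 235), (241, 231, 178), (237, 211, 128), (223, 178, 86)),
        "sds": ((8, 8, 8),) * 4,
        "radius": (14.7, 15.3),
    },
    # Same class means, tighter color spread (blue gaps >= 6 sd) and
    # near-identical tablet sizes: the separable regime.
    "well_separated": {
        "means": ((242, 240, 235), (241, 231, 178), (237, 211, 128), (223, 178, 86)),
        "sds": ((4, 4, 4),) * 4,
        "radius": (14.9, 15.1),
    },
}


class SheetTooCrowdedError(RuntimeError):
    """Raised when tablets cannot be placed under the gap/border constraints."""


@dataclass(frozen=True)
class CoatingClassSpec:
    """Color model for one coating class.

    class_id: 1 (uncoated) ... 4 (fully coated).
    mean_rgb / sd_rgb: per-channel mean and standard deviation of the
    per-tablet base color, in 8-bit intensity units.  Draws are clipped to
    [0, 255] at render time.
    """

    class_id: int
    mean_rgb: tuple[float, float, float]
    sd_rgb: tuple[float, float, float]
    n_tablets: int

    def __post_init__(self) -> None:
        if self.class_id not in (1, 2, 3, 4):
            raise ValueError(f"class_id must be in 1..4, got {self.class_id}")
        if len(self.mean_rgb) != 3 or len(self.sd_rgb) != 3:
            raise ValueError("mean_rgb and sd_rgb must have 3 channels")
        if any(not (0 <= m <= 255) for m in self.mean_rgb):
            raise ValueError(f"mean_rgb must lie in [0, 255], got {self.mean_rgb}")
        if any(s < 0 for s in self.sd_rgb):
            raise ValueError(f"sd_rgb must be non-negative, got {self.sd_rgb}")
        if self.n_tablets < 0:
            raise ValueError("n_tablets must be >= 0")


@dataclass(frozen=True)
class SheetSpec:
    """Geometry and noise model of one synthetic sheet.

    The default geometry is desk-scale (1024 x 768 px) rather than the
    9921 x 7015 px of a 600 dpi A4-ish scan; ``dpi`` is metadata only.
    ``tablet_radius_px`` bounds the semi-axes of each tablet's ellipse; the
    narrow default range models a pharmaceutical batch of near-uniform
    tablets (uniform size is what makes raw summed intensities a usable
    class statistic).  ``min_gap_px`` is the minimum boundary-to-boundary
    distance between tablets; tablets never touch the sheet border.
    """

    width_px: int = 1024
    height_px: int = 768
    dpi: int = 600
    background_rgb: tuple[int, int, int] = (40, 40, 42)
    tablet_radius_px: tuple[float, float] = (14.7, 15.3)
    min_gap_px: float = 4.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("sheet dimensions must be positive")
        rmin, rmax = self.tablet_radius_px
        if rmin <= 0 or rmax < rmin:
            raise ValueError(f"invalid tablet_radius_px {self.tablet_radius_px}")
        if self.min_gap_px < 1:
            raise ValueError("min_gap_px must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(not (0 <= v <= 255) for v in self.background_rgb):
            raise ValueError("background_rgb must lie in [0, 255]")


@dataclass(frozen=True)
class TabletTruth:
    """Ground truth for one rendered tablet (pixel coordinates, 0-based)."""

    sheet_id: str
    tablet_id: int
    class_id: int
    cx: float
    cy: float
    rx: float
    ry: float
    angle_deg: float


class GroundTruth:
    """Ordered collection of :class:`TabletTruth` records.

    ``tablet_id`` is unique within each sheet; across sheets the pair
    (sheet_id, tablet_id) is unique.
    """

    def __init__(self, records: Sequence[TabletTruth]):
        self.records: list[TabletTruth] = list(records)
        seen = set()
        for r in self.records:
            key = (r.sheet_id, r.tablet_id)
            if key in seen:
                raise ValueError(f"duplicate tablet_id {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            counts[r.class_id] = counts.get(r.class_id, 0) + 1
        return dict(sorted(counts.items()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    @classmethod
    def concat(cls, parts: Sequence["GroundTruth"]) -> "GroundTruth":
        recs: list[TabletTruth] = []
        for p in parts:
            recs.extend(p.records)
        return cls(recs)


def _validate_classes(classes: Sequence[CoatingClassSpec]) -> list[CoatingClassSpec]:
    classes = sorted(classes, key=lambda c: c.class_id)
    ids = [c.class_id for c in classes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate class_ids {ids}")
    blues = [c.mean_rgb[2] for c in classes]
    if any(b1 <= b2 for b1, b2 in zip(blues, blues[1:])):
        raise ValueError(
            "mean blue channel must be strictly decreasing with class_id "
            f"(more coating -> yellower -> less blue); got {blues}"
        )
    return classes


def _place_tablets(
    spec: SheetSpec,
    n_total: int,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> list[tuple[float, float, float, float, float]]:
    """Rejection-sample non-overlapping ellipse placements.

    Returns (cx, cy, rx, ry, angle_deg) per tablet.  Overlap is tested on
    bounding circles (radius = max semi-axis), which is conservative for
    rotated ellipses.  Raises :class:`SheetTooCrowdedError` after
    ``max_tries`` failed draws for any single tablet.
    """
    rmin, rmax = spec.tablet_radius_px
    placed: list[tuple[float, float, float, float, float]] = []
    cxs = np.empty(n_total)
    cys = np.empty(n_total)
    rbs = np.empty(n_total)
    for i in range(n_total):
        for _ in range(max_tries):
            rx = rng.uniform(rmin, rmax)
            ry = rng.uniform(rmin, rmax)
            angle = rng.uniform(0.0, 180.0)
            rb = max(rx, ry)
            lo_x, hi_x = rb + 2.0, spec.width_px - 3.0 - rb
            lo_y, hi_y = rb + 2.0, spec.height_px - 3.0 - rb
            if lo_x >= hi_x or lo_y >= hi_y:
                raise SheetTooCrowdedError(
                    f"sheet {spec.width_px}x{spec.height_px} too small for "
                    f"tablet radius {rb:.1f}"
                )
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if i == 0:
                ok = True
            else:
                d = np.hypot(cxs[:i] - cx, cys[:i] - cy)
                ok = bool(np.all(d >= rbs[:i] + rb + spec.min_gap_px))
            if ok:
                cxs[i], cys[i], rbs[i] = cx, cy, rb
                placed.append((cx, cy, rx, ry, angle))
                break
        else:
            raise SheetTooCrowdedError(
                f"sheet too crowded: placed {i} of {n_total} tablets "
                f"({spec.width_px}x{spec.height_px}, gap >= {spec.min_gap_px})"
            )
    return placed


def generate_sheet(
    spec: SheetSpec,
    classes: Sequence[CoatingClassSpec],
    sheet_id: str | None = None,
) -> tuple[SheetImage, GroundTruth]:
    """Render one synthetic sheet and its ground-truth table.

    Tablets are laid down in class order (all class-1 tablets first, then
    class 2, ...).  Each tablet gets one base color drawn from its class
    distribution, rounded to 8-bit and painted into its ellipse; an i.i.d.
    Gaussian noise field of sd ``spec.noise_sd`` is then added to the whole
    sheet and the result clipped to [0, 255].  With ``noise_sd == 0`` every
    interior pixel equals the tablet's drawn base color exactly.
    """
    classes = _validate_classes(classes)
    n_total = sum(c.n_tablets for c in classes)
    if sheet_id is None:
        sheet_id = f"sheet_s{spec.seed}"
    rng = np.random.default_rng(spec.seed)

    placements = _place_tablets(spec, n_total, rng)

    canvas = np.empty((spec.height_px, spec.width_px, 3), dtype=np.float64)
    canvas[:] = np.asarray(spec.background_rgb, dtype=np.float64)

    records: list[TabletTruth] = []
    idx = 0
    for cspec in classes:
        mean = np.asarray(cspec.mean_rgb, dtype=np.float64)
        sd = np.asarray(cspec.sd_rgb, dtype=np.float64)
        for _ in range(cspec.n_tablets):
            cx, cy, rx, ry, angle = placements[idx]
            base = np.clip(np.rint(rng.normal(mean, sd)), 0, 255)
            rr, cc = _draw_ellipse(
                cy, cx, ry, rx, rotation=np.deg2rad(angle),
                shape=(spec.height_px, spec.width_px),
            )
            canvas[rr, cc] = base
            records.append(
                TabletTruth(
                    sheet_id=sheet_id,
                    tablet_id=idx + 1,
                    class_id=cspec.class_id,
                    cx=cx, cy=cy, rx=rx, ry=ry, angle_deg=angle,
                )
            )
            idx += 1

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    meta = {"spec": dataclasses.asdict(spec), "n_tablets": n_total}
    sheet = SheetImage(pixels=pixels, sheet_id=sheet_id, dpi=spec.dpi, meta=meta)
    return sheet, GroundTruth(records)


def default_classes(
    n_per_class: Sequence[int] | int = 8,
    preset: str = "default",
) -> list[CoatingClassSpec]:
    """Build the four coating classes from a named color preset."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    if isinstance(n_per_class, int):
        n_per_class = [n_per_class] * 4
    if len(n_per_class) != 4:
        raise ValueError("n_per_class must be an int or a 4-sequence")
    p = _PRESETS[preset]
    return [
        CoatingClassSpec(class_id=k + 1, mean_rgb=p["means"][k],
                         sd_rgb=p["sds"][k], n_tablets=int(n_per_class[k]))
        for k in range(4)
    ]


def overlap_classes(
    gap: float,
    sd: float = 10.0,
    n_per_class: int = 20,
    center_blue: float = 150.0,
) -> list[CoatingClassSpec]:
    """Adversarial preset: class blue means spaced ``gap`` apart around
    ``center_blue`` with common spread ``sd``.

    Shrinking ``gap`` relative to ``sd`` overlaps the class distributions
    and induces misclassification; used to probe classifier degradation.
    """
    offsets = (1.5, 0.5, -0.5, -1.5)
    specs = []
    for k, off in enumerate(offsets):
        blue = center_blue + off * gap
        if not (0 <= blue <= 255):
            raise ValueError(f"gap {gap} pushes blue mean out of range ({blue})")
        specs.append(
            CoatingClassSpec(
                class_id=k + 1,
                mean_rgb=(230.0, 215.0, blue),
                sd_rgb=(sd, sd, sd),
                n_tablets=n_per_class,
            )
        )
    return specs


def scaled_batch_counts(
    scale: float, counts: Sequence[int] = DEFAULT_BATCH_COUNTS
) -> list[int]:
    """Round-half-up scaling of the reference per-class batch sizes."""
    if not (0 < scale <= 1):
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    scaled = [int(np.floor(scale * c + 0.5)) for c in counts]
    if any(s < 1 for s in scaled):
        raise ValueError(f"scale {scale} leaves an empty class: {scaled}")
    return scaled


def batch_fixture(
    scale: float = 1.0,
    seed: int = 0,
    preset: str = "default",
    counts: Sequence[int] = DEFAULT_BATCH_COUNTS,
    sheet: SheetSpec | None = None,
    tablets_per_sheet: int = 120,
    render: bool = True,
) -> tuple[list[SheetImage], GroundTruth]:
    """Emulate the reference study layout: four batches scanned over as many
    sheets as needed.

    Per-class tablet counts are ``round(scale * counts)`` (half-up); at
    ``scale=1`` with the default counts the total is 2318.  Classes are
    interleaved across sheets so every sheet carries a mix.  Per-sheet
    seeds are spawned deterministically from ``seed``.

    With ``render=False`` only placement and the ground-truth table are
    computed (the returned sheet list is empty); this serves bookkeeping
    checks and layout planning at full scale without rasterizing ~20
    sheets.
    """
    per_class = scaled_batch_counts(scale, counts)
    if sheet is not None:
        template = sheet
    else:
        template = SheetSpec(tablet_radius_px=_PRESETS[preset]["radius"])

    # Interleaved global class sequence, chunked into sheets.
    assignment: list[int] = []
    remaining = list(per_class)
    while any(r > 0 for r in remaining):
        for k in range(4):
            if remaining[k] > 0:
                assignment.append(k + 1)
                remaining[k] -= 1
    chunks = [
        assignment[i : i + tablets_per_sheet]
        for i in range(0, len(assignment), tablets_per_sheet)
    ]

    child_seeds = np.random.SeedSequence(seed).generate_state(len(chunks)) % (2**31)
    sheets: list[SheetImage] = []
    truths: list[GroundTruth] = []
    for j, chunk in enumerate(chunks):
        n_by_class = [chunk.count(k) for k in (1, 2, 3, 4)]
        classes = default_classes(n_by_class, preset=preset)
        spec = dataclasses.replace(template, seed=int(child_seeds[j]))
        sheet_id = f"batch_s{seed}_p{j:03d}"
        if render:
            img, truth = generate_sheet(spec, classes, sheet_id=sheet_id)
            sheets.append(img)
        else:
            rng = np.random.default_rng(spec.seed)
            placements = _place_tablets(spec, len(chunk), rng)
            recs = []
            i = 0
            for cspec in _validate_classes(classes):
                for _ in range(cspec.n_tablets):
                    cx, cy, rx, ry, ang = placements[i]
                    recs.append(
                        TabletTruth(sheet_id, i + 1, cspec.class_id,
                                    cx, cy, rx, ry, ang)
                    )
                    i += 1
            truth = GroundTruth(recs)
        truths.append(truth)
    return sheets, GroundTruth.concat(truths)


def write_sheet(
    sheet: SheetImage, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write one sheet as PNG + truth CSV + metadata JSON.

    Truth CSV columns: tablet_id, class_id, cx, cy, rx, ry, angle_deg
    (pixel units, origin top-left, 0-based).
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    png = outdir / f"{sheet.sheet_id}.png"
    csv = outdir / f"{sheet.sheet_id}_truth.csv"
    meta = outdir / f"{sheet.sheet_id}_meta.json"
    iio.imwrite(png, sheet.pixels)
    df = truth.to_dataframe()
    df[["tablet_id", "class_id", "cx", "cy", "rx", "ry", "angle_deg"]].to_csv(
        csv, index=False
    )
    meta.write_text(json.dumps({"sheet_id": sheet.sheet_id, "dpi": sheet.dpi,
                                **sheet.meta}, indent=2, default=str))
    return {"png": png, "truth": csv, "meta": meta}
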