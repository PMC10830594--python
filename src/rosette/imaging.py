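"""Tray-image analysis: color segmentation and per-pot rosette areas.

The pipeline mirrors a simple top-view phenotyping workflow: from each tray
photograph two masks are produced, one keeping pixels in a configurable green
hue range and one in a red hue range (stressed, anthocyanin-rich leaves); the
two masks are merged by pixelwise OR, plant pixels are summed per pot cell,
and counts are converted to mm^2 with a single mm-per-pixel scale per tray.

Pot cells are half-open pixel rectangles ``[y0, y1) x [x0, x1)``, 0-based and
row-major, so the grid tiles the image exactly with no double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.color import rgb2hsv


@dataclass(frozen=True)
class HueRange:
    """Hue acceptance window in [0, 1); wraps around 1 when low > high."""

    low: float
    high: float

    def contains(self, hue: np.ndarray) -> np.ndarray:
        if self.low <= self.high:
            return (hue >= self.low) & (hue <= self.high)
        return (hue >= self.low) | (hue <= self.high)


@dataclass(frozen=True)
class SegmentationConfig:
    """Green + red hue windows with saturation/value floors.

    The floors reject the unsaturated tray background; defaults are generous
    windows around pure green and red.
    """

    green: HueRange = field(default_factory=lambda: HueRange(0.18, 0.45))
    red: HueRange = field(default_factory=lambda: HueRange(0.92, 0.06))
    min_saturation: float = 0.15
    min_value: float = 0.10

    def __post_init__(self) -> None:
        for r in (self.green, self.red):
            if not (0.0 <= r.low < 1.0 and 0.0 <= r.high < 1.0):
                raise ValueError("hue bounds must lie in [0, 1)")


@dataclass(frozen=True)
class TrayImage:
    """8-bit RGB raster of one tray with its mm-per-pixel calibration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mm_per_px: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.mm_per_px <= 0:
            raise ValueError("mm-per-pixel scale must be positive")


@dataclass(frozen=True)
class PotLayout:
    """Regular pot grid: ``rows x cols`` cells of ``cell_h x cell_w`` pixels.

    ``used`` marks which pots hold a plant; the classic layout uses every
    second pot of a 54-pot (6 x 9) tray, a checkerboard of 27 plants.
    """

    rows: int
    cols: int
    cell_h: int
    cell_w: int
    used: np.ndarray  # (rows, cols) bool

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.cell_h < 1 or self.cell_w < 1:
            raise ValueError("layout dimensions must be positive")
        if self.used.shape != (self.rows, self.cols):
            raise ValueError("used mask shape must match grid")

    @classmethod
    def every_second_pot(
        cls, rows: int = 6, cols: int = 9, cell_h: int = 60, cell_w: int = 60
    ) -> "PotLayout":
        r, c = np.indices((rows, cols))
        return cls(rows, cols, cell_h, cell_w, used=((r * cols + c) % 2 == 0))

    def cell_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(y0, y1, x0, x1), half-open."""
        return (
            row * self.cell_h,
            (row + 1) * self.cell_h,
            col * self.cell_w,
            (col + 1) * self.cell_w,
        )

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.rows * self.cell_h, self.cols * self.cell_w

    def to_yaml(self, path) -> None:
        data = {
            "rows": self.rows,
            "cols": self.cols,
            "cell_h": self.cell_h,
            "cell_w": self.cell_w,
            "used": self.used.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "PotLayout":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            rows=data["rows"],
            cols=data["cols"],
            cell_h=data["cell_h"],
            cell_w=data["cell_w"],
            used=np.asarray(data["used"], dtype=bool),
        )


def segment_plant_pixels(
    image: TrayImage, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Binary plant mask: union of the green-range and red-range masks."""
    cfg = cfg or SegmentationConfig()
    hsv = rgb2hsv(image.pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    saturated = (s >= cfg.min_saturation) & (v >= cfg.min_value)
    green = cfg.green.contains(h) & saturated
    red = cfg.red.contains(h) & saturated
    return green | red


def count_plant_pixels(mask: np.ndarray, layout: PotLayout) -> dict[tuple[int, int], int]:
    """True-pixel count per used pot cell."""
    hh, ww = layout.image_shape
    if mask.shape[0] < hh or mask.shape[1] < ww:
        raise ValueError("layout extends beyond mask bounds")
    counts: dict[tuple[int, int], int] = {}
    for row in range(layout.rows):
        for col in range(layout.cols):
            if not layout.used[row, col]:
                continue
            y0, y1, x0, x1 = layout.cell_bounds(row, col)
            counts[(row, col)] = int(mask[y0:y1, x0:x1].sum())
    return counts


def count_and_convert(
    mask: np.ndarray, layout: PotLayout, mm_per_px: float
) -> dict[tuple[int, int], float]:
    """Per-pot rosette area in mm^2: pixel count times scale squared.

    Unused pots are absent from the result, not reported as zero.
    """
    if mm_per_px <= 0:
        raise ValueError("mm-per-pixel scale must be positive")
    return {
        pot: n * mm_per_px**2 for pot, n in count_plant_pixels(mask, layout).items()
    }


def build_area_series(
    images,
    layout: PotLayout,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Area time series for every used pot of one tray.

    ``images`` maps imaging day to :class:`TrayImage` (a dict or an iterable
    of ``(day, image)`` pairs). Returns a long table (pot_row, pot_col, day,
    area_mm2) sorted by pot then day; a day with no image is simply absent
    (a gap, never a zero).
    """
    pairs = sorted(
        images.items() if isinstance(images, dict) else images, key=lambda p: p[0]
    )
    days = [d for d, _ in pairs]
    if len(days) != len(set(days)):
        raise ValueError("duplicate imaging day for the same tray")
    records = []
    for day, img in pairs:
        mask = segment_plant_pixels(img, cfg)
        for (row, col), area in count_and_convert(mask, layout, img.mm_per_px).items():
            records.append(
                {"pot_row": row, "pot_col": col, "day": day, "area_mm2": area}
            )
    out = pd.DataFrame(records, columns=["pot_row", "pot_col", "day", "area_mm2"])
    return out.sort_values(["pot_row", "pot_col", "day"]).reset_index(drop=True)


# plant color drawn strictly inside the default green hue window
PLANT_RGB = (40, 160, 40)
BACKGROUND_RGB = (128, 128, 128)  # zero saturation: never segmented


def render_tray_image(
    areas: dict[tuple[int, int], float],
    layout: PotLayout,
    mm_per_px: float = 0.5,
    color: tuple[int, int, int] = PLANT_RGB,
) -> tuple[TrayImage, dict[tuple[int, int], int]]:
    """Draw each plant as a filled green disk centered in its pot cell.

    ``areas`` maps (pot_row, pot_col) to target rosette area in mm^2; the
    disk radius is chosen so the ideal disk has that area. Returns the image
    and the exact per-pot drawn pixel counts (the segmentation ground truth;
    every used pot appears, empty ones with count 0).

    Raises if a disk would overflow its cell — the every-second-pot design
    exists precisely to prevent neighbours from touching.
    """
    if mm_per_px <= 0:
        raise ValueError("mm-per-pixel scale must be positive")
    hh, ww = layout.image_shape
    img = np.empty((hh, ww, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    counts: dict[tuple[int, int], int] = {
        (r, c): 0
        for r in range(layout.rows)
        for c in range(layout.cols)
        if layout.used[r, c]
    }
    for (row, col), area in areas.items():
        if not layout.used[row, col]:
            raise ValueError(f"pot {(row, col)} is not a used pot")
        if area < 0:
            raise ValueError("area must be >= 0")
        if area == 0:
            continue
        radius_px = np.sqrt(area / np.pi) / mm_per_px
        y0, y1, x0, x1 = layout.cell_bounds(row, col)
        cy, cx = (y0 + y1 - 1) / 2.0, (x0 + x1 - 1) / 2.0
        if radius_px > min(y1 - y0, x1 - x0) / 2.0 - 1:
            raise ValueError(
                f"disk of radius {radius_px:.1f}px overflows pot cell {(row, col)}"
            )
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        img[y0:y1, x0:x1][disk] = color
        counts[(row, col)] = int(disk.sum())
    return TrayImage(pixels=img, mm_per_px=mm_per_px), counts


def write_png(image: TrayImage, path) -> None:
    from PIL import Image

    Image.fromarray(image.pixels).save(path)


def read_tray_image(path, mm_per_px: float) -> TrayImage:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("RGB"))
    return TrayImage(pixels=arr, mm_per_px=mm_per_px)
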