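"""Image and annotation I/O, tiling of large scans, and mask reassembly.

Slide scanners produce images far larger than a classifier can hold in
memory at once, so full scans are split into overlapping tiles, processed
independently, and the per-tile label masks are merged back into a single
full-resolution mask.

Conventions used throughout the package:

* arrays are row-major with a top-left origin,
* boxes are half-open pixel rectangles ``[row0, row1) x [col0, col1)``,
* class masks are small-integer grids (see :data:`BACKGROUND`,
  :data:`VEIN`, :data:`STOMATE`).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

# Class codes for per-pixel label masks.  STOMATE is the positive class and
# deliberately the largest code: merging overlapping tile masks by
# element-wise maximum implements "positive class wins".
BACKGROUND = 0
VEIN = 1
STOMATE = 2

CLASS_NAMES = {BACKGROUND: "background", VEIN: "vein", STOMATE: "stomate"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

#: Physical sampling of the reference slide scanner, in micrometres per pixel.
DEFAULT_PIXEL_SCALE = 0.25

ANNOTATION_HEADER = ["row0", "col0", "row1", "col1", "label"]
RESULT_HEADER = [
    "source_id",
    "box_row0",
    "box_col0",
    "box_row1",
    "box_col1",
    "status",
    "polarity",
    "area_px",
    "area_um2",
]


class InputFormatError(ValueError):
    """Raised when a file cannot be read as a supported image/annotation."""


class GeometryError(ValueError):
    """Raised when a tile or box falls outside its parent extent."""


@dataclass
class ScanImage:
    """A raster micrograph with its physical pixel scale.

    ``pixels`` is an 8-bit array, either 2-D grayscale or H x W x 3 RGB.
    ``pixel_scale`` is in micrometres per pixel.
    """

    pixels: np.ndarray
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D grayscale or H x W x 3 RGB")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("colour images must have exactly 3 planes")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive (um/px)")
        if self.pixels.dtype != np.uint8:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < 0 or hi > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def gray(self) -> np.ndarray:
        """Luminance view as float64 in [0, 255] (ITU-R BT.601 weights)."""
        return to_gray(self.pixels)


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """Collapse RGB to luminance with 0.299/0.587/0.114 weights."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    return arr @ np.array([0.299, 0.587, 0.114])


@dataclass
class Tile:
    """A rectangular window cut from a parent :class:`ScanImage`."""

    parent_id: str
    row_offset: int
    col_offset: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.row_offset < 0 or self.col_offset < 0:
            raise GeometryError("tile offsets must be non-negative")


@dataclass
class BoxAnnotation:
    """Half-open bounding boxes of one class for one source image."""

    boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    label: str = "stomate"
    source_id: str = ""

    def __post_init__(self) -> None:
        for r0, c0, r1, c1 in self.boxes:
            if not (r1 > r0 and c1 > c0):
                raise ValueError(f"degenerate box {(r0, c0, r1, c1)}")


# ---------------------------------------------------------------------------
# image reading / writing
# ---------------------------------------------------------------------------

def load_image(path: str | Path, pixel_scale: float = DEFAULT_PIXEL_SCALE) -> ScanImage:
    """Read a PNG or TIFF micrograph into a :class:`ScanImage`.

    16-bit inputs are rescaled to 8 bits by a linear min-max map; 8-bit
    data is preserved losslessly.  An alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - reraise with the path named
        raise InputFormatError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise InputFormatError(f"unsupported image layout in {path}: shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = _rescale_to_uint8(arr)
    return ScanImage(arr, pixel_scale=pixel_scale, source_id=path.stem)


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def save_image(image: ScanImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit image to PNG or TIFF, chosen by file extension."""
    pixels = image.pixels if isinstance(image, ScanImage) else np.asarray(image)
    iio.imwrite(Path(path), pixels.astype(np.uint8))


# ---------------------------------------------------------------------------
# tiling and reassembly
# ---------------------------------------------------------------------------

def _tile_offsets(extent: int, tile: int, overlap: int) -> list[int]:
    """Start offsets along one axis; the last tile is shifted flush."""
    if tile >= extent:
        return [0]
    stride = tile - overlap
    offsets = list(range(0, extent - tile, stride))
    offsets.append(extent - tile)  # flush with the border, never padded
    return offsets


def tile_image(image: ScanImage, tile_size: int = 2048, overlap: int = 128) -> list[Tile]:
    """Split an image into overlapping tiles covering every pixel.

    Consecutive tiles share exactly ``overlap`` pixels except the last tile
    along each axis, which is shifted inward to end flush with the image
    border so no synthetic padding enters classification.
    """
    if not 0 <= overlap < tile_size:
        raise ValueError(f"need 0 <= overlap < tile_size, got {overlap} >= {tile_size}")
    h, w = image.shape
    if tile_size > max(h, w):
        raise ValueError(f"tile_size {tile_size} exceeds both image dimensions {h}x{w}")
    th, tw = min(tile_size, h), min(tile_size, w)
    tiles = []
    for r in _tile_offsets(h, th, min(overlap, th - 1) if th < tile_size else overlap):
        for c in _tile_offsets(w, tw, min(overlap, tw - 1) if tw < tile_size else overlap):
            tiles.append(
                Tile(image.source_id, r, c, image.pixels[r : r + th, c : c + tw])
            )
    return tiles


def assemble_label_mask(
    tile_masks: Sequence[tuple[tuple[int, int], np.ndarray]],
    full_shape: tuple[int, int],
) -> np.ndarray:
    """Merge per-tile class grids into one full-size grid.

    Where tiles overlap the highest class code wins, so a "stomate" vote
    from any tile survives (a missed stomate is costlier than a duplicate;
    duplicates merge downstream in connected-component analysis).
    """
    out = np.full(full_shape, BACKGROUND, dtype=np.uint8)
    for (r, c), mask in tile_masks:
        mask = np.asarray(mask)
        if r < 0 or c < 0 or r + mask.shape[0] > full_shape[0] or c + mask.shape[1] > full_shape[1]:
            raise GeometryError(
                f"tile at ({r},{c}) with shape {mask.shape} exceeds {full_shape}"
            )
        region = out[r : r + mask.shape[0], c : c + mask.shape[1]]
        np.maximum(region, mask, out=region)
    return out


def boxes_to_mask(
    boxes: Sequence[tuple[int, int, int, int]],
    shape: tuple[int, int],
    value: int = STOMATE,
) -> np.ndarray:
    """Rasterize half-open boxes into a class mask (clipped to ``shape``)."""
    out = np.zeros(shape, dtype=np.uint8)
    for r0, c0, r1, c1 in boxes:
        out[max(r0, 0) : min(r1, shape[0]), max(c0, 0) : min(c1, shape[1])] = value
    return out


# ---------------------------------------------------------------------------
# annotations and results
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, source_id: str | None = None) -> BoxAnnotation:
    """Read a box-annotation CSV (``row0,col0,row1,col1,label``)."""
    path = Path(path)
    boxes: list[tuple[int, int, int, int]] = []
    label = "stomate"
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0].strip().lower() == "row0"):
                continue
            try:
                r0, c0, r1, c1 = (int(v) for v in row[:4])
                label = row[4].strip()
            except (ValueError, IndexError) as exc:
                raise InputFormatError(f"{path}:{lineno}: malformed annotation row {row!r}") from exc
            boxes.append((r0, c0, r1, c1))
    return BoxAnnotation(boxes, label=label, source_id=source_id or path.stem)


def write_annotations(annotation: BoxAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for box in annotation.boxes:
            writer.writerow([*box, annotation.label])


def write_results(
    estimates: Sequence,  # list of pore_measure.PoreEstimate
    boxes: Sequence[tuple[int, int, int, int]],
    path: str | Path,
    source_id: str = "",
    config: dict | None = None,
) -> None:
    """Write per-stomate results as CSV plus a JSON run summary.

    ``path`` names the CSV; the JSON summary is written next to it with a
    ``.json`` suffix.  Floats are serialized with ``repr`` so a read-back
    reproduces them exactly.
    """
    path = Path(path)
    if len(estimates) != len(boxes):
        raise ValueError("one bounding box is required per estimate")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_HEADER)
        for est, box in zip(estimates, boxes):
            writer.writerow(
                [
                    source_id,
                    *box,
                    est.status,
                    est.polarity,
                    est.area_px,
                    repr(float(est.area_um2)),
                ]
            )
    counts: dict[str, int] = {}
    for est in estimates:
        counts[est.status] = counts.get(est.status, 0) + 1
    summary = {
        "source_id": source_id,
        "n_boxes": len(boxes),
        "status_counts": counts,
        "config": config or {},
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
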