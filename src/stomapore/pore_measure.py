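"""Polarity-robust stomatal pore-area estimation.

The pore of a stomate can appear darker *or* lighter than the surrounding
guard cells depending on where the focal plane sits, which defeats
segmentation methods tuned to one intensity polarity.  The algorithm here
is robust to that choice: the stomate region is found by binary
segmentation, aligned to its major axis, and the pore centre is then
located as the intensity extremum (peak for a light pore, valley for a
dark pore) nearest the region centroid on the vertical cross-section
through that centroid.  The pore is grown from the centre by
intensity-tolerant flood fill and its pixel count converted to um^2.

Stages, in execution order:

1.  ``enhance``            – CLAHE, global contrast stretch, unsharp mask
2.  ``binarize``           – Otsu threshold, minority class as foreground
3.  ``filter_regions``     – drop dust/bubble-sized components
4.  ``select_stomate_region`` – largest component near the patch centre
5.  ``align_to_major_axis``   – rotate stomate to horizontal
6.  ``cross_section``      – intensity profile through the centroid
7.  ``find_pore_center``   – extremum nearest the centroid, fixes polarity
8.  ``grow_pore``          – flood fill at the pore intensity
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks, peak_prominences
from skimage import exposure, filters, segmentation, transform

from .imaging_io import to_gray

Polarity = Literal["dark", "light", "none"]

def _disk(radius: int) -> np.ndarray:
    """Disk structuring element for morphological cleanup."""
    span = np.arange(-radius, radius + 1)
    return (span[:, None] ** 2 + span[None, :] ** 2) <= radius**2

STATUS_ACCEPTED = "accepted"
STATUS_NO_DETECTION = "no_detection"
STATUS_REJECTED = "rejected"


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable intensity structure."""


@dataclass
class PoreConfig:
    """Tunables of the pore-estimation pipeline.

    The defaults reflect 0.25 um/px brightfield imprint imagery; every
    value can be overridden from the YAML config.
    """

    clahe_clip: float = 0.005         # clip-limit fraction of the local histogram
    clahe_tiles: int = 2              # CLAHE kernel grid (tiles per side)
    sharpen_radius: float = 2.0       # unsharp-mask gaussian radius, px
    sharpen_amount: float = 0.5
    min_area_px: int = 50             # components with area <= this are dust
    central_fraction: float = 0.5     # centroid must fall in this central box
    smooth_window: int = 3            # moving-average width on the profile
    prominence_frac: float = 0.05     # extremum prominence vs profile range
    grow_tolerance_frac: float = 0.5  # flood tolerance vs pore-centre prominence
    border_reject_frac: float = 0.5   # pore on >= this much of the border -> reject
    min_axis_ratio: float = 1.05      # below this the mask is circular: skip rotation
    max_extrema: int = 10             # more extrema -> no single discernible pore
    min_pore_px: int = 15             # sub-resolution pore -> no detection


@dataclass
class PorePatch:
    """A grayscale crop around one detected stomate."""

    pixels: np.ndarray
    pixel_scale: float = 0.25
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("empty patch")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.pixels.shape[0] - 1) / 2.0, (self.pixels.shape[1] - 1) / 2.0)


@dataclass
class RegionMask:
    """A single 8-connected binary region with its shape descriptors."""

    mask: np.ndarray
    area_px: int
    centroid: tuple[float, float]
    orientation: float  # degrees from horizontal, in (-90, 90]

    @staticmethod
    def from_mask(mask: np.ndarray) -> "RegionMask":
        mask = np.asarray(mask, dtype=bool)
        area = int(mask.sum())
        if area == 0:
            raise ValueError("empty region mask")
        rows, cols = np.nonzero(mask)
        centroid = (float(rows.mean()), float(cols.mean()))
        return RegionMask(mask, area, centroid, _orientation_deg(rows, cols))

    @property
    def axis_ratio(self) -> float:
        rows, cols = np.nonzero(self.mask)
        major, minor = _axis_lengths(rows, cols)
        return major / max(minor, 1e-9)


def _orientation_deg(rows: np.ndarray, cols: np.ndarray) -> float:
    """Major-axis angle from horizontal, image coordinates, in (-90, 90].

    Positive angles rotate from the +col axis toward the +row axis
    (clockwise on screen, since rows grow downward).
    """
    x = cols - cols.mean()
    y = rows - rows.mean()
    cxx, cyy, cxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    if abs(cxy) < 1e-12 and abs(cxx - cyy) < 1e-12:
        return 0.0
    ang = 0.5 * np.degrees(np.arctan2(2.0 * cxy, cxx - cyy))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def _axis_lengths(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    x = cols - cols.mean()
    y = rows - rows.mean()
    cov = np.cov(np.stack([x, y])) if len(x) > 1 else np.zeros((2, 2))
    eig = np.sort(np.linalg.eigvalsh(cov))
    return float(np.sqrt(max(eig[1], 0.0)) + 1e-9), float(np.sqrt(max(eig[0], 0.0)) + 1e-9)


@dataclass
class CrossSectionProfile:
    """Vertical intensity trace through the aligned-mask centroid."""

    values: np.ndarray          # smoothed intensities along the cut
    raw_values: np.ndarray
    peaks: list[int]
    valleys: list[int]
    centroid_index: int         # index of the mask centroid within the trace
    row_start: int              # patch row of values[0]
    col: int                    # patch column of the cut
    center_index: int | None = None
    polarity: Polarity = "none"
    center_prominence: float = 0.0

    @property
    def intensity_range(self) -> float:
        return float(self.raw_values.max() - self.raw_values.min())


@dataclass
class PoreEstimate:
    """Outcome of the pore-area algorithm for one stomate patch."""

    status: str
    pore_mask: np.ndarray | None = None
    area_px: int = 0
    area_um2: float = 0.0
    polarity: Polarity = "none"
    orientation: float = 0.0
    reason: str = ""
    region: RegionMask | None = None

    @property
    def accepted(self) -> bool:
        return self.status == STATUS_ACCEPTED


# ---------------------------------------------------------------------------
# 1. enhancement
# ---------------------------------------------------------------------------

def enhance(
    patch: PorePatch | np.ndarray,
    clahe_clip: float = 0.005,
    clahe_tiles: int = 2,
    sharpen_amount: float = PoreConfig.sharpen_amount,
    sharpen_radius: float = PoreConfig.sharpen_radius,
) -> np.ndarray:
    """CLAHE -> global linear contrast stretch -> unsharp mask.

    Returns an 8-bit grayscale grid.  A constant patch passes through
    unchanged (stretching a zero range is the identity by convention).
    """
    pixels = patch.pixels if isinstance(patch, PorePatch) else np.asarray(patch)
    gray = to_gray(pixels)
    if gray.size <= 1:
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    lo, hi = float(gray.min()), float(gray.max())
    if hi == lo:
        return np.full(gray.shape, int(round(lo)), dtype=np.uint8)

    kernel = tuple(max(s // clahe_tiles, 1) for s in gray.shape)
    # symmetrised CLAHE: averaging the equalisation of the image and the
    # complement of the equalised inverted image makes the operator exactly
    # anti-symmetric under intensity inversion, E(1-u) = 1-E(u).  Without
    # this the histogram discretisation breaks the polarity equivariance
    # the rest of the pipeline maintains.
    u = gray / 255.0
    eq_pos = exposure.equalize_adapthist(u, kernel_size=kernel, clip_limit=clahe_clip)
    eq_neg = exposure.equalize_adapthist(1.0 - u, kernel_size=kernel, clip_limit=clahe_clip)
    eq = 0.5 * (eq_pos + 1.0 - eq_neg)
    stretched = exposure.rescale_intensity(eq, out_range=(0.0, 1.0))
    sharp = filters.unsharp_mask(stretched, radius=sharpen_radius, amount=sharpen_amount)
    return np.clip(np.round(sharp * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# 2. binarisation
# ---------------------------------------------------------------------------

def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over integer cut points, smallest-t tie-break.

    Returns the ``t`` in [0, 255] maximising the between-class variance of
    the partition {<= t} / {> t}.  Constant images are degenerate.
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("Otsu threshold undefined for a constant image")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                   # pixels <= t
    sum0 = np.cumsum(hist * levels)
    mu_total = sum0[-1] / total
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum0[-1] - sum0) / w1
        sigma_b = w0 / total * w1 / total * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -1.0)
    # argmax takes the first maximum -> smallest-t tie-break
    return int(np.argmax(sigma_b))


def binarize(gray: np.ndarray) -> np.ndarray:
    """Binarise at the Otsu threshold, foreground = the minority class.

    The stomate occupies a minority of a bounding-box patch while the
    epidermal background dominates, so the smaller of the two Otsu classes
    is the structure of interest whichever side of the threshold it falls
    on.  The rule is symmetric under intensity inversion: inverting the
    patch leaves the foreground pixel set unchanged, which is what makes
    the downstream polarity call (peak vs valley) the *only* thing that
    flips on an inverted image.
    """
    gray = np.asarray(gray)
    t = otsu_threshold(gray)
    dark = gray <= t
    if int(dark.sum()) * 2 > dark.size:
        return ~dark
    return dark


# ---------------------------------------------------------------------------
# 3-4. region filtering and selection
# ---------------------------------------------------------------------------

def filter_regions(binary: np.ndarray, min_area_px: int = PoreConfig.min_area_px) -> np.ndarray:
    """Remove 8-connected components with area <= ``min_area_px``.

    Dust particles and air bubbles produce small spurious regions; a
    stomate is assumed strictly larger than the cutoff (a component of
    exactly the cutoff area is removed).
    """
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return binary.copy()
    areas = np.bincount(labels.ravel())
    keep = areas > min_area_px
    keep[0] = False
    return keep[labels]


def select_stomate_region(
    binary: np.ndarray,
    patch_center: tuple[float, float] | None = None,
    central_fraction: float = PoreConfig.central_fraction,
) -> RegionMask | None:
    """Pick the stomate component: largest region with a central centroid.

    Only components whose centroid falls inside the central box of side
    ``central_fraction`` x patch side qualify (shapes hugging the patch
    edge are detector false positives).  Components spanning two opposite
    patch borders are excluded outright: a stomate fits inside its patch,
    so anything crossing it end to end is a vein or cell-wall band.  Ties
    on area break toward the centroid closest to the patch centre.
    Returns ``None`` when nothing qualifies (a no-detection, not an
    error).
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if patch_center is None:
        patch_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    half_h = central_fraction * h / 2.0
    half_w = central_fraction * w / 2.0

    binary = _split_spanning_bands(binary, patch_center, half_h / 2.5, half_w / 2.5)
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    best: tuple[float, float, int] | None = None  # (-area, distance, label)
    for lbl in range(1, n + 1):
        rows, cols = np.nonzero(labels == lbl)
        cy, cx = rows.mean(), cols.mean()
        if abs(cy - patch_center[0]) > half_h or abs(cx - patch_center[1]) > half_w:
            continue
        d = float(np.hypot(cy - patch_center[0], cx - patch_center[1]))
        key = (-float(len(rows)), d, lbl)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    # Fill the interior cavity: when the pore thresholds to the opposite
    # class the raw component is only the guard-cell annulus, but the mask
    # should stand for the whole stomate.  Only holes centred very close
    # to the patch centre qualify — a background pocket enclosed between
    # the stomate and attached wall fragments is offset by at least the
    # minor semi-axis, and filling it would drag the centroid off the pore.
    hole_h, hole_w = half_h / 2.5, half_w / 2.5
    mask = _fill_central_holes(labels == best[2], patch_center, hole_h, hole_w)
    # Thin wall tendrils that survive thresholding are detached by a small
    # opening; only the largest surviving piece is kept.
    opened = ndi.binary_opening(mask, structure=_disk(2))
    if opened.any():
        opened = _largest_component(opened)
        mask = _fill_central_holes(opened, patch_center, hole_h, hole_w)
    # Wider wall bands need a stronger cut: erode by a radius scaled to the
    # mask's minor-axis spread, keep only the core that remains, and grow
    # it back within the original mask.  The elliptical body (half-width =
    # the minor semi-axis) survives; anything thinner is severed.
    rows, cols = np.nonzero(mask)
    radius = int(np.clip(round(0.6 * _axis_lengths(rows, cols)[1]), 2, 7))
    eroded = ndi.binary_erosion(mask, structure=_disk(radius))
    if eroded.any():
        core = ndi.binary_dilation(
            _largest_component(eroded), structure=_disk(radius)
        ) & mask
        mask = _fill_central_holes(core, patch_center, hole_h, hole_w)
    # Stomata are elliptical; wall clutter that survives the opening is
    # shaved off by trimming to the mask's own moment-equivalent ellipse
    # (slightly inflated) and refitting, which recentres the fit on the
    # elliptical body.
    for _ in range(3):
        # the trim ellipse is anchored halfway between the mask centroid
        # and the patch centre: the stomate sits near the centre of its
        # detection box, so pulling the fit that way sheds one-sided
        # clutter that the moments alone would follow
        anchor = (
            0.5 * (float(np.nonzero(mask)[0].mean()) + patch_center[0]),
            0.5 * (float(np.nonzero(mask)[1].mean()) + patch_center[1]),
        )
        trimmed = mask & _moment_ellipse(mask, scale=1.15, center=anchor)
        if not trimmed.any():
            break
        trimmed = _fill_central_holes(
            _largest_component(trimmed), patch_center, hole_h, hole_w
        )
        if trimmed.sum() == mask.sum():
            break
        mask = trimmed
    # The opening and trimming shave a sliver off the component's own
    # boundary (e.g. the corners of an angular region).  Restore original
    # pixels immediately adjacent to the surviving body; detached clutter
    # lies further away and stays removed.
    base = _fill_central_holes(labels == best[2], patch_center, hole_h, hole_w)
    mask = _fill_central_holes(
        ndi.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool)) & base,
        patch_center, hole_h, hole_w,
    )
    # A stomate fits strictly inside its patch; if even the cleaned mask
    # still runs from one border to the opposite one, what was selected is
    # a vein or wall band, not a stomate.
    rows, cols = np.nonzero(mask)
    spans_rows = rows.min() == 0 and rows.max() == h - 1
    spans_cols = cols.min() == 0 and cols.max() == w - 1
    if spans_rows or spans_cols:
        return None
    return RegionMask.from_mask(mask)


def _split_spanning_bands(
    binary: np.ndarray,
    patch_center: tuple[float, float],
    hole_h: float,
    hole_w: float,
    radius: int = 5,
) -> np.ndarray:
    """Break up components that run from one patch border to the other.

    A vein or cell-wall band crossing the patch can share a component
    with the stomate it touches.  The central cavity is filled first so
    the stomate becomes a solid body, then an erosion erases the thin
    band while that body survives as a core; growing the cores back
    restores the stomate without the band.  Compact components are left
    untouched.
    """
    h, w = binary.shape
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    out = binary.copy()
    for lbl in range(1, n + 1):
        comp = labels == lbl
        rows, cols = np.nonzero(comp)
        spans_rows = rows.min() == 0 and rows.max() == h - 1
        spans_cols = cols.min() == 0 and cols.max() == w - 1
        if not (spans_rows or spans_cols):
            continue
        filled = _fill_central_holes(comp, patch_center, hole_h, hole_w)
        cores = ndi.binary_erosion(filled, structure=_disk(radius))
        out[comp] = False
        if cores.any():
            out |= ndi.binary_dilation(cores, structure=_disk(radius)) & filled
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return labels == int(np.argmax(areas))


def _moment_ellipse(
    mask: np.ndarray,
    scale: float = 1.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """The mask's moment-equivalent ellipse, optionally inflated.

    ``center`` overrides the ellipse centre (axes and orientation still
    come from the mask's moments).
    """
    rows, cols = np.nonzero(mask)
    cy, cx = (rows.mean(), cols.mean()) if center is None else center
    theta = math.radians(_orientation_deg(rows, cols))
    major_std, minor_std = _axis_lengths(rows, cols)
    a = max(2.0 * major_std, 1.0) * scale
    b = max(2.0 * minor_std, 1.0) * scale
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    dx = cc - cx
    dy = rr - cy
    xp = math.cos(theta) * dx + math.sin(theta) * dy
    yp = -math.sin(theta) * dx + math.cos(theta) * dy
    return (xp / a) ** 2 + (yp / b) ** 2 <= 1.0


def _fill_central_holes(
    mask: np.ndarray,
    patch_center: tuple[float, float],
    half_h: float,
    half_w: float,
) -> np.ndarray:
    """Fill enclosed background whose centroid lies in the central window."""
    filled = ndi.binary_fill_holes(mask)
    holes, n = ndi.label(filled & ~mask, structure=np.ones((3, 3), dtype=int))
    out = mask.copy()
    for lbl in range(1, n + 1):
        sel = holes == lbl
        rows, cols = np.nonzero(sel)
        if (
            abs(rows.mean() - patch_center[0]) <= half_h
            and abs(cols.mean() - patch_center[1]) <= half_w
        ):
            out[sel] = True
    return out


# ---------------------------------------------------------------------------
# 5. alignment
# ---------------------------------------------------------------------------

def _ellipse_fit_residual(region: RegionMask) -> float:
    """1 - IoU between the mask and its own moment-equivalent ellipse.

    A clean stomate mask fits its moment ellipse closely; a mask merged
    with an adjacent structure does not.
    """
    ell = _moment_ellipse(region.mask, scale=1.0)
    union = int(np.logical_or(region.mask, ell).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(region.mask, ell).sum())
    return 1.0 - inter / union


def _split_merged_region(
    gray: np.ndarray,
    binary: np.ndarray,
    region: RegionMask | None,
    patch_center: tuple[float, float],
    cfg: PoreConfig,
    residual_limit: float = 0.12,
) -> RegionMask | None:
    """Re-threshold the foreground when the selected region is not ellipse-like.

    The global Otsu split can lump the stomate together with an adjacent
    structure of similar tone (e.g. a dark epidermal cell).  When the
    selected region fits its own moment ellipse poorly, a second Otsu
    threshold computed over the foreground pixels alone separates the two
    intensity populations; a sub-population's central region replaces the
    original only when it fits at least twice as well while keeping a
    substantial share of the area (so a healthy mask is never collapsed
    onto just its pore).  The rule is symmetric under intensity inversion
    (both sub-classes are tried).
    """
    if region is None:
        return None
    original_residual = _ellipse_fit_residual(region)
    if original_residual <= residual_limit:
        return region
    values = np.asarray(gray)[np.asarray(binary, dtype=bool)]
    try:
        t2 = otsu_threshold(values)
    except DegenerateInputError:
        return region
    best = region
    best_residual = original_residual
    for sub in (binary & (gray <= t2), binary & (gray > t2)):
        filtered = filter_regions(sub, cfg.min_area_px)
        candidate = select_stomate_region(filtered, patch_center, cfg.central_fraction)
        if candidate is None:
            continue
        residual = _ellipse_fit_residual(candidate)
        if (
            residual < 0.5 * original_residual
            and candidate.area_px >= 0.3 * region.area_px
            and residual < best_residual
        ):
            best, best_residual = candidate, residual
    return best


def align_to_major_axis(
    gray: np.ndarray,
    region: RegionMask,
    min_axis_ratio: float = PoreConfig.min_axis_ratio,
) -> tuple[np.ndarray, RegionMask, float]:
    """Rotate image and mask so the stomate's major axis lies horizontal.

    The canvas is expanded (no content is cropped); the gray image is
    resampled bilinearly and the mask with nearest neighbour.  A nearly
    circular mask (axis ratio < ``min_axis_ratio``) has no meaningful
    orientation, so rotation is skipped.
    """
    angle = region.orientation
    if region.axis_ratio < min_axis_ratio:
        return np.asarray(gray, dtype=np.float64), region, 0.0
    # positive orientation tilts the major axis toward +rows (down-screen);
    # skimage's rotate(angle) cancels exactly that tilt.
    rot_gray = transform.rotate(
        np.asarray(gray, dtype=np.float64), angle, resize=True, order=1,
        mode="constant", cval=float(np.median(gray)), preserve_range=True,
    )
    rot_mask = transform.rotate(
        region.mask.astype(np.float64), angle, resize=True, order=0,
        mode="constant", cval=0.0, preserve_range=True,
    ) > 0.5
    if not rot_mask.any():
        return np.asarray(gray, dtype=np.float64), region, 0.0
    return rot_gray, RegionMask.from_mask(rot_mask), float(angle)


def _expanded_rotation(
    shape: tuple[int, int], angle: float
) -> transform.SimilarityTransform:
    """The map (rotated-canvas coords -> original coords) used by a
    centre rotation with canvas expansion, mirroring ``transform.rotate``
    with ``resize=True``."""
    rows, cols = shape
    center = np.array((cols, rows)) / 2.0 - 0.5
    tform = (
        transform.SimilarityTransform(translation=-center)
        + transform.SimilarityTransform(rotation=np.deg2rad(angle))
        + transform.SimilarityTransform(translation=center)
    )
    corners = np.array(
        [[0, 0], [0, rows - 1], [cols - 1, rows - 1], [cols - 1, 0]], dtype=float
    )
    corners = tform.inverse(corners)
    minc, minr = corners[:, 0].min(), corners[:, 1].min()
    return transform.SimilarityTransform(translation=(minc, minr)) + tform


def rotate_back_mask(
    mask: np.ndarray, angle: float, original_shape: tuple[int, int]
) -> np.ndarray:
    """Undo :func:`align_to_major_axis` for a mask in the rotated frame.

    The forward rotation's coordinate map is inverted exactly, so the
    returned mask is aligned with the original patch to nearest-neighbour
    accuracy (no cumulative shift from a second resampling).
    """
    if angle == 0.0 and mask.shape == tuple(original_shape):
        return np.asarray(mask, dtype=bool)
    tform = _expanded_rotation(original_shape, angle)
    back = transform.warp(
        np.asarray(mask, dtype=np.float64),
        inverse_map=tform.inverse,
        output_shape=original_shape,
        order=0,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return back > 0.5


# ---------------------------------------------------------------------------
# 6-7. cross-section analysis
# ---------------------------------------------------------------------------

def cross_section(
    rot_gray: np.ndarray,
    rot_region: RegionMask,
    smooth_window: int = PoreConfig.smooth_window,
    prominence_frac: float = PoreConfig.prominence_frac,
) -> CrossSectionProfile | None:
    """Intensity profile along the column through the mask centroid.

    The trace is clipped to the mask's vertical extent padded by 2 px,
    smoothed by a centred moving average, and its strict local extrema
    with prominence >= ``prominence_frac`` of the profile range are
    recorded.  Returns ``None`` when the trace is shorter than 5 samples.
    """
    h = rot_gray.shape[0]
    cy, cx = rot_region.centroid
    col = int(round(cx))
    col = min(max(col, 0), rot_gray.shape[1] - 1)
    rows_in_mask = np.nonzero(rot_region.mask.any(axis=1))[0]
    r0 = max(int(rows_in_mask[0]) - 2, 0)
    r1 = min(int(rows_in_mask[-1]) + 2, h - 1)
    raw = np.asarray(rot_gray, dtype=np.float64)[r0 : r1 + 1, col]
    if raw.size < 5:
        return None
    smoothed = ndi.uniform_filter1d(raw, size=smooth_window, mode="nearest")
    prom = prominence_frac * float(smoothed.max() - smoothed.min())
    peaks, _ = find_peaks(smoothed, prominence=max(prom, 1e-9))
    valleys, _ = find_peaks(-smoothed, prominence=max(prom, 1e-9))
    centroid_index = int(round(cy)) - r0
    centroid_index = min(max(centroid_index, 0), raw.size - 1)
    return CrossSectionProfile(
        values=smoothed,
        raw_values=raw,
        peaks=[int(p) for p in peaks],
        valleys=[int(v) for v in valleys],
        centroid_index=centroid_index,
        row_start=r0,
        col=col,
    )


def find_pore_center(
    profile: CrossSectionProfile, tie_band: int = 3
) -> tuple[int, Polarity] | None:
    """The extremum nearest the centroid is the pore centre.

    A peak means the pore is lighter than its surroundings, a valley that
    it is darker.  Distances are compared with a small slack: the mask
    centroid is only accurate to a few pixels, so among extrema within
    ``tie_band`` pixels of the nearest one the most prominent wins (an
    exact residual tie goes to the valley).  Returns ``None`` when the
    profile has no extrema.
    """
    candidates: list[tuple[int, float, str]] = []
    if profile.peaks:
        proms = peak_prominences(profile.values, profile.peaks)[0]
        candidates += [(i, float(p), "light") for i, p in zip(profile.peaks, proms)]
    if profile.valleys:
        proms = peak_prominences(-profile.values, profile.valleys)[0]
        candidates += [(i, float(p), "dark") for i, p in zip(profile.valleys, proms)]
    if not candidates:
        return None
    d_min = min(abs(c[0] - profile.centroid_index) for c in candidates)
    near = [c for c in candidates if abs(c[0] - profile.centroid_index) <= d_min + tie_band]
    # most prominent within the band; residual ties: nearer, then valley
    near.sort(
        key=lambda c: (-c[1], abs(c[0] - profile.centroid_index), c[2] == "light")
    )
    idx, prominence, polarity = near[0]
    profile.center_index = idx
    profile.polarity = polarity  # type: ignore[assignment]
    profile.center_prominence = prominence
    return idx, polarity  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# 8. region growing
# ---------------------------------------------------------------------------

def grow_pore(
    rot_gray: np.ndarray,
    seed: tuple[int, int],
    tolerance: float,
) -> np.ndarray:
    """Flood fill from the pore centre under 8-connectivity.

    A pixel joins the pore iff its intensity differs from the seed's by at
    most ``tolerance`` and it is connected to the seed through accepted
    pixels.
    """
    gray = np.asarray(rot_gray, dtype=np.float64)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < gray.shape[0] and 0 <= c < gray.shape[1]):
        raise ValueError(f"seed {seed} outside image {gray.shape}")
    return segmentation.flood(gray, (r, c), tolerance=tolerance, connectivity=2)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def estimate_pore(patch: PorePatch, config: PoreConfig | None = None) -> PoreEstimate:
    """Run the full pore-area pipeline on one stomate patch.

    Every failure path becomes a status: ``no_detection`` when a stage
    finds nothing to measure (the fate of detector false positives with no
    discernible pore), ``rejected`` with a reason when a sanity check
    fails.  Accepted estimates report the pore mask in the original patch
    frame and the area both in pixels and um^2.
    """
    cfg = config or PoreConfig()
    try:
        gray = enhance(
            patch,
            clahe_clip=cfg.clahe_clip,
            clahe_tiles=cfg.clahe_tiles,
            sharpen_amount=cfg.sharpen_amount,
            sharpen_radius=cfg.sharpen_radius,
        )
    except ValueError:
        return PoreEstimate(STATUS_NO_DETECTION, reason="unusable patch")

    try:
        binary = binarize(gray)
    except DegenerateInputError:
        return PoreEstimate(STATUS_NO_DETECTION, reason="constant intensity patch")

    filtered = filter_regions(binary, cfg.min_area_px)
    region = select_stomate_region(filtered, patch.center, cfg.central_fraction)
    region = _split_merged_region(gray, binary, region, patch.center, cfg)
    if region is None:
        return PoreEstimate(STATUS_NO_DETECTION, reason="no central region above size cutoff")

    rot_gray, rot_region, angle = align_to_major_axis(gray, region, cfg.min_axis_ratio)

    profile = cross_section(rot_gray, rot_region, cfg.smooth_window, cfg.prominence_frac)
    if profile is None:
        return PoreEstimate(STATUS_NO_DETECTION, reason="cross-section too short",
                            orientation=angle, region=region)

    # a cross-section oscillating through many comparable extrema has no
    # single discernible pore (noise or texture, not a stomate)
    if len(profile.peaks) + len(profile.valleys) > cfg.max_extrema:
        return PoreEstimate(STATUS_NO_DETECTION, reason="no single discernible pore",
                            orientation=angle, region=region)

    center = find_pore_center(profile)
    if center is None:
        return PoreEstimate(STATUS_NO_DETECTION, reason="no extrema on cross-section",
                            orientation=angle, region=region)
    center_index, polarity = center

    # map the pore-centre seed from the rotated canvas back to the patch
    # frame and grow there: the flood fill then runs on unresampled pixels
    # and the pore mask needs no back-rotation
    seed_rot = (profile.row_start + center_index, profile.col)
    if angle != 0.0:
        tform = _expanded_rotation(gray.shape, angle)
        x, y = tform(np.array([[seed_rot[1], seed_rot[0]]], dtype=float))[0]
        seed = (int(round(y)), int(round(x)))
    else:
        seed = seed_rot
    seed = (
        min(max(seed[0], 0), gray.shape[0] - 1),
        min(max(seed[1], 0), gray.shape[1] - 1),
    )
    # half-prominence growing: the pore boundary is taken at the contour
    # halfway between the pore-centre extremum and its shoulder, which
    # adapts to the local contrast and so tolerates defocus blur
    tolerance = cfg.grow_tolerance_frac * profile.center_prominence
    pore_mask = grow_pore(gray, seed, tolerance)

    # sanity checks, in increasing order of subtlety
    border = np.zeros_like(pore_mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_frac = float(pore_mask[border].sum()) / float(border.sum())
    if border_frac >= cfg.border_reject_frac:
        return PoreEstimate(STATUS_REJECTED, polarity=polarity, orientation=angle,
                            region=region, reason="pore floods the patch border")

    # the segmented stomate region may be only the guard-cell annulus (its
    # interior thresholds to the other class), so containment and area
    # checks use the hole-filled region
    filled_region = ndi.binary_fill_holes(region.mask)
    area_px = int(pore_mask.sum())
    if area_px < cfg.min_pore_px:
        return PoreEstimate(STATUS_NO_DETECTION, polarity=polarity, orientation=angle,
                            region=region, reason="pore below resolution limit")
    if area_px > int(filled_region.sum()):
        return PoreEstimate(STATUS_REJECTED, polarity=polarity, orientation=angle,
                            region=region, reason="pore larger than stomate mask")

    prows, pcols = np.nonzero(pore_mask)
    pcy, pcx = int(round(prows.mean())), int(round(pcols.mean()))
    if not filled_region[min(pcy, filled_region.shape[0] - 1),
                         min(pcx, filled_region.shape[1] - 1)]:
        return PoreEstimate(STATUS_REJECTED, polarity=polarity, orientation=angle,
                            region=region, reason="pore centroid outside stomate mask")
    return PoreEstimate(
        status=STATUS_ACCEPTED,
        pore_mask=pore_mask,
        area_px=area_px,
        area_um2=area_px * patch.pixel_scale**2,
        polarity=polarity,
        orientation=angle,
        region=region,
    )


def save_debug_bundle(
    patch: PorePatch, out_dir, config: PoreConfig | None = None
) -> "PoreEstimate":
    """Write per-stage images for one patch and return its estimate.

    Produces ``input/enhanced/binary/region/pore_overlay`` PNGs plus the
    cross-section profile as CSV (and as a plot when matplotlib is
    importable) — a visual audit trail of the algorithm's stages.
    """
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or PoreConfig()

    gray8 = np.clip(np.round(to_gray(patch.pixels)), 0, 255).astype(np.uint8)
    iio.imwrite(out / "input.png", gray8)
    enhanced = enhance(patch, cfg.clahe_clip, cfg.clahe_tiles,
                       cfg.sharpen_amount, cfg.sharpen_radius)
    iio.imwrite(out / "enhanced.png", enhanced)
    try:
        binary = binarize(enhanced)
        iio.imwrite(out / "binary.png", binary.astype(np.uint8) * 255)
    except DegenerateInputError:
        binary = None

    est = estimate_pore(patch, cfg)
    if est.region is not None:
        iio.imwrite(out / "region.png", est.region.mask.astype(np.uint8) * 255)
        rot_gray, rot_region, angle = align_to_major_axis(
            enhanced, est.region, cfg.min_axis_ratio
        )
        profile = cross_section(rot_gray, rot_region,
                                cfg.smooth_window, cfg.prominence_frac)
        if profile is not None:
            with open(out / "profile.csv", "w", encoding="utf-8") as fh:
                fh.write("index,raw,smoothed\n")
                for i, (r, s) in enumerate(zip(profile.raw_values, profile.values)):
                    fh.write(f"{i},{r!r},{s!r}\n")
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(5, 3))
                ax.plot(profile.raw_values, label="raw")
                ax.plot(profile.values, label="smoothed")
                ax.axvline(profile.centroid_index, ls="--", c="gray", label="centroid")
                ax.set_xlabel("position along cross-section (px)")
                ax.set_ylabel("intensity")
                ax.legend(fontsize=8)
                fig.tight_layout()
                fig.savefig(out / "profile.png", dpi=100)
                plt.close(fig)
            except ImportError:
                pass
    if est.accepted:
        overlay = np.stack([gray8] * 3, axis=-1)
        overlay[est.pore_mask] = (255, 64, 64)
        iio.imwrite(out / "pore_overlay.png", overlay)
    with open(out / "estimate.txt", "w", encoding="utf-8") as fh:
        fh.write(
            f"status={est.status}\nreason={est.reason}\npolarity={est.polarity}\n"
            f"area_px={est.area_px}\narea_um2={est.area_um2!r}\n"
            f"orientation_deg={est.orientation!r}\n"
        )
    return est


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
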