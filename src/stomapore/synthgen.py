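"""Seeded synthetic micrograph scenes with per-stomate ground truth.

The generator emulates the phenomenology of brightfield leaf-imprint
scans: elliptical stomata (a guard-cell annulus around a lens-shaped
central pore that renders darker or lighter than its surroundings),
elongated dark vein strokes, a low-contrast polygonal epidermal-cell
background, small dust/bubble artifacts, spatially varying blur, and
additive pixel noise.  Noise and blur are applied after the ground-truth
masks are rasterized, so the masks stay exact.

Every scene is a pure function of its :class:`SceneSpec` (including the
seed), which makes the generator usable as a test oracle for the
detection and pore-measurement stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .detection import LabeledPatch
from .imaging_io import DEFAULT_PIXEL_SCALE, ScanImage
from .pore_measure import PorePatch


class PlacementError(RuntimeError):
    """Raised when stomata cannot be placed without overlap."""


class GenerationError(RuntimeError):
    """Raised when a training-patch class cannot be sampled."""


@dataclass
class IntensityLevels:
    """Mean 8-bit intensities of the rendered structures."""

    background: int = 180
    guard: int = 140
    inner: int = 160       # guard-cell interior surrounding the pore
    pore_dark: int = 70
    pore_light: int = 230
    vein: int = 120
    wall_drop: int = 15    # darkening of epidermal cell walls


@dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    ``axis_len_range`` is the full major-axis length of the guard-cell
    ellipse in pixels; ``aspect_range`` is the minor/major ratio.
    ``polarity_mix`` is the fraction of stomata rendered with a light
    pore.  Densities are per megapixel.
    """

    height: int = 768
    width: int = 768
    n_stomata: int = 20
    axis_len_range: tuple[float, float] = (30.0, 60.0)
    aspect_range: tuple[float, float] = (0.4, 0.6)
    polarity_mix: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    vein_density: float = 4.0
    artifact_rate: float = 20.0
    background_cell_scale: float = 40.0
    noise_sigma: float = 3.0
    pore_scale: float = 0.5       # pore lens extent relative to the inner axes
    inner_scale: float = 0.75     # inner ellipse relative to the outer axes
    levels: IntensityLevels = field(default_factory=IntensityLevels)
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("axis_len_range", "aspect_range", "blur_sigma_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must satisfy lo <= hi, got {(lo, hi)}")
        if self.n_stomata < 0:
            raise ValueError("n_stomata must be >= 0")
        if not 0.0 <= self.polarity_mix <= 1.0:
            raise ValueError("polarity_mix must lie in [0, 1]")

    def clean(self) -> "SceneSpec":
        """A copy with blur, noise, veins and artifacts switched off."""
        return replace(
            self, blur_sigma_range=(0.0, 0.0), noise_sigma=0.0,
            vein_density=0.0, artifact_rate=0.0,
        )


@dataclass
class StomateGroundTruth:
    """Geometry and exact masks of one rendered stomate.

    The masks are stored over the bounding-box extent; ``box`` locates
    them in scene coordinates (half-open).
    """

    center: tuple[float, float]
    major_len: float
    minor_len: float
    angle: float                      # degrees from horizontal
    polarity: Literal["dark", "light"]
    box: tuple[int, int, int, int]
    pore_mask: np.ndarray
    stomate_mask: np.ndarray

    @property
    def pore_area_px(self) -> int:
        return int(self.pore_mask.sum())


@dataclass
class GroundTruthScene:
    image: ScanImage
    stomata: list[StomateGroundTruth]
    stomate_mask: np.ndarray
    vein_mask: np.ndarray
    spec: SceneSpec


# ---------------------------------------------------------------------------
# primitive renderers
# ---------------------------------------------------------------------------

def _local_coords(shape, center, angle_deg):
    """Rotated local coordinates (x' along major, y' along minor)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rows - center[0]
    dx = cols - center[1]
    th = math.radians(angle_deg)
    xp = math.cos(th) * dx + math.sin(th) * dy
    yp = -math.sin(th) * dx + math.cos(th) * dy
    return xp, yp


def lens_area(half_len: float, b: float, delta: float) -> float:
    """Analytic area of the lens of two ellipses offset by +-delta.

    Each ellipse has semi-axes (A, b) with A chosen so the lens half-length
    along the major axis is ``half_len``; the centres sit at y = +-delta.
    Scaling y by A/b maps both ellipses onto circles of radius A, where the
    circle-circle lens area is closed-form.
    """
    if delta >= b:
        return 0.0
    a_ell = half_len / math.sqrt(1.0 - (delta / b) ** 2)
    r = a_ell
    d = 2.0 * delta * a_ell / b
    if d >= 2.0 * r:
        return 0.0
    area_circ = 2.0 * r * r * math.acos(d / (2.0 * r)) - (d / 2.0) * math.sqrt(
        4.0 * r * r - d * d
    )
    return area_circ * (b / a_ell)


def render_stomate(
    canvas: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    polarity: Literal["dark", "light"],
    levels: IntensityLevels | None = None,
    pore_scale: float = 0.5,
    inner_scale: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one stomate in place; return (canvas, pore mask, stomate mask).

    ``axes`` are the semi-axes (a, b) of the outer guard-cell ellipse and
    ``angle`` the major-axis angle from horizontal in degrees.  The
    guard-cell annulus (outer minus inner ellipse) is drawn at the guard
    level, the inner ellipse at the inner level, and the pore — the lens
    formed by two ellipses offset along the minor axis — at the dark or
    light pore level.  Masks are returned exactly as rasterized.
    """
    levels = levels or IntensityLevels()
    a, b = axes
    cy, cx = center
    reach = a + 2.0
    if cy - reach < 0 or cx - reach < 0 or cy + reach > canvas.shape[0] or cx + reach > canvas.shape[1]:
        raise ValueError(f"stomate at {center} with semi-major {a} exceeds canvas {canvas.shape}")

    r0, r1 = int(cy - reach), int(math.ceil(cy + reach)) + 1
    c0, c1 = int(cx - reach), int(math.ceil(cx + reach)) + 1
    xp, yp = _local_coords((r1 - r0, c1 - c0), (cy - r0, cx - c0), angle)

    outer = (xp / a) ** 2 + (yp / b) ** 2 <= 1.0
    ai, bi = inner_scale * a, inner_scale * b
    inner = (xp / ai) ** 2 + (yp / bi) ** 2 <= 1.0

    # pore lens: two ellipses with centres at y' = +-delta, delta = bi/2,
    # sized for half-length pore_scale*ai and half-width pore_scale*bi
    delta = (1.0 - pore_scale) * bi
    b_ell = bi
    half_len = pore_scale * ai
    a_ell = half_len / math.sqrt(1.0 - (delta / b_ell) ** 2)
    e1 = (xp / a_ell) ** 2 + ((yp - delta) / b_ell) ** 2 <= 1.0
    e2 = (xp / a_ell) ** 2 + ((yp + delta) / b_ell) ** 2 <= 1.0
    pore = e1 & e2

    sub = canvas[r0:r1, c0:c1]
    sub[outer & ~inner] = levels.guard
    sub[inner & ~pore] = levels.inner
    sub[pore] = levels.pore_dark if polarity == "dark" else levels.pore_light

    pore_full = np.zeros(canvas.shape, dtype=bool)
    stomate_full = np.zeros(canvas.shape, dtype=bool)
    pore_full[r0:r1, c0:c1] = pore
    stomate_full[r0:r1, c0:c1] = outer
    return canvas, pore_full, stomate_full


def _render_background(shape, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-contrast polygonal (Voronoi) epidermal-cell texture."""
    h, w = shape
    lv = spec.levels
    n_cells = max(int(h * w / spec.background_cell_scale**2), 4)
    pts = rng.uniform([0, 0], [h, w], size=(n_cells, 2))
    tree = cKDTree(pts)
    rows, cols = np.mgrid[0:h, 0:w]
    grid = np.stack([rows.ravel(), cols.ravel()], axis=1)
    dists, idx = tree.query(grid, k=2)
    cell_tone = rng.normal(lv.background, 4.0, size=n_cells)
    img = cell_tone[idx[:, 0]].reshape(h, w)
    walls = (dists[:, 1] - dists[:, 0]).reshape(h, w) < 1.5
    img[walls] -= lv.wall_drop
    return img


def _render_veins(canvas: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Dark curved strokes crossing the scene; returns the vein mask."""
    h, w = canvas.shape
    mask = np.zeros((h, w), dtype=bool)
    # at least one vein when veins are requested at all, so every scene
    # can supply all three training classes
    n_veins = max(int(rng.poisson(spec.vein_density * h * w / 1e6)), 1)
    for _ in range(n_veins):
        # anchor in the interior, walk outward both ways with gentle
        # curvature, so every vein crosses the usable central region
        r0 = float(rng.uniform(0.2 * h, 0.8 * h))
        c0 = float(rng.uniform(0.2 * w, 0.8 * w))
        heading0 = float(rng.uniform(0.0, math.pi))
        thickness = rng.uniform(2.0, 5.0)
        curvature = rng.normal(0.0, 0.01)
        t = int(math.ceil(thickness))
        for direction in (1.0, -1.0):
            r, c, heading = r0, c0, heading0
            for _ in range(h + w):
                rr, cc = int(round(r)), int(round(c))
                if not (0 <= rr < h and 0 <= cc < w):
                    break
                mask[max(rr - t, 0) : rr + t + 1, max(cc - t, 0) : cc + t + 1] |= True
                heading += curvature + rng.normal(0.0, 0.02)
                r += direction * math.sin(heading)
                c += direction * math.cos(heading)
    canvas[mask] = spec.levels.vein + 0.0
    return mask


def _render_artifacts(canvas: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    """Small dust specks and air-bubble rings (sub-cutoff area)."""
    h, w = canvas.shape
    n = rng.poisson(spec.artifact_rate * h * w / 1e6)
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        radius = rng.uniform(1.5, 3.5)
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        if rng.random() < 0.5:  # dust: filled dark speck
            canvas[d2 <= radius**2] = rng.uniform(50, 90)
        else:  # bubble: dark ring, bright core
            canvas[d2 <= radius**2] = 230.0
            ring = (d2 <= (radius + 1.2) ** 2) & (d2 > radius**2)
            canvas[ring] = 90.0


def _spatially_varying_blur(
    img: np.ndarray, sigma_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Blend Gaussian blurs under a smooth random sigma field.

    Emulates the focus variation across a slide scan: sigma is drawn on a
    coarse grid, upsampled bilinearly, and the image interpolated between
    blur anchors pixel-wise.
    """
    lo, hi = sigma_range
    if hi <= 0.0:
        return img
    field_lowres = rng.uniform(lo, hi, size=(4, 4))
    zoom = (img.shape[0] / 4.0, img.shape[1] / 4.0)
    sigma_field = ndi.zoom(field_lowres, zoom, order=1)[: img.shape[0], : img.shape[1]]
    anchors = np.linspace(lo, hi, 3) if hi > lo else np.array([lo])
    stack = [ndi.gaussian_filter(img, s) if s > 0 else img for s in anchors]
    if len(anchors) == 1:
        return stack[0]
    out = np.empty_like(img)
    pos = np.clip((sigma_field - lo) / (hi - lo), 0.0, 1.0) * (len(anchors) - 1)
    low = np.clip(pos.astype(int), 0, len(anchors) - 2)
    frac = pos - low
    for i in range(len(anchors) - 1):
        sel = low == i
        out[sel] = (1 - frac[sel]) * stack[i][sel] + frac[sel] * stack[i + 1][sel]
    return out


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _place_stomata(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping centres, axes and angles."""
    placements = []
    margin = spec.axis_len_range[1] / 2.0 + 4.0
    if spec.height <= 2 * margin or spec.width <= 2 * margin:
        if spec.n_stomata > 0:
            raise PlacementError("canvas too small for any stomate; enlarge the scene")
    attempts = 0
    max_attempts = 200 * max(spec.n_stomata, 1)
    while len(placements) < spec.n_stomata:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(placements)}/{spec.n_stomata} stomata; "
                "use a larger canvas or fewer stomata"
            )
        attempts += 1
        major = rng.uniform(*spec.axis_len_range)
        aspect = rng.uniform(*spec.aspect_range)
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        ok = True
        for (pcy, pcx, pmajor, *_rest) in placements:
            if math.hypot(cy - pcy, cx - pcx) < max(major, pmajor):
                ok = False
                break
        if ok:
            angle = rng.uniform(-90.0, 90.0)
            light = rng.random() < spec.polarity_mix
            placements.append((cy, cx, major, aspect, angle, light))
    return placements


def generate_scene(spec: SceneSpec) -> GroundTruthScene:
    """Render a complete scene with exact per-stomate ground truth."""
    rng = np.random.default_rng(spec.seed)
    canvas = _render_background((spec.height, spec.width), spec, rng)
    vein_mask = (
        _render_veins(canvas, spec, rng)
        if spec.vein_density > 0
        else np.zeros(canvas.shape, dtype=bool)
    )
    if spec.artifact_rate > 0:
        _render_artifacts(canvas, spec, rng)

    placements = _place_stomata(spec, rng)
    stomata: list[StomateGroundTruth] = []
    stomate_mask = np.zeros(canvas.shape, dtype=bool)
    for cy, cx, major, aspect, angle, light in placements:
        a, b = major / 2.0, major * aspect / 2.0
        polarity = "light" if light else "dark"
        _, pore_full, stom_full = render_stomate(
            canvas, (cy, cx), (a, b), angle, polarity,
            levels=spec.levels, pore_scale=spec.pore_scale, inner_scale=spec.inner_scale,
        )
        stomate_mask |= stom_full
        rows, cols = np.nonzero(stom_full)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        stomata.append(
            StomateGroundTruth(
                center=(cy, cx), major_len=major, minor_len=major * aspect,
                angle=angle, polarity=polarity, box=(r0, c0, r1, c1),
                pore_mask=pore_full[r0:r1, c0:c1].copy(),
                stomate_mask=stom_full[r0:r1, c0:c1].copy(),
            )
        )
        if not pore_full[r0:r1, c0:c1].any():
            raise AssertionError("rendered stomate has an empty pore mask")

    blurred = _spatially_varying_blur(canvas, spec.blur_sigma_range, rng)
    if spec.noise_sigma > 0:
        blurred = blurred + rng.normal(0.0, spec.noise_sigma, size=blurred.shape)
    pixels = np.clip(np.round(blurred), 0, 255).astype(np.uint8)
    image = ScanImage(pixels, pixel_scale=spec.pixel_scale, source_id=f"synth-{spec.seed}")
    return GroundTruthScene(image, stomata, stomate_mask, vein_mask, spec)


# ---------------------------------------------------------------------------
# derived products
# ---------------------------------------------------------------------------

def extract_patch(
    scene: GroundTruthScene, gt: StomateGroundTruth, margin: int = 12
) -> tuple[PorePatch, np.ndarray]:
    """Crop a pore-measurement patch around one stomate.

    Returns the patch and the true pore mask in patch coordinates.
    """
    h, w = scene.image.shape
    r0 = max(gt.box[0] - margin, 0)
    c0 = max(gt.box[1] - margin, 0)
    r1 = min(gt.box[2] + margin, h)
    c1 = min(gt.box[3] + margin, w)
    patch = PorePatch(
        scene.image.pixels[r0:r1, c0:c1].copy(),
        pixel_scale=scene.image.pixel_scale,
        source_id=scene.image.source_id,
    )
    true_pore = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    pr0, pc0 = gt.box[0] - r0, gt.box[1] - c0
    true_pore[pr0 : pr0 + gt.pore_mask.shape[0], pc0 : pc0 + gt.pore_mask.shape[1]] = gt.pore_mask
    return patch, true_pore


def ground_truth_boxes(scene: GroundTruthScene, padding: int = 4) -> list[tuple[int, int, int, int]]:
    h, w = scene.image.shape
    return [
        (max(gt.box[0] - padding, 0), max(gt.box[1] - padding, 0),
         min(gt.box[2] + padding, h), min(gt.box[3] + padding, w))
        for gt in scene.stomata
    ]


def make_training_patches(
    scene: GroundTruthScene,
    window_size: int,
    n_per_class: int,
    seed: int = 0,
    jitter: int | None = None,
) -> list[LabeledPatch]:
    """Sample window-sized labelled patches from a scene.

    Stomate patches are centred on ground-truth stomata with a small
    positional jitter (default an eighth of the window) so near-centred
    sliding windows are represented in training without teaching the
    classifier to fire far off-centre; vein patches are centred on vein
    pixels away from stomata; background patches contain no stomate or
    vein pixels at all.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.image.shape
    half = window_size // 2
    if jitter is None:
        jitter = window_size // 8
    if h < window_size or w < window_size:
        raise GenerationError("scene smaller than the window size")

    patches: list[LabeledPatch] = []

    def crop(cy: int, cx: int) -> np.ndarray | None:
        r0, c0 = cy - half, cx - half
        if r0 < 0 or c0 < 0 or r0 + window_size > h or c0 + window_size > w:
            return None
        return scene.image.pixels[r0 : r0 + window_size, c0 : c0 + window_size]

    # stomate class: jittered crops around true stomata
    if scene.stomata:
        count = 0
        tries = 0
        while count < n_per_class and tries < 100 * n_per_class:
            tries += 1
            gt = scene.stomata[int(rng.integers(len(scene.stomata)))]
            jr = int(rng.integers(-jitter, jitter + 1))
            jc = int(rng.integers(-jitter, jitter + 1))
            cy = int(round(gt.center[0])) + jr
            cx = int(round(gt.center[1])) + jc
            window = crop(cy, cx)
            if window is not None:
                patches.append(LabeledPatch(window.copy(), "stomate", center=(cy, cx)))
                count += 1
        if count < n_per_class:
            raise GenerationError("could not sample enough stomate patches")
    elif n_per_class > 0:
        raise GenerationError("scene contains no stomata")

    # vein class
    vein_ok = scene.vein_mask & ~ndi.binary_dilation(scene.stomate_mask, iterations=3)
    vr, vc = np.nonzero(vein_ok)
    inside = (vr >= half) & (vc >= half) & (vr < h - half) & (vc < w - half)
    vr, vc = vr[inside], vc[inside]
    if len(vr) == 0 and n_per_class > 0:
        raise GenerationError("scene contains no usable vein pixels")
    picks = rng.integers(len(vr), size=n_per_class)
    for i in picks:
        patches.append(
            LabeledPatch(crop(int(vr[i]), int(vc[i])).copy(), "vein", center=(int(vr[i]), int(vc[i])))
        )

    # background class: windows free of both masks
    forbidden = scene.stomate_mask | scene.vein_mask
    count = 0
    tries = 0
    while count < n_per_class and tries < 200 * n_per_class:
        tries += 1
        cy = int(rng.integers(half, h - half))
        cx = int(rng.integers(half, w - half))
        r0, c0 = cy - half, cx - half
        if forbidden[r0 : r0 + window_size, c0 : c0 + window_size].any():
            continue
        patches.append(LabeledPatch(crop(cy, cx).copy(), "background", center=(cy, cx)))
        count += 1
    if count < n_per_class:
        raise GenerationError("could not sample enough background patches")
    return patches


def make_offcenter_negatives(
    scene: GroundTruthScene,
    window_size: int,
    n_patches: int,
    seed: int = 0,
) -> list[LabeledPatch]:
    """Background-labelled windows that may contain peripheral stomata.

    A sliding window mostly sees stomata off-centre or partially; these
    crops — no stomate pixel in the central quarter, anything allowed
    outside it — teach the classifier to fire only when a stomate is
    centred, which is what keeps detection boxes tight.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.image.shape
    half = window_size // 2
    guard = window_size // 8  # matches the stomate-class jitter radius
    if h < window_size or w < window_size:
        raise GenerationError("scene smaller than the window size")
    patches: list[LabeledPatch] = []
    tries = 0
    while len(patches) < n_patches and tries < 200 * n_patches:
        tries += 1
        cy = int(rng.integers(half, h - half))
        cx = int(rng.integers(half, w - half))
        central = scene.stomate_mask[
            cy - guard : cy + guard, cx - guard : cx + guard
        ]
        if central.any():
            continue
        window = scene.image.pixels[cy - half : cy + half, cx - half : cx + half]
        patches.append(LabeledPatch(window.copy(), "background", center=(cy, cx)))
    if len(patches) < n_patches:
        raise GenerationError("could not sample enough off-centre negatives")
    return patches
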