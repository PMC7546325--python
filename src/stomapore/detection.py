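"""Sliding-window stomate detection.

A three-class patch classifier (stomate / vein / background) is trained on
fixed-size windows and swept across the image.  The three-class design
exists because veins are the most common confounder on leaf imprints:
giving them their own class keeps them out of the stomate decision
boundary.  At box extraction the vein class is folded into "not stomate".

The default feature extractor is a weights-free gradient-orientation
histogram: the window is divided into a grid of square cells, each cell
accumulates a magnitude-weighted histogram of gradient orientations
(unsigned, 9 bins over [0, 180)), and the concatenated vector is L2
normalised.  A deep-feature backbone can be plugged in through the same
``FeatureExtractor`` contract.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from skimage import measure
from sklearn.svm import SVC

from .imaging_io import BACKGROUND, CLASS_CODES, STOMATE, ScanImage, to_gray

CLASS_LABELS = ("stomate", "vein", "background")

#: Default classification window, ~24 um at 0.25 um/px — a typical stomate span.
DEFAULT_WINDOW = 96
#: Default sliding stride; 1/12 window keeps localisation within a cell of
#: the stomate centre so detected components track the true extent.
DEFAULT_STRIDE = 8


class TrainingDataError(ValueError):
    """Raised when the training set is unusable (e.g. a class is absent)."""


@dataclass
class LabeledPatch:
    """A window-sized training example with one of the three class labels.

    ``center`` optionally records the patch centre in scene coordinates
    (set by the synthetic samplers; useful for auditing the sampling).
    """

    pixels: np.ndarray
    label: str
    center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASS_LABELS}")
        h, w = np.asarray(self.pixels).shape[:2]
        if h != w:
            raise ValueError(f"patches must be square, got {h}x{w}")


@dataclass
class FeatureVector:
    values: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


class FeatureExtractor(Protocol):
    """Contract for pluggable patch descriptors."""

    extractor_id: str
    window_size: int

    def __call__(self, window: np.ndarray) -> FeatureVector: ...


@dataclass
class GradientHistogramExtractor:
    """Cell-wise histogram of oriented gradients.

    Gradients are central differences; orientations are unsigned (folded
    into [0, 180)) and shared linearly between the two nearest bins.
    A constant window yields the all-zero vector (the L2 normalisation
    guards against division by zero).
    """

    window_size: int = DEFAULT_WINDOW
    cells: int = 6
    orientations: int = 9

    @property
    def extractor_id(self) -> str:
        return f"grad-hist-w{self.window_size}-c{self.cells}-o{self.orientations}"

    @property
    def n_features(self) -> int:
        return self.cells * self.cells * self.orientations

    def __call__(self, window: np.ndarray) -> FeatureVector:
        gray = to_gray(window)
        if gray.shape != (self.window_size, self.window_size):
            raise ValueError(
                f"window shape {gray.shape} does not match extractor size "
                f"{self.window_size}"
            )
        gr, gc = np.gradient(gray)
        mag = np.hypot(gr, gc)
        # unsigned orientation in [0, 180): 0 means a horizontal gradient
        # (vertical edge), 90 a vertical gradient.
        ang = np.rad2deg(np.arctan2(gr, gc)) % 180.0

        bin_width = 180.0 / self.orientations
        pos = ang / bin_width
        lo = np.floor(pos).astype(int) % self.orientations
        hi = (lo + 1) % self.orientations
        w_hi = pos - np.floor(pos)
        w_lo = 1.0 - w_hi

        cell_px = self.window_size / self.cells
        cr = np.minimum((np.arange(self.window_size) / cell_px).astype(int), self.cells - 1)
        cell_r = cr[:, None] * np.ones(self.window_size, dtype=int)[None, :]
        cell_c = np.ones(self.window_size, dtype=int)[:, None] * cr[None, :]

        hist = np.zeros((self.cells, self.cells, self.orientations))
        np.add.at(hist, (cell_r, cell_c, lo), w_lo * mag)
        np.add.at(hist, (cell_r, cell_c, hi), w_hi * mag)

        vec = hist.ravel()
        norm = np.linalg.norm(vec)
        if norm > 1e-12:
            vec = vec / norm
        else:
            vec = np.zeros_like(vec)
        return FeatureVector(vec, self.extractor_id)


@dataclass
class IntensityAugmentedExtractor:
    """Gradient-orientation histogram plus a central intensity histogram.

    The gradient part captures the stomate's edge structure; the
    normalised histogram of the central half-window captures its
    distinctive intensity extremes (the dark guard-cell outline and the
    very dark or very bright pore), which plain gradient energy misses
    in defocused regions.  This is the pipeline's default descriptor.
    """

    window_size: int = DEFAULT_WINDOW
    cells: int = 6
    orientations: int = 9
    intensity_bins: int = 16

    @property
    def extractor_id(self) -> str:
        return (
            f"grad-hist-int-w{self.window_size}-c{self.cells}"
            f"-o{self.orientations}-i{self.intensity_bins}"
        )

    @property
    def n_features(self) -> int:
        return self.cells * self.cells * self.orientations + self.intensity_bins

    def __call__(self, window: np.ndarray) -> FeatureVector:
        base = GradientHistogramExtractor(
            self.window_size, self.cells, self.orientations
        )(window)
        gray = to_gray(window)
        quarter = self.window_size // 4
        central = gray[quarter:-quarter, quarter:-quarter]
        hist, _ = np.histogram(central, bins=self.intensity_bins, range=(0, 256))
        hist = hist / max(hist.sum(), 1)
        return FeatureVector(np.concatenate([base.values, hist]), self.extractor_id)


def extract_features(
    patch: LabeledPatch | np.ndarray, extractor: FeatureExtractor
) -> FeatureVector:
    """Apply ``extractor`` to a patch or raw window array."""
    window = patch.pixels if isinstance(patch, LabeledPatch) else patch
    return extractor(window)


@dataclass
class ClassifierModel:
    """A fitted three-class patch classifier bound to its extractor."""

    kind: str
    svm: SVC
    extractor_id: str
    window_size: int
    classes: tuple[str, ...] = CLASS_LABELS

    def predict(self, features: Sequence[FeatureVector]) -> list[str]:
        if not features:
            return []
        for f in features:
            if f.extractor_id != self.extractor_id:
                raise ValueError(
                    f"feature from extractor {f.extractor_id!r} fed to model "
                    f"trained with {self.extractor_id!r}"
                )
        X = np.stack([f.values for f in features])
        return [str(lbl) for lbl in self.svm.predict(X)]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path, expected_extractor_id: str | None = None) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise TypeError(f"{path} does not contain a ClassifierModel")
        if expected_extractor_id and model.extractor_id != expected_extractor_id:
            raise ValueError(
                f"model extractor {model.extractor_id!r} does not match "
                f"configured extractor {expected_extractor_id!r}"
            )
        return model


def train_classifier(
    features: Sequence[FeatureVector],
    labels: Sequence[str],
    window_size: int = DEFAULT_WINDOW,
    seed: int = 0,
    C: float = 10.0,
) -> ClassifierModel:
    """Fit the quadratic-kernel SVM on extracted feature vectors.

    All three classes must be represented.  Duplicate feature vectors with
    conflicting labels are tolerated (the SVM simply absorbs the slack).
    """
    if len(features) != len(labels):
        raise TrainingDataError("features and labels differ in length")
    missing = sorted(set(CLASS_LABELS) - set(labels))
    if missing:
        raise TrainingDataError(f"training data missing classes: {missing}")
    lengths = {len(f.values) for f in features}
    if len(lengths) != 1:
        raise TrainingDataError(f"inconsistent feature lengths: {sorted(lengths)}")
    extractor_ids = {f.extractor_id for f in features}
    if len(extractor_ids) != 1:
        raise TrainingDataError(f"mixed extractors in training data: {sorted(extractor_ids)}")

    X = np.stack([f.values for f in features])
    y = np.asarray(labels)
    svm = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=C, random_state=seed)
    svm.fit(X, y)
    return ClassifierModel(
        kind="quadratic-kernel SVM",
        svm=svm,
        extractor_id=extractor_ids.pop(),
        window_size=window_size,
    )


# ---------------------------------------------------------------------------
# sliding window
# ---------------------------------------------------------------------------

def _window_positions(extent: int, window: int, stride: int) -> list[int]:
    """Top-left offsets of the sliding window along one axis, last flush."""
    if window >= extent:
        return [0] if window == extent else []
    pos = list(range(0, extent - window, stride))
    pos.append(extent - window)
    return pos


def sliding_window_classify(
    image: ScanImage,
    model: ClassifierModel,
    extractor: FeatureExtractor,
    window_size: int | None = None,
    stride: int = DEFAULT_STRIDE,
    paint: str = "center",
) -> np.ndarray:
    """Classify every window position and paint a per-pixel class grid.

    With ``paint="center"`` each window writes its predicted class into the
    stride x stride cell at its centre, which keeps localisation crisp;
    ``paint="window"`` votes over the whole window (positive class wins).
    Pixels unreachable by any window centre stay background.
    """
    window_size = window_size or model.window_size
    h, w = image.shape
    if window_size > h or window_size > w:
        raise ValueError(f"window {window_size} exceeds image {h}x{w}")
    if not 1 <= stride <= window_size:
        raise ValueError(f"need 1 <= stride <= window_size, got stride={stride}")
    if extractor.extractor_id != model.extractor_id:
        raise ValueError("extractor does not match the model's extractor_id")

    rows = _window_positions(h, window_size, stride)
    cols = _window_positions(w, window_size, stride)
    feats = []
    for r in rows:
        for c in cols:
            feats.append(extractor(image.pixels[r : r + window_size, c : c + window_size]))
    preds = model.predict(feats)

    out = np.full((h, w), BACKGROUND, dtype=np.uint8)
    half = (window_size - stride) // 2
    k = 0
    for r in rows:
        for c in cols:
            code = CLASS_CODES[preds[k]]
            k += 1
            if paint == "window":
                region = out[r : r + window_size, c : c + window_size]
                np.maximum(region, code, out=region)
            else:
                rr, cc = r + half, c + half
                out[rr : min(rr + stride, h), cc : min(cc + stride, w)] = code
    return out


def mask_to_boxes(
    class_grid: np.ndarray,
    min_region_px: int = 64,
    padding: int = 8,
) -> list["StomateBox"]:
    """Extract one box per 8-connected stomate component.

    The box is the component's tight bounding rectangle dilated by
    ``padding`` pixels and clipped to the image; its score is the fill
    fraction (component area / box area).  Boxes are ordered by
    (row0, col0) for reproducibility.
    """
    stomate = np.asarray(class_grid) == STOMATE
    labels = measure.label(stomate, connectivity=2)
    h, w = stomate.shape
    boxes = []
    for region in measure.regionprops(labels):
        if region.area < min_region_px:
            continue
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(r0 - padding, 0), max(c0 - padding, 0)
        r1, c1 = min(r1 + padding, h), min(c1 + padding, w)
        boxes.append(StomateBox(r0, c0, r1, c1, score=region.area / ((r1 - r0) * (c1 - c0))))
    boxes.sort(key=lambda b: (b.row0, b.col0, b.row1, b.col1))
    return boxes


@dataclass(order=True)
class StomateBox:
    """Half-open bounding box around one detected stomate."""

    row0: int
    col0: int
    row1: int
    col1: int
    score: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        if not (self.row1 > self.row0 and self.col1 > self.col0):
            raise ValueError("box must have positive area")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return (self.row0, self.col0, self.row1, self.col1)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row0 + self.row1) / 2.0, (self.col0 + self.col1) / 2.0)
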