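"""Feature extraction, SVM training, sliding window and box extraction."""

import numpy as np
import pytest

from stomapore import detection as det
from stomapore.imaging_io import BACKGROUND, STOMATE, ScanImage


@pytest.fixture(scope="module")
def extractor():
    return det.GradientHistogramExtractor(window_size=16, cells=2, orientations=9)


class TestGradientHistogramExtractor:
    def test_constant_window_is_zero_vector(self, extractor):
        fv = extractor(np.full((16, 16), 77, dtype=np.uint8))
        assert np.all(fv.values == 0.0)
        assert len(fv.values) == extractor.n_features

    def test_deterministic(self, extractor, rng):
        win = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        np.testing.assert_array_equal(extractor(win).values, extractor(win).values)

    def test_vertical_edge_energy_in_horizontal_gradient_bin(self, extractor):
        # left half dark, right half bright: the gradient points along the
        # columns, i.e. orientation 0 deg, the first histogram bin.  Verified
        # by hand on the central-difference gradient of a step.
        win = np.zeros((16, 16), dtype=np.uint8)
        win[:, 8:] = 200
        v = extractor(win).values.reshape(2, 2, 9)
        total = v.sum()
        assert total > 0
        assert v[:, :, 0].sum() / total > 0.99

    def test_wrong_size_rejected(self, extractor):
        with pytest.raises(ValueError):
            extractor(np.zeros((8, 8), dtype=np.uint8))

    def test_augmented_extractor_adds_intensity_bins(self):
        aug = det.IntensityAugmentedExtractor(window_size=16, cells=2, intensity_bins=8)
        fv = aug(np.full((16, 16), 100, dtype=np.uint8))
        assert len(fv.values) == 2 * 2 * 9 + 8
        # the intensity histogram of a constant window is a single full bin
        assert fv.values[-8:].sum() == pytest.approx(1.0)


def _cluster_features(rng, extractor_id="toy", n=20):
    feats, labels = [], []
    centers = {"stomate": (0, 0), "vein": (10, 0), "background": (0, 10)}
    for label, (x, y) in centers.items():
        for _ in range(n):
            v = np.array([x, y], dtype=float) + rng.normal(0, 0.3, size=2)
            feats.append(det.FeatureVector(v, extractor_id))
            labels.append(label)
    return feats, labels


class TestTrainClassifier:
    def test_separable_clusters_fit_perfectly(self, rng):
        feats, labels = _cluster_features(rng)
        model = det.train_classifier(feats, labels, window_size=16, seed=0)
        assert model.predict(feats) == labels

    def test_missing_class_is_reported(self, rng):
        feats, labels = _cluster_features(rng)
        keep = [i for i, l in enumerate(labels) if l != "vein"]
        with pytest.raises(det.TrainingDataError, match="vein"):
            det.train_classifier([feats[i] for i in keep], [labels[i] for i in keep])

    def test_conflicting_duplicate_still_fits(self, rng):
        feats, labels = _cluster_features(rng)
        feats.append(det.FeatureVector(np.array([0.0, 0.0]), "toy"))
        labels.append("vein")  # same point as a stomate example
        model = det.train_classifier(feats, labels, window_size=16, seed=0)
        assert set(model.predict(feats)) <= {"stomate", "vein", "background"}

    def test_one_example_per_class(self):
        feats = [
            det.FeatureVector(np.array([0.0, 0.0]), "toy"),
            det.FeatureVector(np.array([50.0, 0.0]), "toy"),
            det.FeatureVector(np.array([0.0, 50.0]), "toy"),
        ]
        labels = ["stomate", "vein", "background"]
        model = det.train_classifier(feats, labels, window_size=16, seed=0)
        assert model.predict(feats) == labels

    def test_mismatched_extractor_refused(self, rng):
        feats, labels = _cluster_features(rng)
        model = det.train_classifier(feats, labels, window_size=16, seed=0)
        alien = det.FeatureVector(np.zeros(2), "other-extractor")
        with pytest.raises(ValueError, match="other-extractor"):
            model.predict([alien])

    def test_save_load_round_trip(self, rng, tmp_path):
        feats, labels = _cluster_features(rng)
        model = det.train_classifier(feats, labels, window_size=16, seed=0)
        model.save(tmp_path / "m.pkl")
        back = det.ClassifierModel.load(tmp_path / "m.pkl")
        assert back.extractor_id == model.extractor_id
        assert back.predict(feats) == labels
        with pytest.raises(ValueError):
            det.ClassifierModel.load(tmp_path / "m.pkl", expected_extractor_id="zzz")


class _ConstantModel:
    """Stub model that predicts one class everywhere."""

    def __init__(self, label, extractor_id):
        self.extractor_id = extractor_id
        self.window_size = 16
        self.label = label

    def predict(self, feats):
        return [self.label] * len(feats)


class TestSlidingWindow:
    def test_constant_background_model_paints_nothing(self, extractor):
        img = ScanImage(np.zeros((64, 64), dtype=np.uint8))
        model = _ConstantModel("background", extractor.extractor_id)
        grid = det.sliding_window_classify(img, model, extractor, window_size=16, stride=8)
        assert (grid == BACKGROUND).all()

    def test_position_count_at_full_stride(self, extractor):
        # stride == window: positions per axis = ceil(extent/window) with
        # the last window shifted flush
        calls = []

        class Counting(_ConstantModel):
            def predict(self, feats):
                calls.append(len(feats))
                return ["background"] * len(feats)

        img = ScanImage(np.zeros((70, 50), dtype=np.uint8))
        model = Counting("background", extractor.extractor_id)
        det.sliding_window_classify(img, model, extractor, window_size=16, stride=16)
        rows = int(np.ceil(70 / 16))
        cols = int(np.ceil(50 / 16))
        assert calls == [rows * cols]

    def test_window_larger_than_image_rejected(self, extractor):
        img = ScanImage(np.zeros((8, 8), dtype=np.uint8))
        model = _ConstantModel("background", extractor.extractor_id)
        with pytest.raises(ValueError):
            det.sliding_window_classify(img, model, extractor, window_size=16, stride=8)

    def test_interior_coverage_by_central_cells(self, extractor):
        # with stride <= window every interior pixel lands in some window's
        # painted central cell: an all-stomate model must paint them all
        img = ScanImage(np.zeros((48, 48), dtype=np.uint8))
        model = _ConstantModel("stomate", extractor.extractor_id)
        grid = det.sliding_window_classify(img, model, extractor, window_size=16, stride=8)
        margin = (16 - 8) // 2
        interior = grid[margin : 48 - margin, margin : 48 - margin]
        assert (interior == STOMATE).all()


class TestMaskToBoxes:
    def test_empty_grid(self):
        assert det.mask_to_boxes(np.zeros((32, 32), dtype=np.uint8)) == []

    def test_single_square_tight_box(self):
        grid = np.zeros((32, 32), dtype=np.uint8)
        grid[5:15, 5:15] = STOMATE
        boxes = det.mask_to_boxes(grid, min_region_px=50, padding=0)
        assert len(boxes) == 1
        assert boxes[0].bounds == (5, 5, 15, 15)
        assert boxes[0].score == pytest.approx(1.0)

    def test_diagonal_touch_merges_under_8_connectivity(self):
        from skimage import measure

        grid = np.zeros((20, 20), dtype=np.uint8)
        grid[2:6, 2:6] = STOMATE
        grid[6:10, 6:10] = STOMATE  # corner contact only
        boxes = det.mask_to_boxes(grid, min_region_px=1, padding=0)
        assert len(boxes) == 1  # 8-connectivity merges the corner touch
        n4 = measure.label(grid == STOMATE, connectivity=1).max()
        assert n4 == 2  # 4-connectivity would have kept them apart

    def test_min_region_filters(self):
        grid = np.zeros((32, 32), dtype=np.uint8)
        grid[0:3, 0:3] = STOMATE  # 9 px
        assert det.mask_to_boxes(grid, min_region_px=10) == []
        assert len(det.mask_to_boxes(grid, min_region_px=9)) == 1

    def test_boxes_clipped_and_contain_component(self, rng):
        grid = np.zeros((40, 40), dtype=np.uint8)
        grid[0:6, 34:40] = STOMATE
        (box,) = det.mask_to_boxes(grid, min_region_px=1, padding=8)
        assert box.row0 >= 0 and box.col1 <= 40
        assert box.row0 <= 0 and box.col0 <= 34 and box.row1 >= 6 and box.col1 >= 40


class TestEndToEndDetection:
    # the 10-scene recall/precision target lives in test_acceptance.py;
    # here we only pin the cheap structural invariants
    def test_detection_is_deterministic(self, trained_model):
        from stomapore import cli, synthgen

        model, extractor = trained_model
        scene = synthgen.generate_scene(synthgen.SceneSpec(seed=9001, height=384, width=384, n_stomata=5))
        _, b1 = cli.detect_in_image(scene.image, model, extractor)
        _, b2 = cli.detect_in_image(scene.image, model, extractor)
        assert [b.bounds for b in b1] == [b.bounds for b in b2]
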