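"""Minimum-distance classification and reference-file handling."""

import numpy as np
import pytest

from vinepix.classifier import (
    UNPROCESSED,
    ClassRegistry,
    RegistryError,
    ROIError,
    classify_image,
    load_reference_file,
    save_reference_file,
)
from vinepix.color_model import mahalanobis_distance

from conftest import exact_class, sampled_class


def naive_classify(image, registry):
    """Per-pixel double-loop oracle."""
    H, W = image.shape[:2]
    out = np.empty((H, W), dtype=np.int32)
    for r in range(H):
        for c in range(W):
            dists = [
                mahalanobis_distance(image[r, c].astype(float), ref)
                for ref in registry.classes
            ]
            out[r, c] = int(np.argmin(dists))
    return out


@pytest.fixture
def exact_registry():
    return ClassRegistry(
        [
            exact_class("a", (0, 0, 0)),
            exact_class("b", (10, 0, 0)),
            exact_class("c", (0, 200, 0)),
            exact_class("d", (200, 200, 200)),
        ]
    )


class TestClassifyImage:
    def test_uniform_image_at_a_class_mean(self, exact_registry):
        image = np.full((6, 9, 3), 200, dtype=np.uint8)  # class "d" mean
        labels, _ = classify_image(image, exact_registry)
        assert (labels.labels == 3).all()

    def test_exact_tie_breaks_to_lowest_index(self):
        registry = ClassRegistry([exact_class("a", (0, 0, 0)), exact_class("b", (10, 0, 0))])
        image = np.zeros((1, 1, 3), dtype=np.uint8)
        image[0, 0] = (5, 0, 0)  # d = 5.0 to both classes
        labels, _ = classify_image(image, registry)
        assert labels.labels[0, 0] == 0

    def test_matches_naive_loop_on_random_image(self, rng, four_class_registry):
        image = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
        labels, _ = classify_image(image, four_class_registry)
        assert np.array_equal(labels.labels, naive_classify(image, four_class_registry))

    def test_roi_only_pixels_labeled(self, rng, four_class_registry):
        image = rng.integers(0, 256, size=(12, 10, 3), dtype=np.uint8)
        labels, stack = classify_image(
            image, four_class_registry, roi=(2, 8, 3, 9), keep_distances=True
        )
        inroi = np.zeros((12, 10), dtype=bool)
        inroi[2:8, 3:9] = True
        assert (labels.labels[inroi] >= 0).all()
        assert (labels.labels[~inroi] == UNPROCESSED).all()
        # distance stack argmin reproduces the labels inside the ROI
        assert np.array_equal(
            np.argmin(stack.distances, axis=0)[inroi], labels.labels[inroi]
        )
        assert np.isinf(stack.distances[:, ~inroi]).all()

    @pytest.mark.parametrize("roi", [(5, 5, 0, 4), (0, 20, 0, 4), (-1, 4, 0, 4)])
    def test_bad_roi_rejected(self, rng, four_class_registry, roi):
        image = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
        with pytest.raises(ROIError):
            classify_image(image, four_class_registry, roi=roi)

    def test_determinism(self, rng, four_class_registry):
        image = rng.integers(0, 256, size=(15, 15, 3), dtype=np.uint8)
        a, _ = classify_image(image, four_class_registry)
        b, _ = classify_image(image, four_class_registry)
        assert np.array_equal(a.labels, b.labels)

    def test_permutation_covariance(self, rng):
        """Reversing registry order re-maps labels to the same partition."""
        classes = [
            sampled_class("a", (30, 60, 90), rng),
            sampled_class("b", (200, 40, 40), rng),
            sampled_class("c", (90, 200, 120), rng),
        ]
        fwd = ClassRegistry(list(classes))
        rev = ClassRegistry(list(classes[::-1]))
        image = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        la, _ = classify_image(image, fwd)
        lb, _ = classify_image(image, rev)
        assert np.array_equal(la.labels, 2 - lb.labels)

    def test_pooled_image_covariance_mode(self, rng, four_class_registry):
        image = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
        labels, _ = classify_image(image, four_class_registry, covariance="pooled_image")
        assert (labels.labels >= 0).all()

    def test_nearest_reference_mode_zero_distance_wins(self, four_class_registry):
        ref_px = four_class_registry.classes[2].sample.pixels[0]
        image = np.tile(ref_px.astype(np.uint8), (4, 4, 1))
        labels, _ = classify_image(
            image, four_class_registry, representative="nearest_reference"
        )
        assert (labels.labels == 2).all()


class TestRegistry:
    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(RegistryError):
            ClassRegistry([exact_class("only", (0, 0, 0))])

    def test_duplicate_names_rejected(self):
        with pytest.raises(RegistryError, match="duplicate"):
            ClassRegistry([exact_class("x", (0, 0, 0)), exact_class("x", (9, 9, 9))])

    def test_two_grape_roles_rejected(self):
        with pytest.raises(RegistryError, match="grape"):
            ClassRegistry(
                [
                    exact_class("g1", (0, 0, 0), roles=("grape",)),
                    exact_class("g2", (9, 9, 9), roles=("grape",)),
                ]
            )


class TestReferenceFiles:
    def _seven_class_registry(self, rng):
        from vinepix.synthimage import SceneParams, make_reference_registry

        return make_reference_registry(SceneParams(), n_per_class=40, seed=3)

    def test_seven_class_json_roundtrip(self, rng, tmp_path):
        registry = self._seven_class_registry(rng)
        path = tmp_path / "ref.json"
        save_reference_file(registry, path)
        loaded = load_reference_file(path)
        assert loaded.K == 7
        assert loaded.names == registry.names
        assert sum(c.sample.n for c in loaded.classes) == 280
        for a, b in zip(loaded.classes, registry.classes):
            assert a.roles == b.roles
            assert np.array_equal(a.sample.pixels, b.sample.pixels)

    def test_save_load_save_byte_identical(self, rng, tmp_path):
        registry = self._seven_class_registry(rng)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_reference_file(registry, p1)
        save_reference_file(load_reference_file(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_roundtrip(self, rng, tmp_path):
        registry = self._seven_class_registry(rng)
        path = tmp_path / "ref.csv"
        save_reference_file(registry, path)
        loaded = load_reference_file(path)
        assert loaded.names == registry.names
        for a, b in zip(loaded.classes, registry.classes):
            assert np.array_equal(a.sample.pixels, b.sample.pixels)

    def test_class_with_three_pixels_names_offender(self, tmp_path):
        path = tmp_path / "ref.json"
        path.write_text(
            '{"classes": [{"name": "ok", "pixels": [[1,1,1],[2,2,2],[3,3,3],[4,4,4]]},'
            '{"name": "tiny", "pixels": [[1,1,1],[2,2,2],[3,3,3]]}]}'
        )
        with pytest.raises(RegistryError, match="tiny"):
            load_reference_file(path)

    def test_pixel_out_of_range_names_offender(self, tmp_path):
        path = tmp_path / "ref.json"
        path.write_text(
            '{"classes": [{"name": "ok", "pixels": [[1,1,1],[2,2,2],[3,3,3],[4,4,4]]},'
            '{"name": "hot", "pixels": [[1,1,1],[2,2,2],[3,3,3],[256,0,0]]}]}'
        )
        with pytest.raises(RegistryError, match="hot"):
            load_reference_file(path)

    def test_single_class_file_rejected(self, tmp_path):
        path = tmp_path / "ref.json"
        path.write_text(
            '{"classes": [{"name": "ok", "pixels": [[1,1,1],[2,2,2],[3,3,3],[4,4,4]]}]}'
        )
        with pytest.raises(RegistryError, match="2 classes"):
            load_reference_file(path)
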