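"""Region proposals, classifier contracts, training behaviour and
end-to-end ROI extraction on generated phone scenes."""

import numpy as np
import pytest

from hemocount import (ClassifierConfig, NoRoiFound, RegionBox, RoiClassifier,
                       SceneParams, TrainConfig, build_classifier, extract_roi,
                       make_chamber_image, make_phone_image, make_training_set,
                       preprocess_crop, propose_regions, train_classifier)
from hemocount.roi import _stack_images

from conftest import TEST_INPUT_SIZE


class TestProposals:
    def test_at_least_one_proposal_overlaps_true_roi(self, phone_scene):
        image, truth = phone_scene
        boxes = propose_regions(image)
        assert max(b.iou(truth.roi_box) for b in boxes) >= 0.5

    def test_all_boxes_within_bounds(self, phone_scene):
        image, _ = phone_scene
        for box in propose_regions(image, max_proposals=100):
            assert box.within_image(image.shape)

    def test_max_proposals_truncates(self, phone_scene):
        image, _ = phone_scene
        assert len(propose_regions(image, max_proposals=1)) == 1

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            propose_regions(np.zeros((4, 4, 3), dtype=np.uint8))


class TestPreprocess:
    def test_output_shape_and_range(self, phone_scene):
        image, _ = phone_scene
        out = preprocess_crop(image, RegionBox(10, 20, 200, 150))
        assert out.shape == (256, 256, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_when_box_matches_output_size(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (256, 256, 3)).astype(np.uint8)
        out = preprocess_crop(img, RegionBox(0, 0, 256, 256))
        assert np.allclose(out, img / 255.0)

    def test_constant_stays_constant(self):
        img = np.full((100, 80, 3), 200, dtype=np.uint8)
        out = preprocess_crop(img, RegionBox(0, 0, 80, 100), (64, 64))
        assert np.allclose(out, 200 / 255.0, atol=1e-3)

    def test_out_of_bounds_box_rejected(self):
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            preprocess_crop(img, RegionBox(10, 10, 60, 40))


class TestClassifierBuild:
    def test_softmax_outputs_sum_to_one(self, rng):
        cfg = ClassifierConfig(input_size=(16, 16))
        model = build_classifier(cfg, seed=0)
        x = rng.random((3, 16, 16, 3)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_predictions(self, rng):
        cfg = ClassifierConfig(input_size=(16, 16))
        x = rng.random((2, 16, 16, 3)).astype(np.float32)
        a = build_classifier(cfg, seed=5).predict_proba(x)
        b = build_classifier(cfg, seed=5).predict_proba(x)
        assert np.array_equal(a, b)

    def test_architecture_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(dense_units=(128, 64, 3)).validate()
        with pytest.raises(ValueError):
            ClassifierConfig(input_size=(4, 4)).validate()

    def test_default_config_matches_published_architecture(self):
        cfg = ClassifierConfig()
        assert cfg.input_size == (256, 256)
        assert cfg.conv_filters == (256, 128) and cfg.conv_kernel == 2
        assert cfg.dense_units == (128, 128, 64, 2)


class TestTraining:
    def test_history_length_and_split(self):
        images, labels = make_training_set(30, 30, seed=2)
        model = build_classifier(ClassifierConfig(input_size=TEST_INPUT_SIZE), seed=0)
        x = _stack_images(images, TEST_INPUT_SIZE)
        cfg = TrainConfig(epochs=3, seed=0)
        history = train_classifier(model, x, labels, cfg)
        assert len(history["val_accuracy"]) == 3
        assert len(history["train_accuracy"]) == 3

    def test_single_class_rejected(self):
        images, _ = make_training_set(4, 4, seed=0)
        model = build_classifier(ClassifierConfig(input_size=TEST_INPUT_SIZE), seed=0)
        x = _stack_images(images, TEST_INPUT_SIZE)
        with pytest.raises(ValueError):
            train_classifier(model, x, np.ones(8, dtype=int), TrainConfig(epochs=1))

    def test_horizontal_flip_preserves_labels(self, trained_clf):
        # flipping a chamber crop yields another valid chamber crop and
        # flipping clutter yields clutter: ROI-ness is flip-invariant by
        # construction, and the trained model should respect that
        images, _ = make_training_set(10, 10, seed=3)
        flipped = [img[:, ::-1, :] for img in images]
        agree = trained_clf.predict(images) == trained_clf.predict(flipped)
        assert agree.mean() >= 0.9

    def test_session_classifier_validation_accuracy(self, trained_clf):
        assert trained_clf.history_["val_accuracy"][-1] >= 0.9

    def test_save_load_roundtrip(self, trained_clf, tmp_path, phone_scene):
        image, _ = phone_scene
        crops = [image[:128, :128], image[100:300, 100:300]]
        before = trained_clf.predict_proba(crops)
        trained_clf.save(tmp_path / "model")
        loaded = RoiClassifier.load(tmp_path / "model")
        assert np.allclose(loaded.predict_proba(crops), before)
        assert loaded.get_params() == trained_clf.get_params()

    def test_sklearn_estimator_protocol(self):
        clf = RoiClassifier(epochs=3, input_size=(16, 16))
        params = clf.get_params()
        assert params["epochs"] == 3
        clf.set_params(epochs=5)
        assert clf.epochs == 5
        with pytest.raises(RuntimeError):
            clf.predict([np.zeros((16, 16, 3), dtype=np.uint8)])


class TestExtraction:
    def test_phone_scene_roi_recovered(self, trained_clf):
        for seed in (0, 1, 2):
            image, truth = make_phone_image(SceneParams(seed=seed))
            _, region = extract_roi(image, trained_clf)
            assert region.box.iou(truth.roi_box) >= 0.5
            assert region.label == 1 and 0 <= region.score <= 1

    def test_crop_is_original_resolution_slice(self, trained_clf, phone_scene):
        image, _ = phone_scene
        crop, region = extract_roi(image, trained_clf)
        assert crop.shape[:2] == (region.box.height, region.box.width)
        assert np.array_equal(crop, region.box.crop(image))

    def test_clutter_only_raises_no_roi(self, trained_clf):
        from hemocount.scenes import _clutter_background

        bg = _clutter_background((500, 500), 0.8, 90.0, 4.0,
                                 np.random.default_rng(11))
        image = np.clip(np.repeat(bg[:, :, None], 3, axis=2), 0, 255).astype(np.uint8)
        with pytest.raises(NoRoiFound):
            extract_roi(image, trained_clf)

    def test_chamber_only_image_covered(self, trained_clf, chamber_scene):
        image, _ = chamber_scene
        _, region = extract_roi(image, trained_clf)
        assert region.box.area >= 0.5 * image.shape[0] * image.shape[1]
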