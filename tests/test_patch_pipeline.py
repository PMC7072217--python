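"""Patch sampling rules, balanced batches, and the patch classifier."""

import numpy as np
import pytest

from npcscreen.annotations import AnnotationKind, AnnotationRegion, TrainingClass, Window
from npcscreen.patch_pipeline import (
    CompositionError,
    NoRegionError,
    PatchClassifier,
    SlideDataset,
    SlideRecord,
    TrainingConfig,
    accept_window,
    balanced_patch_batch,
    compliance_audit,
    infer_patch_probs,
    sample_patch,
    sample_window,
)


def _rect(x0, y0, x1, y1, kind):
    return AnnotationRegion(
        np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float), kind)


class TestAcceptWindow:
    def test_benign_requires_full_containment(self):
        reg = _rect(-5, -5, 400, 400, AnnotationKind.BENIGN_TISSUE)
        assert accept_window(Window(0, 0, 256), TrainingClass.BENIGN, [reg])
        part = _rect(10, -5, 400, 400, AnnotationKind.BENIGN_TISSUE)
        assert not accept_window(Window(0, 0, 256), TrainingClass.BENIGN, [part])

    def test_npc_at_exactly_half(self):
        # covers columns [0, 128): exactly 50% of pixel centers
        reg = _rect(0, 0, 128, 256, AnnotationKind.NPC)
        assert accept_window(Window(0, 0, 256), TrainingClass.NPC, [reg])

    def test_npc_below_half_rejected(self):
        reg = _rect(0, 0, 127, 256, AnnotationKind.NPC)  # 127/256 < 50%
        assert not accept_window(Window(0, 0, 256), TrainingClass.NPC, [reg])


class TestSampling:
    def test_no_region_error(self, unit_dataset):
        benign_recs = [r for r in unit_dataset if r.label == "BENIGN"]
        rng = np.random.default_rng(0)
        with pytest.raises(NoRegionError):
            sample_patch(benign_recs[0], TrainingClass.NPC, rng)

    def test_sampled_windows_comply(self, unit_dataset):
        rng = np.random.default_rng(1)
        for rec in unit_dataset:
            for cls in TrainingClass:
                if not rec.has_valid_window(cls):
                    continue
                wins = [sample_window(rec, cls, rng) for _ in range(150)]
                assert compliance_audit(rec, wins, cls).all()

    def test_fixed_seed_same_windows(self, unit_dataset):
        rec = next(r for r in unit_dataset if r.label == "NPC")
        w1 = [sample_window(rec, TrainingClass.NPC, np.random.default_rng(5))
              for _ in range(20)]
        w2 = [sample_window(rec, TrainingClass.NPC, np.random.default_rng(5))
              for _ in range(20)]
        assert w1 == w2

    def test_patch_pixels_match_slide(self, unit_dataset):
        rec = next(r for r in unit_dataset if r.label == "NPC")
        patch = sample_patch(rec, TrainingClass.NPC, np.random.default_rng(2))
        w = patch.window
        np.testing.assert_array_equal(
            patch.pixels, rec.image[w.y0:w.y0 + 256, w.x0:w.x0 + 256])
        assert patch.normalized().max() <= 1.0

    def test_window_overlap_matches_fresh_rasterization(self, unit_dataset):
        from npcscreen.annotations import overlap_fraction

        rec = next(r for r in unit_dataset if r.label == "NPC")
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = Window(int(rng.integers(0, rec.width - 256)),
                       int(rng.integers(0, rec.height - 256)))
            fast = rec.window_overlap(w, TrainingClass.NPC)
            slow = overlap_fraction(w, rec.regions, TrainingClass.NPC)
            assert fast == pytest.approx(slow, abs=0)


class TestBalancedBatch:
    def test_class_histogram(self, unit_dataset):
        batch = balanced_patch_batch(unit_dataset, np.random.default_rng(0))
        counts = {cls: 0 for cls in TrainingClass}
        for p in batch:
            counts[p.label] += 1
        assert counts == {TrainingClass.NPC: 16, TrainingClass.BENIGN: 16,
                          TrainingClass.BACKGROUND: 16}

    def test_missing_class_raises(self, unit_dataset):
        no_background = SlideDataset([
            SlideRecord(r.slide_id, r.image,
                        [reg for reg in r.regions
                         if reg.training_class is not TrainingClass.BACKGROUND],
                        r.label)
            for r in unit_dataset])
        with pytest.raises(CompositionError):
            balanced_patch_batch(no_background, np.random.default_rng(0))

    def test_same_seed_same_batch(self, unit_dataset):
        b1 = balanced_patch_batch(unit_dataset, np.random.default_rng(9))
        b2 = balanced_patch_batch(unit_dataset, np.random.default_rng(9))
        assert [p.window for p in b1] == [p.window for p in b2]
        assert [p.slide_id for p in b1] == [p.slide_id for p in b2]


class TestTrainingConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.0017
        assert cfg.momentum == 0.95
        assert cfg.batch_size == 48
        assert cfg.eval_interval == 1000

    def test_invalid_lr(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0)


@pytest.fixture(scope="module")
def array_model():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 256, (30, 256, 256, 3), dtype=np.uint8)
    y = np.repeat([0, 1, 2], 10)
    est = PatchClassifier(max_steps=5, eval_interval=5, seed=0, batch_size=6)
    est.fit(x, y)
    return est


class TestPatchClassifier:
    def test_probabilities_sum_to_one(self, array_model):
        x = np.random.default_rng(1).integers(0, 256, (7, 256, 256, 3),
                                              dtype=np.uint8)
        p = infer_patch_probs(array_model, x)
        assert p.shape == (7, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_batch_equals_single(self, array_model):
        x = np.random.default_rng(2).integers(0, 256, (5, 256, 256, 3),
                                              dtype=np.uint8)
        batch = array_model.predict_proba(x)
        singles = np.vstack([array_model.predict_proba(x[i]) for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_zeroed_head_uniform(self):
        est = PatchClassifier(seed=0)
        est.net_ = est._make_net()
        est.classes_ = np.array([0, 1, 2])
        head = est.net_.layers[-1]
        head.params["w"][:] = 0.0
        head.params["b"][:] = 0.0
        x = np.random.default_rng(0).integers(0, 256, (2, 256, 256, 3),
                                              dtype=np.uint8)
        np.testing.assert_allclose(est.predict_proba(x), 1 / 3, atol=1e-6)

    def test_checkpoint_round_trip(self, array_model, tmp_path):
        path = tmp_path / "m.npz"
        array_model.save(path)
        loaded = PatchClassifier.load(path)
        x = np.random.default_rng(3).integers(0, 256, (4, 256, 256, 3),
                                              dtype=np.uint8)
        np.testing.assert_array_equal(loaded.predict_proba(x),
                                      array_model.predict_proba(x))

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            PatchClassifier(max_steps=1).fit(np.empty((0, 256, 256, 3)), [])

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = PatchClassifier(learning_rate=0.01, max_steps=42)
        cloned = clone(est)
        assert cloned.get_params()["learning_rate"] == 0.01
        assert cloned.get_params()["max_steps"] == 42

    def test_curves_schema_and_plateau(self):
        """Learning curves carry (step, losses, auc, lr); plateau acts."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 256, (12, 256, 256, 3), dtype=np.uint8)
        y = np.repeat([0, 1, 2], 4)
        est = PatchClassifier(max_steps=8, eval_interval=2, batch_size=6,
                              plateau_patience=2, seed=0)
        est.fit(x, y)
        assert list(est.curves_.columns) == ["step", "train_loss", "val_loss",
                                             "val_auc", "lr"]
        assert len(est.curves_) == 4
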