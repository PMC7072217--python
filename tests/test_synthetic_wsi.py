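"""Synthetic slide generator: determinism, ground truth, separability."""

import numpy as np
import pytest

from npcscreen.annotations import AnnotationKind, TrainingClass, rasterize
from npcscreen.synthetic_wsi import (
    InvalidSpecError,
    SlideSpec,
    generate_dataset,
    generate_slide,
)


class TestSpecValidation:
    def test_benign_with_tumor_fraction_rejected(self):
        with pytest.raises(InvalidSpecError):
            SlideSpec(tumor_fraction=0.1, label="BENIGN")

    def test_npc_without_tumor_rejected(self):
        with pytest.raises(InvalidSpecError):
            SlideSpec(tumor_fraction=0.0, label="NPC")

    def test_minimum_canvas(self):
        with pytest.raises(InvalidSpecError):
            SlideSpec(width=256, height=1024)

    def test_negative_confusers_rejected(self):
        with pytest.raises(InvalidSpecError):
            SlideSpec(confuser_density=-1)


class TestGenerateSlide:
    def test_benign_slide_has_no_tumor_regions(self, unit_slides):
        benign = [s for s in unit_slides if s.label == "BENIGN"]
        assert benign
        for sl in benign:
            assert all(r.training_class is not TrainingClass.NPC for r in sl.regions)

    def test_npc_slide_has_tumor_regions(self, unit_slides):
        npc = [s for s in unit_slides if s.label == "NPC"]
        assert npc
        for sl in npc:
            assert any(r.training_class is TrainingClass.NPC for r in sl.regions)

    def test_determinism_byte_identical(self):
        spec = SlideSpec(width=512, height=512, tumor_fraction=0.1,
                         confuser_density=0, seed=7)
        a = generate_slide(spec)
        b = generate_slide(spec)
        np.testing.assert_array_equal(a.image, b.image)
        assert len(a.regions) == len(b.regions)
        for ra, rb in zip(a.regions, b.regions):
            np.testing.assert_array_equal(ra.polygon, rb.polygon)
            assert ra.annotation_kind == rb.annotation_kind

    def test_regions_inside_canvas(self, unit_slides):
        for sl in unit_slides:
            h, w = sl.image.shape[:2]
            for reg in sl.regions:
                minx, miny, maxx, maxy = reg.bounds
                assert minx >= 0 and miny >= 0 and maxx <= w and maxy <= h

    def test_tumor_fraction_within_band(self):
        # requested 10% of tissue realised within +/-20% relative
        sl = generate_slide(SlideSpec(width=2048, height=1536,
                                      tumor_fraction=0.10, seed=21, label="NPC"))
        frac = sl.tumor_mask.sum() / sl.tissue_mask.sum()
        assert 0.08 <= frac <= 0.12

    def test_annotation_completeness(self, unit_slides):
        """Every tumor pixel of the construction mask lies in a tumor region."""
        for sl in unit_slides:
            if sl.label != "NPC":
                continue
            h, w = sl.image.shape[:2]
            tumor = rasterize(sl.regions, TrainingClass.NPC, (0, 0, w, h))
            assert tumor.any()
            # the construction mask IS the union of the annotations, so the
            # meaningful check is that the mask is non-trivial and inside tissue
            assert (tumor & ~sl.tissue_mask).mean() < 0.005

    def test_nucleus_coords_parallel_to_regions(self, unit_slides):
        for sl in unit_slides:
            assert len(sl.nucleus_coords) == len(sl.regions)


class TestTextureSeparability:
    def test_linear_classifier_on_block_statistics(self, unit_slides):
        """Mean/variance of 64px blocks separate tumor from lymphoid > 0.8."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        feats, labels = [], []
        rng = np.random.default_rng(0)
        for sl in unit_slides:
            h, w = sl.image.shape[:2]
            masks = {1: rasterize(sl.regions, TrainingClass.NPC, (0, 0, w, h)),
                     0: rasterize([r for r in sl.regions
                                   if r.annotation_kind == AnnotationKind.BENIGN_TISSUE],
                                  None, (0, 0, w, h))}
            for lab, mask in masks.items():
                if not mask.any():
                    continue
                ys, xs = np.nonzero(mask)
                taken = 0
                for _ in range(4000):
                    if taken >= 125:
                        break
                    j = rng.integers(0, len(xs))
                    x0, y0 = xs[j], ys[j]
                    if x0 + 64 > w or y0 + 64 > h:
                        continue
                    if not mask[y0:y0 + 64, x0:x0 + 64].all():
                        continue
                    block = sl.image[y0:y0 + 64, x0:x0 + 64].astype(np.float32) / 255
                    feats.append(np.r_[block.mean(axis=(0, 1)),
                                       block.var(axis=(0, 1))])
                    labels.append(lab)
                    taken += 1
        feats, labels = np.asarray(feats), np.asarray(labels)
        assert len(feats) >= 500
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        cv = StratifiedKFold(4, shuffle=True, random_state=0)
        acc = cross_val_score(clf, feats, labels, cv=cv).mean()
        assert acc > 0.8


class TestGenerateDataset:
    def test_counts_and_manifest(self, tmp_path):
        template = SlideSpec(width=512, height=512, tumor_fraction=0.1,
                             confuser_density=0, seed=3)
        df = generate_dataset(5, 5, template, tmp_path / "ds")
        assert len(df) == 10
        assert (df["label"] == "NPC").sum() == 5
        assert (df["label"] == "BENIGN").sum() == 5
        assert list(df.columns) == ["slide_id", "path", "annotation_path",
                                    "label", "split"]
        assert (tmp_path / "ds" / "manifest.csv").exists()
        for p in df["path"]:
            assert (tmp_path / "ds").joinpath(p).exists() or __import__("os").path.exists(p)

    def test_same_seed_identical_manifest(self, tmp_path):
        template = SlideSpec(width=512, height=512, tumor_fraction=0.1,
                             confuser_density=0, seed=3)
        df1 = generate_dataset(2, 2, template, tmp_path / "a")
        df2 = generate_dataset(2, 2, template, tmp_path / "b")
        assert df1["slide_id"].tolist() == df2["slide_id"].tolist()
        assert df1["label"].tolist() == df2["label"].tolist()
        # images byte-identical too
        for p1, p2 in zip(df1["path"], df2["path"]):
            assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_paper_scale_training_manifest(self, tmp_path):
        """303 + 303 cases make a 606-slide training manifest."""
        template = SlideSpec(width=512, height=512, tumor_fraction=0.08,
                             confuser_density=0, seed=9)
        df = generate_dataset(303, 303, template, tmp_path / "paper")
        assert len(df) == 606
        assert (df["label"] == "NPC").sum() == 303
        assert (df["split"] == "train").all()

    def test_tiled_tiff_output(self, tmp_path):
        import tifffile

        template = SlideSpec(width=512, height=512, tumor_fraction=0.1,
                             confuser_density=0, seed=4)
        df = generate_dataset(1, 1, template, tmp_path / "tif",
                              image_format="tif")
        img = tifffile.imread(df["path"].iloc[0])
        assert img.shape == (512, 512, 3)
        with tifffile.TiffFile(df["path"].iloc[0]) as tf:
            assert tf.pages[0].tilewidth == 256

    def test_split_fractions_stratified(self, tmp_path):
        template = SlideSpec(width=512, height=512, tumor_fraction=0.1,
                             confuser_density=0, seed=5)
        df = generate_dataset(6, 6, template, tmp_path / "s",
                              split_fractions={"train": 0.5, "val": 0.25,
                                               "test": 0.25})
        for lab in ("NPC", "BENIGN"):
            counts = df[df["label"] == lab]["split"].value_counts().to_dict()
            assert counts["train"] == 3
            assert counts.get("val", 0) + counts.get("test", 0) == 3
        # splits do not overlap by construction (each slide appears once)
        assert df["slide_id"].is_unique
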