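"""Shared fixtures.

The expensive session fixtures build one small annotated cohort for unit
tests and one full benchmark (patch model trained 3,000 steps on 20 slides,
slide model trained on 60 slide inputs) that the acceptance tests share.
Problem sizes are desk-scale: slides are a few megapixels, not gigapixels.
"""

from __future__ import annotations

import numpy as np
import pytest

from npcscreen import PatchClassifier, SlideDataset, SlideSpec
from npcscreen.synthetic_wsi import generate_slide_with_retry
from npcscreen.slide_pipeline import (
    SlideClassifier,
    build_probability_map,
    compose_slide_input,
)

# study conditions for the synthetic benchmark: patch-capable slides are
# 1280x1024 with an 18-22% tumor share and a handful of confusers;
# slide-stage-only extras are 1024x768 (their maps are 3x4 tiles)
PATCH_SLIDE_KW = dict(width=1280, height=1024, confuser_density=4)
EXTRA_SLIDE_KW = dict(width=1024, height=768, confuser_density=2)


def _cohort(n_npc, n_benign, seed0, tumor_fractions=(0.18, 0.22), **kw):
    slides = []
    for i in range(n_npc):
        tf = tumor_fractions[i % len(tumor_fractions)]
        slides.append(generate_slide_with_retry(
            SlideSpec(tumor_fraction=tf, seed=seed0 + i, label="NPC", **kw)))
    for i in range(n_benign):
        slides.append(generate_slide_with_retry(
            SlideSpec(tumor_fraction=0.0, seed=seed0 + 500 + i, label="BENIGN", **kw)))
    return slides


@pytest.fixture(scope="session")
def unit_slides():
    """2 NPC + 2 benign slides for fast unit tests."""
    return _cohort(2, 2, seed0=11, **PATCH_SLIDE_KW)


@pytest.fixture(scope="session")
def unit_dataset(unit_slides):
    return SlideDataset.from_slides(unit_slides)


@pytest.fixture(scope="session")
def benchmark_slides():
    """20 training + 4 validation + 16 patch-test slides (1280x1024)."""
    return {
        "train": _cohort(10, 10, seed0=1000, **PATCH_SLIDE_KW),
        "val": _cohort(2, 2, seed0=2000, **PATCH_SLIDE_KW),
        "test": _cohort(8, 8, seed0=3000, **PATCH_SLIDE_KW),
    }


@pytest.fixture(scope="session")
def benchmark_patch_model(benchmark_slides):
    """The 3,000-step benchmark patch model (~50k parameters)."""
    train = SlideDataset.from_slides(benchmark_slides["train"])
    val = SlideDataset.from_slides(benchmark_slides["val"])
    est = PatchClassifier(max_steps=3000, eval_interval=1000, seed=7)
    est.fit(train, validation=val)
    return est


@pytest.fixture(scope="session")
def benchmark_slide_stage(benchmark_slides, benchmark_patch_model):
    """Slide model trained on 60 slide inputs; 20 held-out inputs for testing."""
    extra_train = _cohort(20, 20, seed0=4000, tumor_fractions=(0.12, 0.18, 0.15),
                          **EXTRA_SLIDE_KW)
    held_out = _cohort(10, 10, seed0=5000, tumor_fractions=(0.12, 0.18, 0.15),
                       **EXTRA_SLIDE_KW)

    def make_inputs(slides):
        xs, ys = [], []
        for sl in slides:
            pmap = build_probability_map(benchmark_patch_model, sl.image)
            xs.append(compose_slide_input(pmap, sl.image, label=sl.label))
            ys.append(1 if sl.label == "NPC" else 0)
        return xs, np.array(ys)

    x_train, y_train = make_inputs(benchmark_slides["train"] + extra_train)
    x_test, y_test = make_inputs(held_out)
    assert len(x_train) == 60
    sc = SlideClassifier(max_steps=400, eval_interval=100, seed=8)
    sc.fit(x_train, y_train)
    return {"model": sc, "x_test": x_test, "y_test": y_test,
            "held_out_slides": held_out}
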