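"""AUC/ROC, Welch t-test, operating points, reader-overlay figure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcscreen.evaluation import (
    ComparisonResult,
    UndefinedAUCError,
    auc,
    plot_roc_with_readers,
    roc,
    sens_spec,
    welch_t_two_tailed,
)


def _brute_force_auc(scores, labels):
    """Exhaustive positive-negative pair enumeration, ties count half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_example(self):
        # 4 pos-neg pairs, 3 concordant: 0.35>0.1, 0.8>0.1, 0.8>0.4
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # induce ties
            assert abs(auc(scores, labels)
                       - _brute_force_auc(scores, labels)) < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = auc(scores, labels)
        assert auc(np.exp(3 * scores) - 1, labels) == pytest.approx(a, abs=1e-12)
        assert auc(np.log(scores + 1e-9), labels) == pytest.approx(a, abs=1e-12)

    def test_roc_endpoints_and_area(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        res = roc(scores, labels)
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)
        assert res.auc == pytest.approx(auc(scores, labels), abs=1e-12)


class TestWelch:
    def test_hand_example(self):
        # equal variances 1, n=3 each: t = -1/sqrt(2/3), df = 4
        t, df, p = welch_t_two_tailed([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_samples(self):
        t, df, p = welch_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        t, df, p = welch_t_two_tailed([0.0, 0.0], [1.0, 1.0])
        assert p == 0.0

    def test_zero_variance_equal_means(self):
        t, df, p = welch_t_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            welch_t_two_tailed([1.0], [1.0, 2.0])

    def test_agrees_with_permutation_test(self):
        """Two-tailed Welch p within 0.01 of a large permutation test."""
        a = np.array([0.91, 0.93, 0.92, 0.95, 0.90, 0.94])
        b = np.array([0.96, 0.97, 0.95, 0.98, 0.96, 0.99])
        _, _, p_welch = welch_t_two_tailed(a, b)
        rng = np.random.default_rng(0)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        n_perm = 200_000
        idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
        perm = pooled[idx]
        diffs = np.abs(perm[:, :6].mean(axis=1) - perm[:, 6:].mean(axis=1))
        p_perm = (diffs >= observed - 1e-12).mean()
        assert abs(p_welch - p_perm) < 0.01


class _StubPatchModel:
    """Deterministic pixel-statistic scorer standing in for a trained CNN."""

    def __init__(self, bias: float = 0.0):
        self.bias = bias

    def predict_proba(self, x):
        # darker-green patches look more tumor-like to this stub
        score = 1.0 - x[..., 1].mean(axis=(1, 2)) / 255.0 + self.bias
        p_npc = np.clip(score, 0.01, 0.99)
        rest = (1 - p_npc) / 2
        return np.column_stack([p_npc, rest, rest])


class TestRepeatedComparison:
    def test_identical_models_give_p_one(self, unit_dataset):
        from npcscreen.evaluation import repeated_model_comparison

        model = _StubPatchModel()
        res = repeated_model_comparison(model, model, unit_dataset, runs=3,
                                        n_patches=60,
                                        rng=np.random.default_rng(0))
        np.testing.assert_array_equal(res.auc_a, res.auc_b)
        assert res.p == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self, unit_dataset):
        from npcscreen.evaluation import repeated_model_comparison

        a, b = _StubPatchModel(), _StubPatchModel(bias=0.05)
        r1 = repeated_model_comparison(a, b, unit_dataset, runs=3, n_patches=60,
                                       rng=np.random.default_rng(7))
        r2 = repeated_model_comparison(a, b, unit_dataset, runs=3, n_patches=60,
                                       rng=np.random.default_rng(7))
        np.testing.assert_array_equal(r1.auc_a, r2.auc_a)
        assert r1.p == r2.p

    def test_too_few_runs_rejected(self, unit_dataset):
        from npcscreen.evaluation import repeated_model_comparison

        with pytest.raises(ValueError):
            repeated_model_comparison(_StubPatchModel(), _StubPatchModel(),
                                      unit_dataset, runs=1, n_patches=10,
                                      rng=np.random.default_rng(0))


class TestComparisonResult:
    def test_self_comparison(self):
        aucs = np.array([0.9, 0.92, 0.91, 0.93])
        res = ComparisonResult(aucs, aucs.copy())
        assert res.p == pytest.approx(1.0)
        assert res.t == pytest.approx(0.0)

    def test_mismatched_runs_rejected(self):
        with pytest.raises(ValueError):
            ComparisonResult(np.array([0.9, 0.91]), np.array([0.9]))

    def test_paired_variant(self):
        a = np.array([0.90, 0.91, 0.92, 0.93])
        res = ComparisonResult(a, a + 0.02, paired=True)
        assert res.p < 0.001  # constant shift: paired test is certain


class TestSensSpec:
    def test_threshold_below_all(self):
        assert sens_spec([0.2, 0.8], [0, 1], 0.0) == (1.0, 0.0)

    def test_threshold_above_all(self):
        assert sens_spec([0.2, 0.8], [0, 1], 2.0) == (0.0, 1.0)

    def test_confusion_matrix_counts(self):
        s, sp = sens_spec([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0], 0.5)
        assert (s, sp) == (1.0, 1.0)


class TestReaderFigure:
    def test_plain_roc_written(self, tmp_path):
        rng = np.random.default_rng(0)
        res = roc(rng.random(40), rng.integers(0, 2, 40))
        out = tmp_path / "roc.png"
        plot_roc_with_readers(res, [], out)
        assert out.stat().st_size > 0

    def test_point_outside_unit_square_rejected(self, tmp_path):
        rng = np.random.default_rng(0)
        res = roc(rng.random(40), rng.integers(0, 2, 40))
        with pytest.raises(ValueError):
            plot_roc_with_readers(res, [(1.2, 0.5, "resident")],
                                  tmp_path / "bad.png")

    def test_regeneration_byte_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        scores, labels = rng.random(40), rng.integers(0, 2, 40)
        readers = [(0.05, 0.9, "resident"), (0.02, 0.95, "attending"),
                   (0.03, 0.93, "chief resident")]
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        plot_roc_with_readers(roc(scores, labels), readers, p1)
        plot_roc_with_readers(roc(scores, labels), readers, p2)
        assert p1.read_bytes() == p2.read_bytes()
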