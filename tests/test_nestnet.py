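"""Nest sampling, class-logic relabeling, rebalancing, classifier, partition."""

import logging

import numpy as np
import pytest

from skindx.labels import DiagnosisClass, TissueKind
from skindx.maskops import binarize
from skindx.nestnet import (MELANOMA, NEVUS, NestClassifier, NestPatch,
                            NestTrainSet, binary_metrics, rebalance,
                            relabel_dmn_by_class, sample_nests, split_dmn,
                            train_nest_classifier)
from skindx.synthdata import generate_case

PS = 100


def _shared_patch(label, provenance="annotated"):
    # content is irrelevant for bookkeeping tests; share one buffer
    if not hasattr(_shared_patch, "_img"):
        _shared_patch._img = np.zeros((PS, PS, 3), dtype=np.uint8)
    return NestPatch(image=_shared_patch._img, label=label,
                     provenance=provenance)


def brute_force_window_count(mask, stride, min_coverage):
    h, w = mask.shape
    count = 0
    r = 0
    while r + PS <= h:
        c = 0
        while c + PS <= w:
            cov = mask[r:r + PS, c:c + PS].sum()
            if cov >= max(min_coverage * PS * PS, 1):
                count += 1
            c += stride
        r += stride
    return count


class TestSampleNests:
    def test_empty_mask_yields_no_patches(self):
        rgb = np.zeros((300, 300, 3), dtype=np.uint8)
        assert sample_nests(rgb, np.zeros((300, 300), np.uint8), NEVUS) == []

    def test_single_aligned_solid_nest_gives_one_window(self):
        rgb = np.full((PS, PS, 3), 90, dtype=np.uint8)
        mask = np.ones((PS, PS), dtype=np.uint8)
        patches = sample_nests(rgb, mask, MELANOMA, stride=PS)
        assert len(patches) == 1
        assert patches[0].image.shape == (PS, PS, 3)
        assert patches[0].label == MELANOMA

    def test_non_nest_pixels_are_zeroed(self):
        rgb = np.full((PS, PS, 3), 200, dtype=np.uint8)
        mask = np.zeros((PS, PS), dtype=np.uint8)
        mask[:50] = 1
        (patch,) = sample_nests(rgb, mask, NEVUS)
        assert patch.image[:50].min() == 200
        assert patch.image[50:].max() == 0

    @pytest.mark.parametrize("stride", [50, 100])
    def test_count_matches_window_scan_oracle(self, synth_config, stride):
        case = generate_case(synth_config, DiagnosisClass.T1b, 4)
        rgb, mask = case.slices[case.roi[0]]
        dmn = binarize(mask, TissueKind.DMN)
        got = sample_nests(rgb, dmn, MELANOMA, stride=stride)
        assert len(got) == brute_force_window_count(dmn, stride, 0.05)

    def test_small_raster_warns_and_returns_empty(self):
        rgb = np.zeros((40, 40, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="smaller"):
            out = sample_nests(rgb, np.ones((40, 40), np.uint8), NEVUS)
        assert out == []


class TestRelabel:
    def test_benign_case_mask_retyped_in_full(self, mmd_case):
        _, mask = mmd_case.slices[0]
        dmn = binarize(mask, TissueKind.DMN)
        out = relabel_dmn_by_class(mmd_case, dmn)
        assert out is not None
        assert np.array_equal(out, dmn)

    def test_invasive_case_refused(self, t1b_case):
        _, mask = t1b_case.slices[0]
        dmn = binarize(mask, TissueKind.DMN)
        assert relabel_dmn_by_class(t1b_case, dmn) is None

    def test_empty_mask_on_benign_case_is_empty_nevus_mask(self, mmd_case):
        empty = np.zeros(mmd_case.slices[0][1].shape, dtype=np.uint8)
        out = relabel_dmn_by_class(mmd_case, empty)
        assert out.sum() == 0


class TestRebalance:
    def test_upward_balance_reaches_paper_scale_counts(self):
        annotated = NestTrainSet(
            patches=[_shared_patch(NEVUS) for _ in range(604)]
            + [_shared_patch(MELANOMA) for _ in range(5732)])
        pool = [_shared_patch(NEVUS, "relabeled") for _ in range(6000)]
        out = rebalance(annotated, pool, rng_seed=0)
        assert out.counts == {NEVUS: 5732, MELANOMA: 5732}
        # every annotated patch is conserved
        ann = set(map(id, annotated.patches))
        assert ann <= set(map(id, out.patches))

    def test_balanced_input_with_empty_pool_unchanged(self):
        annotated = NestTrainSet(
            patches=[_shared_patch(NEVUS), _shared_patch(MELANOMA)])
        out = rebalance(annotated, [], rng_seed=0)
        assert out.counts == annotated.counts

    def test_insufficient_pool_balances_downward_and_logs(self, caplog):
        annotated = NestTrainSet(
            patches=[_shared_patch(NEVUS) for _ in range(10)]
            + [_shared_patch(MELANOMA) for _ in range(50)])
        pool = [_shared_patch(NEVUS, "relabeled") for _ in range(10)]
        with caplog.at_level(logging.WARNING, logger="skindx.nestnet"):
            out = rebalance(annotated, pool, rng_seed=0)
        assert out.counts == {NEVUS: 20, MELANOMA: 20}
        assert any("short" in rec.message for rec in caplog.records)

    def test_melanoma_in_pool_rejected(self):
        annotated = NestTrainSet(patches=[_shared_patch(NEVUS)])
        with pytest.raises(ValueError, match="nevus"):
            rebalance(annotated, [_shared_patch(MELANOMA)], rng_seed=0)


def _color_coded_patches(n_per_class, seed=0):
    """Trivially separable nests: nevus bluish, melanoma reddish."""
    rng = np.random.default_rng(seed)
    patches = []
    for label, color in ((NEVUS, (40, 40, 200)), (MELANOMA, (200, 40, 40))):
        for _ in range(n_per_class):
            img = np.zeros((PS, PS, 3), dtype=np.uint8)
            img[20:80, 20:80] = np.clip(
                np.asarray(color) + rng.normal(0, 10, (60, 60, 3)), 0, 255)
            patches.append(NestPatch(image=img, label=label))
    return patches


class TestClassifier:
    def test_separable_patches_learned_almost_perfectly(self):
        train = NestTrainSet(patches=_color_coded_patches(40))
        model, metrics = train_nest_classifier(train, epochs=20, seed=0)
        acc = binary_metrics  # noqa: F841 (alias for readability)
        assert metrics["f_score"] >= 0.99
        assert metrics["sensitivity"] >= 0.99

    def test_seeded_training_is_reproducible(self):
        train = NestTrainSet(patches=_color_coded_patches(12))
        _, m1 = train_nest_classifier(train, epochs=2, seed=7)
        _, m2 = train_nest_classifier(train, epochs=2, seed=7)
        assert m1 == m2

    def test_single_class_training_set_rejected(self):
        X = np.zeros((4, PS, PS, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="single class"):
            NestClassifier(epochs=1).fit(X, [NEVUS] * 4)

    def test_pretrained_backbones_unavailable(self):
        X = np.zeros((4, PS, PS, 3), dtype=np.uint8)
        y = [NEVUS, MELANOMA, NEVUS, MELANOMA]
        with pytest.raises(RuntimeError, match="pretrained"):
            NestClassifier(backbone="resnet", epochs=1).fit(X, y)


class _OracleModel:
    """Stub classifier answering a fixed label for every window."""

    def __init__(self, answer):
        self.answer = answer

    def predict(self, X):
        return np.asarray([self.answer] * len(X))


class TestSplitDmn:
    def test_partition_exact_on_synthetic_slice(self, t1b_case):
        rgb, mask = t1b_case.slices[t1b_case.roi[0]]
        dmn = binarize(mask, TissueKind.DMN)
        m, n = split_dmn(rgb, dmn, _OracleModel(MELANOMA))
        assert np.array_equal(m | n, dmn)
        assert not np.any(m & n)

    def test_always_melanoma_oracle_claims_all_dmn(self, t1b_case):
        rgb, mask = t1b_case.slices[t1b_case.roi[0]]
        dmn = binarize(mask, TissueKind.DMN)
        m, n = split_dmn(rgb, dmn, _OracleModel(MELANOMA))
        assert np.array_equal(m, dmn)
        assert n.sum() == 0

    def test_always_nevus_oracle_claims_nothing(self, t1b_case):
        rgb, mask = t1b_case.slices[t1b_case.roi[0]]
        dmn = binarize(mask, TissueKind.DMN)
        m, n = split_dmn(rgb, dmn, _OracleModel(NEVUS))
        assert m.sum() == 0
        assert np.array_equal(n, dmn)

    def test_empty_mask_gives_two_empty_masks(self):
        rgb = np.zeros((150, 150, 3), dtype=np.uint8)
        m, n = split_dmn(rgb, np.zeros((150, 150), np.uint8),
                         _OracleModel(MELANOMA))
        assert m.sum() == 0 and n.sum() == 0
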