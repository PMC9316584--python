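"""Soft labels, aggregator geometry/forward, schedule, checkpoint averaging."""

import numpy as np
import pytest

from skindx.featext import SCALES, ScaleBag
from skindx.labels import DiagnosisClass
from skindx.scat import (Checkpoint, CheckpointSet, ScatConfig, ScatNet,
                         assign_soft_labels, average_checkpoints,
                         desk_profile, scat_forward)
from skindx.synthdata import SlideCase


def _case(n_slices, diagnosis, roi_index=0):
    rng = np.random.default_rng(0)
    slices = [(rng.integers(0, 255, (64, 64, 3), dtype=np.uint8),
               np.zeros((64, 64), dtype=np.uint8)) for _ in range(n_slices)]
    return SlideCase(case_id="toy", diagnosis=diagnosis, slices=slices,
                     roi=(roi_index, (0, 0, 10, 10)))


class TestSoftLabels:
    def test_single_slice_case_is_one_hot(self):
        case = _case(1, DiagnosisClass.T1a)
        labels = assign_soft_labels(case, np.zeros((1, 8)))
        assert np.array_equal(labels, [[0, 0, 1, 0]])

    def test_slice_identical_to_roi_slice_gets_full_class_weight(self):
        case = _case(3, DiagnosisClass.T1b, roi_index=0)
        feats = np.array([[2.0, 1.0], [2.0, 1.0], [-1.0, 0.5]])
        labels = assign_soft_labels(case, feats)
        assert np.array_equal(labels[0], [0, 0, 0, 1])   # ROI slice one-hot
        assert np.array_equal(labels[1], [0, 0, 0, 1])   # identical slice

    def test_three_slice_toy_matches_hand_svd(self):
        # features in 2-D; centered matrix has rank 1 along (1, 0):
        # rows (2,0), (2,0), (-4,0); scores t = (2, 2, -4).
        # slice 1: sign(t1*t0)=+1 -> alpha 1 -> one-hot class.
        # slice 2: sign(t2*t0)=-1 -> alpha 0 -> one-hot MMD.
        case = _case(3, DiagnosisClass.T1a, roi_index=0)
        feats = np.array([[3.0, 5.0], [3.0, 5.0], [-3.0, 5.0]])
        labels = assign_soft_labels(case, feats)
        assert np.allclose(labels[0], [0, 0, 1, 0])
        assert np.allclose(labels[1], [0, 0, 1, 0])
        assert np.allclose(labels[2], [1, 0, 0, 0])

    def test_labels_always_on_simplex(self):
        rng = np.random.default_rng(3)
        for n in (2, 3, 5):
            case = _case(n, DiagnosisClass.MIS, roi_index=n - 1)
            labels = assign_soft_labels(case, rng.normal(size=(n, 6)))
            assert np.all(labels >= 0)
            assert np.allclose(labels.sum(axis=1), 1.0, atol=1e-6)

    def test_onehot_strategy_ignores_features(self):
        case = _case(3, DiagnosisClass.MIS)
        labels = assign_soft_labels(case, np.random.default_rng(0).normal(
            size=(3, 4)), strategy="onehot")
        assert np.array_equal(labels, np.tile([0, 1, 0, 0], (3, 1)))

    def test_case_without_roi_rejected(self):
        case = _case(2, DiagnosisClass.MMD)
        case.roi = None
        with pytest.raises(ValueError, match="ROI"):
            assign_soft_labels(case, np.zeros((2, 4)))


class TestConfig:
    def test_defaults_match_published_geometry(self):
        cfg = ScatConfig()
        assert cfg.n_transformer_units == 2
        assert cfg.n_heads == 4
        assert cfg.ff_dim == 512
        assert cfg.model_dim == 128
        assert cfg.epochs == 200

    def test_model_dim_must_divide_by_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            ScatConfig(model_dim=130)

    def test_scales_required(self):
        with pytest.raises(ValueError, match="scale"):
            ScatConfig(scales=())

    def test_schedule_warms_up_linearly_then_decays(self):
        cfg = ScatConfig(epochs=100, lr=1.0)   # warmup 5, decay every 25
        lrs = [cfg.lr_at(e) for e in range(100)]
        assert lrs[0] == pytest.approx(1.0 / 5)
        assert all(b >= a for a, b in zip(lrs[:5], lrs[1:5]))
        assert lrs[4] == pytest.approx(1.0)
        assert lrs[5 + 25] == pytest.approx(0.5)
        assert lrs[5 + 50] == pytest.approx(0.25)


class TestForward:
    def _bags(self, seed=0):
        rng = np.random.default_rng(seed)
        return {"7.5x": ScaleBag(scale=SCALES["7.5x"],
                                 embeddings=rng.normal(size=(25, 1280)))}

    def test_single_scale_outputs_four_scores(self):
        model = ScatNet(desk_profile(), np.random.default_rng(0))
        scores = scat_forward(self._bags(), model)
        assert scores.shape == (4,)
        assert np.all(np.isfinite(scores))
        p = np.exp(scores - scores.max())
        assert p.sum() > 0

    def test_patch_permutation_invariant_without_positions(self):
        cfg = desk_profile(use_positions=False)
        model = ScatNet(cfg, np.random.default_rng(0))
        bags = self._bags()
        base = scat_forward(bags, model)
        perm = np.random.default_rng(1).permutation(25)
        shuffled = {"7.5x": ScaleBag(scale=SCALES["7.5x"],
                                     embeddings=bags["7.5x"].embeddings[perm])}
        assert np.allclose(scat_forward(shuffled, model), base, atol=1e-4)

    def test_positions_break_permutation_invariance(self):
        model = ScatNet(desk_profile(use_positions=True),
                        np.random.default_rng(0))
        bags = self._bags()
        base = scat_forward(bags, model)
        perm = np.roll(np.arange(25), 7)
        shuffled = {"7.5x": ScaleBag(scale=SCALES["7.5x"],
                                     embeddings=bags["7.5x"].embeddings[perm])}
        assert not np.allclose(scat_forward(shuffled, model), base, atol=1e-4)

    def test_two_scales_share_output_shape(self):
        cfg = desk_profile(scales=("7.5x", "12.5x"))
        model = ScatNet(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        bags = {"7.5x": ScaleBag(scale=SCALES["7.5x"],
                                 embeddings=rng.normal(size=(25, 1280))),
                "12.5x": ScaleBag(scale=SCALES["12.5x"],
                                  embeddings=rng.normal(size=(81, 1280)))}
        assert scat_forward(bags, model).shape == (4,)

    def test_wrong_sequence_length_rejected(self):
        model = ScatNet(desk_profile(), np.random.default_rng(0))
        bad = {"7.5x": np.zeros((1, 24, 1280))}
        with pytest.raises(ValueError, match="expected"):
            model.forward(bad)

    def test_forward_deterministic_given_weights(self):
        model = ScatNet(desk_profile(), np.random.default_rng(5))
        bags = self._bags(3)
        assert np.array_equal(scat_forward(bags, model),
                              scat_forward(bags, model))


def _ckpt(epoch, score, value):
    return Checkpoint(epoch=epoch, score=score,
                      weights={"w": np.full((2, 2), float(value))})


class TestCheckpointAveraging:
    def test_identical_checkpoints_average_to_themselves(self):
        cs = CheckpointSet([_ckpt(e, 0.5, 7.0) for e in range(5)])
        out = average_checkpoints(cs, k=5)
        assert np.array_equal(out["w"], np.full((2, 2), 7.0))

    def test_top_five_selected_by_score(self):
        scores = [0.1, 0.9, 0.5, 0.8, 0.7, 0.6]
        cs = CheckpointSet([_ckpt(e, s, e) for e, s in enumerate(scores)])
        out = average_checkpoints(cs, k=5)
        # epochs 1..5 selected (0.1 at epoch 0 dropped); mean epoch value 3
        assert np.allclose(out["w"], 3.0)

    def test_k_one_returns_argmax_checkpoint(self):
        cs = CheckpointSet([_ckpt(0, 0.2, 10), _ckpt(1, 0.9, 20),
                            _ckpt(2, 0.4, 30)])
        assert np.allclose(average_checkpoints(cs, k=1)["w"], 20.0)

    def test_tie_broken_toward_later_epoch(self):
        cs = CheckpointSet([_ckpt(0, 0.8, 1), _ckpt(1, 0.8, 2)])
        assert np.allclose(average_checkpoints(cs, k=1)["w"], 2.0)

    def test_fewer_than_k_averages_all(self, caplog):
        import logging
        cs = CheckpointSet([_ckpt(0, 0.5, 2), _ckpt(1, 0.6, 4)])
        with caplog.at_level(logging.WARNING, logger="skindx.scat"):
            out = average_checkpoints(cs, k=5)
        assert np.allclose(out["w"], 3.0)
        assert any("averaging all" in r.message for r in caplog.records)

    def test_duplicate_epochs_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CheckpointSet([_ckpt(0, 0.5, 1), _ckpt(0, 0.6, 2)])

    def test_averaging_preserves_weight_shapes(self):
        cs = CheckpointSet([_ckpt(e, 0.1 * e, e) for e in range(7)])
        out = average_checkpoints(cs, k=5)
        assert out["w"].shape == (2, 2)
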