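"""Loss, augmentation, training schedule, patch/ROI inference, Grad-CAM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleoscore.config import AugmentConfig, RegressorConfig
from pleoscore.detection import NoTumorError, detect_cells
from pleoscore.nn import DenseRegressorNet
from pleoscore.regressor import (
    ArraySource,
    PleomorphismRegressor,
    TrainController,
    augment,
    dihedral,
    predict_patch,
    saliency,
    score_roi,
    smooth_l1,
    smooth_l1_grad,
    train,
)
from pleoscore.synthetic import generate_nucleus_field, render_patch

from conftest import StubNet


class TestSmoothL1:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0.0),
        (0.5, 0.125),   # 0.5 * 0.25
        (2.0, 1.5),     # 2 - 0.5
        (-2.0, 1.5),
    ])
    def test_worked_values(self, d, expected):
        assert smooth_l1(d, 0.0) == pytest.approx(expected)

    def test_beta_validation(self):
        with pytest.raises(ValueError):
            smooth_l1(1.0, 0.0, beta=0.0)

    @given(st.floats(-50, 50), st.floats(0.1, 5))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, d, beta):
        """Non-negative, sign-symmetric, monotone, linear tail - beta/2."""
        v = smooth_l1(d, 0.0, beta)
        assert v >= 0
        assert v == pytest.approx(smooth_l1(-d, 0.0, beta))
        assert smooth_l1(abs(d) + 0.5, 0.0, beta) >= v
        if abs(d) > beta:
            assert v == pytest.approx(abs(d) - 0.5 * beta)

    def test_continuous_and_smooth_at_beta(self):
        beta = 1.0
        eps = 1e-7
        lo = smooth_l1(beta - eps, 0.0, beta)
        hi = smooth_l1(beta + eps, 0.0, beta)
        assert hi - lo == pytest.approx(0.0, abs=1e-5)
        g_lo = smooth_l1_grad(beta - eps, 0.0, beta)
        g_hi = smooth_l1_grad(beta + eps, 0.0, beta)
        assert g_hi - g_lo == pytest.approx(0.0, abs=1e-5)


class TestAugment:
    def _patch(self, seed=0):
        nuc = generate_nucleus_field(2.0, 4000, (0, 0, 64, 64),
                                     "tumor", seed)
        return render_patch(nuc, 64, seed=seed)

    def test_zero_ranges_identity(self):
        p = self._patch()
        assert np.array_equal(augment(p, 3, AugmentConfig.off()), p)

    def test_dihedral_only_membership(self):
        p = self._patch(1)
        cfg = AugmentConfig(dihedral=True, stain_scale=0, stain_offset=0,
                            blur_sigma_max=0)
        out = augment(p, 11, cfg)
        variants = [dihedral(p, k) for k in range(8)]
        assert any(np.array_equal(out, v) for v in variants)

    def test_dihedral_preserves_nucleus_count(self):
        """Appearance-only augmentation: geometry cue (count) invariant."""
        nuc = generate_nucleus_field(2.5, 4000, (0, 0, 64, 64), "tumor", 2)
        p = render_patch(nuc, 64, seed=2)
        for k in range(8):
            out = dihedral(p, k)
            assert out.shape == p.shape
            # dark-pixel mass is a proxy for total nuclear content
            assert out.mean() == pytest.approx(p.mean())

    def test_seeded_determinism_and_range(self):
        p = self._patch(3)
        a = augment(p, 5)
        b = augment(p, 5)
        assert np.array_equal(a, b)
        assert a.dtype == np.uint8 and a.shape == p.shape


class TestSchedule:
    def test_controller_exact_decay_and_stop(self):
        """LR x0.7 after exactly 10 stagnant epochs; stop at 10."""
        ctrl = TrainController(lr=1e-4)
        ctrl.update(1, 1.0)   # establishes the best epoch
        for epoch in range(2, 11):   # stagnant counts 1..9: nothing fires
            improved, decayed, stop = ctrl.update(epoch, 1.0)
            assert not decayed and not stop
            assert ctrl.lr == 1e-4
        improved, decayed, stop = ctrl.update(11, 1.0)   # 10th stagnant
        assert decayed and stop
        assert ctrl.lr == pytest.approx(0.7e-4)
        assert ctrl.best_epoch == 1

    def test_controller_decay_resets_lr_counter(self):
        ctrl = TrainController(lr=1.0, lr_patience=3,
                               early_stop_patience=100)
        ctrl.update(1, 1.0)
        lrs = []
        for epoch in range(2, 9):
            ctrl.update(epoch, 1.0)
            lrs.append(ctrl.lr)
        # decays at stagnant counts 3 and 6
        assert lrs == pytest.approx([1, 1, 0.7, 0.7, 0.7, 0.49, 0.49])

    def test_improvement_resets_counters(self):
        ctrl = TrainController(lr=1.0, lr_patience=2,
                               early_stop_patience=3)
        seq = [5.0, 4.0, 4.5, 3.0, 3.5, 3.6, 3.7]
        stops = [ctrl.update(i + 1, v)[2] for i, v in enumerate(seq)]
        assert stops == [False] * 6 + [True]
        assert ctrl.best_epoch == 4


class _ScriptedNet(StubNet):
    """Per-epoch scripted validation output; 1 training iter per epoch."""

    def __init__(self, values):
        super().__init__(values[0])
        self.values = list(values)
        self.iters = 0
        self.params = {"v": np.array([values[0]])}

    def forward(self, x):
        return np.full(len(x), self.value)

    def backward(self, dout, capture_block=None):
        # called once per training iteration = once per epoch
        self.iters += 1
        if self.iters < len(self.values):
            self.value = self.values[self.iters]
        self.params["v"][0] = self.value

    def get_weights(self):
        return [self.params["v"].copy()]

    def set_weights(self, weights):
        self.params["v"][...] = weights[0]


def _stub_config(**kw):
    base = dict(input_size=8, batch_size=2, train_iters_per_epoch=1,
                val_iters_per_epoch=1, max_epochs=50, weight_decay=0.0,
                lr_patience=10, early_stop_patience=10)
    base.update(kw)
    return RegressorConfig.desk(**base)


def _stub_source(target=2.0):
    X = np.full((4, 8, 8, 3), 128, np.uint8)
    return ArraySource(X, np.full(4, target))


class TestTrainLoop:
    def test_frozen_loss_schedule(self):
        """Frozen validation: decay and stop at exactly 10 stagnant."""
        net = _ScriptedNet([2.0] * 60)
        cfg = _stub_config()
        _, hist = train(net, _stub_source(), _stub_source(), cfg,
                        augment_cfg=None)
        assert hist.epoch[-1] == 11          # 1 best + 10 stagnant
        assert hist.best_epoch == 1
        assert hist.lr == pytest.approx([cfg.lr_init] * 11)

    def test_best_epoch_snapshot_returned(self):
        # value after epoch e's single iteration: 3, 2, 2.5, 2.5, 2.5
        # -> val loss vs target 2 is minimal at epoch 2 (value 2.0)
        net = _ScriptedNet([4.0, 3.0, 2.0, 2.5, 2.5, 2.5])
        cfg = _stub_config(early_stop_patience=3, lr_patience=3,
                           max_epochs=6)
        model, hist = train(net, _stub_source(target=2.0),
                            _stub_source(target=2.0), cfg)
        assert hist.best_epoch == 2
        assert model.params["v"][0] == pytest.approx(2.0)
        assert np.argmin(hist.val_loss) + 1 == hist.best_epoch
        # lr non-increasing history invariant
        assert all(b <= a for a, b in zip(hist.lr, hist.lr[1:]))

    def test_nan_loss_aborts(self):
        net = _ScriptedNet([np.nan])
        with pytest.raises((FloatingPointError, ValueError)):
            train(net, _stub_source(), _stub_source(), _stub_config())

    def test_easy_task_converges(self):
        """Brightness-encodes-target toy: val loss collapses quickly."""
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 3, 240)
        X = np.clip((y[:, None, None, None] - 1) / 2 * 200 + 20
                    + rng.normal(0, 2, (240, 16, 16, 3)),
                    0, 255).astype(np.uint8)
        cfg = RegressorConfig.desk(
            input_size=16, stem_channels=4, dense_block_layout=(2, 2),
            growth_rate=4, train_iters_per_epoch=40,
            val_iters_per_epoch=5, max_epochs=10, lr_init=3e-3, seed=0)
        net = DenseRegressorNet(cfg)
        net, hist = train(net, ArraySource(X[:200], y[:200]),
                          ArraySource(X[200:], y[200:]), cfg,
                          augment_cfg=AugmentConfig.off())
        assert min(hist.val_loss) < 0.1 * hist.val_loss[0]

    def test_deterministic_history(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 3, 60)
        X = rng.integers(0, 255, (60, 16, 16, 3)).astype(np.uint8)
        cfg = RegressorConfig.desk(
            input_size=16, stem_channels=4, dense_block_layout=(2, 2),
            growth_rate=3, train_iters_per_epoch=5,
            val_iters_per_epoch=2, max_epochs=3, seed=4)
        hists = []
        for _ in range(2):
            net = DenseRegressorNet(cfg)
            _, hist = train(net, ArraySource(X, y), ArraySource(X, y), cfg)
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss


class TestPredictAndScore:
    def test_constant_model_predicts_two(self, constant_net):
        patch = np.zeros((64, 64, 3), np.uint8)
        assert predict_patch(constant_net, patch) == 2.0

    def test_wrong_shape_rejected(self, constant_net):
        with pytest.raises(ValueError):
            predict_patch(constant_net, np.zeros((32, 32, 3), np.uint8))

    def test_output_clamped(self):
        net = StubNet(7.3)
        assert predict_patch(net, np.zeros((64, 64, 3), np.uint8)) == 3.0
        net = StubNet(-1.0)
        assert predict_patch(net, np.zeros((64, 64, 3), np.uint8)) == 1.0

    def _roi(self, seed=0, size=160):
        nuc = generate_nucleus_field(2.0, 4000, (0, 0, size, size),
                                     "tumor", seed)
        img = render_patch(nuc, size, seed=seed)
        return img, detect_cells(img, "oracle", nuc)

    def test_score_roi_constant_model(self, constant_net):
        roi, dets = self._roi()
        assert score_roi(constant_net, roi, dets, 8, seed=0) == 2.0

    def test_score_roi_no_tumor_errors(self, constant_net):
        roi, dets = self._roi()
        normal = dets.subset(dets.label == "normal")
        with pytest.raises(NoTumorError):
            score_roi(constant_net, roi, normal, 8, seed=0)

    def test_score_roi_variance_shrinks_with_patches(self, desk_model):
        roi, dets = self._roi(seed=9, size=192)
        net = desk_model.net_
        lo = [score_roi(net, roi, dets, 4, seed=s) for s in range(12)]
        hi = [score_roi(net, roi, dets, 32, seed=s) for s in range(12)]
        assert np.var(hi) < np.var(lo)


class TestSaliency:
    def test_contract_and_zero_flag(self, constant_net):
        net = DenseRegressorNet(RegressorConfig.desk(seed=0))
        net.head.params["w"][...] = 0.0
        net.head.params["b"][...] = 2.0
        patch = np.zeros((64, 64, 3), np.uint8)
        cam, flagged = saliency(net, patch)
        assert cam.shape == (64, 64)
        assert flagged and (cam == 0).all()

    def test_trained_model_map_in_range(self, desk_model):
        nuc = generate_nucleus_field(2.5, 4000, (0, 0, 64, 64), "tumor", 1)
        patch = render_patch(nuc, 64, seed=1)
        cam, flagged = saliency(desk_model.net_, patch)
        assert cam.shape == (64, 64)
        assert not flagged
        assert 0 <= cam.min() and cam.max() == pytest.approx(1.0)


class TestEstimator:
    def test_sklearn_protocol(self):
        est = PleomorphismRegressor()
        params = est.get_params()
        assert "config" in params and "augment_config" in params
        est.set_params(val_fraction=0.3)
        assert est.val_fraction == 0.3

    def test_rejects_bad_targets(self):
        est = PleomorphismRegressor(config=RegressorConfig.desk())
        X = np.zeros((4, 64, 64, 3), np.uint8)
        with pytest.raises(ValueError):
            est.fit(X, [0.2, 1.0, 2.0, 3.0])

    def test_fitted_attributes(self, desk_model):
        assert hasattr(desk_model, "net_")
        assert desk_model.n_params_ == desk_model.net_.n_params
        assert desk_model.history_.best_epoch >= 1

    def test_predict_within_range(self, desk_model, patch_split):
        _, (Xte, _) = patch_split
        preds = desk_model.predict(Xte[:50])
        assert ((preds >= 1.0) & (preds <= 3.0)).all()
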