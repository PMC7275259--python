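"""Network architecture exactness, training loop, event prediction."""

import numpy as np
import pytest

from apneaflow import cnn3d, synthdata, windowing
from apneaflow.cnn3d import ArchitectureError
from apneaflow.flowproc import FlowSequence
from apneaflow.nn import Dense, Sequential, TrainConfig
from apneaflow.nn.model import class_weights_from_labels, weighted_bce
from apneaflow.windowing import ApneaEvent

#: Published layer-by-layer output sizes of the whole-body network at the
#: nominal 480x640 input (H, W, T, C; flatten/dense rows as widths).
TABLE_SHAPES = [
    (23, 31, 20, 2),   # average pool 25x25x1 / 20x20x1
    (22, 30, 20, 8),   # conv 8 @ 2x2x1
    (22, 30, 20, 8),   # dropout
    (20, 28, 16, 16),  # conv 16 @ 3x3x5
    (7, 11, 16, 16),   # max pool 8x8x1 / 2x2x1
    (7, 11, 16, 16),   # batch norm
    (6, 10, 15, 64),   # conv 64 @ 2x2x2
    (6, 10, 15, 64),   # batch norm
    (3, 7, 15, 32),    # conv 32 @ 4x4x1
    (3, 7, 15, 32),    # batch norm
    (3, 7, 15, 32),    # dropout
    (2, 6, 15, 16),    # conv 16 @ 2x2x1
    (2, 6, 15, 16),    # batch norm
    2880,              # flatten
    16,                # fully connected
    4,                 # fully connected
    1,                 # sigmoid output
]


class TestWholeBodyArchitecture:
    def test_shapes_match_published_table(self):
        spec, _ = cnn3d.build_whole_body_net(instantiate=False)
        assert spec.propagate() == TABLE_SHAPES

    def test_parameter_counts(self):
        spec, net = cnn3d.build_whole_body_net()
        assert spec.parameter_counts() == (95_649, 95_393, 256)
        assert cnn3d.count_parameters(net) == (95_649, 95_393, 256)
        assert spec.flatten_width == 2880

    def test_desk_preset_is_parameter_identical(self):
        spec, _ = cnn3d.build_whole_body_net((48, 64, 20, 2), instantiate=False)
        assert spec.parameter_counts() == (95_649, 95_393, 256)
        # identical from the first pooled grid onward
        assert spec.propagate() == TABLE_SHAPES

    def test_unknown_frame_size_needs_explicit_pool(self):
        with pytest.raises(ArchitectureError, match="preset"):
            cnn3d.build_whole_body_net((100, 100, 20, 2))

    def test_kernels_clamp_on_small_inputs(self):
        # a 30x30 frame pools to a 1x1 grid; later kernels clamp instead of
        # failing, so the stack stays valid end to end
        spec = cnn3d.NetworkSpec(
            input_shape=(30, 30, 20, 2),
            layers=cnn3d._core_stack((25, 25, 1), (20, 20, 1)),
        )
        shapes = spec.propagate()
        assert shapes[0] == (1, 1, 20, 2)
        assert shapes[-1] == 1

    def test_invalid_layer_errors_name_the_layer(self):
        spec = cnn3d.NetworkSpec(
            input_shape=(8, 8, 4, 2),
            layers=[cnn3d.LayerSpec("dense", filters=4, name="fc_bad")],
        )
        with pytest.raises(ArchitectureError, match="fc_bad"):
            spec.propagate()


def test_count_parameters_hand_examples():
    dense = Sequential([Dense(2880, 16)])
    assert cnn3d.count_parameters(dense) == (46_096, 46_096, 0)
    no_bn = Sequential([Dense(10, 5), Dense(5, 1)])
    assert cnn3d.count_parameters(no_bn)[2] == 0


class TestTwoBranch:
    def test_branch_pool_output(self):
        branch_spec, _ = cnn3d.build_two_branch_net(crop_size=100, instantiate=False)
        assert branch_spec.propagate()[0] == (19, 19, 20, 2)

    def test_forward_probability_on_zeros(self):
        _, model = cnn3d.build_two_branch_net(crop_size=32)
        model.initialize(np.random.default_rng(0))
        za = np.zeros((2, 32, 32, 20, 2), dtype=np.float32)
        p = model.forward((za, za.copy()))
        assert p.shape == (2, 1)
        assert np.all((p > 0) & (p < 1))

    def test_frozen_branch_receives_no_gradient(self):
        _, model = cnn3d.build_two_branch_net(crop_size=32)
        model.initialize(np.random.default_rng(0))
        model.branch_b.frozen = True
        rng = np.random.default_rng(1)
        xa = rng.normal(0, 1, (4, 32, 32, 20, 2)).astype(np.float32)
        xb = rng.normal(0, 1, (4, 32, 32, 20, 2)).astype(np.float32)
        p = model.forward((xa, xb), train=True)
        _, dp = weighted_bce(p, np.array([0, 1, 0, 1]), np.ones(2, dtype=np.float32))
        model.backward(dp)
        frozen_grads = [g for l in model.branch_b.layers for g in l.grads()]
        live_grads = [g for l in model.branch_a.layers for g in l.grads()]
        assert all(np.all(g == 0) for g in frozen_grads)
        assert any(np.any(g != 0) for g in live_grads)
        assert model.branch_b.params() == []  # excluded from the optimizer

    def test_crop_smaller_than_pool_rejected(self):
        with pytest.raises(ArchitectureError, match="pool"):
            cnn3d.build_two_branch_net(crop_size=8)


class TestTraining:
    def test_class_weight_ratio_matches_inverse_frequency(self):
        labels = np.concatenate([np.zeros(313), np.ones(40)])  # OA=0, CA=1
        w = class_weights_from_labels(labels)
        assert w[1] / w[0] == pytest.approx(313 / 40)  # ~7.825
        sample_mean = (313 * w[0] + 40 * w[1]) / 353  # normalized to mean 1
        assert sample_mean == pytest.approx(1.0)

    def test_class_weight_linearity(self):
        """Duplicating CA samples while halving their weight keeps the
        summed epoch-0 loss unchanged."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 12)
        y = np.array([0, 1] * 6)
        w = np.array([1.0, 4.0], dtype=np.float32)
        loss, _ = weighted_bce(p, y, w)
        p2 = np.concatenate([p, p[y == 1]])
        y2 = np.concatenate([y, np.ones(6, dtype=int)])
        w2 = np.array([1.0, 2.0], dtype=np.float32)
        loss2, _ = weighted_bce(p2, y2, w2)
        assert loss * len(y) == pytest.approx(loss2 * len(y2), rel=1e-5)

    def test_single_class_rejected(self):
        net = Sequential([Dense(4, 1)])
        x = np.zeros((6, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="single class"):
            cnn3d.train(net, x, np.zeros(6), x, np.array([0, 1, 0, 1, 0, 1]),
                        TrainConfig(max_epochs=1))

    def test_identical_seeds_reproduce_losses(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (24, 8, 8, 4, 2)).astype(np.float32)
        y = np.tile([0, 1], 12)
        from apneaflow.nn import AvgPool3D, Conv3D, Flatten, ReLU, Sigmoid

        def make():
            return Sequential([
                AvgPool3D((2, 2, 1), (2, 2, 1)), Conv3D(2, 4, (2, 2, 2)), ReLU(),
                Flatten(), Dense(4 * 3 * 3 * 3, 1), Sigmoid(),
            ])

        cfg = TrainConfig(max_epochs=4, batch_size=8, patience=10, seed=11)
        run1 = cnn3d.train(make(), x, y, x, y, cfg)
        run2 = cnn3d.train(make(), x, y, x, y, cfg)
        assert run1.history["loss"] == run2.history["loss"]
        assert run1.history["val_mcc"] == run2.history["val_mcc"]


@pytest.fixture(scope="module")
def trained_whole_body():
    """Whole-body net trained on a small seeded synthetic cohort."""
    scene = synthdata.default_scene((48, 64))
    recs = []
    for i in range(28):
        label = "OA" if i % 2 == 0 else "CA"
        rng = np.random.default_rng(300 + i)
        d = float(rng.uniform(12.0, 16.0))
        spec = synthdata.make_event_spec(label, 5.0, d, rng)
        rec = synthdata.generate_recording(
            scene, [spec], fps=2.0, seed=400 + i, duration=d + 10.5,
            render_frames=False,
        )
        recs.append((rec["events"][0], rec["flow"]))
    tensors, labels = [], []
    for event, flow in recs[:20]:
        stride = 1.0 if event.label == "CA" else 5.0
        for w in windowing.make_windows(event, flow, stride=stride).windows:
            tensors.append(w.tensor)
            labels.append(event.y)
    val_t, val_y = [], []
    for event, flow in recs[20:]:
        for w in windowing.make_windows(event, flow, stride=1.0, mode="test").windows:
            val_t.append(w.tensor)
            val_y.append(event.y)
    _, net = cnn3d.build_whole_body_net((48, 64, 20, 2))
    cfg = TrainConfig(max_epochs=8, batch_size=16, patience=8, seed=5)
    trained = cnn3d.train(
        net,
        np.stack(tensors).astype(np.float32), np.array(labels),
        np.stack(val_t).astype(np.float32), np.array(val_y),
        cfg,
    )
    return trained, recs


def test_training_learns_synthetic_apneas(trained_whole_body):
    trained, _ = trained_whole_body
    loss = trained.history["loss"]
    assert loss[4] < loss[0]  # optimization makes progress
    assert max(trained.history["val_mcc"]) >= 0.8
    assert trained.best_epoch == int(np.argmax(trained.history["val_mcc"]))


def test_predict_event_votes_windows(trained_whole_body):
    trained, recs = trained_whole_body
    correct = 0
    for event, flow in recs[20:]:
        pred = cnn3d.predict_event(trained, event, flow)
        n_expected = windowing.window_count(event.duration, 1.0)
        assert len(pred.probabilities) == n_expected
        correct += pred.label == event.label
    assert correct >= 7  # 8 held-out events


class TestPredictEventContract:
    class _Constant:
        def __init__(self, p):
            self.p = p

        def predict_proba(self, x, batch_size=32):
            return np.full(len(x), self.p)

    def _flow(self):
        return FlowSequence(np.zeros((60, 8, 8, 2), dtype=np.float32), fps=2.0)

    def test_all_high_gives_ca_margin_one(self):
        event = ApneaEvent("r", 10.0, 20.0, "CA")
        pred = cnn3d.predict_event(self._Constant(0.9), event, self._flow())
        assert pred.label == "CA"
        assert pred.margin == 1.0
        assert len(pred.probabilities) == 11  # 10-s event at stride 1

    def test_constant_half_exercises_tie_break(self):
        event = ApneaEvent("r", 10.0, 20.0, "OA")
        pred = cnn3d.predict_event(self._Constant(0.5), event, self._flow())
        assert pred.label == "OA"
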