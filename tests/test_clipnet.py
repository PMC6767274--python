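import numpy as np
import pytest

from vfssdet.errors import ContractError, DegenerateDataError
from vfssdet.net import (NetworkConfig, TrainSchedule, build_network,
                         classify_clip, cosine_lr, count_parameters,
                         evaluate_accuracy, load_checkpoint, save_checkpoint,
                         train)
from vfssdet.net.layers import Conv3d, Linear, softmax
from vfssdet.net.model import STAGE_COUNTS, InceptionModuleSpec

TINY = {"conv1": 8, "stages": (16, 16, 16, 16)}


def tiny_cfg(variant="proposed", stream="rgb", size=32):
    return NetworkConfig(variant=variant, stream=stream,
                         channel_schedule=dict(TINY), input_size=size)


class TestArchitecture:
    def test_stage_counts(self):
        assert STAGE_COUNTS["baseline"] == (0, 2, 5, 2)
        assert STAGE_COUNTS["proposed"] == (3, 4, 6, 3)

    def test_module_spec_concatenates_to_width(self):
        b1, (b2r, b2), (b3r, b3), b4 = InceptionModuleSpec(64)
        assert b1 + b2 + b3 + b4 == 64

    @pytest.mark.parametrize("variant,stream,cin", [
        ("proposed", "rgb", 3), ("baseline", "flow", 2)])
    def test_forward_pass_and_softmax(self, variant, stream, cin):
        net = build_network(tiny_cfg(variant, stream))
        x = np.random.default_rng(0).random((1, 20, 32, 32, cin),
                                            dtype=np.float32)
        p = net.predict_proba(x)
        assert p.shape == (1, 2)
        assert p.sum() == pytest.approx(1.0, abs=1e-5)
        assert (p >= 0).all()

    def test_wrong_input_shape_rejected(self):
        net = build_network(tiny_cfg())
        with pytest.raises(ContractError):
            net.forward(np.zeros((1, 20, 48, 48, 3), dtype=np.float32))
        with pytest.raises(ContractError):
            net.forward(np.zeros((1, 19, 32, 32, 3), dtype=np.float32))

    def test_proposed_has_more_parameters(self):
        p = count_parameters(build_network(tiny_cfg("proposed")))
        b = count_parameters(build_network(tiny_cfg("baseline")))
        assert p > b

    def test_invalid_config(self):
        with pytest.raises(ContractError):
            NetworkConfig(variant="resnet")
        with pytest.raises(ContractError):
            NetworkConfig(stream="depth")


class TestCountParameters:
    def test_pointwise_conv_closed_form(self):
        conv = Conv3d(4, 8, (1, 1, 1))
        assert count_parameters(conv.params()) == 4 * 8 + 8

    def test_3x3x3_conv_closed_form(self):
        conv = Conv3d(2, 4, (3, 3, 3))
        assert count_parameters(conv.params()) == 27 * 2 * 4 + 4

    def test_linear(self):
        assert count_parameters(Linear(10, 2).params()) == 22


class TestCosineSchedule:
    SCHED = TrainSchedule(total_iterations=1000, warmup_iterations=100,
                          initial_lr=0.1)

    def test_peak_at_end_of_warmup(self):
        assert cosine_lr(100, self.SCHED) == pytest.approx(0.1)

    def test_zero_at_end(self):
        assert cosine_lr(1000, self.SCHED) == pytest.approx(0.0, abs=1e-12)

    def test_half_at_midpoint(self):
        assert cosine_lr(550, self.SCHED) == pytest.approx(0.05)

    def test_linear_ramp(self):
        assert cosine_lr(0, self.SCHED) == 0.0
        assert cosine_lr(50, self.SCHED) == pytest.approx(0.05)

    def test_warmup_must_be_shorter(self):
        with pytest.raises(ContractError):
            TrainSchedule(total_iterations=10, warmup_iterations=10)


class TestTraining:
    def test_loss_decreases(self, tiny_trained_net):
        _, _, losses = tiny_trained_net
        assert losses[-1] < losses[0]

    def test_separates_heldout_clips(self, tiny_trained_net):
        from vfssdet.synthetic import generate_clip_dataset

        net, _, _ = tiny_trained_net
        held = generate_clip_dataset(8, 8, seed=99, frame_size=(32, 32))
        assert evaluate_accuracy(net, held.rgb, held.labels) >= 0.75

    def test_bolus_scores_above_static(self, tiny_trained_net):
        net, ds, _ = tiny_trained_net
        pos = ds.rgb[ds.labels == 1][0]
        neg = ds.rgb[ds.labels == 0][0]
        assert classify_clip(net, pos) > classify_clip(net, neg)

    def test_deterministic_given_seed(self):
        from vfssdet.synthetic import generate_clip_dataset

        ds = generate_clip_dataset(4, 4, seed=3, frame_size=(32, 32))
        sched = TrainSchedule(total_iterations=12, warmup_iterations=4, seed=5)
        traces = []
        for _ in range(2):
            net = build_network(tiny_cfg())
            traces.append(train(net, ds.rgb, ds.labels, sched))
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_single_class_rejected(self):
        net = build_network(tiny_cfg())
        clips = np.zeros((4, 20, 32, 32, 3), dtype=np.float32)
        sched = TrainSchedule(total_iterations=5, warmup_iterations=1)
        with pytest.raises(DegenerateDataError):
            train(net, clips, [1, 1, 1, 1], sched)

    def test_classify_clip_range_and_determinism(self, tiny_trained_net):
        net, ds, _ = tiny_trained_net
        s1 = classify_clip(net, ds.rgb[0])
        s2 = classify_clip(net, ds.rgb[0])
        assert 0.0 <= s1 <= 1.0 and s1 == s2


def test_checkpoint_round_trip(tmp_path, tiny_trained_net):
    net, ds, _ = tiny_trained_net
    path = str(tmp_path / "ckpt.npz")
    save_checkpoint(net, path)
    back = load_checkpoint(path)
    np.testing.assert_allclose(back.predict_proba(ds.rgb[:2]),
                               net.predict_proba(ds.rgb[:2]), atol=1e-6)


def test_softmax_rows_sum_to_one():
    z = np.random.default_rng(0).standard_normal((5, 2)) * 10
    np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-6)
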