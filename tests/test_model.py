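"""Assembly and forward-pass behaviour of the six network variants."""

import numpy as np
import pytest

from _reference import two_stage_forward
from conftest import SIX_VARIANTS, extract_node_params, extract_post_params
from rkseg import ArchitectureConfig, build_rkseg
from rkseg.config import scale_schedule
from rkseg.losses import dice_ce_loss
from rkseg.model import RKSegNet
from rkseg.nn import SGD, Tensor


def cfg(o="L", b="E", d=3, k=8, inc=1, c=2, **kw):
    return ArchitectureConfig(orientation=o, backbone=b, depth=d, width=k,
                              in_channels=inc, num_classes=c, **kw)


class TestNodeWidths:
    def test_explicit_backbone_widths_grow_linearly(self):
        widths = RKSegNet.node_input_widths(cfg("L", "E", d=6, k=32))
        assert widths == [32, 64, 96, 128, 160, 192]

    def test_implicit_backbone_increment_nodes_see_all_stages(self):
        widths = RKSegNet.node_input_widths(cfg("L", "I", d=6, k=32))
        assert widths == [32, 64, 96, 96, 96, 96]

    def test_reduced_backbone_at_two_stages(self):
        widths = RKSegNet.node_input_widths(cfg("R", "R", d=4, k=8))
        assert widths == [8, 16, 16, 16]

    def test_built_nodes_match_declared_widths(self):
        net = build_rkseg(cfg("L", "I", d=4, k=4))
        assert [n.in_channels for n in net.nodes] == [4, 8, 8, 8]


class TestForwardContract:
    def test_logits_shape_matches_input_resolution(self, rng):
        net = build_rkseg(cfg("L", "E", d=3, k=8, c=2))
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        assert net.forward(x).data.shape == (1, 2, 64, 64)

    @pytest.mark.parametrize("variant", SIX_VARIANTS,
                             ids=lambda c: f"{c.orientation}{c.backbone}")
    def test_every_variant_emits_full_resolution_logits(self, variant, rng):
        net = build_rkseg(variant)
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        assert net.forward(x).data.shape == (2, 2, 32, 32)

    def test_channel_mismatch_rejected(self, rng):
        net = build_rkseg(cfg(inc=1))
        with pytest.raises(ValueError, match="channel mismatch"):
            net.forward(rng.normal(size=(1, 3, 32, 32)))

    def test_reject_policy_refuses_indivisible_sizes(self, rng):
        net = build_rkseg(cfg(d=3, pad_policy="reject"))
        with pytest.raises(ValueError, match="not divisible"):
            net.forward(rng.normal(size=(1, 1, 30, 30)))

    def test_pad_and_crop_returns_original_size(self, rng):
        net = build_rkseg(cfg(d=3))
        out = net.forward(rng.normal(size=(1, 1, 30, 29)).astype(np.float32))
        assert out.data.shape == (1, 2, 30, 29)


class TestIdentityAtZeroIncrement:
    @pytest.mark.parametrize("variant", SIX_VARIANTS,
                             ids=lambda c: f"{c.orientation}{c.backbone}")
    def test_zeroed_stages_make_y1_equal_y0(self, variant, rng):
        net = build_rkseg(variant, seed=5)
        net.zero_stage_outputs()
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        logits, state = net.forward(x, return_state=True)
        for e in state.e:
            np.testing.assert_array_equal(e, 0.0)
        np.testing.assert_array_equal(state.y1, state.y0)

    def test_zeroed_network_acts_as_pre_then_post(self, rng):
        net = build_rkseg(cfg("L", "E", d=2, k=4), seed=2)
        net.zero_stage_outputs()
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        logits = net.forward(x)
        direct = net.post(net.pre(Tensor(x)))
        np.testing.assert_array_equal(logits.data, direct.data)


class TestScaleBookkeeping:
    @pytest.mark.parametrize("variant", SIX_VARIANTS,
                             ids=lambda c: f"{c.orientation}{c.backbone}")
    def test_increment_shapes_follow_the_schedule(self, variant, rng):
        net = build_rkseg(variant)
        h = w = 32
        _, state = net.forward(
            rng.normal(size=(1, 1, h, w)).astype(np.float32), return_state=True
        )
        sched = scale_schedule(variant)
        s = variant.stages
        if variant.backbone == "E":
            e_div = [div for _, div in sched]
            x_div = []
        else:
            x_div = [div for _, div in sched[:s]]
            e_div = [div for _, div in sched[s:]]
        for e, div in zip(state.e, e_div):
            assert e.shape[2:] == (h // div, w // div)
        for xt, div in zip(state.x, x_div):
            assert xt.shape[2:] == (h // div, w // div)
        assert state.y1.shape == state.y0.shape


class TestOrientationDuality:
    @pytest.mark.parametrize("backbone,depth", [("E", 3), ("E", 6), ("I", 4),
                                                ("I", 6), ("R", 4), ("R", 6)])
    def test_mirror_variants_have_identical_counts_and_widths(self, backbone, depth):
        left = cfg("L", backbone, depth, k=8, inc=2, c=3)
        right = cfg("R", backbone, depth, k=8, inc=2, c=3)
        nl, nr = build_rkseg(left), build_rkseg(right)
        assert (nl.count_parameters_instantiated().total
                == nr.count_parameters_instantiated().total)
        assert sorted(RKSegNet.node_input_widths(left)) == sorted(
            RKSegNet.node_input_widths(right))


class TestStraightLineOracle:
    def test_two_stage_explicit_forward_matches_hand_trace(self, rng):
        """The engine's forward pass equals an independent loop-level trace
        of the two-stage explicit wiring (state + down-sampled increments)."""
        c = cfg("L", "E", d=2, k=1, inc=1, c=2)
        net = RKSegNet(c, rng=np.random.default_rng(9), dtype=np.float64)
        x = rng.normal(size=(1, 1, 8, 8))
        got = net.forward(x).data[0]
        expected = two_stage_forward(
            x[0],
            extract_node_params(net.pre),
            [extract_node_params(n) for n in net.nodes],
            extract_post_params(net.post),
            divisors=[div for _, div in net.schedule],
        )
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_reversed_two_stage_forward_matches_hand_trace(self, rng):
        c = cfg("R", "E", d=2, k=2, inc=1, c=2)
        net = RKSegNet(c, rng=np.random.default_rng(4), dtype=np.float64)
        x = rng.normal(size=(1, 1, 8, 8))
        got = net.forward(x).data[0]
        expected = two_stage_forward(
            x[0],
            extract_node_params(net.pre),
            [extract_node_params(n) for n in net.nodes],
            extract_post_params(net.post),
            divisors=[div for _, div in net.schedule],
        )
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)


def _norm_shadowed_bias(name: str) -> bool:
    # conv biases feeding an instance norm are invariant parameters:
    # the norm subtracts the per-channel mean, so their gradient is ~0
    return name.endswith("conv.bias") and "classifier" not in name


class TestGradientFlow:
    @pytest.mark.parametrize("variant", SIX_VARIANTS,
                             ids=lambda c: f"{c.orientation}{c.backbone}")
    def test_every_live_parameter_receives_gradient(self, variant, rng):
        net = build_rkseg(variant, seed=1)
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        labels = rng.integers(0, 2, size=(2, 32, 32))
        opt = SGD(net.parameters(), lr=0.01, momentum=0.9)
        loss = dice_ce_loss(net.forward(x), labels)
        opt.zero_grad()
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None, name
            if _norm_shadowed_bias(name):
                np.testing.assert_allclose(p.grad, 0.0, atol=1e-5,
                                           err_msg=name)
            else:
                assert np.any(p.grad != 0.0), f"dead branch: {name}"
        opt.step()  # completes one optimizer step without error


class TestCheckpointRoundTrip:
    def test_save_load_forward_is_bitwise_identical(self, tmp_path, rng):
        net = build_rkseg(cfg("L", "I", d=4, k=4, c=3), seed=8)
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        before = net.forward(x).data
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = RKSegNet.load(path)
        np.testing.assert_array_equal(loaded.forward(x).data, before)
        assert loaded.cfg == net.cfg

    def test_mismatched_state_rejected(self, tmp_path):
        net = build_rkseg(cfg("L", "E", d=2, k=2))
        sd = net.state_dict()
        sd.pop(next(iter(sd)))
        with pytest.raises(ValueError, match="state mismatch"):
            net.load_state_dict(sd)
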