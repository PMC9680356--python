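"""Architecture contracts: GC block behavior, bottleneck scale
unification, ExitBundle shape consistency, parameter ordering, frozen
teacher, checkpoints — plus an independent eval-mode forward pass built
on scipy to cross-check exit logits end to end."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import correlate2d

from cytodistill import nn
from cytodistill.models import (
    BACKBONE_PRESETS,
    BasicBlock,
    Bottleneck,
    ConfigurationError,
    ExitBranch,
    ExitBundle,
    GCBlock,
    MultiExitStudent,
    ResNetClassifier,
    StudentConfig,
    build_student,
    build_teacher,
    load_checkpoint,
    save_checkpoint,
)
from cytodistill.metrics import count_parameters


# ---------------------------------------------------------------------------
# independent eval-mode reference forward (scipy + plain numpy)

def _ref_conv(x, layer):
    w, b = layer.weight.data, (layer.bias.data if layer.bias is not None else None)
    s, p = layer.stride, layer.padding
    xp = np.pad(x, ((0, 0), (0, 0), (p,) * 2, (p,) * 2))
    n, _, _, _ = x.shape
    f = w.shape[0]
    outs = []
    for i in range(n):
        maps = [sum(correlate2d(xp[i, c], w[k, c], mode="valid")
                    for c in range(w.shape[1]))[::s, ::s] for k in range(f)]
        outs.append(np.stack(maps))
    out = np.stack(outs)
    if b is not None:
        out = out + b.reshape(1, f, 1, 1)
    return out


def _ref_bn_eval(x, layer):
    c = x.shape[1]
    mu = layer.running_mean.reshape(1, c, 1, 1)
    var = layer.running_var.reshape(1, c, 1, 1)
    xhat = (x - mu) / np.sqrt(var + layer.eps)
    return xhat * layer.weight.data.reshape(1, c, 1, 1) + layer.bias.data.reshape(1, c, 1, 1)


def _ref_forward(module, x):
    if isinstance(module, nn.Sequential):
        for layer in module.layers:
            x = _ref_forward(layer, x)
        return x
    if isinstance(module, nn.Conv2d):
        return _ref_conv(x, module)
    if isinstance(module, nn.BatchNorm2d):
        return _ref_bn_eval(x, module)
    if isinstance(module, nn.ReLU):
        return np.maximum(x, 0)
    if isinstance(module, nn.Identity):
        return x
    if isinstance(module, BasicBlock):
        out = np.maximum(_ref_bn_eval(_ref_conv(x, module.conv1), module.bn1), 0)
        out = _ref_bn_eval(_ref_conv(out, module.conv2), module.bn2)
        return np.maximum(out + _ref_forward(module.shortcut, x), 0)
    if isinstance(module, GCBlock):
        n, c, h, w = x.shape
        logits = _ref_conv(x, module.attn).reshape(n, h * w)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        ctx = (x.reshape(n, c, h * w) @ attn[:, :, None]).reshape(n, c, 1, 1)
        t = _ref_conv(ctx, module.reduce)
        mu = t.mean(axis=1, keepdims=True)
        var = ((t - mu) ** 2).mean(axis=1, keepdims=True)
        hid = t.shape[1]
        t = ((t - mu) / np.sqrt(var + module.norm.eps)
             * module.norm.weight.data.reshape(1, hid, 1, 1)
             + module.norm.bias.data.reshape(1, hid, 1, 1))
        t = _ref_conv(np.maximum(t, 0), module.expand)
        return x + t if module.fusion_mode == "add" else x * t
    if isinstance(module, Bottleneck):
        for unit in module.units:
            x = _ref_forward(unit, x)
        return x
    raise NotImplementedError(type(module))


def _ref_student_logits(student, x):
    x = _ref_forward(student.stem, x)
    logits = []
    for si, stage in enumerate(student.stages):
        x = _ref_forward(stage, x)
        if si in student._exit_stages:
            br = student.exits[student._exit_stages.index(si)]
            f = _ref_forward(br.bottleneck, _ref_forward(br.gc, x))
            pooled = f.mean(axis=(2, 3))
            logits.append(pooled @ br.fc.weight.data + br.fc.bias.data)
    return logits


# ---------------------------------------------------------------------------

class TestGCBlock:
    def test_additive_identity_at_init(self, rng):
        nn.seed_init(0)
        gc = GCBlock(16, reduction=4, fusion_mode="add")
        x = rng.normal(size=(3, 16, 5, 7)).astype(np.float32)
        np.testing.assert_array_equal(gc(x).data, x)

    def test_multiplicative_identity_at_init(self, rng):
        nn.seed_init(0)
        gc = GCBlock(8, reduction=4, fusion_mode="multiply")
        x = rng.normal(size=(2, 8, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(gc(x).data, x, rtol=1e-6)

    def test_attention_weights_sum_to_one(self, rng):
        nn.seed_init(1)
        gc = GCBlock(8, reduction=2)
        x = rng.normal(size=(4, 8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(gc.attention_weights(x).sum(axis=1), 1.0, rtol=1e-5)

    def test_one_by_one_spatial_closed_form(self):
        """On a 1x1 spatial map the attention weight is exactly 1, the
        context vector is the input, and the output follows from the
        transform weights in closed form."""
        nn.seed_init(2)
        gc = GCBlock(4, reduction=2, fusion_mode="add")
        w1 = np.arange(8, dtype=np.float32).reshape(2, 4, 1, 1) * 0.1
        w2 = np.arange(8, dtype=np.float32).reshape(4, 2, 1, 1) * 0.05
        gc.reduce.weight.data = w1
        gc.reduce.bias.data = np.zeros(2, dtype=np.float32)
        gc.expand.weight.data = w2
        gc.expand.bias.data = np.zeros(4, dtype=np.float32)
        x = np.array([1.0, 2.0, 3.0, 4.0], dtype=np.float32).reshape(1, 4, 1, 1)
        assert gc.attention_weights(x)[0, 0] == pytest.approx(1.0)
        # hand computation
        red = (w1.reshape(2, 4) @ x.reshape(4))
        mu, var = red.mean(), red.var()
        normed = (red - mu) / np.sqrt(var + gc.norm.eps)
        t = w2.reshape(4, 2) @ np.maximum(normed, 0)
        np.testing.assert_allclose(gc(x).data.reshape(4), x.reshape(4) + t, rtol=1e-5)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.sampled_from([4, 8, 16]), st.integers(1, 7), st.integers(1, 7),
           st.sampled_from(["add", "multiply"]))
    def test_shape_preserved_over_randomized_sweep(self, c, h, w, fusion):
        nn.seed_init(3)
        gc = GCBlock(c, reduction=2, fusion_mode=fusion)
        x = np.random.default_rng(c * 100 + h * 10 + w).normal(
            size=(2, c, h, w)).astype(np.float32)
        assert gc(x).shape == x.shape

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ConfigurationError, match="reduction"):
            GCBlock(6, reduction=4)


class TestBottleneck:
    @pytest.mark.parametrize("ratio,expected_steps", [(1, 0), (2, 1), (4, 2), (8, 3)])
    def test_strided_depth_equals_log2_spatial_ratio(self, ratio, expected_steps):
        nn.seed_init(0)
        b = Bottleneck(8, 64, ratio)
        assert b.spatial_steps == expected_steps

    def test_unifies_shape_to_deepest(self, rng):
        nn.seed_init(0)
        b = Bottleneck(8, 64, 8)
        x = rng.normal(size=(2, 8, 32, 32)).astype(np.float32)
        assert b(nn.Tensor(x)).shape == (2, 64, 4, 4)

    def test_non_power_of_two_ratio_rejected(self):
        with pytest.raises(ConfigurationError, match="power of two"):
            Bottleneck(8, 64, 3)

    def test_deepest_exit_bottleneck_is_identity(self):
        nn.seed_init(0)
        br = ExitBranch(64, 64, 1, 5, use_gc=False, gc_reduction=4, fusion_mode="add")
        assert isinstance(br.bottleneck, nn.Identity)


class TestMultiExitStudent:
    def test_default_config_shape_contract(self):
        """Default 4-exit student on a batch of 2 synthetic-size 64x64
        images: four (2, 5) logit sets, unified features of one shape."""
        student = build_student(StudentConfig(), init_seed=0)
        x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32)
        student.eval()
        bundle = student(x)
        assert bundle.n == 4
        for z in bundle.logits_per_exit:
            assert z.shape == (2, 5)
        shapes = {tuple(f.shape) for f in bundle.features_per_exit}
        assert shapes == {tuple(bundle.deepest_features.shape)}

    @pytest.mark.parametrize("n_exits", [2, 3, 4])
    def test_feature_unification_for_all_exit_counts(self, n_exits):
        cfg = StudentConfig(backbone_id="resnet8", n_exits=n_exits,
                            gc_reduction_ratio=4)
        student = build_student(cfg, init_seed=1)
        x = np.random.default_rng(1).normal(size=(2, 3, 32, 32)).astype(np.float32)
        bundle = student(x)
        assert bundle.n == n_exits
        assert len({tuple(f.shape) for f in bundle.features_per_exit}) == 1

    def test_parameter_ordering_plain_lt_multiexit_lt_teacher(self):
        nn.seed_init(0)
        plain = ResNetClassifier("resnet18", 5)
        multi = build_student(StudentConfig(backbone_id="resnet18"), init_seed=0)
        teacher = build_teacher("resnet34", 5, init_seed=0)
        assert count_parameters(plain) < count_parameters(multi) < count_parameters(teacher)

    def test_too_many_exits_rejected(self):
        with pytest.raises(ConfigurationError, match="n_exits"):
            StudentConfig(backbone_id="resnet8", n_exits=5)

    def test_deepest_exit_equals_plain_backbone_at_init(self):
        """With additive fusion and zero-initialized GC transforms, the
        deepest-exit logits coincide with a plain classifier carrying the
        same backbone and head weights."""
        student = build_student(StudentConfig(backbone_id="resnet8",
                                              gc_reduction_ratio=4), init_seed=5)
        plain = ResNetClassifier("resnet8", 5)
        plain.load_state_dict({k: v for k, v in student.state_dict().items()
                               if k.startswith(("stem.", "stages."))}, strict=False)
        plain.fc.weight.data = student.exits[-1].fc.weight.data.copy()
        plain.fc.bias.data = student.exits[-1].fc.bias.data.copy()
        x = np.random.default_rng(2).normal(size=(2, 3, 32, 32)).astype(np.float32)
        student.eval(), plain.eval()
        np.testing.assert_allclose(student(x).deepest_logits.data, plain(x).data,
                                   rtol=1e-5, atol=1e-6)

    def test_exit_logits_match_independent_scipy_forward(self):
        """Eval-mode exit logits of a 2-exit reduced student on a tiny
        input reproduce an independent scipy/numpy forward pass."""
        cfg = StudentConfig(backbone_id="resnet8", n_exits=2, gc_reduction_ratio=4)
        student = build_student(cfg, init_seed=9)
        # non-trivial BN stats and GC transforms
        rng = np.random.default_rng(3)
        for _, p in student.named_parameters():
            if p.data.ndim == 4 and p.data.sum() == 0:
                p.data = rng.normal(0, 0.1, p.data.shape).astype(np.float32)
        for name, buf in student.named_buffers():
            if name.endswith("running_mean"):
                buf[...] = rng.normal(0, 0.1, buf.shape)
            else:
                buf[...] = rng.uniform(0.5, 1.5, buf.shape)
        student.eval()
        x = rng.normal(size=(2, 3, 16, 16)).astype(np.float32)
        bundle = student(x)
        ref = _ref_student_logits(student, x.astype(np.float64))
        for got, want in zip(bundle.logits_per_exit, ref):
            np.testing.assert_allclose(got.data, want, rtol=1e-3, atol=1e-4)


class TestTeacher:
    def test_teacher_is_frozen_and_emits_logits(self):
        t = build_teacher("resnet8w", 5, init_seed=0)
        assert t.frozen
        x = np.random.default_rng(0).normal(size=(2, 3, 32, 32)).astype(np.float32)
        t.eval()
        assert t(x).shape == (2, 5)

    def test_checkpoint_round_trip_bit_exact(self, tmp_path):
        t = build_teacher("resnet8w", 5, init_seed=4)
        path = save_checkpoint(tmp_path / "teacher.npz", t)
        t2 = build_teacher(path, 5)
        assert t2.param_hash() == t.param_hash()
        assert t2.frozen

    def test_mismatched_checkpoint_lists_tensors(self, tmp_path):
        t = build_teacher("resnet8w", 5, init_seed=4)
        path = save_checkpoint(tmp_path / "t.npz", t, {"num_classes": 7})
        with pytest.raises(ValueError, match="fc.weight"):
            build_teacher(path, 7)


class TestExitBundle:
    def test_requires_two_exits(self):
        with pytest.raises(ValueError, match="2 exits"):
            ExitBundle(logits_per_exit=[np.zeros((1, 5))],
                       features_per_exit=[np.zeros((1, 4, 1, 1))])

    def test_rejects_inconsistent_shapes(self):
        with pytest.raises(ValueError, match="feature shapes"):
            ExitBundle(logits_per_exit=[np.zeros((1, 5))] * 2,
                       features_per_exit=[np.zeros((1, 4, 1, 1)),
                                          np.zeros((1, 8, 1, 1))])
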