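"""ITCNN segmenter: attention/fusion operators against literal
oracles, block identities, and the tiny end-to-end training run."""

import numpy as np
import pytest

from pulmoseg import evalx, itcnn
from pulmoseg.itcnn import (
    AttentionParams, ISTBlock, MBConv, STCF, SegConfig, SegModel,
    SegTrainConfig, WindowAttention, improved_self_attention,
    relative_position_bias, segment, train_segmenter,
)
from pulmoseg.nn import Tensor


def loop_attention_oracle(q, k, v, bias, mode, scale, d):
    """Form logits elementwise and normalise each row with explicit
    exponentials (independent of the vectorised path)."""
    n = q.shape[0]
    out = np.zeros_like(v)
    for i in range(n):
        logits = []
        for j in range(n):
            s = sum(q[i, a] * k[j, a] for a in range(d))
            if mode == "improved":
                logits.append(scale * ((s * s) / np.sqrt(d) + bias[i, j]))
            else:
                logits.append(s / np.sqrt(d) + bias[i, j])
        m = max(logits)
        e = [np.exp(val - m) for val in logits]
        z = sum(e)
        for j in range(n):
            out[i] += (e[j] / z) * v[j]
    return out


class TestImprovedSelfAttention:
    def test_zero_values_give_zero_output(self):
        rng = np.random.default_rng(0)
        p = AttentionParams(window_p=2, dim_D=3)
        q, k = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        out = improved_self_attention(q, k, np.zeros((4, 3)), p)
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_logits_average_values(self):
        p = AttentionParams(window_p=2, dim_D=2)
        v = np.random.default_rng(1).normal(size=(4, 2))
        out = improved_self_attention(np.zeros((4, 2)), np.zeros((4, 2)), v, p)
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (4, 1)),
                                   atol=1e-12)

    @pytest.mark.parametrize("mode", ["improved", "standard"])
    def test_matches_loop_oracle(self, mode):
        rng = np.random.default_rng(2)
        table = rng.normal(size=(3, 5))
        p = AttentionParams(window_p=2, dim_D=2, bias_table=table,
                            logit_scale=1.3, mode=mode)
        q, k, v = (rng.normal(size=(4, 2)) for _ in range(3))
        bias = relative_position_bias(table, 2)
        scale = p.logit_scale if mode == "improved" else 1.0
        oracle = loop_attention_oracle(q, k, v, bias, mode, scale, 2)
        np.testing.assert_allclose(improved_self_attention(q, k, v, p),
                                   oracle, atol=1e-6)

    @pytest.mark.parametrize("mode", ["improved", "standard"])
    def test_attention_rows_sum_to_one(self, mode):
        rng = np.random.default_rng(3)
        p = AttentionParams(window_p=3, dim_D=4,
                            bias_table=rng.normal(size=(5, 7)), mode=mode)
        q, k = rng.normal(size=(9, 4)), rng.normal(size=(9, 4))
        attn = improved_self_attention(q, k, np.eye(9), p)
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        p = AttentionParams(window_p=2, dim_D=3)
        with pytest.raises(ValueError):
            improved_self_attention(np.zeros((4, 2)), np.zeros((4, 2)),
                                    np.zeros((4, 2)), p)

    def test_bias_table_shape_follows_convention(self):
        p = AttentionParams(window_p=4, dim_D=2)
        assert p.bias_table.shape == (7, 9)  # (2p-1) × (2p+1)


def test_windowed_equals_global_attention_when_window_covers_grid():
    """With one window spanning the whole token grid, W-MSA must equal
    a global-attention oracle on the same projection weights."""
    rng = np.random.default_rng(4)
    dim, p = 8, 4
    wa = WindowAttention(dim, p, heads=2, rng=np.random.default_rng(5))
    wa.bias_table.data = rng.normal(size=wa.bias_table.shape)
    wa.log_scale.data = np.array([0.4])
    x = rng.normal(size=(1, 4, 4, dim))
    out = wa(Tensor(x), shift=False).data

    tokens = x.reshape(16, dim)
    q = tokens @ wa.q.w.data + wa.q.b.data
    k = tokens @ wa.k.w.data + wa.k.b.data
    v = tokens @ wa.v.w.data + wa.v.b.data
    bias = relative_position_bias(
        wa.bias_table.data.reshape(2 * p - 1, 2 * p + 1), p)
    d = dim // 2
    heads_out = []
    for h in range(2):
        sl = slice(h * d, (h + 1) * d)
        heads_out.append(loop_attention_oracle(
            q[:, sl], k[:, sl], v[:, sl], bias, "improved",
            float(np.exp(wa.log_scale.data[0])), d))
    global_out = np.concatenate(heads_out, axis=1) @ wa.proj.w.data \
        + wa.proj.b.data
    np.testing.assert_allclose(out.reshape(16, dim), global_out, atol=1e-6)


class TestISTBlock:
    def test_zeroed_sublayers_give_identity(self):
        blk = ISTBlock(8, 2, 2, np.random.default_rng(0),
                       use_batchnorm=False, pool="none")
        for lin in (blk.attn.q, blk.attn.k, blk.attn.v, blk.attn.proj,
                    blk.fc1, blk.fc2):
            lin.w.data[...] = 0.0
            lin.b.data[...] = 0.0
        x = np.random.default_rng(1).normal(size=(2, 4, 4, 8))
        np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-12)

    def test_avg_pool_halves_dims_and_preserves_constants(self):
        blk = ISTBlock(4, 2, 2, np.random.default_rng(2),
                       use_batchnorm=False, pool="avg2")
        for lin in (blk.attn.q, blk.attn.k, blk.attn.v, blk.attn.proj,
                    blk.fc1, blk.fc2):
            lin.w.data[...] = 0.0
            lin.b.data[...] = 0.0
        x = np.ones((1, 4, 4, 4)) * 0.37
        out = blk(Tensor(x)).data
        assert out.shape == (1, 2, 2, 4)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_nondivisible_grid_is_padded_internally(self):
        blk = ISTBlock(4, 4, 2, np.random.default_rng(3),
                       use_batchnorm=False)
        x = np.random.default_rng(4).normal(size=(1, 6, 6, 4))
        assert blk(Tensor(x)).shape == (1, 6, 6, 4)


class TestMBConv:
    def test_se_gate_forced_to_one_equals_no_se(self):
        mb = MBConv(4, np.random.default_rng(0))
        mb.eval()
        x = np.random.default_rng(1).normal(size=(1, 4, 6, 6))
        # force the SE gate to exactly 1: sigmoid output saturated high
        mb.se_expand.w.data[...] = 0.0
        mb.se_expand.b.data[...] = 60.0
        out_gated = mb(Tensor(x)).data

        # manual path without the SE stage
        y = mb.bn1(mb.expand(Tensor(x))).swish()
        y = mb.bn2(mb.dw(y)).swish()
        y = mb.bn3(mb.project(y))
        expected = y.data + x
        np.testing.assert_allclose(out_gated, expected, atol=1e-10)

    def test_zero_input_zero_biases_give_zero(self):
        mb = MBConv(3, np.random.default_rng(2))
        mb.eval()
        for m in [mb, *mb.modules()]:
            for v in m.__dict__.values():
                if hasattr(v, "data") and getattr(v, "requires_grad", False):
                    if v.data.ndim == 1:  # biases and BN shifts
                        v.data[...] = 0.0
        # sigmoid(0)=0.5 gate scales zeros; output stays zero
        out = mb(Tensor(np.zeros((1, 3, 4, 4)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_layer_by_layer_numpy_oracle(self):
        """Compose the block from independently written conv/pool
        primitives (direct loops) and compare."""
        mb = MBConv(2, np.random.default_rng(3))
        mb.eval()
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 2, 8, 8))

        def np_conv1x1(a, w, b):
            return np.einsum("nchw,oc->nohw", a, w[:, :, 0, 0]) \
                + b[None, :, None, None]

        def np_dw(a, w, b):
            n, c, h, wd = a.shape
            pad = np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)))
            out = np.zeros_like(a)
            for ci in range(c):
                for i in range(h):
                    for j in range(wd):
                        out[0, ci, i, j] = (pad[0, ci, i:i + 3, j:j + 3]
                                            * w[ci]).sum() + b[ci]
            return out

        def np_bn(a, bn):
            mu = bn.running_mean[None, :, None, None]
            sd = np.sqrt(bn.running_var + bn.eps)[None, :, None, None]
            return ((a - mu) / sd * bn.gamma.data[None, :, None, None]
                    + bn.beta.data[None, :, None, None])

        def swish(a):
            return a / (1 + np.exp(-a))

        y = swish(np_bn(np_conv1x1(x, mb.expand.w.data, mb.expand.b.data),
                        mb.bn1))
        y = swish(np_bn(np_dw(y, mb.dw.w.data, mb.dw.b.data), mb.bn2))
        pooled = y.mean(axis=(2, 3))[0]
        s = pooled @ mb.se_reduce.w.data + mb.se_reduce.b.data
        s = swish(s)
        gate = 1 / (1 + np.exp(-(s @ mb.se_expand.w.data
                                 + mb.se_expand.b.data)))
        y = y * gate[None, :, None, None]
        y = np_bn(np_conv1x1(y, mb.project.w.data, mb.project.b.data), mb.bn3)
        expected = y + x
        np.testing.assert_allclose(mb(Tensor(x)).data, expected, atol=1e-5)


class TestSTCF:
    def test_zero_inputs_zero_biases_give_zero(self):
        st = STCF(2, np.random.default_rng(0))
        st.eval()
        for m in [st, *st.modules()]:
            for v in m.__dict__.values():
                if hasattr(v, "data") and getattr(v, "requires_grad", False):
                    if v.data.ndim == 1:
                        v.data[...] = 0.0
        out = st(Tensor(np.zeros((1, 2, 4, 4))),
                 Tensor(np.zeros((1, 2, 4, 4)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_spatial_misalignment_raises(self):
        st = STCF(2, np.random.default_rng(1))
        with pytest.raises(ValueError):
            st(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 2, 6, 6))))

    def test_matches_equation_by_equation_oracle(self):
        """Execute the four fusion equations step by step with plain
        numpy convolutions on the module's own weights."""
        st = STCF(2, np.random.default_rng(2))
        st.eval()
        rng = np.random.default_rng(3)
        tr = rng.normal(size=(1, 2, 6, 6))
        cnn = rng.normal(size=(1, 2, 6, 6))

        def np_conv(a, w, b, pad):
            n, cin, h, wd = a.shape
            cout, _, kh, kw = w.shape
            ap = np.pad(a, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            out = np.zeros((n, cout, h, wd))
            for o in range(cout):
                for i in range(h):
                    for j in range(wd):
                        out[0, o, i, j] = (ap[0, :, i:i + kh, j:j + kw]
                                           * w[o]).sum()
                if b is not None:
                    out[:, o] += b[o]
            return out

        def sigmoid(a):
            return 1 / (1 + np.exp(-a))

        def sa(a):
            stats = np.stack([a.max(axis=1), a.mean(axis=1)], axis=1)
            gate = sigmoid(np_conv(stats, st.sa.conv.w.data,
                                   st.sa.conv.b.data, 3))
            return a * gate

        def scse(a):
            pooled = a.mean(axis=(2, 3))
            hidden = np.maximum(pooled @ st.scse.c_reduce.w.data
                                + st.scse.c_reduce.b.data, 0)
            cgate = sigmoid(hidden @ st.scse.c_expand.w.data
                            + st.scse.c_expand.b.data)
            sgate = sigmoid(np_conv(a, st.scse.s_conv.w.data,
                                    st.scse.s_conv.b.data, 0))
            return a * cgate[:, :, None, None] + a * sgate

        tr1, cnn1 = sa(tr), sa(cnn)                                   # Eq A
        tr_hat = scse(np.concatenate([cnn1, tr], axis=1))             # Eq B
        cnn_hat = scse(np.concatenate([tr1, cnn], axis=1))
        bridge = np_conv(np_conv(tr, st.w1.w.data, None, 0)
                         * np_conv(cnn, st.w2.w.data, None, 0),
                         st.fuse_conv.w.data, st.fuse_conv.b.data, 1)  # Eq C
        fused = np.concatenate([tr_hat, cnn_hat, bridge], axis=1)
        re = np_conv(fused, st.re_conv.w.data, st.re_conv.b.data, 1)
        mu = st.re_bn.running_mean[None, :, None, None]
        sd = np.sqrt(st.re_bn.running_var + st.re_bn.eps)[None, :, None, None]
        re = ((re - mu) / sd * st.re_bn.gamma.data[None, :, None, None]
              + st.re_bn.beta.data[None, :, None, None])
        expected = np.maximum(re, 0)                                   # Eq D
        np.testing.assert_allclose(st(Tensor(tr), Tensor(cnn)).data,
                                   expected, atol=1e-6)


@pytest.fixture(scope="module")
def untrained():
    return SegModel(SegConfig(input_side=32), seed=0)


class TestSegment:
    def test_deterministic_masks(self, untrained):
        img = np.random.default_rng(0).random((64, 64))
        m1 = segment(img, untrained)
        m2 = segment(img, untrained)
        np.testing.assert_array_equal(m1, m2)

    @pytest.mark.parametrize("shape", [(128, 128), (96, 96)])
    def test_mask_shape_and_binary_values(self, untrained, shape):
        img = np.random.default_rng(1).random(shape)
        mask = segment(img, untrained)
        assert mask.shape == shape
        assert set(np.unique(mask)) <= {0, 1}


class TestTrainSegmenter:
    def test_loss_decreases_over_epochs(self, small_phantoms_64):
        subset = small_phantoms_64[27:47]  # 20 lesion-bearing phantoms
        _, hist = train_segmenter(
            [s.image for s in subset], [s.mask for s in subset],
            SegConfig(input_side=32), SegTrainConfig(epochs=2), seed=1)
        assert hist[-1] < hist[0]

    def test_identical_seeds_give_identical_weights(self, small_phantoms_64):
        subset = small_phantoms_64[30:36]
        runs = []
        for _ in range(2):
            model, _ = train_segmenter(
                [s.image for s in subset], [s.mask for s in subset],
                SegConfig(input_side=32), SegTrainConfig(epochs=1), seed=7)
            runs.append(model.state_dict())
        for k in runs[0]:
            np.testing.assert_array_equal(runs[0][k], runs[1][k])

    def test_zero_learning_rate_leaves_weights_unchanged(self,
                                                         small_phantoms_64):
        subset = small_phantoms_64[30:36]
        ref = SegModel(SegConfig(input_side=32), seed=9)
        model, _ = train_segmenter(
            [s.image for s in subset], [s.mask for s in subset],
            SegConfig(input_side=32),
            SegTrainConfig(epochs=1, lr=0.0), seed=9)
        for (ka, va), (kb, vb) in zip(sorted(ref.state_dict().items()),
                                      sorted(model.state_dict().items())):
            if "running" in ka:  # BN statistics do update
                continue
            np.testing.assert_array_equal(va, vb)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train_segmenter([], [], SegConfig(input_side=32),
                            SegTrainConfig(epochs=1), seed=0)


def test_heldout_dice_after_tiny_training_run(tiny_seg_run):
    """5 epochs on 60 phantoms: mean Dice on ~20 held-out phantoms
    must reach 0.80."""
    run = tiny_seg_run
    dices = [evalx.dice(segment(run["images"][i], run["model"]),
                        run["masks"][i]) for i in run["test"]]
    assert float(np.mean(dices)) >= 0.80
    assert run["history"][-1] < run["history"][0]


def test_model_save_load_round_trip(tmp_path, tiny_seg_run):
    model = tiny_seg_run["model"]
    path = tmp_path / "seg.npz"
    itcnn.save_model(model, path)
    loaded = itcnn.load_model(path)
    img = tiny_seg_run["images"][0]
    np.testing.assert_array_equal(segment(img, model), segment(img, loaded))
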