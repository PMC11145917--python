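"""Autodiff correctness, model architecture contracts, attention mask oracle."""

import numpy as np
import pytest

from cfosmap.config import HybridSwinConfig
from cfosmap.nn import Tensor, build_model, concat, conv3d_same, forward
from cfosmap.nn.swin import (
    SwinBlock,
    WindowAttention,
    _window_partition,
    _window_reverse,
)
from cfosmap.nn.train import load_checkpoint, save_checkpoint, train_model

TINY = dict(embed_dim=16, window=(2, 2, 2), depths=(1, 1, 1, 1), heads=(2, 2, 2, 2), conv_channels=2)


def numeric_grad(fn, x, eps=1e-2):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = fn()
        x[i] = old - eps
        fm = fn()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestAutodiffGradients:
    """Every primitive's analytic gradient matches central differences."""

    def check(self, make_output, x_data, rtol=3e-2, atol=3e-3):
        x = Tensor(x_data.copy(), requires_grad=True)
        rng = np.random.default_rng(0)

        def scalar(t):
            return (t * weights).sum()

        out = make_output(x)
        weights = Tensor(rng.normal(size=out.shape).astype(np.float32))
        loss = scalar(out)
        loss.backward()
        analytic = x.grad.astype(np.float64)

        def value():
            x2 = Tensor(x.data)
            return float((make_output(x2) * weights).sum().data)

        numeric = numeric_grad(value, x.data)
        np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)

    @pytest.mark.parametrize(
        "name,fn",
        [
            ("exp", lambda x: x.exp()),
            ("log", lambda x: (x * x + 1.0).log()),
            ("tanh", lambda x: x.tanh()),
            ("gelu", lambda x: x.gelu()),
            ("softmax", lambda x: x.softmax(axis=-1)),
            ("reshape_t", lambda x: x.reshape(4, 6).transpose(1, 0)),
            ("slice", lambda x: x[1:, ::2]),
            ("roll", lambda x: x.roll((1, -1), axes=(0, 1))),
            ("pow", lambda x: (x * x) ** 1.5),
            ("div", lambda x: x / (x * x + 2.0)),
            ("mean", lambda x: x.mean(axis=1, keepdims=True) * x),
        ],
    )
    def test_elementwise_and_shape_ops(self, name, fn):
        rng = np.random.default_rng(3)
        self.check(fn, rng.normal(0, 0.7, size=(4, 6)).astype(np.float32))

    def test_matmul_both_sides(self):
        rng = np.random.default_rng(4)
        w = Tensor(rng.normal(size=(5, 3)).astype(np.float32), requires_grad=True)
        self.check(lambda x: x @ w, rng.normal(size=(6, 5)).astype(np.float32))

    def test_batched_matmul(self):
        rng = np.random.default_rng(5)
        b = Tensor(rng.normal(size=(3, 4, 2)).astype(np.float32))
        self.check(lambda x: x @ b, rng.normal(size=(3, 5, 4)).astype(np.float32))

    def test_concat(self):
        rng = np.random.default_rng(6)
        other = Tensor(rng.normal(size=(4, 3)).astype(np.float32))
        self.check(lambda x: concat([x, other], axis=1) @ Tensor(np.eye(9, dtype=np.float32)),
                   rng.normal(size=(4, 6)).astype(np.float32))

    def test_layernorm(self):
        rng = np.random.default_rng(7)
        g = Tensor(rng.normal(1, 0.1, size=6).astype(np.float32), requires_grad=True)
        b = Tensor(rng.normal(0, 0.1, size=6).astype(np.float32), requires_grad=True)
        self.check(lambda x: x.layernorm(g, b), rng.normal(size=(5, 6)).astype(np.float32), rtol=5e-2)

    def test_conv3d_input_and_weight(self):
        rng = np.random.default_rng(8)
        x_data = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
        w = Tensor(rng.normal(0, 0.3, size=(3, 2, 3, 3, 3)).astype(np.float32), requires_grad=True)
        bias = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
        self.check(lambda x: conv3d_same(x, w, bias, dilation=2), x_data)
        # and weight gradient (fresh accumulation)
        w.grad = None
        bias.grad = None
        x = Tensor(x_data, requires_grad=False)
        weights = Tensor(np.random.default_rng(0).normal(size=(1, 3, 4, 4, 4)).astype(np.float32))
        loss = (conv3d_same(x, w, bias, dilation=2) * weights).sum()
        loss.backward()
        analytic = w.grad.astype(np.float64)

        def value():
            return float((conv3d_same(x, Tensor(w.data), Tensor(bias.data), dilation=2) * weights).sum().data)

        numeric = numeric_grad(value, w.data)
        np.testing.assert_allclose(analytic, numeric, rtol=3e-2, atol=3e-3)

    def test_multiple_contributions_do_not_corrupt_shared_buffers(self):
        """Copy-on-write accumulation: a double-used tensor's second gradient
        contribution must not leak into the other parent's gradient."""
        x = Tensor(np.ones((3, 3), dtype=np.float32), requires_grad=True)
        y = Tensor(np.full((3, 3), 2.0, dtype=np.float32), requires_grad=True)
        z = x + y
        u = z + x          # x contributes twice, y once
        loss = (u * u).sum()
        loss.backward()
        # u = 2x + y = 4; dl/du = 2u = 8; dl/dx = 16, dl/dy = 8
        np.testing.assert_allclose(x.grad, 16.0)
        np.testing.assert_allclose(y.grad, 8.0)


class TestArchitectureContracts:
    def test_encoder_has_four_stages_with_default_depths(self):
        model = build_model(HybridSwinConfig(embed_dim=16))
        assert model.num_stages == 4
        assert model.depths == (2, 2, 6, 2)

    def test_channel_widths_double_per_merging(self):
        model = build_model(HybridSwinConfig(embed_dim=16))
        assert model.stage_widths == (16, 32, 64, 128)

    def test_decoder_consumes_exactly_three_skips(self):
        model = build_model(HybridSwinConfig(embed_dim=16))
        assert model.num_skips == 3

    def test_bottleneck_grid_for_32_cube(self):
        model = build_model(HybridSwinConfig(embed_dim=16, window=(4, 4, 4)))
        grids = model.token_grids((32, 32, 32))
        assert grids[0] == (16, 16, 16)
        assert grids[-1] == (2, 2, 2)

    def test_ablated_variant_has_no_conv_block(self):
        hybrid = build_model(HybridSwinConfig(embed_dim=16))
        plain = build_model(HybridSwinConfig(embed_dim=16, dilated_block=False))
        assert hybrid.conv_block is not None
        assert plain.conv_block is None
        assert plain.n_parameters() < hybrid.n_parameters()


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(HybridSwinConfig(**TINY))


class TestForward:
    def test_output_shape_and_probability_sum(self, tiny_model, rng):
        patch = rng.uniform(0, 1000, size=(16, 16, 16)).astype(np.float32)
        probs = forward(tiny_model, patch)
        assert probs.shape == (16, 16, 16, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert probs.min() >= 0.0

    def test_two_patch_batch(self, tiny_model, rng):
        a = rng.uniform(0, 10, size=(16, 16, 16)).astype(np.float32)
        b = rng.uniform(0, 10, size=(16, 16, 16)).astype(np.float32)
        pa, pb = forward(tiny_model, a, b)
        assert pa.shape == pb.shape == (16, 16, 16, 2)

    def test_zeroed_head_gives_uniform_probabilities(self, rng):
        model = build_model(HybridSwinConfig(**TINY))
        model.head.w.data[:] = 0.0
        model.head.b.data[:] = 0.0
        probs = forward(model, rng.uniform(0, 5, size=(16, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(probs, 0.5, atol=1e-6)

    def test_eval_deterministic(self, tiny_model, rng):
        patch = rng.uniform(0, 100, size=(16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(forward(tiny_model, patch), forward(tiny_model, patch))

    def test_bad_shape_reports_axis(self, tiny_model, rng):
        with pytest.raises(ValueError, match="axis"):
            tiny_model.forward_batch(rng.random((1, 16, 20, 16)).astype(np.float32))


class TestShiftedWindowOracle:
    def region_id(self, pos, grid, window, shift):
        """Independent contiguity regions of the shifted-window scheme."""
        rid = 0
        for a in range(3):
            g, w, s = grid[a], window[a], shift[a]
            if s == 0:
                seg = 0
            elif pos[a] < g - w:
                seg = 0
            elif pos[a] < g - s:
                seg = 1
            else:
                seg = 2
            rid = rid * 3 + seg
        return rid

    def test_masked_window_attention_equals_brute_force(self):
        grid, window, shift = (4, 4, 4), (2, 2, 2), (1, 1, 1)
        rng = np.random.default_rng(12)
        dim = 4
        attn = WindowAttention(np.random.default_rng(0), dim=dim, heads=1, name="t")
        for lin in (attn.q, attn.k, attn.v):
            lin.w.data = rng.normal(0, 0.5, size=lin.w.data.shape).astype(np.float32)
        attn.proj.w.data = np.eye(dim, dtype=np.float32)  # identity output projection
        attn.proj.b.data[:] = 0.0

        x = rng.normal(size=(1, *grid, dim)).astype(np.float32)

        # implementation path: roll -> partition -> masked attention -> reverse
        block = SwinBlock(np.random.default_rng(1), dim, 1, window, shifted=True, mlp_ratio=1.0, name="b")
        w_eff, s_eff = block._geometry(grid)
        assert (w_eff, s_eff) == (window, shift)
        from cfosmap.nn.swin import _attention_mask

        mask = _attention_mask(grid, window, shift)
        xt = Tensor(x)
        y = xt.roll(tuple(-s for s in shift), axes=(1, 2, 3))
        y = _window_partition(y, grid, window)
        y = attn(y, mask, batch=1)
        y = _window_reverse(y, 1, grid, window, dim)
        y = y.roll(shift, axes=(1, 2, 3))
        got = y.data[0]

        # oracle: per-token softmax attention over allowed partners only
        q = x[0] @ attn.q.w.data + attn.q.b.data
        k = x[0] @ attn.k.w.data + attn.k.b.data
        v = x[0] @ attn.v.w.data + attn.v.b.data
        scale = dim**-0.5
        positions = [(z, yy, xx) for z in range(4) for yy in range(4) for xx in range(4)]
        rolled = {p: tuple((p[a] - shift[a]) % grid[a] for a in range(3)) for p in positions}
        expected = np.zeros_like(got)
        for pi in positions:
            ri = rolled[pi]
            allowed = []
            for pj in positions:
                rj = rolled[pj]
                same_window = all(ri[a] // window[a] == rj[a] // window[a] for a in range(3))
                # contiguity regions live in original (unrolled) coordinates
                same_region = self.region_id(pi, grid, window, shift) == self.region_id(
                    pj, grid, window, shift
                )
                if same_window and same_region:
                    allowed.append(pj)
            logits = np.array([float(q[pi] @ k[pj]) * scale for pj in allowed])
            wts = np.exp(logits - logits.max())
            wts /= wts.sum()
            expected[pi] = sum(w * v[pj] for w, pj in zip(wts, allowed))
        np.testing.assert_allclose(got, expected, atol=2e-4)

    def test_shift_zero_and_shifted_blocks_share_shape_contract(self, rng):
        for shifted in (False, True):
            block = SwinBlock(np.random.default_rng(2), 8, 2, (2, 2, 2), shifted, 2.0, "b")
            x = Tensor(rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32))
            assert block(x).shape == x.shape

    def test_window_clamped_when_grid_smaller(self):
        block = SwinBlock(np.random.default_rng(3), 8, 2, (4, 4, 4), True, 2.0, "b")
        window, shift = block._geometry((2, 2, 2))
        assert window == (2, 2, 2)
        assert shift == (0, 0, 0)

    def test_indivisible_grid_rejected(self):
        block = SwinBlock(np.random.default_rng(3), 8, 2, (4, 4, 4), False, 2.0, "b")
        with pytest.raises(ValueError, match="axis"):
            block._geometry((6, 8, 8))


class TestTrainingAndCheckpoints:
    def _pairs(self, n=6, seed=0):
        from cfosmap.trainmask import TrainingPair

        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            img = rng.uniform(0, 500, size=(16, 16, 16)).astype(np.float32)
            mask = np.zeros((16, 16, 16), dtype=np.uint8)
            z, y, x = rng.integers(3, 13, size=3)
            img[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2] += 2000.0
            mask[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2] = 1
            pairs.append(TrainingPair(image=img, mask=mask))
        return pairs

    def test_identical_seed_identical_first_epoch_loss(self):
        pairs = self._pairs()
        reports = []
        for _ in range(2):
            model = build_model(HybridSwinConfig(**TINY))
            reports.append(train_model(model, pairs, epochs=1, lr=1e-3, batch_size=2, seed=3))
        assert reports[0].epoch_loss[0] == reports[1].epoch_loss[0]

    def test_loss_decreases_over_training(self):
        pairs = self._pairs(n=8)
        model = build_model(HybridSwinConfig(**TINY))
        report = train_model(model, pairs, epochs=6, lr=2e-3, batch_size=4, seed=1)
        assert report.epoch_loss[-1] < report.epoch_loss[0]
        assert all(np.isfinite(report.epoch_loss))

    def test_checkpoint_round_trip_bitwise(self, tmp_path, rng):
        model = build_model(HybridSwinConfig(**TINY))
        patch = rng.uniform(0, 10, size=(16, 16, 16)).astype(np.float32)
        before = forward(model, patch)
        save_checkpoint(model, tmp_path / "m.npz")
        restored = load_checkpoint(tmp_path / "m.npz")
        after = forward(restored, patch)
        np.testing.assert_array_equal(before, after)
        assert restored.cfg == model.cfg  # config (incl. seed and depths) preserved

    def test_checkpoint_config_mismatch_rejected(self, tmp_path):
        model = build_model(HybridSwinConfig(**TINY))
        save_checkpoint(model, tmp_path / "m.npz")
        other = build_model(HybridSwinConfig(**{**TINY, "embed_dim": 32}))
        state = model.state_dict()
        with pytest.raises(ValueError):
            other.load_state_dict(state)

    def test_missing_checkpoint_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="checkpoint not found"):
            load_checkpoint(tmp_path / "nope.npz")

    def test_all_negative_masks_warn(self):
        from cfosmap.trainmask import TrainingPair

        rng = np.random.default_rng(0)
        pairs = [
            TrainingPair(
                image=rng.uniform(0, 1, (16, 16, 16)).astype(np.float32),
                mask=np.zeros((16, 16, 16), dtype=np.uint8),
            )
            for _ in range(4)
        ]
        model = build_model(HybridSwinConfig(**TINY))
        with pytest.warns(UserWarning, match="empty"):
            train_model(model, pairs, epochs=1, lr=1e-3, batch_size=2, seed=0)
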