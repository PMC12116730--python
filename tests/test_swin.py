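"""Window partitioning, attention operators, MK-CA and stage plumbing."""

from dataclasses import replace

import numpy as np
import pytest

from ctiqa.kan import SplineGrid
from ctiqa.swin import (
    AttentionProjection,
    MkCaParams,
    StageSchedule,
    TINY_SCHEDULE,
    cosine_window_attention,
    cross_attention,
    init_swin_params,
    merge_windows,
    mk_ca_forward,
    partition_windows,
    patch_embed,
    relative_position_index,
    run_stages,
    score_head,
    shift_attention_mask,
    swin_kat_block,
)
from ctiqa.corpus import ScoreRange


def _attn(rng, c, heads=2, cosine=False, window=None):
    def lin():
        return rng.normal(0.0, 1.0 / np.sqrt(c), size=(c, c))

    return AttentionProjection(
        lin(), np.zeros(c), lin(), np.zeros(c), lin(), np.zeros(c),
        lin(), np.zeros(c), heads,
        np.full(heads, np.log(10.0)) if cosine else None,
        np.zeros(((2 * window - 1) ** 2, heads)) if cosine and window else None,
    )


class TestWindows:
    def test_partition_arithmetic(self, rng):
        x = rng.normal(size=(1, 8, 8, 3))
        blocks, meta = partition_windows(x, 4, 0)
        assert blocks.shape == (4, 16, 3)

    @pytest.mark.parametrize("shift", [0, 2])
    def test_roundtrip_exact(self, rng, shift):
        x = rng.normal(size=(2, 8, 8, 5))
        blocks, meta = partition_windows(x, 4, shift)
        np.testing.assert_array_equal(merge_windows(blocks, meta), x)

    def test_indivisible_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            partition_windows(rng.normal(size=(1, 6, 6, 2)), 4, 0)

    def test_shift_mask_matches_region_labels(self):
        # oracle: enumerate pre-shift region labels on the 8x8 grid and
        # compare the mask with pairwise label equality, window 4 shift 2
        H = W = 8
        w, s = 4, 2
        mask = shift_attention_mask(H, W, w, s)
        assert mask.shape == (4, 16, 16)
        region = np.zeros((H, W), dtype=int)
        for hi, hs in enumerate((slice(0, -w), slice(-w, -s), slice(-s, None))):
            for wi, ws in enumerate((slice(0, -w), slice(-w, -s), slice(-s, None))):
                region[hs, ws] = 3 * hi + wi
        rolled = np.roll(region, (-s, -s), axis=(0, 1))
        win = rolled.reshape(H // w, w, W // w, w).transpose(0, 2, 1, 3)
        win = win.reshape(-1, w * w)
        for b in range(win.shape[0]):
            same = win[b][:, None] == win[b][None, :]
            np.testing.assert_array_equal(mask[b] == 0.0, same)

    def test_no_mask_without_shift(self):
        assert shift_attention_mask(8, 8, 4, 0) is None


class TestCosineAttention:
    def test_single_token_passthrough(self, rng):
        proj = _attn(rng, 4, heads=2, cosine=True, window=1)
        x = rng.normal(size=(1, 1, 4))
        out = cosine_window_attention(x, proj)
        expected = (x[0] @ proj.W_v + proj.b_v) @ proj.W_o + proj.b_o
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_identical_keys_give_uniform_weights(self, rng):
        proj = _attn(rng, 4, heads=2, cosine=True, window=2)
        tok = rng.normal(size=4)
        x = np.tile(tok, (1, 4, 1))
        _, w = cosine_window_attention(x, proj, return_weights=True)
        np.testing.assert_allclose(w, 0.25, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        proj = _attn(rng, 8, heads=4, cosine=True, window=3)
        x = rng.normal(size=(2, 9, 8))
        _, w = cosine_window_attention(x, proj, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_explicit_loop_oracle(self, rng):
        proj = _attn(rng, 6, heads=2, cosine=True, window=None)
        proj.rel_pos_bias = None
        x = rng.normal(size=(1, 3, 6))
        out = cosine_window_attention(x, proj)
        # dense oracle: per-head cosine similarity, softmax, weighted values
        q = x[0] @ proj.W_q
        k = x[0] @ proj.W_k
        v = x[0] @ proj.W_v
        dh = 3
        res = np.zeros((3, 6))
        for h in range(2):
            qs, ks, vs = (m[:, h * dh:(h + 1) * dh] for m in (q, k, v))
            logits = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    logits[i, j] = (
                        qs[i] @ ks[j] / (np.linalg.norm(qs[i]) * np.linalg.norm(ks[j]))
                    ) * 10.0
            wts = np.exp(logits - logits.max(1, keepdims=True))
            wts /= wts.sum(1, keepdims=True)
            res[:, h * dh:(h + 1) * dh] = wts @ vs
        np.testing.assert_allclose(out[0], res @ proj.W_o, atol=1e-8)

    def test_nonfinite_rejected(self, rng):
        proj = _attn(rng, 4)
        x = np.full((1, 2, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            cosine_window_attention(x, proj)


class TestCrossAttention:
    def test_single_token_self_context(self, rng):
        proj = _attn(rng, 4, heads=2)
        x = rng.normal(size=(1, 1, 4))
        out = cross_attention(x, x, proj)
        expected = (x[0] @ proj.W_v + proj.b_v) @ proj.W_o + proj.b_o
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_zero_value_projection_annihilates(self, rng):
        proj = _attn(rng, 4, heads=2)
        proj.W_v = np.zeros_like(proj.W_v)
        proj.b_o = np.zeros_like(proj.b_o)
        out = cross_attention(rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 3, 4)), proj)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_two_token_enumeration_oracle(self, rng):
        c, heads = 4, 1
        proj = _attn(rng, c, heads=heads)
        qs = rng.normal(size=(1, 2, c))
        ctx = rng.normal(size=(1, 2, c))
        out = cross_attention(qs, ctx, proj)
        q = qs[0] @ proj.W_q
        k = ctx[0] @ proj.W_k
        v = ctx[0] @ proj.W_v
        logits = q @ k.T / np.sqrt(c)
        w = np.exp(logits - logits.max(1, keepdims=True))
        w /= w.sum(1, keepdims=True)
        np.testing.assert_allclose(out[0], (w @ v) @ proj.W_o, atol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        proj = _attn(rng, 4)
        with pytest.raises(ValueError, match="mismatch"):
            cross_attention(rng.normal(size=(1, 2, 4)), rng.normal(size=(1, 2, 6)), proj)


def _mkca_params(rng, schedule, c):
    from ctiqa.swin import _init_block

    return _init_block(rng, c, min(schedule.window, 4), schedule)["mkca"]


@pytest.fixture
def tiny_sched():
    return replace(TINY_SCHEDULE, base_channels=8, attn_heads=2, kan_heads=4,
                   kan_grid=SplineGrid())


class TestMkCa:
    def test_omega_is_beta1_plus_beta2(self, rng, tiny_sched):
        d = _mkca_params(rng, tiny_sched, 8)
        p = MkCaParams.from_dict(d, tiny_sched)
        x = rng.normal(size=(2, 4, 8))
        omega = mk_ca_forward(x, p, "mkca")
        b1 = mk_ca_forward(x, p, "ca_mk")
        b2 = mk_ca_forward(x, p, "ca_km")
        np.testing.assert_allclose(omega, b1 + b2, atol=1e-12)

    def test_annihilated_path_reduces_to_other(self, rng, tiny_sched):
        d = _mkca_params(rng, tiny_sched, 8)
        d["ca2"]["Wv"] = np.zeros_like(d["ca2"]["Wv"])
        d["ca2"]["bo"] = np.zeros_like(d["ca2"]["bo"])
        p = MkCaParams.from_dict(d, tiny_sched)
        x = rng.normal(size=(1, 4, 8))
        np.testing.assert_allclose(
            mk_ca_forward(x, p, "mkca"), mk_ca_forward(x, p, "ca_mk"), atol=1e-12
        )

    def test_symmetric_weight_tied_swap_invariance(self, rng, tiny_sched):
        # tie the two attention paths and make mu/kappa produce the same
        # transform; then swapping path roles leaves omega unchanged
        d = _mkca_params(rng, tiny_sched, 8)
        d["ca2"] = {k: np.copy(v) for k, v in d["ca1"].items()}
        p = MkCaParams.from_dict(d, tiny_sched)
        x = rng.normal(size=(1, 4, 8))
        u = mk_ca_forward(x, p, "mlp")
        v = mk_ca_forward(x, p, "kan")
        b_uv = cross_attention(u, v, p.attn_1) + cross_attention(v, u, p.attn_2)
        b_vu = cross_attention(v, u, p.attn_1) + cross_attention(u, v, p.attn_2)
        np.testing.assert_allclose(b_uv, b_vu, atol=1e-10)

    @pytest.mark.parametrize(
        "mode", ["mlp", "kan", "average", "concat", "sum", "ca_mk", "ca_km", "mkca"]
    )
    def test_all_modes_shape_preserving(self, rng, tiny_sched, mode):
        p = MkCaParams.from_dict(_mkca_params(rng, tiny_sched, 8), tiny_sched)
        x = rng.normal(size=(3, 4, 8))
        assert mk_ca_forward(x, p, mode).shape == x.shape

    def test_average_and_sum_definitions(self, rng, tiny_sched):
        p = MkCaParams.from_dict(_mkca_params(rng, tiny_sched, 8), tiny_sched)
        x = rng.normal(size=(1, 4, 8))
        u, v = mk_ca_forward(x, p, "mlp"), mk_ca_forward(x, p, "kan")
        np.testing.assert_allclose(mk_ca_forward(x, p, "sum"), u + v, atol=1e-12)
        np.testing.assert_allclose(
            mk_ca_forward(x, p, "average"), (u + v) / 2, atol=1e-12
        )

    def test_unknown_mode_rejected(self, rng, tiny_sched):
        p = MkCaParams.from_dict(_mkca_params(rng, tiny_sched, 8), tiny_sched)
        with pytest.raises(ValueError, match="combination"):
            mk_ca_forward(rng.normal(size=(1, 4, 8)), p, "geometric")


class TestBlockAndStages:
    def test_block_identity_when_projections_zeroed(self, rng, tiny_sched):
        from ctiqa.swin import _init_block

        bp = _init_block(rng, 8, 4, tiny_sched)
        bp["attn"]["Wo"] = np.zeros_like(bp["attn"]["Wo"])
        bp["attn"]["bo"] = np.zeros_like(bp["attn"]["bo"])
        for ca in ("ca1", "ca2"):
            bp["mkca"][ca]["Wv"] = np.zeros_like(bp["mkca"][ca]["Wv"])
            bp["mkca"][ca]["bo"] = np.zeros_like(bp["mkca"][ca]["bo"])
        x = rng.normal(size=(1, 4, 4, 8))
        out = swin_kat_block(x, bp, tiny_sched, shift=0)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_block_shape_preserved(self, rng, tiny_sched):
        from ctiqa.swin import _init_block

        bp = _init_block(rng, 8, 4, tiny_sched)
        for shape in ((1, 4, 4, 8), (2, 8, 8, 8)):
            x = rng.normal(size=shape)
            assert swin_kat_block(x, bp, tiny_sched, 0).shape == shape

    def test_window_covering_grid_equals_dense_attention(self, rng, tiny_sched):
        # with one window over the whole 4x4 grid, windowed attention must
        # equal a global (dense) attention over all 16 tokens
        from ctiqa.swin import _init_block, layer_norm

        sched = replace(tiny_sched, window=4)
        bp = _init_block(rng, 8, 4, sched)
        x = rng.normal(size=(1, 4, 4, 8))
        out = swin_kat_block(x, bp, sched, shift=0)
        proj = AttentionProjection.from_dict(bp["attn"], sched.attn_heads)
        flat = x.reshape(1, 16, 8)
        dense = cosine_window_attention(flat, proj)
        y = x + layer_norm(dense.reshape(1, 4, 4, 8), bp["ln1"])
        mkca = MkCaParams.from_dict(bp["mkca"], sched)
        m = mk_ca_forward(y.reshape(1, 16, 8), mkca, sched.combination)
        expected = y + layer_norm(m.reshape(1, 4, 4, 8), bp["ln2"])
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_stage_resolution_and_channel_schedule(self):
        sched = StageSchedule(patch=4, repeats=(1, 1, 1, 1), base_channels=4,
                              attn_heads=2, kan_heads=2)
        assert [64 // sched.downsampling(n) for n in range(4)] == [16, 8, 4, 2]
        assert [sched.channels(n) for n in range(4)] == [4, 8, 16, 32]

    def test_run_stages_pooled_width(self, rng):
        sched = StageSchedule(patch=4, window=4, repeats=(1, 1), base_channels=8,
                              attn_heads=2, kan_heads=4)
        params = init_swin_params(sched, 32, rng)
        grid = rng.random((2, 32, 32, 1))
        tokens = patch_embed(grid, params["patch_embed"], sched.patch)
        pooled = run_stages(tokens, sched, params)
        assert pooled.shape == (2, sched.final_channels)
        assert np.all(np.isfinite(pooled))

    def test_gradients_reach_every_parameter_group(self, rng):
        from autograd import grad
        from autograd.misc import flatten

        sched = StageSchedule(patch=4, window=4, repeats=(1,), base_channels=8,
                              attn_heads=2, kan_heads=4)
        params = init_swin_params(sched, 16, rng)
        grid = rng.random((2, 16, 16, 1))

        def loss(p):
            tok = patch_embed(grid, p["patch_embed"], sched.patch)
            return (run_stages(tok, sched, p) ** 2).sum()

        g = grad(loss)(params)
        block = g["stages"][0]["blocks"][0]
        for group in ("Wq", "Wo", "logit_scale"):
            assert np.any(np.asarray(block["attn"][group]) != 0), group
        assert np.any(block["mkca"]["mlp"]["W1"] != 0)
        assert np.any(block["mkca"]["kan"]["coeffs"] != 0)
        assert np.any(block["mkca"]["kan"]["base"] != 0)
        for ca in ("ca1", "ca2"):
            assert np.any(block["mkca"][ca]["Wv"] != 0), ca


class TestScoreHead:
    def test_zero_weights_return_bias(self):
        p = {"W": np.zeros(6), "b": 2.5}
        assert score_head(np.ones((3, 6)), p)[0] == pytest.approx(2.5)

    def test_clipping(self):
        p = {"W": np.zeros(2), "b": -0.3}
        r = ScoreRange(0.0, 4.0)
        assert score_head(np.ones((1, 2)), p, clip_range=r)[0] == 0.0
        assert score_head(np.ones((1, 2)), p, clip_range=None)[0] == pytest.approx(-0.3)

    def test_relative_position_index_symmetry(self):
        idx = relative_position_index(3)
        assert idx.shape == (9, 9)
        assert idx[0, 0] == idx[4, 4]  # zero displacement shares one bias slot
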