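"""Backbone components against naive oracles and printed complexity forms."""

import numpy as np
import pytest

from resswin.autodiff import Tensor
from resswin.nn import count_parameters
from resswin.swin import (MASK_FILL, PatchMerging, SwinClassifier, SwinConfig,
                          WindowAttention, attention_flops, shifted_window_mask,
                          window_partition, window_reverse)

from conftest import SMALL_CFG


def naive_window_attention(attn: WindowAttention, xw: np.ndarray,
                           allowed: np.ndarray | None = None) -> np.ndarray:
    """O(N^2) per-pair attention computed with explicit loops.

    ``allowed[w, i, j]`` optionally restricts which pairs may attend
    (per window of the batch, broadcast over windows-in-batch order).
    """
    Bw, N, C = xw.shape
    h, d = attn.num_heads, attn.head_dim
    Wqkv, bqkv = attn.qkv.weight.data, attn.qkv.bias.data
    Wp, bp = attn.proj.weight.data, attn.proj.bias.data
    table = attn.relative_bias_table.data
    idx = attn._bias_index
    out = np.zeros_like(xw)
    for b in range(Bw):
        qkv = xw[b] @ Wqkv + bqkv  # (N, 3C)
        q, k, v = qkv[:, :C], qkv[:, C:2 * C], qkv[:, 2 * C:]
        heads_out = np.zeros((N, C))
        for head in range(h):
            sl = slice(head * d, (head + 1) * d)
            qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
            for i in range(N):
                logits = np.empty(N)
                for j in range(N):
                    logits[j] = (qh[i] @ kh[j]) * attn.scale + table[idx[i, j], head]
                    if allowed is not None and not allowed[b % allowed.shape[0], i, j]:
                        logits[j] = -np.inf
                w = np.exp(logits - logits.max())
                w /= w.sum()
                heads_out[i, sl] = w @ vh
        out[b] = heads_out @ Wp + bp
    return out


class TestWindows:
    def test_56_grid_gives_64_windows_of_49_tokens(self, rng):
        x = Tensor(rng.normal(size=(1, 56, 56, 8)))
        assert window_partition(x, 7).shape == (64, 49, 8)

    def test_single_window_grid(self, rng):
        x = Tensor(rng.normal(size=(2, 7, 7, 4)))
        assert window_partition(x, 7).shape == (2, 49, 4)

    def test_partition_reverse_roundtrip_bit_exact(self, rng):
        x = rng.normal(size=(2, 14, 14, 6)).astype(np.float32)
        back = window_reverse(window_partition(Tensor(x), 7), 7, 14, 14)
        assert np.array_equal(back.data, x)

    def test_non_divisible_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            window_partition(Tensor(rng.normal(size=(1, 15, 14, 4))), 7)


class TestWindowAttention:
    def test_softmax_rows_sum_to_one_via_uniform_value_probe(self, rng):
        # with V == identity-summing probe the row-stochastic property shows
        # up as output invariance; check directly on a naive recomputation
        attn = WindowAttention(8, 2, 2, np.random.default_rng(0))
        xw = rng.normal(size=(3, 4, 8)).astype(np.float32)
        ours = attn(Tensor(xw)).data
        oracle = naive_window_attention(attn, xw)
        assert np.allclose(ours, oracle, atol=1e-5)

    def test_single_token_window_is_value_projection(self, rng):
        attn = WindowAttention(6, 3, 1, np.random.default_rng(1))
        xw = rng.normal(size=(2, 1, 6)).astype(np.float32)
        out = attn(Tensor(xw)).data
        C = 6
        qkv = xw @ attn.qkv.weight.data + attn.qkv.bias.data
        v = qkv[..., 2 * C:]
        expected = v @ attn.proj.weight.data + attn.proj.bias.data
        assert np.allclose(out, expected, atol=1e-6)

    def test_relative_bias_depends_only_on_offset(self):
        idx = WindowAttention._relative_index(3)
        # token (r, c) is flat index 3r + c; same (drow, dcol) -> same entry
        assert idx[3 * 1 + 1, 3 * 0 + 0] == idx[3 * 2 + 2, 3 * 1 + 1]
        assert idx[0, 1] == idx[3, 4] == idx[7, 8]
        assert len(np.unique(idx)) == (2 * 3 - 1) ** 2

    def test_mask_shape_mismatch_rejected(self, rng):
        attn = WindowAttention(4, 2, 2, np.random.default_rng(2))
        xw = Tensor(rng.normal(size=(2, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            attn(xw, np.zeros((1, 3, 3), dtype=np.float32))


class TestShiftedWindowScheme:
    def test_shifted_grid_has_exactly_nine_regions(self):
        region, mask = shifted_window_mask(14, 14, 7, 3)
        assert len(np.unique(region)) == 9
        assert mask.shape == (4, 49, 49)

    def test_zero_shift_mask_allows_all_pairs(self):
        region, mask = shifted_window_mask(14, 14, 7, 0)
        assert np.all(mask == 0.0)
        assert len(np.unique(region)) == 1

    def test_masked_attention_equals_per_region_attention(self, rng):
        """SW-MSA with the additive mask must equal independent naive
        attention over each pre-shift region's tokens inside every window."""
        M, H = 7, 14
        attn = WindowAttention(4, 2, M, np.random.default_rng(3))
        region, mask = shifted_window_mask(H, H, M, 3)
        x = rng.normal(size=(1, H, H, 4)).astype(np.float32)
        # implementation path: partition the (already shifted) grid + mask
        windows = window_partition(Tensor(x), M)
        ours = attn(windows, mask).data
        # oracle path: loops, with cross-region pairs hard-forbidden
        region_windows = window_partition(Tensor(region[None, :, :, None]
                                                 .astype(np.float32)), M).data[..., 0]
        allowed = region_windows[:, :, None] == region_windows[:, None, :]
        oracle = naive_window_attention(attn, windows.data, allowed)
        assert np.allclose(ours, oracle, atol=1e-5)

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            shifted_window_mask(14, 14, 7, 7)


class TestPatchMerging:
    def test_halves_grid_and_doubles_channels(self, rng):
        pm = PatchMerging(96, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 56, 56, 96)).astype(np.float32))
        assert pm(x).shape == (1, 28, 28, 192)

    def test_parameter_count_is_8c2_plus_8c(self):
        C = 24
        pm = PatchMerging(C, np.random.default_rng(0))
        assert count_parameters(pm) == 4 * C * 2 * C + 2 * 4 * C

    def test_odd_dims_rejected(self, rng):
        pm = PatchMerging(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            pm(Tensor(rng.normal(size=(1, 7, 8, 4)).astype(np.float32)))


class TestComplexityFormulas:
    def test_printed_closed_forms(self):
        H = W = 56
        C, M = 96, 7
        assert attention_flops(H, W, C) == 4 * 56 * 56 * 96 ** 2 + 2 * 3136 ** 2 * 96
        assert (attention_flops(H, W, C, M, windowed=True)
                == 4 * 56 * 56 * 96 ** 2 + 2 * 49 * 3136 * 96)

    def test_windowed_cheaper_whenever_window_smaller_than_grid(self):
        for H, C, M in [(56, 96, 7), (14, 384, 7), (28, 8, 4)]:
            if M * M < H * H:
                assert attention_flops(H, H, C, M, True) < attention_flops(H, H, C)

    def test_windowed_formula_matches_instruction_counting_oracle(self):
        """Count multiply-accumulates of the implemented attention with
        explicit loop nests over windows/tokens/channels."""
        H = W = 14
        C, M = 4, 7
        n_windows = (H // M) * (W // M)
        N = M * M
        macs = 0
        for _ in range(n_windows):
            macs += N * C * (3 * C)      # qkv projection
            macs += N * N * C            # q . k logits
            macs += N * N * C            # attention-weighted sum of values
            macs += N * C * C            # output projection
        assert macs == attention_flops(H, W, C, M, windowed=True)


class TestClassifier:
    def test_stage_shape_chain_and_logits(self, rng):
        model = SwinClassifier(SMALL_CFG, 0).eval()
        x = rng.normal(size=(2, 56, 56, 3)).astype(np.float32)
        logits = model(x)
        assert logits.shape == (2, 3)
        assert model.cache["stage1_input"].shape == (2, 14, 14, 32)
        assert model.cache["stage2_input"].shape == (2, 7, 7, 64)

    def test_inference_is_deterministic(self, rng):
        model = SwinClassifier(SMALL_CFG, 0).eval()
        x = rng.normal(size=(1, 56, 56, 3)).astype(np.float32)
        assert np.array_equal(model(x).data, model(x).data)

    def test_identical_images_in_batch_get_identical_logits(self, rng):
        model = SwinClassifier(SMALL_CFG, 0).eval()
        one = rng.normal(size=(56, 56, 3)).astype(np.float32)
        logits = model(np.stack([one, one])).data
        assert np.allclose(logits[0], logits[1], atol=1e-5)

    def test_wrong_input_size_rejected(self, rng):
        model = SwinClassifier(SMALL_CFG, 0).eval()
        with pytest.raises(ValueError):
            model(rng.normal(size=(1, 57, 57, 3)).astype(np.float32))

    def test_full_config_token_counts(self):
        cfg = SwinConfig()
        assert cfg.stage_grids() == (56, 28, 14, 7)
        assert cfg.stage_dims() == (96, 192, 384, 768)
        assert (224 // 4) ** 2 == 3136

    def test_config_roundtrips_through_json(self):
        cfg = SwinConfig()
        assert SwinConfig.from_json(cfg.to_json()) == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SwinConfig(img_size=225).validate()
        with pytest.raises(ValueError):
            SwinConfig(embed_dim=50, num_heads=(4, 4, 4, 4)).validate()
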