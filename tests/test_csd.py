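"""CSD-map encoding: two-frame case labels, bit-sum oracle, normalization."""

import numpy as np
import pytest

from csdgait.csd import (
    CSDEncoder,
    CSDMap,
    encode_2csd,
    encode_ncsd,
    normalize_csd,
    stream_csd,
)
from csdgait.silhouettes import BinarySilhouette, SilhouetteSequence

from conftest import make_frames


def brute_force_ncsd(masks):
    """Independent per-pixel oracle: enumerate frame memberships and sum
    the bit weights (newest frame = bit 0)."""
    n = len(masks)
    h, w = masks[0].shape
    out = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            value = 0
            for age, k in enumerate(range(n - 1, -1, -1)):  # newest first
                if masks[k][r, c]:
                    value += 2**age
            out[r, c] = value
    return out


class TestEncode2CSD:
    def test_case_labels(self):
        # the three membership cases: current-only -> 1, previous-only -> 2,
        # both -> 3, neither -> 0
        prev = make_frames([np.array([[0, 1, 1]]), np.array([[1, 1, 0]])])
        m = encode_2csd(prev[0], prev[1])
        assert m.values.tolist() == [[1, 3, 2]]

    def test_empty_pair_gives_empty_map(self):
        z = make_frames([np.zeros((4, 4)), np.zeros((4, 4))])
        assert not encode_2csd(z[0], z[1]).values.any()

    def test_identical_masks_give_three_times_mask(self, rng):
        mask = (rng.random((6, 5)) < 0.5).astype(np.uint8)
        fr = make_frames([mask, mask])
        m = encode_2csd(fr[0], fr[1])
        assert np.array_equal(m.values, 3 * mask)

    def test_rejects_dimension_mismatch_and_gaps(self):
        a = BinarySilhouette(np.zeros((3, 3)), frame_index=0)
        b = BinarySilhouette(np.zeros((3, 4)), frame_index=1)
        with pytest.raises(ValueError, match="dimensions"):
            encode_2csd(a, b)
        c = BinarySilhouette(np.zeros((3, 3)), frame_index=5)
        with pytest.raises(ValueError, match="consecutive"):
            encode_2csd(a, c)
        # overridable for ad-hoc pairs
        encode_2csd(a, c, check_consecutive=False)


class TestEncodeNCSD:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_membership_oracle_on_random_windows(self, n, random_window):
        for seed in range(20):
            frames = make_frames(
                (np.random.default_rng([n, seed]).random((n, 9, 7)) < 0.5).astype(
                    np.uint8
                )
            )
            got = encode_ncsd(frames).values
            expected = brute_force_ncsd([f.mask for f in frames])
            assert np.array_equal(got, expected)

    def test_all_foreground_pixel_gets_full_code(self):
        frames = make_frames(np.ones((3, 2, 2)))
        assert encode_ncsd(frames).values.max() == 7

    def test_all_eight_membership_patterns_distinct(self):
        # 8 pixels, one per membership subset of 3 frames
        patterns = np.array([[(p >> b) & 1 for p in range(8)] for b in range(3)])
        # patterns[b] is frame b's mask over the 8 pixels; newest = bit 0
        masks = [patterns[2 - b].reshape(1, 8) for b in range(3)]
        frames = make_frames(masks)
        values = encode_ncsd(frames).values.ravel()
        assert sorted(values.tolist()) == list(range(8))

    def test_agrees_with_two_frame_encoder(self, random_window):
        for seed in range(10):
            frames = random_window(2, seed=seed)
            assert np.array_equal(
                encode_ncsd(frames).values, encode_2csd(*frames).values
            )

    def test_value_alphabet_invariant_under_bit_reversal(self, random_window):
        # relabeling which frame owns which bit permutes values bijectively:
        # the histogram of distinct values has the same size either way
        frames = random_window(4, seed=7)
        fwd = encode_ncsd(frames).values
        rev = np.zeros_like(fwd)
        for bit, f in enumerate(frames):  # oldest gets bit 0 instead
            rev |= f.mask << bit
        assert len(np.unique(fwd)) == len(np.unique(rev))
        assert np.array_equal(fwd == 0, rev == 0)

    def test_window_size_bounds(self, random_window):
        with pytest.raises(ValueError):
            encode_ncsd(random_window(2)[:1])
        with pytest.raises(ValueError):
            encode_ncsd(random_window(9, seed=1))

    def test_anchor_is_newest_frame(self, random_window):
        frames = random_window(3)
        assert encode_ncsd(frames).anchor_frame_index == frames[-1].frame_index


class TestNormalizeCSD:
    def test_output_dims_exact_and_in_unit_range(self, rng):
        vals = np.zeros((40, 30), dtype=np.uint8)
        vals[5:25, 10:20] = rng.integers(1, 4, size=(20, 10))
        m = CSDMap(values=vals, n=2, anchor_frame_index=1)
        out = normalize_csd(m, target_w=32, target_h=48)
        assert out.values.shape == (48, 32)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_constant_map_resizes_to_constant(self):
        vals = np.zeros((20, 20), dtype=np.uint8)
        vals[4:10, 3:9] = 2
        m = CSDMap(values=vals, n=2, anchor_frame_index=1)
        out = normalize_csd(m, target_w=6, target_h=6)
        assert np.allclose(out.values, 2 / 3, atol=1e-6)

    def test_single_pixel_full_value_upsamples_to_ones(self):
        vals = np.zeros((8, 8), dtype=np.uint8)
        vals[3, 4] = 3
        m = CSDMap(values=vals, n=2, anchor_frame_index=1)
        out = normalize_csd(m, target_w=5, target_h=7)
        assert np.allclose(out.values, 1.0)

    def test_translation_invariance(self, rng):
        content = (rng.integers(0, 4, size=(12, 9))).astype(np.uint8)
        content[0, 0] = content[-1, -1] = 3  # pin the bounding box
        base = np.zeros((60, 60), dtype=np.uint8)
        base[5 : 5 + 12, 7 : 7 + 9] = content
        shifted = np.zeros((60, 60), dtype=np.uint8)
        shifted[31 : 31 + 12, 40 : 40 + 9] = content
        out1 = normalize_csd(CSDMap(base, 2, 0), 16, 24)
        out2 = normalize_csd(CSDMap(shifted, 2, 0), 16, 24)
        assert np.allclose(out1.values, out2.values)

    def test_empty_map_raises(self):
        m = CSDMap(values=np.zeros((5, 5), dtype=np.uint8), n=2, anchor_frame_index=0)
        with pytest.raises(ValueError, match="empty CSD-map"):
            normalize_csd(m, 8, 8)


class TestStreamCSD:
    def _sequence(self, n_frames, seed=0, h=16, w=12):
        r = np.random.default_rng(seed)
        masks = np.zeros((n_frames, h, w), dtype=np.uint8)
        for i in range(n_frames):
            masks[i, 2 + (i % 3) : 10 + (i % 3), 3:9] = 1
        return SilhouetteSequence(frames=make_frames(masks), frame_rate_hz=25.0)

    @pytest.mark.parametrize("n,expect", [(2, 9), (6, 5)])
    def test_map_count_and_anchors(self, n, expect):
        seq = self._sequence(10)
        maps = stream_csd(seq, n=n, target_w=8, target_h=12)
        assert len(maps) == expect
        assert [m.anchor_frame_index for m in maps] == list(range(n - 1, 10))

    def test_matches_manual_pairwise_composition(self):
        seq = self._sequence(8)
        maps = stream_csd(seq, n=2, target_w=8, target_h=12)
        for m in maps:
            i = m.anchor_frame_index
            manual = normalize_csd(
                encode_2csd(seq[i - 1], seq[i]), target_w=8, target_h=12
            )
            assert np.allclose(m.values, manual.values)

    def test_all_zero_windows_are_skipped(self):
        masks = np.zeros((6, 8, 8), dtype=np.uint8)
        masks[0, 2:4, 2:4] = 1
        masks[5, 2:4, 2:4] = 1  # frames 1..4 empty -> windows (1,2)..(3,4) empty
        seq = SilhouetteSequence(frames=make_frames(masks), frame_rate_hz=25.0)
        maps = stream_csd(seq, n=2, target_w=4, target_h=4)
        assert [m.anchor_frame_index for m in maps] == [1, 5]

    def test_too_short_sequence_raises(self):
        seq = self._sequence(3)
        with pytest.raises(ValueError, match="too short"):
            stream_csd(seq, n=4)


def test_export_map_png_quantizes_to_255(tmp_path):
    import imageio.v3 as iio
    from csdgait.csd import NormalizedCSDMap, export_map_png

    vals = np.linspace(0, 1, 12, dtype=np.float32).reshape(3, 4)
    m = NormalizedCSDMap(values=vals, n=2, anchor_frame_index=5)
    p = tmp_path / "map.png"
    export_map_png(m, p)
    back = iio.imread(p)
    assert back.shape == (3, 4)
    assert np.array_equal(back, np.round(vals * 255).astype(np.uint8))


class TestCSDEncoderTransformer:
    def test_transform_stacks_maps(self):
        r = np.random.default_rng(3)
        masks = (r.random((7, 20, 16)) < 0.4).astype(np.uint8)
        enc = CSDEncoder(n=3, target_w=8, target_h=12).fit()
        X = enc.transform(masks)
        assert X.shape == (5, 12, 8)
        assert X.dtype == np.float32

    def test_sklearn_param_interface(self):
        enc = CSDEncoder(n=4)
        assert enc.get_params()["n"] == 4
        enc.set_params(n=2, target_w=16)
        assert enc.n == 2 and enc.target_w == 16

    def test_invalid_n_rejected_at_fit(self):
        with pytest.raises(ValueError):
            CSDEncoder(n=1).fit()
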