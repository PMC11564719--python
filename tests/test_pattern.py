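"""Unit and property tests for the BWHPat textural descriptor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bwhpat import pattern as bp


def brute_force_selection(block: bp.BwhBlock, gs: bp.GlobalStats) -> int:
    """Independent argmin over the 14 recomputed (mean, std) distances."""
    dists = []
    for e in range(1, 15):
        mu, sd = bp.group_stats(block, e)
        dists.append(np.hypot(gs.mean - mu, gs.std - sd))
    return int(np.argmin(dists)) + 1


class TestBlockLayout:
    def test_indexed_block_slices(self):
        blk = bp.split_block(np.arange(1, 70))
        assert blk.C == 35            # the singularity is the middle sample
        assert blk.vew[0] == 36
        assert blk.vw[-1] == 69
        assert blk.b[0, 1] == 2       # row-major 5x5 fill
        assert blk.Cb == 13 and blk.Cw == 57
        assert blk.cb == 30 and blk.cw == 40

    def test_region_sizes(self):
        blk = bp.split_block(np.zeros(69))
        assert blk.vb.size == 25 and blk.vw.size == 25
        assert blk.veb.size == 9 and blk.vew.size == 9
        assert blk.b.shape == (5, 5) and blk.eb.shape == (3, 3)

    @pytest.mark.parametrize("n", [0, 68, 70])
    def test_wrong_length_rejected(self, n):
        with pytest.raises(ValueError):
            bp.split_block(np.zeros(n))

    def test_extract_blocks_counts(self, rng):
        assert len(bp.extract_blocks(np.zeros(69))) == 1
        blocks = bp.extract_blocks(np.arange(70.0))
        assert len(blocks) == 2
        assert blocks[1].bl[0] == 1.0            # second block starts one later
        x = rng.standard_normal(300)
        assert len(bp.extract_blocks(x)) == x.size - 68
        with pytest.raises(ValueError):
            bp.extract_blocks(np.zeros(68))


class TestSignumAndPatterns:
    @pytest.mark.parametrize("x,c,expected", [(5, 3, 1), (2, 3, 0), (3, 3, 1)])
    def test_signum_compare(self, x, c, expected):
        assert bp.signum_compare(x, c) == expected

    def test_signum_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            bp.signum_compare(np.nan, 0.0)

    def test_constant_block_gives_all_ones(self):
        blk = bp.split_block(np.full(69, 2.5))
        for e in range(1, 15):
            assert bp.binary_pattern(blk, e).tolist() == [1] * 8

    def test_black_cells_below_center_give_zeros(self):
        vals = np.zeros(69)
        vals[12] = 10.0                   # Cb large, all compared b cells 0
        vals[0] = -1.0
        blk = bp.split_block(vals)
        assert bp.binary_pattern(blk, 1).sum() == 0

    def test_indexed_block_pattern9_all_zero(self):
        # every compared black-hole cell is smaller than its white counterpart
        blk = bp.split_block(np.arange(1, 70))
        assert bp.binary_pattern(blk, 9).sum() == 0

    @pytest.mark.parametrize("e", [0, 15])
    def test_pattern_index_out_of_range(self, e):
        blk = bp.split_block(np.zeros(69))
        with pytest.raises(ValueError):
            bp.binary_pattern(blk, e)


class TestGroupStats:
    def test_constant_block(self):
        blk = bp.split_block(np.full(69, 4.0))
        for e in range(1, 15):
            mu, sd = bp.group_stats(blk, e)
            assert mu == 4.0 and sd == 0.0

    def test_indexed_block_group3_mean(self):
        # group 3 is the black-hole event horizon: values 26..34
        blk = bp.split_block(np.arange(1, 70))
        mu, sd = bp.group_stats(blk, 3)
        assert mu == 30.0
        assert sd == pytest.approx(np.std(np.arange(26, 35), ddof=1))

    def test_concatenated_group_sizes_via_means(self):
        # group 5 = b plus singularity (26 values), group 10 = both horizons (18)
        vals = np.zeros(69)
        vals[34] = 26.0                  # only the singularity is nonzero
        blk = bp.split_block(vals)
        assert bp.group_stats(blk, 5)[0] == pytest.approx(1.0)   # 26/26
        vals = np.zeros(69)
        vals[25:34] = 2.0                # eb only
        blk = bp.split_block(vals)
        assert bp.group_stats(blk, 10)[0] == pytest.approx(1.0)  # 18/18


class TestSelection:
    def test_constant_ties_resolve_to_first_pattern(self):
        blk = bp.split_block(np.full(69, 1.0))
        gs = bp.global_stats(np.full(100, 1.0))
        sel = bp.select_pattern(blk, gs)
        assert sel.idt == 1
        assert np.allclose(sel.distances, 0.0)

    def test_engineered_group7_match(self, rng):
        blk = bp.split_block(rng.standard_normal(69))
        mu7, sd7 = bp.group_stats(blk, 7)
        gs = bp.GlobalStats(mean=mu7, std=sd7, lng=100)
        assert bp.select_pattern(blk, gs).idt == 7

    def test_brute_force_oracle(self, rng):
        sig = rng.standard_normal(400)
        gs = bp.global_stats(sig)
        for blk in bp.extract_blocks(sig)[:150]:
            sel = bp.select_pattern(blk, gs)
            assert sel.idt == brute_force_selection(blk, gs)
            assert np.all(sel.distances >= 0)

    def test_shift_leaves_selection_unchanged(self, rng):
        sig = rng.standard_normal(200)
        gs = bp.global_stats(sig)
        gs_shift = bp.global_stats(sig + 7.0)
        for start in (0, 50, 100):
            blk = bp.split_block(sig[start:start + 69])
            blk_shift = bp.split_block(sig[start:start + 69] + 7.0)
            assert (bp.select_pattern(blk, gs).idt
                    == bp.select_pattern(blk_shift, gs_shift).idt)


class TestMapValue:
    @pytest.mark.parametrize("bits,expected", [
        ([0] * 8, 0),
        ([1] * 8, 255),
        ([1, 0, 0, 0, 0, 0, 0, 0], 128),     # MSB-first weighting
        ([0, 0, 0, 0, 0, 0, 0, 1], 1),
    ])
    def test_values(self, bits, expected):
        assert bp.map_value(np.array(bits)) == expected

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            bp.map_value(np.array([0, 1, 2, 0, 0, 0, 0, 0]))


class TestTransform:
    def test_constant_signal_maps_to_255(self):
        ms = bp.bwhpat_transform(np.full(100, 2.5))
        assert ms.map.tolist() == [255] * 32
        assert ms.pattern_usage[0] == 32          # ties pick pattern 1

    def test_map_length_and_usage(self, rng):
        x = rng.standard_normal(500)
        ms = bp.bwhpat_transform(x)
        assert ms.map.size == x.size - 68
        assert ms.pattern_usage.sum() == ms.map.size
        assert ms.map.min() >= 0 and ms.map.max() <= 255

    def test_short_signal_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            ms = bp.bwhpat_transform(np.zeros(68))
        assert ms.map.size == 0

    def test_numba_matches_numpy_reference(self, rng):
        for n in (69, 137, 1000):
            x = rng.standard_normal(n)
            fast = bp.bwhpat_transform(x)
            ref = bp._transform_numpy(x, bp.global_stats(x))
            assert np.array_equal(fast.map, ref.map)
            assert np.array_equal(fast.pattern_usage, ref.pattern_usage)

    def test_transform_agrees_with_per_block_path(self, rng):
        sig = rng.standard_normal(300)
        gs = bp.global_stats(sig)
        expected = [bp.map_value(bp.select_pattern(blk, gs).bf)
                    for blk in bp.extract_blocks(sig)]
        assert bp.bwhpat_transform(sig).map.tolist() == expected


class TestHistogram:
    def test_constant_signal_histogram(self):
        hist = bp.bwhpat_features(np.full(100, 1.0))
        assert hist.size == 256
        assert hist[255] == 32 and hist.sum() == 32

    def test_empty_for_short_signal(self):
        with pytest.warns(UserWarning):
            hist = bp.bwhpat_features(np.zeros(68))
        assert hist.sum() == 0 and hist.size == 256

    def test_normalized_flag(self, rng):
        x = rng.standard_normal(200)
        hist = bp.bwhpat_features(x, normalize=True)
        assert hist.sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=69,
                    max_size=400))
    def test_mass_conservation_property(self, values):
        x = np.asarray(values)
        hist = bp.bwhpat_features(x)
        assert hist.sum() == x.size - 68
        assert (hist >= 0).all()
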