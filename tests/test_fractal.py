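import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trachea_sr import (
    HeightMap,
    InsufficientScalesError,
    analyze_heightmap,
    brute_force_box_count,
    default_box_sizes,
    dimension_to_sr,
    fractal_dimension,
    irdbc_counts,
    make_test_heightmap,
    quantize_heights,
)


class TestHeightMap:
    def test_normalized_to_zero_minimum(self):
        hm = HeightMap(np.array([[3, 4], [5, 6]]))
        assert hm.pixels.min() == 0
        assert hm.n_gray == 4

    def test_quantization_round_half_up(self):
        hm = quantize_heights(np.array([[0.0, 0.49, 0.5, 7.4]]))
        np.testing.assert_array_equal(hm.pixels, [[0, 0, 1, 7]])
        assert hm.n_gray == 8  # heights spanning 0..7.4 mm -> 8 levels

    def test_dequantization_within_half_mm(self, rng):
        heights = rng.uniform(0, 12, (30, 30))
        hm = quantize_heights(heights)
        recon = hm.pixels * hm.mm_per_gray + heights.min()
        assert np.abs(recon - heights).max() <= 0.5 + 1e-12

    def test_rejects_floats_and_wrong_ndim(self):
        with pytest.raises(ValueError):
            HeightMap(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            HeightMap(np.zeros(4, dtype=int))


class TestCounts:
    def test_flat_map_counts_closed_form(self):
        hm = make_test_heightmap("constant", shape=(64, 64))
        sizes, counts = irdbc_counts(hm, [2, 4, 8, 16])
        assert counts == [(64 / s) ** 2 for s in sizes]

    def test_counts_non_increasing(self, rng):
        for _ in range(5):
            hm = HeightMap(rng.integers(0, 12, (48, 48)).astype(np.int64))
            _, counts = irdbc_counts(hm, list(range(2, 13)))
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_out_of_range_box_size(self):
        hm = make_test_heightmap("constant", shape=(32, 32))
        with pytest.raises(ValueError):
            irdbc_counts(hm, [1])
        with pytest.raises(ValueError):
            irdbc_counts(hm, [17])

    def test_matches_oracle_on_ramp(self):
        hm = make_test_heightmap("ramp", shape=(8, 8), n_gray=8)
        for s in (2, 3, 4):
            assert irdbc_counts(hm, [s])[1][0] == brute_force_box_count(hm, s)

    def test_single_pixel_spike_hand_computed(self):
        """A 4x4 flat map with one 24-level spike at s=2: box height is
        h = 2*24/4 = 12 levels, so the spike's cell spans 24/12 = 2 boxes and
        each of the three flat cells exactly one."""
        px = np.zeros((4, 4), dtype=np.int64)
        px[0, 0] = 23  # n_gray = 24
        hm = HeightMap(px)
        sizes, counts = irdbc_counts(hm, [2])
        assert counts[0] == 3 * 1 + 2  # three flat cells + spike cell
        assert counts[0] == brute_force_box_count(hm, 2)

    def test_oracle_equivalence_random_maps(self, rng):
        for _ in range(40):
            m0, m1 = rng.integers(8, 33, 2)
            n_gray = int(rng.integers(1, 17))
            hm = HeightMap(rng.integers(0, n_gray, (m0, m1)).astype(np.int64))
            for s in range(2, min(m0, m1) // 2 + 1):
                assert irdbc_counts(hm, [s])[1][0] == brute_force_box_count(hm, s)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        m0=st.integers(8, 24), m1=st.integers(8, 24),
        n_gray=st.integers(1, 16), s=st.integers(2, 6),
        seed=st.integers(0, 2**16),
    )
    def test_oracle_equivalence_property(self, m0, m1, n_gray, s, seed):
        if s > min(m0, m1) // 2:
            return
        px = np.random.default_rng(seed).integers(0, n_gray, (m0, m1))
        hm = HeightMap(px.astype(np.int64))
        assert irdbc_counts(hm, [s])[1][0] == brute_force_box_count(hm, s)


class TestDimension:
    def test_flat_map_dimension_exact(self):
        hm = make_test_heightmap("constant", shape=(64, 64))
        sizes, counts = irdbc_counts(hm, [2, 4, 8, 16])
        d, r2 = fractal_dimension(sizes, counts)
        assert d == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_scales(self):
        with pytest.raises(InsufficientScalesError):
            fractal_dimension([2, 4, 8], [16, 4, 1])

    def test_space_filling_random_map_approaches_three(self, rng):
        """I.i.d. uniform gray levels over a wide range fill the box volume."""
        ds = []
        for seed in range(5):
            px = np.random.default_rng(seed).integers(0, 128, (128, 128))
            res = analyze_heightmap(HeightMap(px.astype(np.int64)))
            ds.append(res.D)
        assert np.mean(ds) > 2.8
        assert all(d <= 3.0 for d in ds)

    def test_clamping_logged_in_result(self):
        hm = make_test_heightmap("constant", shape=(64, 64))
        res = analyze_heightmap(hm)
        assert res.D == 2.0 and res.SR == 0.0
        assert "flat map" in res.notes[0]

    def test_fbm_dimension_recovery_single_case(self):
        hm = make_test_heightmap("fbm", shape=(256, 256), hurst=0.5,
                                 amplitude_rms=16.0, seed=0)
        res = analyze_heightmap(hm)
        assert res.D == pytest.approx(2.5, abs=0.2)
        assert res.fit_r2 > 0.98

    def test_default_ladder_bounds(self):
        sizes = default_box_sizes((256, 256))
        assert sizes[0] == 32 and sizes[-1] == 64
        assert default_box_sizes((360, 75)) == list(range(9, 19))


class TestSrConversion:
    @pytest.mark.parametrize("d, sr", [(2.0, 0.0), (3.0, 100.0), (2.16, 16.0)])
    def test_anchors(self, d, sr):
        assert dimension_to_sr(d) == pytest.approx(sr)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dimension_to_sr(1.8)
        with pytest.raises(ValueError):
            dimension_to_sr(3.2)

    def test_monotone_in_dimension(self):
        ds = np.linspace(2, 3, 11)
        srs = [dimension_to_sr(d) for d in ds]
        assert all(a < b for a, b in zip(srs, srs[1:]))


class TestScaleContract:
    def test_sr_invariant_under_height_offset(self, rng):
        heights = rng.standard_normal((64, 64)) * 5
        a = analyze_heightmap(quantize_heights(heights))
        b = analyze_heightmap(quantize_heights(heights + 37.0))
        assert a.SR == b.SR
        assert a.counts == b.counts

    def test_sr_stable_under_theta_roll(self):
        """Rolling the theta origin only re-aligns the counting grid; the SR
        shift stays within the grid-alignment sensitivity of small maps."""
        hm = make_test_heightmap("fbm", shape=(128, 128), hurst=0.5,
                                 amplitude_rms=10.0, seed=2)
        for roll in (13, 31, 64):
            rolled = HeightMap(np.roll(hm.pixels, roll, axis=0))
            a = analyze_heightmap(hm)
            b = analyze_heightmap(rolled)
            assert abs(a.SR - b.SR) < 8.0

    def test_result_serializable(self):
        import json

        res = analyze_heightmap(make_test_heightmap("fbm", shape=(64, 64),
                                                    hurst=0.5, amplitude_rms=8.0,
                                                    seed=1))
        payload = json.dumps(res.to_dict())
        assert "box_sizes" in payload
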