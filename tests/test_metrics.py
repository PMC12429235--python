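import numpy as np
import pandas as pd
import pytest

from trachea_sr import (
    AnalysisConfig,
    CtVolume,
    DegenerateInputError,
    TubeSpec,
    VoxelMask,
    WindowError,
    compute_all,
    crop_trachea,
    laa950,
    make_tube_mask,
    run_batch,
    tracheal_index,
    write_mask,
)


class TestTrachealIndex:
    def test_circular_tube_ti_near_one(self, smooth_bif):
        mask, _ = smooth_bif
        m = compute_all(mask)
        assert m.TI == pytest.approx(1.0, abs=0.05)

    def test_elliptical_tube_ti(self, elliptical_bif):
        mask, _ = elliptical_bif
        m = compute_all(mask)
        assert m.TI == pytest.approx(0.75, abs=0.05)

    def test_ti_is_minimum_of_emitted_table(self, elliptical_bif):
        mask, _ = elliptical_bif
        m = compute_all(mask)
        tbl = m.per_slice_diameters
        in_window = tbl[tbl["z_mm"] >= 20.0]
        assert m.TI <= in_window["ratio"].min() + 1e-12

    def test_varying_ratio_minimum_at_window_bottom(self):
        """With d_c/d_s shrinking toward the carina, the TI must be attained
        at the inferior window bound (2 cm above the carina); narrower slices
        below the window are excluded."""
        spec = TubeSpec(base_radius=9.0, length=80.0, cross_section_ratio=(1.0, 0.7))
        mask, truth = make_tube_mask(spec)
        seg = crop_trachea(mask, z_carina=0)
        ti, ti_slice, tbl = tracheal_index(seg)
        z_at_min = tbl.loc[tbl[tbl["z_mm"] >= 20.0]["ratio"].idxmin(), "z_mm"]
        assert z_at_min == pytest.approx(20.0, abs=1.5)
        expected = float(spec.ratio_at(20.0))
        assert ti == pytest.approx(expected, abs=0.05)
        assert ti > float(spec.ratio_at(0.0))  # sub-window slices excluded

    def test_empty_window_raises(self, straight_tube):
        mask, _ = straight_tube
        seg = crop_trachea(mask, z_carina=0)
        with pytest.raises(WindowError):
            tracheal_index(seg, window_mm=(200.0, 300.0))


class TestLaa950:
    def _pair(self, hu):
        ct = CtVolume(hu, (1.0, 1.0, 1.0))
        lung = VoxelMask(np.ones_like(hu, dtype=np.uint8), (1.0, 1.0, 1.0))
        return ct, lung

    def test_uniform_above_threshold_is_zero(self):
        ct, lung = self._pair(np.full((10, 10, 10), -900.0))
        assert laa950(ct, lung) == 0.0

    def test_exact_ten_percent(self):
        hu = np.full((10, 10, 10), -900.0)
        hu.ravel()[:100] = -980.0
        ct, lung = self._pair(hu)
        assert laa950(ct, lung) == pytest.approx(10.0)

    def test_threshold_is_strict(self):
        ct, lung = self._pair(np.full((5, 5, 5), -950.0))
        assert laa950(ct, lung) == 0.0

    def test_empty_lung_rejected(self):
        ct, _ = self._pair(np.full((5, 5, 5), -900.0))
        lung = VoxelMask(np.zeros((5, 5, 5), dtype=np.uint8), (1.0, 1.0, 1.0))
        with pytest.raises(DegenerateInputError):
            laa950(ct, lung)

    def test_shape_mismatch_rejected(self):
        ct, _ = self._pair(np.full((5, 5, 5), -900.0))
        lung = VoxelMask(np.ones((6, 6, 6), dtype=np.uint8), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            laa950(ct, lung)


class TestComputeAll:
    def test_smooth_phantom_near_flat(self, smooth_bif):
        mask, truth = smooth_bif
        m = compute_all(mask)
        assert m.SR_S < 3.0
        assert m.SR_C < 3.0
        assert m.TI == pytest.approx(1.0, abs=0.05)
        assert abs(m.z_carina - truth.carina_index) <= 2

    def test_textured_rougher_than_smooth(self, smooth_bif, textured_bif):
        sm = compute_all(smooth_bif[0])
        tx = compute_all(textured_bif[0])
        assert tx.SR_S > sm.SR_S + 1.0

    def test_deterministic(self, textured_bif):
        mask, _ = textured_bif
        a = compute_all(mask)
        b = compute_all(mask)
        assert a.to_row() == b.to_row()
        pd.testing.assert_frame_equal(a.per_slice_diameters, b.per_slice_diameters)

    def test_manual_carina_override(self, straight_tube):
        mask, _ = straight_tube
        m = compute_all(mask, AnalysisConfig(carina_slice=0))
        assert m.z_carina == 0
        assert "manually" in " ".join(m.qc_flags)

    def test_unusable_mask_rejected(self):
        empty = VoxelMask(np.zeros((20, 20, 20), dtype=np.uint8), (1.0, 1.0, 1.0))
        with pytest.raises(DegenerateInputError):
            compute_all(empty)

    def test_config_hash_stable(self):
        assert AnalysisConfig().hash == AnalysisConfig().hash
        assert AnalysisConfig().hash != AnalysisConfig(n_theta=180).hash


class TestRunBatch:
    def test_batch_with_corrupt_file(self, tmp_path, smooth_bif, textured_bif):
        write_mask(smooth_bif[0], tmp_path / "case_a.nii.gz")
        write_mask(textured_bif[0], tmp_path / "case_b.nii.gz")
        (tmp_path / "case_c.nii.gz").write_bytes(b"not a nifti")
        df = run_batch(tmp_path, tmp_path / "out.csv", AnalysisConfig())
        assert len(df) == 3
        assert (df["status"] == "ok").sum() == 2
        failed = df[df["case_id"] == "case_c"]
        assert failed["status"].str.startswith("failed").all()

    def test_batch_reproducible(self, tmp_path, smooth_bif):
        write_mask(smooth_bif[0], tmp_path / "case.nii.gz")
        df1 = run_batch(tmp_path, tmp_path / "a.csv", AnalysisConfig())
        df2 = run_batch(tmp_path, tmp_path / "b.csv", AnalysisConfig())
        pd.testing.assert_frame_equal(df1, df2)
        assert (tmp_path / "a.csv").read_text() == (tmp_path / "b.csv").read_text()

    def test_missing_directory(self):
        with pytest.raises(OSError):
            run_batch("no/such/dir", None)
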