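"""Phantom generation, NIfTI/bval/bvec round-trips, volume fitting and ROI
statistics."""

import numpy as np
import pytest

from ivimkit import (
    DWISeries,
    FitOptions,
    NoiseSpec,
    collapse_directions,
    fit_volume,
    generate_phantom,
    ivim_signal,
    read_dwi,
    roi_stats,
    write_dwi,
)
from ivimkit.volume import MISSING


class TestGeneratePhantom:
    def test_zero_noise_matches_truth_exactly(self, kidney):
        series, truth = generate_phantom(
            kidney, shape=(4, 4, 2), noise=NoiseSpec("gaussian", 1e18, seed=3),
        )
        from ivimkit import IVIMParams

        idx = (1, 1, 1)
        p = IVIMParams(**{k: truth.maps[k][idx] for k in ("f", "D", "Dstar", "S0")})
        assert np.allclose(series.data[idx], ivim_signal(p, series.bvalues), atol=1e-9)

    def test_same_seed_bit_identical(self, kidney):
        a, _ = generate_phantom(kidney, shape=(5, 5, 2), noise=NoiseSpec("rician", 40, seed=8))
        b, _ = generate_phantom(kidney, shape=(5, 5, 2), noise=NoiseSpec("rician", 40, seed=8))
        assert np.array_equal(a.data, b.data)

    def test_truth_defined_wherever_labelled(self, kidney):
        series, truth = generate_phantom(kidney, shape=(6, 6, 3),
                                         noise=NoiseSpec("rician", 50, seed=1))
        inside = truth.labels > 0
        for name in ("f", "D", "Dstar", "S0"):
            assert (truth.maps[name][inside] > 0).all()


class TestDWIRoundTrip:
    def test_write_read_preserves_everything(self, kidney, tmp_path):
        series, _ = generate_phantom(kidney, shape=(4, 3, 2),
                                     noise=NoiseSpec("rician", 50, seed=2),
                                     n_directions=3)
        paths = write_dwi(series, tmp_path / "phantom")
        back = read_dwi(paths["nii"], mask_path=paths["mask"])
        assert np.allclose(back.data, series.data, rtol=1e-6)  # float32 storage
        assert np.array_equal(back.bvalues, series.bvalues)
        assert np.allclose(back.directions, series.directions, atol=1e-6)
        assert np.array_equal(back.mask, series.mask)

    def test_bval_line_matches_fsl_dialect(self, kidney, tmp_path):
        series, _ = generate_phantom(kidney, shape=(2, 2, 1),
                                     noise=NoiseSpec("gaussian", 50, seed=0))
        paths = write_dwi(series, tmp_path / "k")
        assert paths["bval"].read_text().strip() == "0 30 70 100 200 800"
        assert len(paths["bvec"].read_text().strip().splitlines()) == 3

    def test_length_mismatch_names_both_counts(self, kidney, tmp_path):
        series, _ = generate_phantom(kidney, shape=(2, 2, 1),
                                     noise=NoiseSpec("gaussian", 50, seed=0))
        paths = write_dwi(series, tmp_path / "k")
        paths["bval"].write_text("0 30 70 100 200\n")
        with pytest.raises(ValueError, match="5.*6|6.*5"):
            read_dwi(paths["nii"])

    def test_series_invariants_enforced(self):
        with pytest.raises(ValueError, match="b-table length"):
            DWISeries(data=np.ones((2, 2, 1, 4)), bvalues=[0, 200, 800])
        with pytest.raises(ValueError, match="excluded"):
            DWISeries(data=np.ones((2, 2, 1, 3)), bvalues=[0, 200, 800], excluded=[5])


class TestCollapseAndFitVolume:
    def test_trace_is_geometric_mean_of_directions(self):
        data = np.zeros((1, 1, 1, 4))
        data[0, 0, 0] = [1.0, 0.5, 0.6, 0.7]
        dirs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        series = DWISeries(data=data, bvalues=[0, 200, 200, 200], directions=dirs)
        out, b = collapse_directions(series)
        assert list(b) == [0, 200]
        assert out[0, 0, 0, 1] == pytest.approx((0.5 * 0.6 * 0.7) ** (1 / 3))

    def test_excluded_volume_dropped_with_warning_when_b_disappears(self):
        data = np.ones((1, 1, 1, 4))
        series = DWISeries(data=data, bvalues=[0, 100, 200, 800], excluded=[1])
        with pytest.warns(UserWarning, match="100"):
            _, b = collapse_directions(series)
        assert list(b) == [0, 200, 800]

    def test_two_voxel_noiseless_recovery(self, kidney):
        from ivimkit import IVIMParams

        b = np.array(kidney.minimal_b, float)
        p1 = IVIMParams(f=0.1, D=1.2e-3, Dstar=30e-3, S0=100.0)
        p2 = IVIMParams(f=0.25, D=1.8e-3, Dstar=60e-3, S0=100.0)
        data = np.zeros((2, 1, 1, b.size))
        data[0, 0, 0] = ivim_signal(p1, b)
        data[1, 0, 0] = ivim_signal(p2, b)
        maps = fit_volume(DWISeries(data=data, bvalues=b), preset=kidney)
        assert maps["D"][0, 0, 0] == pytest.approx(p1.D, rel=1e-3)
        assert maps["D"][1, 0, 0] == pytest.approx(p2.D, rel=1e-3)
        assert maps["f"][0, 0, 0] == pytest.approx(p1.f, rel=1e-2)
        assert maps["Dstar"][1, 0, 0] == pytest.approx(p2.Dstar, rel=0.05)

    def test_masked_voxels_carry_missing_code(self, kidney):
        from ivimkit import IVIMParams

        b = np.array(kidney.minimal_b, float)
        p = IVIMParams(f=0.15, D=1.5e-3, Dstar=50e-3, S0=1.0)
        data = np.tile(ivim_signal(p, b), (2, 1, 1, 1))
        mask = np.array([[[True]], [[False]]])
        maps = fit_volume(DWISeries(data=data, bvalues=b, mask=mask), preset=kidney)
        assert maps["f"][1, 0, 0] == MISSING
        assert maps["flags"][1, 0, 0] == 1
        assert maps["flags"][0, 0, 0] == 0

    def test_unfittable_design_fails_with_brange_message(self, kidney):
        data = np.ones((1, 1, 1, 3))
        series = DWISeries(data=data, bvalues=[0, 50, 100])
        with pytest.raises(ValueError, match="segmented"):
            fit_volume(series, preset=kidney)


class TestROIStats:
    def test_constant_map(self):
        labels = np.ones((2, 2, 1), int)
        df = roi_stats({"D": np.full((2, 2, 1), 3.0)}, labels)
        row = df.loc[(1, "D")]
        assert row["mean"] == row["median"] == 3.0
        assert row["sd"] == row["iqr"] == 0.0

    def test_quartiles_linear_interpolation(self):
        labels = np.ones((4, 1, 1), int)
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        row = roi_stats({"x": vals}, labels).loc[(1, "x")]
        assert row["median"] == 2.5
        assert row["iqr"] == pytest.approx(np.percentile([1, 2, 3, 4], 75) -
                                           np.percentile([1, 2, 3, 4], 25))

    def test_statistics_invariant_to_voxel_order(self, rng):
        labels = np.ones((3, 3, 3), int)
        vals = rng.normal(size=(3, 3, 3))
        a = roi_stats({"x": vals}, labels)
        perm = rng.permutation(27)
        b = roi_stats({"x": vals.ravel()[perm].reshape(3, 3, 3)}, labels)
        for col in ("mean", "sd", "median", "iqr"):
            assert a.loc[(1, "x"), col] == pytest.approx(b.loc[(1, "x"), col])

    def test_empty_label_omitted_with_warning(self):
        labels = np.array([[[1, 2]]])
        maps = {"x": np.array([[[1.0, 2.0]]])}
        valid = np.array([[[True, False]]])
        with pytest.warns(UserWarning, match="ROI 2"):
            df = roi_stats(maps, labels, valid=valid)
        assert (2, "x") not in df.index

    def test_phantom_roi_mean_consistent_with_truth(self, kidney):
        series, truth = generate_phantom(kidney, shape=(8, 8, 4),
                                         noise=NoiseSpec("rician", 80, seed=4))
        maps = fit_volume(series, preset=kidney)
        df = roi_stats({"D": maps["D"]}, truth.labels, valid=maps["flags"] == 0)
        inside = truth.labels > 0
        se = truth.maps["D"][inside].std() / np.sqrt(inside.sum())
        assert abs(df.loc[(1, "D"), "mean"] - truth.maps["D"][inside].mean()) < 3 * se + 5e-5
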