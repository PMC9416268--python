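"""Hypercube data model, normalization, band extraction, binning and I/O."""

import numpy as np
import pytest

from hsical.cube import HyperCube, ReflectanceCube, bin_spatial, extract_band, normalize
from hsical.errors import CubeFormatError, CubeSizeError, WavelengthRangeError
from hsical.io import read_cube, write_cube


def _cube(values, wavelength=None, **meta):
    return HyperCube(np.asarray(values, float), wavelength, dict(meta))


class TestHyperCubeValidation:
    def test_rejects_non_3d(self):
        with pytest.raises(ValueError, match="3-D"):
            HyperCube(np.zeros((4, 4)))

    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError, match="non-negative"):
            HyperCube(np.full((2, 2, 2), -1.0))
        bad = np.ones((2, 2, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            HyperCube(bad)

    def test_wavelength_axis_must_match_and_increase(self):
        with pytest.raises(ValueError, match="does not match"):
            HyperCube(np.ones((1, 1, 3)), wavelength_nm=[500.0, 501.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            HyperCube(np.ones((1, 1, 3)), wavelength_nm=[500.0, 500.0, 501.0])


class TestNormalize:
    @pytest.mark.parametrize(
        "sample_of, expected",
        [
            ("white", 1.0),   # S equals the white mean -> R = 1
            ("dark", 0.0),    # S equals the dark mean -> R = 0
            ("mid", 0.5),     # S at the midpoint -> R = 0.5
        ],
    )
    def test_reference_identities(self, sample_of, expected):
        white = _cube(np.full((5, 4, 3), 200.0))
        dark = _cube(np.full((5, 4, 3), 40.0))
        values = {"white": 200.0, "dark": 40.0, "mid": 120.0}[sample_of]
        refl = normalize(_cube(np.full((2, 4, 3), values)), white, dark)
        np.testing.assert_allclose(refl.values, expected, atol=1e-14)
        assert not refl.mask.any()

    def test_nonpositive_denominator_flagged_not_nan(self):
        white = _cube(np.full((1, 2, 2), 100.0))
        white.values[0, 0, 0] = 10.0
        dark = _cube(np.full((1, 2, 2), 10.0))  # denominator 0 at one pixel
        refl = normalize(_cube(np.full((3, 2, 2), 55.0)), white, dark)
        assert np.isfinite(refl.values).all()
        assert refl.mask[:, 0, 0].all()
        assert not refl.mask[:, 1, :].any()

    def test_clipping_recorded_in_mask(self):
        white = _cube(np.full((1, 2, 2), 100.0))
        refl = normalize(_cube(np.full((1, 2, 2), 400.0)), white)
        assert refl.values.max() == pytest.approx(1.5)
        assert refl.mask.all()

    def test_binning_commutes_with_normalize_on_uniform_references(self):
        # with white/dark constant along the slit, averaging groups of slit
        # pixels before or after the per-pixel ratio is algebraically equal
        rng = np.random.default_rng(0)
        raw = _cube(rng.uniform(50, 150, size=(3, 8, 5)))
        white = _cube(np.full((2, 8, 5), 180.0))
        dark = _cube(np.full((2, 8, 5), 20.0))
        a = bin_spatial_refl(normalize(raw, white, dark), 2)
        b = normalize(bin_spatial(raw, 2), bin_spatial(white, 2), bin_spatial(dark, 2))
        np.testing.assert_allclose(a, b.values, rtol=1e-12)


def bin_spatial_refl(refl: ReflectanceCube, factor: int) -> np.ndarray:
    v = refl.values
    return v.reshape(v.shape[0], v.shape[1] // factor, factor, v.shape[2]).mean(axis=2)


class TestExtractBand:
    axis = [499.8, 500.1, 500.4]

    def test_nearest_band(self):
        cube = _cube(np.arange(3.0).reshape(1, 1, 3), self.axis)
        assert extract_band(cube, 500.0)[0, 0] == 1.0

    def test_tie_breaks_to_lower_index(self):
        cube = _cube(np.arange(2.0).reshape(1, 1, 2), [500.0, 501.0])
        assert extract_band(cube, 500.5)[0, 0] == 0.0

    def test_out_of_range_raises(self):
        axis = np.linspace(400, 1000, 50)
        cube = _cube(np.ones((1, 1, 50)), axis)
        with pytest.raises(WavelengthRangeError):
            extract_band(cube, 350.0)


class TestBinSpatial:
    def test_factor_one_is_identity(self):
        cube = _cube(np.random.default_rng(1).uniform(size=(2, 4, 3)))
        np.testing.assert_array_equal(bin_spatial(cube, 1).values, cube.values)

    def test_averages_groups(self):
        values = np.zeros((1, 4, 1))
        values[0, :, 0] = [1, 3, 5, 7]
        binned = bin_spatial(_cube(values), 2)
        np.testing.assert_allclose(binned.values[0, :, 0], [2.0, 6.0])
        assert binned.meta["binning"] == 2

    def test_remainder_rows_dropped_with_warning(self, caplog):
        cube = _cube(np.ones((1, 5, 2)))
        with caplog.at_level("WARNING"):
            binned = bin_spatial(cube, 2)
        assert binned.n_slit == 2
        assert any("dropping" in r.message for r in caplog.records)

    def test_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            bin_spatial(_cube(np.ones((1, 4, 2))), 0)


class TestEnviIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(2)
        cube = _cube(
            rng.uniform(0, 4000, size=(3, 5, 7)),
            np.linspace(400.123456789, 900.987654321, 7),
            exposure_ms=20.0, binning=2,
        )
        path = tmp_path / "cube.raw"
        write_cube(cube, path)
        back = read_cube(path)
        np.testing.assert_array_equal(back.values, cube.values)
        np.testing.assert_array_equal(back.wavelength_nm, cube.wavelength_nm)
        assert back.meta["binning"] == 2

    def test_extent_mismatch_raises_size_error(self, tmp_path):
        cube = _cube(np.ones((2, 3, 4)))
        path = tmp_path / "cube.raw"
        write_cube(cube, path)
        hdr = path.with_suffix(".raw.hdr")
        hdr.write_text(hdr.read_text().replace("bands = 4", "bands = 5"))
        with pytest.raises(CubeSizeError, match="payload"):
            read_cube(path)

    def test_malformed_header_names_key(self, tmp_path):
        cube = _cube(np.ones((2, 3, 4)))
        path = tmp_path / "cube.raw"
        write_cube(cube, path)
        hdr = path.with_suffix(".raw.hdr")
        hdr.write_text(hdr.read_text().replace("samples = 3", "samples = three"))
        with pytest.raises(CubeFormatError, match="samples"):
            read_cube(path)

    def test_missing_wavelength_axis_omitted(self, tmp_path):
        path = tmp_path / "cube.raw"
        write_cube(_cube(np.ones((2, 2, 2))), path)
        assert "wavelength" not in path.with_suffix(".raw.hdr").read_text()
        assert read_cube(path).wavelength_nm is None

    def test_bil_payload_order(self, tmp_path):
        # hand-built 2x2x2 cube: BIL runs line -> band -> sample
        values = np.arange(8.0).reshape(2, 2, 2)  # (scan, slit, spectral)
        path = tmp_path / "cube.raw"
        write_cube(_cube(values), path)
        raw = np.fromfile(path, dtype="<f8")
        # line 0: band 0 samples (0, 2), band 1 samples (1, 3); then line 1
        np.testing.assert_array_equal(raw, [0, 2, 1, 3, 4, 6, 5, 7])


class TestHdf5IO:
    def test_round_trip(self, tmp_path):
        cube = _cube(
            np.random.default_rng(3).uniform(size=(2, 3, 4)),
            [500.0, 501.0, 502.0, 503.0],
            exposure_ms=10.0,
        )
        path = tmp_path / "cube.h5"
        write_cube(cube, path, dialect="hdf5")
        back = read_cube(path, dialect="hdf5")
        np.testing.assert_array_equal(back.values, cube.values)
        np.testing.assert_array_equal(back.wavelength_nm, cube.wavelength_nm)
        assert back.meta["exposure_ms"] == 10.0

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            write_cube(_cube(np.ones((1, 1, 1))), tmp_path / "x", dialect="npz")
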