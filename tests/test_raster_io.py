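import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omfwls.raster_io import (BinaryMask, MultispectralCube, RAW_ROLES,
                              SpectralLibrary, flatten, read_cube, read_mask,
                              read_spectral_library, unflatten, write_cube,
                              write_mask, write_spectral_library)


class TestCube:
    def test_roles_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band roles"):
            MultispectralCube(np.zeros((4, 2, 2)), ("a", "b", "c", "d", "e"))

    def test_nonfinite_outside_nodata_rejected(self):
        data = np.zeros((2, 3, 3))
        data[0, 1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            MultispectralCube(data, ("a", "b"))
        # same NaN under the nodata mask is fine
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        MultispectralCube(data, ("a", "b"), mask)

    def test_band_lookup_by_role(self, small_cube):
        assert np.array_equal(small_cube.band("red"), small_cube.data[2])
        with pytest.raises(KeyError):
            small_cube.band("swir")


class TestFlatten:
    def test_row_major_index(self):
        """Pixel (r, c) lands at flat column r*WIDTH + c."""
        cube = MultispectralCube(np.arange(6, dtype=float).reshape(1, 2, 3), ("a",))
        X, shape = flatten(cube)
        assert shape == (2, 3)
        assert X[0, 1 * 3 + 2] == cube.data[0, 1, 2]

    def test_single_pixel(self):
        cube = MultispectralCube(np.ones((2, 1, 1)), ("a", "b"))
        X, shape = flatten(cube)
        assert X.shape == (2, 1) and shape == (1, 1)

    @settings(deadline=None, max_examples=25)
    @given(rows=st.integers(1, 7), cols=st.integers(1, 7), bands=st.integers(1, 5))
    def test_roundtrip_any_shape(self, rows, cols, bands):
        data = np.random.default_rng(rows * 100 + cols * 10 + bands).normal(
            size=(bands, rows, cols)
        )
        cube = MultispectralCube(data, tuple(f"b{i}" for i in range(bands)))
        X, shape = flatten(cube)
        assert np.array_equal(unflatten(X, shape), cube.data)

    def test_score_vector_roundtrip(self):
        v = np.arange(12.0)
        assert unflatten(v, (3, 4)).shape == (3, 4)
        assert unflatten(v, (3, 4))[2, 3] == v[11]


class TestTiffRoundtrip:
    def test_float32_bit_exact(self, small_cube, tmp_path):
        p = tmp_path / "cube.tif"
        write_cube(small_cube, p)
        back = read_cube(p)
        assert back.band_roles == small_cube.band_roles
        assert np.array_equal(back.data, small_cube.data.astype(np.float32))

    def test_nodata_pixels_roundtrip(self, small_cube, tmp_path):
        mask = np.zeros(small_cube.shape, bool)
        mask[0, 0] = mask[2, 3] = mask[5, 4] = True
        cube = MultispectralCube(small_cube.data, RAW_ROLES, mask)
        p = tmp_path / "nodata.tif"
        write_cube(cube, p)
        back = read_cube(p)
        assert back.nodata_mask.sum() == 3
        assert np.array_equal(back.nodata_mask, mask)

    def test_role_override_and_mismatch(self, small_cube, tmp_path):
        p = tmp_path / "cube.tif"
        write_cube(small_cube, p)
        renamed = read_cube(p, band_roles=("b1", "b2", "b3", "b4"))
        assert renamed.band_roles == ("b1", "b2", "b3", "b4")
        with pytest.raises(ValueError, match="band roles"):
            read_cube(p, band_roles=("a", "b", "c", "d", "e"))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_cube(tmp_path / "nope.tif")


class TestEnvi:
    def test_bsq_roundtrip(self, small_cube, tmp_path):
        p = tmp_path / "cube.dat"
        write_cube(small_cube, p)
        back = read_cube(p)
        assert back.band_roles == small_cube.band_roles
        assert np.allclose(back.data, small_cube.data, atol=1e-6)

    def test_nodata_roundtrip(self, small_cube, tmp_path):
        mask = np.zeros(small_cube.shape, bool)
        mask[1, 1] = True
        cube = MultispectralCube(small_cube.data, RAW_ROLES, mask)
        p = tmp_path / "cube.dat"
        write_cube(cube, p)
        assert np.array_equal(read_cube(p).nodata_mask, mask)


class TestSpectralLibrary:
    def test_read_ten_targets(self, tmp_path):
        p = tmp_path / "lib.csv"
        lines = ["name,role,blue,green,red,nir"]
        lines += [f"t{i},target,0.04,0.06,0.04,{0.4 + i / 100}" for i in range(10)]
        lines += ["water,background,0.06,0.05,0.03,0.01"]
        p.write_text("\n".join(lines))
        lib = read_spectral_library(p)
        assert lib.spectra("target").shape == (10, 4)
        assert lib.spectra("background").shape == (1, 4)
        assert lib.band_roles == RAW_ROLES

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("name,role,blue,green,red,nir\n")
        with pytest.raises(ValueError):
            read_spectral_library(p)

    def test_unknown_role_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,role,blue,green,red,nir\nx,mystery,1,2,3,4\n")
        with pytest.raises(ValueError, match="role"):
            read_spectral_library(p)

    def test_background_only_library_constructible(self):
        lib = SpectralLibrary([("w", np.ones(4), "background")], RAW_ROLES)
        assert lib.background_matrix.shape == (4, 1)
        with pytest.raises(ValueError, match="target"):
            lib.target_mean

    def test_write_read_roundtrip(self, tmp_path, clean_scene):
        _, _, lib = clean_scene
        p = tmp_path / "lib.csv"
        write_spectral_library(lib, p)
        back = read_spectral_library(p)
        assert np.allclose(back.target_mean, lib.target_mean)
        assert np.allclose(back.background_matrix, lib.background_matrix)


class TestMaskIO:
    @pytest.mark.parametrize("pattern", ["zeros", "checkerboard"])
    def test_roundtrip(self, pattern, tmp_path):
        if pattern == "zeros":
            data = np.zeros((4, 4), bool)
        else:
            data = np.indices((4, 4)).sum(axis=0) % 2 == 0
        p = tmp_path / "mask.tif"
        write_mask(BinaryMask(data), p)
        assert np.array_equal(read_mask(p).data, data)

    def test_geo_meta_preserved(self, tmp_path):
        geo = {"crs": "EPSG:4326", "transform": [0.1, 0, 20.0, 0, -0.1, 45.0]}
        p = tmp_path / "mask.tif"
        write_mask(BinaryMask(np.ones((2, 2), bool), geo), p)
        assert read_mask(p).geo_meta == geo
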