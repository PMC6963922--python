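import numpy as np
import pytest

from hsifruit.cube import (
    Hypercube,
    ReferenceFrames,
    WavelengthAxis,
    correct_reflectance,
    read_cube,
    read_envi,
    write_cube,
    write_envi,
)
from hsifruit.errors import DegenerateReferenceError, FormatError, WavelengthRangeError


@pytest.fixture
def small_axis():
    return WavelengthAxis(np.linspace(874.0, 1734.0, 256))


def _cube(data, axis, kind="raw"):
    return Hypercube(data=data, axis=axis, kind=kind)


class TestWavelengthAxis:
    def test_default_axis_spans_instrument_range(self):
        axis = WavelengthAxis.default()
        assert len(axis) == 256
        assert axis.values[0] == 874.0
        assert axis.values[-1] == 1734.0

    def test_must_be_strictly_ascending(self):
        with pytest.raises(ValueError):
            WavelengthAxis(np.array([1000.0, 999.0, 1100.0]))

    def test_nearest_exact_hit(self, small_axis):
        idx = small_axis.nearest(small_axis.values[100])
        assert idx == 100

    def test_nearest_out_of_range(self, small_axis):
        with pytest.raises(WavelengthRangeError):
            small_axis.nearest(500.0)


class TestCorrection:
    def test_raw_equals_white_gives_ones(self, small_axis):
        shape = (4, 5, 256)
        dark = np.full((4, 256), 100.0)
        white = np.full((4, 256), 900.0)
        raw = _cube(np.broadcast_to(white[:, None, :], shape).copy(), small_axis)
        out = correct_reflectance(raw, ReferenceFrames(dark, white))
        assert out.kind == "reflectance"
        np.testing.assert_allclose(out.data, 1.0)

    def test_raw_equals_dark_gives_zeros(self, small_axis):
        shape = (4, 5, 256)
        dark = np.full((4, 256), 100.0)
        white = np.full((4, 256), 900.0)
        raw = _cube(np.broadcast_to(dark[:, None, :], shape).copy(), small_axis)
        out = correct_reflectance(raw, ReferenceFrames(dark, white))
        np.testing.assert_allclose(out.data, 0.0)

    def test_midpoint(self, small_axis):
        dark = np.full((4, 256), 100.0)
        white = np.full((4, 256), 900.0)
        raw = _cube(np.full((4, 5, 256), 500.0), small_axis)
        out = correct_reflectance(raw, ReferenceFrames(dark, white))
        np.testing.assert_allclose(out.data, 0.5)

    def test_affine_invariance_under_common_scaling(self, small_axis):
        rng = np.random.default_rng(3)
        dark = rng.uniform(90, 110, size=(4, 256))
        white = rng.uniform(800, 900, size=(4, 256))
        raw_data = rng.uniform(200, 700, size=(4, 5, 256))
        base = correct_reflectance(_cube(raw_data, small_axis), ReferenceFrames(dark, white))
        scaled = correct_reflectance(
            _cube(3.7 * raw_data, small_axis), ReferenceFrames(3.7 * dark, 3.7 * white)
        )
        np.testing.assert_allclose(scaled.data, base.data, rtol=1e-12)

    def test_identity_references_are_idempotent(self, small_axis):
        rng = np.random.default_rng(4)
        refl = rng.uniform(0, 1, size=(4, 5, 256))
        out = correct_reflectance(
            _cube(refl.copy(), small_axis),
            ReferenceFrames(np.zeros((4, 256)), np.ones((4, 256))),
        )
        np.testing.assert_allclose(out.data, refl, rtol=1e-12)

    def test_degenerate_reference_reports_element(self, small_axis):
        dark = np.full((4, 256), 100.0)
        white = np.full((4, 256), 900.0)
        white[2, 17] = 100.0
        raw = _cube(np.full((4, 5, 256), 500.0), small_axis)
        with pytest.raises(DegenerateReferenceError, match="17"):
            correct_reflectance(raw, ReferenceFrames(dark, white))

    def test_full_frame_references_accepted(self, small_axis):
        rng = np.random.default_rng(5)
        shape = (4, 5, 256)
        dark = np.full(shape, 100.0)
        white = np.full(shape, 900.0)
        raw = _cube(rng.uniform(150, 850, size=shape), small_axis)
        out = correct_reflectance(raw, ReferenceFrames(dark, white))
        np.testing.assert_allclose(out.data, (raw.data - 100.0) / 800.0)

    def test_rejects_reflectance_input(self, small_axis):
        cube = _cube(np.zeros((2, 2, 256)), small_axis, kind="reflectance")
        with pytest.raises(ValueError):
            correct_reflectance(cube, ReferenceFrames(np.zeros((2, 256)), np.ones((2, 256))))


class TestIO:
    def test_hdf5_round_trip_bit_exact(self, tmp_path, small_axis):
        rng = np.random.default_rng(6)
        cube = _cube(rng.uniform(0, 1000, size=(8, 10, 256)), small_axis)
        refs = ReferenceFrames(
            rng.uniform(90, 110, (8, 256)), rng.uniform(800, 900, (8, 256))
        )
        write_cube(cube, tmp_path / "c.h5", refs=refs)
        back, back_refs = read_cube(tmp_path / "c.h5")
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.axis.values, small_axis.values)
        assert back.kind == "raw"
        np.testing.assert_array_equal(back_refs.dark, refs.dark)
        np.testing.assert_array_equal(back_refs.white, refs.white)

    def test_band_axis_mismatch_is_format_error(self, small_axis):
        with pytest.raises(FormatError, match="255"):
            Hypercube(
                data=np.zeros((2, 2, 255)),
                axis=small_axis,
                kind="raw",
            )

    def test_envi_round_trip(self, tmp_path, small_axis):
        rng = np.random.default_rng(7)
        cube = _cube(rng.uniform(0, 1000, size=(6, 9, 256)), small_axis)
        write_envi(cube, tmp_path / "scene")
        back = read_envi(tmp_path / "scene")
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.axis.values, small_axis.values, atol=1e-6)

    def test_envi_header_wavelength_count_mismatch(self, tmp_path, small_axis):
        rng = np.random.default_rng(8)
        cube = _cube(rng.uniform(0, 1, size=(4, 4, 256)), small_axis)
        hdr, _ = write_envi(cube, tmp_path / "scene")
        text = hdr.read_text()
        # drop one wavelength from the list, keep the band count
        lines = text.splitlines()
        drop = next(i for i, ln in enumerate(lines) if ln.strip().endswith(",") and "." in ln)
        hdr.write_text("\n".join(lines[:drop] + lines[drop + 1 :]))
        with pytest.raises(FormatError):
            read_envi(tmp_path / "scene")

    def test_envi_matches_hdf5_copy(self, tmp_path, noiseless_scene):
        raw, dark, white, truth, cfg = noiseless_scene
        write_cube(raw, tmp_path / "scene.h5")
        write_envi(raw, tmp_path / "scene")
        via_h5, _ = read_cube(tmp_path / "scene.h5")
        via_envi = read_envi(tmp_path / "scene")
        np.testing.assert_array_equal(via_h5.data, via_envi.data)
        np.testing.assert_allclose(via_h5.axis.values, via_envi.axis.values, atol=1e-6)
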