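import numpy as np
import pytest

from hsifruit import selection as sel
from hsifruit.cube import WavelengthAxis
from hsifruit.errors import ParameterError, WavelengthRangeError
from hsifruit.preprocess import SpectrumTable


@pytest.fixture
def retained_axis():
    # the 200-band retained window
    return WavelengthAxis(np.linspace(874.0, 1734.0, 256)[30:230])


def _gaussian_features(axis, centers, depths, width=9.0):
    lam = axis.values
    curve = np.full(lam.size, 0.5)
    for c, d in zip(centers, depths):
        curve -= d * np.exp(-0.5 * ((lam - c) / width) ** 2)
    return curve


class TestSecondDerivative:
    def test_linear_spectrum_has_zero_derivative(self, retained_axis):
        lam = np.arange(200, dtype=float)
        spectra = np.vstack([2.0 + 3.0 * lam, 1.0 - 0.5 * lam])
        out = sel.second_derivative(spectra, retained_axis)
        np.testing.assert_allclose(out.curves, 0.0, atol=1e-8)

    def test_quadratic_in_band_index_gives_constant_two(self, retained_axis):
        lam = np.arange(200, dtype=float)
        out = sel.second_derivative(lam[None, :] ** 2, retained_axis)
        np.testing.assert_allclose(out.curves, 2.0, atol=1e-8)

    def test_sine_matches_analytic_second_derivative(self, retained_axis):
        x = np.arange(200, dtype=float)
        freq = 2.0 * np.pi / 60.0
        spectrum = np.sin(freq * x)[None, :]
        out = sel.second_derivative(spectrum, retained_axis, window=13, polyorder=4)
        analytic = -(freq**2) * np.sin(freq * x)
        interior = slice(10, -10)
        err = np.abs(out.curves[0, interior] - analytic[interior])
        assert err.max() < 0.02 * np.abs(analytic).max()

    def test_invalid_window_raises(self, retained_axis):
        with pytest.raises(ParameterError):
            sel.second_derivative(np.zeros((2, 200)), retained_axis, window=12)
        with pytest.raises(ParameterError):
            sel.second_derivative(np.zeros((2, 200)), retained_axis, window=5, polyorder=7)


class TestSelectEffective:
    def test_identical_class_curves_give_empty_selection(self, retained_axis):
        curve = _gaussian_features(retained_axis, [1100.0, 1300.0], [0.1, 0.1])
        deriv = sel.second_derivative(np.tile(curve, (3, 1)), retained_axis)
        ew = sel.select_effective(deriv)
        assert len(ew) == 0

    def test_planted_features_recovered_within_one_band(self, retained_axis):
        centers = [1020.0, 1150.0, 1280.0, 1420.0, 1560.0]
        base = [0.08, 0.08, 0.08, 0.08, 0.08]
        rows = []
        for cls in range(3):
            depths = [d * (1.0 + 0.4 * (cls - 1)) for d in base]
            rows.append(_gaussian_features(retained_axis, centers, depths))
        deriv = sel.second_derivative(np.vstack(rows), retained_axis)
        ew = sel.select_effective(deriv, n_max=5, min_separation_nm=20.0)
        assert len(ew) == 5
        for c in centers:
            nearest = np.abs(retained_axis.values[ew.band_indices] - c).min()
            assert nearest <= retained_axis.spacing  # within +/- 1 band

    def test_n_max_3_keeps_largest_spread_centers(self, retained_axis):
        centers = [1020.0, 1150.0, 1280.0, 1420.0, 1560.0]
        spreads = [0.02, 0.05, 0.01, 0.04, 0.03]
        rows = []
        for cls in range(3):
            depths = [0.08 + s * (cls - 1) for s in spreads]
            rows.append(_gaussian_features(retained_axis, centers, depths))
        deriv = sel.second_derivative(np.vstack(rows), retained_axis)
        ew = sel.select_effective(deriv, n_max=3, min_separation_nm=20.0)
        # brute-force oracle: per planted center, the between-class spread of
        # the derivative curves at the nearest band; top-3 centers must win
        curves = deriv.curves
        center_idx = [int(np.argmin(np.abs(retained_axis.values - c))) for c in centers]
        spread_at = curves.max(axis=0) - curves.min(axis=0)
        window_spread = [
            spread_at[max(0, i - 2) : i + 3].max() for i in center_idx
        ]
        expected = {centers[i] for i in np.argsort(window_spread)[-3:]}
        got = set()
        for w in ew.wavelengths_nm:
            got.add(min(centers, key=lambda c: abs(c - w)))
        assert got == expected

    def test_selection_scale_invariant(self, retained_axis):
        rng = np.random.default_rng(0)
        curves = rng.random((3, 200))
        deriv = sel.SecondDerivativeSet(curves, retained_axis, 13, 2)
        scaled = sel.SecondDerivativeSet(4.2 * curves, retained_axis, 13, 2)
        a = sel.select_effective(deriv)
        b = sel.select_effective(scaled)
        np.testing.assert_array_equal(a.band_indices, b.band_indices)

    def test_selection_permutation_invariant_in_classes(self, retained_axis):
        rng = np.random.default_rng(1)
        curves = rng.random((3, 200))
        a = sel.select_effective(sel.SecondDerivativeSet(curves, retained_axis, 13, 2))
        b = sel.select_effective(sel.SecondDerivativeSet(curves[::-1], retained_axis, 13, 2))
        np.testing.assert_array_equal(a.band_indices, b.band_indices)

    def test_min_separation_respected(self, retained_axis):
        rng = np.random.default_rng(2)
        curves = rng.random((3, 200))
        ew = sel.select_effective(
            sel.SecondDerivativeSet(curves, retained_axis, 13, 2), min_separation_nm=25.0
        )
        lam = ew.wavelengths_nm
        if len(lam) > 1:
            assert np.diff(lam).min() >= 25.0


class TestSubsetTable:
    def _table(self, retained_axis):
        rng = np.random.default_rng(3)
        n = 9
        return SpectrumTable(
            matrix=rng.random((n, 200)),
            axis=retained_axis,
            labels=np.arange(n) % 3,
            sample_ids=[f"s{i}" for i in range(n)],
        )

    def test_22_of_200_columns(self, retained_axis):
        table = self._table(retained_axis)
        idx = np.linspace(0, 199, 22).astype(int)
        ew = sel.EffectiveWavelengths(
            wavelengths_nm=retained_axis.values[idx],
            band_indices=idx,
            scores=np.ones(22),
        )
        sub = sel.subset_table(table, ew)
        assert sub.matrix.shape == (9, 22)
        np.testing.assert_array_equal(sub.labels, table.labels)
        assert sub.sample_ids == table.sample_ids

    def test_select_all_is_identity(self, retained_axis):
        table = self._table(retained_axis)
        idx = np.arange(200)
        ew = sel.EffectiveWavelengths(retained_axis.values[idx], idx, np.ones(200))
        sub = sel.subset_table(table, ew)
        np.testing.assert_array_equal(sub.matrix, table.matrix)

    def test_out_of_range_index_raises(self, retained_axis):
        table = self._table(retained_axis)
        ew = sel.EffectiveWavelengths(np.array([1000.0]), np.array([500]), np.array([1.0]))
        with pytest.raises(WavelengthRangeError):
            sel.subset_table(table, ew)

    def test_fixed_wavelength_mode(self, retained_axis):
        listed = [995.0, 1136.0, 1244.0, 1433.0, 1632.0]
        ew = sel.fixed_wavelengths(retained_axis, listed)
        assert len(ew) == 5
        for want, got in zip(listed, ew.wavelengths_nm):
            assert abs(want - got) <= retained_axis.spacing / 2.0 + 1e-9

    def test_json_round_trip(self, tmp_path, retained_axis):
        idx = np.array([3, 50, 120])
        ew = sel.EffectiveWavelengths(retained_axis.values[idx], idx, np.array([1.0, 2.0, 3.0]))
        ew.to_json(tmp_path / "ew.json")
        back = sel.EffectiveWavelengths.from_json(tmp_path / "ew.json")
        np.testing.assert_array_equal(back.band_indices, ew.band_indices)
        np.testing.assert_allclose(back.wavelengths_nm, ew.wavelengths_nm)
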