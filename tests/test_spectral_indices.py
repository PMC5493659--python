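"""The 1,540-index catalog: band statistics, derivatives, characteristic
features and assembly."""

import numpy as np
import pytest

from hyperphen.cube_io import SpectralCube, default_wavelengths
from hyperphen.segmentation import PlantMask
from hyperphen.spectral_indices import (
    CHARACTERISTIC_NAMES,
    IndexCatalogSpec,
    assemble_index_vector,
    band_stats,
    catalog_spec,
    characteristic_indices,
    combine_views,
    derivative_spectrum,
    feature_names,
    index_table,
)

from conftest import make_flat_cube

WL = default_wavelengths()


def random_cube(rng, bands=250, rows=8, cols=8):
    return SpectralCube(rng.uniform(0.05, 0.9, (bands, rows, cols)),
                        default_wavelengths(bands))


class TestBandStats:
    def test_uniform_cube(self):
        cube = make_flat_cube(0.5, shape=(250, 5, 5), wavelengths=WL)
        mask = np.zeros((5, 5), dtype=bool)
        mask.ravel()[:10] = True
        T, A = band_stats(cube, mask)
        np.testing.assert_allclose(T, 5.0)
        np.testing.assert_allclose(A, 0.5)

    def test_single_pixel_T_equals_A(self, rng):
        cube = random_cube(rng)
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 4] = True
        T, A = band_stats(cube, mask)
        np.testing.assert_array_equal(T, A)

    def test_matches_per_pixel_loop(self, rng):
        cube = random_cube(rng, bands=12)
        mask = rng.random((8, 8)) < 0.4
        T, A = band_stats(cube, mask)
        for b in range(12):
            total = 0.0
            for i in range(8):
                for j in range(8):
                    if mask[i, j]:
                        total += cube.reflectance[b, i, j]
            assert T[b] == pytest.approx(total)
            assert A[b] == pytest.approx(total / mask.sum())

    def test_conservation_A_times_S_is_T(self, rng):
        for _ in range(5):
            cube = random_cube(rng, bands=30)
            mask = rng.random((8, 8)) < 0.5
            if not mask.any():
                continue
            T, A = band_stats(cube, mask)
            np.testing.assert_allclose(A * mask.sum(), T, rtol=1e-12)

    def test_empty_mask_raises(self, rng):
        cube = random_cube(rng, bands=5)
        with pytest.raises(ValueError, match="S = 0"):
            band_stats(cube, np.zeros((8, 8), dtype=bool))


class TestDerivativeSpectrum:
    def test_linear_spectrum(self):
        c = 0.0031
        d1, d2 = derivative_spectrum(0.2 + c * (WL - 400), WL)
        np.testing.assert_allclose(d1, c, rtol=1e-10)
        np.testing.assert_allclose(d2[1:-1], 0.0, atol=1e-15)

    def test_constant_spectrum(self):
        d1, d2 = derivative_spectrum(np.full(250, 0.7), WL)
        assert np.all(d1 == 0) and np.all(d2 == 0)

    def test_cubic_matches_analytic_interior(self):
        u = (WL - 700.0) / 100.0
        values = u**3
        d1, d2 = derivative_spectrum(values, WL)
        analytic1 = 3 * u**2 / 100.0
        analytic2 = 6 * u / 100.0**2
        h = 600 / 249
        # central differences are exact up to the O(h^2) truncation term
        np.testing.assert_allclose(d1[1:-1], analytic1[1:-1],
                                   atol=6 / 100**3 * h**2)
        np.testing.assert_allclose(d2[2:-2], analytic2[2:-2], atol=1e-6)

    def test_linearity(self, rng):
        x = rng.normal(size=250)
        y = rng.normal(size=250)
        a, b = 2.5, -1.3
        d1_mix, _ = derivative_spectrum(a * x + b * y, WL)
        d1_x, _ = derivative_spectrum(x, WL)
        d1_y, _ = derivative_spectrum(y, WL)
        np.testing.assert_allclose(d1_mix, a * d1_x + b * d1_y, rtol=1e-10)

    def test_non_monotone_wavelengths_raise(self):
        wl = WL.copy()
        wl[5] = wl[7]
        with pytest.raises(ValueError, match="increasing"):
            derivative_spectrum(np.ones(250), wl)


def _red_edge_area_oracle(spectrum, wl):
    """Independent loop: central differences then trapezoid over 680-760."""
    n = len(wl)
    d1 = np.empty(n)
    d1[0] = (spectrum[1] - spectrum[0]) / (wl[1] - wl[0])
    d1[-1] = (spectrum[-1] - spectrum[-2]) / (wl[-1] - wl[-2])
    for i in range(1, n - 1):
        h1, h2 = wl[i] - wl[i - 1], wl[i + 1] - wl[i]
        d1[i] = (
            spectrum[i + 1] * h1**2
            + (h2**2 - h1**2) * spectrum[i]
            - spectrum[i - 1] * h2**2
        ) / (h1 * h2 * (h1 + h2))
    idx = [i for i in range(n) if 680 <= wl[i] <= 760]
    area = 0.0
    for a, b in zip(idx[:-1], idx[1:]):
        area += 0.5 * (d1[a] + d1[b]) * (wl[b] - wl[a])
    return area


class TestCharacteristicIndices:
    def test_sigmoid_red_edge_position(self):
        spectrum = 0.05 + 0.5 / (1 + np.exp(-(WL - 710.0) / 9.0))
        cp = characteristic_indices(spectrum, WL)
        slot = CHARACTERISTIC_NAMES.index("red_edge_position")
        # dense-grid argmax of the logistic derivative sits at the inflection
        dense = np.linspace(680, 760, 20001)
        truth = dense[np.argmax(np.gradient(
            0.05 + 0.5 / (1 + np.exp(-(dense - 710.0) / 9.0)), dense))]
        assert abs(cp[slot] - truth) <= 600 / 249  # within one band

    def test_flat_spectrum_zero_edges(self):
        cp = dict(zip(CHARACTERISTIC_NAMES,
                      characteristic_indices(np.full(250, 0.4), WL)))
        for name in ("blue_edge_amplitude", "yellow_edge_amplitude",
                     "red_edge_amplitude", "blue_edge_area",
                     "yellow_edge_area", "red_edge_area",
                     "red_valley_depth"):
            assert cp[name] == pytest.approx(0.0, abs=1e-14)

    def test_scaling_doubles_areas_keeps_positions(self, rng):
        spectrum = 0.1 + 0.4 / (1 + np.exp(-(WL - 705) / 11)) \
            + 0.05 * np.exp(-((WL - 550) ** 2) / 800)
        c1 = dict(zip(CHARACTERISTIC_NAMES, characteristic_indices(spectrum, WL)))
        c2 = dict(zip(CHARACTERISTIC_NAMES,
                      characteristic_indices(2 * spectrum, WL)))
        for name in CHARACTERISTIC_NAMES:
            if name.startswith(("ratio_", "nd_")):
                # pure ratios are scale-invariant
                assert c2[name] == pytest.approx(c1[name], rel=1e-12)
            elif name.endswith(("_area", "_amplitude", "_height", "_depth",
                                "_mean")):
                assert c2[name] == pytest.approx(2 * c1[name], rel=1e-12)
            elif name.endswith("_position"):
                assert c2[name] == c1[name]

    def test_red_edge_area_matches_trapezoid_oracle(self, rng):
        slot = CHARACTERISTIC_NAMES.index("red_edge_area")
        for _ in range(10):
            coeffs = rng.normal(0, 0.05, 6)
            u = (WL - 700) / 300
            spectrum = 0.4 + sum(c * u**k for k, c in enumerate(coeffs))
            cp = characteristic_indices(spectrum, WL)
            assert cp[slot] == pytest.approx(
                _red_edge_area_oracle(spectrum, WL), abs=1e-10
            )

    def test_window_outside_range_raises(self):
        wl = np.linspace(500, 900, 64)
        with pytest.raises(ValueError, match="window"):
            characteristic_indices(np.ones(64), wl)


class TestCatalogAssembly:
    def test_catalog_counts(self):
        spec = catalog_spec()
        assert spec.total == 1540
        assert spec.family_sizes == {
            "T": 250, "A": 250, "dT": 250, "dA": 250, "ddT": 250, "ddA": 250,
            "CPT": 20, "CPA": 20,
        }
        names = feature_names()
        assert len(names) == 1540
        assert len(set(names)) == 1540

    def test_assembled_vector_has_catalog_plus_area(self, small_sim,
                                                    small_cube):
        iv = assemble_index_vector(small_cube, small_sim.truth_mask)
        assert len(iv) == 1540
        assert len(iv.with_area()) == 1541
        assert iv.with_area()["S"] == small_sim.truth_mask.sum()
        # conservation inside the assembled vector
        s = iv.s_pixels
        for i in (1, 106, 250):
            assert iv.values[f"A_{i}"] * s == pytest.approx(
                iv.values[f"T_{i}"], rel=1e-10
            )

    def test_combine_views_averages(self, small_sim, small_cube):
        iv = assemble_index_vector(small_cube, small_sim.truth_mask)
        doubled = assemble_index_vector(
            SpectralCube(small_cube.reflectance * 2, small_cube.wavelengths),
            small_sim.truth_mask,
        )
        merged = combine_views(iv, doubled)
        assert merged.values["T_100"] == pytest.approx(
            (iv.values["T_100"] + doubled.values["T_100"]) / 2
        )
        assert merged.s_pixels == iv.s_pixels

    def test_index_table_shape(self, small_sim, small_cube):
        iv = assemble_index_vector(small_cube, small_sim.truth_mask)
        df = index_table([iv, iv])
        assert df.shape == (2, 1540 + 3)  # + accession, stage, S
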