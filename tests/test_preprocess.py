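"""Vectorization, normalization, averaging, background removal, peak/SNR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sweatsers as sw
from tests.conftest import GRID200


def _spec(values, grid=None):
    grid = grid or sw.WavenumberGrid(0.0, float(len(values) - 1), len(values))
    return sw.Spectrum(grid, np.asarray(values, dtype=float))


class TestVectorize:
    def test_identity_on_grid_samples(self):
        grid = GRID200
        y = np.sin(grid.axis / 100.0) + 2.0
        out = sw.vectorize(np.column_stack([grid.axis, y]), grid)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-12)

    def test_default_grid_length_is_1321(self):
        wn = np.linspace(450, 1680, 3000)
        out = sw.vectorize(np.column_stack([wn, np.ones_like(wn)]))
        assert out.intensities.shape == (1321,)

    @given(k=st.floats(-5, 5))
    def test_constant_trace_interpolates_to_constant(self, k):
        wn = np.linspace(450, 1680, 500)
        out = sw.vectorize(np.column_stack([wn, np.full_like(wn, k)]), GRID200)
        np.testing.assert_allclose(out.intensities, k, atol=1e-12)

    def test_insufficient_coverage_fails(self):
        wn = np.linspace(500, 1600, 100)
        with pytest.raises(ValueError, match="does not cover"):
            sw.vectorize(np.column_stack([wn, np.ones_like(wn)]), GRID200)

    def test_unsorted_input_fails(self):
        raw = np.array([[500.0, 1.0], [450.0, 2.0], [1700.0, 1.0]])
        with pytest.raises(ValueError, match="sorted"):
            sw.vectorize(raw, GRID200)


class TestMinMaxNormalize:
    def test_affine_example(self):
        out = sw.minmax_normalize(_spec([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.intensities, [0.0, 0.5, 1.0])

    @given(
        values=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=50
        ).filter(lambda v: max(v) > min(v))
    )
    def test_output_range_is_exactly_unit(self, values):
        out = sw.minmax_normalize(_spec(values))
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        first = sw.minmax_normalize(_spec(rng.uniform(3, 9, 64)))
        second = sw.minmax_normalize(first)
        np.testing.assert_allclose(second.intensities, first.intensities)

    def test_constant_spectrum_fails(self):
        with pytest.raises(ValueError, match="constant"):
            sw.minmax_normalize(_spec([1.0, 1.0, 1.0]))

    def test_normalize_set_matches_per_spectrum(self, desk_dataset):
        normed = sw.normalize_set(desk_dataset)
        assert normed.normalized
        for i in (0, 5, desk_dataset.n_spectra - 1):
            expect = sw.minmax_normalize(desk_dataset.spectrum(i))
            np.testing.assert_allclose(normed.spectra[i], expect.intensities)

    def test_normalize_set_is_idempotent_flagged(self, desk_dataset):
        normed = sw.normalize_set(desk_dataset)
        assert sw.normalize_set(normed) is normed


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        s = _spec([1.0, 2.0, 3.0])
        out = sw.average_replicates([s] * 6)
        np.testing.assert_allclose(out.intensities, s.intensities)

    def test_mean_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        grid = sw.WavenumberGrid(0, 9, 10)
        spectra = [sw.Spectrum(grid, rng.uniform(0, 1, 10)) for _ in range(7)]
        out = sw.average_replicates(spectra)
        oracle = [
            sum(s.intensities[j] for s in spectra) / 7 for j in range(10)
        ]
        np.testing.assert_allclose(out.intensities, oracle)

    def test_variance_reduction_for_iid_noise(self):
        rng = np.random.default_rng(2)
        grid = sw.WavenumberGrid(0, 199, 200)
        sigma, n = 0.5, 6
        means = []
        for _ in range(300):
            reps = [
                sw.Spectrum(grid, rng.normal(0, sigma, 200)) for _ in range(n)
            ]
            means.append(sw.average_replicates(reps).intensities)
        var = np.var(np.stack(means))
        assert var == pytest.approx(sigma**2 / n, rel=0.1)

    def test_empty_list_fails(self):
        with pytest.raises(ValueError, match="no spectra"):
            sw.average_replicates([])


class TestSubtractBackground:
    def test_exact_background_gives_zero(self):
        s = _spec([1.0, 2.0, 3.0])
        out = sw.subtract_background(s, s, scale=1.0)
        np.testing.assert_allclose(out.intensities, 0.0)

    def test_zero_background_is_identity(self):
        s = _spec([1.0, 2.0, 3.0])
        zero = s.with_intensities(np.zeros(3))
        out = sw.subtract_background(s, zero, scale=1.0)
        np.testing.assert_allclose(out.intensities, s.intensities)

    def test_recovers_admixture_scale(self, library):
        """Spectrum + 0.7 x background; fit over background-only bands."""
        grid = GRID200
        analyte = sw.clean_spectrum(library, {"uric_acid": 20.0}, grid)
        bg = sw.clean_spectrum(library, {"background": 1.0}, grid)
        mixed = analyte.with_intensities(
            analyte.intensities + 0.7 * bg.intensities
        )
        # windows over broad background bands far from the 635 region
        out = sw.subtract_background(
            mixed, bg, fit_windows=[(1080.0, 1160.0), (1430.0, 1470.0)]
        )
        residual = out.intensities - analyte.intensities
        assert np.abs(residual).max() < 0.05 * bg.intensities.max()


class TestPeakIntensity:
    def test_flat_spectrum_is_zero(self):
        s = sw.Spectrum(GRID200, np.full(200, 3.0))
        assert sw.peak_intensity(s, 859.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("offset", [0.0, 0.5, 10.0])
    def test_unit_lorentzian_on_flat_baseline(self, offset):
        """Wide window recovers ~unit height regardless of the baseline."""
        grid = sw.WavenumberGrid(457, 1674, 1321)
        peak = sw.spectral_sim.PeakDef(859.0, 12.0, 1.0)
        s = sw.Spectrum(grid, peak.lineshape(grid.axis) + offset)
        got = sw.peak_intensity(s, 859.0, half_window=60.0)
        assert got == pytest.approx(1.0, abs=0.02)

    def test_proportional_to_concentration(self, library):
        grid = GRID200
        vals = []
        for c in (5.0, 10.0, 20.0, 40.0):
            s = sw.clean_spectrum(library, {"uric_acid": c}, grid)
            vals.append(sw.peak_intensity(s, 635.0))
        ratios = np.diff(np.log(vals))
        np.testing.assert_allclose(
            ratios, np.diff(np.log([5, 10, 20, 40])), rtol=1e-6
        )

    def test_window_outside_grid_fails(self):
        s = sw.Spectrum(GRID200, np.ones(200))
        with pytest.raises(ValueError, match="outside"):
            sw.peak_intensity(s, 460.0, half_window=15.0)


class TestSNR:
    def test_simple_ratio(self):
        rng = np.random.default_rng(3)
        grid = sw.WavenumberGrid(0, 99, 100)
        # two noise spectra engineered to pooled sd 2
        base = rng.normal(0, 1, 200)
        base = (base - base.mean()) / base.std(ddof=1) * 2.0
        noise = [sw.Spectrum(grid, base[:100]), sw.Spectrum(grid, base[100:])]
        sd = np.concatenate([n.intensities for n in noise]).std(ddof=1)
        assert sw.snr(10.0, noise) == pytest.approx(10.0 / sd)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        grid = sw.WavenumberGrid(0, 49, 50)
        noise = [sw.Spectrum(grid, rng.normal(0, 1, 50)) for _ in range(3)]
        doubled = [s.with_intensities(2 * s.intensities) for s in noise]
        assert sw.snr(10.0, noise) == pytest.approx(sw.snr(20.0, doubled))

    def test_gaussian_monte_carlo(self):
        """Pooled sd of N(0, sigma) noise -> SNR ~ peak/sigma."""
        rng = np.random.default_rng(5)
        grid = sw.WavenumberGrid(0, 999, 1000)
        sigma = 0.25
        noise = [
            sw.Spectrum(grid, rng.normal(0, sigma, 1000)) for _ in range(5)
        ]
        assert sw.snr(5.0, noise) == pytest.approx(5.0 / sigma, rel=0.05)

    def test_too_few_noise_spectra_fail(self):
        s = sw.Spectrum(GRID200, np.ones(200))
        with pytest.raises(ValueError, match="at least 2"):
            sw.snr(1.0, [s])

    def test_zero_variance_fails(self):
        grid = sw.WavenumberGrid(0, 9, 10)
        flat = [sw.Spectrum(grid, np.ones(10))] * 3
        with pytest.raises(ValueError, match="zero variance"):
            sw.snr(1.0, flat)
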