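"""Stoichiometry, expression levels, and the constrained log-normal mixture."""

import numpy as np
import pytest
from hypothesis import given, strategies as st_
from scipy.integrate import quad

from snb import compute_nb_maps, nb
from snb import stoichiometry as st
from snb.simulate import SimulationConfig, SpeciesSpec, simulate_frame_counts
from .conftest import make_stack


def histogram_from_values(values, bin_width=0.004):
    lo = np.floor(values.min() / bin_width) * bin_width
    edges = np.arange(lo, values.max() + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return st.BrightnessHistogram(bin_edges=edges, counts=counts.astype(float),
                                  n_pixels=len(values))


def histogram_from_density(density, x_max=1.0, bin_width=0.002):
    """Noise-free histogram sampled from a density curve on (0, x_max]."""
    edges = np.arange(0.0, x_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return st.BrightnessHistogram(bin_edges=edges, counts=density(centers),
                                  n_pixels=100000)


class TestSubunitsPerComplex:
    def test_worked_example(self, calibration):
        assert round(st.subunits_per_complex(0.0798, calibration), 2) == 1.66

    def test_monomer_identity(self, calibration):
        assert st.subunits_per_complex(calibration.epsilon0, calibration) == pytest.approx(1.0)

    def test_dimer_multiple(self, calibration):
        assert st.subunits_per_complex(0.096, calibration) == pytest.approx(2.0)


class TestExpressionLevel:
    def test_uniform_map_at_eps0(self, calibration):
        mean_map = np.full((10, 10), 0.048)
        assert st.expression_level(mean_map, np.ones((10, 10), bool), calibration) \
            == pytest.approx(1.0)

    def test_median_scaling(self, calibration):
        mean_map = np.full((10, 10), 4.8)
        assert st.expression_level(mean_map, np.ones((10, 10), bool), calibration) \
            == pytest.approx(100.0)

    def test_empty_mask_raises(self, calibration):
        with pytest.raises(ValueError):
            st.expression_level(np.ones((4, 4)), np.zeros((4, 4), bool), calibration)

    def test_doubling_density_doubles_expression_not_stoichiometry(self, calibration):
        results = {}
        for nbar in (25.0, 50.0):
            maps = compute_nb_maps(make_stack(subunits=2, nbar=nbar, seed=21))
            expr = st.expression_level(maps.mean_map, maps.valid_mask, calibration)
            results[nbar] = (expr, nb.roi_brightness(maps))
        assert results[50.0][0] / results[25.0][0] == pytest.approx(2.0, rel=0.05)
        assert results[50.0][1] == pytest.approx(results[25.0][1], abs=0.01)


class TestExpressionRegimes:
    @pytest.mark.parametrize("expr, regime", [
        (50.0, "low"),
        (300.0, "physiological"),
        (90.0, "physiological"),   # closed-left window edge
        (600.0, "high"),           # open-right window edge
        (2000.0, "high"),
    ])
    def test_regime_boundaries(self, expr, regime):
        assert st.classify_expression_regime(expr) == regime

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            st.classify_expression_regime(-1.0)


class TestROIHistogram:
    def test_delta_map_occupies_single_bin(self):
        bmap = np.full((20, 20), 0.1)
        hist = st.roi_brightness_histogram(bmap, np.ones((20, 20), bool))
        assert (hist.counts > 0).sum() == 1
        assert hist.n_pixels == 400

    def test_histogram_mean_matches_sample_mean(self, rng):
        vals = rng.normal(0.1, 0.02, size=(40, 40))
        hist = st.roi_brightness_histogram(vals, np.ones((40, 40), bool))
        hmean = np.sum(hist.bin_centers * hist.counts) / hist.counts.sum()
        assert hmean == pytest.approx(vals.mean(), abs=hist.bin_width)

    def test_too_few_pixels_raises(self):
        with pytest.raises(ValueError, match="valid pixels"):
            st.roi_brightness_histogram(np.ones((5, 5)), np.ones((5, 5), bool))


class TestGaussianPeak:
    def test_exact_gaussian_recovered(self):
        hist = histogram_from_density(
            lambda x: 100 * np.exp(-((x - 0.096) ** 2) / (2 * 0.02**2)), x_max=0.3
        )
        fit = st.fit_gaussian_peak(hist)
        assert fit.peak_brightness == pytest.approx(0.096, abs=hist.bin_width / 2)
        assert fit.converged

    def test_peak_tracks_dominant_mode_of_skewed_mixture(self):
        def density(x):
            return 100 * np.exp(-((x - 0.10) ** 2) / (2 * 0.02**2)) + \
                   30 * np.exp(-((x - 0.25) ** 2) / (2 * 0.05**2))
        hist = histogram_from_density(density, x_max=0.5)
        fit = st.fit_gaussian_peak(hist)
        # oracle: dense-grid argmax of the generating curve
        grid = np.linspace(0.0, 0.5, 20001)
        mode = grid[np.argmax(density(grid))]
        assert fit.peak_brightness == pytest.approx(mode, abs=0.02)

    def test_simulated_monomer_peak_near_eps0(self, calibration):
        maps = compute_nb_maps(make_stack(subunits=1, nbar=20.0, seed=31))
        smoothed = nb.smooth_brightness(maps.brightness_map, 3)
        hist = st.roi_brightness_histogram(smoothed, maps.valid_mask)
        fit = st.fit_gaussian_peak(hist, calibration=calibration)
        eps_vals = smoothed[np.isfinite(smoothed)]
        se = 3 * eps_vals.std() / np.sqrt(eps_vals.size / 9)  # 3x3 smoothing correlates pixels
        assert fit.peak_brightness == pytest.approx(0.048, abs=3 * se + 0.005)
        assert fit.subunits_per_complex == pytest.approx(1.0, abs=0.25)


class TestLogNormalComponent:
    def test_area_matches_quadrature(self):
        comp = st.LogNormalComponent(mode=0.096, shape=0.4, area=2.5, role="dimer")
        numeric, _ = quad(lambda x: comp.density(np.array([x]))[0], 1e-9, 10.0, limit=200)
        assert numeric == pytest.approx(2.5, abs=1e-6)

    def test_mode_is_argmax(self):
        comp = st.LogNormalComponent(mode=0.2, shape=0.6, area=1.0, role="larger")
        x = np.linspace(1e-4, 2.0, 200001)
        assert x[np.argmax(comp.density(x))] == pytest.approx(0.2, abs=1e-3)

    def test_amplitude_is_peak_height(self):
        comp = st.LogNormalComponent(mode=0.1, shape=0.3, area=1.7, role="tetramer")
        assert comp.density(np.array([0.1]))[0] == pytest.approx(comp.amplitude)


class TestMonomerReference:
    def test_recovers_known_mode_from_samples(self, rng):
        shape = 0.25
        mode = 0.048
        mu = np.log(mode) + shape**2
        samples = rng.lognormal(mu, shape, size=200000)
        hist = histogram_from_values(samples, bin_width=0.002)
        comp = st.fit_monomer_reference(hist)
        assert comp.mode == pytest.approx(mode, rel=0.02)
        assert comp.role == "monomer"

    def test_narrow_histogram_mode_near_mean(self, rng):
        samples = rng.normal(0.05, 0.002, size=100000)
        hist = histogram_from_values(samples[samples > 0], bin_width=0.0005)
        comp = st.fit_monomer_reference(hist)
        assert comp.mode == pytest.approx(0.05, rel=0.02)


def simulate_cell_brightness(subunits, nbar, seed, calibration,
                             frames=8192, size=32):
    maps = compute_nb_maps(make_stack(subunits=subunits, nbar=nbar,
                                      frames=frames, size=size, seed=seed))
    vals = maps.brightness_map[maps.valid_mask]
    expr = st.expression_level(maps.mean_map, maps.valid_mask, calibration)
    return st.CellBrightness(roi_id=f"s{subunits}-{seed}", expression=expr,
                             values=vals[np.isfinite(vals)])


@pytest.fixture()
def monomer_anchor():
    return st.LogNormalComponent(mode=0.048, shape=0.3, area=1.0, role="monomer")


class TestMixture:

    def test_anchored_modes_are_exact_multiples(self, monomer_anchor):
        hist = histogram_from_density(
            lambda x: st._lognormal_density(x, 0.7, 0.096, 0.2)
            + st._lognormal_density(x, 0.3, 0.192, 0.15),
            x_max=0.8,
        )
        fit = st.fit_lognormal_mixture(hist, monomer_anchor)
        by_role = {c.role: c for c in fit.components}
        assert by_role["dimer"].mode == 2 * monomer_anchor.mode
        assert by_role["tetramer"].mode == 4 * monomer_anchor.mode
        assert by_role["dimer"].mode_fixed and by_role["tetramer"].mode_fixed
        assert not by_role["larger"].mode_fixed

    def test_self_consistency_refit(self, monomer_anchor):
        """Refitting a histogram built from the model recovers the fractions."""
        truth = {"dimer": 0.55, "tetramer": 0.35, "larger": 0.10}
        hist = histogram_from_density(
            lambda x: st._lognormal_density(x, truth["dimer"], 0.096, 0.25)
            + st._lognormal_density(x, truth["tetramer"], 0.192, 0.18)
            + st._lognormal_density(x, truth["larger"], 0.40, 0.12),
            x_max=1.0,
        )
        fit = st.fit_lognormal_mixture(hist, monomer_anchor)
        for role, frac in truth.items():
            assert fit.fractions[role] == pytest.approx(frac, abs=0.02)

    def test_pure_dimer_cohort(self, calibration, monomer_anchor):
        cells = [simulate_cell_brightness(2, 60.0, 50 + i, calibration) for i in range(2)]
        hist = st.accumulate_histograms(cells)
        fit = st.fit_lognormal_mixture(hist, monomer_anchor)
        assert fit.fractions["dimer"] == pytest.approx(1.0, abs=0.05)
        assert fit.fractions["tetramer"] <= 0.05
        assert fit.fractions["larger"] <= 0.05

    def test_fraction_normalization(self, monomer_anchor):
        hist = histogram_from_density(
            lambda x: st._lognormal_density(x, 1.0, 0.096, 0.3), x_max=0.8
        )
        fit = st.fit_lognormal_mixture(hist, monomer_anchor)
        assert sum(fit.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_area_fit_raises(self):
        fit = st.MixtureFit(components=[
            st.LogNormalComponent(mode=0.1, shape=0.2, area=0.0, role="dimer")
        ], fractions={}, expression_window=(90, 600), n_cells=0, goodness=0.0)
        with pytest.raises(ValueError):
            st.species_fractions(fit)


class TestStoichiometryLinearity:
    @pytest.mark.parametrize("subunits", [1, 2, 4, 8])
    def test_pure_species_recovery(self, subunits, calibration):
        """Pooled brightness over pure-species stacks recovers s within 10%."""
        nbar = 80.0 / subunits  # fixed fluorophore density
        maps = compute_nb_maps(make_stack(subunits=subunits, nbar=nbar,
                                          frames=400, size=48, seed=60 + subunits))
        estimated = nb.roi_brightness(maps) / calibration.epsilon0
        assert estimated == pytest.approx(subunits, rel=0.10)


class TestAccumulation:
    def _cell(self, values, expression):
        return st.CellBrightness(roi_id="c", expression=expression,
                                 values=np.asarray(values, dtype=float))

    def test_single_cell_equals_own_normalized_histogram(self, rng):
        vals = rng.normal(0.1, 0.02, 5000)
        acc = st.accumulate_histograms([self._cell(vals, 200.0)])
        area = np.sum(acc.counts * np.diff(acc.bin_edges))
        assert area == pytest.approx(1.0)
        own, _ = np.histogram(vals, bins=acc.bin_edges, density=True)
        assert np.allclose(acc.counts, own)

    def test_duplicate_cells_leave_shape_unchanged(self, rng):
        vals = rng.normal(0.1, 0.02, 5000)
        one = st.accumulate_histograms([self._cell(vals, 200.0)])
        two = st.accumulate_histograms([self._cell(vals, 200.0)] * 2)
        assert np.allclose(one.counts, two.counts)

    def test_cells_outside_window_excluded(self, rng):
        inside = self._cell(rng.normal(0.1, 0.01, 3000), 200.0)
        outside = self._cell(rng.normal(0.4, 0.01, 3000), 700.0)
        acc = st.accumulate_histograms([inside, outside])
        assert acc.n_pixels == 3000
        with pytest.raises(ValueError):
            st.accumulate_histograms([outside])


class TestExternalScaling:
    def test_worked_example(self):
        out = st.expression_scale_external([10.0, 20.0], 450.0, 15.0)
        assert np.allclose(out, [300.0, 600.0])

    def test_scaling_by_own_mean_sets_mean(self, rng):
        intensities = rng.gamma(3.0, 2.0, size=500)
        out = st.expression_scale_external(intensities, 450.0, intensities.mean())
        assert out.mean() == pytest.approx(450.0)

    @given(st_.lists(st_.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=50),
           st_.floats(min_value=1.0, max_value=1e4))
    def test_cv_invariance(self, intensities, ref_expr):
        arr = np.asarray(intensities)
        out = st.expression_scale_external(arr, ref_expr, arr.mean())
        if arr.std() > 0:
            assert out.std() / out.mean() == pytest.approx(arr.std() / arr.mean(), rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            st.expression_scale_external([1.0], 100.0, 0.0)
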