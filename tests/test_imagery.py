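"""Vegetation indices, buffer extraction, canopy temperature and WDI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from orchard_phenomics import imagery as im
from orchard_phenomics import synthdata as sd

# 27-July trapezoid vertex temperatures (saturated soil, WW vegetation,
# dry soil, WS vegetation), deg C above air temperature
JULY27_VERTICES = (0.87, -1.34, 21.86, 5.6)


def uniform_stack(values: dict, shape=(4, 4), pixel_size=0.1) -> im.BandStack:
    bands = {nm: np.full(shape, v, dtype=float) for nm, v in values.items()}
    return im.BandStack(
        bands=bands, transform=im.RasterTransform(0.0, 0.0, pixel_size)
    )


FLAT = {450: 0.05, 530: 0.08, 570: 0.10, 675: 0.10, 730: 0.3, 850: 0.50}


class TestThermalCalibration:
    def test_two_point_line_is_exact(self):
        cal = im.calibrate_thermal([100, 200], [20, 40])
        assert cal.slope == pytest.approx(0.2)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.apply(150) == pytest.approx(30.0)

    def test_noisy_targets_recover_slope_within_three_se(self, rng):
        dn = np.linspace(50, 250, 10)
        slope, intercept, sd = 0.21, -3.0, 0.2
        temp = slope * dn + intercept + rng.normal(0, sd, size=10)
        cal = im.calibrate_thermal(dn, temp)
        se = sd / np.sqrt(np.sum((dn - dn.mean()) ** 2))
        assert abs(cal.slope - slope) < 3 * se

    def test_single_or_constant_targets_rejected(self):
        with pytest.raises(ValueError):
            im.calibrate_thermal([100], [20])
        with pytest.raises(ValueError, match="singular"):
            im.calibrate_thermal([100, 100], [20, 40])


class TestIndices:
    def test_ndvi_zero_when_nir_equals_red(self):
        stack = uniform_stack({**FLAT, 850: 0.1, 675: 0.1})
        assert im.compute_indices(stack)["NDVI"] == pytest.approx(0.0)

    def test_ndvi_arithmetic(self):
        stack = uniform_stack({**FLAT, 850: 0.5, 675: 0.1})
        assert im.compute_indices(stack)["NDVI"] == pytest.approx(0.4 / 0.6)

    def test_pri_zero_when_greens_equal(self):
        stack = uniform_stack({**FLAT, 530: 0.09, 570: 0.09})
        assert im.compute_indices(stack)["PRI"] == pytest.approx(0.0)

    def test_missing_band_raises(self):
        bands = {nm: np.zeros((2, 2)) for nm in (450, 530, 570, 675, 730)}
        stack = im.BandStack(bands=bands, transform=im.RasterTransform(0, 0, 0.1))
        with pytest.raises(im.BandMissingError):
            im.compute_indices(stack)

    def test_zero_denominator_flagged_missing(self):
        stack = uniform_stack({**FLAT, 850: 0.0, 675: 0.0})
        assert np.isnan(im.compute_indices(stack)["NDVI"]).all()

    def test_normalized_indices_bounded_on_random_reflectances(self, rng):
        bands = {nm: rng.uniform(0, 1, size=(20, 20)) for nm in im.BANDS_NM}
        stack = im.BandStack(bands=bands, transform=im.RasterTransform(0, 0, 0.1))
        idx = im.compute_indices(stack)
        for name in ("NDVI", "GNDVI", "PRI"):
            v = idx[name][np.isfinite(idx[name])]
            assert np.all(v >= -1) and np.all(v <= 1)


class TestClassificationAndBuffer:
    def test_mask_matches_planted_footprints(self, noiseless_orchard):
        design, stack, thermal, truth = noiseless_orchard
        mask = im.classify_vegetation(stack)
        assert mask.sum() == truth["true_vegetation_pixels"].sum()

    def test_threshold_extremes(self, small_orchard):
        _, stack, _, _ = small_orchard
        assert im.classify_vegetation(stack, threshold=-1.0).all()
        assert not im.classify_vegetation(stack, threshold=+1.0).any()

    def test_zero_trees_all_soil(self):
        design = sd.OrchardDesign(n_rows=0, trees_per_row=0, margin=3.0, seed=2)
        stack, thermal, truth = sd.generate_orchard_images(design)
        assert len(truth) == 0
        assert not im.classify_vegetation(stack).any()

    def test_buffer_pix_num_matches_truth(self, small_orchard):
        design, stack, thermal, truth = small_orchard
        rec = truth.iloc[0]
        pix = im.extract_buffer(stack, thermal, (rec.x, rec.y), radius=0.70)
        assert pix.pix_num == rec.true_vegetation_pixels

    def test_tiny_buffer_captures_at_most_one_pixel(self, small_orchard):
        design, stack, thermal, truth = small_orchard
        rec = truth.iloc[0]
        pix = im.extract_buffer(stack, thermal, (rec.x, rec.y), radius=0.04)
        assert len(pix.t_surf) <= 1

    def test_adjacent_buffers_are_disjoint_at_two_metre_spacing(self, small_orchard):
        # 2 * 0.70 m < 2 m within-row spacing
        design, stack, thermal, truth = small_orchard
        a, b = truth.iloc[0], truth.iloc[1]
        mask = np.zeros(stack.shape, dtype=bool)
        x, y = stack.transform.pixel_centers(stack.shape)
        in_a = (x - a.x) ** 2 + (y - a.y) ** 2 <= 0.49
        in_b = (x - b.x) ** 2 + (y - b.y) ** 2 <= 0.49
        assert not (in_a & in_b).any()

    def test_buffer_outside_extent_warns_and_is_empty(self, small_orchard):
        _, stack, thermal, _ = small_orchard
        with pytest.warns(RuntimeWarning, match="no pixel"):
            pix = im.extract_buffer(stack, thermal, (1e4, 1e4))
        assert pix.pix_num == 0

    def test_pix_num_invariant_under_band_order(self, small_orchard):
        design, stack, thermal, truth = small_orchard
        rec = truth.iloc[2]
        shuffled = im.BandStack(
            bands={nm: stack.bands[nm] for nm in reversed(im.BANDS_NM)},
            transform=stack.transform,
        )
        p1 = im.extract_buffer(stack, thermal, (rec.x, rec.y))
        p2 = im.extract_buffer(shuffled, thermal, (rec.x, rec.y))
        assert p1.pix_num == p2.pix_num


class TestTreeTemperature:
    def _pixels(self, temps, veg=None):
        temps = np.asarray(temps, dtype=float)
        veg = np.ones_like(temps, bool) if veg is None else np.asarray(veg)
        return im.TreePixelSet(
            tree_id="t", center=(0, 0), buffer_radius=0.7,
            reflectance={}, t_surf=temps, vegetation=veg,
        )

    def test_uniform_canopy(self):
        mean, sdev = im.tree_temperature(self._pixels([30.0] * 5), t_air=27.0)
        assert mean == pytest.approx(3.0)
        assert sdev == pytest.approx(0.0)

    def test_two_pixel_sample_sd_convention(self):
        mean, sdev = im.tree_temperature(self._pixels([29.0, 31.0]), t_air=28.0)
        assert mean == pytest.approx(2.0)
        assert sdev == pytest.approx(np.sqrt(2), abs=1e-12)  # sample (n-1) SD

    def test_soil_pixels_excluded(self):
        mean, _ = im.tree_temperature(
            self._pixels([30.0, 50.0], veg=[True, False]), t_air=27.0
        )
        assert mean == pytest.approx(3.0)

    def test_no_vegetation_yields_missing(self):
        mean, sdev = im.tree_temperature(self._pixels([], veg=[]), t_air=27.0)
        assert np.isnan(mean) and np.isnan(sdev)

    def test_recovered_noise_sd_on_synthetic_tree(self, small_orchard):
        design, stack, thermal, truth = small_orchard
        rec = truth.iloc[3]
        pix = im.extract_buffer(stack, thermal, (rec.x, rec.y))
        mean, sdev = im.tree_temperature(pix, design.air_temperature)
        true_dt = rec.true_canopy_temperature - design.air_temperature
        assert mean == pytest.approx(true_dt, abs=3 * design.thermal_noise_sd / np.sqrt(pix.pix_num))
        assert sdev == pytest.approx(design.thermal_noise_sd, rel=0.25)


class TestTrapezoid:
    def test_manual_mode_echoes_vertices(self):
        trap = im.fit_trapezoid([], [], manual_vertices=JULY27_VERTICES)
        assert (trap.t_sat_soil, trap.t_ww_veg, trap.t_dry_soil, trap.t_ws_veg) == JULY27_VERTICES

    def test_planted_trapezoid_recovered_within_half_degree(self, rng):
        true = im.Trapezoid(*JULY27_VERTICES, ndvi_soil=0.05, ndvi_veg=0.80)
        n = 30_000
        ndvi = rng.uniform(0.02, 0.85, n)
        dt = rng.uniform(true.wet_edge(ndvi), true.dry_edge(ndvi))
        fit = im.fit_trapezoid(ndvi, dt)
        assert fit.t_sat_soil == pytest.approx(true.wet_edge(fit.ndvi_soil), abs=0.5)
        assert fit.t_ww_veg == pytest.approx(true.wet_edge(fit.ndvi_veg), abs=0.5)
        assert fit.t_dry_soil == pytest.approx(true.dry_edge(fit.ndvi_soil), abs=0.5)
        assert fit.t_ws_veg == pytest.approx(true.dry_edge(fit.ndvi_veg), abs=0.5)

    def test_single_ndvi_cluster_rejected(self, rng):
        ndvi = np.full(500, 0.5) + rng.normal(0, 1e-9, 500)
        dt = rng.uniform(0, 10, 500)
        with pytest.raises(ValueError):
            im.fit_trapezoid(ndvi, dt)

    def test_too_few_pixels_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            im.fit_trapezoid(rng.uniform(0, 1, 50), rng.uniform(0, 10, 50))

    def test_inverted_vertices_rejected(self):
        with pytest.raises(ValueError):
            im.Trapezoid(t_sat_soil=0.9, t_ww_veg=5.6, t_dry_soil=21.9, t_ws_veg=-1.3)


class TestWDI:
    trap = im.Trapezoid(*JULY27_VERTICES)

    def test_corner_values_bracket_the_range(self):
        assert im.compute_wdi(self.trap.ndvi_veg, -1.34, self.trap) == 0.0
        assert im.compute_wdi(self.trap.ndvi_veg, 5.6, self.trap) == 1.0

    def test_midway_is_half(self):
        for ndvi in (0.0, 0.3, 0.8, 1.0):
            mid = 0.5 * (self.trap.wet_edge(ndvi) + self.trap.dry_edge(ndvi))
            assert im.compute_wdi(ndvi, mid, self.trap) == pytest.approx(0.5)

    def test_monotone_in_dt_and_clipped(self):
        dts = np.linspace(-10, 30, 41)
        wdi = im.compute_wdi(np.full_like(dts, 0.5), dts, self.trap)
        assert np.all(np.diff(wdi) >= 0)
        assert wdi.min() == 0.0 and wdi.max() == 1.0

    def test_invariant_under_common_temperature_shift(self):
        shifted = im.Trapezoid(
            self.trap.t_sat_soil + 4, self.trap.t_ww_veg + 4,
            self.trap.t_dry_soil + 4, self.trap.t_ws_veg + 4,
        )
        assert im.compute_wdi(0.6, 3.0, self.trap) == pytest.approx(
            im.compute_wdi(0.6, 7.0, shifted)
        )

    def test_degenerate_edge_rejected(self):
        # a validly constructed trapezoid cannot degenerate, so exercise the
        # guard with a stub whose edges meet at the query NDVI
        class Collapsed:
            def wet_edge(self, ndvi):
                return 3.0

            def dry_edge(self, ndvi):
                return 3.0

        with pytest.raises(ValueError, match="degenerate"):
            im.compute_wdi(0.5, 4.0, Collapsed())

    @settings(max_examples=80, derandomize=True)
    @given(
        wet_veg=st.floats(-5, 2),
        dry_veg_gap=st.floats(0.5, 20),
        wet_soil_gap=st.floats(0.1, 10),
        dry_soil_gap=st.floats(0.5, 30),
        ndvi=st.floats(0, 1),
        dt_lo=st.floats(-30, 40),
        dt_step=st.floats(0, 30),
    )
    def test_bounds_and_monotonicity_hold_for_any_valid_trapezoid(
        self, wet_veg, dry_veg_gap, wet_soil_gap, dry_soil_gap, ndvi, dt_lo, dt_step
    ):
        trap = im.Trapezoid(
            t_sat_soil=wet_veg + wet_soil_gap,
            t_ww_veg=wet_veg,
            t_dry_soil=wet_veg + wet_soil_gap + dry_soil_gap,
            t_ws_veg=wet_veg + dry_veg_gap,
        )
        lo = im.compute_wdi(ndvi, dt_lo, trap)
        hi = im.compute_wdi(ndvi, dt_lo + dt_step, trap)
        assert 0.0 <= lo <= hi <= 1.0

    def test_tree_wdi_rank_matches_planted_stress(self):
        design = sd.OrchardDesign(
            n_rows=2, trees_per_row=5, band_noise_sd=0.0, thermal_noise_sd=0.0, seed=13
        )
        stack, thermal, truth = sd.generate_orchard_images(design)

        def ndvi_of(refl):
            return (refl[850] - refl[675]) / (refl[850] + refl[675])

        # trapezoid abscissae anchored at the generator's soil/vegetation NDVI
        trap = im.fit_trapezoid([], [], manual_vertices=(
            design.soil_t_offsets[0], design.t_veg_offsets[0],
            design.soil_t_offsets[1], design.t_veg_offsets[1],
            ndvi_of(sd.SOIL_REFLECTANCE), ndvi_of(sd.VEGETATION_REFLECTANCE),
        ))
        wdi = []
        for rec in truth.itertuples():
            # buffer inside the canopy footprint: vegetation pixels only
            pix = im.extract_buffer(stack, thermal, (rec.x, rec.y), radius=0.5)
            s = im.summarize_tree(pix, design.air_temperature, trap)
            wdi.append(s.wdi)
        rho = spearmanr(wdi, truth["stress"]).statistic
        assert rho == pytest.approx(1.0)
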