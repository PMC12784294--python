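import numpy as np
import pytest
from conftest import modified_z_scores, naive_snip, small_spec
from hypothesis import given
from hypothesis import strategies as st

from ramantag.containers import HyperspectralCube, Spectrum
from ramantag.errors import AxisError
from ramantag.phantom import PhantomSpec, lorentzian, make_phantom
from ramantag.preprocess import (
    CalibrationTable,
    PreprocessConfig,
    ResampleGrid,
    SnipSection,
    calibrate,
    despike,
    preprocess_cube,
    resample,
    sectioned_correct,
    snip_baseline,
)


class TestDespike:
    def test_constant_spectrum_unchanged_no_flags(self):
        x = np.full(100, 42.0)
        out, flags = despike(x)
        assert np.array_equal(out, x) and not flags.any()

    def test_single_spike_on_flat_floor_flagged_and_repaired(self):
        x = np.full(200, 100.0)
        x += np.sin(np.arange(200)) * 0.5  # tiny texture so MAD > 0
        x[80] += 1e4
        z = modified_z_scores(x)  # independent brute-force oracle
        assert abs(z[80]) > 37
        out, flags = despike(x, 37.0)
        assert flags[80]
        assert out[80] == pytest.approx(100.0, rel=0.01)

    def test_smooth_lorentzian_band_yields_zero_flags(self):
        axis = np.arange(2150.0, 2301.0, 2.0)  # band sampled over ~+-5 FWHM
        y = 50 + 300 * lorentzian(axis, 2223, 15)
        assert np.max(np.abs(modified_z_scores(y))) < 37  # oracle confirms
        _, flags = despike(y, 37.0)
        assert not flags.any()

    def test_mad_zero_rule_flags_nothing(self):
        x = np.r_[np.full(50, 5.0), 5e6, np.full(50, 5.0)]
        # differences are zero except around the spike -> MAD = 0 -> no flags
        _, flags = despike(x, 37.0)
        assert not flags.any()

    def test_despiking_is_idempotent(self):
        spec = small_spec(spike_rate=2e-4, spike_amplitude=5000, seed=8)
        cube, _ = make_phantom(spec)
        once, flags1 = despike(cube.intensities)
        twice, flags2 = despike(once)
        assert not (flags2 & ~flags1).any()  # a second pass flags nothing new
        assert np.allclose(once, twice)


class TestSnipBaseline:
    def test_flat_spectrum_baseline_equals_input(self):
        y = np.full(300, 7.5)
        assert np.array_equal(snip_baseline(y, 7), y)

    def test_narrow_peak_survives_gentle_correction(self):
        axis = np.arange(1800.0, 2801.0, 2.0)
        y = 10 + lorentzian(axis, 2223, 8)
        residual = y - snip_baseline(y, 7)
        assert residual.max() >= 0.70  # >= 70% of unit peak height

    def test_broad_band_is_removed(self):
        axis = np.arange(1800.0, 2801.0, 2.0)
        y = np.exp(-0.5 * ((axis - 2200) / (400 / 2.355)) ** 2)  # FWHM 400
        residual = y - snip_baseline(y, 7)
        assert residual.max() <= 0.10

    @pytest.mark.parametrize("iterations", [7, 100])
    def test_matches_independent_naive_implementation(self, iterations):
        rng = np.random.default_rng(0)
        axis = np.linspace(550, 3150, 1000)
        y = (
            100
            + 0.02 * axis
            + 80 * lorentzian(axis, 1450, 16)
            + 50 * lorentzian(axis, 2150, 400)
            + rng.normal(0, 1.5, axis.size)
        )
        assert np.allclose(snip_baseline(y, iterations), naive_snip(y, iterations))

    def test_baseline_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        y = rng.normal(50, 10, 400).cumsum() / 10
        for iterations in (1, 7, 100):
            assert np.all(snip_baseline(y, iterations) <= y + 1e-12)

    def test_too_few_samples_error_states_requirement(self):
        with pytest.raises(ValueError, match="100"):
            snip_baseline(np.zeros(150), 100)


class TestSectionedCorrect:
    def test_flat_spectrum_corrects_to_zero_in_covered_range(self):
        axis = np.arange(550.0, 3151.0, 2.0)
        out = sectioned_correct(np.full(axis.size, 33.0), axis)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_merge_is_continuous_across_overlaps(self):
        spec = small_spec(seed=3)
        cube, _ = make_phantom(spec)
        y = cube.intensities[20, 20]
        out = sectioned_correct(y, cube.wavenumbers)
        steps = np.abs(np.diff(out))
        overlap = (cube.wavenumbers[1:] >= 2600) & (cube.wavenumbers[1:] <= 2800)
        # cross-fade: steps inside the overlap are no larger than elsewhere
        assert steps[overlap].max() <= steps.max()

    def test_silent_region_keeps_tag_band_drops_water(self):
        axis = np.arange(550.0, 3151.0, 2.0)
        peak = 80 * lorentzian(axis, 2223, 12)
        water = 50 * lorentzian(axis, 2150, 400)
        out = sectioned_correct(peak + water + 100.0, axis)
        at_2223 = out[np.argmin(np.abs(axis - 2223))]
        at_2500 = out[np.argmin(np.abs(axis - 2500))]  # water + floor only
        assert at_2223 >= 0.6 * 80
        assert abs(at_2500) <= 0.1 * 50

    def test_section_outside_axis_is_an_error(self):
        axis = np.arange(600.0, 3051.0, 2.0)
        with pytest.raises(AxisError, match="outside"):
            sectioned_correct(np.zeros(axis.size), axis,
                              [SnipSection(lo=500, hi=1900, iterations=10)])


class TestCalibrate:
    def test_zero_shift_for_matching_pairs(self):
        axis = np.arange(600.0, 700.0, 2.0)
        table = CalibrationTable(pairs=[(650.0, 650.0), (680.0, 680.0)])
        shifted, shift = calibrate(axis, table)
        assert shift == 0.0 and np.array_equal(shifted, axis)

    def test_mean_of_pair_shifts(self):
        table = CalibrationTable(pairs=[(1000.0, 998.0), (2000.0, 1996.0)])
        _, shift = calibrate(np.arange(600.0, 3000.0), table)
        assert shift == pytest.approx(3.0)

    def test_single_pair(self):
        _, shift = calibrate(np.arange(600.0, 3000.0),
                             CalibrationTable(pairs=[(1000.0, 998.0)]))
        assert shift == pytest.approx(2.0)


class TestResample:
    def test_default_grid_has_1226_channels(self):
        axis = np.arange(550.0, 3151.0, 2.0)
        out, new_axis = resample(np.zeros(axis.size), axis)
        assert new_axis.size == 1226
        assert new_axis[0] == 600.0 and new_axis[-1] == 3050.0

    def test_identity_on_target_grid(self):
        axis = np.arange(600.0, 3051.0, 2.0)
        y = np.sin(axis / 100)
        out, new_axis = resample(y, axis)
        assert np.allclose(out, y)

    def test_linear_ramp_reproduced_exactly(self):
        axis = np.arange(500.0, 3200.0, 3.7)
        y = 2.5 * axis - 7
        out, new_axis = resample(y, axis)
        assert np.allclose(out, 2.5 * new_axis - 7)

    def test_no_extrapolation(self):
        axis = np.arange(700.0, 3000.0, 2.0)
        with pytest.raises(AxisError, match="cover"):
            resample(np.zeros(axis.size), axis)


@given(constant=st.floats(-50, 50))
def test_calibrate_then_resample_commutes_with_constant_offset(constant):
    axis = np.arange(550.0, 3151.0, 2.0)
    y = 10 + 30 * lorentzian(axis, 1450, 20)
    table = CalibrationTable(pairs=[(1002.0, 1000.0)])
    shifted, _ = calibrate(axis, table)
    base, _ = resample(y, shifted)
    offset, _ = resample(y + constant, shifted)
    assert np.allclose(offset, base + constant, atol=1e-9)


class TestPreprocessCube:
    def test_flat_noise_free_cube_maps_to_zero_on_1226_channels(self):
        axis = np.arange(550.0, 3151.0, 2.0)
        cube = HyperspectralCube(axis, np.full((3, 3, axis.size), 250.0))
        out, report = preprocess_cube(cube)
        assert out.intensities.shape == (3, 3, 1226)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)
        assert report.n_spike_flags == 0

    def test_seeded_spikes_are_flagged(self):
        spec = small_spec(spike_rate=5e-4, spike_amplitude=150.0 * 1.5, seed=13)
        cube, truth = make_phantom(spec)
        _, report = preprocess_cube(cube)
        pos = truth.spike_positions
        hit = report.spike_flags[pos[:, 0], pos[:, 1], pos[:, 2]]
        assert hit.mean() >= 0.95

    def test_deterministic(self):
        cube, _ = make_phantom(small_spec(seed=2))
        out1, _ = preprocess_cube(cube)
        out2, _ = preprocess_cube(cube)
        assert np.array_equal(out1.intensities, out2.intensities)

    def test_calibration_shift_propagates(self):
        cube, _ = make_phantom(small_spec(seed=2, noise_sd=0.0))
        config = PreprocessConfig(calibration_pairs=[(1000.0, 999.0)])
        out, report = preprocess_cube(cube, config)
        assert report.calibration_shift == pytest.approx(1.0)
        assert out.wavenumbers[0] == 600.0  # grid unchanged; data shifted
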