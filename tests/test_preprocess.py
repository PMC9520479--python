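"""Preprocessing chain: each stage's contract plus the composed pipeline."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from ramanbiopsy import (
    Band,
    ComponentProfile,
    FluorescenceConfig,
    GeneratorConfig,
    MorletFitConfig,
    SpectralAxis,
    Spectrum,
    SpectrumMeta,
    SpectrumSet,
    average_background,
    crop_range,
    default_axis,
    exclude_saturated,
    fit_morlet_baseline,
    generate_dataset,
    generate_fluorescence,
    morlet_sum,
    normalize_integral,
    preprocess_pipeline,
    remove_baseline,
    savitzky_golay,
    subtract_background,
)
from ramanbiopsy.preprocess import PreprocessError
from ramanbiopsy.synthetic import component_curve, default_components


def spec(y, axis=None, sid="s"):
    axis = axis or default_axis(len(np.atleast_1d(y)))
    return Spectrum(axis, np.asarray(y, float), SpectrumMeta(sid))


class TestBackground:
    def test_mean_of_identical_frames_is_the_frame(self):
        frames = [spec(np.full(50, 3.5), sid=f"f{i}") for i in range(5)]
        avg = average_background(frames)
        np.testing.assert_array_equal(avg.intensities, np.full(50, 3.5))
        assert avg.meta.frame_kind == "background"

    def test_mean_of_two_constants(self):
        avg = average_background([spec(np.zeros(10)), spec(np.full(10, 2.0))])
        np.testing.assert_array_equal(avg.intensities, np.ones(10))

    def test_noisy_frames_average_to_level(self):
        rng = np.random.default_rng(3)
        sd, level, n = 2.0, 100.0, 5
        frames = [spec(level + rng.normal(0, sd, 400)) for _ in range(n)]
        avg = average_background(frames)
        assert np.all(np.abs(avg.intensities - level) < 3 * sd)  # pointwise

    def test_empty_set_raises(self):
        with pytest.raises(PreprocessError):
            average_background([])

    def test_subtraction_identities(self):
        s = spec(np.arange(20, dtype=float))
        assert np.all(subtract_background(s, s).intensities == 0.0)
        z = spec(np.zeros(20))
        np.testing.assert_array_equal(subtract_background(s, z).intensities,
                                      s.intensities)

    def test_subtraction_axis_mismatch(self):
        with pytest.raises(PreprocessError):
            subtract_background(spec(np.zeros(10)), spec(np.zeros(11)))

    def test_negative_residuals_preserved(self):
        s = spec(np.full(10, 1.0))
        bg = spec(np.full(10, 2.0))
        assert np.all(subtract_background(s, bg).intensities == -1.0)


class TestSaturationExclusion:
    def test_below_threshold_kept(self):
        sset = SpectrumSet([spec(np.full(10, 50.0), sid=f"s{i}")
                            for i in range(4)])
        kept, excluded = exclude_saturated(sset, 100.0, 0.90)
        assert len(kept) == 4 and excluded == []

    def test_pinned_spectrum_removed(self):
        good = spec(np.full(10, 50.0), sid="good")
        bad = spec(np.full(10, 100.0), sid="bad")
        kept, excluded = exclude_saturated(SpectrumSet([good, bad]), 100.0, 0.90)
        assert excluded == ["bad"]
        assert [s.meta.spectrum_id for s in kept] == ["good"]

    def test_matches_generator_truth_flags(self, paper_dataset):
        measurements, _, truth = paper_dataset
        _, excluded = exclude_saturated(measurements, 65535.0, 0.90)
        flagged = [s.meta.spectrum_id
                   for s, sat in zip(measurements, truth.saturated) if sat]
        assert sorted(excluded) == sorted(flagged)


class TestSavitzkyGolay:
    def test_reproduces_cubic_exactly(self):
        x = np.linspace(0, 1, 101)
        y = 2.0 - 3.0 * x + 0.5 * x**2 + 4.0 * x**3
        out = savitzky_golay(spec(y), 15, 3).intensities
        np.testing.assert_allclose(out, y, rtol=1e-9)

    def test_constant_preserved(self):
        out = savitzky_golay(spec(np.full(60, 7.0)), 15, 3).intensities
        np.testing.assert_allclose(out, 7.0, rtol=1e-12)

    def test_noise_variance_reduction_matches_weights(self):
        """Interior output variance equals sum of squared SG weights."""
        w = savgol_coeffs(15, 3)
        factor = float(np.sum(w**2))
        rng = np.random.default_rng(9)
        ratios = []
        for _ in range(100):
            y = rng.normal(0, 1, 300)
            out = savitzky_golay(spec(y), 15, 3).intensities
            ratios.append(out[20:-20].var())
        assert np.mean(ratios) == pytest.approx(factor, rel=0.10)

    def test_window_too_large_raises(self):
        with pytest.raises(PreprocessError):
            savitzky_golay(spec(np.zeros(10)), 15, 3)


class TestMorletBaseline:
    def test_recovers_single_morlet_term(self):
        ax = default_axis()
        y = morlet_sum(ax.wavenumbers, [100.0], [1400.0], [400.0], 5.0)
        model = fit_morlet_baseline(spec(y, ax), MorletFitConfig(n_wavelets=1))
        assert model.amplitudes[0] == pytest.approx(100.0, rel=0.01)
        assert model.centers[0] == pytest.approx(1400.0, rel=0.01)
        assert model.scales[0] == pytest.approx(400.0, rel=0.01)
        assert model.fit_loss < 1e-6

    def test_zero_spectrum_gives_zero_model(self):
        model = fit_morlet_baseline(spec(np.zeros(500)))
        assert np.all(model.amplitudes == 0.0)
        assert model.converged

    def test_tracks_true_fluorescence_under_peaks(self):
        """On a noiseless fluorescence+peaks spectrum the fitted continuum
        explains >=99% of the true fluorescence variance and stays below
        the peak tops."""
        ax = default_axis()
        x = ax.wavenumbers
        fl = generate_fluorescence(ax, FluorescenceConfig(),
                                   np.random.default_rng(4))
        peaks = np.zeros_like(x)
        for p in default_components():
            peaks += component_curve(p, x, p.class_mean_amplitude["normal"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_morlet_baseline(spec(fl + peaks, ax))
        b = model.evaluate(x)
        r2 = 1 - np.sum((b - fl)**2) / np.sum((fl - fl.mean())**2)
        assert r2 >= 0.99
        # peak tops remain above the baseline
        for p in default_components():
            if p.class_mean_amplitude["normal"] > 0:
                i = np.argmin(np.abs(x - p.peak_centers[0]))
                assert (fl + peaks)[i] > b[i]

    def test_fitted_baseline_is_smooth(self):
        ax = default_axis()
        x = ax.wavenumbers
        fl = generate_fluorescence(ax, FluorescenceConfig(),
                                   np.random.default_rng(8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_morlet_baseline(spec(fl, ax))
        b = model.evaluate(x)
        dx = float(x[1] - x[0])
        assert np.max(np.abs(np.diff(b, 2))) <= model.curvature_bound(dx)

    def test_removal_identities(self):
        ax = default_axis(300)
        y = np.linspace(10, 20, 300)
        s = spec(y, ax)
        zero_model = fit_morlet_baseline(spec(np.zeros(300), ax))
        np.testing.assert_array_equal(
            remove_baseline(s, zero_model).intensities, y)
        exact = morlet_sum(ax.wavenumbers, [50.0], [1500.0], [600.0], 5.0)
        model = fit_morlet_baseline(spec(exact, ax),
                                    MorletFitConfig(n_wavelets=1))
        resid = remove_baseline(spec(exact, ax), model).intensities
        np.testing.assert_allclose(resid, 0.0, atol=1e-4)


class TestCropAndNormalize:
    def test_crop_full_span_is_identity(self):
        s = spec(np.arange(100, dtype=float))
        out = crop_range(s, s.axis.wavenumbers[0], s.axis.wavenumbers[-1])
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_crop_closed_interval(self):
        axis = SpectralAxis(np.array([899.0, 900.0, 1800.0, 1801.0]))
        out = crop_range(Spectrum(axis, np.arange(4.0), SpectrumMeta("s")),
                         900, 1800)
        np.testing.assert_array_equal(out.axis.wavenumbers, [900.0, 1800.0])

    def test_crop_count_on_even_grid(self):
        """2050 even points on 127-2830 cropped to [900, 1800] keep 683."""
        s = spec(np.ones(2050), default_axis())
        assert len(crop_range(s, 900, 1800).axis) == 683

    def test_normalize_constant_closed_form(self):
        axis = SpectralAxis(np.linspace(900, 1800, 10))
        s = Spectrum(axis, np.full(10, 2.0), SpectrumMeta("s"))
        out = normalize_integral(s)
        np.testing.assert_allclose(out.intensities, 1.0 / 900.0, rtol=1e-12)

    def test_normalize_scale_invariant_and_idempotent(self):
        rng = np.random.default_rng(2)
        s = spec(rng.uniform(1, 5, 200))
        once = normalize_integral(s)
        np.testing.assert_allclose(
            normalize_integral(s.with_intensities(7.0 * s.intensities)).intensities,
            once.intensities, rtol=1e-12)
        np.testing.assert_allclose(normalize_integral(once).intensities,
                                   once.intensities, rtol=1e-12)

    def test_non_positive_integral_raises(self):
        with pytest.raises(PreprocessError, match="non-positive"):
            normalize_integral(spec(np.full(50, -1.0)))


@pytest.fixture(scope="module")
def tiny_dataset():
    cfg = GeneratorConfig(
        axis_n_points=600,
        n_samples={"normal": 2, "edge": 2, "center": 2},
        replicates_per_sample=3,
        seed=5)
    return generate_dataset(cfg)


class TestPipeline:
    def test_deterministic(self, tiny_dataset):
        meas, bgs, _ = tiny_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = preprocess_pipeline(meas, bgs)
            b = preprocess_pipeline(meas, bgs)
        np.testing.assert_array_equal(a.intensity_matrix(), b.intensity_matrix())

    def test_unit_integral_and_axis(self, tiny_dataset):
        meas, bgs, _ = tiny_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = preprocess_pipeline(meas, bgs)
        x = out.axis.wavenumbers
        assert x[0] >= 900.0 and x[-1] <= 1800.0
        for s in out:
            assert np.trapezoid(s.intensities, x) == pytest.approx(1.0, abs=1e-9)

    def test_provenance_records_steps(self, tiny_dataset):
        meas, bgs, _ = tiny_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = preprocess_pipeline(meas, bgs)
        text = " ".join(out.provenance)
        for token in ("saturated", "savitzky_golay", "morlet", "crop", "normalize"):
            assert token in text

    def test_class_band_ordering_preserved(self, paper_processed):
        """Carotenoid band intensity orders normal > edge > center in the
        preprocessed class means, as configured in the generator."""
        x = paper_processed.axis.wavenumbers
        band = Band("carotenoid", 1150, 1165)
        sel = band.mask(x)
        means = {}
        for cls in ("normal", "edge", "center"):
            rows = [s.intensities[sel].sum() for s in paper_processed
                    if s.meta.tissue_class == cls]
            means[cls] = np.mean(rows)
        assert means["normal"] > means["edge"] > means["center"]
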