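"""Synthetic Raman datasets with known ground truth.

The generator emulates intraoperative brain-tissue Raman acquisition: three
tissue classes (normal white matter, tumor edge / infiltration area, tumor
center), a handful of samples per class each measured five times, an intense
smooth fluorescence continuum on top of sharp biochemical peaks, ambient
background frames, detector noise, and occasional saturated replicates.

Class contrasts follow the qualitative biochemistry of glioblastoma:
cholesterol and carotenoid bands decrease from normal tissue through the
infiltration area to the tumor center, hemoglobin (blood filling) and water
(edema / necrosis) increase toward the center, and a couple of cholesterol
shifts are elevated specifically at the edge.  A set of broad bands common
to all classes (phenylalanine, CH2 deformation, amide I/III, phospholipids)
varies strongly from sample to sample without carrying class information;
together with the imperfectly removable fluorescence this provides the dense
nuisance variance against which sparse discriminative bands must be found.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra_io import (
    AXIS_HI,
    AXIS_LO,
    AXIS_N_POINTS,
    Band,
    SpectralAxis,
    Spectrum,
    SpectrumMeta,
    SpectrumSet,
    TISSUE_CLASSES,
    default_axis,
)


@dataclass(frozen=True)
class ComponentProfile:
    """One biochemical component: peaks inside a band, class amplitudes.

    ``class_mean_amplitude`` maps tissue class to the mean peak amplitude in
    detector counts; ``between_sample_cv`` / ``within_sample_cv`` are
    lognormal coefficients of variation across samples and across replicates
    of one sample.
    """

    band: Band
    peak_centers: tuple[float, ...]
    peak_width: float  # FWHM, cm^-1
    class_mean_amplitude: Mapping[str, float]
    between_sample_cv: float = 0.15
    within_sample_cv: float = 0.08
    shape: str = "gaussian"  # or "pseudo_voigt"
    voigt_eta: float = 0.3

    def __post_init__(self) -> None:
        for c in self.peak_centers:
            if not (self.band.lo <= c <= self.band.hi):
                raise ValueError(
                    f"peak center {c} outside band "
                    f"[{self.band.lo}, {self.band.hi}] of {self.band.component}")
        if self.between_sample_cv < 0 or self.within_sample_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")

    @property
    def key(self) -> str:
        return f"{self.band.component}_{int(round(self.peak_centers[0]))}"

    def is_discriminative(self) -> bool:
        vals = [self.class_mean_amplitude.get(c, 0.0) for c in TISSUE_CLASSES]
        return max(vals) - min(vals) > 1e-12


def _disc(band, centers, width, normal, edge, center):
    return ComponentProfile(
        band=band, peak_centers=centers, peak_width=width,
        class_mean_amplitude={"normal": normal, "edge": edge, "center": center},
        between_sample_cv=0.10, within_sample_cv=0.15)


def _nuis(component, lo, hi, centers, width, amp):
    # replicates probe different tissue spots, so most nuisance variation
    # is spot-to-spot (within-sample); sample-level offsets are milder
    return ComponentProfile(
        band=Band(component, lo, hi), peak_centers=centers, peak_width=width,
        class_mean_amplitude={c: amp for c in TISSUE_CLASSES},
        between_sample_cv=0.10, within_sample_cv=0.20)


def default_components() -> tuple[ComponentProfile, ...]:
    """Default component library: sparse discriminative + dense nuisance."""
    return (
        # discriminative: cholesterol falls toward tumor center, but the
        # 960 and 1228 cm^-1 shifts peak at the infiltration edge
        _disc(Band("cholesterol", 920, 932), (926.0,), 10.0, 100.0, 80.0, 45.0),
        _disc(Band("cholesterol", 954, 966), (960.0,), 10.0, 70.0, 95.0, 50.0),
        _disc(Band("cholesterol", 1222, 1234), (1228.0,), 10.0, 60.0, 85.0, 42.0),
        # carotenoids fall with tumor progression
        _disc(Band("carotenoid", 1150, 1165), (1157.0,), 11.0, 90.0, 62.0, 30.0),
        _disc(Band("carotenoid", 1515, 1528), (1521.0,), 11.0, 85.0, 58.0, 28.0),
        # hemoglobin (blood filling) and water (edema) rise toward the center
        _disc(Band("hemoglobin", 1546, 1558), (1552.0,), 10.0, 40.0, 70.0, 110.0),
        _disc(Band("water", 1615, 1655), (1635.0,), 30.0, 60.0, 90.0, 130.0),
        # protein C-N rises in tumor
        _disc(Band("protein", 1090, 1104), (1097.0,), 10.0, 50.0, 65.0, 85.0),
        # nuisance: strong bands shared by all classes, high sample-to-sample
        # variation, no class information
        _nuis("phenylalanine", 998, 1010, (1004.0,), 9.0, 120.0),
        _nuis("phospholipid", 1060, 1090, (1066.0, 1082.0), 12.0, 80.0),
        _nuis("protein", 1172, 1184, (1178.0,), 10.0, 70.0),
        _nuis("amide_iii", 1240, 1300, (1262.0, 1288.0), 20.0, 100.0),
        _nuis("ch2_deformation", 1420, 1470, (1440.0,), 22.0, 150.0),
        _nuis("amide_i", 1650, 1680, (1662.0,), 20.0, 140.0),
        _nuis("ch_stretch", 2820, 2830, (2825.0,), 15.0, 90.0),
    )


@dataclass(frozen=True)
class FluorescenceConfig:
    n_lobes: int = 3
    amplitude_scale: float = 1200.0   # counts; dominates peaks ~10x
    smoothness_scale: float = 500.0   # lobe sigma, cm^-1
    replicate_jitter_cv: float = 0.05


@dataclass(frozen=True)
class AmbientConfig:
    level: float = 200.0       # counts
    drift_scale: float = 30.0  # amplitude of a slow linear drift across axis


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one synthetic dataset."""

    axis_n_points: int = AXIS_N_POINTS
    axis_lo: float = AXIS_LO
    axis_hi: float = AXIS_HI
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 3, "edge": 3, "center": 4})
    replicates_per_sample: int = 5
    background_frames_per_sample: int = 5
    components: tuple[ComponentProfile, ...] = field(default_factory=default_components)
    fluorescence: FluorescenceConfig = field(default_factory=FluorescenceConfig)
    ambient: AmbientConfig = field(default_factory=AmbientConfig)
    noise_sd: float = 4.0
    dynamic_range_max: float = 65535.0
    saturation_fraction: float = 0.0
    # exact per-class saturated replicate counts; overrides the Bernoulli
    # saturation_fraction when set (e.g. {"normal": 1, "edge": 0, "center": 1}
    # turns the 15/15/20 design into 14/15/19 usable measurements)
    saturate_counts: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.noise_sd < 0 or self.dynamic_range_max <= 0:
            raise ValueError("noise_sd >= 0 and dynamic_range_max > 0 required")
        if not (0 <= self.saturation_fraction <= 1):
            raise ValueError("saturation_fraction must be in [0, 1]")

    def axis(self) -> SpectralAxis:
        return default_axis(self.axis_n_points, self.axis_lo, self.axis_hi)


def paper_like_config(seed: int = 0) -> GeneratorConfig:
    """The emulated study design: 3/3/4 samples x 5 replicates, with one
    saturated replicate in the normal and one in the center group, leaving
    14/15/19 usable measurements after saturation exclusion."""
    return GeneratorConfig(
        saturate_counts={"normal": 1, "edge": 0, "center": 1}, seed=seed)


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    classes: list[str]                      # per measurement spectrum
    sample_ids: list[str]
    amplitudes: list[dict[str, float]]      # per spectrum, by component key
    fluorescence: list[np.ndarray]          # per spectrum (incl. jitter)
    ambient: dict[str, np.ndarray]          # per sample id
    saturated: list[bool]
    discriminative_bands: list[Band]
    component_keys: list[str]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _gaussian_peak(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _lorentzian_peak(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return gamma * gamma / ((x - center) ** 2 + gamma * gamma)


def component_curve(profile: ComponentProfile, x: np.ndarray,
                    amplitude: float) -> np.ndarray:
    """Line-shape curve of one component at a given amplitude (unit height
    per peak)."""
    y = np.zeros_like(x)
    for c in profile.peak_centers:
        if profile.shape == "pseudo_voigt":
            g = _gaussian_peak(x, c, profile.peak_width)
            l = _lorentzian_peak(x, c, profile.peak_width)
            y += (1.0 - profile.voigt_eta) * g + profile.voigt_eta * l
        else:
            y += _gaussian_peak(x, c, profile.peak_width)
    return amplitude * y


def generate_fluorescence(axis: SpectralAxis, cfg: FluorescenceConfig,
                          rng: np.random.Generator,
                          max_component_width: float = 30.0) -> np.ndarray:
    """Smooth, non-negative, broad fluorescence continuum: a sum of wide
    Gaussian lobes.  Raises if the lobes are narrow enough to be confusable
    with Raman peaks (smoothness below 3x the widest component)."""
    if cfg.smoothness_scale < 3.0 * max_component_width:
        raise ValueError(
            f"fluorescence smoothness {cfg.smoothness_scale} cm^-1 is below "
            f"3x the maximum component width ({max_component_width} cm^-1)")
    x = axis.wavenumbers
    if cfg.amplitude_scale == 0:
        return np.zeros_like(x)
    span = x[-1] - x[0]
    y = np.zeros_like(x)
    for _ in range(cfg.n_lobes):
        center = x[0] + rng.uniform(0.15, 0.85) * span
        width = cfg.smoothness_scale * rng.uniform(0.8, 1.6)
        amp = cfg.amplitude_scale * rng.uniform(0.4, 1.0)
        y += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    return y


def _ambient_curve(axis: SpectralAxis, cfg: AmbientConfig,
                   rng: np.random.Generator) -> np.ndarray:
    x = axis.wavenumbers
    t = (x - x[0]) / (x[-1] - x[0])
    slope = rng.uniform(-1.0, 1.0) * cfg.drift_scale
    return cfg.level + slope * (t - 0.5)


def generate_dataset(config: GeneratorConfig) -> tuple[SpectrumSet, SpectrumSet, GroundTruth]:
    """Generate measurement spectra, background frames and ground truth.

    Measurement = ambient + fluorescence + sum of component peaks + noise,
    clipped to [0, dynamic_range_max].  Background frames carry ambient +
    noise only.  Identical seed gives a bit-identical dataset.
    """
    axis = config.axis()
    x = axis.wavenumbers
    ss = np.random.SeedSequence(config.seed)
    # independent sub-streams: changing noise_sd never reshuffles the design
    ss_structure, ss_noise, ss_saturation = ss.spawn(3)
    rng_structure = np.random.default_rng(ss_structure)
    rng_noise = np.random.default_rng(ss_noise)
    rng_sat = np.random.default_rng(ss_saturation)

    max_width = max(p.peak_width for p in config.components) if config.components else 30.0

    measurements: list[Spectrum] = []
    backgrounds: list[Spectrum] = []
    truth = GroundTruth(
        classes=[], sample_ids=[], amplitudes=[], fluorescence=[],
        ambient={}, saturated=[], discriminative_bands=[],
        component_keys=[p.key for p in config.components])
    seen = set()
    for p in config.components:
        if p.is_discriminative() and p.key not in seen:
            truth.discriminative_bands.append(p.band)
            seen.add(p.key)

    # decide saturated replicate indices up front
    sat_flags: dict[str, np.ndarray] = {}
    for cls in TISSUE_CLASSES:
        n_meas = config.n_samples.get(cls, 0) * config.replicates_per_sample
        if config.saturate_counts is not None:
            k = int(config.saturate_counts.get(cls, 0))
            flags = np.zeros(n_meas, dtype=bool)
            if k > 0:
                flags[rng_sat.choice(n_meas, size=k, replace=False)] = True
        else:
            flags = rng_sat.random(n_meas) < config.saturation_fraction
        sat_flags[cls] = flags

    patient_counter = 0
    for cls in TISSUE_CLASSES:
        flags = sat_flags[cls]
        meas_idx = 0
        for si in range(config.n_samples.get(cls, 0)):
            patient_counter += 1
            sample_id = f"{cls}_s{si + 1}"
            patient_id = f"p{patient_counter}"
            ambient = _ambient_curve(axis, config.ambient, rng_structure)
            truth.ambient[sample_id] = ambient
            sample_amp = {
                p.key: p.class_mean_amplitude.get(cls, 0.0)
                * _lognormal_factor(rng_structure, p.between_sample_cv)
                for p in config.components
            }
            for bi in range(config.background_frames_per_sample):
                y = ambient + rng_noise.normal(0.0, config.noise_sd, x.size)
                y = np.clip(y, 0.0, config.dynamic_range_max)
                backgrounds.append(Spectrum(axis, y, SpectrumMeta(
                    spectrum_id=f"{sample_id}_bg{bi + 1}",
                    patient_id=patient_id, sample_id=sample_id,
                    replicate=bi + 1, tissue_class=cls,
                    frame_kind="background")))
            for ri in range(config.replicates_per_sample):
                rep_amp = {
                    p.key: sample_amp[p.key]
                    * _lognormal_factor(rng_structure, p.within_sample_cv)
                    for p in config.components
                }
                peaks = np.zeros_like(x)
                for p in config.components:
                    peaks += component_curve(p, x, rep_amp[p.key])
                # every replicate probes a fresh spot: its own continuum
                rep_fluor = generate_fluorescence(
                    axis, config.fluorescence, rng_structure, max_width)
                rep_fluor *= _lognormal_factor(
                    rng_structure, config.fluorescence.replicate_jitter_cv)
                y = ambient + rep_fluor + peaks \
                    + rng_noise.normal(0.0, config.noise_sd, x.size)
                saturated = bool(flags[meas_idx])
                if saturated:
                    # drive the replicate near the detector ceiling
                    y = y * (1.05 * config.dynamic_range_max / max(y.max(), 1.0))
                y = np.clip(y, 0.0, config.dynamic_range_max)
                measurements.append(Spectrum(axis, y, SpectrumMeta(
                    spectrum_id=f"{sample_id}_r{ri + 1}",
                    patient_id=patient_id, sample_id=sample_id,
                    replicate=ri + 1, tissue_class=cls,
                    frame_kind="measurement")))
                truth.classes.append(cls)
                truth.sample_ids.append(sample_id)
                truth.amplitudes.append(rep_amp)
                truth.fluorescence.append(rep_fluor)
                truth.saturated.append(saturated)
                meas_idx += 1

    n_sat = sum(truth.saturated)
    if measurements and n_sat > 0.5 * len(measurements):
        warnings.warn(
            f"{n_sat}/{len(measurements)} replicates saturated (> 50%)",
            stacklevel=2)

    mset = SpectrumSet(measurements)
    mset.log(f"simulated {len(measurements)} measurement spectra (seed={config.seed})")
    bset = SpectrumSet(backgrounds)
    bset.log(f"simulated {len(backgrounds)} background frames (seed={config.seed})")
    return mset, bset, truth


def zero_contrast_config(seed: int = 0) -> GeneratorConfig:
    """Null dataset: identical class-mean amplitudes everywhere (the class
    labels carry no information).  Used for chance-level controls."""
    base = paper_like_config(seed)
    flat = []
    for p in base.components:
        mean = float(np.mean([p.class_mean_amplitude.get(c, 0.0)
                              for c in TISSUE_CLASSES]))
        flat.append(replace(p, class_mean_amplitude={c: mean for c in TISSUE_CLASSES}))
    return replace(base, components=tuple(flat), seed=seed)
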