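# Methods

This note records the models, parameter choices and numerical decisions
behind `ramanbiopsy`, and what the synthetic benchmark does and does not
show about real tissue spectra.

## Signal model

A measured spectrum on the instrument axis (2050 points, 127–2830 cm⁻¹) is
modeled as

    y(ν) = ambient(ν) + fluorescence(ν) + Σ_c A_c · g_c(ν) + ε(ν)

where `ambient` is the background illumination (also captured in dedicated
background frames), `fluorescence` is a smooth continuum 5–20× larger than
the Raman peaks, `g_c` are unit-height line shapes (Gaussian by default,
pseudo-Voigt optional) of biochemical components, `A_c` their amplitudes,
and ε i.i.d. detector noise. Intensities are clipped to the detector range
[0, 65535]; replicates can saturate and are then excluded upstream.

## Preprocessing

Stages run in a fixed order: saturation exclusion (raw maximum above 90% of
the dynamic range) → per-sample background averaging and subtraction →
Savitzky–Golay smoothing → Morlet-sum baseline removal → crop to
900–1800 cm⁻¹ (closed interval; 683 points on the even synthetic grid) →
integral normalization (trapezoidal area = 1). The chain is a pure function
of inputs and configuration; nothing draws random numbers.

Savitzky–Golay uses window 15, order 3; edge samples are handled by
polynomial fits on the truncated window (`scipy` mode `interp`), so any
polynomial of degree ≤ 3 passes through unchanged. Negative intensities
after background subtraction are preserved (they are noise, and clipping
would bias the later integrals); an optional zero-clip flag exists.
Normalization divides by the trapezoidal integral over the cropped axis and
raises on a non-positive integral, which almost always indicates a failed
baseline fit.

### Morlet baseline

The fluorescence continuum is modeled as a sum of K = 4 real-valued Morlet
wavelets with carrier ω₀ = 5. Parameters (amplitude, center, scale per
wavelet) are fitted by bounded nonlinear least squares with an asymmetric
loss: residuals where the baseline exceeds the signal are weighted
50× more than residuals below. This is the standard asymmetry trick of
baseline estimation — Raman peaks only add to the continuum, so the
estimate must hug the signal from below. The asymmetry ratio matters for
quantification: at ratio 10 the fitted continuum still rides into
peak-dense regions (1150–1300 cm⁻¹) and absorbs ~15% of true band area; at
50 the residual band-area error drops below 5% while the fit to the true
continuum is unchanged (R² ≈ 1.0 on noiseless synthetic spectra). Ratio 50
is therefore the default, exposed in `MorletFitConfig`.

Scale bounds are 150–4000 cm⁻¹. The upper bound is deliberately larger
than the axis span: the central positive lobe of exp(−t²/2)cos(5t) spans
only ≈ 0.63·s cm⁻¹, so representing a continuum lobe several hundred cm⁻¹
wide requires scales of a few thousand. With scales capped at ~1500 the
basis provably cannot represent the continuum (best achievable R² ≤ 0.43
in direct capacity probes); with the 4000 cap it reaches R² = 1.0.

Optimization runs three deterministic starts (quantile-spaced centers,
amplitudes from the local signal level, ascending scale levels), each
refined in two stages — symmetric least squares first to lock onto the
overall shape, then the asymmetric objective — with an analytic Jacobian
and fitting on every 2nd point (the baseline is smooth by construction).
The best asymmetric loss wins. The two-stage scheme is what makes the
oscillatory Morlet basis optimizable in practice: starting the asymmetric
fit cold routinely strands it in poor local minima.

## Feature filtering

Per wavenumber, a one-way ANOVA F statistic across the three tissue
classes; keep if F exceeds the F(k−1, n−k) upper-α quantile, α = 0.05 by
default (no value is canonical; 0.05 is the field's convention). No
multiple-testing correction is applied by default — the filter is a
screening step whose downstream consumer is a classifier, not an inference
— but a Benjamini–Hochberg switch exists, as does a Fisher
discriminant-ratio variant of the statistic for sensitivity analysis.
Band summaries sum only mask-retained wavenumbers inside each band
(a full-band option exists) and re-test the band sums with a fresh ANOVA
for the significance tiers, because band-level and point-level significance
are different questions.

The default band library encodes the shifts with known tissue contrasts:
cholesterol (926, 960, 1228 cm⁻¹), protein C–N (1097), carotenoids (1157,
1521), protein/cholesterol overlap (1178), hemoglobin (1546–1558), water
(~1635), and the amide I/III regions. Users can override it with any
`component,lo,hi` CSV.

## Classification

PCA is computed from the eigendecomposition of the covariance matrix of
column-centered data (via the Gram matrix when wavenumbers outnumber
spectra), eigenvalues non-increasing, and a fixed sign convention (largest
absolute loading entry positive) for reproducibility. PCA is fitted on
training rows only and test rows are projected through the training model;
a fit-on-all flag exists for figure reproduction but leaks information.

The SVM is a soft-margin RBF classifier (C = 1, gamma = 1/(n_features ×
variance), one-vs-one); no hyperparameter search is performed by default.
Filtered features are z-scored with training-set statistics before the SVM
(RBF kernels are scale-sensitive); PC scores are used as-is.

Splits take 30% for training with a per-class minimum of 5, using half-up
rounding so class sizes 14/15/19 give training counts 5/5/6. A
patient-grouped mode keeps all spectra of one patient on one side of the
split; it errors when a class is sampled from a single patient. Binary
metrics collapse edge ∪ center into "malignant"; an edge-vs-center
confusion still counts as a true positive.

The three variants share split seeds derived from one base seed, so
variant comparisons are paired. The Fisher mask is estimated once on the
full dataset by default (`mask_scope="all"`, mirroring the filter-then-
classify protocol); `mask_scope="train"` re-estimates it inside every
split for a leakage-free analysis.

## Synthetic benchmark

The generator emulates the acquisition design: 3/3/4 samples for
normal/edge/center, 5 replicates per sample, 5 background frames per
sample, with a configurable number of saturated replicates
(`paper_like_config` saturates one normal and one center replicate, so
exclusion leaves 14/15/19 usable measurements out of 15/15/20).

Class contrasts follow glioblastoma biochemistry qualitatively:
cholesterol and carotenoids decrease from normal through edge to center;
hemoglobin (blood filling) and water (edema, necrosis) increase toward the
center; the 960 and 1228 cm⁻¹ cholesterol shifts peak at the infiltration
edge; protein C–N rises in tumor. Alongside these sparse discriminative
bands, several strong bands (phenylalanine 1004, phospholipids, amide I
and III, CH₂ deformation 1440 cm⁻¹) carry no class information but vary
between measurements — the dense nuisance variance that plain PCA soaks up.

Variation is structured hierarchically with lognormal multipliers: a
between-sample CV of 0.10 and a within-sample (spot-to-spot) CV of 0.15
for discriminative components and 0.20 for nuisance components. The
fluorescence continuum is redrawn for every replicate. Treating the
replicate, not the sample, as the dominant unit of variation reflects the
acquisition: each replicate probes a different spot at a different angle,
so spot heterogeneity and continuum changes dominate. It also keeps the
benchmark honest — when nuisance variation sits at the sample level,
replicates of one sample are correlated, and an ungrouped split lets the
classifier recognize *samples* rather than tissue classes: in a null
experiment with class contrasts removed we measured 90% apparent accuracy
from this leakage alone (and the pointwise F test retains 20% of
wavenumbers instead of α). With spot-level nuisance the null dataset is
exchangeable: the filter retains ≈5% of wavenumbers at α = 0.05 and all
variants drop to chance. The spot-level CV of 0.20 places the default
benchmark at the operating point where the three variants reach comparable
accuracy while plain PCA loses specificity — the regime the pipeline is
designed to probe.

Randomness is split into independent sub-streams (structure, noise,
saturation) from one seed, so changing the noise level never reshuffles
the sampled design.

What the benchmark does **not** emulate: wavelength-dependent instrument
response and pixel spacing (the axis is linear in wavenumber; the real
instrument's 900–1800 cm⁻¹ window maps to 646 pixels, the synthetic grid
to 683), cosmic-ray spikes, water/substrate interference, inter-patient
biochemical covariance, and any physics of Raman cross-sections. Passing
tests on synthetic data therefore validates the *computational chain* —
recovery of known baselines, calibration of the filter, contracts of the
classifier — not clinical performance on real tissue.

## Reported sizes and runtimes

Default problem sizes were chosen so the whole suite runs on a laptop
core: 48-spectrum datasets at 2050 points, 50 split repeats, 20-spectrum
baseline-recovery studies, 50-replicate null calibrations at 646 columns.
The repeated-split design replaces the original single 30% split because
a lone split of 48 spectra has metric standard deviations of ±10 points;
means over 50 paired splits are stable to ~1 point.

## Known limitations

* The Morlet baseline fit is local optimization; pathological continua
  (sharp steps, strong negative drift) can defeat the deterministic
  starts. The `converged` flag and `fit_loss` expose this.
* The Fisher filter tests each wavenumber marginally; correlated
  discriminative structure spread thinly over many wavenumbers can be
  missed at small n.
* With 14–19 spectra per class, SVM metrics have broad sampling
  distributions; single-split numbers should not be quoted without the
  repeated-split summary.
* The grouped-split mode requires each class to span ≥ 2 patients, which
  the emulated design only just satisfies; grouped estimates are
  correspondingly coarse.
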