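# Methods

This note documents the models and procedures implemented in `theranost`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Raman preprocessing chain

Spectra are processed independently, in a fixed order: crop → baseline
subtraction → despiking → Savitzky–Golay smoothing → area normalization.
Mean-centering is excluded from the chain on purpose: it pools information
across spectra and therefore belongs to model fitting, where it is learnt
on training folds only.

**Crop.** The fingerprint region 510–1825 cm⁻¹ (closed interval, inclusive
endpoints). On a 1 cm⁻¹ grid from 400–2000 cm⁻¹ this keeps 1316 channels.

**Baseline.** Tissue fluorescence forms a broad background under the
narrow Raman bands. The baseline `z` minimizes

```
sum_i w_i (y_i - z_i)^2  +  lambda * sum_i (Delta^2 z_i)^2
```

with second differences on the channel index (unit spacing, matching the
single dimensionless λ convention of common implementations) and
iteratively reweighted asymmetric weights: `w_i = p` where `y_i > z_i`,
`w_i = 1 − p` otherwise. Points above the baseline — the peaks — barely
pull on it, so the smooth curve settles under the spectrum. Defaults:
λ = 1e5, p = 0.001, 10 reweighting iterations with early exit on weight
convergence. A plain symmetric Whittaker smoother would track the peaks
and cannot serve as a baseline; the asymmetric variant is the standard
baseline reading of a "Whittaker filter" used for background subtraction.
The pentadiagonal normal equations `(W + λDᵀD) z = W y` are solved by a
symmetric banded Cholesky factorization. At large λ the system's
conditioning costs several digits, so each solve is followed by two
iterative-refinement steps whose residuals are evaluated from the
second-difference stencil in extended precision — forming `λDᵀD·z`
directly would cancel catastrophically (λ·z terms of order 1e7 summing to
order 0.1). In the λ→∞ limit with symmetric weights the baseline is the
ordinary-least-squares straight line through the data; as λ→0 it
reproduces the data; both limits and the dense-solver equivalence are
exercised in the tests.

**Despiking.** Cosmic rays are rare, sharp, large-amplitude artefacts.
Channels are scored by the modified z-score of the first-difference
series, `0.6745·|Δy − median Δy| / MAD`, with threshold 8. A cosmic spike
produces an anomalous up-jump immediately followed by an anomalous
down-jump, so flagged gaps of opposite sign within 4 channels of each
other are paired and the channels strictly between them are replaced by
linear interpolation of the nearest unflagged neighbours. This pairing
keeps the rule local (a single-channel spike changes exactly one channel)
and leaves steep genuine spectral slopes — which produce runs of
same-signed anomalous gaps — untouched; an isolated unpaired jump is
treated as a step artefact and both endpoints are interpolated. If the
flag set covers the majority of channels the spectrum is rejected as
degenerate rather than silently reconstructed. The MAD-based score assumes
first differences dominated by noise; on strictly noiseless, smooth
synthetic input the score can be large on band flanks, which the pairing
rule absorbs.

**Smoothing.** First-order Savitzky–Golay filter with a 7-channel frame:
each channel becomes the centre value of a degree-1 least-squares fit over
the symmetric window (for order 1 this equals a 7-point moving average).
Edge channels are re-fit on the window truncated at the boundary, so
spectra are never shortened. A degree-1 filter reproduces affine signals
exactly — a property test.

**Normalization.** Intensities are divided by the trapezoidal area over
the physical wavenumber axis (area-under-curve normalization), making
spectra comparable across integration times and collection efficiencies.
The operation is idempotent and scale-invariant.

## PLS-DA diagnosis

Classification regresses a one-hot class-indicator matrix on the spectra
by NIPALS PLS2 (6 latent variables by default) and assigns the class with
the largest predicted indicator, ties to the lowest class index. NIPALS
was chosen over SIMPLS because its full-rank limit provably coincides with
ordinary least squares, which gives the test suite an exact independent
oracle; the implementation is also cross-checked against an independent
NIPALS implementation (scikit-learn) in the tests, never used as the
estimator itself.

Cross-validation is Venetian blinds with 10 splits: fold of sample *i* in
acquisition order is *i* mod 10. Mean-centring happens inside the fit, on
the training folds only — no leakage through the centring step. Note that
with replicate spectra of one subject adjacent in acquisition order,
Venetian blinds places replicates of the same subject in different folds;
this mirrors the convention of the established chemometrics toolboxes but
is optimistic when replicates are highly correlated. A subject-blocked
fold variant (`subject_ids=` / `blocked_folds`) is provided, default off.
Both the estimator and the cross-validation are fully deterministic given
input order.

## Quality statistics and monitoring

* **SNR**: mean over replicates of the peak intensity within ±10 cm⁻¹ of
  1650 cm⁻¹, divided by the per-channel sample standard deviation across
  replicates averaged over the spectroscopically silent 1780–1820 cm⁻¹
  band. The band is interpreted as estimating replicate noise; identical
  replicates (zero noise) are rejected rather than returned as infinite.
* **Spectral CV**: per-channel SD across replicates over per-channel
  |mean|, averaged over channels whose |mean| exceeds 1e-12 of the maximum
  — near-zero-mean channels would dominate the ratio meaninglessly.
* **Peak intensity** is a windowed maximum (default half-width 10 cm⁻¹),
  robust to a few channels of calibration shift; the window centred at
  1440 cm⁻¹ covers the 1445 cm⁻¹ CH₂ deformation band.
* **Difference spectra** are channelwise differences of group means;
  monitoring reduces each day's tumour-minus-control difference spectrum
  to the 1440 cm⁻¹ peak statistic normalised to day 0. Signed peak values
  are the default; an `absolute` flag handles negative-going difference
  features. By linearity, a treatment that scales the tumour-specific
  contrast scales the statistic identically, so the time course tracks the
  underlying response multiplier.
* **Outliers** use the 1.5×IQR rule with type-7 (linear interpolation)
  quartiles, the most common quantile convention, stated here to make the
  exclusions reproducible. **Group comparisons** use two-tailed Welch's
  t-tests with Satterthwaite degrees of freedom. **Normalized growth**
  divides each day's tumour-burden signal (e.g. bioluminescence total
  flux) by the pre-treatment value.

## PPIX quantification assay

Fluorescence emission spectra of dissolved tumour tissue are cropped to
450–750 nm; the solvent blank is subtracted channelwise; the broad tissue
autofluorescence is removed with the same asymmetric Whittaker solver at
λ = 10; the residual is smoothed (Savitzky–Golay 1, 7); and the PPIX
emission band 620–640 nm (main emission near 630 nm; the readout band is a
package default, not an instrument constant) is integrated by the
trapezoidal rule. A linear standard curve fitted by OLS to spiked control
tissue maps integrated signal to PPIX amount; tissue concentration is
`amount × dilution_factor / tumour_mass`, with the dilution factor
defaulting to the 50 µL-into-1 mL aliquot chain, (1000+50)/50 = 21.
Negative back-calculated amounts are floored at zero with a warning flag.

Two numerical points deserve emphasis. First, λ = 10 is an extremely
flexible background: its first, symmetric iterate lies essentially *on*
the spectrum, including on the PPIX peak, and the background only settles
underneath the peak as the asymmetric reweighting proceeds. The
fluorescence configuration therefore uses a strong asymmetry (p = 1e-5)
and runs the reweighting to convergence (50 iterations); with the Raman
defaults (p = 0.001, 10 iterations) roughly 5–10% of the peak area would
be absorbed into the background. Second, the chain retains a stable
fraction (≈96%) of the injected band area rather than all of it — the
λ = 10 filter and the smoothing each shave a few percent. Because
standards and samples are processed identically, this throughput factor
cancels in the standard-curve calibration: end-to-end tissue
concentrations are recovered without systematic bias (median relative
error ≈5% at the generator's default noise), even though the raw spectral
slope underestimates the injected signal-per-ng by ≈4%. The slope
*estimator* itself (OLS on amounts/signals) is unbiased, verified over 200
seeded noisy replicates.

Dosimetry helpers convert mass concentration to molarity
(µM = (ng/mL)/(g/mol), reported to 3 significant figures; e.g. 1000 ng/mL
of PPIX, M = 562.66 g/mol, is 1.78 µM) and fluence to exposure time
(30 J/cm² at 50 mW/cm² is 600 s).

## Synthetic data generators

The generators are pure functions of (configuration, seed) and emit
ground-truth sidecars (noiseless templates, baselines, spike channels,
injected amounts) alongside every dataset.

**Raman tissue spectra** are sums of Lorentzian bands at 936, 1078, 1265,
1302, 1445 and 1655 cm⁻¹ (HWHM 9–14 cm⁻¹, amplitudes 200–420 counts) on a
broad smooth fluorescence background (~800 counts), with iid Gaussian
noise (SD 10 counts), Bernoulli cosmic spikes (probability 0.1 per
spectrum, amplitude ≥20× the noise SD), multiplicative per-subject
per-band jitter (lognormal, 8%) and per-replicate jitter (2%). Lorentzian
line shapes and additive Gaussian noise are modelling choices, not
measured facts. Tumour tissue multiplies the 1265/1302/1445/1655 bands by
0.78–0.95 — control tissue is more intense at those bands, and because the
1655 cm⁻¹ amide I band is reduced least, the tumour 1655/1445 ratio rises,
the signature the classifier exploits. A photosensitiser load adds
baseline amplitude and, for PPIX, a porphyrin band at 1550 cm⁻¹. These
effect sizes were fixed once so that the two-class classification problem
at n = 120 lands near the high-90s cross-validated accuracy regime typical
of tissue Raman classification (0.975 at the default seed).

**Longitudinal studies** follow two arms (control, PDT-treated) of 5
subjects over days 0/3/6 with 20 spectra per site, tumour and
contralateral flank. The tumour-specific contrast is scaled per arm and
day: 1 → 0.6 → 0.35 after PDT (tumour-cell density in the sampling volume
falling), 1 → 1.15 → 1.3 in controls (tumour growing). Subject jitters
persist across days so each animal is internally consistent.

**Fluorescence standards** are a PPIX emission Gaussian at 630 nm (σ =
5 nm, ~12 nm FWHM) whose band-integrated area is slope×amount (default
sensitivity 50 signal/ng), over a tissue autofluorescence hump (centre
500 nm, σ = 80 nm, amplitude 400) and a solvent blank, with noise at 0.5%
of the autofluorescence peak — the high-SNR regime of a benchtop
spectrofluorometer.

**What passing these experiments does not show.** The generators emulate
statistical structure, not physics: no instrument line-shape function,
wavenumber calibration error, detector etaloning, shot-noise scaling with
intensity, or tissue heterogeneity within a sampling volume. Accuracies
obtained on synthetic data are properties of the chosen effect sizes and
noise levels, and are surrogates for — not reproductions of — accuracies
on real tissue spectra. In vivo effect sizes in particular are not
derivable from summary statistics, so the longitudinal response
multipliers are plausible surrogates chosen once.

## Problem sizes and determinism

The default experiment sizes — 120 spectra for classification, 200 for
the permutation null, 1200 for the longitudinal study (2 arms × 5 subjects
× 3 days × 2 sites × 20 spectra), 12 tissue samples and 6 standards for
the assay, 200 replicates for the slope-bias study — were chosen as the
package's standard desk-scale configurations; the full test suite and the
acceptance script each complete in well under a minute on one CPU. All
randomness flows through explicit seeds; pipelines write plain CSV with a
fixed float format, so identical inputs and seeds produce byte-identical
report payloads. Manifest files additionally record per-stage wall times
and input digests for provenance (wall times naturally vary between runs
and are excluded from the determinism guarantee).

## Known limitations

* Venetian-blinds folds leak replicate correlation by design (see above);
  use the blocked variant for subject-level generalization estimates.
* The despike rule assumes noise-dominated first differences; completely
  noiseless data can trigger flank flagging, absorbed by the pairing rule.
* The asymmetric-Whittaker fixed point is not unique to machine precision:
  points lying within rounding error of the baseline can flip weights
  between otherwise equivalent solvers. Oracle comparisons are therefore
  made against an independent solve of the same weighted system.
* The fluorescence chain's throughput (<100%) is calibrated away by the
  standard curve, which assumes standards and samples share matrix
  effects — the same assumption the physical assay makes.
* Axes are never resampled implicitly; collections must share a grid for
  matrix operations, and interpolation between instruments is out of
  scope.
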