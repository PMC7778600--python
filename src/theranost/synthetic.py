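"""Seeded generators for synthetic Raman and fluorescence datasets.

The generators emulate the statistical structure of in vivo / in vitro
tissue Raman acquisitions and of spectrofluorometric PPIX readouts, so the
whole analysis chain is testable without any instrument data:

* Raman spectra are sums of Lorentzian bands at the prominent tissue peaks
  (936, 1078, 1265, 1302, 1445, 1655 cm⁻¹) riding on a broad smooth
  fluorescence baseline, with per-subject amplitude jitter, iid Gaussian
  detector noise, and Bernoulli cosmic-ray spikes.
* Tumour tissue differs from control by multiplicative amplitude effects:
  reduced 1265/1302/1445/1655 band intensities with the 1655 band reduced
  least, i.e. an increased 1655/1445 (amide I over CH₂ deformation) ratio.
* A photosensitiser load adds extra fluorescence baseline and, for PPIX, a
  porphyrin band near 1550 cm⁻¹.
* Longitudinal studies scale the tumour effect per arm and day (shrinking
  after photodynamic therapy, growing in controls).
* Fluorescence standards are a PPIX emission Gaussian at 630 nm over a
  tissue autofluorescence hump plus a solvent blank.

Every generator is a pure function of (config, seed) and returns
ground-truth sidecars (noiseless templates, spike channels, injected
amounts) so downstream tests can compare against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .spectra_io import Spectrum, SpectrumCollection


def _lorentzian(x, center, hwhm, amplitude):
    return amplitude * hwhm**2 / ((x - center) ** 2 + hwhm**2)


def _gaussian(x, center, sigma, amplitude):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


#: Default Raman band table: (center cm⁻¹, HWHM cm⁻¹, amplitude counts).
#: Centres are the prominent tissue bands; widths and amplitudes are
#: modelling choices typical of fingerprint-region tissue spectra.
DEFAULT_PEAKS = (
    (936.0, 9.0, 220.0),    # ν(C-C) proteins
    (1078.0, 9.0, 200.0),   # ν(C-C) lipids
    (1265.0, 11.0, 260.0),  # amide III
    (1302.0, 10.0, 280.0),  # CH2 twist, lipids
    (1445.0, 12.0, 420.0),  # CH2 deformation
    (1655.0, 14.0, 380.0),  # amide I
)

#: Tumour-vs-control multiplicative amplitude effects.  Control tissue shows
#: greater intensity at 1265/1302/1445/1655; the 1655 band is reduced least
#: in tumour, raising the tumour 1655/1445 ratio.
DEFAULT_CLASS_EFFECTS = {
    "control": {},
    "tumour": {1265.0: 0.78, 1302.0: 0.78, 1445.0: 0.80, 1655.0: 0.95},
}


@dataclass
class RamanGenConfig:
    """Full parameterization of the Raman spectrum generator."""

    axis_lo: float = 400.0
    axis_hi: float = 2000.0
    axis_step: float = 1.0
    peak_table: tuple = DEFAULT_PEAKS
    class_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_EFFECTS.items()}
    )
    ps_background: str = "none"     # none | ppix | verteporfin | temoporfin
    ps_baseline_amp: float = 400.0  # extra fluorescence from photosensitiser
    ppix_band_amp: float = 60.0     # 1550 cm-1 porphyrin band (ppix only)
    baseline_amp: float = 800.0     # broad tissue fluorescence, counts
    noise_sd: float = 10.0          # iid Gaussian detector noise, counts
    spike_rate: float = 0.1         # per-spectrum cosmic-ray probability
    subject_jitter_sd: float = 0.08  # per-subject per-peak lognormal sd
    replicate_jitter_sd: float = 0.02
    replicates_per_subject: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for _, w, _ in self.peak_table):
            raise ValidationError("peak widths must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValidationError("spike_rate must be a probability")
        if self.ps_background not in ("none", "ppix", "verteporfin", "temoporfin"):
            raise ValidationError(f"unknown ps_background {self.ps_background!r}")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return self.axis_lo + self.axis_step * np.arange(n)


def _baseline(cfg: RamanGenConfig, x: np.ndarray) -> np.ndarray:
    """Broad smooth fluorescence background, decaying toward high shift."""
    amp = cfg.baseline_amp
    if cfg.ps_background != "none":
        amp = amp + cfg.ps_baseline_amp
    return amp * (0.55 * np.exp(-(x - 400.0) / 900.0)
                  + 0.45 * np.exp(-0.5 * ((x - 1000.0) / 550.0) ** 2))


def class_template(
    class_label: str, cfg: RamanGenConfig, amp_factors: dict | None = None,
    effect_scale: float = 1.0,
) -> np.ndarray:
    """Noiseless peaks-only template for a class (no baseline, no noise).

    ``effect_scale`` scales the class effect toward (0) or beyond (>1) the
    control template: the effective multiplier of a peak is
    ``1 + effect_scale·(m − 1)``.
    """
    effects = cfg.class_effects.get(class_label, {})
    x = cfg.axis
    y = np.zeros_like(x)
    for center, width, amp in cfg.peak_table:
        m = effects.get(center, 1.0)
        m = 1.0 + effect_scale * (m - 1.0)
        jit = amp_factors.get(center, 1.0) if amp_factors else 1.0
        y += _lorentzian(x, center, width, amp * m * jit)
    if cfg.ps_background == "ppix":
        y += _lorentzian(x, 1550.0, 12.0, cfg.ppix_band_amp)
    return y


def generate_spectrum(
    class_label: str,
    cfg: RamanGenConfig,
    rng: np.random.Generator,
    amp_factors: dict | None = None,
    effect_scale: float = 1.0,
    meta: dict | None = None,
):
    """Draw one synthetic Raman spectrum; returns ``(Spectrum, truth)``.

    ``truth`` carries the peaks-only template, the baseline, and the spike
    channel indices actually injected.
    """
    x = cfg.axis
    peaks = class_template(class_label, cfg, amp_factors, effect_scale)
    if cfg.replicate_jitter_sd > 0:
        peaks = peaks * rng.lognormal(0.0, cfg.replicate_jitter_sd)
    base = _baseline(cfg, x)
    y = peaks + base
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=x.size)
    spike_channels = []
    if cfg.spike_rate > 0 and rng.random() < cfg.spike_rate:
        ch = int(rng.integers(0, x.size))
        # cosmic rays are sharp and large: >= 20x the detector noise
        amp = max(cfg.noise_sd, 1.0) * rng.uniform(20.0, 60.0)
        y = y.copy()
        y[ch] += amp
        spike_channels.append(ch)
    m = {"tissue_class": class_label, "photosensitiser": cfg.ps_background}
    if meta:
        m.update(meta)
    spec = Spectrum(axis=x, intensity=y, axis_kind="raman_shift", meta=m)
    truth = {"template": peaks, "baseline": base, "spike_channels": spike_channels}
    return spec, truth


def _subject_jitter(cfg: RamanGenConfig, rng: np.random.Generator) -> dict:
    return {
        center: float(rng.lognormal(0.0, cfg.subject_jitter_sd))
        for center, _, _ in cfg.peak_table
    }


def generate_classification_dataset(
    cfg: RamanGenConfig,
    n_per_class: int = 60,
    classes=("control", "tumour"),
):
    """Two-class (or k-class) dataset with subject/replicate structure.

    ``n_per_class`` spectra per class are produced as
    ``n_per_class // replicates_per_subject`` subjects with
    ``replicates_per_subject`` replicate spectra each.  Subjects of the
    different classes are interleaved in the output order, so
    Venetian-blinds folds stay class-balanced and every fold's training set
    contains every class.

    Returns ``(SpectrumCollection, labels, truths)``.
    """
    if n_per_class % cfg.replicates_per_subject:
        raise ValidationError(
            "n_per_class must be a multiple of replicates_per_subject"
        )
    rng = np.random.default_rng(cfg.seed)
    n_subj = n_per_class // cfg.replicates_per_subject
    per_subject = []
    for k, cls_name in enumerate(classes):
        for j in range(n_subj):
            per_subject.append((cls_name, f"{cls_name}_{j:03d}",
                                _subject_jitter(cfg, rng)))
    # interleave classes: c0 s0, c1 s0, c0 s1, c1 s1, ...
    interleaved = []
    for j in range(n_subj):
        for k in range(len(classes)):
            interleaved.append(per_subject[k * n_subj + j])

    spectra, labels, truths = [], [], []
    for cls_name, subj_id, jitter in interleaved:
        for r in range(cfg.replicates_per_subject):
            spec, truth = generate_spectrum(
                cls_name, cfg, rng, amp_factors=jitter,
                meta={"subject_id": subj_id, "replicate": str(r)},
            )
            spectra.append(spec)
            labels.append(cls_name)
            truths.append(truth)
    return SpectrumCollection(spectra=spectra, labels=labels), labels, truths


@dataclass
class StudyDesign:
    """Longitudinal two-arm monitoring design (control vs PDT-treated).

    ``response_model[arm][day]`` multiplies the tumour-effect amplitude on
    that day: 1 at day 0 for both arms by definition, decreasing post-PDT
    (tumour load shrinking) and increasing in untreated controls.
    """

    n_subjects: int = 5
    arms: tuple = ("control", "pdt")
    days: tuple = (0, 3, 6)
    spectra_per_site: int = 20
    response_model: dict = field(default_factory=lambda: {
        "control": {0: 1.0, 3: 1.15, 6: 1.3},
        "pdt": {0: 1.0, 3: 0.6, 6: 0.35},
    })

    def __post_init__(self):
        for arm in self.arms:
            if self.response_model[arm][0] != 1.0:
                raise ValidationError("day 0 response multiplier must be 1")


def generate_longitudinal_study(design: StudyDesign, cfg: RamanGenConfig):
    """Generate tumour + control-flank collections per (arm, day).

    Returns a dict ``(arm, day) -> {"tumour": coll, "flank": coll}``; subject
    jitters persist across days so each animal is internally consistent.
    Spectrum metadata carries ``subject_id``, ``arm``, ``timepoint_days``.
    """
    rng = np.random.default_rng(cfg.seed)
    jitters = {
        (arm, j): _subject_jitter(cfg, rng)
        for arm in design.arms for j in range(design.n_subjects)
    }
    out = {}
    for arm in design.arms:
        for day in design.days:
            scale = design.response_model[arm][day]
            tum, flank = [], []
            for j in range(design.n_subjects):
                meta = {"subject_id": f"{arm}_{j:02d}", "arm": arm,
                        "timepoint_days": str(day)}
                for _ in range(design.spectra_per_site):
                    s, _ = generate_spectrum(
                        "tumour", cfg, rng, amp_factors=jitters[(arm, j)],
                        effect_scale=scale, meta=meta,
                    )
                    tum.append(s)
                    s, _ = generate_spectrum(
                        "control", cfg, rng, amp_factors=jitters[(arm, j)],
                        meta=meta,
                    )
                    flank.append(s)
            out[(arm, day)] = {
                "tumour": SpectrumCollection(tum, labels=["tumour"] * len(tum)),
                "flank": SpectrumCollection(flank, labels=["control"] * len(flank)),
            }
    return out


# ---------------------------------------------------------------------------
# fluorescence standards
# ---------------------------------------------------------------------------

_FLUOR_AXIS = np.arange(430.0, 761.0, 1.0)
_PPIX_CENTER_NM = 630.0
_PPIX_SIGMA_NM = 5.0  # ~12 nm FWHM emission line


def _ppix_unit_band_area(band=(620.0, 640.0)) -> float:
    """Integral over the readout band of a unit-height PPIX emission Gaussian."""
    lo, hi = band
    grid = _FLUOR_AXIS[(_FLUOR_AXIS >= lo) & (_FLUOR_AXIS <= hi)]
    return float(np.trapezoid(_gaussian(grid, _PPIX_CENTER_NM, _PPIX_SIGMA_NM, 1.0),
                              grid))


def generate_fluorescence_standards(
    n_levels: int = 6,
    slope_truth: float = 50.0,
    noise_rel: float = 0.005,
    seed: int = 0,
    max_amount_ng: float = 100.0,
    amounts=None,
):
    """Synthetic PPIX standards in a tissue-autofluorescence background.

    Each standard is solvent blank + tissue autofluorescence hump + a PPIX
    emission Gaussian at 630 nm whose band-integrated area is
    ``slope_truth × amount``, plus iid Gaussian noise of SD
    ``noise_rel × autofluorescence peak``.  Returns
    ``(SpectrumCollection, amounts, blank, truth)``.
    """
    if n_levels < 3:
        raise ValidationError("need at least 3 standard levels")
    rng = np.random.default_rng(seed)
    x = _FLUOR_AXIS
    if amounts is None:
        amounts = np.linspace(0.0, max_amount_ng, n_levels)
    amounts = np.asarray(amounts, dtype=float)

    solvent = _gaussian(x, 480.0, 60.0, 300.0) + 50.0
    autofl = _gaussian(x, 500.0, 80.0, 400.0)
    noise_sd = noise_rel * autofl.max()
    unit_area = _ppix_unit_band_area()

    spectra = []
    for i, amt in enumerate(amounts):
        height = slope_truth * amt / unit_area
        y = solvent + autofl + _gaussian(x, _PPIX_CENTER_NM, _PPIX_SIGMA_NM, height)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=x.size)
        spectra.append(Spectrum(
            axis=x, intensity=y, axis_kind="wavelength",
            meta={"spectrum_id": f"std_{i:02d}", "ppix_amount_ng": f"{amt:.6g}"},
        ))
    blank = Spectrum(axis=x, intensity=solvent.copy(), axis_kind="wavelength",
                     meta={"spectrum_id": "blank", "role": "blank"})
    truth = {"slope": slope_truth, "autofluorescence": autofl,
             "noise_sd": noise_sd, "unit_band_area": unit_area}
    return SpectrumCollection(spectra, labels=None), amounts, blank, truth


def generate_tissue_fluorescence(
    ng_per_g, mass_g, dilution_factor: float = 21.0,
    slope_truth: float = 50.0, noise_rel: float = 0.005, seed: int = 0,
):
    """Fluorescence spectra of dissolved tumours with known PPIX content.

    The per-aliquot PPIX amount is ``ng_per_g × mass / dilution_factor``,
    matching the back-calculation in the quantification assay.  Returns
    ``(SpectrumCollection, amounts_ng, blank, truth)``.
    """
    ng_per_g = np.asarray(ng_per_g, dtype=float)
    mass_g = np.asarray(mass_g, dtype=float)
    amounts = ng_per_g * mass_g / dilution_factor
    coll, amounts, blank, truth = generate_fluorescence_standards(
        n_levels=max(3, len(amounts)), slope_truth=slope_truth,
        noise_rel=noise_rel, seed=seed, amounts=amounts,
    )
    for s, c in zip(coll.spectra, ng_per_g):
        s.meta["true_ng_per_g"] = f"{c:.6g}"
    return coll, amounts, blank, truth
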