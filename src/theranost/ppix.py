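"""PPIX tissue quantification from fluorescence spectra, plus PDT dosimetry.

Protoporphyrin IX (PPIX) content of dissolved tumour tissue is read from
fluorescence emission spectra: the spectrum is cropped to 450–750 nm, the
solvent blank is subtracted, the broad tissue autofluorescence is removed
with a low-stiffness asymmetric Whittaker baseline (λ = 10), the residual is
Savitzky–Golay smoothed (order 1, frame 7), and the PPIX emission band
around 630 nm is integrated.  A linear standard curve built from spiked
control tissue maps the integrated signal to a PPIX amount, which the
dilution chain (a 50 µL aliquot into 1 mL ⇒ 21×) and the tumour mass turn
into ng PPIX per g tissue.

Small dosimetry helpers convert photosensitiser mass concentrations to
molarity and PDT fluence/fluence-rate pairs to exposure times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .errors import ValidationError
from .preprocess import crop, savgol, whittaker_baseline
from .spectra_io import Spectrum

#: Molar masses (g/mol) of the three clinically employed photosensitisers.
PPIX_MOLAR_MASS = 562.66
TEMOPORFIN_MOLAR_MASS = 680.75
VERTEPORFIN_MOLAR_MASS = 718.79

#: 50 µL aliquot diluted in 1 mL of solvent: (1000 + 50) / 50.
ALIQUOT_DILUTION_FACTOR = (1000.0 + 50.0) / 50.0


@dataclass
class FluorQuantConfig:
    """Parameters of the fluorescence-processing chain and readout band.

    The λ = 10 background filter is far more flexible than the Raman
    baseline (λ = 1e5), so its first, symmetric iterate sits on top of the
    PPIX emission band; a strong asymmetry (p = 1e-5) and enough
    reweighting iterations to converge (50) are needed for the background
    to settle underneath the peak instead.
    """

    crop_lo_nm: float = 450.0
    crop_hi_nm: float = 750.0
    lam_bg: float = 10.0            # Whittaker penalty for autofluorescence
    asym_p: float = 1e-5
    bg_iters: int = 50
    sg_order: int = 1
    sg_frame: int = 7
    signal_band_nm: tuple = (620.0, 640.0)  # PPIX main emission ~630 nm

    def __post_init__(self):
        if not self.crop_lo_nm < self.crop_hi_nm:
            raise ValidationError("crop_lo_nm must be < crop_hi_nm")
        lo, hi = self.signal_band_nm
        if not (self.crop_lo_nm <= lo < hi <= self.crop_hi_nm):
            raise ValidationError("signal band must lie within the crop window")


def process_fluorescence(
    s: Spectrum, blank: Spectrum, cfg: FluorQuantConfig | None = None
) -> Spectrum:
    """Blank-subtract and background-correct a fluorescence emission spectrum.

    Stage order: crop to [450, 750] nm → subtract the solvent blank
    channelwise → subtract the asymmetric-Whittaker autofluorescence
    background (λ = 10) → Savitzky–Golay smooth (1, 7).
    """
    cfg = cfg or FluorQuantConfig()
    if s.axis_kind != "wavelength" or blank.axis_kind != "wavelength":
        raise ValidationError("fluorescence processing expects wavelength spectra")
    if len(s.axis) != len(blank.axis) or not np.array_equal(s.axis, blank.axis):
        raise ValidationError("sample and blank are on different wavelength grids")
    out = crop(s, cfg.crop_lo_nm, cfg.crop_hi_nm)
    blank_c = crop(blank, cfg.crop_lo_nm, cfg.crop_hi_nm)
    out = out.copy_with(intensity=out.intensity - blank_c.intensity)
    _, out = whittaker_baseline(out, lam=cfg.lam_bg, asym_p=cfg.asym_p,
                                iters=cfg.bg_iters)
    return savgol(out, order=cfg.sg_order, frame=cfg.sg_frame)


def integrate_signal(s: Spectrum, band_nm) -> float:
    """Trapezoidal integral of intensity over a wavelength band."""
    lo, hi = band_nm
    mask = (s.axis >= lo) & (s.axis <= hi)
    if mask.sum() < 2:
        raise ValidationError(f"band {band_nm} covers fewer than 2 channels")
    return float(np.trapezoid(s.intensity[mask], s.axis[mask]))


# ---------------------------------------------------------------------------
# standard curve (model / results)
# ---------------------------------------------------------------------------


@dataclass
class StandardCurve:
    """Fitted linear standard curve: signal = slope·amount + intercept."""

    slope: float                # signal per ng PPIX
    intercept: float            # signal at zero amount
    r_squared: float
    points: list = field(default_factory=list)  # (amount ng, signal)
    slope_stderr: float = float("nan")

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValidationError("standard curve needs at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError("r_squared must lie in [0, 1]")

    def invert(self, signal: float) -> float:
        """Back-calculate the amount (ng) producing ``signal``."""
        if self.slope == 0:
            raise ValidationError("zero slope: curve cannot be inverted")
        return (signal - self.intercept) / self.slope

    def summary(self) -> str:
        return "\n".join([
            "PPIX standard curve",
            "=" * 38,
            f"points:     {len(self.points)}",
            f"slope:      {self.slope:.6g} signal/ng (SE {self.slope_stderr:.3g})",
            f"intercept:  {self.intercept:.6g}",
            f"r-squared:  {self.r_squared:.5f}",
        ])


class StandardCurveModel:
    """OLS model for a fluorescence standard curve.

    ``StandardCurveModel(amounts, signals).fit()`` returns a
    :class:`StandardCurve` results object.
    """

    def __init__(self, amounts, signals):
        self.amounts = np.asarray(amounts, dtype=float)
        self.signals = np.asarray(signals, dtype=float)
        if self.amounts.shape != self.signals.shape or self.amounts.ndim != 1:
            raise ValidationError("amounts and signals must be equal-length vectors")
        if len(np.unique(self.amounts)) < 3:
            raise ValidationError("need at least 3 distinct standard amounts")

    def fit(self) -> StandardCurve:
        res = scipy.stats.linregress(self.amounts, self.signals)
        return StandardCurve(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            points=list(zip(self.amounts.tolist(), self.signals.tolist())),
            slope_stderr=float(res.stderr),
        )


def fit_standard_curve(amounts, signals) -> StandardCurve:
    """Functional wrapper around :class:`StandardCurveModel`."""
    return StandardCurveModel(amounts, signals).fit()


@dataclass
class QuantResult:
    """Back-calculated PPIX tissue concentration for one sample."""

    ng_per_g: float
    amount_ng: float            # amount in the measured aliquot, post-flooring
    clipped: bool               # True if a negative back-calculation was floored


def quantify_ppix(
    signal: float,
    curve: StandardCurve,
    dilution_factor: float = ALIQUOT_DILUTION_FACTOR,
    tumour_mass_g: float = 1.0,
) -> QuantResult:
    """Convert an integrated PPIX signal to ng PPIX per g tissue.

    ``amount = (signal − intercept) / slope`` scaled by the dilution factor
    and divided by the tumour mass.  Negative back-calculated amounts are
    floored at zero with a warning and flagged on the result.
    """
    if tumour_mass_g <= 0:
        raise ValidationError("tumour mass must be positive")
    amount = curve.invert(signal)
    clipped = False
    if amount < 0:
        warnings.warn(
            f"back-calculated PPIX amount {amount:.4g} ng is negative; floored to 0",
            stacklevel=2,
        )
        amount, clipped = 0.0, True
    return QuantResult(
        ng_per_g=amount * dilution_factor / tumour_mass_g,
        amount_ng=amount,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# dosimetry helpers
# ---------------------------------------------------------------------------


def _round_sig(x: float, sig: int = 3) -> float:
    return float(f"{x:.{sig}g}")


def mass_to_molar(c_mass_ng_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert ng/mL to µM for a compound of the given molar mass.

    1 ng/mL = 1 µg/L, so µmol/L = (ng/mL) / (g/mol) exactly; the result is
    reported to 3 significant figures.
    """
    if c_mass_ng_per_ml <= 0 or molar_mass_g_per_mol <= 0:
        raise ValidationError("concentration and molar mass must be positive")
    return _round_sig(c_mass_ng_per_ml / molar_mass_g_per_mol, 3)


def exposure_time(fluence_j_per_cm2: float, fluence_rate_mw_per_cm2: float) -> float:
    """Seconds of illumination delivering ``fluence`` at ``fluence_rate``."""
    if fluence_j_per_cm2 <= 0 or fluence_rate_mw_per_cm2 <= 0:
        raise ValidationError("fluence and fluence rate must be positive")
    return fluence_j_per_cm2 / (fluence_rate_mw_per_cm2 / 1000.0)
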