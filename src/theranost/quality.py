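"""Spectral quality statistics and treatment-monitoring arithmetic.

Covers the replicate-level statistics used to judge Raman acquisitions
(signal-to-noise ratio from a silent noise band, mean spectral coefficient
of variation), group-contrast tools (difference spectra, windowed peak
intensities), and the longitudinal monitoring arithmetic (peak time courses
normalised to baseline, 1.5×IQR outlier flagging, Welch's t-test,
normalized tumour growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import ValidationError
from .spectra_io import Spectrum, SpectrumCollection


@dataclass
class BandDef:
    """Signal and noise band definition for the replicate SNR statistic.

    The SNR numerator is the windowed peak intensity at ``signal_peak``
    (default 1650 cm⁻¹, the amide I band); the denominator is the noise
    estimated in the spectroscopically silent region
    [``noise_lo``, ``noise_hi``] (default 1780–1820 cm⁻¹).
    """

    center: float = 1650.0
    window_half_width: float = 10.0
    noise_lo: float = 1780.0
    noise_hi: float = 1820.0
    signal_peak: float = 1650.0

    def __post_init__(self):
        if not self.noise_lo < self.noise_hi:
            raise ValidationError("noise_lo must be < noise_hi")


def peak_intensity(s: Spectrum, center: float, half_width: float = 10.0) -> float:
    """Maximum intensity within ``center ± half_width`` on the axis."""
    mask = (s.axis >= center - half_width) & (s.axis <= center + half_width)
    if not mask.any():
        raise ValidationError(
            f"window {center}±{half_width} contains no channels"
        )
    return float(np.max(s.intensity[mask]))


def snr(coll: SpectrumCollection, band: BandDef | None = None) -> float:
    """Replicate signal-to-noise ratio of a collection.

    numerator: mean over replicates of the peak intensity near
    ``band.signal_peak``; denominator: per-channel sample SD (ddof=1) across
    replicates, averaged over channels in the silent noise band.
    """
    band = band or BandDef()
    axis = coll.require_shared_axis()
    if len(coll) < 2:
        raise ValidationError("SNR needs at least 2 replicate spectra")
    peaks = [peak_intensity(s, band.signal_peak, band.window_half_width)
             for s in coll.spectra]
    numerator = float(np.mean(peaks))
    mask = (axis >= band.noise_lo) & (axis <= band.noise_hi)
    if not mask.any():
        raise ValidationError("noise band is empty on this axis")
    X = coll.to_matrix()
    denom = float(np.mean(np.std(X[:, mask], axis=0, ddof=1)))
    if denom == 0:
        raise ValidationError("zero noise estimate: replicates identical in noise band")
    return numerator / denom


def spectral_cv(coll: SpectrumCollection) -> float:
    """Mean spectral coefficient of variation across replicates.

    Per-channel SD across replicates divided by the per-channel absolute
    mean, averaged over channels whose |mean| exceeds 1e-12 of the maximum
    |mean| (near-zero-mean channels would blow the ratio up).
    """
    coll.require_shared_axis()
    if len(coll) < 2:
        raise ValidationError("spectral CV needs at least 2 replicates")
    X = coll.to_matrix()
    mu = np.abs(X.mean(axis=0))
    sd = X.std(axis=0, ddof=1)
    keep = mu > 1e-12 * mu.max()
    if not keep.any():
        raise ValidationError("all channels have near-zero mean")
    return float(np.mean(sd[keep] / mu[keep]))


def difference_spectrum(
    group_a: SpectrumCollection, group_b: SpectrumCollection
) -> Spectrum:
    """Channelwise mean(A) − mean(B) on a shared axis."""
    ax_a = group_a.require_shared_axis()
    ax_b = group_b.require_shared_axis()
    if len(ax_a) != len(ax_b) or not np.array_equal(ax_a, ax_b):
        raise ValidationError("groups do not share an axis")
    diff = group_a.to_matrix().mean(axis=0) - group_b.to_matrix().mean(axis=0)
    return group_a.spectra[0].copy_with(
        intensity=diff,
        meta={"n_a": str(len(group_a)), "n_b": str(len(group_b)),
              "role": "difference"},
    )


def monitoring_timecourse(
    diffs_by_day: dict,
    center: float = 1440.0,
    half_width: float = 10.0,
    absolute: bool = False,
) -> dict:
    """Peak time course of difference spectra, normalised to day 0.

    ``value(day) = peak(diff(day)) / peak(diff(0))`` with the windowed-max
    peak statistic; ``absolute=True`` takes the windowed maximum of
    |intensity| instead (for difference features that are negative-going).
    """
    if 0 not in diffs_by_day:
        raise ValidationError("day 0 difference spectrum is required")

    def _peak(s: Spectrum) -> float:
        if absolute:
            return peak_intensity(s.copy_with(intensity=np.abs(s.intensity)),
                                  center, half_width)
        return peak_intensity(s, center, half_width)

    d0 = _peak(diffs_by_day[0])
    if d0 == 0:
        raise ValidationError("day-0 peak is zero; cannot normalise")
    return {day: _peak(s) / d0 for day, s in sorted(diffs_by_day.items())}


def iqr_outliers(values) -> np.ndarray:
    """1.5×IQR outlier mask with type-7 (linear interpolation) quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("IQR outlier test needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (values < lo) | (values > hi)


def welch_t(a, b):
    """Two-tailed Welch's t-test.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and the
    p-value from the t survival function, clipped to (0, 1].  Two
    zero-variance groups with equal means give (0, inf-free) p = 1; zero
    variance with unequal means is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValidationError(
            "zero variance in both groups with unequal means: t undefined"
        )
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(min(max(2.0 * scipy.stats.t.sf(abs(t), df), np.nextafter(0, 1)), 1.0))
    return float(t), float(df), p


def normalized_growth(signal_by_day: dict, baseline_day=0) -> dict:
    """Divide each day's size signal by the baseline day's value.

    The signal is typically a bioluminescence total flux acting as a
    tumour-burden proxy; day ``baseline_day`` maps to exactly 1.
    """
    if baseline_day not in signal_by_day:
        raise ValidationError(f"baseline day {baseline_day} missing")
    base = float(signal_by_day[baseline_day])
    if base <= 0:
        raise ValidationError("baseline signal must be positive")
    return {day: float(v) / base for day, v in sorted(signal_by_day.items())}
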