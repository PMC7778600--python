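"""Raman spectrum preprocessing chain.

The chain mirrors the processing applied to fibreoptic and confocal Raman
acquisitions of tissue and cells before chemometric analysis:

1. **crop** to the fingerprint region (default 510–1825 cm⁻¹);
2. **baseline subtraction** with an asymmetric penalized-least-squares
   (Whittaker) smoother, penalty λ = 100 000 by default, which estimates and
   removes the broad fluorescence background that sits under the narrow
   Raman bands;
3. **despiking** of cosmic-ray artefacts via a modified z-score on the
   first-difference series;
4. **Savitzky–Golay smoothing** (1st order, frame 7);
5. **area-under-curve normalization**.

Mean-centering is deliberately *not* part of the per-spectrum chain: it is a
collection-level operation that belongs to model fitting (and must be learnt
on training folds only during cross-validation).

Baseline model
--------------
The Whittaker baseline ``z`` minimizes

    sum_i w_i (y_i - z_i)^2  +  λ sum_i (Δ² z_i)^2

with second differences taken on the channel index (unit spacing), solved
from the banded normal equations ``(W + λ DᵀD) z = W y``.  The weights are
re-estimated iteratively: ``w_i = p`` where ``y_i > z_i`` (points above the
baseline, i.e. peaks, barely pull on it) and ``w_i = 1 − p`` otherwise, with
a small asymmetry parameter ``p`` (default 0.001).  In the symmetric limit
this is a plain Whittaker smoother; λ → ∞ drives the baseline to the
ordinary-least-squares straight line through the data, λ → 0 reproduces the
data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.signal
import scipy.sparse
import yaml

from .errors import StageError, ValidationError
from .spectra_io import Spectrum, SpectrumCollection


@dataclass
class PreprocessConfig:
    """Parameters of the Raman preprocessing chain.

    Defaults are the values used throughout the package for tissue and cell
    spectra: fingerprint crop 510–1825 cm⁻¹, baseline penalty λ = 1e5,
    Savitzky–Golay order 1 / frame 7, area normalization on.
    """

    crop_lo: float = 510.0          # cm-1
    crop_hi: float = 1825.0         # cm-1
    lam: float = 100_000.0          # Whittaker penalty, dimensionless
    asym_p: float = 0.001           # asymmetry weight in (0, 1)
    baseline_iters: int = 10
    spike_z: float = 8.0            # modified-z despike threshold
    sg_order: int = 1
    sg_frame: int = 7               # odd window length
    normalize: str = "auc"          # "auc" or "none"
    mean_center: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.crop_lo < self.crop_hi:
            raise ValidationError("crop_lo must be < crop_hi")
        if self.lam <= 0:
            raise ValidationError("lam must be positive")
        if not 0 < self.asym_p < 1:
            raise ValidationError("asym_p must lie in (0, 1)")
        if self.baseline_iters < 1:
            raise ValidationError("baseline_iters must be >= 1")
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_order:
            raise ValidationError("sg_frame must be odd and > sg_order")
        if self.normalize not in ("auc", "none"):
            raise ValidationError("normalize must be 'auc' or 'none'")

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to the closed axis interval [lo, hi]."""
    mask = (s.axis >= lo) & (s.axis <= hi)
    if not mask.any():
        raise ValidationError("crop window excludes all channels")
    return s.copy_with(axis=s.axis[mask], intensity=s.intensity[mask])


def asls_baseline(
    y: np.ndarray,
    lam: float = 100_000.0,
    asym_p: float = 0.001,
    iters: int = 10,
    return_weights: bool = False,
):
    """Asymmetric penalized-least-squares baseline of a raw intensity vector.

    Solves ``(W + λ DᵀD) z = W y`` with the pentadiagonal second-difference
    penalty via a symmetric banded Cholesky solve, re-estimating the
    asymmetric weights up to ``iters`` times (early exit on weight
    convergence).  With ``return_weights=True`` the weights used in the
    final solve are returned alongside the baseline, so the solution can be
    checked against an independent solve of the same weighted system.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValidationError(
            "baseline needs at least 4 channels (second differences undefined)"
        )
    D = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    K = (lam * (D.T @ D)).tocsr()
    # upper banded storage for solveh_banded: rows = superdiag2, superdiag1, diag
    ab0 = np.zeros((3, n))
    ab0[0, 2:] = K.diagonal(2)
    ab0[1, 1:] = K.diagonal(1)
    kdiag = K.diagonal(0)

    def residual(w, z):
        # (W + lam D'D) z suffers heavy cancellation at large lam; evaluate
        # the second-difference stencil in extended precision so iterative
        # refinement can converge to the true solution of the weighted system
        zl = z.astype(np.longdouble)
        d2 = zl[2:] - 2.0 * zl[1:-1] + zl[:-2]
        back = np.zeros_like(zl)
        back[2:] += d2
        back[1:-1] -= 2.0 * d2
        back[:-2] += d2
        r = w * y.astype(np.longdouble) - (w * zl + np.longdouble(lam) * back)
        return r.astype(float)

    w = np.ones(n)
    z = y
    w_used = w
    for _ in range(iters):
        ab = ab0.copy()
        ab[2] = kdiag + w
        z = scipy.linalg.solveh_banded(ab, w * y)
        # two refinement steps: the normal equations are badly conditioned
        # at large lambda and the raw banded solve loses several digits
        for _ in range(2):
            z = z + scipy.linalg.solveh_banded(ab, residual(w, z))
        w_used = w
        w_new = np.where(y > z, asym_p, 1.0 - asym_p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    if return_weights:
        return z, w_used
    return z


def whittaker_baseline(
    s: Spectrum,
    lam: float = 100_000.0,
    asym_p: float = 0.001,
    iters: int = 10,
):
    """Estimate and subtract the fluorescence baseline of a spectrum.

    Returns ``(baseline, corrected)`` spectra; the corrected intensities are
    unclipped (small negative residuals are kept).
    """
    z = asls_baseline(s.intensity, lam=lam, asym_p=asym_p, iters=iters)
    return s.copy_with(intensity=z), s.copy_with(intensity=s.intensity - z)


def _modified_z(d: np.ndarray) -> np.ndarray:
    med = np.median(d)
    dev = np.abs(d - med)
    mad = np.median(dev)
    if mad > 0:
        return 0.6745 * dev / mad
    return np.where(dev > 0, np.inf, 0.0)


def find_spikes(y: np.ndarray, spike_z: float = 8.0, max_span: int = 4) -> np.ndarray:
    """Boolean mask of cosmic-ray channels.

    A cosmic spike produces an anomalous up-jump followed by an anomalous
    down-jump in the first-difference series (or vice versa for a negative
    artefact).  Gaps whose modified z-score ``0.6745·|Δy − median Δy| / MAD``
    exceeds ``spike_z`` are flagged; opposite-signed flagged gaps within
    ``max_span`` channels are paired and the channels strictly between them
    marked as spike channels, so single-channel spikes flag exactly one
    channel and runs of adjacent spikes are flagged as a block.  An
    *isolated* unpaired anomalous gap (both neighbouring gaps ordinary) is
    treated as a step artefact and flags both endpoint channels; runs of
    same-signed anomalous gaps are genuine steep spectral slopes and are
    left untouched.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValidationError("despike needs at least 5 channels")
    d = np.diff(y)
    z = _modified_z(d)
    med = np.median(d)
    hot = np.flatnonzero(z > spike_z)
    flags = np.zeros(n, dtype=bool)
    used = np.zeros(len(hot), dtype=bool)
    for a, j in enumerate(hot):
        if used[a]:
            continue
        sj = 1.0 if d[j] >= med else -1.0
        for b in range(a + 1, len(hot)):
            k = hot[b]
            if k - j > max_span:
                break
            if used[b]:
                continue
            sk = 1.0 if d[k] >= med else -1.0
            if sk == -sj:
                flags[j + 1 : k + 1] = True
                used[a] = used[b] = True
                break
    hotset = set(hot.tolist())
    for a, j in enumerate(hot):  # isolated unmatched jumps: step artefacts
        if not used[a] and (j - 1) not in hotset and (j + 1) not in hotset:
            flags[j] = True
            flags[j + 1] = True
    return flags


def despike(s: Spectrum, spike_z: float = 8.0) -> Spectrum:
    """Remove cosmic-ray spikes by interpolating across flagged channels.

    Unflagged channels are returned bit-identical to the input.
    """
    flags = find_spikes(s.intensity, spike_z=spike_z)
    if flags.mean() > 0.5:
        raise ValidationError(
            "degenerate spectrum: majority of channels flagged as spikes"
        )
    if not flags.any():
        return s.copy_with()
    y = s.intensity.copy()
    good = np.flatnonzero(~flags)
    bad = np.flatnonzero(flags)
    y[bad] = np.interp(bad, good, y[good])
    return s.copy_with(intensity=y)


def savgol(s: Spectrum, order: int = 1, frame: int = 7) -> Spectrum:
    """Savitzky–Golay smoothing with truncated one-sided windows at the edges.

    Interior channels are the centre values of degree-``order`` polynomial
    least-squares fits over the symmetric ``frame``-point window; each edge
    channel is re-fit on the window truncated at the spectrum boundary so the
    spectrum is never shortened.
    """
    if frame % 2 == 0 or frame <= order:
        raise ValidationError("frame must be odd and > order")
    n = len(s.intensity)
    if frame >= n:
        raise ValidationError(f"frame {frame} must be < spectrum length {n}")
    half = frame // 2
    y = s.intensity
    out = scipy.signal.savgol_filter(y, frame, order)
    idx = np.arange(n, dtype=float)
    for i in range(half):
        w = slice(0, i + half + 1)
        coef = np.polynomial.polynomial.polyfit(idx[w], y[w], order)
        out[i] = np.polynomial.polynomial.polyval(idx[i], coef)
    for i in range(n - half, n):
        w = slice(i - half, n)
        coef = np.polynomial.polynomial.polyfit(idx[w], y[w], order)
        out[i] = np.polynomial.polynomial.polyval(idx[i], coef)
    return s.copy_with(intensity=out)


def normalize_auc(s: Spectrum) -> Spectrum:
    """Divide intensities by the trapezoidal area over the physical axis."""
    area = np.trapezoid(s.intensity, s.axis)
    if area <= 0:
        raise ValidationError("cannot AUC-normalize: nonpositive total area")
    return s.copy_with(intensity=s.intensity / area)


def mean_center(coll: SpectrumCollection):
    """Subtract the per-channel mean spectrum from a shared-axis collection.

    Returns ``(centered_collection, mean_spectrum)``.
    """
    axis = coll.require_shared_axis()
    if len(coll) < 2:
        raise ValidationError("mean centering needs at least 2 spectra")
    X = coll.to_matrix()
    mu = X.mean(axis=0)
    centered = SpectrumCollection(
        spectra=[s.copy_with(intensity=s.intensity - mu) for s in coll.spectra],
        labels=list(coll.labels) if coll.labels is not None else None,
    )
    mean_spec = coll.spectra[0].copy_with(intensity=mu, meta={"role": "mean"})
    assert mean_spec.axis.shape == axis.shape
    return centered, mean_spec


_STAGES = ("crop", "baseline", "despike", "savgol", "normalize")


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Apply the full per-spectrum chain (crop → baseline → despike → smooth
    → normalize) to one spectrum, wrapping stage failures with the stage name."""
    stage = "crop"
    try:
        out = crop(s, cfg.crop_lo, cfg.crop_hi)
        stage = "baseline"
        _, out = whittaker_baseline(
            out, lam=cfg.lam, asym_p=cfg.asym_p, iters=cfg.baseline_iters
        )
        stage = "despike"
        out = despike(out, spike_z=cfg.spike_z)
        stage = "savgol"
        out = savgol(out, order=cfg.sg_order, frame=cfg.sg_frame)
        if cfg.normalize == "auc":
            stage = "normalize"
            out = normalize_auc(out)
        return out
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc


def preprocess_collection(
    coll: SpectrumCollection, cfg: PreprocessConfig | None = None
) -> SpectrumCollection:
    """Apply :func:`preprocess_spectrum` independently to every member.

    No information flows between spectra here; mean-centering (which does)
    is left to the modelling step.  An empty collection passes through.
    """
    cfg = cfg or PreprocessConfig()
    return SpectrumCollection(
        spectra=[preprocess_spectrum(s, cfg) for s in coll.spectra],
        labels=list(coll.labels) if coll.labels is not None else None,
    )
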