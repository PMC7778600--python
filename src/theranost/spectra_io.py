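"""Spectra containers and delimited-text I/O.

A :class:`Spectrum` is the atomic unit of the package: one monotonically
increasing axis (Raman shift in cm⁻¹ or wavelength in nm), one intensity
vector, and a flat string-valued metadata map.  A
:class:`SpectrumCollection` is an ordered set of spectra, optionally sharing
an axis, with per-spectrum group labels.

Two text layouts are supported:

* ``wide``  — first column is the axis, one further column per spectrum
  (requires a shared axis);
* ``long``  — three columns ``spectrum_id, axis, intensity``, allowing
  heterogeneous axes.

Metadata travels in a JSON sidecar next to the data file
(``<stem>.meta.json``) holding the axis kind, labels, and per-spectrum
metadata.  Axes are stored at full precision and never resampled on I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

AXIS_KINDS = ("raman_shift", "wavelength")

#: Minimum number of channels for a physically meaningful spectrum.
MIN_CHANNELS = 8


@dataclass
class Spectrum:
    """A single-point spectrum: axis, intensity, and metadata.

    Parameters
    ----------
    axis
        Strictly increasing axis values (cm⁻¹ for Raman shift, nm for
        wavelength).
    intensity
        Intensity counts, same length as ``axis``, all finite.
    axis_kind
        ``"raman_shift"`` or ``"wavelength"``.
    meta
        Flat key → string map (subject_id, tissue_class, timepoint_days, ...).
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "raman_shift"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValidationError(
                f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}"
            )
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("axis and intensity must be 1-D vectors")
        if len(self.axis) != len(self.intensity):
            raise ValidationError(
                f"axis length {len(self.axis)} != intensity length {len(self.intensity)}"
            )
        if len(self.axis) < MIN_CHANNELS:
            raise ValidationError(
                f"spectrum needs at least {MIN_CHANNELS} channels, got {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.axis)):
            raise ValidationError("axis contains non-finite values")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity contains non-finite values")
        if np.any(np.diff(self.axis) <= 0):
            name = self.meta.get("spectrum_id", "<unnamed>")
            raise ValidationError(
                f"axis of spectrum {name!r} is not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.axis)

    def copy_with(self, intensity=None, axis=None, meta=None) -> "Spectrum":
        """Return a copy, optionally replacing intensity/axis/meta."""
        return Spectrum(
            axis=self.axis.copy() if axis is None else np.asarray(axis, float),
            intensity=self.intensity.copy()
            if intensity is None
            else np.asarray(intensity, float),
            axis_kind=self.axis_kind,
            meta=dict(self.meta) if meta is None else dict(meta),
        )


@dataclass
class SpectrumCollection:
    """Ordered set of spectra with optional per-spectrum class labels."""

    spectra: list
    labels: list | None = None

    def __post_init__(self):
        self.spectra = list(self.spectra)
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != len(self.spectra):
                raise ValidationError(
                    f"{len(self.labels)} labels for {len(self.spectra)} spectra"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def shared_axis(self) -> np.ndarray | None:
        """The common axis if every member shares one, else ``None``."""
        if not self.spectra:
            return None
        first = self.spectra[0].axis
        for s in self.spectra[1:]:
            if len(s.axis) != len(first) or not np.array_equal(s.axis, first):
                return None
        return first

    def require_shared_axis(self) -> np.ndarray:
        ax = self.shared_axis
        if ax is None:
            raise ValidationError("operation requires a shared axis across spectra")
        return ax

    def to_matrix(self) -> np.ndarray:
        """Stack intensities into a (n_spectra, n_channels) matrix."""
        self.require_shared_axis()
        return np.vstack([s.intensity for s in self.spectra])

    @classmethod
    def from_matrix(
        cls,
        axis: np.ndarray,
        X: np.ndarray,
        axis_kind: str = "raman_shift",
        labels: Sequence | None = None,
        metas: Sequence[dict] | None = None,
    ) -> "SpectrumCollection":
        X = np.atleast_2d(np.asarray(X, float))
        metas = metas if metas is not None else [{} for _ in range(X.shape[0])]
        spectra = [
            Spectrum(axis=np.asarray(axis, float), intensity=row,
                     axis_kind=axis_kind, meta=dict(m))
            for row, m in zip(X, metas)
        ]
        return cls(spectra=spectra, labels=list(labels) if labels is not None else None)

    def subset(self, idx) -> "SpectrumCollection":
        idx = list(idx)
        return SpectrumCollection(
            spectra=[self.spectra[i] for i in idx],
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def _spectrum_ids(coll: SpectrumCollection) -> list:
    ids = []
    for i, s in enumerate(coll.spectra):
        ids.append(str(s.meta.get("spectrum_id", f"s{i:04d}")))
    if len(set(ids)) != len(ids):  # enforce uniqueness for column/group keys
        ids = [f"s{i:04d}" for i in range(len(coll.spectra))]
    return ids


def write_spectra(coll: SpectrumCollection, path, format: str = "wide") -> Path:
    """Write a collection as delimited text plus a JSON metadata sidecar.

    ``wide`` requires a shared axis; use ``long`` for heterogeneous axes.
    """
    path = Path(path)
    ids = _spectrum_ids(coll)
    if format == "wide":
        if len(coll) and coll.shared_axis is None:
            raise ValidationError(
                "wide format requires a shared axis; write heterogeneous "
                "collections in long format"
            )
        axis = coll.shared_axis
        data = {"axis": axis if axis is not None else []}
        for sid, s in zip(ids, coll.spectra):
            data[sid] = s.intensity
        df = pd.DataFrame(data)
    elif format == "long":
        frames = []
        for sid, s in zip(ids, coll.spectra):
            frames.append(
                pd.DataFrame(
                    {"spectrum_id": sid, "axis": s.axis, "intensity": s.intensity}
                )
            )
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["spectrum_id", "axis", "intensity"])
        )
    else:
        raise ValidationError(f"unknown format {format!r}")

    df.to_csv(path, index=False, float_format="%.17g")

    sidecar = {
        "format": format,
        "axis_kind": coll.spectra[0].axis_kind if len(coll) else "raman_shift",
        "labels": coll.labels,
        "spectra": {sid: {k: str(v) for k, v in s.meta.items()}
                    for sid, s in zip(ids, coll.spectra)},
        "order": ids,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_table(path: Path) -> pd.DataFrame:
    # comma/tab auto-detection; ragged rows surface as NaN cells below
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return df


def read_spectra(path, format: str | None = None) -> SpectrumCollection:
    """Read a collection written by :func:`write_spectra`.

    ``format`` may be ``"wide"``, ``"long"``, or ``None`` to infer from the
    sidecar (falling back to column-name detection).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    if format is None:
        format = sidecar.get("format")

    df = _read_table(path)
    if format is None:
        format = "long" if "spectrum_id" in df.columns else "wide"

    axis_kind = sidecar.get("axis_kind", "raman_shift")
    metas = sidecar.get("spectra", {})
    labels = sidecar.get("labels")

    def _check_numeric(col: pd.Series, name: str):
        vals = pd.to_numeric(col, errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(float)))[0]
        if bad.size:
            # +2: header line plus 1-based indexing
            raise ParseError(
                f"non-numeric or missing value in column {name!r} "
                f"at line {bad[0] + 2} of {path.name}"
            )
        return vals.to_numpy(float)

    spectra = []
    if format == "wide":
        if df.shape[1] < 2:
            raise ParseError(f"wide file {path.name} needs axis + >=1 spectrum column")
        axis = _check_numeric(df.iloc[:, 0], df.columns[0])
        for col in df.columns[1:]:
            inten = _check_numeric(df[col], col)
            meta = dict(metas.get(str(col), {}))
            meta.setdefault("spectrum_id", str(col))
            spectra.append(
                Spectrum(axis=axis.copy(), intensity=inten,
                         axis_kind=axis_kind, meta=meta)
            )
    elif format == "long":
        for need in ("spectrum_id", "axis", "intensity"):
            if need not in df.columns:
                raise ParseError(f"long file {path.name} lacks column {need!r}")
        order = sidecar.get("order") or list(dict.fromkeys(df["spectrum_id"].astype(str)))
        grouped = {str(k): g for k, g in df.groupby("spectrum_id", sort=False)}
        for sid in order:
            g = grouped[str(sid)]
            axis = _check_numeric(g["axis"], "axis")
            inten = _check_numeric(g["intensity"], "intensity")
            meta = dict(metas.get(str(sid), {}))
            meta.setdefault("spectrum_id", str(sid))
            spectra.append(
                Spectrum(axis=axis, intensity=inten, axis_kind=axis_kind, meta=meta)
            )
    else:
        raise ValidationError(f"unknown format {format!r}")

    return SpectrumCollection(spectra=spectra, labels=labels)
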