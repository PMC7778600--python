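"""End-to-end study workflows: diagnose, monitor, quantify.

Each runner reads delimited-text inputs, executes the corresponding
analysis chain, and writes a report directory of plain CSV tables plus a
JSON run manifest (config snapshot, input/output digests, per-stage wall
times).  Reports are deterministic: identical inputs and configuration
produce byte-identical CSV payloads.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import PLSDAConfig, cross_validate
from .errors import StageError, ValidationError
from .ppix import (
    ALIQUOT_DILUTION_FACTOR,
    FluorQuantConfig,
    fit_standard_curve,
    integrate_signal,
    process_fluorescence,
    quantify_ppix,
)
from .preprocess import PreprocessConfig, preprocess_collection
from .quality import (
    difference_spectrum,
    iqr_outliers,
    monitoring_timecourse,
    normalized_growth,
    peak_intensity,
    welch_t,
)
from .spectra_io import read_spectra, write_spectra

_CSV_FLOAT = "%.10g"


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class RunManifest:
    """Ordered per-stage record of a pipeline run."""

    def __init__(self, workflow: str, config: dict, inputs: dict, seed=None):
        self.data = {
            "workflow": workflow,
            "tool_version": __version__,
            "seed": seed,
            "config": config,
            "inputs": {k: _digest(v) for k, v in inputs.items()},
            "stages": [],
        }

    def stage(self, name: str, **params):
        rec = {"name": name, "parameters": params, "outputs": {}, "wall_time_s": None}
        self.data["stages"].append(rec)
        return _StageTimer(rec)

    def add_output(self, path: Path):
        if self.data["stages"]:
            self.data["stages"][-1]["outputs"][Path(path).name] = _digest(path)

    def write(self, path: Path):
        names = [s["name"] for s in self.data["stages"]]
        assert len(names) == len(set(names)), "stages must be listed exactly once"
        Path(path).write_text(json.dumps(self.data, indent=1))


class _StageTimer:
    def __init__(self, rec):
        self.rec = rec

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.rec["wall_time_s"] = round(time.perf_counter() - self.t0, 4)
        return False


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest, index=False):
    df.to_csv(path, index=index, float_format=_CSV_FLOAT)
    manifest.add_output(path)


# ---------------------------------------------------------------------------
# diagnosis
# ---------------------------------------------------------------------------


def run_diagnosis(
    spectra_path,
    labels_path,
    out_dir,
    preprocess_cfg: PreprocessConfig | None = None,
    plsda_cfg: PLSDAConfig | None = None,
) -> Path:
    """Preprocess → PLS-DA Venetian-blinds CV → accuracy/confusion/scores report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pre = preprocess_cfg or PreprocessConfig()
    cfg = plsda_cfg or PLSDAConfig()
    labels_path = Path(labels_path)
    if not labels_path.exists():
        raise StageError("read_inputs", f"labels file not found: {labels_path}")
    manifest = RunManifest(
        "diagnosis", {"preprocess": asdict(pre), "plsda": asdict(cfg)},
        {"spectra": spectra_path, "labels": labels_path},
    )
    with manifest.stage("read_inputs"):
        coll = read_spectra(spectra_path)
        lab_df = pd.read_csv(labels_path)
        if "label" not in lab_df.columns:
            raise StageError("read_inputs", "labels file needs a 'label' column")
        labels = lab_df["label"].astype(str).tolist()
        if len(labels) != len(coll):
            raise StageError(
                "read_inputs",
                f"{len(labels)} labels for {len(coll)} spectra",
            )
    with manifest.stage("preprocess", **asdict(pre)):
        proc = preprocess_collection(coll, pre)
    with manifest.stage("cross_validate", n_lv=cfg.n_lv, splits=cfg.cv_splits):
        cv = cross_validate(proc.to_matrix(), labels, cfg)
    with manifest.stage("report"):
        _write_csv(pd.DataFrame({"metric": ["cv_accuracy"], "value": [cv.accuracy]}),
                   out_dir / "metrics.csv", manifest)
        _write_csv(cv.confusion, out_dir / "confusion.csv", manifest, index=True)
        scores = pd.DataFrame(
            cv.scores, columns=[f"LV{a + 1}" for a in range(cv.scores.shape[1])]
        )
        scores.insert(0, "label", labels)
        scores.insert(1, "fold", cv.fold_of)
        scores.insert(2, "predicted", cv.predicted)
        _write_csv(scores, out_dir / "scores.csv", manifest)
    manifest.write(out_dir / "manifest.json")
    return out_dir


# ---------------------------------------------------------------------------
# monitoring
# ---------------------------------------------------------------------------


def _study_files(study_dir: Path):
    """Discover `{arm}_day{D}_{site}.csv` collections in a study directory."""
    found = {}
    for p in sorted(study_dir.glob("*_day*_*.csv")):
        stem = p.stem
        if stem.endswith(".meta"):
            continue
        try:
            arm, daypart, site = stem.rsplit("_", 2)
            day = int(daypart.removeprefix("day"))
        except ValueError:
            continue
        found[(arm, day, site)] = p
    return found


def run_monitoring(
    study_dir,
    out_dir,
    peak_center: float = 1440.0,
    half_width: float = 10.0,
    preprocess_cfg: PreprocessConfig | None = None,
    bli_path=None,
) -> Path:
    """Difference-spectrum monitoring of a two-arm longitudinal study.

    Expects per-(arm, day, site) wide-format collections named
    ``{arm}_day{D}_{tumour|flank}.csv`` with ``subject_id`` metadata.  Per
    subject and day, the tumour-minus-flank difference spectrum is reduced
    to the windowed peak statistic near ``peak_center`` and normalised to
    that subject's day-0 value; arms are compared per day with Welch's
    t-test.  If a BLI table (columns subject_id, day, flux) is supplied the
    normalized-growth table is emitted with 1.5×IQR outliers flagged.
    """
    study_dir, out_dir = Path(study_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pre = preprocess_cfg or PreprocessConfig()
    files = _study_files(study_dir)
    if not files:
        raise StageError("read_inputs", f"no study collections found in {study_dir}")
    arms = sorted({k[0] for k in files})
    days = sorted({k[1] for k in files})
    if 0 not in days:
        raise StageError("read_inputs", "day 0 collections are required")
    inputs = {f"{a}_day{d}_{s}": p for (a, d, s), p in files.items()}
    if bli_path is not None:
        inputs["bli"] = bli_path
    manifest = RunManifest(
        "monitoring",
        {"preprocess": asdict(pre), "peak_center": peak_center,
         "half_width": half_width},
        inputs,
    )

    with manifest.stage("preprocess", **asdict(pre)):
        proc = {}
        for key, path in files.items():
            proc[key] = preprocess_collection(read_spectra(path), pre)

    with manifest.stage("difference_spectra"):
        # per-subject tumour-vs-flank difference at each (arm, day)
        per_subject_diff = {}
        for arm in arms:
            for day in days:
                tum = proc.get((arm, day, "tumour"))
                fla = proc.get((arm, day, "flank"))
                if tum is None or fla is None:
                    raise StageError(
                        "difference_spectra",
                        f"missing tumour/flank pair for {arm} day {day}",
                    )
                subjects = sorted(
                    {s.meta.get("subject_id", "?") for s in tum.spectra}
                )
                for subj in subjects:
                    ti = [i for i, s in enumerate(tum.spectra)
                          if s.meta.get("subject_id", "?") == subj]
                    fi = [i for i, s in enumerate(fla.spectra)
                          if s.meta.get("subject_id", "?") == subj]
                    per_subject_diff[(arm, day, subj)] = difference_spectrum(
                        tum.subset(ti), fla.subset(fi)
                    )

    with manifest.stage("timecourse", peak=peak_center, half_width=half_width):
        rows = []
        subjects_by_arm = {
            arm: sorted({k[2] for k in per_subject_diff if k[0] == arm})
            for arm in arms
        }
        course = {}
        for arm in arms:
            for subj in subjects_by_arm[arm]:
                diffs = {d: per_subject_diff[(arm, d, subj)] for d in days}
                vals = monitoring_timecourse(diffs, peak_center, half_width)
                course[(arm, subj)] = vals
                for d, v in vals.items():
                    rows.append({"arm": arm, "subject_id": subj, "day": d,
                                 "peak_ratio_vs_day0": v})
        tc_df = pd.DataFrame(rows)
        _write_csv(tc_df, out_dir / "timecourse.csv", manifest)

    with manifest.stage("welch_tests"):
        test_rows = []
        if len(arms) == 2:
            a0, a1 = arms
            for d in days:
                if d == 0:
                    continue  # both arms are 1 by construction at day 0
                va = [course[(a0, s)][d] for s in subjects_by_arm[a0]]
                vb = [course[(a1, s)][d] for s in subjects_by_arm[a1]]
                t, df_, p = welch_t(va, vb)
                test_rows.append({"day": d, "arm_a": a0, "arm_b": a1,
                                  "t": t, "df": df_, "p": p})
        _write_csv(pd.DataFrame(test_rows), out_dir / "welch.csv", manifest)

    if bli_path is not None:
        with manifest.stage("normalized_growth"):
            bli = pd.read_csv(bli_path)
            growth_rows = []
            for (subj,), g in bli.groupby(["subject_id"]):
                series = dict(zip(g["day"].astype(int), g["flux"].astype(float)))
                arm = str(g["arm"].iloc[0]) if "arm" in g else ""
                for d, v in normalized_growth(series, baseline_day=0).items():
                    growth_rows.append({"subject_id": subj, "arm": arm,
                                        "day": d, "normalized_growth": v})
            gdf = pd.DataFrame(growth_rows)
            gdf["outlier"] = False
            for d in sorted(gdf["day"].unique()):
                if d == 0:
                    continue
                for arm in gdf["arm"].unique():
                    sel = (gdf["day"] == d) & (gdf["arm"] == arm)
                    if sel.sum() >= 4:
                        gdf.loc[sel, "outlier"] = iqr_outliers(
                            gdf.loc[sel, "normalized_growth"].to_numpy()
                        )
            _write_csv(gdf, out_dir / "growth.csv", manifest)

    with manifest.stage("write_difference_spectra"):
        # arm-level mean difference spectra for plotting / inspection
        from .spectra_io import SpectrumCollection

        arm_specs, arm_labels = [], []
        for arm in arms:
            for d in days:
                subj_diffs = [per_subject_diff[(arm, d, s)]
                              for s in subjects_by_arm[arm]]
                mean_diff = difference_spectrum(
                    SpectrumCollection(subj_diffs), SpectrumCollection(
                        [sd.copy_with(intensity=np.zeros(len(sd)))
                         for sd in subj_diffs])
                )
                mean_diff.meta["spectrum_id"] = f"{arm}_day{d}"
                arm_specs.append(mean_diff)
                arm_labels.append(arm)
        write_spectra(
            SpectrumCollection(arm_specs, labels=arm_labels),
            out_dir / "difference_spectra.csv", format="wide",
        )
        manifest.add_output(out_dir / "difference_spectra.csv")
    manifest.write(out_dir / "manifest.json")
    return out_dir


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def run_quantification(
    samples_path,
    blank_path,
    standards_path,
    masses_path,
    out_dir,
    cfg: FluorQuantConfig | None = None,
) -> Path:
    """Fluorescence processing → standard curve → per-tumour ng/g table.

    Standards carry their spiked amount in ``ppix_amount_ng`` metadata;
    the masses table needs columns ``sample_id, mass_g`` (optional
    ``dilution_factor``, defaulting to the 21× aliquot chain).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or FluorQuantConfig()
    manifest = RunManifest(
        "quantification", {"fluor": asdict(cfg)},
        {"samples": samples_path, "blank": blank_path,
         "standards": standards_path, "masses": masses_path},
    )
    with manifest.stage("read_inputs"):
        samples = read_spectra(samples_path)
        blank = read_spectra(blank_path).spectra[0]
        standards = read_spectra(standards_path)
        if len(standards) < 3:
            raise StageError("read_inputs", "need at least 3 standards")
        masses = pd.read_csv(masses_path).set_index("sample_id")

    with manifest.stage("process_fluorescence", **asdict(cfg)):
        proc_std = [process_fluorescence(s, blank, cfg) for s in standards]
        proc_smp = [process_fluorescence(s, blank, cfg) for s in samples]

    with manifest.stage("standard_curve"):
        amounts = [float(s.meta["ppix_amount_ng"]) for s in standards]
        signals = [integrate_signal(p, cfg.signal_band_nm) for p in proc_std]
        curve = fit_standard_curve(amounts, signals)
        _write_csv(
            pd.DataFrame({
                "amount_ng": amounts, "signal": signals,
                "slope": curve.slope, "intercept": curve.intercept,
                "r_squared": curve.r_squared,
            }),
            out_dir / "standard_curve.csv", manifest,
        )

    with manifest.stage("quantify"):
        rows = []
        for s, p in zip(samples.spectra, proc_smp):
            sid = s.meta.get("spectrum_id", "?")
            if sid not in masses.index:
                raise StageError("quantify", f"no mass entry for sample {sid!r}")
            mass = float(masses.loc[sid, "mass_g"])
            dil = float(masses.loc[sid].get("dilution_factor",
                                            ALIQUOT_DILUTION_FACTOR))
            sig = integrate_signal(p, cfg.signal_band_nm)
            q = quantify_ppix(sig, curve, dilution_factor=dil, tumour_mass_g=mass)
            rows.append({"sample_id": sid, "signal": sig, "mass_g": mass,
                         "dilution_factor": dil, "amount_ng": q.amount_ng,
                         "ng_per_g": q.ng_per_g, "clipped": q.clipped})
        _write_csv(pd.DataFrame(rows), out_dir / "ppix.csv", manifest)
    manifest.write(out_dir / "manifest.json")
    return out_dir
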