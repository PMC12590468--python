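"""LC-MS ingestion, extracted-ion chromatograms, and feature detection.

mzML goes through :mod:`biospot.mzml_io`. Feature detection is a deliberately
minimal two-stage finder: (1) greedy mass-trace chaining of centroid
peaks of consistent m/z across consecutive MS1 scans, (2) prominence-
based elution-peak picking within each trace. Features from external
untargeted workflows can be imported from CSV instead; the correlation
stage is agnostic to the feature source.

Retention times are minutes everywhere; scan times are converted on
read regardless of the source unit. Positive ion mode is assumed and
features are plain (m/z, RT) entities -- no adduct or isotope grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from biospot.errors import ValidationError
from biospot.mzml_io import iter_spectra

REQUIRED_FEATURE_COLUMNS = (
    "feature_id", "mz", "apex_rt", "start_rt", "end_rt", "apex_intensity",
)


@dataclass
class Scan:
    """One mass spectrum: centroided (m/z, intensity) pairs at a retention time."""

    rt_min: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("m/z and intensity arrays must match")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be nonnegative")
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise ValidationError("MS2 scans must carry a precursor m/z")


@dataclass
class SpectrumSeries:
    """An LC-MS run: scans ordered by retention time."""

    scans: list[Scan]

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValidationError("scan retention times must be nondecreasing")

    def ms1(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class MassTrace:
    """A chain of centroid peaks of consistent m/z across MS1 scans."""

    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def mean_mz(self) -> float:
        # intensity-weighted: strong scans pin the mass
        w = self.intensity.sum()
        if w == 0:
            return float(self.mz.mean())
        return float((self.mz * self.intensity).sum() / w)

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class MSFeature:
    """A resolved (m/z, retention time) entity with an elution profile."""

    feature_id: str
    mz: float
    apex_rt: float
    start_rt: float
    end_rt: float
    apex_intensity: float
    profile: Optional[np.ndarray] = None  # (n, 2) array of (rt, intensity)

    def __post_init__(self) -> None:
        if not (self.start_rt <= self.apex_rt <= self.end_rt):
            raise ValidationError(
                f"feature {self.feature_id}: apex_rt must lie within "
                "[start_rt, end_rt]"
            )
        if self.profile is not None:
            self.profile = np.asarray(self.profile, dtype=float).reshape(-1, 2)
            if np.any(self.profile[:, 1] < 0):
                raise ValidationError("profile intensities must be nonnegative")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_mzml(path) -> SpectrumSeries:
    """Read all MS1/MS2 scans from an mzML file (RT in minutes)."""
    scans: list[Scan] = []
    warned_profile = False
    for spec in iter_spectra(path):
        if not spec["centroided"] and not warned_profile:
            warnings.warn(
                "spectra not marked centroided; treating peaks as centroids",
                stacklevel=2)
            warned_profile = True
        scans.append(Scan(
            rt_min=spec["rt_min"],
            ms_level=spec["ms_level"],
            mz=spec["mz"],
            intensity=spec["intensity"],
            precursor_mz=spec["precursor_mz"],
            scan_id=spec["id"],
        ))
    return SpectrumSeries(scans=scans)


# ---------------------------------------------------------------------------
# XICs
# ---------------------------------------------------------------------------

def extract_xic(
    series: SpectrumSeries, mz: float, ppm_tol: float = 10.0
) -> np.ndarray:
    """Extracted-ion chromatogram at a target m/z.

    Returns an (n_ms1, 2) array of (rt_min, intensity): per MS1 scan,
    the summed intensity of centroid peaks within ppm_tol of ``mz``
    (zero when none match).
    """
    if ppm_tol <= 0:
        raise ValidationError("ppm_tol must be positive")
    tol = mz * ppm_tol * 1e-6
    out = []
    for scan in series.ms1():
        sel = np.abs(scan.mz - mz) <= tol
        out.append((scan.rt_min, float(scan.intensity[sel].sum())))
    return np.asarray(out).reshape(-1, 2)


# ---------------------------------------------------------------------------
# mass traces
# ---------------------------------------------------------------------------

class _OpenTrace:
    __slots__ = ("rts", "mzs", "ints", "misses")

    def __init__(self) -> None:
        self.rts: list[float] = []
        self.mzs: list[float] = []
        self.ints: list[float] = []
        self.misses = 0

    @property
    def mean_mz(self) -> float:
        return float(np.mean(self.mzs))

    def add(self, rt: float, mz: float, inten: float) -> None:
        self.rts.append(rt)
        self.mzs.append(mz)
        self.ints.append(inten)
        self.misses = 0


def build_mass_traces(
    series: SpectrumSeries,
    ppm_tol: float = 10.0,
    min_trace_length: int = 5,
    gap_scans: int = 1,
    min_intensity: float = 0.0,
) -> list[MassTrace]:
    """Greedy mass-trace chaining over consecutive MS1 scans.

    Each centroid peak at or above ``min_intensity`` either extends the
    open trace whose running mean m/z is within ``ppm_tol`` (nearest
    wins; exact ties go to the lower-m/z trace) or opens a new trace.
    A trace missing from more than ``gap_scans`` consecutive scans is
    closed; traces shorter than ``min_trace_length`` scans are dropped.
    """
    open_traces: list[_OpenTrace] = []
    closed: list[_OpenTrace] = []

    def close(trace: _OpenTrace) -> None:
        if len(trace.rts) >= min_trace_length:
            closed.append(trace)

    for scan in series.ms1():
        order = np.argsort(scan.mz)  # ascending m/z: ties resolve low-first
        claimed: set[int] = set()
        extended: set[int] = set()
        for j in order:
            mz_j = float(scan.mz[j])
            int_j = float(scan.intensity[j])
            if int_j < min_intensity or int_j <= 0:
                continue
            best, best_err = None, np.inf
            for k, tr in enumerate(open_traces):
                if k in claimed:
                    continue
                mean = tr.mean_mz
                err = abs(mz_j - mean)
                if err <= mean * ppm_tol * 1e-6 and err < best_err:
                    best, best_err = k, err
            if best is None:
                tr = _OpenTrace()
                tr.add(scan.rt_min, mz_j, int_j)
                open_traces.append(tr)
                claimed.add(len(open_traces) - 1)
                extended.add(len(open_traces) - 1)
            else:
                open_traces[best].add(scan.rt_min, mz_j, int_j)
                claimed.add(best)
                extended.add(best)
        survivors = []
        for k, tr in enumerate(open_traces):
            if k in extended:
                survivors.append(tr)
            else:
                tr.misses += 1
                if tr.misses > gap_scans:
                    close(tr)
                else:
                    survivors.append(tr)
        open_traces = survivors

    for tr in open_traces:
        close(tr)

    traces = [
        MassTrace(rt=np.array(t.rts), mz=np.array(t.mzs), intensity=np.array(t.ints))
        for t in closed
    ]
    traces.sort(key=lambda t: (t.mean_mz, t.rt[0]))
    return traces


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

def detect_feature_peaks(
    trace: MassTrace,
    min_prominence_rel: float = 0.1,
    smooth_sigma: float = 1.0,
    id_prefix: str = "F",
    id_start: int = 0,
) -> list[MSFeature]:
    """Split a mass trace into elution peaks (one MSFeature each).

    The intensity series is lightly Gaussian-smoothed (``smooth_sigma``
    in scans; 0 disables) before picking local maxima with prominence
    >= min_prominence_rel * trace apex, so scan-to-scan intensity jitter
    does not split a single elution peak. Bounds come from the smoothed
    prominence bases; the reported apex and profile use the raw
    intensities. A trace with no interior maximum (e.g. monotone, apex
    at a boundary) yields a single feature spanning the whole trace with
    the apex at its highest point.
    """
    y = trace.intensity
    apex_val = float(y.max()) if len(y) else 0.0
    if apex_val <= 0:
        return []
    ys = gaussian_filter1d(y, smooth_sigma, mode="reflect") if smooth_sigma > 0 else y
    idx, props = find_peaks(ys, prominence=min_prominence_rel * float(ys.max()))
    if len(idx) == 0:
        bounds = [(0, len(y) - 1)]
    else:
        bounds = [
            (int(props["left_bases"][j]), int(props["right_bases"][j]))
            for j in range(len(idx))
        ]
    features = []
    for n, (lo, hi) in enumerate(bounds):
        p = lo + int(np.argmax(y[lo:hi + 1]))
        profile = np.column_stack([trace.rt[lo:hi + 1], y[lo:hi + 1]])
        features.append(MSFeature(
            feature_id=f"{id_prefix}{id_start + n}",
            mz=trace.mean_mz,
            apex_rt=float(trace.rt[p]),
            start_rt=float(trace.rt[lo]),
            end_rt=float(trace.rt[hi]),
            apex_intensity=float(y[p]),
            profile=profile,
        ))
    return features


def find_features(
    series: SpectrumSeries,
    ppm_tol: float = 10.0,
    min_trace_length: int = 5,
    gap_scans: int = 1,
    min_intensity: float = 0.0,
    min_prominence_rel: float = 0.1,
    smooth_sigma: float = 1.0,
) -> list[MSFeature]:
    """Full minimal feature finding: mass traces, then elution peaks."""
    traces = build_mass_traces(
        series, ppm_tol=ppm_tol, min_trace_length=min_trace_length,
        gap_scans=gap_scans, min_intensity=min_intensity,
    )
    features: list[MSFeature] = []
    for trace in traces:
        features.extend(detect_feature_peaks(
            trace, min_prominence_rel=min_prominence_rel,
            smooth_sigma=smooth_sigma, id_start=len(features),
        ))
    return features


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    path, series: Optional[SpectrumSeries] = None, ppm_tol: float = 10.0
) -> list[MSFeature]:
    """Import features from a CSV produced by an external workflow.

    Required columns: feature_id, mz, apex_rt, start_rt, end_rt,
    apex_intensity (RT in minutes). When ``series`` is given, missing
    elution profiles are reconstructed from XICs restricted to each
    feature's RT bounds.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"feature table is missing required column(s): {', '.join(missing)}")
    features = []
    for i, row in df.iterrows():
        if row["start_rt"] > row["end_rt"]:
            raise ValidationError(
                f"feature table row {i} (id {row['feature_id']}): "
                "start_rt exceeds end_rt")
        feat = MSFeature(
            feature_id=str(row["feature_id"]),
            mz=float(row["mz"]),
            apex_rt=float(row["apex_rt"]),
            start_rt=float(row["start_rt"]),
            end_rt=float(row["end_rt"]),
            apex_intensity=float(row["apex_intensity"]),
        )
        if series is not None:
            xic = extract_xic(series, feat.mz, ppm_tol=ppm_tol)
            sel = (xic[:, 0] >= feat.start_rt) & (xic[:, 0] <= feat.end_rt)
            feat.profile = xic[sel]
        features.append(feat)
    return features


def write_feature_table(features: Sequence[MSFeature], path) -> None:
    rows = [{
        "feature_id": f.feature_id,
        "mz": f.mz,
        "apex_rt": f.apex_rt,
        "start_rt": f.start_rt,
        "end_rt": f.end_rt,
        "apex_intensity": f.apex_intensity,
        "n_profile_points": 0 if f.profile is None else len(f.profile),
    } for f in features]
    pd.DataFrame(rows, columns=[
        "feature_id", "mz", "apex_rt", "start_rt", "end_rt",
        "apex_intensity", "n_profile_points",
    ]).to_csv(path, index=False)
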