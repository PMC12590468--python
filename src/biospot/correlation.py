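"""Feature-to-bioactivity correlation, ranking, and networking export.

A bioactive compound elutes once, so its MS feature and the bioactivity
peak it causes share both retention time (up to a fixed instrumental
offset between the MS detector and the spotting needle) and elution
peak shape. Candidate pairs are first gated by retention time with a
configurable bias and window, then scored by the Pearson correlation of
the activity values against the feature's elution profile interpolated
onto the fraction grid. Pairs above the correlation threshold are
ranked per activity peak; the retained features drive the MS2 filter
that produces a networking-ready mzML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from biospot.chromatogram import ActivityChromatogram, ActivityPeak
from biospot.errors import ValidationError
from biospot.lcms import MSFeature, SpectrumSeries
from biospot.mzml_io import write_mzml

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "activity_peak_apex_rt", "activity_auc", "feature_id", "mz",
    "feature_apex_rt", "rt_offset_s", "pearson_r", "n_points", "rank",
]


@dataclass(frozen=True)
class CorrelationConfig:
    """Parameters of the RT gate and shape correlation.

    rt_bias_s: systematic offset between MS detection and spot
        deposition, defined as feature_apex - activity_apex (seconds)
        for a true co-elution; may be negative. The split-flow path
        lengths differ by a user-calibratable delay.
    rt_window_s: allowed |apex difference - bias| in seconds.
    r_threshold: minimum Pearson coefficient; results are kept only
        when strictly above it.
    min_overlap_points: minimum common samples for a defined correlation.
    mz_tol_ms2: precursor m/z tolerance (Da) for the MS2 export.
    """

    rt_bias_s: float = 0.0
    rt_window_s: float = 10.0
    r_threshold: float = 0.8
    min_overlap_points: int = 5
    mz_tol_ms2: float = 0.01

    def __post_init__(self) -> None:
        if self.rt_window_s < 0:
            raise ValidationError("rt_window_s must be >= 0")
        if not -1 <= self.r_threshold <= 1:
            raise ValidationError("r_threshold must be in [-1, 1]")
        if self.min_overlap_points < 3:
            raise ValidationError("min_overlap_points must be >= 3")


@dataclass
class CorrelationResult:
    """A gated, scored feature/activity-peak pair."""

    feature_id: str
    mz: float
    peak_apex_rt: float    # min
    peak_auc: float
    feature_apex_rt: float  # min
    pearson_r: float
    rt_offset_s: float     # feature apex - activity apex, seconds
    n_points: int
    rank: int = 0          # 1-based within its activity peak; 0 = unranked


def gate_by_retention_time(
    peak: ActivityPeak, feature: MSFeature, cfg: CorrelationConfig
) -> bool:
    """Can this feature and activity peak represent the same compound?

    Passes iff |(feature_apex - peak_apex) * 60 - bias| <= window
    (everything in seconds).
    """
    offset_s = (feature.apex_rt - peak.apex_rt) * 60.0
    return abs(offset_s - cfg.rt_bias_s) <= cfg.rt_window_s


def correlate_shapes(
    peak: ActivityPeak,
    chrom: ActivityChromatogram,
    feature: MSFeature,
    cfg: CorrelationConfig,
) -> Optional[tuple[float, int]]:
    """Pearson correlation of activity vs feature elution shape.

    The evaluation grid is the chromatogram's fraction times within the
    activity peak's bounds (activity is the coarser fixed-rate signal);
    the feature profile is shifted by the RT bias and linearly
    interpolated onto that grid, zero outside its own support. Returns
    (r, n_points), or None when the correlation is undefined (fewer
    than ``min_overlap_points`` samples, or either vector constant).
    """
    if feature.profile is None or len(feature.profile) == 0:
        raise ValidationError(
            f"feature {feature.feature_id} has no elution profile; "
            "reconstruct it from an XIC first")
    sel = (chrom.rt >= peak.start_rt) & (chrom.rt <= peak.end_rt)
    grid = chrom.rt[sel]
    act = chrom.activity[sel]
    if len(grid) < cfg.min_overlap_points:
        return None
    prof_rt = feature.profile[:, 0] - cfg.rt_bias_s / 60.0
    prof_int = feature.profile[:, 1]
    interp = np.interp(grid, prof_rt, prof_int, left=0.0, right=0.0)
    if np.ptp(act) == 0 or np.ptp(interp) == 0:
        logger.debug("constant vector for feature %s; correlation undefined",
                     feature.feature_id)
        return None
    r = float(pearsonr(act, interp).statistic)
    return r, len(grid)


def rank_features(
    results: Sequence[CorrelationResult], cfg: CorrelationConfig
) -> list[CorrelationResult]:
    """Keep results above the correlation threshold and rank them.

    Ranking is per activity peak: descending Pearson r, ties broken by
    smaller |RT offset|, then lower m/z. Ranks are 1-based.
    """
    retained: list[CorrelationResult] = []
    by_peak: dict[float, list[CorrelationResult]] = {}
    for res in results:
        if res.pearson_r > cfg.r_threshold:
            by_peak.setdefault(res.peak_apex_rt, []).append(res)
    for apex in sorted(by_peak):
        group = by_peak[apex]
        group.sort(key=lambda r: (-r.pearson_r, abs(r.rt_offset_s), r.mz))
        for k, res in enumerate(group, start=1):
            res.rank = k
        retained.extend(group)
    return retained


def correlate_and_rank(
    peaks: Sequence[ActivityPeak],
    chrom: ActivityChromatogram,
    features: Sequence[MSFeature],
    cfg: CorrelationConfig,
) -> list[CorrelationResult]:
    """Gate, score, and rank every feature against every activity peak.

    A feature may match several activity peaks; results are grouped and
    ranked per peak, not globally.
    """
    scored: list[CorrelationResult] = []
    for peak in peaks:
        for feat in features:
            if not gate_by_retention_time(peak, feat, cfg):
                continue
            out = correlate_shapes(peak, chrom, feat, cfg)
            if out is None:
                continue
            r, n = out
            scored.append(CorrelationResult(
                feature_id=feat.feature_id,
                mz=feat.mz,
                peak_apex_rt=peak.apex_rt,
                peak_auc=peak.auc,
                feature_apex_rt=feat.apex_rt,
                pearson_r=r,
                rt_offset_s=(feat.apex_rt - peak.apex_rt) * 60.0,
                n_points=n,
            ))
    return rank_features(scored, cfg)


def results_to_frame(ranked: Sequence[CorrelationResult]) -> pd.DataFrame:
    rows = [{
        "activity_peak_apex_rt": r.peak_apex_rt,
        "activity_auc": r.peak_auc,
        "feature_id": r.feature_id,
        "mz": r.mz,
        "feature_apex_rt": r.feature_apex_rt,
        "rt_offset_s": r.rt_offset_s,
        "pearson_r": r.pearson_r,
        "n_points": r.n_points,
        "rank": r.rank,
    } for r in ranked]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(["activity_peak_apex_rt", "rank"]).reset_index(drop=True)


def export_results(ranked: Sequence[CorrelationResult], path) -> None:
    """Write the ranked results CSV, sorted by (peak apex, rank)."""
    results_to_frame(ranked).to_csv(path, index=False)


def read_results(path) -> list[CorrelationResult]:
    df = pd.read_csv(path)
    return [CorrelationResult(
        feature_id=str(r.feature_id), mz=float(r.mz),
        peak_apex_rt=float(r.activity_peak_apex_rt),
        peak_auc=float(r.activity_auc),
        feature_apex_rt=float(r.feature_apex_rt),
        pearson_r=float(r.pearson_r), rt_offset_s=float(r.rt_offset_s),
        n_points=int(r.n_points), rank=int(r.rank),
    ) for r in df.itertuples()]


def filter_ms2_for_networking(
    series: SpectrumSeries,
    ranked: Sequence[CorrelationResult],
    features: Sequence[MSFeature],
    cfg: CorrelationConfig,
    path,
) -> int:
    """Write the networking-ready mzML of MS2 scans on retained features.

    Keeps exactly the MS2 scans whose precursor m/z is within
    ``mz_tol_ms2`` of a retained feature's m/z and whose RT lies within
    that feature's elution bounds; scan order is preserved. Returns the
    number of exported spectra (an empty but valid mzML is written when
    none qualify).
    """
    by_id = {f.feature_id: f for f in features}
    windows = []
    for res in ranked:
        feat = by_id.get(res.feature_id)
        if feat is None:
            raise ValidationError(
                f"ranked result references unknown feature {res.feature_id}")
        windows.append((feat.mz, feat.start_rt, feat.end_rt, feat.feature_id))

    kept = []
    hit_features = set()
    for scan in series.scans:
        if scan.ms_level != 2 or scan.precursor_mz is None:
            continue
        for mz, lo, hi, fid in windows:
            if abs(scan.precursor_mz - mz) <= cfg.mz_tol_ms2 and lo <= scan.rt_min <= hi:
                kept.append(scan)
                hit_features.add(fid)
                break
    for mz, lo, hi, fid in windows:
        if fid not in hit_features:
            logger.warning("retained feature %s (m/z %.4f) has no MS2 scan "
                           "in its RT range", fid, mz)
    write_mzml(kept, path, run_id="biospot_ms2_filtered")
    return len(kept)
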