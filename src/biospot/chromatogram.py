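"""Bioactivity chromatogram construction and peak detection.

Each uPAD fraction was deposited during a known 1/frequency-second
window of the LC run, so the spot table maps directly onto retention
time: fraction i covers [t0 + i/f, t0 + (i+1)/f] seconds and is
assigned the midpoint as its retention time. The resulting per-fraction
activity series is smoothed with a 1D Gaussian kernel (default sigma of
1 fraction) and bioactivity peaks are picked by prominence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from biospot.errors import ValidationError
from biospot.imaging import SpotTable


@dataclass(frozen=True)
class SpottingSchedule:
    """When fractions were collected.

    t0_min: retention time (minutes) at which spotting started; the LC
    dead time before it is diverted to waste and never spotted.
    frequency_hz: fractions collected per second.
    n_fractions: capacity of the PAD (e.g. 500 circles).
    """

    t0_min: float
    frequency_hz: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValidationError("spotting frequency must be positive")
        if self.n_fractions < 1:
            raise ValidationError("need at least one fraction")

    @property
    def coverage_duration_s(self) -> float:
        """Seconds of the LC run covered by all fractions."""
        return self.n_fractions / self.frequency_hz

    @property
    def coverage_end_min(self) -> float:
        return self.t0_min + self.n_fractions / (60.0 * self.frequency_hz)

    def fraction_rt_min(self, i) -> np.ndarray:
        """Midpoint retention time of fraction(s) i, in minutes."""
        return self.t0_min + (np.asarray(i, dtype=float) + 0.5) / (60.0 * self.frequency_hz)

    def deposited_volume_ul(self, flow_ml_min: float, split_to_spotter: float) -> float:
        """Volume deposited per fraction (uL) for a post-column flow split.

        E.g. 1 mL/min with 90% diverted to the spotter at 1 Hz deposits
        1000 * 0.9 / 60 = 15 uL per fraction.
        """
        if not 0 <= split_to_spotter <= 1:
            raise ValidationError("split_to_spotter must be in [0, 1]")
        return flow_ml_min * 1000.0 * split_to_spotter / (60.0 * self.frequency_hz)


@dataclass
class ActivityChromatogram:
    """Retention-time series of median-normalized bioactivity."""

    rt: np.ndarray            # minutes, strictly increasing, constant step
    activity: np.ndarray
    sigma: float = 0.0        # smoothing width already applied (fractions)
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.rt.shape != self.activity.shape:
            raise ValidationError("rt and activity must have equal length")
        if len(self.rt) > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValidationError("retention times must be strictly increasing")

    @property
    def step_min(self) -> float:
        return float(self.rt[1] - self.rt[0]) if len(self.rt) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rt_min": self.rt, "activity": self.activity})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sigma: float = 0.0) -> "ActivityChromatogram":
        df = pd.read_csv(path)
        return cls(rt=df["rt_min"].to_numpy(), activity=df["activity"].to_numpy(),
                   sigma=sigma)


@dataclass
class ActivityPeak:
    """A detected bioactivity peak."""

    apex_rt: float      # min
    start_rt: float
    end_rt: float
    height: float       # activity at apex
    prominence: float
    auc: float          # trapezoidal area between bounds (activity * min)

    def __post_init__(self) -> None:
        if not (self.start_rt < self.apex_rt < self.end_rt):
            raise ValidationError("peak bounds must bracket the apex")


def assign_retention_times(
    table: SpotTable, schedule: SpottingSchedule
) -> ActivityChromatogram:
    """Assign each fraction its retention time (midpoint convention).

    Fraction i, collected over the i-th 1/f-second interval after t0,
    gets rt_i = t0 + (i + 0.5) / (60 f) minutes.
    """
    indices = np.array([s.serpentine_index for s in table.spots])
    if len(indices) == 0:
        raise ValidationError("empty spot table")
    if not np.array_equal(indices, np.arange(indices[0], indices[0] + len(indices))):
        raise ValidationError("spot table indices must be contiguous")
    if len(indices) > schedule.n_fractions:
        raise ValidationError(
            f"{len(indices)} fractions exceed schedule capacity "
            f"{schedule.n_fractions}"
        )
    activity = np.array([s.norm_activity for s in table.spots])
    if not np.all(np.isfinite(activity)):
        raise ValidationError("normalize the spot table before assigning RTs")
    return ActivityChromatogram(
        rt=schedule.fraction_rt_min(indices), activity=activity, sigma=0.0,
    )


def smooth_chromatogram(
    chrom: ActivityChromatogram, sigma: float = 1.0
) -> ActivityChromatogram:
    """Gaussian-smooth the activity trace (sigma in fraction units).

    Uses reflect boundary handling; sigma=0 returns the trace unchanged.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return ActivityChromatogram(chrom.rt.copy(), chrom.activity.copy(), sigma=0.0)
    smoothed = gaussian_filter1d(chrom.activity, sigma=sigma, mode="reflect")
    return ActivityChromatogram(chrom.rt.copy(), smoothed, sigma=sigma)


def detect_activity_peaks(
    chrom: ActivityChromatogram,
    min_prominence: float = 0.5,
    min_width_fractions: int = 2,
) -> list[ActivityPeak]:
    """Prominence-based peak picking on the (smoothed) chromatogram.

    Peak bounds are the crossings at 95% of the prominence below the
    apex (the nearest approach to the peak's own base), which keeps each
    peak's support compact even when a taller neighbor would drag the
    raw prominence base across the valley. AUC is the trapezoid between
    the bounds (baseline-inclusive). On the median-normalized scale the
    baseline sits near 1, so the default prominence of 0.5 requires a
    peak to rise half a baseline unit above its surroundings. Peaks are
    returned sorted by apex retention time.
    """
    if chrom.sigma == 0:
        warnings.warn("detecting peaks on an unsmoothed chromatogram",
                      stacklevel=2)
    y = chrom.activity
    idx, props = find_peaks(y, prominence=min_prominence,
                            width=min_width_fractions, rel_height=0.95)
    peaks = []
    for j, p in enumerate(idx):
        lo = int(np.floor(props["left_ips"][j]))
        hi = int(np.ceil(props["right_ips"][j]))
        lo, hi = max(lo, 0), min(hi, len(y) - 1)
        if lo >= p or hi <= p:
            continue
        auc = float(np.trapezoid(y[lo:hi + 1], chrom.rt[lo:hi + 1]))
        peaks.append(ActivityPeak(
            apex_rt=float(chrom.rt[p]),
            start_rt=float(chrom.rt[lo]),
            end_rt=float(chrom.rt[hi]),
            height=float(y[p]),
            prominence=float(props["prominences"][j]),
            auc=auc,
        ))
    peaks.sort(key=lambda pk: pk.apex_rt)
    return peaks


def peaks_to_frame(peaks: list[ActivityPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"apex_rt": p.apex_rt, "start_rt": p.start_rt, "end_rt": p.end_rt,
          "height": p.height, "prominence": p.prominence, "auc": p.auc}
         for p in peaks],
        columns=["apex_rt", "start_rt", "end_rt", "height", "prominence", "auc"],
    )


def peaks_from_frame(df: pd.DataFrame) -> list[ActivityPeak]:
    return [ActivityPeak(apex_rt=r.apex_rt, start_rt=r.start_rt, end_rt=r.end_rt,
                         height=r.height, prominence=r.prominence, auc=r.auc)
            for r in df.itertuples()]
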