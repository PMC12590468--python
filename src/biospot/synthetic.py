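"""Seeded synthetic fixtures: ground-truthed uPAD images and LC-MS runs.

Every stage of the pipeline is testable without downloads: this module
renders uPAD luminescence images (Gaussian-profile spots on a rotated
lattice, optional annular halos, linear background gradient, shot-like
noise) and writes matching mzML runs (Gaussian elution profiles,
decoy features, data-dependent MS2 scans), linked through planted
active compounds whose elution generated the bioactivity trace.

All generators are pure functions of (parameters, seed): the same seed
yields bit-identical output. The bioreporter response is modeled as
linear in the deposited amount on top of a baseline of 1 (the
median-normalized scale); an optional saturation ceiling can clip it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from PIL import Image

from biospot.chromatogram import SpottingSchedule
from biospot.errors import ValidationError
from biospot.imaging import PadLayout, IntensityImage, grid_to_serpentine
from biospot.lcms import Scan, SpectrumSeries
from biospot.mzml_io import write_mzml


@dataclass
class PlantedCompound:
    """One compound eluting from the LC column.

    ``apex_intensity`` is the MS1 peak height at the elution apex;
    ``activity_gain`` converts integrated deposited intensity (counts *
    min) into bioactivity units for active compounds.
    """

    mz: float
    apex_rt: float          # min
    elution_sigma: float    # min
    apex_intensity: float
    is_active: bool = False
    activity_gain: float = 0.0
    ms2_template: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.elution_sigma <= 0 or self.apex_intensity <= 0:
            raise ValidationError("elution_sigma and apex_intensity must be > 0")
        if self.is_active and self.activity_gain <= 0:
            raise ValidationError("active compounds need a positive activity_gain")

    def intensity_at(self, rt) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        return self.apex_intensity * np.exp(
            -0.5 * ((rt - self.apex_rt) / self.elution_sigma) ** 2)

    def integral(self, a: float, b: float) -> float:
        """Integral of the elution profile over [a, b] minutes."""
        s = self.elution_sigma
        return float(
            self.apex_intensity * s * np.sqrt(2 * np.pi)
            * (norm.cdf((b - self.apex_rt) / s) - norm.cdf((a - self.apex_rt) / s))
        )


@dataclass
class FixtureTruth:
    """Ground truth of a generated fixture (JSON-serializable)."""

    seed: int
    compounds: list[PlantedCompound] = field(default_factory=list)
    spot_centers: Optional[np.ndarray] = None     # (n, 2) px, serpentine order
    spot_activities: Optional[np.ndarray] = None  # serpentine order
    halo_radii: Optional[dict[int, float]] = None  # serpentine idx -> outer px
    layout: Optional[PadLayout] = None
    schedule: Optional[SpottingSchedule] = None
    rt_bias_s: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=default)


# ---------------------------------------------------------------------------
# uPAD image rendering
# ---------------------------------------------------------------------------

def lattice_centers(
    layout: PadLayout, rotation_deg: float = 0.0, margin: Optional[float] = None
) -> tuple[np.ndarray, tuple[int, int]]:
    """Rotated lattice centers (n_rows, n_cols, 2) and image (h, w)."""
    if margin is None:
        margin = layout.pitch
    w = int(np.ceil(2 * margin + (layout.n_cols - 1) * layout.pitch)) + 1
    h = int(np.ceil(2 * margin + (layout.n_rows - 1) * layout.pitch)) + 1
    rr, cc = np.mgrid[0:layout.n_rows, 0:layout.n_cols]
    x = margin + cc * layout.pitch
    y = margin + rr * layout.pitch
    theta = np.deg2rad(rotation_deg)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    xr = cx + (x - cx) * np.cos(theta) - (y - cy) * np.sin(theta)
    yr = cy + (x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    centers = np.stack([xr, yr], axis=-1)
    if (xr.min() < layout.spot_radius or yr.min() < layout.spot_radius
            or xr.max() > w - 1 - layout.spot_radius
            or yr.max() > h - 1 - layout.spot_radius):
        raise ValidationError(
            "rotated lattice leaves the image; increase margin or reduce rotation")
    return centers, (h, w)


def generate_upad_image(
    layout: PadLayout,
    activities: Sequence[float],
    rotation_deg: float = 0.0,
    noise_sd: float = 0.0,
    background: float = 30.0,
    background_gradient: float = 0.0,
    amplitude_scale: float = 1000.0,
    halos: Optional[dict[int, tuple[float, float, float]]] = None,
    seed: int = 0,
) -> tuple[IntensityImage, FixtureTruth]:
    """Render a uPAD luminescence image from per-spot activities.

    ``activities`` are in grid row-major order (row 0 left-to-right,
    row 1 left-to-right, ...); spot amplitude = activity *
    ``amplitude_scale`` with a Gaussian radial profile of sigma =
    spot_radius / 2. ``halos`` maps grid-row-major spot index ->
    (inner_radius, outer_radius, amplitude) annuli. The background is
    ``background + background_gradient * x / width`` plus clipped
    additive Gaussian noise.
    """
    activities = np.asarray(activities, dtype=float)
    if activities.size != layout.n_spots:
        raise ValidationError(
            f"need {layout.n_spots} activities, got {activities.size}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    centers, (h, w) = lattice_centers(layout, rotation_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    img = background + background_gradient * xx / max(w - 1, 1)
    img = img.astype(float)
    sigma = layout.spot_radius / 2.0
    flat_centers = centers.reshape(-1, 2)
    for k, (cx, cy) in enumerate(flat_centers):
        amp = activities[k] * amplitude_scale
        if amp <= 0:
            continue
        r = 4 * sigma
        x_lo, x_hi = int(max(0, cx - r)), int(min(w, cx + r + 1))
        y_lo, y_hi = int(max(0, cy - r)), int(min(h, cy + r + 1))
        d2 = ((xx[y_lo:y_hi, x_lo:x_hi] - cx) ** 2
              + (yy[y_lo:y_hi, x_lo:x_hi] - cy) ** 2)
        img[y_lo:y_hi, x_lo:x_hi] += amp * np.exp(-0.5 * d2 / sigma ** 2)
    halo_truth: dict[int, float] = {}
    if halos:
        for k, (r_in, r_out, amp) in halos.items():
            cx, cy = flat_centers[k]
            if r_out >= 0.5 * layout.pitch:
                raise ValidationError("halo outer radius exceeds half the pitch")
            d = np.hypot(xx - cx, yy - cy)
            img[(d >= r_in) & (d <= r_out)] += amp
            halo_truth[k] = r_out
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    # truth in serpentine order for direct comparison with SpotTables
    serp_centers = np.empty_like(flat_centers)
    serp_act = np.empty(layout.n_spots)
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            k = r * layout.n_cols + c
            i = grid_to_serpentine(r, c, layout.n_cols)
            serp_centers[i] = flat_centers[k]
            serp_act[i] = activities[k]
    truth = FixtureTruth(
        seed=seed, layout=layout, spot_centers=serp_centers,
        spot_activities=serp_act,
        halo_radii={grid_to_serpentine(k // layout.n_cols, k % layout.n_cols,
                                       layout.n_cols): v
                    for k, v in halo_truth.items()} or None,
    )
    return IntensityImage(pixels=img, source=f"synthetic_seed{seed}"), truth


def save_image_png(img: IntensityImage, path) -> None:
    """Save as 16-bit grayscale PNG (values clipped to [0, 65535])."""
    arr = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# LC-MS run generation
# ---------------------------------------------------------------------------

def _draw_decoys(
    rng: np.random.Generator,
    n_decoys: int,
    rt_start: float,
    rt_end: float,
    exclusion: Sequence[tuple[float, float]],
    elution_sigma: float,
    intensity_range: tuple[float, float],
    mz_range: tuple[float, float] = (150.0, 800.0),
) -> list[PlantedCompound]:
    decoys = []
    mzs: list[float] = []
    attempts = 0
    while len(decoys) < n_decoys and attempts < 100 * n_decoys:
        attempts += 1
        rt = float(rng.uniform(rt_start + 3 * elution_sigma,
                               rt_end - 3 * elution_sigma))
        if any(lo <= rt <= hi for lo, hi in exclusion):
            continue
        mz = float(rng.uniform(*mz_range))
        if any(abs(mz - m) < 0.1 for m in mzs):
            continue
        mzs.append(mz)
        decoys.append(PlantedCompound(
            mz=mz, apex_rt=rt,
            elution_sigma=float(elution_sigma * rng.uniform(0.7, 1.4)),
            apex_intensity=float(rng.uniform(*intensity_range)),
        ))
    return decoys


def generate_lcms_run(
    compounds: Sequence[PlantedCompound],
    rt_start: float = 0.0,
    rt_span: float = 5.0,
    scan_rate_hz: float = 3.0,
    noise_rel: float = 0.0,
    n_decoys: int = 0,
    decoy_exclusion_min: float = 0.5,
    seed: int = 0,
    path=None,
    intensity_floor: float = 1.0,
) -> tuple[SpectrumSeries, FixtureTruth]:
    """Simulate a centroided LC-MS run and optionally write it as mzML.

    MS1 scans are emitted at ``scan_rate_hz`` over
    [rt_start, rt_start + rt_span] minutes; each compound contributes a
    centroid at its m/z with a Gaussian elution profile (peaks below
    ``intensity_floor`` are dropped, emulating the detector threshold).
    ``noise_rel`` applies multiplicative Gaussian jitter to every peak.
    Decoy compounds get seeded random m/z and RT, excluding a
    ``decoy_exclusion_min`` zone around each active compound's apex so
    that decoys are either RT-separated or shape-uncorrelated. Three
    data-dependent MS2 scans are emitted around the apex of every
    compound carrying an ms2_template.
    """
    if scan_rate_hz <= 0:
        raise ValidationError("scan_rate_hz must be positive")
    for c in compounds:
        if not (rt_start <= c.apex_rt <= rt_start + rt_span):
            raise ValidationError(
                f"compound apex {c.apex_rt} min outside the run span")
    rng = np.random.default_rng(seed)
    exclusion = [(c.apex_rt - decoy_exclusion_min, c.apex_rt + decoy_exclusion_min)
                 for c in compounds if c.is_active]
    sigma_ref = (np.median([c.elution_sigma for c in compounds])
                 if compounds else 0.05)
    amp_ref = (np.median([c.apex_intensity for c in compounds])
               if compounds else 1e6)
    decoys = _draw_decoys(
        rng, n_decoys, rt_start, rt_start + rt_span, exclusion,
        float(sigma_ref), (0.2 * amp_ref, 2.0 * amp_ref),
    )
    everything = list(compounds) + decoys

    scans: list[tuple[float, int, Scan]] = []  # (rt, tiebreak, scan)
    n_ms1 = int(np.floor(rt_span * 60.0 * scan_rate_hz)) + 1
    for i in range(n_ms1):
        rt = rt_start + i / (60.0 * scan_rate_hz)
        mzs, ints = [], []
        for c in everything:
            inten = float(c.intensity_at(rt))
            if noise_rel > 0:
                inten *= max(0.0, 1.0 + rng.normal(0.0, noise_rel))
            if inten >= intensity_floor:
                mzs.append(c.mz)
                ints.append(inten)
        order = np.argsort(mzs) if mzs else []
        scans.append((rt, 0, Scan(
            rt_min=rt, ms_level=1,
            mz=np.asarray(mzs, dtype=float)[order] if len(mzs) else np.empty(0),
            intensity=np.asarray(ints, dtype=float)[order] if len(ints) else np.empty(0),
        )))

    for c in everything:
        if not c.ms2_template:
            continue
        for k, off_s in enumerate((-2.0, 0.0, 2.0)):
            rt = c.apex_rt + off_s / 60.0
            if not (rt_start <= rt <= rt_start + rt_span):
                continue
            prec_int = float(c.intensity_at(rt))
            frag = np.asarray(c.ms2_template, dtype=float)
            scans.append((rt, 1 + k, Scan(
                rt_min=rt, ms_level=2,
                mz=frag[:, 0], intensity=frag[:, 1] * prec_int,
                precursor_mz=c.mz,
            )))

    scans.sort(key=lambda t: (t[0], t[1]))
    series = SpectrumSeries(scans=[s for _, _, s in scans])
    truth = FixtureTruth(seed=seed, compounds=everything)
    if path is not None:
        write_mzml(series.scans, path)
    return series, truth


# ---------------------------------------------------------------------------
# linked end-to-end dataset
# ---------------------------------------------------------------------------

def fraction_activities(
    compounds: Sequence[PlantedCompound],
    schedule: SpottingSchedule,
    rt_bias_s: float = 0.0,
    assay_noise: float = 0.0,
    saturation: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-fraction bioactivity driven by the active compounds.

    activity_i = 1 + sum over active compounds of activity_gain times
    the compound intensity integrated over fraction i's collection
    window shifted by the RT bias (bias = feature apex - activity apex:
    the fraction deposited at LC time t carries material the MS detects
    at t + bias), plus additive Gaussian noise (sd = ``assay_noise``),
    clipped at 0. ``saturation`` optionally caps the response.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_fractions
    step = 1.0 / (60.0 * schedule.frequency_hz)
    starts = schedule.t0_min + np.arange(n) * step
    act = np.ones(n)
    shift = rt_bias_s / 60.0
    for c in compounds:
        if not c.is_active:
            continue
        for i in range(n):
            act[i] += c.activity_gain * c.integral(
                starts[i] + shift, starts[i] + step + shift)
    if saturation is not None:
        act = np.minimum(act, saturation)
    if assay_noise > 0:
        act = act + rng.normal(0.0, assay_noise, size=n)
    return np.clip(act, 0.0, None)


def generate_linked_dataset(
    compounds: Sequence[PlantedCompound],
    layout: PadLayout,
    schedule: SpottingSchedule,
    assay_noise: float = 0.05,
    rt_bias_s: float = 0.0,
    n_decoys: int = 20,
    rotation_deg: float = 1.0,
    image_noise_sd: float = 5.0,
    scan_rate_hz: float = 3.0,
    ms_noise_rel: float = 0.02,
    seed: int = 0,
    outdir=None,
) -> tuple[list[IntensityImage], SpectrumSeries, FixtureTruth]:
    """End-to-end fixture: uPAD block images + mzML + ground truth.

    The full pad (``layout``) is rendered as one image per
    ``layout.block_shape`` block of rows, mirroring acquisition in
    10x10 squares. When ``outdir`` is given, writes block_XX.png,
    run.mzML and truth.json there.
    """
    if layout.n_spots < schedule.n_fractions:
        raise ValidationError(
            f"layout holds {layout.n_spots} spots but schedule has "
            f"{schedule.n_fractions} fractions")
    block_rows, block_cols = layout.block_shape
    if block_cols != layout.n_cols or layout.n_rows % block_rows:
        raise ValidationError(
            "block_shape must cover full rows and divide the layout")
    if block_rows % 2:
        raise ValidationError(
            "block_shape rows must be even so each block starts a fresh "
            "serpentine sweep")

    rng = np.random.default_rng(seed)
    truth_warnings = []
    for c in compounds:
        if c.is_active and not (
                schedule.t0_min - rt_bias_s / 60.0 <= c.apex_rt
                <= schedule.coverage_end_min - rt_bias_s / 60.0):
            truth_warnings.append(
                f"active compound m/z {c.mz} elutes outside the spotted window")

    act = fraction_activities(
        compounds, schedule, rt_bias_s=rt_bias_s, assay_noise=assay_noise,
        seed=int(rng.integers(2 ** 31)),
    )

    # activities per lattice node (grid row-major) via the serpentine map
    grid_act = np.zeros(layout.n_spots)
    for i in range(schedule.n_fractions):
        r = i // layout.n_cols
        c = (i % layout.n_cols) if r % 2 == 0 else (
            layout.n_cols - 1 - i % layout.n_cols)
        grid_act[r * layout.n_cols + c] = act[i]

    images = []
    centers_all = []
    n_blocks = layout.n_rows // block_rows
    block_layout = PadLayout(block_rows, block_cols, layout.pitch,
                             layout.spot_radius, layout.block_shape)
    for b in range(n_blocks):
        rows = slice(b * block_rows * layout.n_cols,
                     (b + 1) * block_rows * layout.n_cols)
        img, btruth = generate_upad_image(
            block_layout, grid_act[rows], rotation_deg=rotation_deg,
            noise_sd=image_noise_sd, seed=int(rng.integers(2 ** 31)),
        )
        img.source = f"block_{b:02d}"
        images.append(img)
        centers_all.append(btruth.spot_centers)

    run_seed = int(rng.integers(2 ** 31))
    mzml_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mzml_path = outdir / "run.mzML"
    series, run_truth = generate_lcms_run(
        compounds,
        rt_start=max(0.0, schedule.t0_min - 0.5),
        rt_span=schedule.coverage_end_min - schedule.t0_min + 1.0,
        scan_rate_hz=scan_rate_hz, noise_rel=ms_noise_rel,
        n_decoys=n_decoys, seed=run_seed, path=mzml_path,
    )

    truth = FixtureTruth(
        seed=seed, compounds=run_truth.compounds,
        spot_centers=np.concatenate(centers_all),
        spot_activities=act, layout=layout, schedule=schedule,
        rt_bias_s=rt_bias_s, warnings=truth_warnings,
    )
    if outdir is not None:
        for b, img in enumerate(images):
            save_image_png(img, outdir / f"block_{b:02d}.png")
        truth.to_json(outdir / "truth.json")
    return images, series, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def three_antibiotics_preset() -> tuple[list[PlantedCompound], PadLayout, SpottingSchedule]:
    """Three baseline-separated active compounds on a 200-fraction pad.

    Emulates the structure of a validation mixture of three antibiotics
    with distinct retention times (masses are arbitrary): 200 fractions
    at 1 Hz starting at 1.00 min, imaged as two 10x10 blocks.
    """
    compounds = [
        PlantedCompound(mz=291.1452, apex_rt=1.80, elution_sigma=0.05,
                        apex_intensity=1.0e6, is_active=True,
                        activity_gain=2.0e-4,
                        ms2_template=[(123.05, 1.0), (230.10, 0.6), (273.13, 0.3)]),
        PlantedCompound(mz=332.1404, apex_rt=2.55, elution_sigma=0.05,
                        apex_intensity=8.0e5, is_active=True,
                        activity_gain=2.5e-4,
                        ms2_template=[(110.07, 0.8), (261.10, 1.0), (315.11, 0.4)]),
        PlantedCompound(mz=401.1717, apex_rt=3.60, elution_sigma=0.06,
                        apex_intensity=1.2e6, is_active=True,
                        activity_gain=1.8e-4,
                        ms2_template=[(84.08, 1.0), (358.14, 0.7), (384.17, 0.5)]),
    ]
    layout = PadLayout(n_rows=20, n_cols=10, pitch=16.0, spot_radius=4.0,
                       block_shape=(10, 10))
    schedule = SpottingSchedule(t0_min=1.0, frequency_hz=1.0, n_fractions=200)
    return compounds, layout, schedule


def single_active_preset() -> tuple[list[PlantedCompound], PadLayout, SpottingSchedule]:
    """One active compound among shape-uncorrelated decoys (see
    :func:`generate_linked_dataset` for how decoys are placed)."""
    compounds = [PlantedCompound(
        mz=291.1452, apex_rt=2.20, elution_sigma=0.05,
        apex_intensity=1.0e6, is_active=True, activity_gain=2.0e-4,
        ms2_template=[(123.05, 1.0), (230.10, 0.6)],
    )]
    layout = PadLayout(n_rows=20, n_cols=10, pitch=16.0, spot_radius=4.0,
                       block_shape=(10, 10))
    schedule = SpottingSchedule(t0_min=1.0, frequency_hz=1.0, n_fractions=200)
    return compounds, layout, schedule
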