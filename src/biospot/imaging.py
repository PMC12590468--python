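"""uPAD luminescence image analysis.

A spotted uPAD carries a rectangular lattice of paper "wells", each
holding one LC fraction. After incubation with a luciferase bioreporter,
active fractions luminesce; an imager records a grayscale picture per
10x10 block. This module detects the bright spots, fits the full
lattice (so dark, inactive fractions still get coordinates), measures
per-spot mean intensity and optional luminescent halo radii, combines
them into a bioactivity score, and normalizes by the image median.

Conventions: pixel origin top-left, coordinates are (x, y) = (column,
row); lattice rows are lettered A.. top-down, columns numbered 1..
left-right; the serpentine (boustrophedon) spotting path starts at A1
moving along the first row.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.feature import blob_log

from biospot.errors import GridFitError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensityImage:
    """A nonnegative grayscale luminescence image.

    ``pixels`` is row-major with origin top-left. ``inverted`` records
    whether gray values were inverted on load (imagers often export
    dark-on-light scans; analysis assumes luminescence is bright).
    """

    pixels: np.ndarray
    pixel_size_mm: Optional[float] = None
    inverted: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("image must be a non-empty 2D array")
        if np.any(self.pixels < 0):
            raise ValidationError("image intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PadLayout:
    """Geometry of the spotted lattice.

    ``pitch`` and ``spot_radius`` are in pixels. ``block_shape`` is the
    (rows, cols) grouping covered by a single image when one PAD is
    photographed in several blocks.
    """

    n_rows: int
    n_cols: int
    pitch: float
    spot_radius: float
    block_shape: tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("layout must have at least one row and column")
        if self.pitch <= 2 * self.spot_radius:
            raise ValidationError(
                f"pitch ({self.pitch}) must exceed the spot diameter "
                f"({2 * self.spot_radius}) or spots overlap"
            )

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class GridModel:
    """Affine lattice fitted to detected spot centers.

    ``origin`` is the pixel center of spot (row 0, col 0); ``row_step``
    and ``col_step`` are the 2D basis vectors (they encode pitch and
    rotation). All in (x, y) pixel coordinates.
    """

    origin: np.ndarray
    row_step: np.ndarray
    col_step: np.ndarray
    rms_residual: float = 0.0

    def predict(self, grid_row, grid_col) -> np.ndarray:
        """Pixel center(s) of lattice node(s)."""
        r = np.asarray(grid_row, dtype=float)
        c = np.asarray(grid_col, dtype=float)
        return (
            self.origin
            + r[..., None] * self.row_step
            + c[..., None] * self.col_step
        )


@dataclass
class Spot:
    """One fraction's measurement record."""

    serpentine_index: int
    grid_row: int
    grid_col: int
    label: str
    center: np.ndarray  # (x, y) pixels
    mean_intensity: float = np.nan
    halo_radius: Optional[float] = None
    raw_activity: float = np.nan
    norm_activity: float = np.nan
    source_image: str = ""


@dataclass
class SpotTable:
    """Ordered collection of spots (by serpentine index)."""

    spots: list[Spot]
    source_images: list[str] = field(default_factory=list)
    normalization_median: Optional[float] = None

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.spots:
            rows.append({
                "serpentine_index": s.serpentine_index,
                "label": s.label,
                "grid_row": s.grid_row,
                "grid_col": s.grid_col,
                "center_x_px": float(s.center[0]),
                "center_y_px": float(s.center[1]),
                "mean_intensity": s.mean_intensity,
                "halo_radius_px": s.halo_radius,
                "raw_activity": s.raw_activity,
                "norm_activity": s.norm_activity,
                "source_image": s.source_image,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpotTable":
        spots = []
        for _, row in df.iterrows():
            halo = row.get("halo_radius_px")
            spots.append(Spot(
                serpentine_index=int(row["serpentine_index"]),
                grid_row=int(row["grid_row"]),
                grid_col=int(row["grid_col"]),
                label=str(row["label"]),
                center=np.array([row["center_x_px"], row["center_y_px"]]),
                mean_intensity=float(row["mean_intensity"]),
                halo_radius=None if pd.isna(halo) else float(halo),
                raw_activity=float(row["raw_activity"]),
                norm_activity=float(row["norm_activity"]),
                source_image=str(row.get("source_image", "")),
            ))
        spots.sort(key=lambda s: s.serpentine_index)
        sources = sorted({s.source_image for s in spots if s.source_image})
        return cls(spots=spots, source_images=sources)

    @classmethod
    def from_csv(cls, path) -> "SpotTable":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

def load_luminescence_image(path, invert: bool = False) -> IntensityImage:
    """Load a PNG/TIFF as a nonnegative intensity image.

    RGB inputs are collapsed to luminance by channel mean. With
    ``invert=True`` pixel values become ``max - value`` so that
    luminescence is bright regardless of how the imager exported the
    scan (inversion is explicit, never auto-detected).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=float)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if arr.size == 0:
        raise ValidationError(f"image {path} is empty")
    if invert:
        arr = arr.max() - arr
    arr = arr - min(arr.min(), 0.0)
    return IntensityImage(pixels=arr, inverted=invert, source=path.name)


# ---------------------------------------------------------------------------
# spot detection and lattice fitting
# ---------------------------------------------------------------------------

def detect_candidate_spots(
    img: IntensityImage,
    radius_range: tuple[float, float],
    min_contrast: float = 0.05,
) -> np.ndarray:
    """Detect bright, roughly circular blobs; return (n, 2) centers (x, y).

    Only luminescent (active) spots are detectable -- dark fractions
    emit no light. The downstream lattice fit imputes their positions.
    Centers are refined to sub-pixel accuracy by intensity-weighted
    centroiding within the estimated blob radius.
    """
    r_min, r_max = radius_range
    if r_min <= 0 or r_max < r_min:
        raise ValidationError("radius_range must satisfy 0 < min <= max")
    pix = img.pixels
    span = pix.max() - pix.min()
    if span == 0:
        return np.empty((0, 2))
    norm = (pix - pix.min()) / span
    blobs = blob_log(
        norm,
        min_sigma=r_min / np.sqrt(2),
        max_sigma=r_max / np.sqrt(2),
        num_sigma=6,
        threshold=min_contrast,
    )
    centers = []
    h, w = pix.shape
    for y0, x0, sigma in blobs:
        r = max(sigma * np.sqrt(2), 1.5)
        y_lo, y_hi = int(max(0, y0 - r)), int(min(h, y0 + r + 1))
        x_lo, x_hi = int(max(0, x0 - r)), int(min(w, x0 + r + 1))
        patch = pix[y_lo:y_hi, x_lo:x_hi]
        wts = patch - patch.min()
        if wts.sum() == 0:
            centers.append((x0, y0))
            continue
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        centers.append((
            float((wts * xx).sum() / wts.sum()),
            float((wts * yy).sum() / wts.sum()),
        ))
    return np.asarray(centers).reshape(-1, 2)


def _estimate_rotation(candidates: np.ndarray, pitch: float) -> float:
    """Lattice rotation (rad) from near-pitch pairwise displacement angles."""
    d = candidates[None, :, :] - candidates[:, None, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    iu = np.triu_indices(len(candidates), k=1)
    sel = (dist[iu] > 0.7 * pitch) & (dist[iu] < 1.3 * pitch)
    vx, vy = d[..., 0][iu][sel], d[..., 1][iu][sel]
    if len(vx) == 0:
        return 0.0
    # fold angles into (-45, 45] deg about the nearest lattice axis
    ang = np.arctan2(vy, vx)
    ang = (ang + np.pi / 4) % (np.pi / 2) - np.pi / 4
    # circular mean with period pi/2 for stability near the fold
    c = np.cos(4 * ang).mean()
    s = np.sin(4 * ang).mean()
    return float(np.arctan2(s, c) / 4)


def _lattice_lstsq(
    candidates: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares origin/basis given integer node assignments."""
    A = np.column_stack([np.ones(len(candidates)), rows, cols])
    if np.linalg.matrix_rank(A) < 3:
        raise GridFitError(
            "degenerate spot geometry (candidates span fewer than two "
            "lattice directions); supply corner_hints"
        )
    sol, _, _, _ = np.linalg.lstsq(A, candidates, rcond=None)
    origin, row_step, col_step = sol[0], sol[1], sol[2]
    resid = candidates - (A @ sol)
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return origin, row_step, col_step, rms


def _grid_from_hints(
    corner_hints: Sequence[Sequence[float]], layout: PadLayout
) -> GridModel:
    """Build a lattice from 2-4 approximate corner-spot centers.

    Hint order: (row 0, col 0), (row 0, col C-1), then optionally
    (row R-1, col C-1) and (row R-1, col 0).
    """
    hints = np.asarray(corner_hints, dtype=float)
    if hints.ndim != 2 or hints.shape[1] != 2 or not 2 <= len(hints) <= 4:
        raise ValidationError("corner_hints must be 2-4 (x, y) points")
    origin = hints[0]
    if layout.n_cols > 1:
        col_step = (hints[1] - hints[0]) / (layout.n_cols - 1)
    else:
        col_step = np.array([layout.pitch, 0.0])
    if len(hints) >= 3 and layout.n_rows > 1:
        row_step = (hints[2] - hints[1]) / (layout.n_rows - 1)
    else:
        # assume a square lattice: row axis perpendicular to the column
        # axis, pointing down the image
        perp = np.array([-col_step[1], col_step[0]])
        if perp[1] < 0:
            perp = -perp
        row_step = perp / np.linalg.norm(perp) * layout.pitch
    return GridModel(origin=origin, row_step=row_step, col_step=col_step)


def _place_window(idx: np.ndarray, n: int, what: str) -> int:
    """Shift integer assignments into [0, n), centering when ambiguous."""
    lo, hi = int(idx.min()), int(idx.max())
    span = hi - lo
    if span > n - 1:
        raise GridFitError(
            f"candidates span {span + 1} {what}s but layout has {n}; "
            "check pitch or supply corner_hints"
        )
    slack = (n - 1) - span
    return -lo + slack // 2


def fit_spot_grid(
    candidates: np.ndarray,
    layout: PadLayout,
    corner_hints: Optional[Sequence[Sequence[float]]] = None,
) -> GridModel:
    """Fit the full spot lattice to detected (bright-spot) centers.

    Estimates the lattice rotation from near-pitch pairwise displacement
    vectors, assigns each candidate to an integer node, and solves the
    origin and two basis vectors by least squares (one re-assignment
    pass). Dark spots obtain predicted centers from the model. When the
    candidates do not span the full layout, the lattice window is
    centered over them -- supply ``corner_hints`` to resolve the
    ambiguity explicitly.
    """
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 2)

    if corner_hints is not None:
        grid = _grid_from_hints(corner_hints, layout)
        if len(candidates) >= 3:
            grid = _refine_assignments(candidates, grid, layout, fixed_window=True)
        return grid

    if len(candidates) < 3:
        raise GridFitError(
            f"need at least 3 candidate spots to fit a lattice "
            f"(got {len(candidates)}); supply corner_hints"
        )

    theta = _estimate_rotation(candidates, layout.pitch)
    rot = np.array([[np.cos(-theta), -np.sin(-theta)],
                    [np.sin(-theta), np.cos(-theta)]])
    derot = candidates @ rot.T
    cols = np.round((derot[:, 0] - derot[:, 0].min()) / layout.pitch).astype(int)
    rows = np.round((derot[:, 1] - derot[:, 1].min()) / layout.pitch).astype(int)

    origin, row_step, col_step, rms = _lattice_lstsq(candidates, rows, cols)
    grid = GridModel(origin, row_step, col_step, rms)
    return _refine_assignments(candidates, grid, layout)


def _refine_assignments(
    candidates: np.ndarray,
    grid: GridModel,
    layout: PadLayout,
    fixed_window: bool = False,
) -> GridModel:
    """One re-assignment + refit pass, then window placement."""
    basis = np.column_stack([grid.row_step, grid.col_step])
    try:
        inv = np.linalg.inv(basis)
    except np.linalg.LinAlgError as exc:
        raise GridFitError("lattice basis vectors are collinear") from exc
    rc = (candidates - grid.origin) @ inv.T
    rows = np.round(rc[:, 0]).astype(int)
    cols = np.round(rc[:, 1]).astype(int)
    origin, row_step, col_step, rms = _lattice_lstsq(candidates, rows, cols)

    if fixed_window:
        # hints pinned node (0, 0); keep the window where it is
        return GridModel(origin, row_step, col_step, rms)

    dr = _place_window(rows, layout.n_rows, "row")
    dc = _place_window(cols, layout.n_cols, "column")
    origin = origin - dr * row_step - dc * col_step
    return GridModel(origin, row_step, col_step, rms)


# ---------------------------------------------------------------------------
# serpentine enumeration
# ---------------------------------------------------------------------------

def row_letter(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA (spreadsheet style)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = string.ascii_uppercase[rem] + letters
    return letters


def serpentine_to_grid(index: int, n_cols: int) -> tuple[int, int]:
    """Map a serpentine fraction index to (row, col) lattice indices."""
    r, k = divmod(index, n_cols)
    c = k if r % 2 == 0 else n_cols - 1 - k
    return r, c


def grid_to_serpentine(row: int, col: int, n_cols: int) -> int:
    """Inverse of :func:`serpentine_to_grid`."""
    k = col if row % 2 == 0 else n_cols - 1 - col
    return row * n_cols + k


def enumerate_spots(
    grid: GridModel,
    layout: PadLayout,
    index_offset: int = 0,
    source_image: str = "",
) -> SpotTable:
    """Enumerate all lattice nodes in serpentine order (positions only).

    Row 0 runs left-to-right, row 1 right-to-left, alternating -- the
    spotting path keeps consecutive fractions spatially adjacent.
    ``index_offset`` shifts serpentine indices (and row letters, by
    whole rows) when one PAD is covered by several images.
    """
    if index_offset < 0:
        raise ValidationError("index_offset must be >= 0")
    if index_offset % layout.n_cols:
        row_off = 0
    else:
        row_off = index_offset // layout.n_cols
    spots = []
    for i in range(layout.n_spots):
        r, c = serpentine_to_grid(i, layout.n_cols)
        center = grid.predict(r, c)
        spots.append(Spot(
            serpentine_index=index_offset + i,
            grid_row=r,
            grid_col=c,
            label=f"{row_letter(r + row_off)}{c + 1}",
            center=np.asarray(center, dtype=float).ravel(),
            source_image=source_image,
        ))
    return SpotTable(spots=spots,
                     source_images=[source_image] if source_image else [])


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], center: np.ndarray, radius: float):
    h, w = shape
    cx, cy = float(center[0]), float(center[1])
    x_lo = max(0, int(np.floor(cx - radius)))
    x_hi = min(w, int(np.ceil(cx + radius)) + 1)
    y_lo = max(0, int(np.floor(cy - radius)))
    y_hi = min(h, int(np.ceil(cy + radius)) + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return None, None
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    return (slice(y_lo, y_hi), slice(x_lo, x_hi)), mask


def measure_spot_intensity(
    img: IntensityImage, center: np.ndarray, measure_radius: float
) -> float:
    """Mean pixel intensity within the measurement disk around a center.

    The disk is clipped (with a warning) if it extends past the image
    border; a disk entirely outside the image is an error.
    """
    window, mask = _disk_mask(img.shape, center, measure_radius)
    if window is None or not mask.any():
        raise ValidationError(
            f"measurement disk at {tuple(np.round(center, 1))} lies "
            "entirely outside the image"
        )
    full_area = np.pi * measure_radius ** 2
    if mask.sum() < 0.6 * full_area:
        warnings.warn(
            f"measurement disk at {tuple(np.round(center, 1))} clipped by "
            "the image border", stacklevel=2)
    return float(img.pixels[window][mask].mean())


def estimate_background(
    img: IntensityImage, grid: GridModel, layout: PadLayout, exclude_radius: float
) -> tuple[float, float]:
    """Robust background level and scale from inter-spot pixels.

    Returns (median, 1.4826*MAD) over pixels farther than
    ``exclude_radius`` from every lattice node.
    """
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    keep = np.ones((h, w), dtype=bool)
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            cx, cy = grid.predict(r, c)
            keep &= (xx - cx) ** 2 + (yy - cy) ** 2 > exclude_radius ** 2
    vals = img.pixels[keep]
    if vals.size == 0:
        vals = img.pixels.ravel()
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, 1.4826 * mad


def measure_halo(
    img: IntensityImage,
    center: np.ndarray,
    measure_radius: float,
    search_radius: float,
    background: float,
    background_scale: float,
    k_mad: float = 3.0,
) -> Optional[float]:
    """Outer radius of a luminescent halo around a spot, if present.

    Halos are annular rings of light around growth-inhibition zones.
    The median radial profile is computed in 1-px annuli from
    ``measure_radius`` to ``search_radius``; a halo is the innermost
    contiguous band exceeding ``background + k_mad * background_scale``,
    reported by its outer radius. A band that starts flush against the
    measurement disk and only decays outward is the spot's own skirt,
    not a halo, and is rejected. Returns None when no halo is found.
    """
    if search_radius <= measure_radius:
        raise ValidationError("search_radius must exceed measure_radius")
    h, w = img.shape
    cx, cy = float(center[0]), float(center[1])
    window, _ = _disk_mask(img.shape, center, search_radius)
    if window is None:
        return None
    yy, xx = np.mgrid[window[0], window[1]]
    dist = np.hypot(xx - cx, yy - cy)
    pix = img.pixels[window]

    edges = np.arange(np.floor(measure_radius), search_radius + 1.0)
    profile = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi)
        profile.append(np.median(pix[sel]) if sel.any() else -np.inf)
    profile = np.asarray(profile)
    threshold = background + k_mad * background_scale
    above = profile > threshold
    if not above.any():
        return None

    # contiguous runs of above-threshold annuli
    idx = np.flatnonzero(above)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        band = profile[run]
        if run[0] == 0 and int(np.argmax(band)) == 0:
            # flush against the measurement disk with its maximum at the
            # inner edge: either the spot's own decaying skirt (not a
            # halo) or a skirt merging into a ring. A ring shows a
            # significant re-rise after the initial decay.
            rise = band - np.minimum.accumulate(band)
            if rise.max() <= k_mad * background_scale:
                continue
        return float(edges[run[-1] + 1])
    return None


def compute_activity(
    mean_intensity: float,
    halo_radius: Optional[float],
    halo_weight: float,
    pitch: float,
    intensity_scale: float,
) -> float:
    """Combine spot luminescence and halo size into one activity score.

    The score is the sum of the spot's mean luminescence and its halo
    diameter; to make the two addends commensurate, the halo diameter
    is expressed in pitch units and multiplied by the image's median
    spot intensity (``intensity_scale``)::

        raw = mean + halo_weight * (2 * halo_radius / pitch) * scale

    With ``halo_weight=0`` (or no halo) this reduces to pure
    densitometry.
    """
    if halo_radius is None or halo_weight == 0:
        return float(mean_intensity)
    return float(
        mean_intensity
        + halo_weight * (2.0 * halo_radius / pitch) * intensity_scale
    )


def normalize_by_median(table: SpotTable) -> SpotTable:
    """Divide raw activities by the per-image median.

    Normalization is per source image (applied before merging blocks of
    one PAD) so that images acquired with different exposure remain
    comparable: the median fraction of each image maps to activity 1.
    """
    if not table.spots:
        raise ValidationError("cannot normalize an empty spot table")
    raw = np.array([s.raw_activity for s in table.spots])
    if not np.all(np.isfinite(raw)):
        raise ValidationError("raw_activity must be measured before normalizing")
    sources = np.array([s.source_image for s in table.spots])
    new_spots = []
    medians = {}
    for src in np.unique(sources):
        med = float(np.median(raw[sources == src]))
        if med <= 0:
            raise ValidationError(
                f"median raw activity of image '{src}' is {med}; blank image?")
        medians[src] = med
    for s in table.spots:
        new_spots.append(replace(s, norm_activity=s.raw_activity / medians[s.source_image]))
    med_all = medians[sources[0]] if len(medians) == 1 else float(np.median(raw))
    return SpotTable(spots=new_spots, source_images=list(table.source_images),
                     normalization_median=med_all)


def merge_spot_tables(tables: Sequence[SpotTable]) -> SpotTable:
    """Merge per-image tables into one PAD-wide table.

    Serpentine index ranges must be disjoint and contiguous after the
    per-image offsets (no overlap, no gap).
    """
    if not tables:
        raise ValidationError("no tables to merge")
    spots = [s for t in tables for s in t.spots]
    spots.sort(key=lambda s: s.serpentine_index)
    indices = [s.serpentine_index for s in spots]
    lo = indices[0]
    expected = list(range(lo, lo + len(indices)))
    if indices != expected:
        dup = len(indices) != len(set(indices))
        kind = "overlapping" if dup else "gapped"
        raise ValidationError(
            f"{kind} serpentine index ranges; expected contiguous "
            f"{lo}..{lo + len(indices) - 1}"
        )
    sources = []
    for t in tables:
        for src in t.source_images:
            if src not in sources:
                sources.append(src)
    return SpotTable(spots=spots, source_images=sources)


# ---------------------------------------------------------------------------
# per-image orchestration
# ---------------------------------------------------------------------------

def analyze_pad_image(
    img: IntensityImage,
    layout: PadLayout,
    index_offset: int = 0,
    corner_hints: Optional[Sequence[Sequence[float]]] = None,
    measure_radius: Optional[float] = None,
    halo_weight: float = 1.0,
    halo_search_factor: float = 2.0,
    k_mad: float = 3.0,
    min_contrast: float = 0.05,
) -> SpotTable:
    """Full densitometry of one uPAD image: detect, fit, measure, normalize.

    ``measure_radius`` defaults to 0.8 * layout.spot_radius (avoids rim
    and printing artifacts). Halo search extends to
    ``halo_search_factor * spot_radius`` but never past half the pitch.
    Returns a median-normalized SpotTable for this image's block.
    """
    if measure_radius is None:
        measure_radius = 0.8 * layout.spot_radius
    candidates = detect_candidate_spots(
        img, (0.5 * layout.spot_radius, 1.5 * layout.spot_radius),
        min_contrast=min_contrast,
    )
    grid = fit_spot_grid(candidates, layout, corner_hints=corner_hints)
    logger.info("grid fit: %d candidates, rms residual %.3f px",
                len(candidates), grid.rms_residual)
    table = enumerate_spots(grid, layout, index_offset=index_offset,
                            source_image=img.source)

    search_radius = min(halo_search_factor * layout.spot_radius,
                        0.5 * layout.pitch - 1.0)
    bg_med, bg_scale = estimate_background(img, grid, layout, search_radius)

    means = []
    for spot in table.spots:
        spot.mean_intensity = measure_spot_intensity(img, spot.center, measure_radius)
        means.append(spot.mean_intensity)
        if halo_weight != 0 and search_radius > measure_radius:
            spot.halo_radius = measure_halo(
                img, spot.center, measure_radius, search_radius,
                bg_med, bg_scale, k_mad=k_mad,
            )
    intensity_scale = float(np.median(means))
    for spot in table.spots:
        spot.raw_activity = compute_activity(
            spot.mean_intensity, spot.halo_radius, halo_weight,
            layout.pitch, intensity_scale,
        )
    return normalize_by_median(table)
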