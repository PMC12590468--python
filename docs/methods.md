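# Methods

This note documents the models, conventions, and numerical choices
behind `biospot`, and what the synthetic fixtures do and do not emulate.

## Spotting model and retention-time assignment

A μPAD holds `n_fractions` printed circles filled in serpentine
(boustrophedon) order at `frequency_hz` fractions per second, starting
at LC time `t0_min` (dead time before t₀ is diverted to waste and never
spotted; there is no zero-padding for it). Fraction *i* therefore
collects the eluate of the window \[t₀ + i/f, t₀ + (i+1)/f\] seconds and
is assigned the **midpoint** retention time

    rt_i = t0 + (i + 0.5) / (60 f)   [min]

The midpoint is an unbiased summary of the 1/f-second collection
interval; window arithmetic is exposed separately
(`coverage_duration_s`, `coverage_end_min`, `deposited_volume_ul`).
Whether the upstream acquisition software uses window start or midpoint
is not observable from the data; the midpoint convention is ours, and
the half-fraction difference (0.5 s at 1 Hz) is far below the default
10 s RT gate.

Serpentine indexing: row 0 runs left→right, row 1 right→left,
alternating; labels combine a top-down row letter with a 1-based column
number (A1 is the first fraction). When one pad is imaged in several
blocks, each image gets an `index_offset` (a whole number of rows) and
row letters continue across blocks.

## Image analysis

**Spot detection and lattice fit.** Only luminescent spots are
detectable; inactive fractions are dark. Bright blobs are found with a
Laplacian-of-Gaussian detector and refined by intensity-weighted
centroiding, then a full affine lattice (origin + two basis vectors,
encoding pitch and rotation) is fitted by least squares: rotation is
estimated from the angles of near-pitch pairwise displacement vectors
(folded mod 90° and averaged circularly), candidates are snapped to
integer nodes, and the basis is solved linearly with one re-assignment
pass. Every node — including dark spots — gets a predicted center.

*Identifiability caveat:* if the detected spots do not span the full
layout (an entirely dark border row or column), the placement of the
layout window on the fitted lattice is ambiguous; the fit centers the
candidate span and `corner_hints` resolve it explicitly. In practice
baseline bioreporter luminescence makes all spots faintly visible, so
the span is almost always complete.

**Densitometry.** Per-spot activity starts from the mean pixel intensity
in a disk of radius 0.8 × expected spot radius (the 0.8 factor avoids
rim and wax-printing artifacts). The measurement disk is clipped with a
warning at image borders.

**Halos.** Luminescent rings around inhibition zones are detected on the
median radial profile in 1-px annuli between the measurement radius and
a search radius (default 2 × spot radius, capped at half the pitch).
Background level and scale are the median and 1.4826·MAD of pixels
farther than the search radius from every lattice node. A halo is the
innermost contiguous band of annuli exceeding background + k·scale
(k = 3 by default), reported by its outer radius. A band flush against
the measurement disk whose maximum sits at its inner edge is the spot's
own decaying skirt and is rejected — unless the profile re-rises within
the band by more than k·scale, which is the signature of a skirt merging
into a true ring. A halo whose ring never rises above the skirt at the
measurement boundary is therefore missed; widening the measurement
radius resolves such cases.

**Activity score.** The assay readout is "luminescence plus halo size",
which mixes units. The combination used here is

    raw = mean_intensity + halo_weight · (2·halo_radius / pitch) · scale

where `scale` is the image's median spot intensity, making the halo term
commensurate with the densitometric term: a halo as wide as the pitch
contributes `halo_weight` median-spot-intensities. `halo_weight` defaults
to 1 and 0 disables halos entirely (pure densitometry). This
commensuration rule is a documented design choice, not a published
formula.

**Normalization** divides by the median raw activity *per source image*
(not per pad), so images with different exposure remain comparable; the
median fraction of each image maps to activity 1. With an odd spot count
the median of normalized activities is exactly 1.

## Bioactivity chromatogram

The normalized activity series is smoothed by discrete Gaussian
convolution with σ = 1 fraction (reflect boundary; σ = 0 is the
identity). Peaks are local maxima with prominence ≥ 0.5 (on the
normalized scale, where baseline ≈ 1) and width ≥ 2 fractions. Peak
bounds are the crossings at 95% of the prominence below the apex rather
than the raw prominence bases: in multi-peak chromatograms scipy's
prominence base of a tall peak extends across the valley past shorter
neighbors, which would both inflate the AUC and drag unrelated structure
into the shape-correlation grid. The 95% crossing keeps each peak's
support compact while still reaching essentially to its own base. AUC is
the baseline-inclusive trapezoid between the bounds — a semiquantitative
measure (it grows with amplitude but sublinearly, since the baseline
portion is constant). The prominence/width defaults are this package's
own; the upstream application's values are not published.

## LC-MS feature finding

mzML I/O is self-contained (`biospot.mzml_io`): a streaming lxml reader
covering the centroided-run subset of the PSI-MS vocabulary (ms level,
scan start time in any time unit, selected ion m/z, 32/64-bit float
arrays, optional zlib), and a writer emitting plain mzML 1.1 with
uncompressed 64-bit arrays. The writer's output is cross-validated
against Bioconductor's mzR parser in the test suite.

Feature detection is a deliberately minimal two-stage finder:

1. **Mass traces** — greedy chaining: per MS1 scan, each centroid at or
   above `min_intensity` extends the open trace whose running mean m/z
   is within `ppm_tol` (nearest wins; exact ties to the lower-m/z trace)
   or opens a new trace; traces missing for more than `gap_scans`
   consecutive scans close; traces shorter than `min_trace_length` scans
   are dropped. Defaults: 10 ppm, 5 scans, 1 gap, `min_intensity` 0.
2. **Elution peaks** — the trace intensity series is lightly smoothed
   (Gaussian, σ = 1 scan) so scan-to-scan jitter does not split a peak,
   then local maxima with prominence ≥ 0.1 × trace apex are cut at their
   prominence bases; apex and profile are reported from the raw
   intensities. A trace with no interior maximum yields one feature
   spanning the whole trace (apex at its highest point).

Features are plain (m/z, RT, profile) entities; isotope and adduct
grouping, cross-run alignment, and profile-mode picking are out of
scope. A CSV import path (`read_feature_table`) accepts features from
external untargeted workflows, reconstructing missing elution profiles
from XICs restricted to the feature's RT bounds; the correlation stage
is agnostic to the feature source.

## Correlation and ranking

**RT gate.** A feature and an activity peak may represent the same
compound iff |(feature_apex − peak_apex)·60 − bias| ≤ window (seconds).
`rt_bias_s` is defined as *feature apex minus activity apex* for a true
co-elution — the split-flow path lengths differ by a user-calibratable
delay of either sign. Defaults: bias 0, window 10 s (our choices; the
true bias depends on tubing geometry and should be calibrated with a
standard).

**Shape score.** The evaluation grid is the chromatogram's fraction
times within the activity peak's bounds — the activity trace is the
coarser, fixed-rate signal, so the denser MS profile is the one
interpolated (linearly, zero outside its own support, shifted by the
bias). Pearson r is computed on (activity, interpolated intensity);
pairs with fewer than `min_overlap_points` (default 5) samples or a
constant vector are *excluded* as undefined rather than scored 0 —
mathematically honest, and logged.

**Ranking.** Results with r strictly above `r_threshold` (default 0.8;
"above" read literally) are ranked per activity peak by descending r,
ties broken by smaller |RT offset| then lower m/z. A feature may appear
under several peaks; ranking is per peak because identification is asked
per bioactivity peak.

**MS2 export** writes the mzML of exactly those MS2 scans whose
precursor is within `mz_tol_ms2` (default 0.01 Da) of a retained
feature's m/z and whose RT lies in that feature's elution bounds, in
original scan order — the input for downstream molecular networking.

## Synthetic fixtures

The generators are pure functions of (parameters, seed); identical seeds
give bit-identical images, mzML bytes, and truth records.

- **μPAD images**: Gaussian-profile spots (σ = spot_radius/2, amplitude
  proportional to activity) on a lattice with configurable rotation,
  optional explicit annuli as halos, a linear background gradient, and
  clipped additive Gaussian noise. Rendered as 16-bit PNGs.
- **LC-MS runs**: MS1 scans at a fixed rate with each compound a
  Gaussian elution profile at its m/z (multiplicative intensity jitter;
  a 1-count detector floor truncates far tails); decoys get seeded
  random m/z (≥ 0.1 Da apart) and RT, excluding ±0.5 min around active
  apexes so decoys are RT-separated or shape-uncorrelated by
  construction; three data-dependent MS2 scans around each templated
  compound's apex.
- **Linked datasets**: per-fraction activity = 1 + Σ gain ×
  (compound intensity integrated over the fraction's collection window,
  shifted by the configured bias) + Gaussian noise, clipped at 0 — a
  linear bioreporter response on the median-normalized scale, with an
  optional saturation ceiling (default off). The default presets use
  200 fractions at 1 Hz from 1.00 min, imaged as two 10×10 blocks,
  elution σ ≈ 3 s, apex intensities near 10⁶ counts, gains chosen so
  peak activities reach ≈ 3–4× baseline, 5% assay noise, 2% MS intensity
  jitter, 1° lattice rotation, and 20 decoys — magnitudes typical of the
  bench setup the model emulates.

What the fixtures do **not** emulate: chromatographic tailing, detector
saturation, isotope envelopes, droplet spreading and paper texture,
flat-field/vignetting, and bioreporter response nonlinearity (beyond the
optional hard ceiling). Passing tests therefore demonstrate correctness
of the geometry, bookkeeping, and statistics under idealized peak
shapes — not robustness to every instrumental artifact of real data.

## Problem sizes and determinism

Test and acceptance runs use 10×10-block pads (200 fractions), ~780-scan
runs and ≤ 23 features — small enough for the full end-to-end pipeline
to run in a couple of seconds while exercising every stage, including
file round-trips through PNG and mzML. All randomness flows from
explicit `numpy.random.default_rng` seeds; re-running any pipeline on
identical inputs produces byte-identical CSV and mzML outputs.

## Known limitations

- Lattice-window placement needs the detected spots to span the layout
  (or corner hints); fully dark border rows are otherwise ambiguous.
- Halos overlapping a neighboring spot's skirt (outer radius near half
  the pitch) are truncated by the search-radius cap.
- The greedy trace builder is O(peaks × open traces) per scan — fine for
  the intended small-molecule runs, not optimized for profile-mode or
  very dense data.
- Features without MS2 scans in range are retained in the ranked list
  but contribute nothing to the networking export (a warning is logged).
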