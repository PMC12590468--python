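"""End-to-end pipeline: images + mzML -> ranked bioactive candidates.

Chains all stages: image analysis -> spot table -> bioactivity
chromatogram -> peak detection -> LC-MS feature detection -> retention
time gating + Pearson shape correlation -> ranked CSV + MS2-filtered
mzML + plain-text report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from biospot import chromatogram as chrom_mod
from biospot import imaging, lcms
from biospot.chromatogram import SpottingSchedule
from biospot.config import RunConfig
from biospot.correlation import (
    correlate_and_rank, export_results, filter_ms2_for_networking,
)
from biospot.imaging import PadLayout

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _layout_from_config(cfg: RunConfig) -> tuple[PadLayout, PadLayout]:
    """(full pad layout, per-image block layout)."""
    lc = cfg.layout
    block = (lc.block_rows, lc.block_cols)
    full = PadLayout(lc.n_rows, lc.n_cols, lc.pitch_px, lc.spot_radius_px, block)
    per_image = PadLayout(lc.block_rows, lc.block_cols, lc.pitch_px,
                          lc.spot_radius_px, block)
    return full, per_image


def analyze_images(
    images: Sequence, cfg: RunConfig
) -> imaging.SpotTable:
    """Run densitometry over the image blocks of one PAD and merge.

    ``images`` may be paths or pre-loaded IntensityImages, in block
    (serpentine) order; image k gets index offset k * block size.
    """
    _, block_layout = _layout_from_config(cfg)
    im = cfg.imaging
    tables = []
    for k, item in enumerate(images):
        if isinstance(item, imaging.IntensityImage):
            img = item
        else:
            img = imaging.load_luminescence_image(item, invert=im.invert)
        table = imaging.analyze_pad_image(
            img, block_layout,
            index_offset=k * block_layout.n_spots,
            measure_radius=im.measure_radius_factor * block_layout.spot_radius,
            halo_weight=im.halo_weight,
            halo_search_factor=im.halo_search_factor,
            k_mad=im.k_mad,
            min_contrast=im.min_contrast,
        )
        tables.append(table)
    return imaging.merge_spot_tables(tables)


def run_pipeline(
    image_paths: Sequence,
    mzml_path,
    cfg: Optional[RunConfig] = None,
    outdir="biospot_out",
) -> dict:
    """Execute the full workflow and write all outputs.

    Writes spots.csv, chromatogram.csv, peaks.csv, features.csv,
    ranked.csv, ms2_filtered.mzML and report.txt under ``outdir``.
    Returns a summary dict (spot/peak/feature/retained counts). Stage
    errors are re-raised as StageError naming the failed stage, and
    partial outputs are removed.
    """
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        try:
            logger.info("stage image: %d image(s), layout %dx%d blocks of %dx%d",
                        len(image_paths), cfg.layout.n_rows, cfg.layout.n_cols,
                        cfg.layout.block_rows, cfg.layout.block_cols)
            table = analyze_images(image_paths, cfg)
            table.to_csv(out("spots.csv"))
        except Exception as exc:
            raise StageError("image", exc) from exc

        try:
            schedule = SpottingSchedule(
                cfg.schedule.t0_min, cfg.schedule.frequency_hz,
                cfg.schedule.n_fractions)
            chrom = chrom_mod.assign_retention_times(table, schedule)
            chrom = chrom_mod.smooth_chromatogram(
                chrom, sigma=cfg.chromatogram.sigma_fractions)
            chrom.to_csv(out("chromatogram.csv"))
            peaks = chrom_mod.detect_activity_peaks(
                chrom,
                min_prominence=cfg.chromatogram.min_prominence,
                min_width_fractions=cfg.chromatogram.min_width_fractions)
            chrom_mod.peaks_to_frame(peaks).to_csv(out("peaks.csv"), index=False)
            logger.info("stage chromatogram: %d fractions, %d peaks",
                        len(chrom.rt), len(peaks))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("chromatogram", exc) from exc

        try:
            series = lcms.read_mzml(mzml_path)
            fc = cfg.features
            features = lcms.find_features(
                series, ppm_tol=fc.ppm_tol,
                min_trace_length=fc.min_trace_length,
                gap_scans=fc.gap_scans, min_intensity=fc.min_intensity,
                min_prominence_rel=fc.min_prominence_rel,
                smooth_sigma=fc.smooth_sigma)
            lcms.write_feature_table(features, out("features.csv"))
            logger.info("stage features: %d scans, %d features",
                        len(series), len(features))
        except Exception as exc:
            raise StageError("features", exc) from exc

        try:
            ccfg = cfg.correlation.to_correlation_config()
            ranked = correlate_and_rank(peaks, chrom, features, ccfg)
            export_results(ranked, out("ranked.csv"))
            n_ms2 = filter_ms2_for_networking(
                series, ranked, features, ccfg, out("ms2_filtered.mzML"))
            logger.info("stage correlate: %d retained, %d MS2 exported",
                        len(ranked), n_ms2)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("correlate", exc) from exc

        summary = {
            "n_spots": len(table),
            "n_peaks": len(peaks),
            "n_features": len(features),
            "n_retained": len(ranked),
            "n_ms2_exported": n_ms2,
        }
        report = out("report.txt")
        with open(report, "w") as fh:
            fh.write("biospot pipeline report\n")
            fh.write(f"images: {', '.join(str(p) for p in image_paths)}\n")
            fh.write(f"mzml: {mzml_path}\n")
            for key, val in summary.items():
                fh.write(f"{key}: {val}\n")
        summary["ranked"] = ranked
        summary["peaks"] = peaks
        summary["chromatogram"] = chrom
        summary["features"] = features
        return summary
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
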