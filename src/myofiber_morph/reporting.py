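"""Per-image and per-batch outputs, and the batch driver.

Each processed image yields a numbered overlay (``final.tif``) saved in the
image's own folder, plus quantitative text files in a ``Results`` folder
inside the main folder: ``<folder>_CSA.csv`` (comma-separated CSA list, in
fiber-number order), optionally ``<folder>_MFI.csv``, and
``<folder>_fibers.txt`` (tab-separated table: fiber number, CSA in μm²,
central-nucleation status, MFI when computed). A failing image never aborts
the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from skimage.segmentation import find_boundaries

from .dataset_io import (ChannelMap, DiscoveryReport, ImageJob, PixelScale,
                         discover_image_folders, load_job_channels,
                         write_gray_tiff)
from .morphometry import (FiberRecord, SizeLimits, apply_size_filter,
                          measure_regions)
from .nucleation import (CentralZoneParams, classify_all_fibers,
                         compute_all_mfi, detect_nuclei)
from .segmentation import (QualityMode, SegmentationParams, preprocess_boundary,
                           segment_fiber_maps)

logger = logging.getLogger("myofiber_morph")

RESULTS_DIRNAME = "Results"
OVERLAY_FILENAME = "final.tif"

# 3×5 bitmap digits for the overlay numbering (deterministic, no font deps)
_DIGITS = {
    "0": ("111", "101", "101", "101", "111"),
    "1": ("010", "110", "010", "010", "111"),
    "2": ("111", "001", "111", "100", "111"),
    "3": ("111", "001", "111", "001", "111"),
    "4": ("101", "101", "111", "001", "001"),
    "5": ("111", "100", "111", "001", "111"),
    "6": ("111", "100", "111", "101", "111"),
    "7": ("111", "001", "010", "010", "010"),
    "8": ("111", "101", "111", "101", "111"),
    "9": ("111", "101", "111", "001", "111"),
}


@dataclass(frozen=True)
class BatchConfig:
    """Everything one run needs; mirrors the CLI flags."""

    main_folder: Path
    channels: ChannelMap
    scale: PixelScale
    quality: QualityMode = QualityMode.high
    limits: SizeLimits = SizeLimits()
    central: CentralZoneParams = CentralZoneParams()
    segmentation: Optional[SegmentationParams] = None
    keep_intermediates: bool = False
    watershed: bool = False

    def seg_params(self) -> SegmentationParams:
        if self.segmentation is not None:
            return self.segmentation
        return SegmentationParams(quality=self.quality,
                                  watershed_split=self.watershed)


@dataclass
class ResultsBundle:
    overlay_path: Path
    csa_csv_path: Path
    fiber_table_path: Path
    mfi_csv_path: Optional[Path] = None


@dataclass
class JobResult:
    job: ImageJob
    fibers: list[FiberRecord]
    labels_measured: np.ndarray
    labels_interior: np.ndarray
    boundary_img: Optional[np.ndarray] = None
    bundle: Optional[ResultsBundle] = None

    @property
    def mean_csa(self) -> Optional[float]:
        if not self.fibers:
            return None
        return float(np.mean([f.csa_um2 for f in self.fibers]))

    @property
    def pct_cnf(self) -> Optional[float]:
        flags = [f.cnf for f in self.fibers if f.cnf is not None]
        if not flags:
            return None
        return 100.0 * sum(flags) / len(flags)


@dataclass
class BatchSummary:
    results: list[JobResult] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)


def _fmt(v: float) -> str:
    s = f"{v:.4f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


def _draw_text(canvas: np.ndarray, text: str, center_rc: tuple[float, float],
               color: tuple[int, int, int], px: int = 2) -> None:
    """Stamp *text* (digits) onto an RGB canvas, centred at center_rc."""
    glyph_w, glyph_h, gap = 3 * px, 5 * px, px
    total_w = len(text) * glyph_w + (len(text) - 1) * gap
    top = int(round(center_rc[0] - glyph_h / 2))
    left = int(round(center_rc[1] - total_w / 2))
    h, w = canvas.shape[:2]
    for ch in text:
        rows = _DIGITS.get(ch)
        if rows is None:
            left += glyph_w + gap
            continue
        for gr, rowbits in enumerate(rows):
            for gc, bit in enumerate(rowbits):
                if bit != "1":
                    continue
                r0, c0 = top + gr * px, left + gc * px
                rr = slice(max(r0, 0), min(r0 + px, h))
                cc = slice(max(c0, 0), min(c0 + px, w))
                canvas[rr, cc] = color
        left += glyph_w + gap


def render_final_overlay(
    boundary_img: np.ndarray,
    labels_measured: np.ndarray,
    fibers: list[FiberRecord],
    out_path: Path | str,
) -> Path:
    """Write ``final.tif``: the boundary channel as backdrop, each reported
    fiber outlined and its number stamped at its centroid. Deterministic —
    identical inputs produce a byte-identical file."""
    img = np.asarray(boundary_img, dtype=np.float64)
    vmax = img.max()
    backdrop = (img / vmax * 255.0).astype(np.uint8) if vmax > 0 \
        else np.zeros(img.shape, dtype=np.uint8)
    canvas = np.stack([backdrop] * 3, axis=-1)

    keep = np.isin(labels_measured, [f.label for f in fibers])
    shown = np.where(keep, labels_measured, 0)
    outline = find_boundaries(shown, mode="inner")
    canvas[outline] = (0, 255, 0)
    for f in fibers:
        _draw_text(canvas, str(f.number), f.centroid, (255, 255, 0))
    out_path = Path(out_path)
    tifffile.imwrite(str(out_path), canvas, photometric="rgb")
    return out_path


def write_fiber_outputs(job: ImageJob, fibers: list[FiberRecord],
                        results_dir: Path) -> ResultsBundle:
    """Write the quantitative text files for one image into *results_dir*.

    CSA CSV: one comma-separated line of CSAs in fiber-number order. MFI
    CSV likewise, only when MFI was computed. Fiber table: tab-separated,
    one row per fiber with number, CSA, CNF status (TRUE/FALSE, or NA when
    no nuclear channel was analyzed) and MFI when present.
    """
    results_dir.mkdir(parents=True, exist_ok=True)
    name = job.name
    has_mfi = any(f.mfi is not None for f in fibers)

    csa_path = results_dir / f"{name}_CSA.csv"
    csa_path.write_text(",".join(_fmt(f.csa_um2) for f in fibers) + "\n")

    mfi_path: Optional[Path] = None
    if has_mfi:
        mfi_path = results_dir / f"{name}_MFI.csv"
        mfi_path.write_text(
            ",".join(_fmt(f.mfi) for f in fibers if f.mfi is not None) + "\n")

    table_path = results_dir / f"{name}_fibers.txt"
    header = "fiber\tcsa_um2\tcnf" + ("\tmfi_au" if has_mfi else "")
    lines = [header]
    for f in fibers:
        cnf = "NA" if f.cnf is None else ("TRUE" if f.cnf else "FALSE")
        row = f"{f.number}\t{_fmt(f.csa_um2)}\t{cnf}"
        if has_mfi:
            row += f"\t{_fmt(f.mfi)}"
        lines.append(row)
    table_path.write_text("\n".join(lines) + "\n")

    return ResultsBundle(overlay_path=job.folder / OVERLAY_FILENAME,
                         csa_csv_path=csa_path, fiber_table_path=table_path,
                         mfi_csv_path=mfi_path)


def process_job(job: ImageJob, config: BatchConfig) -> JobResult:
    """Run the full measurement pipeline on one image field (no file output)."""
    channels = load_job_channels(job)
    pre = preprocess_boundary(channels["boundary"], config.quality)
    params = config.seg_params()
    maps = segment_fiber_maps(pre, params)
    candidates = measure_regions(maps.measured, job.scale)
    fibers = apply_size_filter(candidates, config.limits)

    if "nuclei" in channels and fibers:
        nuclei = detect_nuclei(channels["nuclei"],
                               min_nucleus_area=config.central.min_nucleus_area)
        cnf = classify_all_fibers(maps.interior, nuclei, config.central)
        for f in fibers:
            f.cnf = cnf.get(f.label, False)
    if "intensity" in channels and fibers:
        mfi = compute_all_mfi(maps.interior, channels["intensity"])
        for f in fibers:
            f.mfi = mfi.get(f.label)

    return JobResult(job=job, fibers=fibers,
                     labels_measured=maps.measured,
                     labels_interior=maps.interior,
                     boundary_img=channels["boundary"])


def _write_job_outputs(result: JobResult, config: BatchConfig,
                       results_dir: Path) -> None:
    render_final_overlay(result.boundary_img, result.labels_measured,
                         result.fibers,
                         result.job.folder / OVERLAY_FILENAME)
    result.bundle = write_fiber_outputs(result.job, result.fibers, results_dir)
    if config.keep_intermediates:
        write_gray_tiff(result.job.folder / "labels.tif",
                        result.labels_measured.astype(np.int32))
        write_gray_tiff(result.job.folder / "interior_labels.tif",
                        result.labels_interior.astype(np.int32))


def run_batch(config: BatchConfig) -> BatchSummary:
    """Process every image folder under the main folder, sequentially.

    Individual job failures are logged in the summary and never abort the
    batch. Returns per-job fiber count, mean CSA and %CNF plus errors.
    """
    report: DiscoveryReport = discover_image_folders(
        config.main_folder, config.channels, config.scale)
    summary = BatchSummary(errors=list(report.errors))
    results_dir = Path(config.main_folder) / RESULTS_DIRNAME
    n = len(report.jobs)
    for k, job in enumerate(report.jobs, start=1):
        logger.info("[%d/%d] processing %s", k, n, job.name)
        try:
            result = process_job(job, config)
            _write_job_outputs(result, config, results_dir)
            summary.results.append(result)
            logger.info("[%d/%d] %s: %d fibers", k, n, job.name,
                        len(result.fibers))
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.error("[%d/%d] %s failed: %s", k, n, job.name, exc)
            summary.errors.append((job.name, str(exc)))
    return summary
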