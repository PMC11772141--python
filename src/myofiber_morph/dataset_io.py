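"""Input discovery and image loading.

A batch is a main folder with one subfolder per imaged field; each subfolder
holds unmerged single-channel grayscale images (e.g. ``Laminin.tif``,
``DAPI.tif``, ``RFP.tif``) whose names are consistent across the batch.
Images must be in a lossless format (TIFF preferred) so pixel intensities
carry through to the measurements unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import imageio.v3 as iio
import tifffile

logger = logging.getLogger("myofiber_morph")

PREFERRED_EXTENSIONS = (".tif", ".tiff")
FALLBACK_EXTENSIONS = (".png", ".jpg", ".jpeg")


class DatasetError(RuntimeError):
    """Fatal problem with the input folder layout or configuration."""


@dataclass(frozen=True)
class PixelScale:
    """Effective pixel size: physical camera pixel size divided by total
    magnification, in μm per image pixel. Squared, it converts pixel counts
    to areas in μm²."""

    um_per_pixel: float

    def __post_init__(self) -> None:
        if not self.um_per_pixel > 0:
            raise ValueError(f"um_per_pixel must be > 0, got {self.um_per_pixel}")

    @property
    def area_factor(self) -> float:
        """μm² per pixel."""
        return self.um_per_pixel ** 2


@dataclass(frozen=True)
class ChannelMap:
    """Filename stems of the channels, shared by every folder of a batch.

    ``boundary_name`` (e.g. Laminin) is always required; ``nuclei_name``
    (e.g. DAPI) is needed for central-nucleation calls; ``intensity_name``
    (e.g. RFP) only when per-fiber mean fluorescence intensity is requested.
    """

    boundary_name: str
    nuclei_name: Optional[str] = None
    intensity_name: Optional[str] = None

    def required_stems(self) -> list[str]:
        stems = [self.boundary_name]
        if self.nuclei_name:
            stems.append(self.nuclei_name)
        if self.intensity_name:
            stems.append(self.intensity_name)
        return stems


@dataclass
class ImageJob:
    """One image field: its folder plus the channel stems resolved to files."""

    folder: Path
    channel_files: dict[str, Path]  # role -> concrete file
    scale: PixelScale

    @property
    def name(self) -> str:
        return self.folder.name


@dataclass
class DiscoveryReport:
    jobs: list[ImageJob] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (folder, reason)


def _find_channel_file(folder: Path, stem: str) -> Optional[Path]:
    """Case-insensitive stem match; TIFF preferred over PNG/JPEG fallback."""
    candidates: dict[str, Path] = {}
    for p in folder.iterdir():
        if p.is_file() and p.stem.lower() == stem.lower():
            candidates[p.suffix.lower()] = p
    for ext in PREFERRED_EXTENSIONS:
        if ext in candidates:
            return candidates[ext]
    for ext in FALLBACK_EXTENSIONS:
        if ext in candidates:
            logger.warning(
                "%s: channel %r found only as %s — lossy/fallback format, "
                "intensities may not be preserved", folder.name, stem,
                candidates[ext].name)
            return candidates[ext]
    return None


def discover_image_folders(
    main_folder: Path | str,
    channels: ChannelMap,
    scale: PixelScale,
) -> DiscoveryReport:
    """Scan the immediate subfolders of *main_folder* for image jobs.

    Returns one job per subfolder containing every required channel, sorted
    lexicographically by folder name. Subfolders missing a required channel
    are reported in ``errors`` rather than silently skipped.

    Raises
    ------
    DatasetError
        If *main_folder* does not exist or no subfolder yields a valid job.
    """
    main = Path(main_folder)
    if not main.is_dir():
        raise DatasetError(f"main folder not found: {main}")

    report = DiscoveryReport()
    subfolders = sorted((p for p in main.iterdir() if p.is_dir()),
                        key=lambda p: p.name)
    for sub in subfolders:
        if sub.name.lower() == "results":  # output folder of a previous run
            continue
        files: dict[str, Path] = {}
        missing: list[str] = []
        for role, stem in (("boundary", channels.boundary_name),
                           ("nuclei", channels.nuclei_name),
                           ("intensity", channels.intensity_name)):
            if stem is None:
                continue
            found = _find_channel_file(sub, stem)
            if found is None:
                missing.append(stem)
            else:
                files[role] = found
        if missing:
            report.errors.append(
                (sub.name, f"missing channel file(s): {', '.join(missing)}"))
            continue
        report.jobs.append(ImageJob(folder=sub, channel_files=files, scale=scale))

    if not report.jobs:
        detail = "; ".join(f"{n}: {r}" for n, r in report.errors)
        raise DatasetError(
            "no image folders found under "
            f"{main}" + (f" ({detail})" if detail else ""))
    return report


class ChannelLoadError(RuntimeError):
    """Per-job problem reading a channel image."""


def _to_gray(arr: np.ndarray, source: Path) -> np.ndarray:
    """Reduce a loaded array to a single 2-D gray plane.

    Multi-page stacks use page 0; RGB(A) collapses by the maximum across
    color planes (a fluorescence stain occupies one plane, and max is robust
    to export variations).
    """
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):  # RGB / RGBA
            logger.warning("%s: color image, converting to gray by max over "
                           "color planes", source.name)
            return arr[..., :3].max(axis=-1)
        logger.warning("%s: multi-page image, using page 0 of %d",
                       source.name, arr.shape[0])
        return arr[0]
    raise ChannelLoadError(f"{source}: unsupported image shape {arr.shape}")


def load_channel(job: ImageJob, which: str) -> np.ndarray:
    """Load one channel of a job as a 2-D intensity array.

    ``which`` is a role: ``boundary``, ``nuclei`` or ``intensity``. Pixel
    values are returned exactly as stored (no rescaling); 16-bit data stays
    16-bit. All channels of a job must share identical pixel dimensions —
    the first channel loaded fixes the reference shape.
    """
    if which not in job.channel_files:
        raise ChannelLoadError(f"{job.name}: no file for channel role {which!r}")
    path = job.channel_files[which]
    try:
        if path.suffix.lower() in PREFERRED_EXTENSIONS:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as per-job error
        raise ChannelLoadError(f"{job.name}: cannot read {path.name}: {exc}") from exc
    gray = np.asarray(_to_gray(np.asarray(arr), path))
    if gray.ndim != 2 or gray.size == 0:
        raise ChannelLoadError(f"{job.name}: {path.name} is not a 2-D image")
    return gray


def load_job_channels(job: ImageJob) -> dict[str, np.ndarray]:
    """Load every channel of a job, enforcing identical dimensions."""
    out: dict[str, np.ndarray] = {}
    ref_shape: Optional[tuple[int, int]] = None
    ref_name = ""
    for role in ("boundary", "nuclei", "intensity"):
        if role not in job.channel_files:
            continue
        img = load_channel(job, role)
        if ref_shape is None:
            ref_shape, ref_name = img.shape, job.channel_files[role].name
        elif img.shape != ref_shape:
            raise ChannelLoadError(
                f"{job.name}: channel dimension mismatch — "
                f"{ref_name} is {ref_shape}, "
                f"{job.channel_files[role].name} is {img.shape}")
        out[role] = img
    return out


def write_gray_tiff(path: Path | str, img: np.ndarray) -> None:
    """Write a 2-D image as an uncompressed TIFF, preserving dtype/values."""
    tifffile.imwrite(str(path), np.asarray(img))
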