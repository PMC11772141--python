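"""Synthetic muscle-cross-section generator with exact ground truth.

A scene emulates a transverse immunofluorescence field: a bright, closed
boundary network (laminin-like) enclosing convex-ish fiber interiors, a
nuclear channel with one blob per assigned nucleus (placed centrally or
just under the fiber border), and an optional intensity channel in which
every fiber is filled at a known mean. Fibers are cells of a Voronoi
tessellation of the field, regularized by a couple of Lloyd relaxation
steps so cells are roundish and fairly uniform, as in healthy muscle.

The ground truth records each cell's exact polygon (and its shoelace area),
nucleus placement and true intensity mean, so every pipeline stage can be
checked against a known answer. A single seeded generator drives all
randomness: the same spec and seed reproduce a scene bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon

from .dataset_io import PixelScale, write_gray_tiff


class GenerationError(RuntimeError):
    """The requested scene cannot be built (e.g. too many fibers for the field)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field.

    Areas are in μm² and converted internally with ``um_per_pixel``. The
    per-fiber target areas are drawn from a lognormal distribution with the
    given mean and log-space sigma, truncated to ``area_range`` (muscle CSA
    histograms are right-skewed); they set the relative sizes of the Voronoi
    seeds, while ``lloyd_iters`` relaxation steps regularize cell shapes.
    The field is sized so the mean realized cell area equals
    ``area_mean_um2`` when ``field_size`` is not given.

    ``boundary_gap_rate`` removes approximately that fraction of boundary
    pixels by punching small holes (radius ``gap_radius``) through the band,
    mimicking local staining dropout. ``noise_sigma`` is the σ of additive
    Gaussian noise, in the same AU as the channel intensities
    (``ridge_intensity`` for the boundary band).
    """

    n_fibers: int = 50
    seed: int = 0
    field_size: Optional[int] = None          # px; derived from areas if None
    area_mean_um2: float = 2000.0             # uninjured mouse TA scale
    area_sigma_log: float = 0.30
    area_range: tuple[float, float] = (200.0, 4800.0)
    um_per_pixel: float = 1.0
    boundary_width: float = 3.0               # px, full band thickness
    boundary_gap_rate: float = 0.0
    gap_radius: int = 1
    noise_sigma: float = 0.0
    ridge_intensity: float = 200.0
    nucleus_intensity: float = 200.0
    nucleus_radius: int = 3
    central_fraction_of_fibers: float = 0.0
    peripheral_fraction_of_fibers: float = 0.0
    per_fiber_intensity_means: Optional[Sequence[float]] = None
    intensity_mean_range: Optional[tuple[float, float]] = None
    lloyd_iters: int = 2

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        for name in ("boundary_gap_rate", "central_fraction_of_fibers",
                     "peripheral_fraction_of_fibers"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if (self.central_fraction_of_fibers
                + self.peripheral_fraction_of_fibers) > 1.0 + 1e-9:
            raise ValueError("nucleus fractions sum to more than 1")
        if self.per_fiber_intensity_means is not None and \
                len(self.per_fiber_intensity_means) != self.n_fibers:
            raise ValueError("per_fiber_intensity_means length != n_fibers")


@dataclass
class FiberTruth:
    """Exact truth for one synthetic fiber (1-based id)."""

    id: int
    polygon_xy: np.ndarray          # (k, 2) vertices, (x=col, y=row) in px
    area_um2: float                 # shoelace polygon area × scale²
    perimeter_px: float
    centroid_rc: tuple[float, float]
    nucleus: str                    # 'central' | 'peripheral' | 'none'
    nucleus_rc: Optional[tuple[float, float]] = None
    intensity_mean: Optional[float] = None


@dataclass
class GroundTruth:
    spec: SceneSpec
    fibers: list[FiberTruth]
    label_map: np.ndarray           # pixel -> fiber id (covers whole field)
    boundary_band: np.ndarray       # bool mask of the rendered band
    field_size: int

    @property
    def n_central(self) -> int:
        return sum(f.nucleus == "central" for f in self.fibers)


@dataclass
class Scene:
    boundary: np.ndarray
    nuclei: np.ndarray
    intensity: Optional[np.ndarray]
    truth: GroundTruth


# ---------------------------------------------------------------- geometry

def _bounded_voronoi(points: np.ndarray, size: float) -> list[Polygon]:
    """Voronoi cells of *points* clipped to the square [0, size]².

    Uses the reflection trick: mirror every seed across the four box sides;
    the cells of the original seeds in the augmented diagram are finite and
    tile the box exactly.
    """
    p = points
    mirrored = np.vstack([
        p,
        np.column_stack([-p[:, 0], p[:, 1]]),
        np.column_stack([2 * size - p[:, 0], p[:, 1]]),
        np.column_stack([p[:, 0], -p[:, 1]]),
        np.column_stack([p[:, 0], 2 * size - p[:, 1]]),
    ])
    vor = Voronoi(mirrored)
    polys = []
    for i in range(len(p)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys.append(poly)
    return polys


def _sample_target_areas(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated-lognormal target areas (μm²), rescaled to the exact mean."""
    mu = math.log(spec.area_mean_um2) - 0.5 * spec.area_sigma_log ** 2
    lo, hi = spec.area_range
    out = np.empty(spec.n_fibers)
    filled = 0
    for _ in range(1000):
        draw = rng.lognormal(mu, spec.area_sigma_log, size=spec.n_fibers)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), spec.n_fibers - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
        if filled == spec.n_fibers:
            break
    else:
        raise GenerationError("area distribution truncation rejects everything")
    out *= spec.area_mean_um2 / out.mean()
    return np.clip(out, lo, hi)


def _throw_seeds(areas_px: np.ndarray, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Dart-throw one seed per fiber, larger targets first, keeping seeds
    apart in proportion to their target radii. Raises when the field cannot
    host the request."""
    n = len(areas_px)
    radii = np.sqrt(areas_px / math.pi)
    order = np.argsort(-radii)
    placed: list[tuple[float, float, float]] = []  # x, y, r
    coords = np.empty((n, 2))
    for idx in order:
        r = radii[idx]
        margin = min(0.5 * r, size / 2 - 1)
        ok = False
        for _ in range(5000):
            x = rng.uniform(margin, size - margin)
            y = rng.uniform(margin, size - margin)
            if all((x - px) ** 2 + (y - py) ** 2 >= (0.7 * (r + pr)) ** 2
                   for px, py, pr in placed):
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"cannot place {n} fibers of the requested areas in a "
                f"{size}×{size} px field")
        placed.append((x, y, r))
        coords[idx] = (x, y)
    return coords


def _edge_pixels(label_map: np.ndarray) -> np.ndarray:
    """One-sided inter-cell edge: pixels whose right or lower neighbour
    belongs to a different cell (the field frame is not an edge)."""
    edge = np.zeros(label_map.shape, dtype=bool)
    edge[:, :-1] |= label_map[:, :-1] != label_map[:, 1:]
    edge[:-1, :] |= label_map[:-1, :] != label_map[1:, :]
    return edge


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return np.column_stack([dy[keep], dx[keep]])


def _punch_gaps(band: np.ndarray, rate: float, gap_radius: int,
                rng: np.random.Generator) -> np.ndarray:
    """Delete ≈ rate × band pixels by punching isolated disks through the
    band. Punch centres are kept apart so individual gaps stay the size set
    by *gap_radius* (openings of about 2 × gap_radius) instead of fusing
    into longer breaks."""
    if rate <= 0:
        return band
    band = band.copy()
    total = int(band.sum())
    target = int(round(rate * total))
    offs = _disk_offsets(gap_radius)
    block_offs = _disk_offsets(2 * gap_radius + 2)
    allowed = band.copy()
    h, w = band.shape
    removed = 0
    for _ in range(4 * total):
        if removed >= target:
            break
        ys, xs = np.nonzero(allowed)
        if len(ys) == 0:
            break
        k = rng.integers(len(ys))
        rr = ys[k] + offs[:, 0]
        cc = xs[k] + offs[:, 1]
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        before = int(band.sum())
        band[rr[keep], cc[keep]] = False
        removed += before - int(band.sum())
        br = ys[k] + block_offs[:, 0]
        bc = xs[k] + block_offs[:, 1]
        bkeep = (br >= 0) & (br < h) & (bc >= 0) & (bc < w)
        allowed[br[bkeep], bc[bkeep]] = False
    return band


# ---------------------------------------------------------------- generator

def generate_cross_section(spec: SceneSpec) -> Scene:
    """Build one synthetic field: boundary, nuclei and optional intensity
    channels plus exact ground truth. Fully determined by the spec (incl.
    its seed)."""
    rng = np.random.default_rng(spec.seed)
    scale = PixelScale(spec.um_per_pixel)
    areas_um2 = _sample_target_areas(spec, rng)
    areas_px = areas_um2 / scale.area_factor

    if spec.field_size is None:
        size = int(round(math.sqrt(areas_px.sum())))
    else:
        size = int(spec.field_size)
        ratio = areas_px.sum() / size ** 2
        if not (0.4 <= ratio <= 2.5):
            raise GenerationError(
                f"{spec.n_fibers} fibers of mean {spec.area_mean_um2} μm² "
                f"do not fit a {size}×{size} px field")
        areas_px = areas_px * (size ** 2 / areas_px.sum())

    lo_px = spec.area_range[0] / scale.area_factor
    hi_px = spec.area_range[1] / scale.area_factor

    best: Optional[tuple[np.ndarray, list[Polygon]]] = None
    best_violation = math.inf
    for _attempt in range(5):
        seeds = _throw_seeds(areas_px, size, rng)
        polys = _bounded_voronoi(seeds, size)
        for it in range(spec.lloyd_iters + 4):
            realized = np.array([p.area for p in polys])
            violation = max(0.0, float(lo_px - realized.min())) + \
                max(0.0, float(realized.max() - hi_px))
            in_range = violation == 0.0
            if in_range and it >= spec.lloyd_iters:
                break
            if it == spec.lloyd_iters + 3:
                break
            seeds = np.array([[p.centroid.x, p.centroid.y] for p in polys])
            seeds = np.clip(seeds, 1.0, size - 1.0)
            polys = _bounded_voronoi(seeds, size)
        realized = np.array([p.area for p in polys])
        violation = max(0.0, float(lo_px - realized.min())) + \
            max(0.0, float(realized.max() - hi_px))
        if violation < best_violation:
            best_violation = violation
            best = (seeds, polys)
        if violation == 0.0:
            break
    assert best is not None
    seeds, polys = best
    if best_violation > 0:
        warnings.warn(
            "realized cell areas exceed the requested truncation range "
            f"(violation {best_violation:.1f} px²)", stacklevel=2)

    # pixel -> cell assignment: nearest seed (exact for a Voronoi diagram)
    rows, cols = np.mgrid[0:size, 0:size]
    pix = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])  # (x, y)
    _, nearest = cKDTree(seeds).query(pix)
    label_map = (nearest.reshape(size, size) + 1).astype(np.int32)

    # boundary band centred on inter-cell edges
    edge = _edge_pixels(label_map)
    dist_to_edge = ndi.distance_transform_edt(~edge)
    band = dist_to_edge <= max(0.0, (spec.boundary_width - 1.0) / 2.0)
    band = _punch_gaps(band, spec.boundary_gap_rate, spec.gap_radius, rng)

    # nucleus assignment
    n = spec.n_fibers
    n_central = round(spec.central_fraction_of_fibers * n)
    n_periph = round(spec.peripheral_fraction_of_fibers * n)
    perm = rng.permutation(n)
    placement = {int(perm[i]) + 1: ("central" if i < n_central else
                                    "peripheral" if i < n_central + n_periph
                                    else "none")
                 for i in range(n)}

    # interior depth per pixel (distance to the nearest inter-cell edge)
    interior_depth = dist_to_edge
    nuclei_img = np.zeros((size, size), dtype=np.float64)
    nuc_offs = _disk_offsets(spec.nucleus_radius)

    # intensity means
    if spec.per_fiber_intensity_means is not None:
        means: Optional[np.ndarray] = np.asarray(
            spec.per_fiber_intensity_means, dtype=float)
    elif spec.intensity_mean_range is not None:
        lo_i, hi_i = spec.intensity_mean_range
        means = rng.uniform(lo_i, hi_i, size=n)
    else:
        means = None

    fibers: list[FiberTruth] = []
    for fid in range(1, n + 1):
        poly = polys[fid - 1]
        verts = np.asarray(poly.exterior.coords[:-1])
        cen = poly.centroid
        cell = label_map == fid
        nuc_rc: Optional[tuple[float, float]] = None
        kind = placement[fid]
        if kind == "central":
            depth = np.where(cell, interior_depth, -1.0)
            r0, c0 = np.unravel_index(int(depth.argmax()), depth.shape)
            nuc_rc = (float(r0), float(c0))
        elif kind == "peripheral":
            want = spec.nucleus_radius + 1.0
            depth = np.where(cell, interior_depth, np.nan)
            cand = np.flatnonzero(cell.ravel() &
                                  (np.abs(interior_depth - want).ravel() <= 0.5))
            if len(cand) == 0:
                cand = np.array([np.nanargmin(np.abs(depth - want))])
            k = int(cand[rng.integers(len(cand))])
            r0, c0 = np.unravel_index(k, cell.shape)
            nuc_rc = (float(r0), float(c0))
        if nuc_rc is not None:
            rr = int(nuc_rc[0]) + nuc_offs[:, 0]
            cc = int(nuc_rc[1]) + nuc_offs[:, 1]
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            nuclei_img[rr[keep], cc[keep]] = spec.nucleus_intensity
        fibers.append(FiberTruth(
            id=fid, polygon_xy=verts,
            area_um2=float(poly.area) * scale.area_factor,
            perimeter_px=float(poly.length),
            centroid_rc=(float(cen.y), float(cen.x)),
            nucleus=kind, nucleus_rc=nuc_rc,
            intensity_mean=(float(means[fid - 1]) if means is not None else None),
        ))

    boundary_img = np.where(band, spec.ridge_intensity, 0.0)
    intensity_img: Optional[np.ndarray] = None
    if means is not None:
        intensity_img = means[label_map - 1].astype(np.float64)

    if spec.noise_sigma > 0:
        boundary_img = boundary_img + rng.normal(0, spec.noise_sigma,
                                                 boundary_img.shape)
        nuclei_img = nuclei_img + rng.normal(0, spec.noise_sigma,
                                             nuclei_img.shape)
        np.clip(boundary_img, 0, None, out=boundary_img)
        np.clip(nuclei_img, 0, None, out=nuclei_img)
        if intensity_img is not None:
            intensity_img = intensity_img + rng.normal(
                0, spec.noise_sigma, intensity_img.shape)
            np.clip(intensity_img, 0, None, out=intensity_img)

    truth = GroundTruth(spec=spec, fibers=fibers, label_map=label_map,
                        boundary_band=band, field_size=size)
    return Scene(boundary=boundary_img.astype(np.float32),
                 nuclei=nuclei_img.astype(np.float32),
                 intensity=(intensity_img.astype(np.float32)
                            if intensity_img is not None else None),
                 truth=truth)


# ---------------------------------------------------------------- fixtures

TRUTH_FILENAME = "ground_truth.tsv"


def write_truth_table(truth: GroundTruth, path: Path) -> None:
    """Tab-separated ground-truth table (one row per fiber; seed recorded)."""
    lines = [f"# seed={truth.spec.seed}\tfield_size={truth.field_size}"
             f"\tum_per_pixel={truth.spec.um_per_pixel}"]
    lines.append("fiber\tarea_um2\tcentroid_row\tcentroid_col\tnucleus"
                 "\tnucleus_row\tnucleus_col\tintensity_mean")
    for f in truth.fibers:
        nr = "" if f.nucleus_rc is None else f"{f.nucleus_rc[0]:.1f}"
        nc = "" if f.nucleus_rc is None else f"{f.nucleus_rc[1]:.1f}"
        im = "" if f.intensity_mean is None else f"{f.intensity_mean:.6f}"
        lines.append(f"{f.id}\t{f.area_um2:.4f}\t{f.centroid_rc[0]:.3f}"
                     f"\t{f.centroid_rc[1]:.3f}\t{f.nucleus}\t{nr}\t{nc}\t{im}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_batch(
    specs: Sequence[SceneSpec],
    out_folder: Path | str,
    boundary_name: str = "Laminin",
    nuclei_name: str = "DAPI",
    intensity_name: str = "RFP",
) -> list[Path]:
    """Render scenes into the on-disk layout the pipeline consumes: one
    subfolder per scene with single-channel TIFFs plus the truth table.
    Returns the scene folders (scene_001, scene_002, ...)."""
    out = Path(out_folder)
    out.mkdir(parents=True, exist_ok=True)
    folders = []
    for i, spec in enumerate(specs, start=1):
        scene = generate_cross_section(spec)
        sub = out / f"scene_{i:03d}"
        sub.mkdir(exist_ok=True)
        write_gray_tiff(sub / f"{boundary_name}.tif", scene.boundary)
        write_gray_tiff(sub / f"{nuclei_name}.tif", scene.nuclei)
        if scene.intensity is not None:
            write_gray_tiff(sub / f"{intensity_name}.tif", scene.intensity)
        write_truth_table(scene.truth, sub / TRUTH_FILENAME)
        folders.append(sub)
    return folders
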