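"""Synthetic multichannel stacks, ground truth, and beating traces.

The generator emulates the statistical structure of stained whole-mount
preparations of multiciliated ependymal cells so that every downstream stage
(detection, geometry, orientation, intensity ratios, kinetics) can be tested
against exact ground truth:

* a field tiled by convex (rectangular) cell-border polygons;
* per cell, a centriolar patch — a disk placed with a configurable anterior
  offset — containing ``centrioles_per_cell`` centrin puncta with a minimum
  inter-centriole spacing (dart-throwing; generation fails loudly when the
  requested spacing cannot fit in the patch);
* one Cep164 punctum per centriole, displaced in xy by ``cep164_offset_um``
  along a per-cell mean direction with wrapped-normal angular dispersion
  (a single displaced punctum per centriole: the orientation pipeline needs
  one Cep164 centroid per basal body, not a resolved appendage ring);
* puncta rendered as 3D Gaussians of PSF width; an actin channel with two
  z-bands (apical at the Cep164 plane, subapical deeper by a configurable
  offset, default 1.4 um so the two 6-slice measurement windows are disjoint
  at 0.23 um z-sampling) rendered
  piecewise-constant so that the patch/rest mean ratio equals the requested
  value exactly before noise; a membrane channel marking cell borders;
* Poisson-then-Gaussian noise, both stages seeded (camera statistics);
* sinusoidal or asymmetric-stroke beating traces with exact peak-to-peak
  amplitude before noise.

Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from shapely.geometry import Polygon, box

from .detection import VoxelGrid
from .kinetics import BeatTrace

__all__ = [
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "BeatSpec",
    "render_stack",
    "render_trace",
    "write_scene",
]

#: Random-sequential-adsorption feasibility margin for disk packing: we refuse
#: specs denser than ~40% of the jamming density so dart throwing terminates.
_PACKING_FACTOR = 1.6


@dataclass
class SceneSpec:
    """Parameters of a synthetic multicell scene.

    Axis conventions follow the rest of the package: arrays are (z, y, x) and
    ``voxel_size_um`` / ``psf_sigma_um`` are given in (z, y, x) order; the
    default z-step is 0.23 um, the standard sampling used to include all
    centrioles of a cell in one stack.
    """

    n_cells: int = 4
    cell_size_um: float = 8.0
    centrioles_per_cell: int | tuple[int, ...] = 30  # scalar or one count per cell
    patch_radius_um: float = 1.8
    patch_offset_um: float = 1.2  # anterior (+x) displacement of the patch centre
    min_spacing_um: float = 0.4
    cep164_offset_um: float = 0.25
    orientation_mean_rad: float | None = None  # None: per-cell uniform random
    orientation_sd_rad: float = 0.35  # wrapped-normal angular dispersion
    actin_ratio_apical: float = 2.0
    actin_ratio_subapical: float = 1.5
    actin_base: float = 100.0
    border_width_um: float = 0.3
    psf_sigma_um: tuple[float, float, float] = (0.25, 0.1, 0.1)
    puncta_amplitude: float = 1000.0
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float = 0.0  # 0 disables shot noise
    voxel_size_um: tuple[float, float, float] = (0.23, 0.1, 0.1)
    n_z: int = 20
    apical_z_um: float = 2.5
    subapical_depth_um: float = 1.4  # subapical band anchor this far below the apical plane
    centriole_z_jitter_um: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "cell_size_um": self.cell_size_um,
            "patch_radius_um": self.patch_radius_um,
            "min_spacing_um": self.min_spacing_um,
            "actin_base": self.actin_base,
            "puncta_amplitude": self.puncta_amplitude,
        }
        for name, value in positives.items():
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        counts = self.cell_counts()
        if len(counts) != self.n_cells:
            raise ValueError("per-cell counts must have one entry per cell")
        if any(c < 0 for c in counts):
            raise ValueError("centrioles_per_cell must be >= 0")
        if self.cep164_offset_um < 0 or self.orientation_sd_rad < 0:
            raise ValueError("cep164 offset and angular dispersion must be >= 0")
        if self.actin_ratio_apical < 0 or self.actin_ratio_subapical < 0:
            raise ValueError("actin ratios must be >= 0")
        if any(d <= 0 for d in self.voxel_size_um) or any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("voxel sizes and PSF sigmas must be strictly positive")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        # Spacing feasibility inside the patch disk (loud failure, not a hang).
        n = max(counts)
        if n > 1 and n * self.min_spacing_um**2 > _PACKING_FACTOR * self.patch_radius_um**2:
            raise ValueError(
                f"{n} centrioles with min spacing {self.min_spacing_um} um cannot be "
                f"packed into a patch of radius {self.patch_radius_um} um"
            )
        # The patch (plus Cep164 offsets) must fit inside the cell interior.
        reach = self.patch_offset_um + self.patch_radius_um + self.cep164_offset_um
        if reach + self.border_width_um >= self.cell_size_um / 2:
            raise ValueError(
                "patch offset + radius + cep164 offset + border width exceed the half "
                "cell size; the patch would cross the cell border"
            )
        if not (0 <= self.apical_z_um < self.n_z * self.voxel_size_um[0]):
            raise ValueError("apical plane must lie inside the stack")
        if self.apical_z_um + self.subapical_depth_um >= self.n_z * self.voxel_size_um[0]:
            raise ValueError("subapical plane must lie inside the stack")
        # The two 6-slice measurement windows must not overlap in z, otherwise
        # the requested patch/rest ratios are not individually recoverable.
        dz = self.voxel_size_um[0]
        a = _band_slices(self.apical_z_um, 6, dz, self.n_z)
        s = _band_slices(self.apical_z_um + self.subapical_depth_um, 6, dz, self.n_z)
        if a.stop > s.start:
            raise ValueError(
                "apical and subapical 6-slice bands overlap in z; increase "
                "subapical_depth_um or refine the z-sampling"
            )

    def cell_counts(self) -> tuple[int, ...]:
        """Per-cell centriole counts (a scalar spec applies to every cell)."""
        if isinstance(self.centrioles_per_cell, int):
            return (self.centrioles_per_cell,) * self.n_cells
        return tuple(int(c) for c in self.centrioles_per_cell)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Cell layout (rows, cols): the most square grid holding n_cells."""
        cols = int(np.ceil(np.sqrt(self.n_cells)))
        rows = int(np.ceil(self.n_cells / cols))
        return rows, cols

    @property
    def stack_shape(self) -> tuple[int, int, int]:
        rows, cols = self.grid_shape
        dy, dx = self.voxel_size_um[1], self.voxel_size_um[2]
        return (
            self.n_z,
            int(round(rows * self.cell_size_um / dy)),
            int(round(cols * self.cell_size_um / dx)),
        )


@dataclass
class CellTruth:
    """Ground truth for one cell."""

    cell_id: int
    polygon: Polygon  # cell border in xy (um)
    centrin_um: np.ndarray  # (n, 3) columns (x, y, z)
    cep164_um: np.ndarray  # (n, 3), index-aligned with centrin_um
    angles_rad: np.ndarray  # (n,) true per-pair displacement directions
    mean_direction_rad: float
    patch_center_um: tuple[float, float]
    patch_radius_um: float


@dataclass
class GroundTruth:
    """Scene-level ground truth: per-cell point sets plus global geometry."""

    cells: list[CellTruth]
    apical_z_um: float
    subapical_z_um: float
    actin_ratio_apical: float
    actin_ratio_subapical: float
    voxel_size_um: tuple[float, float, float]
    stack_shape: tuple[int, int, int]
    border_width_um: float

    def all_centrin(self) -> np.ndarray:
        arrs = [c.centrin_um for c in self.cells if len(c.centrin_um)]
        return np.vstack(arrs) if arrs else np.empty((0, 3))

    def all_cep164(self) -> np.ndarray:
        arrs = [c.cep164_um for c in self.cells if len(c.cep164_um)]
        return np.vstack(arrs) if arrs else np.empty((0, 3))

    def cell_polygons(self) -> dict[int, Polygon]:
        return {c.cell_id: c.polygon for c in self.cells}

    def _xy_pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        _, ny, nx = self.stack_shape
        dy, dx = self.voxel_size_um[1], self.voxel_size_um[2]
        ys = (np.arange(ny) + 0.5) * dy
        xs = (np.arange(nx) + 0.5) * dx
        return np.meshgrid(ys, xs, indexing="ij")

    def masks(self, cell_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(cell_mask, patch_mask) boolean xy rasters for one cell.

        The cell mask is the border-eroded cell interior (border pixels are
        excluded, as they are from intensity measurements); the patch mask is
        the patch disk.  These are the exact masks the actin renderer uses.
        """
        cell = next(c for c in self.cells if c.cell_id == cell_id)
        yy, xx = self._xy_pixel_centres()
        minx, miny, maxx, maxy = cell.polygon.bounds
        b = self.border_width_um
        cell_mask = (
            (xx >= minx + b) & (xx <= maxx - b) & (yy >= miny + b) & (yy <= maxy - b)
        )
        px, py = cell.patch_center_um
        patch_mask = (xx - px) ** 2 + (yy - py) ** 2 <= cell.patch_radius_um**2
        return cell_mask, patch_mask & cell_mask

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: cell_id, object_type, x_um, y_um, z_um, partner_id, angle_rad."""
        rows = []
        for cell in self.cells:
            for i, ((cx, cy, cz), (ax, ay, az), th) in enumerate(
                zip(cell.centrin_um, cell.cep164_um, cell.angles_rad)
            ):
                rows.append((cell.cell_id, "centrin", cx, cy, cz, i, th))
                rows.append((cell.cell_id, "cep164", ax, ay, az, i, th))
        return pd.DataFrame(
            rows, columns=["cell_id", "object_type", "x_um", "y_um", "z_um", "partner_id", "angle_rad"]
        )


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _sample_patch_points(
    rng: np.random.Generator,
    centre: tuple[float, float],
    radius: float,
    n: int,
    min_spacing: float,
) -> np.ndarray:
    """Dart-throwing sample of n xy points in a disk with pairwise min spacing."""
    pts: list[np.ndarray] = []
    max_attempts = 400 * max(n, 1)
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} points with spacing {min_spacing} um in a "
                f"disk of radius {radius} um after {max_attempts} attempts"
            )
        attempts += 1
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        p = np.array([centre[0] + r * np.cos(phi), centre[1] + r * np.sin(phi)])
        if all(np.hypot(*(p - q)) >= min_spacing for q in pts):
            pts.append(p)
    return np.array(pts) if pts else np.empty((0, 2))


def _add_gaussian_punctum(
    stack: np.ndarray,
    pos_xyz_um: np.ndarray,
    sigma_zyx_um: tuple[float, float, float],
    amplitude: float,
    voxel_size_zyx: tuple[float, float, float],
) -> None:
    """Add one 3D Gaussian punctum (evaluated at voxel centres) in place."""
    centre_zyx = pos_xyz_um[::-1]
    vox = np.asarray(voxel_size_zyx)
    sig = np.asarray(sigma_zyx_um)
    centre_idx = centre_zyx / vox - 0.5
    half = np.ceil(4 * sig / vox).astype(int)
    lo = np.maximum(np.floor(centre_idx).astype(int) - half, 0)
    hi = np.minimum(np.floor(centre_idx).astype(int) + half + 1, stack.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    d2 = (
        ((zz - centre_idx[0]) * vox[0] / sig[0]) ** 2
        + ((yy - centre_idx[1]) * vox[1] / sig[1]) ** 2
        + ((xx - centre_idx[2]) * vox[2] / sig[2]) ** 2
    )
    stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-0.5 * d2)


def _band_slices(anchor_z_um: float, n_slices: int, dz: float, nz: int) -> slice:
    """z-slice window: anchor plane plus 3 above / 2 below for 6 slices."""
    anchor = int(np.floor(anchor_z_um / dz))
    below = (n_slices - 1) // 2 if n_slices % 2 == 1 else n_slices // 2 - 1
    above = n_slices - 1 - below
    return slice(max(anchor - below, 0), min(anchor + above + 1, nz))


def render_stack(spec: SceneSpec) -> tuple[dict[str, VoxelGrid], GroundTruth]:
    """Render a multichannel scene and its exact ground truth.

    Returns ``(channels, truth)`` where ``channels`` maps
    ``{"centrin", "cep164", "actin", "membrane"}`` to VoxelGrids.  Centrin and
    Cep164 puncta are 3D Gaussians of PSF width at the ground-truth positions;
    the actin channel is piecewise-constant inside two 6-slice z-bands so its
    patch/rest mean ratio equals the requested value exactly before noise;
    noise is Poisson (optional) then Gaussian, both driven by ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows, cols = spec.grid_shape
    nz, ny, nx = spec.stack_shape
    dz, dy, dx = spec.voxel_size_um

    cells: list[CellTruth] = []
    counts = spec.cell_counts()
    for cid in range(spec.n_cells):
        r, c = divmod(cid, cols)
        x0, y0 = c * spec.cell_size_um, r * spec.cell_size_um
        poly = box(x0, y0, x0 + spec.cell_size_um, y0 + spec.cell_size_um)
        centre = (x0 + spec.cell_size_um / 2 + spec.patch_offset_um, y0 + spec.cell_size_um / 2)
        n = counts[cid]
        xy = _sample_patch_points(rng, centre, spec.patch_radius_um, n, spec.min_spacing_um)
        z = spec.apical_z_um + (
            rng.normal(0.0, spec.centriole_z_jitter_um, size=n) if n else np.empty(0)
        )
        z = np.clip(z, 0.5 * dz, (nz - 0.5) * dz)
        centrin = np.column_stack([xy, z]) if n else np.empty((0, 3))
        mean_dir = (
            rng.uniform(0, 2 * np.pi)
            if spec.orientation_mean_rad is None
            else float(spec.orientation_mean_rad)
        )
        angles = mean_dir + rng.normal(0.0, spec.orientation_sd_rad, size=n)
        offs = spec.cep164_offset_um * np.column_stack([np.cos(angles), np.sin(angles)])
        cep164 = (
            np.column_stack([xy + offs, z]) if n else np.empty((0, 3))
        )
        cells.append(
            CellTruth(
                cell_id=cid,
                polygon=poly,
                centrin_um=centrin,
                cep164_um=cep164,
                angles_rad=np.asarray(angles, dtype=float),
                mean_direction_rad=mean_dir,
                patch_center_um=centre,
                patch_radius_um=spec.patch_radius_um,
            )
        )

    truth = GroundTruth(
        cells=cells,
        apical_z_um=spec.apical_z_um,
        subapical_z_um=spec.apical_z_um + spec.subapical_depth_um,
        actin_ratio_apical=spec.actin_ratio_apical,
        actin_ratio_subapical=spec.actin_ratio_subapical,
        voxel_size_um=spec.voxel_size_um,
        stack_shape=(nz, ny, nx),
        border_width_um=spec.border_width_um,
    )

    centrin_ch = np.zeros((nz, ny, nx))
    cep164_ch = np.zeros((nz, ny, nx))
    for cell in cells:
        for pos in cell.centrin_um:
            _add_gaussian_punctum(centrin_ch, pos, spec.psf_sigma_um, spec.puncta_amplitude, spec.voxel_size_um)
        for pos in cell.cep164_um:
            _add_gaussian_punctum(cep164_ch, pos, spec.psf_sigma_um, spec.puncta_amplitude, spec.voxel_size_um)

    actin_ch = np.zeros((nz, ny, nx))
    membrane_ch = np.zeros((nz, ny, nx))
    apical_band = _band_slices(spec.apical_z_um, 6, dz, nz)
    subapical_band = _band_slices(spec.apical_z_um + spec.subapical_depth_um, 6, dz, nz)
    border_2d = np.zeros((ny, nx), dtype=bool)
    for cell in cells:
        cell_mask, patch_mask = truth.masks(cell.cell_id)
        for band, ratio in ((apical_band, spec.actin_ratio_apical), (subapical_band, spec.actin_ratio_subapical)):
            plane = np.zeros((ny, nx))
            plane[cell_mask] = spec.actin_base
            plane[patch_mask] = ratio * spec.actin_base
            actin_ch[band] += plane
        # Border band of this cell: inside the polygon, outside the eroded interior.
        minx, miny, maxx, maxy = cell.polygon.bounds
        yy, xx = truth._xy_pixel_centres()
        inside = (xx >= minx) & (xx < maxx) & (yy >= miny) & (yy < maxy)
        border_2d |= inside & ~cell_mask
    membrane_ch[apical_band] = np.where(border_2d, spec.actin_base, 0.0)

    channels: dict[str, VoxelGrid] = {}
    noise_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    for name, data in (
        ("centrin", centrin_ch),
        ("cep164", cep164_ch),
        ("actin", actin_ch),
        ("membrane", membrane_ch),
    ):
        noisy = data
        if spec.noise_poisson_scale > 0:
            noisy = noise_rng.poisson(np.maximum(noisy, 0) * spec.noise_poisson_scale) / spec.noise_poisson_scale
        if spec.noise_gaussian_sd > 0:
            noisy = noisy + noise_rng.normal(0.0, spec.noise_gaussian_sd, size=noisy.shape)
        channels[name] = VoxelGrid(noisy, spec.voxel_size_um, channel=name)
    return channels, truth


# ---------------------------------------------------------------------------
# Beating traces
# ---------------------------------------------------------------------------

@dataclass
class BeatSpec:
    """Parameters of a synthetic beating trace.

    The 250 Hz default sampling rate matches high-speed phase-contrast
    recording of ependymal cilia.  ``amplitude`` is half the peak-to-peak
    excursion: the rendered noiseless trace is affinely normalised so its
    range is exactly ``2 * amplitude``.
    """

    frequency_hz: float = 28.0
    amplitude_um: float = 5.0
    sampling_rate_hz: float = 250.0
    duration_s: float = 1.0
    noise_sd: float = 0.0
    waveform: str = "sinusoid"  # or "asymmetric"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.frequency_hz < 0 or self.amplitude_um < 0 or self.noise_sd < 0:
            raise ValueError("frequency, amplitude and noise must be >= 0")
        if self.frequency_hz >= self.sampling_rate_hz / 2:
            raise ValueError(
                f"frequency {self.frequency_hz} Hz violates Nyquist at "
                f"{self.sampling_rate_hz} Hz sampling"
            )
        if self.frequency_hz > 0 and self.duration_s * self.frequency_hz < 2:
            raise ValueError("duration must cover at least 2 full beat periods")
        if self.waveform not in {"sinusoid", "asymmetric"}:
            raise ValueError(f"unknown waveform {self.waveform!r}")


def render_trace(spec: BeatSpec) -> BeatTrace:
    """Render a tip-position beating trace (um) per the BeatSpec.

    The noiseless trace has peak-to-peak range exactly ``2 * amplitude_um``
    (affine normalisation of the sampled waveform); ``frequency_hz = 0``
    yields a constant trace.  Gaussian noise is added afterwards, seeded.
    """
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = np.arange(n) / spec.sampling_rate_hz
    if spec.frequency_hz == 0 or spec.amplitude_um == 0:
        x = np.zeros(n)
    else:
        phase = 2 * np.pi * spec.frequency_hz * t
        if spec.waveform == "sinusoid":
            raw = np.sin(phase)
        else:  # asymmetric power/recovery stroke: fast rise, slow return
            raw = _signal.sawtooth(phase, width=0.3)
        lo, hi = float(raw.min()), float(raw.max())
        x = (raw - (hi + lo) / 2) * (2 * spec.amplitude_um / (hi - lo))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return BeatTrace(samples=x, sampling_rate=spec.sampling_rate_hz, roi=f"synthetic-{spec.waveform}")


# ---------------------------------------------------------------------------
# Scene export
# ---------------------------------------------------------------------------

def write_scene(
    channels: dict[str, VoxelGrid],
    truth: GroundTruth,
    spec: SceneSpec,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one TIFF per channel, the ground-truth CSV and the spec JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, grid in channels.items():
        p = out / f"{name}.tif"
        tifffile.imwrite(p, grid.data.astype(np.float32))
        paths[name] = p
    gt_path = out / "ground_truth.csv"
    truth.to_dataframe().to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path
    spec_path = out / "scene_spec.json"
    spec_path.write_text(json.dumps(asdict(spec), indent=2))
    paths["scene_spec"] = spec_path
    return paths
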