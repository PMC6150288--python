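"""Water-occupancy grids and hydration sites from trajectory frames.

Occupancy of a voxel is the fraction of trajectory frames in which at least
one water oxygen falls inside it (binary per frame), on a regular grid of
1 angstrom mesh by default.  Contiguous (26-connected) clusters of voxels
above an occupancy threshold — 0.8 by default — are reported as hydration
sites: structurally conserved water positions in a binding site.

Only water oxygens are counted; hydrogens are ignored.  Frames from multiple
replica trajectories are pooled before computing occupancy.  Voxels use
half-open axis-aligned intervals ``[low, low + spacing)`` anchored at an
origin snapped to integer angstrom below the region's lower corner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = ["FrameSet", "Sphere", "Box", "OccupancyGrid", "HydrationSite",
           "occupancy_map", "hydration_sites", "synth_water_trajectory",
           "read_water_frames", "write_water_pdb", "write_water_xyz",
           "write_dx", "write_sites_pdb", "write_sites_csv"]

WATER_RESNAMES = ("HOH", "WAT", "SOL", "TIP3", "SPC")
WATER_OXYGEN_NAMES = ("O", "OW", "OH2")


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def bounds(self):
        c = np.asarray(self.center, dtype=float)
        return c - self.radius, c + self.radius


@dataclass(frozen=True)
class Box:
    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def bounds(self):
        return (np.asarray(self.lower, dtype=float),
                np.asarray(self.upper, dtype=float))


@dataclass
class FrameSet:
    """Water-oxygen coordinates per frame (angstrom, Cartesian)."""

    frames: list[np.ndarray]
    center: tuple[float, float, float] | None = None
    radius: float | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("FrameSet needs at least one frame")
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3)
                       for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.size and not np.isfinite(f).all():
                raise ValidationError(f"non-finite coordinates in frame {i}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class OccupancyGrid:
    """Per-voxel water counts and frame-fraction occupancy."""

    origin: np.ndarray            # (3,), angstrom
    spacing: float                # angstrom
    dims: tuple[int, int, int]
    counts: np.ndarray            # total water observations per voxel
    occupancy: np.ndarray         # fraction of frames with >= 1 water
    n_frames: int
    mask: np.ndarray | None = None  # True where the voxel is inside the region

    def voxel_centers(self) -> np.ndarray:
        """Centers of all voxels, shape ``dims + (3,)``."""
        idx = np.indices(self.dims).transpose(1, 2, 3, 0)
        return self.origin + (idx + 0.5) * self.spacing


@dataclass(frozen=True)
class HydrationSite:
    """Occupancy-weighted centroid of a connected above-threshold cluster."""

    position: tuple[float, float, float]
    peak_occupancy: float
    n_voxels: int


def _resolve_region(frames: FrameSet, region):
    if region is not None:
        return region
    if frames.center is not None and frames.radius is not None:
        return Sphere(tuple(frames.center), float(frames.radius))
    coords = np.vstack([f for f in frames.frames if f.size]
                       or [np.zeros((1, 3))])
    return Box(tuple(coords.min(axis=0)), tuple(coords.max(axis=0)))


def occupancy_map(frames: FrameSet, spacing: float = 1.0,
                  region: Sphere | Box | None = None) -> OccupancyGrid:
    """Bin water oxygens onto a regular grid and compute voxel occupancy.

    A voxel's occupancy is the fraction of frames with at least one water
    oxygen inside the half-open voxel cube.  For a spherical region, voxels
    whose centers lie outside the sphere are masked (occupancy forced to 0).
    The grid origin is snapped down to integer angstrom.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    region = _resolve_region(frames, region)
    lo, hi = region.bounds()
    origin = np.floor(lo)
    dims = np.maximum(np.ceil((hi - origin) / spacing).astype(int), 1)
    if np.prod(dims) < 1:
        raise ValidationError("region covers no voxels")
    dims_t = tuple(int(d) for d in dims)

    counts = np.zeros(dims_t, dtype=np.int64)
    presence = np.zeros(dims_t, dtype=np.int64)
    for f in frames.frames:
        if not f.size:
            continue
        idx = np.floor((f - origin) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < dims), axis=1)
        idx = idx[inside]
        if not idx.size:
            continue
        np.add.at(counts, tuple(idx.T), 1)
        uniq = np.unique(idx, axis=0)
        presence[tuple(uniq.T)] += 1

    occupancy = presence / frames.n_frames
    mask = None
    if isinstance(region, Sphere):
        centers = origin + (np.indices(dims_t).transpose(1, 2, 3, 0) + 0.5) * spacing
        mask = (np.sum((centers - np.asarray(region.center)) ** 2, axis=-1)
                <= region.radius ** 2)
        occupancy = np.where(mask, occupancy, 0.0)
        counts = np.where(mask, counts, 0)
    return OccupancyGrid(origin=origin, spacing=float(spacing), dims=dims_t,
                         counts=counts, occupancy=occupancy,
                         n_frames=frames.n_frames, mask=mask)


def hydration_sites(grid: OccupancyGrid,
                    threshold: float = 0.8) -> list[HydrationSite]:
    """Extract 26-connected clusters of voxels with occupancy > threshold.

    One site per cluster, positioned at the occupancy-weighted centroid of
    the member voxel centers; sorted by descending peak occupancy, ties by
    centroid lexicographic order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    above = grid.occupancy > threshold
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    sites = []
    centers = grid.voxel_centers()
    for lab in range(1, n + 1):
        sel = labels == lab
        w = grid.occupancy[sel]
        pos = centers[sel]
        centroid = tuple(float(x) for x in
                         (w[:, None] * pos).sum(axis=0) / w.sum())
        sites.append(HydrationSite(position=centroid,
                                   peak_occupancy=float(w.max()),
                                   n_voxels=int(sel.sum())))
    sites.sort(key=lambda s: (-s.peak_occupancy, s.position))
    return sites


def synth_water_trajectory(sites, n_frames: int, n_bulk_waters: int,
                           region: Sphere | Box, seed: int = 0) -> FrameSet:
    """Synthetic water trajectory with planted hydration sites.

    ``sites`` is a list of ``(center, jitter_sigma, presence_probability)``;
    in each frame every site water is present with its probability, placed
    at the center plus isotropic Gaussian jitter.  ``jitter_sigma`` is the
    total 3-D RMS displacement of the tethered water (the RMSF convention),
    i.e. per-axis standard deviation ``jitter_sigma / sqrt(3)``.
    ``n_bulk_waters`` waters per frame are placed uniformly in the region.
    Seeded and reproducible.
    """
    for _, _, p in sites:
        if not 0.0 <= p <= 1.0:
            raise ValidationError("presence probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        pts = []
        for center, sig, p in sites:
            if rng.random() < p:
                pts.append(np.asarray(center, dtype=float)
                           + sig / np.sqrt(3.0) * rng.standard_normal(3))
        for _ in range(n_bulk_waters):
            pts.append(_uniform_point(region, rng))
        frames.append(np.asarray(pts).reshape(-1, 3))
    center = radius = None
    if isinstance(region, Sphere):
        center, radius = tuple(region.center), float(region.radius)
    return FrameSet(frames=frames, center=center, radius=radius)


def _uniform_point(region, rng: np.random.Generator) -> np.ndarray:
    if isinstance(region, Box):
        lo, hi = region.bounds()
        return rng.uniform(lo, hi)
    # uniform in a sphere: direction times cube-root radial law
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return (np.asarray(region.center)
            + v * region.radius * rng.random() ** (1 / 3))


# ---------------------------------------------------------------------------
# file I/O


def read_water_frames(path: str | Path) -> FrameSet:
    """Read water-oxygen frames from a multi-model PDB or XYZ trajectory.

    PDB: atoms with residue name HOH/WAT/SOL/TIP3/SPC and atom name
    O/OW/OH2 are selected.  XYZ: atoms named O or OW.  Parsing is done with
    MDAnalysis.
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        if path.suffix.lower() == ".xyz":
            sel = u.select_atoms(
                "name " + " ".join(WATER_OXYGEN_NAMES))
        else:
            sel = u.select_atoms(
                f"resname {' '.join(WATER_RESNAMES)} and "
                f"name {' '.join(WATER_OXYGEN_NAMES)}")
        if sel.n_atoms == 0:
            raise ValidationError(f"no water oxygens found in {path}")
        frames = [sel.positions.astype(float).copy() for _ in u.trajectory]
    return FrameSet(frames=frames)


def write_water_pdb(frames: FrameSet, path: str | Path) -> None:
    """Write frames as a multi-model PDB of HOH oxygen pseudo-atoms."""
    with open(path, "w") as fh:
        for m, coords in enumerate(frames.frames, start=1):
            fh.write(f"MODEL     {m:>4}\n")
            for i, (x, y, z) in enumerate(coords, start=1):
                fh.write(
                    f"HETATM{i:>5}  O   HOH A{i:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_water_xyz(frames: FrameSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, coords in enumerate(frames.frames):
            fh.write(f"{len(coords)}\nframe {m}\n")
            for x, y, z in coords:
                fh.write(f"O {x:.4f} {y:.4f} {z:.4f}\n")


def write_dx(grid: OccupancyGrid, path: str | Path,
             comment: str = "") -> None:
    """Write the occupancy grid as an OpenDX scalar field.

    The header records the metric: occupancy = fraction of frames with at
    least one water oxygen per voxel.
    """
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    vals = grid.occupancy.ravel(order="C")
    lines = [
        "# fepkit water occupancy map",
        "# metric: fraction of frames with >= 1 water oxygen per voxel",
    ]
    if comment:
        lines.append(f"# {comment}")
    lines += [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {vals.size} "
        "data follows",
    ]
    for i in range(0, vals.size, 3):
        lines.append(" ".join(f"{v:.6f}" for v in vals[i:i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "occupancy" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_pdb(sites: list[HydrationSite], path: str | Path) -> None:
    """Write hydration sites as pseudo-atom HETATM records (B = occupancy)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            x, y, z = s.position
            fh.write(
                f"HETATM{i:>5}  O   HYD A{i:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00{s.peak_occupancy:6.2f}"
                f"           O\n")
        fh.write("END\n")


def write_sites_csv(sites: list[HydrationSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_A", "y_A", "z_A", "peak_occupancy", "n_voxels"])
        for s in sites:
            w.writerow([f"{s.position[0]:.4f}", f"{s.position[1]:.4f}",
                        f"{s.position[2]:.4f}", f"{s.peak_occupancy:.4f}",
                        s.n_voxels])
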