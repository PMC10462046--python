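"""Protein-centred alignment, RMSD series and 3-D number-density maps.

Frames are rigid-body superposed onto a reference (Kabsch
least-squares fit over a fit selection, proper rotations only), then
target particles are accumulated on a regular voxel grid.  The stored
quantity is time-averaged number density in nm^-3, so summing density
times voxel volume recovers the mean in-bounds particle count per
frame exactly.  Grids are exported as plain-text OpenDX scalar fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory_io import Frame, Selection, Trajectory

__all__ = [
    "AlignmentReference",
    "RigidTransform",
    "DensityGrid",
    "GridSpec",
    "kabsch_superpose",
    "rmsd_series",
    "accumulate_density",
    "write_dx",
    "read_dx",
]


@dataclass(frozen=True)
class AlignmentReference:
    """Reference coordinates plus the selection used for the fit."""

    coordinates: np.ndarray
    fit: Selection

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("reference coordinates must be N x 3")
        pts = coords[self.fit.indices]
        if len(pts) < 3:
            raise ValueError("alignment needs at least 3 fit particles")
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
            raise ValueError("fit particles are collinear; rotation is underdetermined")

    @property
    def fit_coordinates(self) -> np.ndarray:
        return self.coordinates[self.fit.indices]


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation


def kabsch_superpose(mobile: Frame, ref: AlignmentReference) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of a frame onto the reference.

    Returns the transform mapping mobile coordinates onto the
    reference frame and the post-fit RMSD (nm) over the fit selection.
    Reflections are excluded (proper rotation, determinant +1).
    """
    mob = mobile.positions[ref.fit.indices]
    tgt = ref.fit_coordinates
    if mob.shape != tgt.shape:
        raise ValueError("fit-particle counts differ between mobile and reference")
    mob_c = mob.mean(axis=0)
    tgt_c = tgt.mean(axis=0)
    rot, rssd = Rotation.align_vectors(tgt - tgt_c, mob - mob_c)
    r = rot.as_matrix()
    t = tgt_c - r @ mob_c
    rmsd = rssd / np.sqrt(len(mob))
    return RigidTransform(rotation=r, translation=t), float(rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    trajectory: Trajectory,
    ref: AlignmentReference,
    report: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMSD after superposition on the fit selection.

    The fit uses ``ref.fit``; the RMSD is reported over ``report``
    (default: the fit selection itself).  This mirrors the usual
    backbone-fit / subset-report protocol, e.g. fitting on the whole
    backbone while reporting cavity-helix residues only.
    """
    report = report if report is not None else ref.fit
    if len(report) == 0:
        raise ValueError("report selection is empty")
    times, values = [], []
    for frame in trajectory:
        transform, _ = kabsch_superpose(frame, ref)
        aligned = transform.apply(frame.positions[report.indices])
        values.append(_rmsd(aligned, ref.coordinates[report.indices]))
        times.append(frame.time)
    return np.array(times), np.array(values)


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (nm), voxel spacing per axis (nm), shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be at least 1 per axis")

    @classmethod
    def cubic(cls, origin, extent: float, spacing: float = 0.1) -> "GridSpec":
        n = int(np.ceil(extent / spacing))
        return cls(origin=tuple(origin), spacing=(spacing,) * 3, shape=(n, n, n))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def edges(self) -> list[np.ndarray]:
        return [self.origin[a] + self.spacing[a] * np.arange(self.shape[a] + 1)
                for a in range(3)]


@dataclass
class DensityGrid:
    """Accumulated voxel counts with frame-count normalisation."""

    spec: GridSpec
    counts: np.ndarray
    n_frames: int
    n_out_of_bounds: int = 0

    @property
    def density(self) -> np.ndarray:
        """Time-averaged number density, nm^-3."""
        if self.n_frames < 1:
            raise ValueError("no frames accumulated")
        return self.counts / (self.n_frames * self.spec.voxel_volume)

    @property
    def mean_in_bounds_count(self) -> float:
        return float(self.counts.sum()) / self.n_frames


def accumulate_density(
    trajectory: Trajectory,
    target: Selection,
    spec: GridSpec,
    ref: AlignmentReference | None = None,
    interval: float = 10.0,
) -> DensityGrid:
    """Bin target particles on the grid, one snapshot every ``interval`` ns.

    With an alignment reference each analysed frame is superposed on
    it first, centring the map on the protein.  Out-of-bounds
    particles are counted, not silently dropped.
    """
    counts = np.zeros(spec.shape)
    edges = spec.edges
    n_frames = 0
    n_oob = 0
    next_time = None
    for frame in trajectory:
        if next_time is None:
            next_time = frame.time
        if frame.time < next_time - 1e-9:
            continue
        next_time += interval
        pos = frame.positions[target.indices]
        if ref is not None:
            transform, _ = kabsch_superpose(frame, ref)
            pos = transform.apply(pos)
        hist, _ = np.histogramdd(pos, bins=edges)
        counts += hist
        n_oob += len(pos) - int(hist.sum())
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames analysed; check interval vs trajectory span")
    return DensityGrid(spec=spec, counts=counts, n_frames=n_frames, n_out_of_bounds=n_oob)


# ---------------------------------------------------------------------------
# OpenDX I/O (plain-text regular-grid scalar field)


def write_dx(grid: DensityGrid, path) -> None:
    """Write the density as an OpenDX regular-grid scalar file.

    Values are written in C order (z fastest), three per line, full
    float precision; lengths stay in nm.
    """
    spec = grid.spec
    nx, ny, nz = spec.shape
    dens = grid.density.ravel(order="C")
    with open(path, "w") as fh:
        fh.write("# scramblekit density map (nm, nm^-3)\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.10g} {:.10g} {:.10g}\n".format(*spec.origin))
        fh.write(f"delta {spec.spacing[0]:.10g} 0 0\n")
        fh.write(f"delta 0 {spec.spacing[1]:.10g} 0\n")
        fh.write(f"delta 0 0 {spec.spacing[2]:.10g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        for i in range(0, len(dens), 3):
            fh.write(" ".join(f"{v:.17g}" for v in dens[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an OpenDX regular-grid scalar file.

    Returns (origin, spacing, values) with values shaped like the
    grid.  Only the orthogonal-delta subset written by
    :func:`write_dx` (and VMD/Volmap-style files) is supported.
    """
    origin = None
    deltas = []
    shape = None
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                shape = tuple(int(v) for v in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(v) for v in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
            elif n_items is not None and len(values) < n_items:
                values.extend(float(v) for v in s.split())
    if shape is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path}: not a regular-grid OpenDX scalar file")
    d = np.array(deltas)
    if not np.allclose(d, np.diag(np.diag(d))):
        raise ValueError(f"{path}: non-orthogonal grid deltas are not supported")
    if len(values) != n_items or n_items != int(np.prod(shape)):
        raise ValueError(f"{path}: value count does not match grid shape")
    return origin, np.diag(d).copy(), np.array(values).reshape(shape, order="C")
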