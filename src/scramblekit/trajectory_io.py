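"""Structure/trajectory input and particle selection.

Coordinates are stored in nm, times in ns.  Only orthorhombic boxes are
supported; triclinic input raises :class:`UnsupportedBoxError`.  Residue
ids are kept 1-based as printed in GRO/PDB files, internal particle
indices are 0-based.

Standard formats (GRO, PDB, XTC, TRR) are read through MDAnalysis; a
plain ``.npz`` array container (keys ``times``, ``positions``, ``box``)
is provided for dependency-free synthetic fixtures.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BoxVectors",
    "Frame",
    "Trajectory",
    "SystemTopology",
    "Selection",
    "ParseError",
    "UnsupportedBoxError",
    "SelectionSyntaxError",
    "read_structure",
    "read_trajectory",
    "iter_frames",
    "write_array_trajectory",
    "select",
    "wrap_to_box",
]

#: Particle names recognised as the lipid phosphate marker: "PO4" for
#: Martini coarse-grained lipids, "P" for atomistic phosphorus.
PHOSPHATE_NAMES = ("PO4", "P")

_ANGSTROM_PER_NM = 10.0


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


class UnsupportedBoxError(ValueError):
    """The simulation box is not orthorhombic."""


class SelectionSyntaxError(ValueError):
    """A selection expression failed to parse."""


@dataclass(frozen=True)
class BoxVectors:
    """Orthorhombic box edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        for name, v in (("lx", self.lx), ("ly", self.ly), ("lz", self.lz)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"box edge {name} must be strictly positive, got {v}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz


@dataclass
class Frame:
    """One trajectory frame: time (ns), N x 3 positions (nm) and box."""

    time: float
    positions: np.ndarray
    box: BoxVectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be N x 3, got shape {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class SystemTopology:
    """Per-particle records plus the lipid-residue -> phosphate map.

    ``residue_index`` groups particles into residues in order of
    appearance (robust against the resid wrap-around of large GRO
    files).  ``phosphate_map`` maps each lipid residue_index to the
    particle index of its single phosphate bead/atom.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    residue_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    masses: np.ndarray | None = None
    phosphate_map: dict[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype="U8")
        self.resnames = np.asarray(self.resnames, dtype="U8")
        self.resids = np.asarray(self.resids, dtype=int)
        n = len(self.names)
        if not (len(self.resnames) == len(self.resids) == n):
            raise ValueError("names/resnames/resids must have equal length")
        if self.residue_index is None:
            self.residue_index = _residue_runs(self.resids, self.resnames)
        else:
            self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.phosphate_map is None:
            self.phosphate_map = build_phosphate_map(self)

    @property
    def n_particles(self) -> int:
        return len(self.names)

    @property
    def n_lipids(self) -> int:
        return len(self.phosphate_map)

    @property
    def phosphate_indices(self) -> np.ndarray:
        """Phosphate particle indices ordered by lipid residue."""
        return np.array([self.phosphate_map[r] for r in sorted(self.phosphate_map)], dtype=int)


def _residue_runs(resids: np.ndarray, resnames: np.ndarray) -> np.ndarray:
    """Consecutive-run residue numbering (0-based, order of appearance)."""
    if len(resids) == 0:
        return np.zeros(0, dtype=int)
    change = np.ones(len(resids), dtype=bool)
    change[1:] = (resids[1:] != resids[:-1]) | (resnames[1:] != resnames[:-1])
    return np.cumsum(change) - 1


def build_phosphate_map(top: SystemTopology) -> dict[int, int]:
    """Map lipid residue_index -> phosphate particle index.

    A residue is a lipid iff it contains a particle named PO4 or P;
    such a residue must contain exactly one.
    """
    mapping: dict[int, int] = {}
    is_phos = np.isin(top.names, PHOSPHATE_NAMES)
    for idx in np.nonzero(is_phos)[0]:
        res = int(top.residue_index[idx])
        if res in mapping:
            raise ParseError(
                f"residue {top.resnames[idx]}{top.resids[idx]} has more than one "
                "phosphate particle; cannot build a unique phosphate map"
            )
        mapping[res] = int(idx)
    return mapping


@dataclass(frozen=True)
class Selection:
    """Named, sorted, unique particle index set."""

    label: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)
        if len(idx) and idx[0] < 0:
            raise ValueError(f"selection '{self.label}' has negative indices")

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, n_particles: int) -> "Selection":
        if len(self.indices) and self.indices[-1] >= n_particles:
            raise ValueError(
                f"selection '{self.label}' references particle {self.indices[-1]} "
                f"but the system has only {n_particles} particles"
            )
        return self


class Trajectory:
    """Ordered frames with a topology reference.

    Either fully materialised (``frames`` list) or backed by a factory
    of frame iterators so large trajectories can be streamed without
    holding every frame in memory.
    """

    def __init__(self, source, topology: SystemTopology | None = None, n_frames: int | None = None):
        if callable(source):
            self._factory = source
            self._frames: list[Frame] | None = None
        else:
            self._frames = list(source)
            self._factory = None
            n_frames = len(self._frames)
            _check_frames(self._frames)
        self.topology = topology
        self._n_frames = n_frames

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], topology: SystemTopology | None = None) -> "Trajectory":
        return cls(list(frames), topology=topology)

    def __iter__(self) -> Iterator[Frame]:
        if self._frames is not None:
            return iter(self._frames)
        return self._factory()

    def __len__(self) -> int:
        if self._n_frames is None:
            raise TypeError("streaming trajectory with unknown frame count")
        return self._n_frames

    @property
    def frames(self) -> list[Frame]:
        """Materialised frame list (loads a streaming trajectory)."""
        if self._frames is None:
            self._frames = list(self._factory())
            _check_frames(self._frames)
            self._n_frames = len(self._frames)
        return self._frames

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def _check_frames(frames: list[Frame]) -> None:
    if not frames:
        return
    n = frames[0].n_particles
    prev = -np.inf
    for i, f in enumerate(frames):
        if f.n_particles != n:
            raise ValueError(f"frame {i} has {f.n_particles} particles, expected {n}")
        if f.time <= prev:
            raise ValueError(f"frame times must be strictly increasing (frame {i})")
        prev = f.time


# ---------------------------------------------------------------------------
# readers


def _box_from_mda(dimensions, path: str) -> BoxVectors:
    if dimensions is None or not np.any(dimensions[:3]):
        raise ParseError(f"{path}: no box record found")
    lx, ly, lz, alpha, beta, gamma = dimensions
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"{path}: triclinic box (angles {alpha:.2f}/{beta:.2f}/{gamma:.2f}) is not supported"
        )
    return BoxVectors(float(lx) / _ANGSTROM_PER_NM, float(ly) / _ANGSTROM_PER_NM,
                      float(lz) / _ANGSTROM_PER_NM)


def read_structure(path: str | os.PathLike) -> tuple[SystemTopology, Frame]:
    """Read a GRO or PDB structure into a topology and a single frame."""
    import MDAnalysis as mda

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
            names = u.atoms.names
            resnames = u.atoms.resnames
            resids = u.atoms.resids
            positions = u.atoms.positions / _ANGSTROM_PER_NM
            box = _box_from_mda(u.dimensions, path)
            try:
                masses = u.atoms.masses.copy()
                if not np.all(masses > 0):
                    masses = None
            except Exception:
                masses = None
            time_ns = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0) / 1000.0
    except (UnsupportedBoxError, ParseError):
        raise
    except Exception as exc:  # malformed record, truncated file, ...
        raise ParseError(f"{path}: failed to parse structure ({exc})") from exc
    top = SystemTopology(names=names, resnames=resnames, resids=resids, masses=masses)
    return top, Frame(time=time_ns, positions=positions, box=box)


def iter_frames(path: str | os.PathLike, topology: SystemTopology) -> Iterator[Frame]:
    """Stream frames from an XTC/TRR or ``.npz`` array trajectory.

    Frames are yielded one at a time; nothing requires the whole
    trajectory in memory.
    """
    path = os.fspath(path)
    if path.endswith(".npz"):
        yield from _iter_array_frames(path, topology)
        return
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_particles, trajectory=True)
        try:
            u.load_new(path)
        except Exception as exc:
            if "atoms" in str(exc).lower() or "natoms" in str(exc).lower():
                raise ValueError(
                    f"{path}: particle count does not match topology ({topology.n_particles})"
                ) from exc
            raise ParseError(f"{path}: unreadable trajectory ({exc})") from exc
        for i, ts in enumerate(u.trajectory):
            try:
                if ts.n_atoms != topology.n_particles:
                    raise ValueError(
                        f"{path}: frame {i} has {ts.n_atoms} particles, topology has "
                        f"{topology.n_particles}"
                    )
                box = _box_from_mda(ts.dimensions, path)
                yield Frame(
                    time=float(ts.time) / 1000.0,
                    positions=ts.positions / _ANGSTROM_PER_NM,
                    box=box,
                )
            except (ValueError, UnsupportedBoxError):
                raise
            except Exception as exc:
                raise ParseError(f"{path}: unreadable frame {i} ({exc})") from exc


def _iter_array_frames(path: str, topology: SystemTopology) -> Iterator[Frame]:
    with np.load(path) as data:
        try:
            times = data["times"]
            positions = data["positions"]
            box = data["box"]
        except KeyError as exc:
            raise ParseError(f"{path}: array trajectory missing key {exc}") from exc
        if positions.shape[1] != topology.n_particles:
            raise ValueError(
                f"{path}: trajectory has {positions.shape[1]} particles, topology has "
                f"{topology.n_particles}"
            )
        bv = BoxVectors(*np.asarray(box, dtype=float))
        for t, pos in zip(times, positions):
            yield Frame(time=float(t), positions=np.array(pos, dtype=float), box=bv)


def read_trajectory(path: str | os.PathLike, topology: SystemTopology) -> Trajectory:
    """Open a trajectory for streaming iteration (frames loaded lazily)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    # fail fast on particle-count mismatch by touching the first frame
    probe = iter_frames(path, topology)
    try:
        next(probe)
    except StopIteration:
        raise ParseError(f"{path}: trajectory contains no frames")
    return Trajectory(lambda: iter_frames(path, topology), topology=topology)


def write_array_trajectory(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory to the ``.npz`` array container (fixture format)."""
    frames = trajectory.frames
    if not frames:
        raise ValueError("cannot write an empty trajectory")
    times = np.array([f.time for f in frames])
    positions = np.stack([f.positions for f in frames])
    box = frames[0].box.lengths
    np.savez(os.fspath(path), times=times, positions=positions, box=box)


# ---------------------------------------------------------------------------
# selection mini-language: name/resname equality, resid ranges, and/or/not


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    def __init__(self, top: SystemTopology, expression: str):
        self.top = top
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, msg: str, pos: int | None = None):
        if pos is None:
            pos = self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.expr)
        raise SelectionSyntaxError(f"selection syntax error at position {pos}: {msg}")

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self.fail("empty expression", 0)
        mask = self.parse_or()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() == "or":
            self.next()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() == "and":
            self.next()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.next()
            return ~self.parse_not()
        return self.parse_primary()

    def parse_primary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "(":
            self.next()
            mask = self.parse_or()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.next()
            return mask
        if tok in ("name", "resname", "resid"):
            self.next()
            return self.parse_keyword(tok)
        self.fail(f"expected name/resname/resid/not/'(', got {tok!r}")

    _STOP = {"and", "or", "not", "(", ")", None}

    def parse_keyword(self, kind: str) -> np.ndarray:
        values = []
        while self.peek() not in self._STOP:
            values.append(self.next()[0])
        if not values:
            self.fail(f"'{kind}' needs at least one value")
        if kind == "name":
            return np.isin(self.top.names, values)
        if kind == "resname":
            return np.isin(self.top.resnames, values)
        mask = np.zeros(self.top.n_particles, dtype=bool)
        for v in values:
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
            if m is None:
                self.fail(f"bad resid value {v!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            mask |= (self.top.resids >= lo) & (self.top.resids <= hi)
        return mask


def select(topology: SystemTopology, expression: str) -> Selection:
    """Evaluate a selection expression against a topology.

    Grammar: ``name``/``resname`` followed by one or more values
    (union), ``resid`` with values or 1-based inclusive ranges
    (``74-100``), combined with ``and``/``or``/``not`` and parentheses.
    An expression matching nothing yields an empty selection.
    """
    mask = _SelParser(topology, expression).parse()
    return Selection(label=expression, indices=np.nonzero(mask)[0])


def wrap_to_box(frame: Frame, axes: Iterable[int] | None = None) -> Frame:
    """Wrap coordinates into [0, L) along the given axes (default: all).

    Idempotent and minimum-image-distance preserving.
    """
    lengths = frame.box.lengths
    pos = frame.positions.copy()
    for ax in range(3) if axes is None else axes:
        pos[:, ax] = np.mod(pos[:, ax], lengths[ax])
    return Frame(time=frame.time, positions=pos, box=frame.box)


def minimum_image(delta: np.ndarray, length: float) -> np.ndarray:
    """Signed minimum-image convention for coordinate differences."""
    return delta - length * np.round(delta / length)
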