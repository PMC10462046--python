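"""Flip-flop collective variable, bias potentials and umbrella windows.

The CV is the oriented z distance between a chosen lipid phosphate and
the local membrane centre of mass, the latter computed from membrane
beads whose xy minimum-image distance to the phosphate is within a
cylinder radius (2.0 nm for a proteinless membrane, 3.0 nm next to a
scramblase).  Biases are a harmonic umbrella on the CV plus an
optional flat-bottom xy restraint tying the phosphate to an anchor
particle (reference distance 2.5 nm, force constant
500 kJ mol^-1 nm^-2 by default).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Frame, Selection, minimum_image

__all__ = [
    "CylinderCVSpec",
    "HarmonicUmbrella",
    "FlatBottomXY",
    "BiasPotential",
    "UmbrellaWindow",
    "WindowSet",
    "cylinder_cv",
    "bias_energy",
    "place_windows",
    "spacing_scheme_centers",
    "harvest_samples",
    "read_window_manifest",
]


@dataclass(frozen=True)
class CylinderCVSpec:
    """Specification of the cylinder flip-flop CV.

    ``membrane`` are the beads contributing to the local centre of
    mass; the target particle itself is excluded if present.  With
    ``mass_weighted`` and per-particle masses the centre is
    mass-weighted, otherwise unweighted (coarse-grained beads are
    treated as equal mass).
    """

    target_index: int
    radius: float = 2.0
    membrane: Selection = None  # type: ignore[assignment]
    mass_weighted: bool = False
    masses: np.ndarray | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.membrane is None or len(self.membrane) == 0:
            raise ValueError("membrane selection must be non-empty")
        if self.mass_weighted and self.masses is None:
            raise ValueError("mass_weighted=True requires masses")


def cylinder_cv(frame: Frame, spec: CylinderCVSpec) -> float:
    """Oriented distance xi = z_target - z_COM(local membrane) in nm.

    Membership uses the xy minimum-image distance to the target's
    axis; member z coordinates are taken in the periodic image nearest
    the target so a z-connected membrane is averaged correctly.
    """
    pos = frame.positions
    box = frame.box
    target = pos[spec.target_index]
    members = spec.membrane.indices[spec.membrane.indices != spec.target_index]
    dx = minimum_image(pos[members, 0] - target[0], box.lx)
    dy = minimum_image(pos[members, 1] - target[1], box.ly)
    inside = dx * dx + dy * dy <= spec.radius**2
    if not np.any(inside):
        raise ValueError(
            f"no membrane beads inside the {spec.radius} nm cylinder around "
            f"particle {spec.target_index}"
        )
    dz = minimum_image(pos[members[inside], 2] - target[2], box.lz)
    if spec.mass_weighted:
        w = np.asarray(spec.masses, dtype=float)[members[inside]]
        mean_dz = float(np.average(dz, weights=w))
    else:
        mean_dz = float(np.mean(dz))
    return -mean_dz  # xi = z_target - z_com


@dataclass(frozen=True)
class HarmonicUmbrella:
    """Harmonic umbrella bias (1/2) k (xi - center)^2 on the CV."""

    center: float
    force_constant: float

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")

    def energy(self, xi) -> np.ndarray | float:
        return 0.5 * self.force_constant * (np.asarray(xi, dtype=float) - self.center) ** 2


@dataclass(frozen=True)
class FlatBottomXY:
    """Flat-bottom restraint on the xy distance to an anchor particle.

    Zero inside the reference distance d0, harmonic (1/2) k (d-d0)^2
    outside.  Confines the translocating lipid to a pathway without
    biasing the interior.
    """

    anchor_index: int
    reference_distance: float = 2.5
    force_constant: float = 500.0

    def __post_init__(self):
        if self.reference_distance <= 0:
            raise ValueError("reference distance must be positive")
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")

    def energy_distance(self, d_xy) -> np.ndarray | float:
        d = np.asarray(d_xy, dtype=float)
        excess = np.maximum(d - self.reference_distance, 0.0)
        out = 0.5 * self.force_constant * excess**2
        return out if out.ndim else float(out)

    def energy(self, frame: Frame, target_index: int) -> float:
        pos = frame.positions
        dx = minimum_image(pos[target_index, 0] - pos[self.anchor_index, 0], frame.box.lx)
        dy = minimum_image(pos[target_index, 1] - pos[self.anchor_index, 1], frame.box.ly)
        return float(self.energy_distance(np.hypot(dx, dy)))


@dataclass(frozen=True)
class BiasPotential:
    """Composite bias: harmonic umbrella and/or flat-bottom xy restraint."""

    umbrella: HarmonicUmbrella | None = None
    flat_bottom: FlatBottomXY | None = None

    def energy_cv(self, xi) -> np.ndarray | float:
        """CV-dependent part (the umbrella) only."""
        if self.umbrella is None:
            xi = np.asarray(xi, dtype=float)
            return np.zeros_like(xi) if xi.ndim else 0.0
        return self.umbrella.energy(xi)

    def energy(self, xi=None, frame: Frame | None = None,
               target_index: int | None = None) -> float:
        total = 0.0
        if self.umbrella is not None:
            if xi is None:
                raise ValueError("umbrella bias needs a CV value")
            total += float(self.umbrella.energy(xi))
        if self.flat_bottom is not None:
            if frame is None or target_index is None:
                raise ValueError("flat-bottom bias needs a frame and target index")
            total += self.flat_bottom.energy(frame, target_index)
        return total


def bias_energy(bias: BiasPotential, xi=None, frame: Frame | None = None,
                target_index: int | None = None) -> float:
    """Total bias energy in kJ mol^-1; components sum."""
    return bias.energy(xi=xi, frame=frame, target_index=target_index)


# ---------------------------------------------------------------------------
# windows


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias definition plus harvested CV samples."""

    center: float
    force_constant: float
    times: np.ndarray
    samples: np.ndarray
    equilibration_cutoff: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.times.shape != self.samples.shape:
            raise ValueError("times and samples must align")
        if len(self.samples) == 0:
            raise ValueError(
                f"window at {self.center} has no samples after equilibration cutoff"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def bias(self) -> HarmonicUmbrella:
        return HarmonicUmbrella(self.center, self.force_constant)


@dataclass
class WindowSet:
    """Ordered umbrella windows spanning the CV range."""

    windows: list[UmbrellaWindow]
    overlap_warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        centers = np.array([w.center for w in self.windows])
        if len(centers) == 0:
            raise ValueError("window set is empty")
        if np.any(np.diff(centers) <= 0):
            order = np.argsort(centers)
            self.windows = [self.windows[i] for i in order]
            centers = centers[order]
            if np.any(np.diff(centers) <= 0):
                raise ValueError("window centers must be strictly monotone")
        self.overlap_warnings = list(self.overlap_warnings) + self._check_overlap()

    def _check_overlap(self) -> list[str]:
        msgs = []
        for a, b in zip(self.windows[:-1], self.windows[1:]):
            hi_a = np.percentile(a.samples, 99)
            lo_b = np.percentile(b.samples, 1)
            if lo_b > hi_a:
                msg = (f"windows at {a.center:.3f} and {b.center:.3f} nm have "
                       f"< 1% estimated sample overlap")
                warnings.warn(msg, stacklevel=3)
                msgs.append(msg)
        return msgs

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @property
    def cv_range(self) -> tuple[float, float]:
        lo = min(w.samples.min() for w in self.windows)
        hi = max(w.samples.max() for w in self.windows)
        return float(lo), float(hi)

    def __len__(self) -> int:
        return len(self.windows)


def spacing_scheme_centers(
    cv_range: tuple[float, float] = (-2.3, 2.3),
    surface_spacing: float = 0.1,
    core_spacing: float = 0.03,
    core_halfwidth: float = 0.5,
) -> np.ndarray:
    """Non-uniform window centers, dense near the membrane centre.

    Spacing ramps linearly from ``core_spacing`` at |xi| <=
    ``core_halfwidth`` up to ``surface_spacing`` at the range edges.
    Centers are strictly monotone and symmetric about 0.
    """
    lo, hi = cv_range
    if not (lo < 0 < hi):
        raise ValueError("cv_range must straddle 0")

    def spacing(x: float) -> float:
        a = abs(x)
        if a <= core_halfwidth:
            return core_spacing
        frac = min(1.0, (a - core_halfwidth) / max(hi - core_halfwidth, 1e-12))
        return core_spacing + (surface_spacing - core_spacing) * frac

    right = [0.0]
    while right[-1] < hi:
        right.append(min(hi, right[-1] + spacing(right[-1])))
    left = [-c for c in right[1:]]
    left_clip = [c for c in left if c >= lo]
    if not left_clip or left_clip[-1] > lo:
        left_clip.append(lo)
    return np.array(sorted(left_clip) + right)


def place_windows(
    times: np.ndarray,
    xi: np.ndarray,
    centers: np.ndarray | None = None,
    scheme: dict | None = None,
) -> list[dict]:
    """Pick, for each requested window center, the pulling-trace frame
    whose CV is nearest (earliest frame on ties).

    Either explicit ``centers`` or a ``scheme`` dict forwarded to
    :func:`spacing_scheme_centers` must be given.
    """
    times = np.asarray(times, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if centers is None:
        if scheme is None:
            raise ValueError("give either explicit centers or a spacing scheme")
        centers = spacing_scheme_centers(**scheme)
    centers = np.asarray(centers, dtype=float)
    lo, hi = xi.min(), xi.max()
    uncovered = centers[(centers < lo) | (centers > hi)]
    if len(uncovered):
        raise ValueError(
            f"pulling trace spans [{lo:.3f}, {hi:.3f}] nm; uncovered centers: "
            f"{', '.join(f'{c:.3f}' for c in uncovered)}"
        )
    out = []
    for c in centers:
        dist = np.abs(xi - c)
        i = int(np.argmin(dist))  # argmin returns the earliest minimiser
        out.append({"center": float(c), "frame_index": i,
                    "time": float(times[i]), "xi": float(xi[i])})
    return out


def _read_xvg_like(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Two-column (time, CV) text, tolerant of # and @ comment lines."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns, got {s!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1]


def read_window_manifest(path: str) -> list[dict]:
    """Manifest lines: ``center force_constant sample_file`` (paths
    relative to the manifest's directory; # comments allowed)."""
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'center k file', got {s!r}")
            fpath = parts[2]
            if not os.path.isabs(fpath):
                fpath = os.path.join(base, fpath)
            entries.append({"center": float(parts[0]),
                            "force_constant": float(parts[1]), "path": fpath})
    if not entries:
        raise ValueError(f"{path}: empty window manifest")
    return entries


def harvest_samples(entries: list[dict], cutoff: float = 10.0) -> WindowSet:
    """Load per-window CV series and discard equilibration samples.

    ``entries`` as from :func:`read_window_manifest`, or with inline
    ``times``/``samples`` arrays instead of ``path``.  Samples with
    time <= ``cutoff`` (ns) are excluded; a window left empty is an
    error naming its center.
    """
    if cutoff < 0:
        raise ValueError("equilibration cutoff must be >= 0")
    windows = []
    for e in entries:
        if "path" in e:
            t, x = _read_xvg_like(e["path"])
        else:
            t, x = np.asarray(e["times"], dtype=float), np.asarray(e["samples"], dtype=float)
        keep = t > cutoff
        if not np.any(keep):
            raise ValueError(
                f"window at center {e['center']} has no samples after the "
                f"{cutoff} ns equilibration cutoff"
            )
        windows.append(UmbrellaWindow(
            center=float(e["center"]), force_constant=float(e["force_constant"]),
            times=t[keep], samples=x[keep], equilibration_cutoff=cutoff,
        ))
    return WindowSet(windows=windows)
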