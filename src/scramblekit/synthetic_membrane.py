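"""Synthetic bilayer simulator with known ground truth.

Each lipid is reduced to its phosphate bead.  The phosphate z
coordinate evolves by overdamped Langevin dynamics in a quartic
double-well flip-flop potential

    U(z) = B(x, y) * (1 - (z / z0)^2)^2

whose local barrier ``B`` equals the bulk flip-flop barrier outside a
scramblase "groove" and a much lower value on the groove axis,
blending smoothly over a radial margin.  An optional Gaussian "gate
bump" adds a secondary maximum on the groove path, mimicking a
hydrophobic gate.  Lateral xy motion is free diffusion under periodic
boundaries.

The simulator provides unbiased trajectories, biased (umbrella +
flat-bottom restrained) collective-variable samples for free-energy
reconstruction, and deterministic planted-flip fixtures that serve as
an exact oracle for the scrambling counter.

This is a toy model: barrier heights, minima positions and the
diffusion constant are prescribed, but there are no lipid-lipid
interactions and the kinetic prefactor is not calibrated to any real
membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory_io import BoxVectors, Frame, SystemTopology, Trajectory
from .units import kbt

__all__ = [
    "GrooveSpec",
    "FlipFlopPotential",
    "LangevinParams",
    "SyntheticScenario",
    "evaluate_potential",
    "simulate_unbiased",
    "sample_biased",
    "metropolis_sample",
    "plant_events",
    "build_topology",
]


@dataclass(frozen=True)
class GrooveSpec:
    """Low-barrier cylindrical region representing a scramblase groove.

    ``center_xy`` is the groove axis position (nm), ``radius`` the
    region where the groove barrier applies, ``blend_margin`` the
    radial width of the smooth transition to the bulk barrier.  The
    optional gate bump is a Gaussian of height ``gate_height`` centred
    at ``gate_z`` with width ``gate_width``, active only inside the
    groove.
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.0
    barrier: float = 7.0
    blend_margin: float = 0.5
    gate_height: float = 0.0
    gate_z: float = -0.5
    gate_width: float = 0.3

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("groove radius must be positive")
        if self.barrier < 0 or self.gate_height < 0:
            raise ValueError("groove barrier and gate height must be non-negative")
        if self.blend_margin <= 0 or self.gate_width <= 0:
            raise ValueError("blend margin and gate width must be positive")


@dataclass(frozen=True)
class FlipFlopPotential:
    """Quartic double-well flip-flop potential, optionally groove-aware.

    ``barrier`` is the bulk flip-flop free-energy barrier (kJ mol^-1),
    ``z0`` the half-separation of the two minima (nm, roughly the
    phosphate half-thickness of a POPC bilayer).
    """

    barrier: float = 62.0
    z0: float = 2.0
    groove: GrooveSpec | None = None

    def __post_init__(self):
        if self.barrier < 0:
            raise ValueError("barrier must be non-negative")
        if self.z0 <= 0:
            raise ValueError("z0 must be positive")

    # -- groove weight -----------------------------------------------------
    def _groove_weight(self, x, y):
        """Smoothstep weight: 1 on the groove axis, 0 in the bulk."""
        g = self.groove
        r = np.hypot(np.asarray(x, dtype=float) - g.center_xy[0],
                     np.asarray(y, dtype=float) - g.center_xy[1])
        t = np.clip((r - g.radius) / g.blend_margin, 0.0, 1.0)
        return 1.0 - t * t * (3.0 - 2.0 * t)

    def local_barrier(self, x, y):
        """Barrier of the double well at lateral position (x, y)."""
        if self.groove is None:
            return np.broadcast_to(np.float64(self.barrier), np.shape(x)).copy() \
                if np.ndim(x) else float(self.barrier)
        w = self._groove_weight(x, y)
        return self.barrier + (self.groove.barrier - self.barrier) * w

    def energy(self, position) -> np.ndarray | float:
        """Potential energy (kJ mol^-1) at one or many 3-D points."""
        pos = np.asarray(position, dtype=float)
        x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
        b = self.local_barrier(x, y)
        u = (z / self.z0) ** 2
        e = b * (1.0 - u) ** 2
        if self.groove is not None and self.groove.gate_height > 0:
            w = self._groove_weight(x, y)
            g = self.groove
            e = e + w * g.gate_height * np.exp(-((z - g.gate_z) ** 2) / (2.0 * g.gate_width**2))
        return e if e.ndim else float(e)

    def axis_energy(self, z):
        """1-D potential along the groove axis (or any bulk axis)."""
        z = np.asarray(z, dtype=float)
        if self.groove is None:
            xy = (0.0, 0.0)
        else:
            xy = self.groove.center_xy
        pts = np.stack([np.full_like(z, xy[0]), np.full_like(z, xy[1]), z], axis=-1)
        return self.energy(pts)

    def dudz(self, x, y, z):
        """Analytic dU/dz (kJ mol^-1 nm^-1)."""
        b = self.local_barrier(x, y)
        z = np.asarray(z, dtype=float)
        u = z / self.z0
        de = -4.0 * b * u * (1.0 - u * u) / self.z0
        if self.groove is not None and self.groove.gate_height > 0:
            g = self.groove
            w = self._groove_weight(x, y)
            de = de + w * g.gate_height * np.exp(
                -((z - g.gate_z) ** 2) / (2.0 * g.gate_width**2)
            ) * (-(z - g.gate_z) / g.gate_width**2)
        return de

    def max_force(self, z_extent: float = 3.0) -> float:
        """Max |dU/dz| over the relevant z range (numeric, for stability checks)."""
        z = np.linspace(-z_extent, z_extent, 2001)
        forces = [np.max(np.abs(self.dudz(0.0, 0.0, z)))]
        if self.groove is not None:
            far = self.groove.radius + 10 * self.groove.blend_margin
            forces.append(np.max(np.abs(self.dudz(self.groove.center_xy[0] + far,
                                                  self.groove.center_xy[1], z))))
        return float(max(forces))


def evaluate_potential(potential: FlipFlopPotential, position) -> float:
    """Energy (kJ mol^-1) of the flip-flop potential at a 3-D point."""
    return potential.energy(position)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Langevin integrator parameters.

    D is the phosphate diffusion coefficient (nm^2 ns^-1), dt the time
    step (ns), T the temperature (K).  Defaults are chosen for
    desk-scale event statistics, not physical fidelity.
    """

    diffusion: float = 0.1
    dt: float = 0.01
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self):
        # D = 0 is allowed as the degenerate no-motion limit
        if self.diffusion < 0 or self.dt <= 0 or self.temperature <= 0:
            raise ValueError("diffusion must be >= 0, dt and temperature positive")

    def validate_stability(self, potential: FlipFlopPotential) -> None:
        kt = kbt(self.temperature)
        drift = self.dt * potential.max_force() * self.diffusion / kt
        if drift >= 0.1 * potential.z0:
            raise ValueError(
                f"time step dt={self.dt} ns too large: deterministic drift per step "
                f"{drift:.3f} nm exceeds 0.1*z0; decrease dt"
            )


@dataclass(frozen=True)
class SyntheticScenario:
    """A complete synthetic membrane experiment definition.

    The default scenario mirrors a small proteinless POPC patch of
    ~290 lipids; a scramblase scenario uses ~920 lipids with a groove.
    """

    name: str = "proteinless"
    n_lipids: int = 290
    box: BoxVectors = field(default_factory=lambda: BoxVectors(9.5, 9.5, 10.0))
    potential: FlipFlopPotential = field(default_factory=FlipFlopPotential)
    langevin: LangevinParams = field(default_factory=LangevinParams)
    duration: float = 10000.0
    snapshot_interval: float = 10.0
    n_waters: int = 0
    protein_xy: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_lipids < 1:
            raise ValueError("need at least one lipid")
        if not (self.duration >= self.snapshot_interval > 0):
            raise ValueError("require duration >= snapshot_interval > 0")

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, langevin=replace(self.langevin, seed=int(seed)))


def build_topology(n_lipids: int, n_waters: int = 0, n_protein: int = 0) -> SystemTopology:
    """Topology for a synthetic system: one PO4 bead per lipid, then
    optional water (W) and protein backbone (BB) pseudo-particles."""
    names = ["PO4"] * n_lipids + ["W"] * n_waters + ["BB"] * n_protein
    resnames = ["POPC"] * n_lipids + ["W"] * n_waters + ["PROT"] * n_protein
    resids = list(range(1, n_lipids + 1)) + list(range(1, n_waters + 1)) + \
        list(range(1, n_protein + 1))
    return SystemTopology(names=np.array(names), resnames=np.array(resnames),
                          resids=np.array(resids))


def _initial_positions(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    n = scenario.n_lipids
    box = scenario.box.lengths
    pos = np.empty((n, 3))
    pos[:, 0] = rng.uniform(0, box[0], n)
    pos[:, 1] = rng.uniform(0, box[1], n)
    z0 = scenario.potential.z0
    # alternate leaflets so both are half-populated
    pos[:, 2] = np.where(np.arange(n) % 2 == 0, z0, -z0)
    return pos


def simulate_unbiased(scenario: SyntheticScenario) -> Trajectory:
    """Integrate the scenario and return snapshots every
    ``snapshot_interval`` ns (the initial state is frame 0).

    Per-lipid z follows overdamped Langevin dynamics in the flip-flop
    potential; xy is free diffusion with periodic wrapping.  All
    randomness derives from ``scenario.langevin.seed`` through one
    counter-based Philox stream, so identical scenario + seed gives a
    bit-identical trajectory.
    """
    lp = scenario.langevin
    pot = scenario.potential
    lp.validate_stability(pot)
    kt = kbt(lp.temperature)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(lp.seed)))

    n = scenario.n_lipids
    pos = _initial_positions(scenario, rng)
    box = scenario.box.lengths
    n_snap_steps = max(1, int(round(scenario.snapshot_interval / lp.dt)))
    n_snapshots = int(np.floor(scenario.duration / scenario.snapshot_interval))

    n_w = scenario.n_waters
    if n_w:
        wpos = rng.uniform(0, 1, (n_w, 3)) * box
    prot = None
    if scenario.protein_xy is not None:
        px, py = scenario.protein_xy
        zs = np.linspace(-pot.z0, pot.z0, 9)
        prot = np.column_stack([np.full_like(zs, px), np.full_like(zs, py), zs])

    c_drift = lp.diffusion * lp.dt / kt
    c_noise = np.sqrt(2.0 * lp.diffusion * lp.dt)
    groove_aware = pot.groove is not None

    def assemble(t: float) -> Frame:
        parts = [pos.copy()]
        if n_w:
            parts.append(wpos.copy())
        if prot is not None:
            parts.append(prot.copy())
        return Frame(time=t, positions=np.vstack(parts), box=scenario.box)

    frames = [assemble(0.0)]
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    max_step = pot.z0
    for snap in range(1, n_snapshots + 1):
        eta = rng.standard_normal((n_snap_steps, n))
        eta_xy = rng.standard_normal((n_snap_steps, n, 2))
        if n_w:
            eta_w = rng.standard_normal((n_snap_steps, n_w, 3))
        for s in range(n_snap_steps):
            if groove_aware:
                force = pot.dudz(x, y, z)
            else:
                u = z / pot.z0
                force = -4.0 * pot.barrier * u * (1.0 - u * u) / pot.z0
            dz = -c_drift * force + c_noise * eta[s]
            if np.max(np.abs(dz)) > max_step:
                raise RuntimeError(
                    "Langevin step exceeded z0 in a single update; "
                    "reduce dt for a stable integration"
                )
            z += dz
            x += c_noise * eta_xy[s, :, 0]
            y += c_noise * eta_xy[s, :, 1]
            np.mod(x, box[0], out=x)
            np.mod(y, box[1], out=y)
            if n_w:
                wpos += c_noise * eta_w[s]
                np.mod(wpos, box, out=wpos)
        frames.append(assemble(snap * scenario.snapshot_interval))

    top = build_topology(n, n_w, 0 if prot is None else len(prot))
    return Trajectory.from_frames(frames, topology=top)


# ---------------------------------------------------------------------------
# biased CV sampling


def sample_biased(
    scenario: SyntheticScenario,
    bias,
    n_samples: int,
    seed: int,
    z_range: tuple[float, float] = (-3.5, 3.5),
    n_grid: int = 8001,
    sample_spacing: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw i.i.d. Boltzmann samples of the flip-flop CV under a bias.

    The 1-D marginal density p(z) ~ exp(-(U0(z) + U_bias(z)) / kT) is
    tabulated on a fine grid along the groove axis (or the bulk axis if
    no groove) and sampled exactly by inverse-CDF transform.  Returns
    (times, samples); times are synthetic stamps ``sample_spacing`` ns
    apart starting at ``sample_spacing``.
    """
    kt = kbt(scenario.langevin.temperature)
    z = np.linspace(z_range[0], z_range[1], n_grid)
    u = scenario.potential.axis_energy(z) + _bias_on_cv(bias, z)
    logp = -(u - u.min()) / kt
    keep = logp > -40.0
    if keep.sum() < 5:
        warnings.warn(
            "biased density has (nearly) no support on the sampling grid; "
            "the bias may not overlap the potential range",
            stacklevel=2,
        )
        keep = logp >= np.sort(logp)[-5]
    lo, hi = np.nonzero(keep)[0][[0, -1]]
    lo, hi = max(0, lo - 2), min(n_grid - 1, hi + 2)
    zf = np.linspace(z[lo], z[hi], 4001)
    uf = scenario.potential.axis_energy(zf) + _bias_on_cv(bias, zf)
    pf = np.exp(-(uf - uf.min()) / kt)
    cdf = np.concatenate([[0.0], np.cumsum((pf[1:] + pf[:-1]) * 0.5 * np.diff(zf))])
    if cdf[-1] <= 0:
        raise RuntimeError("biased density integrates to zero")
    cdf /= cdf[-1]
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    uu = rng.uniform(0.0, 1.0, n_samples)
    samples = np.interp(uu, cdf, zf)
    times = sample_spacing * np.arange(1, n_samples + 1)
    return times, samples


def _bias_on_cv(bias, z: np.ndarray) -> np.ndarray:
    """Evaluate a bias on CV values; accepts BiasPotential-likes or callables."""
    if bias is None:
        return np.zeros_like(z)
    if callable(bias) and not hasattr(bias, "energy_cv"):
        return np.asarray(bias(z), dtype=float)
    return np.asarray(bias.energy_cv(z), dtype=float)


def metropolis_sample(
    u_func,
    n_samples: int,
    seed: int,
    temperature: float = 310.0,
    x0: float = 0.0,
    step: float = 0.25,
    burn_in: int = 2000,
    thin: int = 5,
) -> np.ndarray:
    """Brute-force 1-D Metropolis chain sampling exp(-U(x)/kT).

    Kept deliberately simple and independent of :func:`sample_biased`;
    used as an independent sampler oracle in the test suite.
    """
    kt = kbt(temperature)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    total = burn_in + n_samples * thin
    prop = rng.normal(0.0, step, total)
    accept = rng.uniform(0.0, 1.0, total)
    out = np.empty(n_samples)
    x = float(x0)
    ux = float(u_func(x))
    k = 0
    for i in range(total):
        xn = x + prop[i]
        un = float(u_func(xn))
        if un <= ux or accept[i] < np.exp(-(un - ux) / kt):
            x, ux = xn, un
        if i >= burn_in and (i - burn_in) % thin == thin - 1:
            out[k] = x
            k += 1
    return out


# ---------------------------------------------------------------------------
# planted-event fixtures


def plant_events(
    n_lipids: int,
    schedule: list[tuple[int, float]],
    duration: float = 100.0,
    snapshot_interval: float = 10.0,
    z0: float = 2.0,
    box: BoxVectors | None = None,
) -> Trajectory:
    """Deterministic trajectory with flips exactly at scheduled times.

    Each lipid sits at +z0 (even index) or -z0 (odd index); at every
    scheduled (lipid, time) its phosphate z crosses the midplane, i.e.
    changes sign, at the first snapshot with t >= time.  All other
    lipids never leave their leaflet.  The schedule is the exact oracle
    for downstream event counting.
    """
    if box is None:
        box = BoxVectors(10.0, 10.0, 10.0)
    seen: set[tuple[int, float]] = set()
    buckets: set[tuple[int, int]] = set()
    for lipid, t in schedule:
        if not (0 <= lipid < n_lipids):
            raise ValueError(f"scheduled lipid {lipid} outside [0, {n_lipids})")
        if not (0 < t <= duration):
            raise ValueError(f"flip time {t} outside (0, {duration}]")
        key = (lipid, float(t))
        if key in seen:
            raise ValueError(f"duplicate scheduled event {key}")
        seen.add(key)
        # two flips of one lipid inside a single snapshot interval would
        # cancel invisibly, breaking the schedule-as-oracle contract
        bucket = (lipid, int(np.ceil(t / snapshot_interval - 1e-9)))
        if bucket in buckets:
            raise ValueError(f"lipid {lipid} has two flips within one snapshot interval")
        buckets.add(bucket)

    times = np.arange(0.0, duration + 1e-9, snapshot_interval)
    sign = np.where(np.arange(n_lipids) % 2 == 0, 1.0, -1.0)
    # flips[i, j] = number of scheduled flips of lipid j with time <= t_i
    frames = []
    flips = np.zeros(n_lipids, dtype=int)
    events = sorted(schedule, key=lambda e: e[1])
    ei = 0
    rng_x = np.linspace(0.5, box.lx - 0.5, n_lipids)
    for t in times:
        while ei < len(events) and events[ei][1] <= t + 1e-9:
            flips[events[ei][0]] += 1
            ei += 1
        z = sign * np.where(flips % 2 == 0, z0, -z0)
        pos = np.column_stack([rng_x, np.full(n_lipids, box.ly / 2.0), z])
        frames.append(Frame(time=float(t), positions=pos, box=box))
    top = build_topology(n_lipids)
    return Trajectory.from_frames(frames, topology=top)
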