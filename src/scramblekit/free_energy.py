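"""WHAM reconstruction of flip-flop free-energy profiles.

Standard self-consistent weighted-histogram iteration over umbrella
windows:

    P(b) = sum_i n_i(b) / sum_i N_i exp[(f_i - U_i(xi_b)) / kT]
    f_i  = -kT ln sum_b P(b) exp(-U_i(xi_b) / kT)

solved in log space to machine stability, with offsets reported
relative to the first window.  Profiles are F = -kT ln P shifted so
the global minimum is zero; the flip-flop barrier is then simply the
profile maximum.  The error estimate follows the profile-asymmetry
heuristic (a symmetric bilayer must give a symmetric profile); an
optional Bayesian bootstrap over windows is provided as a second,
resampling-based estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .reaction_coordinate import WindowSet
from .units import kbt

__all__ = [
    "WhamParams",
    "WhamResult",
    "FreeEnergyProfile",
    "BarrierReport",
    "ConvergenceError",
    "make_bins",
    "wham_solve",
    "to_profile",
    "extract_barrier",
    "bootstrap_error",
    "mean_profile",
]


class ConvergenceError(RuntimeError):
    """WHAM failed to reach the offset tolerance within max_iterations."""


def make_bins(cv_range: tuple[float, float], width: float = 0.05) -> np.ndarray:
    """Bin edges of the given width aligned so that xi = 0 is a bin center.

    Aligning a center at zero puts the top of a symmetric barrier on a
    bin center rather than an edge, avoiding a systematic
    discretization bias in the reported barrier height.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = cv_range
    if hi <= lo:
        raise ValueError("empty CV range")
    k_lo = np.floor((lo + width / 2) / width)
    k_hi = np.ceil((hi - width / 2) / width)
    return (np.arange(k_lo, k_hi + 2) - 0.5) * width


@dataclass(frozen=True)
class WhamParams:
    """WHAM solver settings (temperature in K, tolerance in kJ mol^-1)."""

    bin_edges: np.ndarray
    temperature: float = 310.0
    tolerance: float = 1e-8
    max_iterations: int = 100000
    seed: int | None = None

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        if len(edges) < 3:
            raise ValueError("need at least 2 bins")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class WhamResult:
    """Self-consistent WHAM solution.

    ``bin_counts`` holds the total sample count per bin across all
    windows; downstream consumers use it to mask bins whose free
    energy is statistically meaningless.
    """

    bin_centers: np.ndarray
    probability: np.ndarray
    offsets: np.ndarray
    iterations: int
    converged: bool
    temperature: float
    residual: float
    bin_counts: np.ndarray | None = None
    overlap_warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.probability < 0):
            raise ValueError("probabilities must be non-negative")


def wham_solve(windows: WindowSet, params: WhamParams) -> WhamResult:
    """Solve the WHAM equations for a window set.

    Deterministic given inputs.  Raises :class:`ConvergenceError` with
    the final residual if the offset update never drops below tolerance.
    """
    kt = kbt(params.temperature)
    edges = params.bin_edges
    centers = params.bin_centers
    n_win = len(windows)

    counts = np.empty((n_win, len(centers)))
    n_tot = np.empty(n_win)
    for i, w in enumerate(windows.windows):
        if w.samples.min() < edges[0] or w.samples.max() > edges[-1]:
            raise ValueError(
                f"window at {w.center} has samples outside the binned CV range "
                f"[{edges[0]:.3f}, {edges[-1]:.3f}]"
            )
        counts[i], _ = np.histogram(w.samples, bins=edges)
        n_tot[i] = w.n_samples

    # bias energy of window i at bin center b, in units of kT
    u = np.stack([w.bias().energy(centers) for w in windows.windows]) / kt
    log_counts_tot = np.log(np.maximum(counts.sum(axis=0), 1e-300))
    has_counts = counts.sum(axis=0) > 0
    log_n = np.log(n_tot)

    f = np.zeros(n_win)  # offsets in units of kT
    residual = np.inf
    for it in range(1, params.max_iterations + 1):
        # log denominator per bin: logsumexp_i [ log N_i + f_i - u_ib ]
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        log_p = np.where(has_counts, log_counts_tot - log_denom, -np.inf)
        # normalize (not required for the fixed point, keeps numbers tame)
        log_p -= logsumexp(log_p[has_counts])
        f_new = -logsumexp(log_p[None, :] - u, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f))) * kt
        f = f_new
        if residual < params.tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {params.max_iterations} iterations "
            f"(residual {residual:.3e} kJ/mol > tolerance {params.tolerance:.1e})"
        )

    log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    log_p = np.where(has_counts, log_counts_tot - log_denom, -np.inf)
    log_p -= logsumexp(log_p[has_counts])
    prob = np.exp(log_p)
    prob[~has_counts] = 0.0
    prob /= prob.sum()

    return WhamResult(
        bin_centers=centers, probability=prob, offsets=f * kt,
        iterations=it, converged=True, temperature=params.temperature,
        residual=residual, bin_counts=counts.sum(axis=0),
        overlap_warnings=list(windows.overlap_warnings),
    )


@dataclass
class FreeEnergyProfile:
    """Free energy vs CV, global minimum shifted to zero.

    Bins without sampling support hold NaN (masked, never
    extrapolated).  ``asymmetry_error`` is max over xi of
    |F(xi) - F(-xi)| / 2 on the mirrored common support.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    asymmetry_error: float
    temperature: float

    @property
    def supported(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    @property
    def barrier(self) -> float:
        if not np.any(self.supported):
            raise ValueError("profile has no supported bins")
        return float(np.nanmax(self.free_energy))

    def to_tsv(self, path) -> None:
        header = "xi_nm\tfree_energy_kJ_per_mol\tasymmetry_error_kJ_per_mol"
        err = np.full(len(self.bin_centers), self.asymmetry_error)
        np.savetxt(path, np.column_stack([self.bin_centers, self.free_energy, err]),
                   delimiter="\t", header=header, comments="", fmt="%.6f")


def _asymmetry(centers: np.ndarray, f: np.ndarray) -> float:
    ok = np.isfinite(f)
    if ok.sum() < 2:
        return float("nan")
    c, v = centers[ok], f[ok]
    lo, hi = c.min(), c.max()
    mirrored_ok = (-c >= lo) & (-c <= hi)
    if not np.any(mirrored_ok):
        return float("nan")
    f_mirror = np.interp(-c[mirrored_ok], c, v)
    return float(np.max(np.abs(v[mirrored_ok] - f_mirror)) / 2.0)


def to_profile(result: WhamResult, min_count: int = 1) -> FreeEnergyProfile:
    """Convert a WHAM solution to a min-zeroed free-energy profile.

    Bins holding fewer than ``min_count`` samples (summed over all
    windows) are masked before the shift: a near-empty bin has an
    essentially unconstrained free energy, and letting it set the
    zero point would corrupt the whole profile.
    """
    if not result.converged:
        raise ValueError("WHAM result is not converged")
    kt = kbt(result.temperature)
    with np.errstate(divide="ignore"):
        f = -kt * np.log(result.probability)
    f[result.probability <= 0] = np.nan
    if min_count > 1 and result.bin_counts is not None:
        f[result.bin_counts < min_count] = np.nan
    f -= np.nanmin(f)
    return FreeEnergyProfile(
        bin_centers=result.bin_centers.copy(), free_energy=f,
        asymmetry_error=_asymmetry(result.bin_centers, f),
        temperature=result.temperature,
    )


@dataclass
class BarrierReport:
    """Flip-flop barrier and, optionally, the reduction vs a reference."""

    barrier: float
    reference_barrier: float | None = None
    reduction_percent: float | None = None

    def __post_init__(self):
        if self.barrier < 0:
            raise ValueError("barrier must be non-negative")
        if self.reduction_percent is not None and self.reduction_percent > 100:
            raise ValueError("reduction cannot exceed 100%")


def extract_barrier(
    profile: FreeEnergyProfile,
    reference: FreeEnergyProfile | float | None = None,
) -> BarrierReport:
    """Barrier = profile maximum (minimum is 0 by construction).

    With a reference profile (or a bare reference barrier height), the
    relative reduction (ref - barrier) / ref is reported in percent.
    """
    barrier = profile.barrier
    if reference is None:
        return BarrierReport(barrier=barrier)
    ref = reference if isinstance(reference, (int, float)) else reference.barrier
    if ref <= 0:
        raise ValueError("reference barrier must be positive")
    reduction = (ref - barrier) / ref * 100.0
    return BarrierReport(barrier=barrier, reference_barrier=float(ref),
                         reduction_percent=reduction)


def bootstrap_error(
    windows: WindowSet,
    params: WhamParams,
    n_boot: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Bayesian-bootstrap standard error of F per bin.

    Windows are reweighted with Dirichlet(1,...,1) weights applied to
    their sample counts; WHAM is re-solved for each replicate.
    Complements the asymmetry heuristic with a resampling estimate.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    base = [w for w in windows.windows]
    for _ in range(n_boot):
        weights = rng.dirichlet(np.ones(len(base))) * len(base)
        resampled = WindowSet(windows=[
            _reweighted(w, wt, rng) for w, wt in zip(base, weights)
        ])
        prof = to_profile(wham_solve(resampled, params))
        profiles.append(prof.free_energy)
    return np.nanstd(np.stack(profiles), axis=0)


def _reweighted(window, weight: float, rng):
    from .reaction_coordinate import UmbrellaWindow

    n = max(1, int(round(window.n_samples * weight)))
    idx = rng.integers(0, window.n_samples, n)
    return UmbrellaWindow(
        center=window.center, force_constant=window.force_constant,
        times=np.arange(1.0, n + 1.0), samples=window.samples[idx],
        equilibration_cutoff=window.equilibration_cutoff,
    )


def mean_profile(profiles: list[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Pointwise mean of profiles on identical bins (e.g. the two
    pulling directions of a hysteresis-free calculation), re-zeroed."""
    if not profiles:
        raise ValueError("no profiles to combine")
    centers = profiles[0].bin_centers
    for p in profiles[1:]:
        if not np.allclose(p.bin_centers, centers):
            raise ValueError("profiles must share bin centers")
    stack = np.stack([p.free_energy for p in profiles])
    mean = np.nanmean(stack, axis=0)
    mean -= np.nanmin(mean)
    return FreeEnergyProfile(
        bin_centers=centers.copy(), free_energy=mean,
        asymmetry_error=_asymmetry(centers, mean),
        temperature=profiles[0].temperature,
    )
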