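"""Thermal units, umbrella-window planning, WHAM, and 1-D diffusive kinetics.

The free-energy profile G(x) along the lateral peptide--cholesterol distance
is reconstructed from harmonically biased umbrella windows with the weighted
histogram analysis method (WHAM). Binding kinetics are then obtained from
the mean first-passage time of an overdamped 1-D diffusion on G(x),

    tau(a -> b) = int_a^b dx  e^{beta G(x)} / D(x)  int_{x0}^{x} dy e^{-beta G(y)},

with a the bound state, b the dissociated state, and x0 a reflecting
barrier below the bound state. The position-dependent diffusivity is
estimated per window as D = Var(x) / theta, with theta the integrated
autocorrelation time of the sampled coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1.
KB_KJ_MOL_K = 0.0083145


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and derived inverse thermal energy beta = 1/(kB T)."""

    temperature_K: float = 300.0
    kB: float = KB_KJ_MOL_K

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return self.kB * self.temperature_K

    @property
    def beta(self) -> float:
        """Inverse thermal energy in mol/kJ."""
        return 1.0 / self.kbt


def to_kbt(energy_kj_mol, context: ThermalContext = ThermalContext()):
    """Convert kJ/mol to units of kB*T (5 kJ/mol at 300 K -> ~2 kBT)."""
    return np.asarray(energy_kj_mol, dtype=float) * context.beta


def from_kbt(energy_kbt, context: ThermalContext = ThermalContext()):
    return np.asarray(energy_kbt, dtype=float) * context.kbt


def arrhenius_ratio(delta_G_kbt: float) -> float:
    """Fold change in residence time from a barrier change of delta_G (kBT).

    Assumes an unchanged kinetic prefactor: ratio = exp(delta_G). A 14 kBT
    difference gives ~1.2e6.
    """
    return float(np.exp(delta_G_kbt))


def plan_windows(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic grid of umbrella window centers.

    The production protocol spans 0.7-2.3 nm at 0.2 nm spacing -> 9 windows.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n_float = (hi - lo) / spacing
    n = round(n_float)
    if abs(n_float - n) > 1e-9:
        suggestion = (hi - lo) / max(n, 1)
        raise ValueError(
            f"spacing {spacing} does not divide the range {hi - lo}; "
            f"nearest valid spacing is {suggestion:.10g}"
        )
    return lo + spacing * np.arange(n + 1)


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic bias."""

    center: float            # nm
    spring_k: float          # kJ mol^-1 nm^-2; 0 allowed (unbiased window)
    samples: np.ndarray      # nm

    def __post_init__(self):
        if self.spring_k < 0:
            raise ValueError("spring constant must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 2:
            raise ValueError("need >= 2 samples per window")

    def bias_energy(self, x) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(x, dtype=float) - self.center) ** 2

    def to_files(self, samples_path, meta_path, dt_ps: float | None = None) -> None:
        np.savetxt(samples_path, self.samples, fmt="%.10g")
        meta = {"center_nm": self.center, "spring_k_kj_mol_nm2": self.spring_k}
        if dt_ps is not None:
            meta["dt_ps"] = dt_ps
        with open(meta_path, "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def from_files(cls, samples_path, meta_path) -> "UmbrellaWindow":
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(center=meta["center_nm"], spring_k=meta["spring_k_kj_mol_nm2"],
                   samples=np.loadtxt(samples_path))


@dataclass
class FreeEnergyProfile:
    """G(x) in kJ/mol on a strictly ascending nm grid, min-normalized to 0."""

    x: np.ndarray
    G: np.ndarray
    context: ThermalContext = field(default_factory=ThermalContext)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.x.shape != self.G.shape or self.x.ndim != 1:
            raise ValueError("x and G must be 1-D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("grid must be strictly ascending")
        self.G = self.G - np.min(self.G)

    def interp(self, xq) -> np.ndarray:
        return np.interp(xq, self.x, self.G)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x_nm\tG_kJ_mol\n")
            for xi, gi in zip(self.x, self.G):
                fh.write(f"{xi:.10g}\t{gi:.10g}\n")

    @classmethod
    def from_tsv(cls, path, context: ThermalContext = ThermalContext()):
        data = np.loadtxt(path, skiprows=1)
        return cls(x=data[:, 0], G=data[:, 1], context=context)


def wham(windows, grid, context: ThermalContext = ThermalContext(),
         tol: float = 1e-7, max_iter: int = 100_000) -> FreeEnergyProfile:
    """Self-consistent binned WHAM over harmonically biased windows.

    Histograms all windows on bins defined by the (uniform) grid, then
    iterates the window free-energy constants f_i until max|delta f| < tol
    (kJ/mol). Returns -kBT ln(unbiased density), min-normalized, with
    convergence metadata in ``meta``.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one umbrella window")
    grid = np.asarray(grid, dtype=float)
    widths = np.diff(grid)
    if np.any(widths <= 0):
        raise ValueError("grid must be strictly ascending")
    if not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValueError("wham requires a uniform grid")
    # bin edges centered on the grid points
    h = widths[0]
    edges = np.concatenate([[grid[0] - h / 2], grid[:-1] + h / 2, [grid[-1] + h / 2]])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    N_i = counts.sum(axis=1)
    if np.any(N_i == 0):
        empty = [windows[i].center for i in np.flatnonzero(N_i == 0)]
        raise ValueError(f"windows at {empty} have no samples inside the grid span")
    total_counts = counts.sum(axis=0)
    occupied = total_counts > 0
    if occupied.any():
        first, last = np.flatnonzero(occupied)[[0, -1]]
        gap = ~occupied[first:last + 1]
        if gap.any():
            lo_gap = grid[first:last + 1][gap][0]
            hi_gap = grid[first:last + 1][gap][-1]
            raise ValueError(
                f"empty bins span a gap in sampling between {lo_gap:.4g} and "
                f"{hi_gap:.4g} nm; windows do not overlap"
            )

    beta = context.beta
    bias = np.stack([w.bias_energy(grid) for w in windows])  # (n_win, n_bins)
    boltz_bias = np.exp(-beta * bias)
    f = np.zeros(len(windows))
    for iteration in range(1, max_iter + 1):
        # unbiased density estimate (unnormalized; bin width cancels in gauge)
        denom = (N_i[:, None] * np.exp(beta * f)[:, None] * boltz_bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, total_counts / denom, 0.0)
        z = (boltz_bias * rho[None, :]).sum(axis=1)
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.3g})"
        )

    with np.errstate(divide="ignore"):
        G = np.where(rho > 0, -np.log(np.where(rho > 0, rho, 1.0)) / beta, np.nan)
    valid = np.isfinite(G)
    profile = FreeEnergyProfile(
        x=grid[valid], G=G[valid], context=context,
        meta={"iterations": iteration, "residual_kj_mol": delta,
              "n_windows": len(windows)},
    )
    return profile


def autocorr_time(series, dt: float = 1.0) -> float:
    """Integrated autocorrelation time of a stationary series.

    theta = dt * sum_{k>=0} rho_k, the one-sided rectangle sum of the
    normalized ACF up to the first lag at which the estimate drops below
    zero (adaptive cutoff). This is the convention under which
    D = Var(x)/theta recovers the diffusion coefficient of an
    Ornstein-Uhlenbeck process (theta -> its relaxation time). White noise
    gives theta ~= dt; an AR(1) process with coefficient phi gives
    theta ~= dt/(1 - phi).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need >= 100 samples for a stable estimate")
    x = x - x.mean()
    var = float(np.dot(x, x)) / x.size
    if var == 0:
        raise ValueError("zero-variance series has no autocorrelation time")
    n = x.size
    # FFT-based ACF
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n
    rho = acov / acov[0]
    total = 1.0
    for k in range(1, n):
        if rho[k] < 0:
            break
        total += rho[k]
    return float(total * dt)


def diffusion_from_window(window: UmbrellaWindow, dt: float) -> float:
    """Diffusion coefficient at the window center: D = Var(x) / theta.

    For an Ornstein-Uhlenbeck process this is exact: Var = kBT/k and
    theta = Var/D, so the estimate is invariant to the bias spring constant.
    """
    if window.samples.size < 100:
        raise ValueError("need >= 100 samples per window")
    theta = autocorr_time(window.samples, dt)
    return float(np.var(window.samples) / theta)


@dataclass
class DiffusionProfile:
    """D(x) interpolated linearly between per-window estimates (nm^2/ps).

    Held constant beyond the outermost window centers.
    """

    centers: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D <= 0):
            raise ValueError("diffusion coefficients must be positive")
        order = np.argsort(self.centers)
        self.centers = self.centers[order]
        self.D = self.D[order]

    @classmethod
    def constant(cls, D: float) -> "DiffusionProfile":
        return cls(centers=np.array([0.0]), D=np.array([D]))

    def interp(self, xq) -> np.ndarray:
        return np.interp(xq, self.centers, self.D)


def residence_time(G: FreeEnergyProfile, D: DiffusionProfile,
                   a: float, b: float, x0: float,
                   n_refine: int = 4) -> float:
    """Mean first-passage time from the bound state a to the dissociated
    state b, with a reflecting boundary at x0 (x0 <= a < b).

    Computed by nested composite-trapezoid quadrature of

        tau = int_a^b dx e^{beta G(x)}/D(x) int_{x0}^{x} dy e^{-beta G(y)}

    on the profile grid densified ``n_refine``-fold. Time unit follows D
    (ps for nm^2/ps).
    """
    if not (x0 <= a < b):
        raise ValueError("require x0 <= a < b")
    if x0 < G.x[0] - 1e-9 or b > G.x[-1] + 1e-9:
        raise ValueError("integration limits fall outside the profile grid")
    beta = G.context.beta

    n_pts = max(2, int(np.ceil((b - x0) / (G.x[1] - G.x[0]) * n_refine)) + 1)
    y = np.linspace(x0, b, n_pts)
    g = G.interp(y)
    inner = np.concatenate([[0.0], np.cumsum(
        0.5 * (np.exp(-beta * g[1:]) + np.exp(-beta * g[:-1])) * np.diff(y))])
    # restrict the outer integral to [a, b]
    mask = y >= a - 1e-12
    xo = y[mask]
    outer_integrand = np.exp(beta * G.interp(xo)) / D.interp(xo) * inner[mask]
    tau = float(np.trapezoid(outer_integrand, xo))
    return tau
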