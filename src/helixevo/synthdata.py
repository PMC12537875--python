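"""Synthetic-data generators with analytic references.

Every generator here is seeded and deterministic, and produces data in the
exact formats the analysis modules consume, so each analysis operation can
be tested against a known ground truth:

* 1-D overdamped Langevin trajectories on a known free-energy profile
  (optionally under a harmonic umbrella bias, optionally reflected at a
  boundary) — the oracle for WHAM and for the residence-time integral;
* direct mean first-passage time simulation — the independent kinetic
  reference;
* membrane point-cloud snapshots with a prescribed radial composition — the
  oracle for the cholesterol-ratio statistic;
* separable additive fitness landscapes with an analytic optimum — the
  convergence oracle for the genetic algorithm;
* toy proteomes with controlled TM-span lengths — fixtures for window
  normalization;
* surrogate-labeled random sequence datasets for the CNN regressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from helixevo.fitness import surrogate_fitness, SurrogateParams
from helixevo.memanalysis import MembraneSnapshot
from helixevo.seqcore import ALPHABET
from helixevo.thermo import ThermalContext
from helixevo.tmdprep import ProteinRecord


# ---------------------------------------------------------------------------
# Analytic PMFs

@dataclass
class GaussianPMF:
    """Sum-of-Gaussians free-energy profile with an analytic gradient.

    G(x) = sum_j A_j exp(-(x - mu_j)^2 / (2 s_j^2)), kJ/mol. Negative A_j
    make wells, positive A_j barriers.
    """

    amplitudes: np.ndarray
    centers: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.centers) / self.widths
        return (self.amplitudes * np.exp(-0.5 * z ** 2)).sum(axis=-1)

    def grad(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.centers) / self.widths
        return (-self.amplitudes * z / self.widths
                * np.exp(-0.5 * z ** 2)).sum(axis=-1)


def flat_pmf() -> GaussianPMF:
    return GaussianPMF(amplitudes=[0.0], centers=[0.0], widths=[1.0])


def single_well_pmf(depth_kbt: float = 2.0, center: float = 0.9,
                    width: float = 0.15,
                    context: ThermalContext = ThermalContext()) -> GaussianPMF:
    """A single attractive well of the requested depth (in kBT)."""
    return GaussianPMF(amplitudes=[-depth_kbt * context.kbt],
                       centers=[center], widths=[width])


def double_well_pmf(context: ThermalContext = ThermalContext()) -> GaussianPMF:
    """Two wells separated by a barrier, spanning roughly 0.7-2.3 nm."""
    kbt = context.kbt
    return GaussianPMF(
        amplitudes=[-2.0 * kbt, 1.0 * kbt, -1.2 * kbt],
        centers=[1.0, 1.5, 2.0],
        widths=[0.15, 0.12, 0.15],
    )


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics

@dataclass
class LangevinSpec:
    """Euler-Maruyama integration of overdamped 1-D diffusion on a PMF.

    x <- x - beta D G'(x) dt + sqrt(2 D dt) xi, with optional harmonic bias
    0.5 k (x - c)^2 added to G and optional reflecting boundary (position
    mirroring).
    """

    pmf: GaussianPMF
    D: float = 0.05              # nm^2/ps
    dt: float = 0.05             # ps
    n_steps: int = 10_000
    x_init: float = 1.0
    context: ThermalContext = field(default_factory=ThermalContext)
    seed: int = 0
    bias_center: float | None = None
    bias_k: float = 0.0          # kJ mol^-1 nm^-2
    reflect_at: float | None = None
    probe_range: tuple = (0.0, 3.0)

    def total_grad(self, x):
        g = self.pmf.grad(x)
        if self.bias_center is not None and self.bias_k > 0:
            g = g + self.bias_k * (np.asarray(x) - self.bias_center)
        return g

    def check_stability(self) -> None:
        """Euler-Maruyama stability: relaxation per step must stay below 2.

        The stiffest local curvature k_max of the total potential gives a
        per-step relaxation factor beta*D*k_max*dt; the scheme diverges
        beyond 2 and is accurate well below 1.
        """
        probe = np.linspace(*self.probe_range, 1024)
        grad = self.total_grad(probe)
        k_max = float(np.max(np.abs(np.gradient(grad, probe))))
        relax = self.context.beta * self.D * k_max * self.dt
        if relax > 1.0:
            raise ValueError(
                f"unstable integration: beta*D*k_max*dt = {relax:.3g} > 1 "
                f"(local stiffness {k_max:.3g} kJ/mol/nm^2); reduce dt"
            )


def _step_ensemble(x: np.ndarray, spec: LangevinSpec,
                   noise: np.ndarray) -> np.ndarray:
    x = x - spec.context.beta * spec.D * spec.total_grad(x) * spec.dt + noise
    if spec.reflect_at is not None:
        below = x < spec.reflect_at
        x[below] = 2 * spec.reflect_at - x[below]
    return x


def langevin_1d(spec: LangevinSpec) -> np.ndarray:
    """One seeded trajectory of n_steps positions (x_init excluded)."""
    spec.check_stability()
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(2 * spec.D * spec.dt)
    noise = rng.normal(0.0, sigma, size=spec.n_steps)
    out = np.empty(spec.n_steps)
    x = np.array([spec.x_init])
    for i in range(spec.n_steps):
        x = _step_ensemble(x, spec, noise[i])
        out[i] = x[0]
    return out


def mfpt_direct(spec: LangevinSpec, a: float, b: float,
                x0_reflect: float, n_traj: int = 2000,
                max_steps: int | None = None) -> float:
    """Mean first-passage time a -> b by direct simulation.

    All n_traj walkers start at a, are reflected at x0_reflect, and are
    absorbed at b; the returned value is the mean absorption time (same
    unit as dt). Walkers are stepped together as one vector.
    """
    if not a < b:
        raise ValueError("require a < b")
    spec.check_stability()
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(2 * spec.D * spec.dt)
    reflected = LangevinSpec(**{**spec.__dict__, "reflect_at": x0_reflect})
    if max_steps is None:
        # generous cap: ~50x the flat-landscape expectation
        tau_flat = ((b - x0_reflect) ** 2 - (a - x0_reflect) ** 2) / (2 * spec.D)
        max_steps = max(1000, int(50 * tau_flat / spec.dt))
    x = np.full(n_traj, float(a))
    alive = np.ones(n_traj, dtype=bool)
    fpt = np.empty(n_traj)
    for step in range(1, max_steps + 1):
        idx = np.flatnonzero(alive)
        x[idx] = _step_ensemble(x[idx], reflected, rng.normal(0, sigma, idx.size))
        crossed = idx[x[idx] >= b]
        if crossed.size:
            fpt[crossed] = step * spec.dt
            alive[crossed] = False
        if not alive.any():
            break
    else:
        raise RuntimeError(
            f"{int(alive.sum())} of {n_traj} walkers not absorbed within "
            f"{max_steps} steps; increase max_steps or check the landscape"
        )
    return float(fpt.mean())


def umbrella_series(pmf: GaussianPMF, centers, spring_k: float,
                    n_steps: int, dt: float = 0.05, D: float = 0.05,
                    context: ThermalContext = ThermalContext(),
                    seed: int = 0, burn_in: int = 1000) -> list:
    """Biased Langevin sample series for each umbrella window center."""
    series = []
    for i, center in enumerate(centers):
        spec = LangevinSpec(
            pmf=pmf, D=D, dt=dt, n_steps=n_steps + burn_in,
            x_init=float(center), context=context, seed=seed + i,
            bias_center=float(center), bias_k=spring_k,
        )
        series.append(langevin_1d(spec)[burn_in:])
    return series


# ---------------------------------------------------------------------------
# Membrane snapshots

@dataclass
class SnapshotSpec:
    """Point-cloud membrane snapshot with piecewise-constant radial densities.

    Each species is placed at a lateral distance from the (box-centered)
    peptide drawn from a piecewise-constant radial density over annuli
    bounded by ``radial_edges``; angles are uniform. Defaults mirror the
    template membrane composition of 90 POPC + 38 CHOL.
    """

    n_popc: int = 90
    n_chol: int = 38
    box: tuple = (5.6, 5.6, 10.0)
    radial_edges: tuple = (0.0, 2.8)
    popc_density: tuple = (1.0,)
    chol_density: tuple = (1.0,)
    seed: int = 0

    def __post_init__(self):
        if self.n_popc < 0 or self.n_chol < 0:
            raise ValueError("counts must be >= 0")
        edges = np.asarray(self.radial_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("radial_edges must be ascending")
        for dens, n in ((self.popc_density, self.n_popc),
                        (self.chol_density, self.n_chol)):
            dens = np.asarray(dens, dtype=float)
            if dens.size != edges.size - 1:
                raise ValueError("density needs one value per annulus")
            if np.any(dens < 0):
                raise ValueError("densities must be >= 0")
            if n > 0 and not np.any(dens > 0):
                raise ValueError("density integrates to zero with nonzero count")


def _sample_radii(n: int, edges: np.ndarray, density: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of r from a piecewise-constant areal density."""
    # annulus mass proportional to density * (r_hi^2 - r_lo^2)
    mass = density * (edges[1:] ** 2 - edges[:-1] ** 2)
    mass = mass / mass.sum()
    which = rng.choice(len(mass), size=n, p=mass)
    u = rng.random(n)
    lo, hi = edges[which], edges[which + 1]
    return np.sqrt(lo ** 2 + u * (hi ** 2 - lo ** 2))


def membrane_snapshot(spec: SnapshotSpec, frame_time: float = 0.0
                      ) -> MembraneSnapshot:
    """Generate one snapshot with the peptide at the lateral box center."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    edges = np.asarray(spec.radial_edges, dtype=float)
    points = {}
    for name, n, density in (("popc", spec.n_popc, spec.popc_density),
                             ("chol", spec.n_chol, spec.chol_density)):
        if n == 0:
            points[name] = np.empty((0, 3))
            continue
        r = _sample_radii(n, edges, np.asarray(density, dtype=float), rng)
        phi = rng.uniform(0, 2 * np.pi, size=n)
        z = rng.uniform(center[2] - 1.0, center[2] + 1.0, size=n)
        xyz = np.column_stack([center[0] + r * np.cos(phi),
                               center[1] + r * np.sin(phi), z])
        xyz[:, :2] %= box[:2]  # periodic wrap
        points[name] = xyz
    return MembraneSnapshot(peptide_com=center, chol_points=points["chol"],
                            popc_points=points["popc"], box=box,
                            frame_time=frame_time)


# ---------------------------------------------------------------------------
# Fitness landscapes and sequence datasets

def additive_landscape(weights: np.ndarray | None = None, seed: int = 0,
                       half_length: int = 10, alphabet: str = ALPHABET):
    """A separable fitness landscape over the free half-genome.

    fitness(s) = sum_i w[i, index(s_i)] over the first ``half_length``
    positions of the (palindromic) sequence. Returns (fitness_callable,
    optimum_sequence, optimum_fitness); the optimum is the per-position
    argmax, expanded to the full palindrome.
    """
    if weights is None:
        rng = np.random.default_rng(seed)
        weights = rng.normal(0.0, 1.0, size=(half_length, len(alphabet)))
    weights = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    index = {aa: i for i, aa in enumerate(alphabet)}

    def fitness(sequence: str) -> float:
        free = sequence[:half_length]
        return float(sum(weights[i, index[aa]] for i, aa in enumerate(free)))

    best_free = "".join(alphabet[int(j)] for j in weights.argmax(axis=1))
    optimum_sequence = best_free + best_free[::-1]
    optimum_fitness = float(weights.max(axis=1).sum())
    return fitness, optimum_sequence, optimum_fitness


def rugged_landscape(seed: int = 0, half_length: int = 10,
                     n_interactions: int = 30, alphabet: str = ALPHABET):
    """An additive landscape plus random pairwise epistatic terms.

    Used to compare GA population sizes: small populations converge to
    local optima on such landscapes.
    """
    rng = np.random.default_rng(seed)
    add, _, _ = additive_landscape(seed=seed, half_length=half_length,
                                   alphabet=alphabet)
    index = {aa: i for i, aa in enumerate(alphabet)}
    pairs = []
    for _ in range(n_interactions):
        i, j = rng.choice(half_length, size=2, replace=False)
        table = rng.normal(0.0, 2.0, size=(len(alphabet), len(alphabet)))
        pairs.append((int(i), int(j), table))

    def fitness(sequence: str) -> float:
        total = add(sequence)
        for i, j, table in pairs:
            total += table[index[sequence[i]], index[sequence[j]]]
        return float(total)

    return fitness


def random_sequences(n: int, length: int = 20, seed: int = 0,
                     alphabet: str = ALPHABET) -> list:
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    return ["".join(letters[rng.integers(0, len(letters), size=length)])
            for _ in range(n)]


def surrogate_labeled_dataset(n: int, seed: int = 0,
                              params: SurrogateParams | None = None) -> list:
    """(sequence, fitness) pairs: random 20-mers labeled by the surrogate."""
    return [(s, surrogate_fitness(s, params))
            for s in random_sequences(n, 20, seed)]


def toy_proteome(n_proteins: int, span_length_law=None, seed: int = 0,
                 spans_per_protein=(1, 3), linker_length: int = 12) -> list:
    """Seeded random proteins with non-overlapping TM spans.

    ``span_length_law`` is a callable rng -> span length (default: uniform
    16..24); ``spans_per_protein`` bounds the number of spans (inclusive).
    """
    if n_proteins < 1:
        raise ValueError("need n_proteins >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    if span_length_law is None:
        span_length_law = lambda r: int(r.integers(16, 25))
    records = []
    for p in range(n_proteins):
        n_spans = int(rng.integers(spans_per_protein[0],
                                   spans_per_protein[1] + 1))
        lengths = [span_length_law(rng) for _ in range(n_spans)]
        if any(l < 1 for l in lengths):
            raise ValueError("span length law produced a non-positive length")
        spans = []
        pos = 1 + linker_length
        for length in lengths:
            spans.append((pos, pos + length - 1))
            pos += length + linker_length
        total = pos - 1
        seq = "".join(letters[rng.integers(0, 20, size=total)])
        records.append(ProteinRecord(f"prot{p:04d}", seq, spans))
    return records
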