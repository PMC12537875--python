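"""Fitness backends for the peptide GA.

Three routes are provided:

* :func:`fitness_from_energy_series` — the production definition: the
  absolute value of the ensemble-averaged peptide--cholesterol short-ranged
  interaction energy taken from an MD energy time series after discarding
  the equilibration segment.
* :func:`surrogate_fitness` — a fast, fully documented closed-form score
  used for desk-scale runs and testing. It is deliberately simple and
  non-physical, but its optimum expresses the same qualitative design
  pattern as the simulations select: a short central hydrophobic block
  flanked by stacked K/R residues, acidic termini, and a penalty for bulky
  aromatic residues.
* :func:`emit_run_recipe` — emits (never executes) the coarse-grained MD
  protocol as a documented key = value parameter file plus a job manifest
  with charge bookkeeping, so production runs can be reconstructed outside
  this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# Energy time series

@dataclass
class EnergySeries:
    """Per-frame interaction energy: time in ps (strictly increasing), kJ/mol."""

    time: np.ndarray
    energy: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.time.shape != self.energy.shape or self.time.ndim != 1:
            raise ValueError("time and energy must be 1-D arrays of equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time values must be strictly increasing")


def read_xvg(path) -> EnergySeries:
    """Read a two-column xvg-dialect text file (``#``/``@`` lines ignored)."""
    times, energies = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "@")):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            try:
                times.append(float(fields[0]))
                energies.append(float(fields[1]))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric data")
    if not times:
        raise ValueError(f"{path}: no data rows (empty series)")
    return EnergySeries(np.array(times), np.array(energies))


def write_xvg(series: EnergySeries, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("@ title \"peptide-cholesterol interaction energy\"\n")
        fh.write("@ xaxis label \"time (ps)\"\n")
        fh.write("@ yaxis label \"energy (kJ/mol)\"\n")
        if comment:
            fh.write(f"# {comment}\n")
        for t, e in zip(series.time, series.energy):
            fh.write(f"{t:.10g} {e:.10g}\n")


def fitness_from_energy_series(series: EnergySeries,
                               equilibration_ns: float = 50.0) -> float:
    """|mean energy| over frames with time >= the equilibration cutoff.

    Interaction energies are negative for attraction; the absolute value is
    returned so that larger = fitter.
    """
    cutoff_ps = equilibration_ns * 1000.0
    kept = series.energy[series.time >= cutoff_ps]
    if kept.size == 0:
        raise ValueError(
            f"all frames fall before the {equilibration_ns} ns equilibration cutoff"
        )
    return float(abs(np.mean(kept)))


# ---------------------------------------------------------------------------
# Mechanistic surrogate

#: Approximate residue van-der-Waals volumes (A^3), used as a bulk penalty
#: scale. Only relative magnitudes matter.
RESIDUE_VOLUME = {
    "G": 60.1, "A": 88.6, "S": 89.0, "C": 108.5, "D": 111.1, "P": 112.7,
    "N": 114.1, "T": 116.1, "E": 138.4, "V": 140.0, "Q": 143.8, "H": 153.2,
    "M": 162.9, "I": 166.7, "L": 166.7, "K": 168.6, "R": 173.4, "F": 189.9,
    "Y": 193.6, "W": 227.8,
}

HYDROPHOBIC = frozenset("ACGILMPVFWY")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")
AROMATIC = frozenset("FYW")


@dataclass
class SurrogateParams:
    """Weights of the closed-form surrogate score (see surrogate_fitness)."""

    charged_flank_reward: float = 10.0
    terminal_acid_reward: float = 4.0
    bulk_penalty_scale: float = 0.05
    aromatic_penalty: float = 8.0
    min_block_length: float = 6
    instability_penalty: float = 25.0
    mismatch_reward: float = 3.0

    def __post_init__(self):
        if min(self.charged_flank_reward, self.terminal_acid_reward,
               self.bulk_penalty_scale, self.aromatic_penalty,
               self.instability_penalty, self.mismatch_reward) < 0:
            raise ValueError("penalties and rewards must be >= 0")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")

    @classmethod
    def from_json(cls, path) -> "SurrogateParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def _longest_block(sequence: str) -> tuple[int, int]:
    """(start, length) of the longest contiguous hydrophobic run (first wins)."""
    best_start = best_len = 0
    run_start = run_len = 0
    for i, aa in enumerate(sequence):
        if aa in HYDROPHOBIC:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    return best_start, best_len


def surrogate_fitness(sequence: str,
                      params: SurrogateParams | None = None) -> float:
    """Deterministic closed-form sequence score (to maximize).

    With b = length of the longest contiguous hydrophobic block and L = 20::

        score = charged_flank_reward * (# K/R adjacent to that block, up to
                    3 deep on each side)
              + terminal_acid_reward  * (# D/E within the first/last 2 positions)
              + mismatch_reward * (L - b)          if b >= min_block_length
              - instability_penalty * (min_block_length - b)   otherwise
              - aromatic_penalty * (# F/Y/W)
              - bulk_penalty_scale * sum of residue volumes inside the block

    The mismatch term rewards short (negatively mismatched) blocks, the
    instability term dominates once the block is too short to hold a
    transmembrane orientation, and the bulk/aromatic terms favor small
    hydrophobic residues over leucine and aromatics.
    """
    if params is None:
        params = SurrogateParams()
    L = len(sequence)
    if L != 20:
        raise ValueError(f"surrogate expects length-20 sequences, got {L}")
    for aa in sequence:
        if aa not in RESIDUE_VOLUME:
            raise ValueError(f"unknown residue {aa!r}")

    start, b = _longest_block(sequence)
    score = 0.0

    # stacked K/R directly flanking the hydrophobic block (up to 3 per side)
    flank = 0
    for i in range(start - 1, max(start - 4, -1), -1):
        if sequence[i] in BASIC:
            flank += 1
        else:
            break
    for i in range(start + b, min(start + b + 3, L)):
        if sequence[i] in BASIC:
            flank += 1
        else:
            break
    score += params.charged_flank_reward * flank

    score += params.terminal_acid_reward * sum(
        1 for i in (0, 1, L - 2, L - 1) if sequence[i] in ACIDIC
    )

    if b >= params.min_block_length:
        score += params.mismatch_reward * (L - b)
    else:
        score -= params.instability_penalty * (params.min_block_length - b)

    score -= params.aromatic_penalty * sum(1 for aa in sequence if aa in AROMATIC)
    score -= params.bulk_penalty_scale * sum(
        RESIDUE_VOLUME[aa] for aa in sequence[start:start + b]
    )
    return score


# ---------------------------------------------------------------------------
# Charge bookkeeping and run-recipe emission

RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}  # H treated as neutral


def net_charge(sequence: str) -> int:
    return sum(RESIDUE_CHARGE.get(aa, 0) for aa in sequence)


def counter_ions(sequence: str) -> tuple[str, int]:
    """(ion species, count) needed to neutralize the peptide's net charge."""
    q = net_charge(sequence)
    if q > 0:
        return "CL-", q
    if q < 0:
        return "NA+", -q
    return "none", 0


@dataclass
class MDRunRecipe:
    """The coarse-grained production protocol, recorded (not executed)."""

    production_ns: float = 500.0
    equilibration_ns: float = 50.0
    timestep_fs: float = 30.0
    temperature_K: float = 300.0
    thermostat: str = "velocity-rescale tau=1ps groups=membrane,peptide,solvent"
    barostat: str = "semi-isotropic Berendsen 1bar tau=8ps compressibility=4.5e-5bar^-1"
    insertion_softcore_lambda: float = 0.75
    n_popc: int = 90
    n_chol: int = 38
    n_water_beads: int = 1598
    flat_bottom_restraints: bool = False
    restraint_force_kj_mol_nm2: float = 1000.0
    restraint_nc3_nm: float = 2.0
    restraint_roh_nm: float = 1.5

    def __post_init__(self):
        for name in ("production_ns", "equilibration_ns", "timestep_fs",
                     "temperature_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.equilibration_ns >= self.production_ns:
            raise ValueError("equilibration must be shorter than production")


def emit_run_recipe(sequence: str, recipe: MDRunRecipe, outdir) -> dict:
    """Write a key = value parameter file and a JSON job manifest.

    Returns the manifest dict. Nothing is executed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = asdict(recipe)
    with open(outdir / "run_recipe.dat", "w") as fh:
        fh.write("; coarse-grained production run parameters (emitted, not run)\n")
        for key, value in params.items():
            fh.write(f"{key} = {value}\n")
    species, n_ions = counter_ions(sequence)
    manifest = {
        "sequence": sequence,
        "net_charge": net_charge(sequence),
        "counter_ion_species": species,
        "counter_ion_count": n_ions,
        "recipe_file": "run_recipe.dat",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def parse_run_recipe(path) -> MDRunRecipe:
    """Parse a key = value recipe file back into an MDRunRecipe."""
    fields = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("thermostat", "barostat"):
                fields[key] = value
            elif key == "flat_bottom_restraints":
                fields[key] = value == "True"
            elif key in ("n_popc", "n_chol", "n_water_beads"):
                fields[key] = int(value)
            else:
                fields[key] = float(value)
    return MDRunRecipe(**fields)
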