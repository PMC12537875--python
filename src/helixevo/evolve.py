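"""Genetic-algorithm engine for palindromic transmembrane peptide evolution.

Each generation the population is evaluated by a fitness backend (a callable
``sequence -> float`` to MAXIMIZE), the best performers form a parent pool,
elites pass unaltered into the next generation, and the remainder is filled
by single-point crossover plus per-residue mutation on the free half-genome
(palindromy is therefore preserved by construction).

A rerun mechanism accounts for noisy backends: if a sequence reoccurs in a
later generation it is evaluated again, and its recorded fitness is the
running mean of all its evaluations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from helixevo.seqcore import ALPHABET, PalindromicGenotype

SENTINEL_WORST = -math.inf


@dataclass
class GAConfig:
    """Genetic-algorithm run parameters.

    Defaults follow the converged production setting: population 128,
    selection pool of 16 parents, 2 iteration elites + 2 rerun elites, and a
    mutation probability of 1/20 per amino acid.
    """

    population_size: int = 128
    parents: int = 16
    iteration_elites: int = 2
    rerun_elites: int = 2
    mutation_rate: float = 1.0 / 20.0
    generations: int = 40
    seed: int = 0
    length: int = 20
    alphabet: str = ALPHABET

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 1 <= self.parents <= self.population_size:
            raise ValueError("parents must satisfy 1 <= parents <= population_size")
        if self.iteration_elites < 0 or self.rerun_elites < 0:
            raise ValueError("elite counts must be non-negative")
        if self.iteration_elites + self.rerun_elites >= self.population_size:
            raise ValueError("iteration_elites + rerun_elites must be < population_size")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.length % 2 != 0:
            raise ValueError("length must be even")

    @classmethod
    def from_json(cls, path) -> "GAConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class FitnessRecord:
    """Running fitness ledger for one sequence (supports rerun averaging)."""

    sequence: str
    evaluations: list = field(default_factory=list)

    @property
    def n_evals(self) -> int:
        return len(self.evaluations)

    @property
    def mean_fitness(self) -> float:
        if not self.evaluations:
            raise ValueError("no evaluations recorded")
        return float(np.mean(self.evaluations))

    def add(self, value: float) -> None:
        self.evaluations.append(float(value))


@dataclass
class GenerationLog:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_sequence: str
    diversity: float


def _rank_key(record: FitnessRecord):
    # fitness desc, n_evals desc, then lexicographic for full determinism
    return (-record.mean_fitness, -record.n_evals, record.sequence)


def init_population(config: GAConfig, rng: np.random.Generator | None = None):
    """Draw population_size genotypes uniformly over alphabet^(L/2)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    half = config.length // 2
    letters = np.array(list(config.alphabet))
    return [
        PalindromicGenotype(
            "".join(letters[rng.integers(0, len(letters), size=half)]), config.length
        )
        for _ in range(config.population_size)
    ]


def select_parents(ledger: dict, population, config: GAConfig):
    """The `parents` highest-mean-fitness distinct sequences of the population.

    If the population holds fewer distinct sequences than requested, the pool
    is all distinct sequences.
    """
    distinct = {g.expand() for g in population}
    records = sorted((ledger[s] for s in distinct), key=_rank_key)
    return [r.sequence for r in records[: config.parents]]


def recombine(parent_a: PalindromicGenotype, parent_b: PalindromicGenotype,
              config: GAConfig, rng: np.random.Generator) -> PalindromicGenotype:
    """Single-point crossover on the free half-genome, then per-residue mutation.

    The crossover point is uniform on 1..L/2-1 so both parents always
    contribute. Each free position is then independently replaced with a
    uniformly random alphabet symbol with probability ``mutation_rate``
    (self-replacement allowed).
    """
    if parent_a.length != parent_b.length:
        raise ValueError("parents must have equal length")
    half = parent_a.length // 2
    p = int(rng.integers(1, half)) if half > 1 else 1
    child = list(parent_a.free[:p] + parent_b.free[p:])
    letters = config.alphabet
    for i in range(half):
        if rng.random() < config.mutation_rate:
            child[i] = letters[int(rng.integers(0, len(letters)))]
    return PalindromicGenotype("".join(child), parent_a.length)


@dataclass
class GAState:
    config: GAConfig
    population: list
    ledger: dict
    rng: np.random.Generator
    generation: int = 0


def initialize(config: GAConfig) -> GAState:
    rng = np.random.default_rng(config.seed)
    return GAState(config=config, population=init_population(config, rng),
                   ledger={}, rng=rng)


def _evaluate(state: GAState, fitness_backend) -> None:
    """Evaluate every distinct sequence present in the current population.

    Sequences seen in earlier generations are evaluated again and their
    running mean updated (the rerun mechanism). Backend failures record the
    sentinel worst fitness instead of aborting the run.
    """
    distinct = sorted({g.expand() for g in state.population})
    for seq in distinct:
        try:
            value = float(fitness_backend(seq))
        except Exception:
            value = SENTINEL_WORST
        record = state.ledger.setdefault(seq, FitnessRecord(seq))
        record.add(value)


def _diversity(population) -> float:
    """Mean pairwise Hamming distance between free half-genomes."""
    frees = [g.free for g in population]
    n = len(frees)
    if n < 2:
        return 0.0
    arr = np.frombuffer("".join(frees).encode(), dtype=np.uint8).reshape(n, -1)
    total = 0
    for i in range(n - 1):
        total += int((arr[i + 1:] != arr[i]).sum())
    return total / (n * (n - 1) / 2)


def step_generation(state: GAState, fitness_backend) -> GenerationLog:
    """One GA generation: evaluate, log, select, recombine.

    Elites: the ``iteration_elites`` best sequences of the current generation
    and the ``rerun_elites`` best multiply-evaluated ledger sequences pass
    unchanged (duplicates collapsed); the remainder of the new population is
    produced by recombination of randomly drawn parents.
    """
    cfg = state.config
    _evaluate(state, fitness_backend)

    pop_records = sorted(
        (state.ledger[s] for s in {g.expand() for g in state.population}),
        key=_rank_key,
    )
    best = pop_records[0]
    mean_fit = float(np.mean([state.ledger[g.expand()].mean_fitness
                              for g in state.population]))
    log = GenerationLog(
        generation=state.generation,
        best_fitness=best.mean_fitness,
        mean_fitness=mean_fit,
        best_sequence=best.sequence,
        diversity=_diversity(state.population),
    )

    pool = select_parents(state.ledger, state.population, cfg)

    elite_seqs: list[str] = []
    for r in pop_records[: cfg.iteration_elites]:
        if r.sequence not in elite_seqs:
            elite_seqs.append(r.sequence)
    rerun_records = sorted(
        (r for r in state.ledger.values() if r.n_evals >= 2), key=_rank_key
    )
    for r in rerun_records[: cfg.rerun_elites]:
        if r.sequence not in elite_seqs:
            elite_seqs.append(r.sequence)

    half = cfg.length // 2
    new_pop = [PalindromicGenotype(s[:half], cfg.length) for s in elite_seqs]
    genos = {g.expand(): g for g in state.population}
    pool_genos = [genos[s] for s in pool]
    while len(new_pop) < cfg.population_size:
        ia = int(state.rng.integers(0, len(pool_genos)))
        ib = int(state.rng.integers(0, len(pool_genos)))
        if len(pool_genos) >= 2:
            while ib == ia:
                ib = int(state.rng.integers(0, len(pool_genos)))
        new_pop.append(recombine(pool_genos[ia], pool_genos[ib], cfg, state.rng))

    state.population = new_pop
    state.generation += 1
    return log


@dataclass
class EvolutionReport:
    config: GAConfig
    logs: list
    ledger: dict

    @property
    def best_record(self) -> FitnessRecord:
        return min(self.ledger.values(), key=_rank_key)

    def top_sequences(self, n: int) -> list[str]:
        """The n highest-fitness distinct sequences (for logo analysis)."""
        return [r.sequence for r in sorted(self.ledger.values(), key=_rank_key)[:n]]

    def write_log_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gen\tbest_fitness\tmean_fitness\tbest_seq\tdiversity\n")
            for log in self.logs:
                fh.write(f"{log.generation}\t{log.best_fitness:.10g}\t"
                         f"{log.mean_fitness:.10g}\t{log.best_sequence}\t"
                         f"{log.diversity:.10g}\n")

    def write_ledger_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tmean_fitness\tn_evals\n")
            for r in sorted(self.ledger.values(), key=_rank_key):
                fh.write(f"{r.sequence}\t{r.mean_fitness:.10g}\t{r.n_evals}\n")


def run(config: GAConfig, fitness_backend) -> EvolutionReport:
    """Run the GA for ``config.generations`` generations.

    Deterministic given (config.seed, backend): two runs with the same seed
    produce byte-identical logs.
    """
    state = initialize(config)
    logs = []
    for _ in range(config.generations):
        logs.append(step_generation(state, fitness_backend))
    if config.generations == 0:
        _evaluate(state, fitness_backend)
        pop_records = sorted(
            (state.ledger[s] for s in {g.expand() for g in state.population}),
            key=_rank_key,
        )
        logs.append(GenerationLog(
            generation=0,
            best_fitness=pop_records[0].mean_fitness,
            mean_fitness=float(np.mean([r.mean_fitness for r in pop_records])),
            best_sequence=pop_records[0].sequence,
            diversity=_diversity(state.population),
        ))
    return EvolutionReport(config=config, logs=logs, ledger=state.ledger)
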