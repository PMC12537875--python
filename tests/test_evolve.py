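"""GA engine: determinism, selection, operators, elitism, convergence."""

import numpy as np
import pytest

from helixevo import evolve
from helixevo.evolve import (
    FitnessRecord,
    GAConfig,
    GAState,
    init_population,
    recombine,
    run,
    select_parents,
    step_generation,
)
from helixevo.seqcore import ALPHABET, PalindromicGenotype
from helixevo.synthdata import additive_landscape, rugged_landscape


def length_fitness(seq):
    """Toy deterministic backend: favors lysines."""
    return seq.count("K")


class TestConfig:
    def test_validates_bounds(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=4, parents=8)
        with pytest.raises(ValueError):
            GAConfig(population_size=4, parents=2, iteration_elites=2,
                     rerun_elites=2)
        with pytest.raises(ValueError):
            GAConfig(mutation_rate=1.5)

    def test_json_round_trip(self, tmp_path):
        cfg = GAConfig(population_size=16, parents=4, seed=7)
        cfg.to_json(tmp_path / "ga.json")
        assert GAConfig.from_json(tmp_path / "ga.json") == cfg


class TestInitPopulation:
    def test_deterministic_under_seed(self):
        cfg = GAConfig(population_size=4, parents=2, iteration_elites=1,
                       rerun_elites=1, seed=1)
        assert init_population(cfg) == init_population(cfg)

    def test_sizes_and_lengths(self):
        cfg = GAConfig(population_size=128, parents=16, seed=0)
        pop = init_population(cfg)
        assert len(pop) == 128
        assert all(len(g.free) == 10 for g in pop)

    def test_symbol_frequencies_uniform(self):
        # 1e5 residue draws; each symbol count ~ Binomial(n, 1/20)
        cfg = GAConfig(population_size=10_000, parents=16, seed=3)
        pop = init_population(cfg)
        counts = np.zeros(20)
        for g in pop:
            for aa in g.free:
                counts[ALPHABET.index(aa)] += 1
        n = counts.sum()
        p = 1 / 20
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 4 * sigma)


class TestSelection:
    def _ledger(self, seq_fit):
        return {s: FitnessRecord(s, [f]) for s, f in seq_fit.items()}

    def test_top_n_by_fitness(self):
        seqs = ["A" * 20, "C" * 20, "D" * 20, "E" * 20]
        fits = dict(zip(seqs, [5, 3, 9, 1]))
        pop = [PalindromicGenotype(s[:10], 20) for s in seqs]
        cfg = GAConfig(population_size=4, parents=2, iteration_elites=1,
                       rerun_elites=0)
        pool = select_parents(self._ledger(fits), pop, cfg)
        assert pool == ["D" * 20, "A" * 20]

    def test_tie_break_deterministic(self):
        seqs = ["C" * 20, "A" * 20, "D" * 20]
        fits = {s: 1.0 for s in seqs}
        pop = [PalindromicGenotype(s[:10], 20) for s in seqs]
        cfg = GAConfig(population_size=4, parents=2, iteration_elites=1,
                       rerun_elites=0)
        pool = select_parents(self._ledger(fits), pop, cfg)
        assert pool == ["A" * 20, "C" * 20]  # lexicographic among equals

    def test_matches_brute_force_sort(self, rng):
        frees = {"".join(rng.choice(list(ALPHABET), size=10))
                 for _ in range(30)}
        seqs = [f + f[::-1] for f in frees]
        fits = {s: float(rng.normal()) for s in seqs}
        pop = [PalindromicGenotype(s[:10], 20) for s in seqs]
        cfg = GAConfig(population_size=64, parents=8)
        pool = select_parents({s: FitnessRecord(s, [f])
                               for s, f in fits.items()}, pop, cfg)
        expected = sorted(seqs, key=lambda s: (-fits[s], s))[:8]
        assert pool == expected

    def test_pool_shrinks_to_distinct(self):
        pop = [PalindromicGenotype("A" * 10, 20)] * 5
        cfg = GAConfig(population_size=8, parents=4)
        pool = select_parents({"A" * 20: FitnessRecord("A" * 20, [1.0])},
                              pop, cfg)
        assert pool == ["A" * 20]


class TestRecombine:
    def test_crossover_inherits_left_then_right(self):
        cfg = GAConfig(mutation_rate=0.0)
        a = PalindromicGenotype("A" * 10, 20)
        b = PalindromicGenotype("C" * 10, 20)
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(300):
            child = recombine(a, b, cfg, rng)
            p = child.free.rstrip("C").count("A")
            assert child.free == "A" * p + "C" * (10 - p)
            assert 1 <= p <= 9  # crossover point excludes the ends
            seen.add(p)
        assert seen == set(range(1, 10))

    def test_identical_parents_zero_mutation_is_identity(self):
        cfg = GAConfig(mutation_rate=0.0)
        a = PalindromicGenotype("DKKLLLLLKD", 20)
        rng = np.random.default_rng(1)
        assert recombine(a, a, cfg, rng) == a

    def test_mutation_count_binomial(self):
        # expected mutations/child = 10 * (1/20) = 0.5
        cfg = GAConfig(mutation_rate=1 / 20)
        a = PalindromicGenotype("A" * 10, 20)
        rng = np.random.default_rng(2)
        n_children = 20_000
        total = sum(
            sum(1 for aa in recombine(a, a, cfg, rng).free if aa != "A")
            for _ in range(n_children)
        )
        # observed-change rate is 19/400 per position (self-replacement allowed)
        p_change = (1 / 20) * (19 / 20)
        expected = n_children * 10 * p_change
        sigma = np.sqrt(n_children * 10 * p_change * (1 - p_change))
        assert abs(total - expected) < 4 * sigma

    def test_length_mismatch_rejected(self):
        cfg = GAConfig()
        with pytest.raises(ValueError, match="equal length"):
            recombine(PalindromicGenotype("A" * 10, 20),
                      PalindromicGenotype("A" * 5, 10), cfg,
                      np.random.default_rng(0))


class TestStepAndRun:
    def test_elites_pass_verbatim(self):
        cfg = GAConfig(population_size=16, parents=4, iteration_elites=2,
                       rerun_elites=0, generations=1, seed=0)
        state = evolve.initialize(cfg)
        step_generation(state, length_fitness)
        ranked = sorted(state.ledger.values(),
                        key=lambda r: (-r.mean_fitness, r.sequence))
        new_seqs = [g.expand() for g in state.population]
        assert ranked[0].sequence in new_seqs
        assert ranked[1].sequence in new_seqs

    def test_running_mean_after_rerun(self):
        values = iter([10.0, 20.0])
        record = FitnessRecord("X" * 20)
        record.add(next(values))
        record.add(next(values))
        assert record.mean_fitness == 15.0
        assert record.n_evals == 2

    def test_population_size_conserved(self):
        cfg = GAConfig(population_size=32, parents=8, generations=5, seed=4)
        state = evolve.initialize(cfg)
        for _ in range(5):
            step_generation(state, length_fitness)
            assert len(state.population) == 32

    def test_backend_failure_gets_sentinel(self):
        def flaky(seq):
            if seq[0] == "A":
                raise RuntimeError("boom")
            return 1.0

        cfg = GAConfig(population_size=8, parents=2, generations=1, seed=0)
        state = evolve.initialize(cfg)
        state.population[0] = PalindromicGenotype("A" * 10, 20)
        step_generation(state, flaky)
        assert state.ledger["A" * 20].mean_fitness == evolve.SENTINEL_WORST

    def test_run_reproducible_byte_identical(self, tmp_path):
        cfg = GAConfig(population_size=16, parents=4, generations=6, seed=9)
        paths = []
        for tag in ("a", "b"):
            report = run(cfg, length_fitness)
            p = tmp_path / f"log_{tag}.tsv"
            report.write_log_tsv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_best_fitness_non_decreasing_with_elitism(self):
        cfg = GAConfig(population_size=24, parents=6, iteration_elites=1,
                       rerun_elites=0, generations=12, seed=2)
        report = run(cfg, length_fitness)
        best = [log.best_fitness for log in report.logs]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_zero_generations_reports_initial_population(self):
        cfg = GAConfig(population_size=8, parents=2, generations=0, seed=1)
        report = run(cfg, length_fitness)
        assert len(report.logs) == 1
        assert report.logs[0].generation == 0

    def test_recovers_additive_optimum(self):
        fitness, opt_seq, opt_fit = additive_landscape(seed=17)
        cfg = GAConfig(population_size=128, parents=16, iteration_elites=2,
                       rerun_elites=2, generations=40, seed=17)
        report = run(cfg, fitness)
        assert report.best_record.sequence == opt_seq
        assert report.best_record.mean_fitness == pytest.approx(opt_fit)

    def test_larger_population_beats_smaller_on_rugged_landscape(self):
        # mirrors the population-size convergence comparison
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            fitness = rugged_landscape(seed=seed)
            final = {}
            for pop in (8, 128):
                cfg = GAConfig(population_size=pop, parents=max(2, pop // 8),
                               iteration_elites=1, rerun_elites=1,
                               generations=15, seed=seed)
                final[pop] = run(cfg, fitness).best_record.mean_fitness
            if final[128] >= final[8]:
                wins += 1
        assert wins >= 0.9 * n_seeds
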