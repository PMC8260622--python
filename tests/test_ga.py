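import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utrkit.ga import (
    GAConfig,
    GeneticDesigner,
    diverse_top_k,
    evolve,
    gc_dinucleotide_fitness,
    hamming,
    mutate,
    recombine,
)
from utrkit.io import UtrkitError

from conftest import random_member


@pytest.fixture(scope="module")
def seed_pool():
    rng = np.random.default_rng(42)
    return [random_member(rng) for _ in range(120)]


class TestHamming:
    def test_basic(self):
        assert hamming("AAAA", "AAAA") == 0
        assert hamming("AAAA", "TTTT") == 4
        with pytest.raises(UtrkitError):
            hamming("AA", "AAA")

    @given(st.integers(1, 60), st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_elementwise_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(rng.choice(list("ACGT"), n))
        assert hamming(a, b) == sum(1 for x, y in zip(a, b) if x != y)


class TestMutate:
    def test_rate_zero_is_identity(self, seed_pool):
        rng = np.random.default_rng(0)
        assert mutate(seed_pool[0], 0.0, rng) == seed_pool[0]

    def test_rate_one_changes_every_position(self):
        # all-T input: mutants contain no T, hence no ATG and no repair,
        # so every position must differ
        rng = np.random.default_rng(5)
        out = mutate("T" * 100, 1.0, rng)
        assert hamming(out, "T" * 100) == 100
        assert "T" not in out

    def test_empirical_rate_matches_binomial(self, seed_pool):
        rng = np.random.default_rng(11)
        seq = "T" * 100  # repair-free so substitutions are directly countable
        trials, rate = 100, 0.02
        total = sum(hamming(seq, mutate(seq, rate, rng)) for _ in range(trials))
        n = trials * len(seq)
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(total / n - rate) <= 3 * se

    def test_output_is_always_atg_free(self, seed_pool):
        rng = np.random.default_rng(2)
        for seq in seed_pool[:20]:
            out = mutate(seq, 0.1, rng)
            assert len(out) == len(seq) and "ATG" not in out


class TestRecombine:
    def test_self_cross_is_identity(self, seed_pool):
        rng = np.random.default_rng(0)
        assert recombine(seed_pool[0], seed_pool[0], rng) == seed_pool[0]

    def test_seeded_cut_reconstruction(self, seed_pool):
        a, b = seed_pool[0], seed_pool[1]
        seed = 9
        cut = int(np.random.default_rng(seed).integers(1, len(a)))
        child = recombine(a, b, np.random.default_rng(seed))
        if "ATG" not in a[:cut] + b[cut:]:  # repair-free reconstruction
            assert child == a[:cut] + b[cut:]
        assert len(child) == len(a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(UtrkitError):
            recombine("AAAA", "AAAAA", np.random.default_rng(0))


class TestDiverseTopK:
    def test_identical_sequences_collapse(self):
        cands = [("AAAA", 1.0), ("AAAA", 1.0), ("AAAA", 1.0)]
        assert diverse_top_k(cands, k=5, min_dist=1) == [("AAAA", 1.0)]

    def test_min_dist_zero_is_plain_top_k(self):
        cands = [(s, f) for s, f in zip(["AAAA", "AAAT", "AATT", "ATTT"],
                                        [1.0, 4.0, 3.0, 2.0])]
        out = diverse_top_k(cands, k=2, min_dist=0)
        assert out == [("AAAT", 4.0), ("AATT", 3.0)]

    def test_matches_brute_force_greedy_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            length = int(rng.integers(4, 8))
            cands = [
                ("".join(rng.choice(list("ACGT"), length)),
                 float(rng.integers(0, 5)))
                for _ in range(n)
            ]
            k = int(rng.integers(1, 5))
            d = int(rng.integers(0, length + 1))
            # oracle: same greedy, written independently over sorted tuples
            ordered, seen = [], set()
            for s, f in sorted(cands, key=lambda c: (-c[1], c[0])):
                if s not in seen:
                    seen.add(s)
                    ordered.append((s, f))
            expected = []
            for s, f in ordered:
                if len(expected) == k:
                    break
                if all(sum(x != y for x, y in zip(s, t)) >= d
                       for t, _ in expected):
                    expected.append((s, f))
            assert diverse_top_k(cands, k=k, min_dist=d) == expected


class TestEvolve:
    def test_reaches_near_optimal_on_gc_toy(self, seed_pool):
        result = evolve(seed_pool, gc_dinucleotide_fitness, GAConfig(seed=1))
        max_fit = 99.0  # any all-G/C 100-mer
        assert result.best_fitness_trajectory[-1] >= 0.9 * max_fit
        traj = result.best_fitness_trajectory
        assert len(traj) == 51  # initial + 50 generations
        assert all(b >= a for a, b in zip(traj, traj[1:]))  # elitism
        assert result.kept
        for seq, fit, gen in result.kept:
            assert len(seq) == 100 and "ATG" not in seq
            assert fit >= result.initial_best + 0.05
            assert 0 <= gen <= 50
        kept_seqs = [s for s, _, _ in result.kept]
        for i, a in enumerate(kept_seqs):
            for b in kept_seqs[i + 1:]:
                assert hamming(a, b) >= 5

    def test_constant_fitness_keeps_nothing(self, seed_pool):
        result = evolve(seed_pool, lambda s: 3.0,
                        GAConfig(seed=0, max_generations=3))
        assert result.kept == []

    def test_deterministic_under_seed(self, seed_pool):
        cfg = GAConfig(seed=7, max_generations=10)
        r1 = evolve(seed_pool, gc_dinucleotide_fitness, cfg)
        r2 = evolve(seed_pool, gc_dinucleotide_fitness, cfg)
        assert r1.kept == r2.kept
        assert r1.best_fitness_trajectory == r2.best_fitness_trajectory

    def test_small_seed_pool_rejected(self, seed_pool):
        with pytest.raises(UtrkitError, match="seed pool"):
            evolve(seed_pool[:10], gc_dinucleotide_fitness, GAConfig(seed=0))

    def test_fitness_failure_reports_generation(self, seed_pool):
        def broken(seq):
            raise ValueError("boom")

        with pytest.raises(UtrkitError, match="generation"):
            evolve(seed_pool, broken, GAConfig(seed=0, max_generations=1))

    def test_two_generation_variant_mode_stays_near_seeds(self, seed_pool):
        """Short runs produce variants within a few mutations of their seeds.

        Emulates generating a test set of lightly evolved variants: with 2
        generations the evaluated sequences should sit statistically close
        to the seed pool (about L * mutation_rate substitutions per
        generation plus crossover between seeds).
        """
        cfg = GAConfig(seed=4, max_generations=2, min_improvement=-1e9,
                       crossover_rate=0.0)
        result = evolve(seed_pool, gc_dinucleotide_fitness, cfg)
        assert result.kept  # relaxed improvement keeps designs
        dists = [
            min(hamming(seq, s) for s in seed_pool)
            for seq, _, _ in result.kept
        ]
        # each generation adds Binomial(100, 0.02) substitutions, so kept
        # variants should carry ~4 and far fewer than the ~75 expected
        # between unrelated sequences
        assert np.mean(dists) <= 12

    def test_estimator_wrapper_exposes_results(self, seed_pool):
        designer = GeneticDesigner(
            fitness=gc_dinucleotide_fitness, max_generations=5, random_state=2
        )
        designer.fit(seed_pool)
        assert designer.best_fitness_trajectory_[0] == designer.initial_best_
        assert designer.transform() == [s for s, _, _ in designer.kept_]
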