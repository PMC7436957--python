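"""Genetic-algorithm operators and search behaviour."""

import numpy as np
import pytest
from scipy import stats

from mininfer.community import CommunityModelConfig
from mininfer.ga import (Chromosome, GAConfig, Gene, Solution, _cluster_by_mse,
                         _splice, crossover, decode, evolve, fitness,
                         infer_solution_set, init_population, mutate)
from mininfer.ga import _evaluate_population
from mininfer.glv import GLVParameters, reconstruct_profile
from mininfer.metrics import bcd_overall


def make_chromosome(L, flat_positions, values, growth=None):
    flat = np.asarray(flat_positions)
    return Chromosome(L, flat // L, flat % L, np.asarray(values, float),
                      np.zeros(L) if growth is None else np.asarray(growth))


# ---------------------------------------------------------------------------
# encoding

def test_decode_empty_and_single_gene():
    empty = Chromosome(2, np.array([], dtype=int), np.array([], dtype=int),
                       np.array([]), np.zeros(2))
    params = decode(empty, 2)
    assert np.all(params.A == 0) and np.all(params.r == 0)

    single = Chromosome.from_genes([Gene(0, 1, 0.4)], np.zeros(2), 2)
    params = decode(single, 2)
    assert params.A[0, 1] == 0.4
    assert np.count_nonzero(params.A) == 1


def test_decode_encode_roundtrip(rng):
    L = 4
    A = np.zeros((L, L))
    flat = rng.choice(L * L, size=6, replace=False)
    A[flat // L, flat % L] = rng.normal(0, 1, 6)
    r = rng.uniform(0, 1, L)
    rows, cols = np.nonzero(A)
    chrom = Chromosome(L, rows, cols, A[rows, cols], r)
    params = decode(chrom, L)
    np.testing.assert_array_equal(params.A, A)
    np.testing.assert_array_equal(params.r, r)


def test_decode_out_of_range_position():
    chrom = make_chromosome(4, [14], [1.0])
    with pytest.raises(ValueError):
        decode(chrom, 3)


def test_duplicate_positions_rejected():
    with pytest.raises(ValueError):
        make_chromosome(3, [1, 1], [0.5, 0.7])


def test_gene_count_config_error():
    cfg = GAConfig(sparsity_prior=0.1)
    with pytest.raises(ValueError):
        cfg.n_genes(2)  # round(0.1 * 4) = 0 genes


# ---------------------------------------------------------------------------
# initial population

def test_init_population_size_and_gene_count(rng):
    cfg = GAConfig(population_size=13, sparsity_prior=0.5)
    pop = init_population(4, cfg, rng)
    assert len(pop) == 13
    assert all(c.n_genes == 8 for c in pop)


def test_init_population_full_sparsity_covers_all_positions(rng):
    cfg = GAConfig(population_size=3, sparsity_prior=1.0)
    for c in init_population(3, cfg, rng):
        assert sorted((c.rows * 3 + c.cols).tolist()) == list(range(9))


def test_init_population_positions_uniform():
    cfg = GAConfig(population_size=200, sparsity_prior=0.5)
    rng = np.random.default_rng(99)
    counts = np.zeros(9)
    for _ in range(10):
        for c in init_population(3, cfg, rng):
            counts[c.rows * 3 + c.cols] += 1
    assert stats.chisquare(counts).pvalue > 0.01


# ---------------------------------------------------------------------------
# mutation and crossover

def test_mutation_rate_zero_is_identity(rng):
    cfg = GAConfig(mutation_rate=0.0)
    chrom = make_chromosome(3, [0, 4, 7], [0.1, -0.2, 0.3], [0.5, 0.5, 0.5])
    out = mutate(chrom, cfg, rng)
    np.testing.assert_array_equal(out.values, chrom.values)
    np.testing.assert_array_equal(out.rows, chrom.rows)
    np.testing.assert_array_equal(out.growth, chrom.growth)


def test_mutation_preserves_gene_count_and_uniqueness(rng):
    cfg = GAConfig(mutation_rate=0.8, relocation_rate=0.5)
    chrom = make_chromosome(3, [0, 4, 7, 2], [0.1, -0.2, 0.3, 1.0])
    for _ in range(200):
        chrom = mutate(chrom, cfg, rng)
        flat = chrom.rows * 3 + chrom.cols
        assert len(np.unique(flat)) == chrom.n_genes == 4


def test_relocation_reaches_every_position():
    """With certain relocation, all 9 cells of a 3x3 grid are visited."""
    cfg = GAConfig(mutation_rate=1.0, relocation_rate=1.0)
    rng = np.random.default_rng(4)
    chrom = make_chromosome(3, [0, 1], [0.1, 0.2])
    seen = set()
    for _ in range(300):
        chrom = mutate(chrom, cfg, rng)
        seen.update((chrom.rows * 3 + chrom.cols).tolist())
    assert seen == set(range(9))


def test_splice_boundary_cuts(rng):
    p1 = make_chromosome(3, [0, 1, 2], [1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
    p2 = make_chromosome(3, [4, 5, 6], [4.0, 5.0, 6.0], [0.9, 0.9, 0.9])
    child_all_p1 = _splice(p1, p2, k=3, kg=3, rng=rng)
    np.testing.assert_array_equal(child_all_p1.values, p1.values)
    np.testing.assert_array_equal(child_all_p1.rows, p1.rows)
    child_all_p2 = _splice(p1, p2, k=0, kg=0, rng=rng)
    np.testing.assert_array_equal(child_all_p2.values, p2.values)
    np.testing.assert_array_equal(child_all_p2.growth, p2.growth)


def test_crossover_never_duplicates_positions():
    rng = np.random.default_rng(8)
    L, k = 4, 8
    for _ in range(10_000):
        f1 = rng.choice(L * L, size=k, replace=False)
        f2 = rng.choice(L * L, size=k, replace=False)
        p1 = make_chromosome(L, f1, rng.normal(size=k))
        p2 = make_chromosome(L, f2, rng.normal(size=k))
        child = crossover(p1, p2, rng)
        flat = child.rows * L + child.cols
        assert len(np.unique(flat)) == k


def test_crossover_requires_equal_gene_counts(rng):
    p1 = make_chromosome(3, [0, 1], [1.0, 2.0])
    p2 = make_chromosome(3, [3, 4, 5], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        crossover(p1, p2, rng)


# ---------------------------------------------------------------------------
# fitness

def test_fitness_decomposition_and_lambda(two_otu_profile, rng):
    profile, truth = two_otu_profile
    ref = rng.normal(0, 1, 500)
    chrom = make_chromosome(2, [1, 2], [0.5, -0.3], [0.2, 0.2])
    for lam in (0.0, 1.0, 2.5):
        cfg = GAConfig(lambda_ks=lam)
        sol = fitness(chrom, profile, cfg, ref)
        assert sol.fitness == pytest.approx(sol.f1 + lam * sol.f2)
        assert sol.accuracy == pytest.approx((1 - sol.f1) * 100)
    sol0 = fitness(chrom, profile, GAConfig(lambda_ks=0.0), ref)
    assert sol0.fitness == pytest.approx(sol0.f1)


def test_fitness_zero_bcd_for_true_parameters(two_otu_profile, rng):
    profile, truth = two_otu_profile
    rows, cols = np.nonzero(truth.A)
    chrom = Chromosome(2, rows, cols, truth.A[rows, cols], truth.r)
    sol = fitness(chrom, profile, GAConfig(), rng.normal(0, 1, 500))
    assert sol.f1 == pytest.approx(0.0, abs=1e-12)
    assert sol.accuracy == pytest.approx(100.0)


def test_fitness_all_zeroed_gets_maximal_ks_penalty(two_otu_profile, rng):
    profile, _ = two_otu_profile
    chrom = make_chromosome(2, [1, 2], [1e-6, -1e-7], [0.0, 0.0])
    sol = fitness(chrom, profile, GAConfig(zero_threshold=1e-3),
                  rng.normal(0, 1, 500))
    assert sol.f2 == 1.0
    assert np.all(sol.params.A == 0.0)


def test_vectorised_evaluation_matches_scalar(two_otu_profile, rng):
    profile, _ = two_otu_profile
    cfg = GAConfig(population_size=8, model_prior=CommunityModelConfig(n=2))
    pop = init_population(2, cfg, rng)
    ref = np.sort(rng.normal(0, 1, 500))
    f1, f2, fit = _evaluate_population(pop, profile.values, cfg, ref)
    for i, c in enumerate(pop):
        sol = fitness(c, profile, cfg, ref)
        assert f1[i] == pytest.approx(sol.f1, abs=1e-12)
        assert f2[i] == pytest.approx(sol.f2, abs=1e-12)
        assert fit[i] == pytest.approx(sol.fitness, abs=1e-12)


# ---------------------------------------------------------------------------
# evolution

def test_elitism_makes_best_fitness_monotone(two_otu_profile):
    profile, _ = two_otu_profile
    cfg = GAConfig(population_size=30, generations=40, seed=5,
                   model_prior=CommunityModelConfig(n=2))
    sol = evolve(profile, cfg)
    traj = np.array(sol.trajectory)
    assert np.all(np.diff(traj) <= 0.0)
    assert sol.fitness == pytest.approx(traj[-1])


def test_evolve_is_deterministic(two_otu_profile):
    profile, _ = two_otu_profile
    cfg = GAConfig(population_size=25, generations=20, seed=21,
                   model_prior=CommunityModelConfig(n=2))
    a = evolve(profile, cfg)
    b = evolve(profile, cfg)
    np.testing.assert_array_equal(a.params.A, b.params.A)
    np.testing.assert_array_equal(a.params.r, b.params.r)
    assert a.fitness == b.fitness and a.trajectory == b.trajectory


def grid_oracle_min_bcd(profile, r, grid):
    """Exhaustive search of the two off-diagonal interaction values."""
    best = np.inf
    for a01 in grid:
        for a10 in grid:
            params = GLVParameters(A=np.array([[0.0, a01], [a10, 0.0]]), r=r)
            recon = reconstruct_profile(profile.values[:, 0], params,
                                        profile.n_times)
            best = min(best, bcd_overall(profile, recon))
    return best


def test_two_otu_search_matches_grid_oracle(two_otu_profile):
    profile, truth = two_otu_profile
    grid = np.round(np.arange(-1.0, 1.01, 0.1), 10)
    oracle = grid_oracle_min_bcd(profile, truth.r, grid)
    cfg = GAConfig(population_size=60, generations=120, seed=17,
                   lambda_ks=0.0, allow_self_interactions=False,
                   fixed_growth=truth.r, zero_threshold=0.0,
                   model_prior=CommunityModelConfig(n=2))
    sol = evolve(profile, cfg)
    assert sol.f1 <= oracle + 0.02


def test_sign_recovery_beats_chance_on_three_otus():
    """Median sign agreement of inferred vs true interactions exceeds chance.

    Agreement is evaluated where both the truth and the inferred network
    carry a nonzero coefficient; the nominal interaction distribution is
    symmetric about zero, so chance level is 1/2.
    """
    agreements = []
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        model_cfg = CommunityModelConfig(n=3, p=0.5)
        from mininfer.simulate import generate_dataset

        profile, truth = generate_dataset(model_cfg, T=50, rng=rng)
        if np.count_nonzero(truth.A) == 0:
            continue
        cfg = GAConfig(population_size=60, generations=100, seed=rep,
                       model_prior=model_cfg)
        sol = evolve(profile, cfg)
        both = (truth.A != 0) & (sol.params.A != 0)
        if both.sum() == 0:
            continue
        agreements.append(np.mean(np.sign(sol.params.A[both])
                                  == np.sign(truth.A[both])))
    assert len(agreements) >= 15
    assert np.median(agreements) > 0.5


# ---------------------------------------------------------------------------
# multi-restart solution sets

def _solution_with(A, fitness_value):
    params = GLVParameters(A=A, r=np.zeros(A.shape[0]))
    f1 = fitness_value
    return Solution(params=params, f1=f1, f2=0.0, fitness=f1,
                    accuracy=(1 - f1) * 100)


def test_single_restart_gives_single_cluster(small_dataset, tiny_ga_config):
    profile, _, _ = small_dataset
    from dataclasses import replace

    sol_set = infer_solution_set(profile, replace(tiny_ga_config, restarts=1))
    assert len(sol_set.solutions) == 1
    assert sol_set.clusters == [[0]]


def test_single_linkage_clustering_oracle():
    base = np.zeros((2, 2))
    near = base.copy()
    near[0, 1] = 0.1          # MSE to base = 0.0025
    far = base.copy()
    far[0, 1] = 2.0           # MSE to base = 1.0
    sols = [_solution_with(base, 0.1), _solution_with(near, 0.2),
            _solution_with(far, 0.3)]
    clusters = _cluster_by_mse(sols, delta_distinct=0.1)
    assert sorted(map(sorted, clusters)) == [[0, 1], [2]]

    # chaining: a-b close, b-c close, a-c far -> one single-linkage cluster
    mid = base.copy()
    mid[0, 1] = 0.6
    end = base.copy()
    end[0, 1] = 1.2
    chain = [_solution_with(base, 0.1), _solution_with(mid, 0.2),
             _solution_with(end, 0.3)]
    assert len(_cluster_by_mse(chain, delta_distinct=0.1)) == 1


def test_identical_solutions_form_one_cluster():
    A = np.array([[0.0, 0.5], [0.0, 0.0]])
    sols = [_solution_with(A, 0.1) for _ in range(4)]
    assert len(_cluster_by_mse(sols, delta_distinct=0.1)) == 1


def test_infer_solution_set_is_deterministic(small_dataset, tiny_ga_config):
    profile, _, _ = small_dataset
    a = infer_solution_set(profile, tiny_ga_config)
    b = infer_solution_set(profile, tiny_ga_config)
    assert len(a.solutions) == len(b.solutions)
    for sa, sb in zip(a.solutions, b.solutions):
        np.testing.assert_array_equal(sa.params.A, sb.params.A)
        assert sa.fitness == sb.fitness
    assert a.clusters == b.clusters


def test_retention_margin_keeps_near_best_only(small_dataset, tiny_ga_config):
    profile, _, _ = small_dataset
    sol_set = infer_solution_set(profile, tiny_ga_config)
    best = max(s.accuracy for s in sol_set.solutions)
    assert all(s.accuracy >= best - tiny_ga_config.retention_margin
               for s in sol_set.solutions)
    assert sol_set.solutions[0].fitness == min(s.fitness
                                               for s in sol_set.solutions)
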