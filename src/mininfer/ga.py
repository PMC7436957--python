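"""Genetic-algorithm inference of sparse interaction networks.

A candidate interaction matrix is encoded as a chromosome: a fixed-size
list of genes, each gene one (row, col, value) entry of the matrix, plus
a vector of candidate growth rates.  Because interaction networks are
expected to be sparse, a chromosome carries only
``round(sparsity_prior * L**2)`` genes rather than all L**2 entries.

Fitness is two-fold and minimised:

    fitness = f1 + lambda_ks * f2

where f1 is the mean Bray-Curtis dissimilarity between the observed
profile and the profile reconstructed from the candidate parameters, and
f2 is the Kolmogorov-Smirnov statistic between the candidate's nonzero
interaction strengths and a reference sample drawn from the community
dynamics model.  f2 penalises candidates that are statistically
implausible under the community prior; both terms live in [0, 1].

Near-zero interaction values are zeroed before scoring to keep candidate
networks sparse.  Mutation perturbs gene values and, with some
probability, relocates a gene to a fresh random matrix position (the
Monte Carlo gene introduction, which lets rare OTUs enter the network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .community import CommunityModelConfig, sample_reference_values
from .glv import GLVParameters, glv_step_batch, reconstruct_profile
from .metrics import bcd_overall, ks_statistic_presorted, matrix_mse
from .profiles import AbundanceProfile

__all__ = [
    "Gene",
    "Chromosome",
    "GAConfig",
    "Solution",
    "SolutionSet",
    "decode",
    "init_population",
    "mutate",
    "crossover",
    "fitness",
    "evolve",
    "infer_solution_set",
]


@dataclass
class Gene:
    """One interaction-matrix entry: value at (row, col)."""

    row: int
    col: int
    value: float


@dataclass
class Chromosome:
    """Sparse encoding of candidate gLV parameters.

    Gene positions are stored as parallel (rows, cols, values) arrays;
    positions are unique within a chromosome.  ``growth`` holds the
    candidate intrinsic growth rates.
    """

    n_otus: int
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    growth: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=float)
        self.growth = np.asarray(self.growth, dtype=float)
        if not (len(self.rows) == len(self.cols) == len(self.values)):
            raise ValueError("rows, cols, values must have equal length")
        flat = self.rows * self.n_otus + self.cols
        if len(np.unique(flat)) != len(flat):
            raise ValueError("duplicate gene positions")

    @property
    def n_genes(self) -> int:
        return len(self.values)

    @property
    def genes(self) -> list:
        return [Gene(int(i), int(j), float(v))
                for i, j, v in zip(self.rows, self.cols, self.values)]

    @classmethod
    def from_genes(cls, genes, growth, n_otus: int) -> "Chromosome":
        rows = [g.row for g in genes]
        cols = [g.col for g in genes]
        vals = [g.value for g in genes]
        return cls(n_otus, np.array(rows, dtype=np.intp),
                   np.array(cols, dtype=np.intp),
                   np.array(vals, dtype=float), np.asarray(growth, dtype=float))

    def copy(self) -> "Chromosome":
        return Chromosome(self.n_otus, self.rows.copy(), self.cols.copy(),
                          self.values.copy(), self.growth.copy())


@dataclass
class GAConfig:
    """Knobs of the genetic algorithm and its community-model prior.

    sparsity_prior is the assumed fraction of nonzero interactions; a
    chromosome carries round(sparsity_prior * L**2) genes.  lambda_ks
    weights the community-model (KS) penalty against the reconstruction
    term.  retention_margin (percentage points of reconstruction
    accuracy) and delta_distinct (an MSE threshold between interaction
    matrices) govern which multi-restart solutions are kept and how they
    are clustered into distinct networks.
    """

    sparsity_prior: float = 0.5
    population_size: int = 100
    generations: int = 500
    mutation_rate: float = 0.1
    relocation_rate: float = 0.2
    mutation_scale: float = 0.1
    lambda_ks: float = 1.0
    zero_threshold: float = 1e-3
    tournament_size: int = 3
    elite_count: int = 1
    restarts: int = 10
    seed: int = 0
    model_prior: CommunityModelConfig = field(default_factory=CommunityModelConfig)
    ks_reference_size: int = 1000
    early_stop_window: int = 100
    early_stop_tol: float = 1e-6
    retention_margin: float = 2.0
    delta_distinct: float = 0.1
    allow_self_interactions: bool = True
    fixed_growth: Optional[np.ndarray] = None
    dt: float = 1.0

    def __post_init__(self):
        for name in ("mutation_rate", "relocation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.sparsity_prior <= 1.0):
            raise ValueError("sparsity_prior must be in (0, 1]")
        for name in ("population_size", "generations", "tournament_size",
                     "restarts", "ks_reference_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.elite_count < 0 or self.elite_count > self.population_size:
            raise ValueError("elite_count must be in [0, population_size]")
        if self.lambda_ks < 0 or self.zero_threshold < 0:
            raise ValueError("lambda_ks and zero_threshold must be nonnegative")
        if self.fixed_growth is not None:
            self.fixed_growth = np.asarray(self.fixed_growth, dtype=float)

    def n_genes(self, L: int) -> int:
        k = int(round(self.sparsity_prior * L * L))
        if k < 1:
            raise ValueError(
                f"sparsity_prior {self.sparsity_prior} gives no genes for L={L}")
        n_allowed = L * L if self.allow_self_interactions else L * L - L
        if k > n_allowed:
            raise ValueError(f"{k} genes exceed the {n_allowed} allowed positions")
        return k


@dataclass
class Solution:
    """One inferred network with its fitness decomposition.

    f1 is the mean Bray-Curtis dissimilarity of the reconstruction, f2
    the KS statistic against the community-model prior;
    fitness = f1 + lambda_ks * f2 and accuracy = (1 - f1) * 100%.
    """

    params: GLVParameters
    f1: float
    f2: float
    fitness: float
    accuracy: float
    seed: int = 0
    trajectory: Optional[list] = field(default=None, repr=False)


@dataclass
class SolutionSet:
    """Retained solutions from multi-restart inference, best first.

    ``clusters`` partitions solution indices by single-linkage on
    pairwise interaction-matrix MSE: solutions in different clusters are
    distinct networks that nevertheless reconstruct the observed profile
    almost equally well.
    """

    solutions: list
    clusters: list

    @property
    def best(self) -> Solution:
        return self.solutions[0]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_representatives(self) -> list:
        """Best (lowest-fitness) solution of each cluster."""
        reps = []
        for members in self.clusters:
            reps.append(min((self.solutions[i] for i in members),
                            key=lambda s: s.fitness))
        return reps

    def pairwise_mse(self) -> np.ndarray:
        n = len(self.solutions)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = matrix_mse(self.solutions[i].params.A,
                                               self.solutions[j].params.A)
        return D

    def max_pairwise_mse(self) -> float:
        if len(self.solutions) < 2:
            return 0.0
        return float(self.pairwise_mse().max())


# ---------------------------------------------------------------------------
# chromosome operations

def _allowed_flat_positions(L: int, allow_self: bool) -> np.ndarray:
    flat = np.arange(L * L)
    if allow_self:
        return flat
    return flat[flat // L != flat % L]


def decode(chromosome: Chromosome, L: int) -> GLVParameters:
    """Expand a chromosome into a dense (A, r) parameter set."""
    if np.any(chromosome.rows >= L) or np.any(chromosome.cols >= L):
        raise ValueError("gene position out of range for L OTUs")
    A = np.zeros((L, L))
    A[chromosome.rows, chromosome.cols] = chromosome.values
    return GLVParameters(A=A, r=chromosome.growth.copy())


def _initial_growth(L: int, config: GAConfig, rng) -> np.ndarray:
    if config.fixed_growth is not None:
        return config.fixed_growth.copy()
    return rng.uniform(0.0, 1.0, size=L)


def init_population(L: int, config: GAConfig, rng) -> list:
    """Random initial population.

    Gene positions are uniform over all allowed (i, j) pairs without
    replacement within a chromosome; values are drawn from the nominal
    interaction distribution Normal(0, sigma_prior^2); growth genes are
    Uniform(0, 1) unless growth rates are fixed.
    """
    k = config.n_genes(L)
    allowed = _allowed_flat_positions(L, config.allow_self_interactions)
    population = []
    for _ in range(config.population_size):
        flat = rng.choice(allowed, size=k, replace=False)
        values = rng.normal(0.0, config.model_prior.sigma, size=k)
        population.append(Chromosome(L, flat // L, flat % L, values,
                                     _initial_growth(L, config, rng)))
    return population


def mutate(chromosome: Chromosome, config: GAConfig, rng) -> Chromosome:
    """Mutate gene values and positions.

    Each gene is hit independently with probability mutation_rate; a hit
    gene is relocated to an unused random position with probability
    relocation_rate, otherwise its value is perturbed by
    Normal(0, mutation_scale^2).  Growth genes are perturbed likewise.
    Gene count and position uniqueness are preserved.
    """
    L = chromosome.n_otus
    new = chromosome.copy()
    k = new.n_genes
    hit = rng.random(k) < config.mutation_rate
    relocate = hit & (rng.random(k) < config.relocation_rate)
    perturb = hit & ~relocate
    if perturb.any():
        new.values[perturb] += rng.normal(0.0, config.mutation_scale,
                                          size=int(perturb.sum()))
    if relocate.any():
        allowed = _allowed_flat_positions(L, config.allow_self_interactions)
        used = set((new.rows * L + new.cols).tolist())
        for idx in np.flatnonzero(relocate):
            old = int(new.rows[idx] * L + new.cols[idx])
            free = np.array(sorted(set(allowed.tolist()) - used))
            if free.size == 0:
                continue
            target = int(rng.choice(free))
            used.discard(old)
            used.add(target)
            new.rows[idx] = target // L
            new.cols[idx] = target % L
    if config.fixed_growth is None:
        hit_g = rng.random(L) < config.mutation_rate
        if hit_g.any():
            new.growth[hit_g] += rng.normal(0.0, config.mutation_scale,
                                            size=int(hit_g.sum()))
    return new


def _splice(parent1: Chromosome, parent2: Chromosome, k: int, kg: int,
            rng, allow_self: bool = True) -> Chromosome:
    """Single-point crossover at gene cut k and growth cut kg.

    Duplicate positions arising from the splice keep their first
    occurrence; the later duplicates are redrawn uniformly from unused
    positions (keeping their values).
    """
    L = parent1.n_otus
    rows = np.concatenate([parent1.rows[:k], parent2.rows[k:]])
    cols = np.concatenate([parent1.cols[:k], parent2.cols[k:]])
    values = np.concatenate([parent1.values[:k], parent2.values[k:]])
    flat = rows * L + cols
    seen = set()
    dup_idx = []
    for i, f in enumerate(flat.tolist()):
        if f in seen:
            dup_idx.append(i)
        else:
            seen.add(f)
    if dup_idx:
        allowed = set(_allowed_flat_positions(L, allow_self).tolist())
        for i in dup_idx:
            free = np.array(sorted(allowed - seen))
            target = int(rng.choice(free))
            seen.add(target)
            rows[i] = target // L
            cols[i] = target % L
    growth = np.concatenate([parent1.growth[:kg], parent2.growth[kg:]])
    return Chromosome(L, rows, cols, values, growth)


def crossover(parent1: Chromosome, parent2: Chromosome, rng,
              allow_self: bool = True) -> Chromosome:
    """Single-point crossover with an independent cut for growth genes."""
    if parent1.n_genes != parent2.n_genes:
        raise ValueError("parents must have equal gene counts")
    k = int(rng.integers(0, parent1.n_genes + 1))
    kg = int(rng.integers(0, parent1.n_otus + 1))
    return _splice(parent1, parent2, k, kg, rng, allow_self=allow_self)


# ---------------------------------------------------------------------------
# fitness

def _thresholded(chromosome: Chromosome, zero_threshold: float) -> GLVParameters:
    params = decode(chromosome, chromosome.n_otus)
    params.A[np.abs(params.A) < zero_threshold] = 0.0
    return params


def fitness(chromosome: Chromosome, profile: AbundanceProfile,
            config: GAConfig, reference_sample: np.ndarray) -> Solution:
    """Score one chromosome against an observed profile.

    Near-zero interaction values are zeroed first to satisfy sparseness;
    f1 is the mean BCD of the reconstruction from the profile's initial
    composition, f2 the KS statistic of the nonzero interaction values
    against the community-model reference sample (1, the maximal
    penalty, if no nonzero value survives the zeroing).
    """
    params = _thresholded(chromosome, config.zero_threshold)
    recon = reconstruct_profile(profile.values[:, 0], params, profile.n_times,
                                dt=config.dt)
    f1 = bcd_overall(profile, recon)
    nonzero = params.A[params.A != 0.0]
    if nonzero.size == 0:
        f2 = 1.0
    else:
        f2 = ks_statistic_presorted(nonzero, np.sort(np.asarray(reference_sample,
                                                                dtype=float)))
    fit = f1 + config.lambda_ks * f2
    return Solution(params=params, f1=f1, f2=f2, fitness=fit,
                    accuracy=(1.0 - f1) * 100.0, seed=config.seed)


def _evaluate_population(population, profile_values: np.ndarray,
                         config: GAConfig, sorted_reference: np.ndarray):
    """Vectorised fitness of the whole population.

    Reconstruction is propagated for all candidates simultaneously
    (batched gLV steps); returns (f1, f2, fitness) arrays.
    """
    P = len(population)
    L, T = profile_values.shape
    A = np.zeros((P, L, L))
    R = np.empty((P, L))
    for i, c in enumerate(population):
        vals = np.where(np.abs(c.values) >= config.zero_threshold, c.values, 0.0)
        A[i, c.rows, c.cols] = vals
        R[i] = c.growth
    X = np.tile(profile_values[:, 0], (P, 1))
    bcd_sum = np.zeros(P)
    for k in range(1, T):
        X = glv_step_batch(X, A, R, dt=config.dt)
        obs = profile_values[:, k]
        denom = X.sum(axis=1) + obs.sum()
        num = np.abs(X - obs).sum(axis=1)
        with np.errstate(invalid="ignore"):
            bcd_sum += np.where(denom > 0, num / denom, 0.0)
    f1 = bcd_sum / T
    f2 = np.empty(P)
    for i in range(P):
        nonzero = A[i][A[i] != 0.0]
        f2[i] = 1.0 if nonzero.size == 0 else ks_statistic_presorted(
            nonzero, sorted_reference)
    return f1, f2, f1 + config.lambda_ks * f2


def _tournament(fitness_values: np.ndarray, size: int, rng) -> int:
    contenders = rng.integers(0, len(fitness_values), size=size)
    return int(contenders[np.argmin(fitness_values[contenders])])


def evolve(profile: AbundanceProfile, config: GAConfig,
           rng: Optional[np.random.Generator] = None) -> Solution:
    """Run the genetic algorithm once and return the best solution found.

    Tournament selection with elitism, single-point crossover and the
    mutation operator above; stops after ``generations`` rounds or when
    the best fitness has improved by less than early_stop_tol over the
    last early_stop_window generations.  Fully deterministic given
    (config, rng state).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not profile.is_normalized():
        profile = profile.normalized()
    L = profile.n_otus
    config.n_genes(L)  # validate early
    sorted_ref = np.sort(sample_reference_values(
        config.model_prior, config.ks_reference_size, rng))
    population = init_population(L, config, rng)
    f1, f2, fit = _evaluate_population(population, profile.values, config,
                                       sorted_ref)
    best_i = int(np.argmin(fit))
    best = (population[best_i].copy(), f1[best_i], f2[best_i], fit[best_i])
    trajectory = [float(fit[best_i])]
    for _ in range(config.generations):
        order = np.argsort(fit, kind="stable")
        next_pop = [population[i].copy() for i in order[:config.elite_count]]
        while len(next_pop) < config.population_size:
            a = _tournament(fit, config.tournament_size, rng)
            b = _tournament(fit, config.tournament_size, rng)
            child = crossover(population[a], population[b], rng,
                              allow_self=config.allow_self_interactions)
            next_pop.append(mutate(child, config, rng))
        population = next_pop
        f1, f2, fit = _evaluate_population(population, profile.values, config,
                                           sorted_ref)
        best_i = int(np.argmin(fit))
        if fit[best_i] < best[3]:
            best = (population[best_i].copy(), f1[best_i], f2[best_i],
                    fit[best_i])
        trajectory.append(float(best[3]))
        w = config.early_stop_window
        if len(trajectory) > w and trajectory[-w - 1] - trajectory[-1] < config.early_stop_tol:
            break
    chrom, bf1, bf2, bfit = best
    params = _thresholded(chrom, config.zero_threshold)
    return Solution(params=params, f1=float(bf1), f2=float(bf2),
                    fitness=float(bfit), accuracy=(1.0 - float(bf1)) * 100.0,
                    seed=config.seed, trajectory=trajectory)


def _cluster_by_mse(solutions, delta_distinct: float):
    """Single-linkage clusters: components of the (MSE <= delta) graph."""
    n = len(solutions)
    rows, cols = [], []
    for i in range(n):
        for j in range(n):
            if i == j or matrix_mse(solutions[i].params.A,
                                    solutions[j].params.A) <= delta_distinct:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append(i)
    clusters.sort(key=lambda members: min(solutions[i].fitness for i in members))
    return clusters


def infer_solution_set(profile: AbundanceProfile, config: GAConfig) -> SolutionSet:
    """Multi-restart inference returning all near-equally-good networks.

    Runs ``restarts`` independent GA searches (seeds derived from
    config.seed), retains every solution whose reconstruction accuracy is
    within retention_margin percentage points of the best, and clusters
    the retained solutions by single-linkage on pairwise
    interaction-matrix MSE at threshold delta_distinct.  Distinct
    clusters are distinct candidate networks for the same data.
    """
    if config.restarts < 1:
        raise ValueError("need at least one restart")
    profile = profile.normalized()
    solutions = []
    for i in range(config.restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,)))
        sol = evolve(profile, config, rng=rng)
        sol.seed = i
        solutions.append(sol)
    best_acc = max(s.accuracy for s in solutions)
    retained = [s for s in solutions if s.accuracy >= best_acc - config.retention_margin]
    retained.sort(key=lambda s: s.fitness)
    clusters = _cluster_by_mse(retained, config.delta_distinct)
    return SolutionSet(solutions=retained, clusters=clusters)
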