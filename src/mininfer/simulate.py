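"""Synthetic-community experiments.

Generates ground-truth communities from the community dynamics model,
propagates them with the gLV simulator, and reproduces the package's
benchmark experiments: the heterogeneity/sparsity error sweep, the
Gaussian-noise robustness check and the solution-multiplicity
demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .community import (CommunityModelConfig, sample_growth_rates,
                        sample_initial_abundances, sample_interaction_matrix)
from .ga import GAConfig, infer_solution_set
from .glv import GLVParameters, reconstruct_profile
from .metrics import matrix_mse
from .profiles import AbundanceProfile, normalize_timepoint

__all__ = [
    "generate_dataset",
    "add_gaussian_noise",
    "heterogeneity_sparsity_sweep",
    "noise_robustness_experiment",
    "multiplicity_experiment",
    "NoiseRobustnessResult",
    "MultiplicityReport",
]

DEFAULT_TIMEPOINTS = 100


def generate_dataset(model_config: CommunityModelConfig,
                     T: int = DEFAULT_TIMEPOINTS,
                     rng: np.random.Generator | None = None,
                     return_draw: bool = False):
    """Simulate one community: ground-truth parameters and its profile.

    The interaction matrix comes from the community dynamics model,
    growth rates from the uniform growth prior, and initial abundances
    from Uniform(0, 1) normalised to a composition; the profile is the
    T-step gLV trajectory.

    Returns ``(profile, truth)`` or ``(profile, truth, draw)`` when
    ``return_draw`` is set.
    """
    if rng is None:
        rng = np.random.default_rng()
    draw = sample_interaction_matrix(model_config, rng)
    r = sample_growth_rates(model_config, rng)
    truth = GLVParameters(A=draw.A, r=r)
    x0 = sample_initial_abundances(model_config.n, rng)
    profile = reconstruct_profile(x0, truth, T)
    if return_draw:
        return profile, truth, draw
    return profile, truth


def add_gaussian_noise(profile: AbundanceProfile, mu: float = 0.0,
                       sigma: float = 0.01,
                       rng: np.random.Generator | None = None) -> AbundanceProfile:
    """Perturb every entry with Normal(mu, sigma^2) measurement noise.

    Entries are clamped at zero and each time-point column renormalised,
    so the result is again a valid composition profile.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    if sigma == 0 and mu == 0:
        return AbundanceProfile(list(profile.otu_ids), list(profile.times),
                                profile.values.copy())
    noisy = profile.values + rng.normal(mu, sigma, size=profile.values.shape)
    noisy = np.maximum(noisy, 0.0)
    cols = [normalize_timepoint(noisy[:, k]) for k in range(noisy.shape[1])]
    return AbundanceProfile(list(profile.otu_ids), list(profile.times),
                            np.column_stack(cols))


def heterogeneity_sparsity_sweep(alphas, ps, replicates: int,
                                 base_config: CommunityModelConfig,
                                 ga_config: GAConfig,
                                 T: int = DEFAULT_TIMEPOINTS,
                                 seed: int = 0):
    """Inference error across heterogeneity (alpha) and sparsity (p).

    For every (alpha, p) cell: simulate `replicates` communities, infer a
    network from each profile and record the MSE between inferred and
    ground-truth interaction matrices.  Returns ``(table, manifest)``
    where ``table`` is a DataFrame of mean MSE (rows alpha, columns p)
    and ``manifest`` records every per-replicate MSE and seed for
    bit-identical re-runs.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    table = pd.DataFrame(index=pd.Index(alphas, name="alpha"),
                         columns=pd.Index(ps, name="p"), dtype=float)
    manifest = {"seed": seed, "replicates": replicates, "T": T, "cells": []}
    for alpha in alphas:
        for p in ps:
            cell_cfg = replace(base_config, alpha=float(alpha), p=float(p))
            mses, seeds = [], []
            for rep in range(replicates):
                ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(int(round(alpha * 1000)),
                                             int(round(p * 1000)), rep))
                rng = np.random.default_rng(ss)
                profile, truth = generate_dataset(cell_cfg, T=T, rng=rng)
                rep_seed = int(ss.generate_state(1)[0] % (2**31))
                cfg = replace(ga_config, seed=rep_seed,
                              model_prior=replace(ga_config.model_prior,
                                                  alpha=float(alpha), p=float(p)))
                result = infer_solution_set(profile, cfg)
                mses.append(matrix_mse(truth.A, result.best.params.A))
                seeds.append(rep_seed)
            table.loc[alpha, p] = float(np.mean(mses))
            manifest["cells"].append({"alpha": float(alpha), "p": float(p),
                                      "mse": mses, "ga_seeds": seeds})
    return table, manifest


@dataclass
class NoiseRobustnessResult:
    """Spread of the retained solutions on a noise-perturbed profile."""

    max_pairwise_mse: float
    n_retained: int
    accuracies: list
    solution_set: object = field(repr=False, default=None)


def noise_robustness_experiment(model_config: CommunityModelConfig,
                                ga_config: GAConfig,
                                n_restarts: int = 10,
                                noise_sigma: float = 0.01,
                                T: int = DEFAULT_TIMEPOINTS,
                                rng: np.random.Generator | None = None
                                ) -> NoiseRobustnessResult:
    """Measure solution-cluster spread under measurement noise.

    Simulates a community, perturbs the observed profile with
    Normal(0, noise_sigma^2), runs multi-restart inference, and reports
    the maximum pairwise interaction-matrix MSE among the retained
    solutions.  Small spread means the near-optimal solutions agree.
    """
    if n_restarts < 2:
        raise ValueError("need at least two restarts to measure a spread")
    if rng is None:
        rng = np.random.default_rng(ga_config.seed)
    profile, _truth = generate_dataset(model_config, T=T, rng=rng)
    noisy = add_gaussian_noise(profile, 0.0, noise_sigma, rng)
    cfg = replace(ga_config, restarts=n_restarts)
    sol_set = infer_solution_set(noisy, cfg)
    return NoiseRobustnessResult(
        max_pairwise_mse=sol_set.max_pairwise_mse(),
        n_retained=len(sol_set.solutions),
        accuracies=[s.accuracy for s in sol_set.solutions],
        solution_set=sol_set)


@dataclass
class MultiplicityReport:
    """Distinct near-equally-accurate networks for one dataset.

    One row per cluster: the representative's reconstruction accuracy
    and its MSE to the simulated ground truth.  ``multiple_solutions``
    flags >= 2 distinct clusters within the retention margin.
    """

    cluster_accuracies: list
    cluster_mse_to_truth: list
    n_solutions: int
    multiple_solutions: bool
    solution_set: object = field(repr=False, default=None)


def multiplicity_experiment(model_config: CommunityModelConfig,
                            ga_config: GAConfig,
                            T: int = DEFAULT_TIMEPOINTS,
                            rng: np.random.Generator | None = None
                            ) -> MultiplicityReport:
    """Demonstrate solution multiplicity on one simulated dataset.

    Runs multi-restart inference and reports, per distinct cluster, the
    representative solution's accuracy and its MSE to the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(ga_config.seed)
    profile, truth = generate_dataset(model_config, T=T, rng=rng)
    sol_set = infer_solution_set(profile, ga_config)
    reps = sol_set.cluster_representatives()
    return MultiplicityReport(
        cluster_accuracies=[s.accuracy for s in reps],
        cluster_mse_to_truth=[matrix_mse(truth.A, s.params.A) for s in reps],
        n_solutions=len(sol_set.solutions),
        multiple_solutions=len(reps) >= 2,
        solution_set=sol_set)
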