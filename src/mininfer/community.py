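"""Community dynamics model: a generative prior for interaction matrices.

The interaction matrix of a microbial community is modelled as

    A = (N H) o G * s

where N is an n x n "nominal" matrix with N_ij ~ Normal(0, sigma^2), H is
a diagonal heterogeneity matrix with H_ii drawn from a truncated power
law (a minority of taxa are highly influential), G is the adjacency
matrix of an Erdos-Renyi random graph G(n, p) encoding sparsity, `o` is
the Hadamard (elementwise) product and s a global scale.

This module both simulates ground-truth communities and supplies the
reference distribution of nonzero interaction strengths used as a
goodness-of-fit penalty during inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CommunityModelConfig",
    "CommunityModelDraw",
    "sample_interaction_matrix",
    "sample_reference_values",
    "sample_initial_abundances",
    "sample_growth_rates",
]


@dataclass
class CommunityModelConfig:
    """Parameters (n, sigma, alpha, p, s) of the community dynamics model.

    Attributes
    ----------
    n : int
        Number of OTUs (>= 2).
    sigma : float
        Standard deviation of the nominal interaction strengths N_ij.
    alpha : float
        Exponent of the power-law heterogeneity distribution; smaller
        alpha puts more mass on large influence values.
    p : float
        Erdos-Renyi edge probability: the expected fraction of nonzero
        interactions (1 - sparsity).
    s : float
        Global scaling coefficient applied to every interaction.
    h_bounds : (float, float)
        Truncation bounds of the power law; H_ii has density
        proportional to x**(-alpha) on this interval.
    heterogeneity_axis : {'columns', 'rows'}
        'columns' scales the acting OTU's outgoing effects
        (A_ij ~ N_ij * H_jj, the default); 'rows' scales incoming ones.
    growth_bounds : (float, float)
        Uniform bounds for simulated intrinsic growth rates.
    """

    n: int = 10
    sigma: float = 1.0
    alpha: float = 0.6
    p: float = 0.4
    s: float = 0.1
    h_bounds: tuple = (1.0, 10.0)
    heterogeneity_axis: str = "columns"
    growth_bounds: tuple = (0.0, 1.0)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least n=2 OTUs")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("edge probability p must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        lo, hi = self.h_bounds
        if not (0 < lo <= hi):
            raise ValueError("h_bounds must satisfy 0 < lo <= hi")
        if self.heterogeneity_axis not in ("columns", "rows"):
            raise ValueError("heterogeneity_axis must be 'columns' or 'rows'")


@dataclass
class CommunityModelDraw:
    """One sampled (N, H, G, A) realisation of the community model."""

    N: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)
    G: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)


def _sample_truncated_powerlaw(alpha: float, bounds: tuple, size, rng) -> np.ndarray:
    """Inverse-CDF draws from density proportional to x**(-alpha) on [lo, hi]."""
    lo, hi = bounds
    if lo == hi:
        return np.full(size, float(lo))
    u = rng.random(size)
    if abs(alpha - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    e = 1.0 - alpha
    return (lo**e + u * (hi**e - lo**e)) ** (1.0 / e)


def sample_interaction_matrix(config: CommunityModelConfig,
                              rng: np.random.Generator) -> CommunityModelDraw:
    """Draw one interaction matrix A = (N H) o G * s.

    N_ij are i.i.d. Normal(0, sigma^2); H is diagonal with truncated
    power-law entries; G_ij are i.i.d. Bernoulli(p).
    """
    n = config.n
    N = rng.normal(0.0, config.sigma, size=(n, n))
    h = _sample_truncated_powerlaw(config.alpha, config.h_bounds, n, rng)
    H = np.diag(h)
    G = (rng.random((n, n)) < config.p).astype(float)
    if config.heterogeneity_axis == "columns":
        M = N * h[np.newaxis, :]        # (N H)_ij = N_ij * H_jj
    else:
        M = N * h[:, np.newaxis]
    A = M * G * config.s
    return CommunityModelDraw(N=N, H=H, G=G, A=A)


def sample_reference_values(config: CommunityModelConfig, m: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample m nonzero interaction strengths under the community model.

    These are draws of s * N_ij * H_jj conditional on the edge existing;
    they form the reference empirical distribution against which inferred
    interaction coefficients are tested (Kolmogorov-Smirnov penalty).
    """
    if m < 100:
        raise ValueError("reference sample needs m >= 100 draws")
    normals = rng.normal(0.0, config.sigma, size=m)
    h = _sample_truncated_powerlaw(config.alpha, config.h_bounds, m, rng)
    return config.s * normals * h


def sample_initial_abundances(n: int, rng: np.random.Generator) -> np.ndarray:
    """Initial composition: n Uniform(0,1) draws normalised to sum 1."""
    if n < 1:
        raise ValueError("need at least one OTU")
    x = rng.random(n)
    total = x.sum()
    if total == 0.0:          # measure-zero, but keep the convention
        return x
    return x / total


def sample_growth_rates(config: CommunityModelConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Simulated intrinsic growth rates, i.i.d. uniform on growth_bounds."""
    lo, hi = config.growth_bounds
    return rng.uniform(lo, hi, size=config.n)
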