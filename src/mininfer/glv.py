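"""Discrete-time generalized Lotka-Volterra (gLV) dynamics.

The per-step update for OTU i is

    x_i(t+1) = x_i(t) + dt * [ r_i x_i(t) + x_i(t) * sum_j A_ij x_j(t) ]

followed by clamping at zero and per-time-point renormalisation, so the
state stays a composition.  ``A[i, j]`` is the effect OF OTU j ON OTU i
(the acting OTU indexes the column).  No saturation / carrying-capacity
term is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import AbundanceProfile, normalize_timepoint

__all__ = ["GLVParameters", "glv_step", "reconstruct_profile"]


@dataclass
class GLVParameters:
    """Interaction matrix and intrinsic growth rates of a gLV system.

    Attributes
    ----------
    A : ndarray, shape (L, L)
        Interaction coefficients; ``A[i, j]`` is the per-unit-abundance
        effect of OTU j on the growth of OTU i.
    r : ndarray, shape (L,)
        Intrinsic growth rates (per unit time).
    """

    A: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be a square matrix")
        if self.r.shape != (self.A.shape[0],):
            raise ValueError("r length must match A dimension")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.r))):
            raise ValueError("parameters must be finite")

    @property
    def n_otus(self) -> int:
        return self.A.shape[0]


def glv_step(x: np.ndarray, params: GLVParameters, dt: float = 1.0) -> np.ndarray:
    """Advance a composition one time step under discrete gLV dynamics.

    Negative raw abundances are clamped to zero before renormalisation
    (relative abundances cannot be negative).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_otus,):
        raise ValueError(f"state length {x.shape} does not match {params.n_otus} OTUs")
    if dt <= 0:
        raise ValueError("dt must be positive")
    raw = x + dt * (params.r * x + x * (params.A @ x))
    raw = np.maximum(raw, 0.0)
    return normalize_timepoint(raw)


def glv_step_batch(X: np.ndarray, A: np.ndarray, r: np.ndarray,
                   dt: float = 1.0) -> np.ndarray:
    """Vectorised :func:`glv_step` over a batch of parameter sets.

    X : (P, L) states, A : (P, L, L) matrices, r : (P, L) growth rates.
    Used by the genetic algorithm to score a whole population per step.
    """
    Ax = np.einsum("pij,pj->pi", A, X)
    raw = X + dt * (r * X + X * Ax)
    np.maximum(raw, 0.0, out=raw)
    sums = raw.sum(axis=1, keepdims=True)
    safe = np.where(sums > 0, sums, 1.0)
    return np.where(sums > 0, raw / safe, raw)


def reconstruct_profile(x0: np.ndarray, params: GLVParameters, T: int,
                        dt: float = 1.0, otu_ids=None, times=None) -> AbundanceProfile:
    """Propagate initial abundances x0 forward for T time points.

    Column 0 is the normalised ``x0``; column k+1 is ``glv_step`` applied
    to column k.  This is the profile "reconstruction" used to score a
    candidate interaction network against an observed profile.
    """
    if T < 2:
        raise ValueError("need at least T=2 time points")
    L = params.n_otus
    cols = np.empty((L, T))
    cols[:, 0] = normalize_timepoint(np.asarray(x0, dtype=float))
    for k in range(T - 1):
        cols[:, k + 1] = glv_step(cols[:, k], params, dt=dt)
    if otu_ids is None:
        otu_ids = [f"OTU{i}" for i in range(L)]
    if times is None:
        times = list(range(T))
    return AbundanceProfile(list(otu_ids), list(times), cols)
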