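"""Model / Results interface for interaction-network inference.

`MicrobialInteractionModel` is constructed from a temporal abundance
profile (an :class:`~mininfer.profiles.AbundanceProfile` or a pandas
DataFrame) together with a community-model prior and genetic-algorithm
settings; :meth:`MicrobialInteractionModel.fit` runs the multi-restart
search and returns a :class:`MINResults` carrying the best network, the
full set of retained near-equivalent solutions, their clustering and a
text summary.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .community import CommunityModelConfig
from .ga import GAConfig, SolutionSet, infer_solution_set
from .glv import reconstruct_profile
from .metrics import matrix_mse
from .profiles import AbundanceProfile

__all__ = ["MicrobialInteractionModel", "MINResults"]


class MicrobialInteractionModel:
    """Infer a sparse interaction network from a temporal abundance profile.

    Parameters
    ----------
    profile : AbundanceProfile or pandas.DataFrame
        OTUs x time points; counts or proportions (normalised per time
        point internally).
    prior : CommunityModelConfig, optional
        Community dynamics model used both to initialise candidate
        interaction strengths and as the reference distribution of the
        Kolmogorov-Smirnov penalty.
    ga_config : GAConfig, optional
        Full genetic-algorithm configuration; additional keyword
        arguments override single fields (e.g. ``generations=200``).

    Examples
    --------
    >>> model = MicrobialInteractionModel(profile, generations=200)
    >>> res = model.fit(restarts=5, seed=1)
    >>> res.accuracy        # reconstruction accuracy of the best network
    >>> res.summary()
    """

    def __init__(self, profile, prior: CommunityModelConfig | None = None,
                 ga_config: GAConfig | None = None, **ga_overrides):
        if isinstance(profile, pd.DataFrame):
            profile = AbundanceProfile.from_dataframe(profile)
        if not isinstance(profile, AbundanceProfile):
            raise TypeError("profile must be an AbundanceProfile or DataFrame")
        self.profile = profile.normalized()
        if ga_config is None:
            ga_config = GAConfig()
        if prior is not None:
            ga_config = replace(ga_config, model_prior=prior)
        if ga_overrides:
            ga_config = replace(ga_config, **ga_overrides)
        self.ga_config = ga_config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, otus_as: str = "rows",
                       **kwargs) -> "MicrobialInteractionModel":
        return cls(AbundanceProfile.from_dataframe(df, otus_as=otus_as),
                   **kwargs)

    @property
    def n_otus(self) -> int:
        return self.profile.n_otus

    def fit(self, restarts: int | None = None,
            seed: int | None = None) -> "MINResults":
        """Run the multi-restart genetic algorithm.

        Deterministic given (configuration, seed): the same call
        reproduces the same results bit for bit.
        """
        cfg = self.ga_config
        if restarts is not None:
            cfg = replace(cfg, restarts=restarts)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        sol_set = infer_solution_set(self.profile, cfg)
        return MINResults(self, cfg, sol_set)


class MINResults:
    """Results of a fitted interaction-network model.

    Attributes
    ----------
    solution_set : SolutionSet
        All retained near-equivalent solutions, best first, with their
        clustering into distinct networks.
    params : GLVParameters
        The best solution's interaction matrix and growth rates.
    accuracy, f1, f2, fitness : float
        Best solution's reconstruction accuracy (%), mean Bray-Curtis
        dissimilarity, KS penalty and combined fitness.
    """

    def __init__(self, model: MicrobialInteractionModel, config: GAConfig,
                 solution_set: SolutionSet):
        self.model = model
        self.config = config
        self.solution_set = solution_set

    @property
    def best(self):
        return self.solution_set.best

    @property
    def params(self):
        return self.best.params

    @property
    def accuracy(self) -> float:
        return self.best.accuracy

    @property
    def f1(self) -> float:
        return self.best.f1

    @property
    def f2(self) -> float:
        return self.best.f2

    @property
    def fitness(self) -> float:
        return self.best.fitness

    @property
    def n_clusters(self) -> int:
        return self.solution_set.n_clusters

    @property
    def interaction_matrix(self) -> pd.DataFrame:
        ids = self.model.profile.otu_ids
        return pd.DataFrame(self.params.A, index=ids, columns=ids)

    @property
    def growth_rates(self) -> pd.Series:
        return pd.Series(self.params.r, index=self.model.profile.otu_ids,
                         name="growth_rate")

    def reconstructed_profile(self) -> AbundanceProfile:
        """Profile regenerated from the best network and the observed x0."""
        prof = self.model.profile
        return reconstruct_profile(prof.values[:, 0], self.params,
                                   prof.n_times, dt=self.config.dt,
                                   otu_ids=prof.otu_ids, times=prof.times)

    def mse_to(self, A_true: np.ndarray) -> float:
        """MSE between the best inferred matrix and a reference matrix."""
        return matrix_mse(A_true, self.params.A)

    def save(self, out_dir, input_checksum: str | None = None):
        from .io import write_solution_set

        return write_solution_set(self.solution_set,
                                  self.model.profile.otu_ids, out_dir,
                                  config=self.config,
                                  input_checksum=input_checksum)

    def summary(self) -> str:
        """Human-readable run summary."""
        prof = self.model.profile
        lines = [
            "Microbial interaction network inference",
            "=" * 55,
            f"OTUs: {prof.n_otus}    time points: {prof.n_times}",
            f"restarts: {self.config.restarts}    retained solutions: "
            f"{len(self.solution_set.solutions)}    distinct clusters: "
            f"{self.n_clusters}",
            "",
            "Best solution",
            "-" * 55,
            f"reconstruction accuracy : {self.accuracy:8.2f} %",
            f"Bray-Curtis (f1)        : {self.f1:8.4f}",
            f"KS penalty (f2)         : {self.f2:8.4f}",
            f"fitness (f1 + lambda*f2): {self.fitness:8.4f}",
            f"nonzero interactions    : {int(np.count_nonzero(self.params.A))}",
            "",
            "Retained solutions (best first)",
            "-" * 55,
            "  idx  cluster  accuracy(%)       f1       f2  fitness",
        ]
        cluster_of = {}
        for cl, members in enumerate(self.solution_set.clusters):
            for i in members:
                cluster_of[i] = cl
        for i, s in enumerate(self.solution_set.solutions):
            lines.append(f"  {i:3d}  {cluster_of[i]:7d}  {s.accuracy:11.2f}"
                         f"  {s.f1:7.4f}  {s.f2:7.4f}  {s.fitness:7.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MINResults: accuracy={self.accuracy:.2f}%, "
                f"{len(self.solution_set.solutions)} solutions in "
                f"{self.n_clusters} clusters>")
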