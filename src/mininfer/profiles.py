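"""Temporal relative-abundance profiles.

An abundance profile is an L x T matrix of per-time-point relative
abundances of L OTUs over T ordered time points.  Every column is
normalised to sum to one; a column that is entirely zero (an empty
sample) is left as zeros by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AbundanceProfile", "normalize_timepoint"]


def normalize_timepoint(x: np.ndarray) -> np.ndarray:
    """Scale a nonnegative abundance vector to sum to one.

    Parameters
    ----------
    x : array_like, shape (L,)
        Nonnegative, finite abundances (counts or proportions) of the L
        OTUs at one time point.

    Returns
    -------
    ndarray, shape (L,)
        ``x / x.sum()`` when the column carries any mass; an all-zero
        column is returned unchanged.

    Raises
    ------
    ValueError
        If ``x`` contains negative or non-finite entries.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d abundance vector, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("abundance vector contains non-finite entries")
    if np.any(x < 0):
        raise ValueError("abundance vector contains negative entries")
    total = x.sum()
    if total > 0:
        return x / total
    return x.copy()


@dataclass
class AbundanceProfile:
    """Relative abundances of L OTUs across T ordered time points.

    Attributes
    ----------
    otu_ids : list of str
        Opaque OTU labels, one per row.
    times : list
        Ordered time labels, one per column.
    values : ndarray, shape (L, T)
        Nonnegative matrix; each column sums to one after
        :meth:`normalized` (all-zero columns stay zero).
    """

    otu_ids: list
    times: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (L x T) matrix")
        L, T = self.values.shape
        if L < 1:
            raise ValueError("profile needs at least one OTU")
        if T < 2:
            raise ValueError("profile needs at least two time points")
        if len(self.otu_ids) != L:
            raise ValueError(f"{len(self.otu_ids)} OTU ids for {L} rows")
        if len(self.times) != T:
            raise ValueError(f"{len(self.times)} time labels for {T} columns")
        if len(set(map(str, self.otu_ids))) != L:
            raise ValueError("duplicate OTU ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("profile contains negative entries")

    @property
    def n_otus(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def normalized(self) -> "AbundanceProfile":
        """Return a copy with every time-point column normalised to sum 1."""
        cols = [normalize_timepoint(self.values[:, k]) for k in range(self.n_times)]
        return AbundanceProfile(list(self.otu_ids), list(self.times),
                                np.column_stack(cols))

    def is_normalized(self, tol: float = 1e-9) -> bool:
        sums = self.values.sum(axis=0)
        return bool(np.all((np.abs(sums - 1.0) <= tol) | (sums == 0.0)))

    @classmethod
    def from_dataframe(cls, df, otus_as: str = "rows") -> "AbundanceProfile":
        """Build a normalised profile from a pandas DataFrame.

        ``otus_as='rows'`` (default) reads rows as OTUs and columns as time
        points; ``'columns'`` transposes first.
        """
        if otus_as not in ("rows", "columns"):
            raise ValueError("otus_as must be 'rows' or 'columns'")
        if otus_as == "columns":
            df = df.T
        prof = cls(list(map(str, df.index)), list(df.columns),
                   df.to_numpy(dtype=float))
        return prof.normalized()

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.times)
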