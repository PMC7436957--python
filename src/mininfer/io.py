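"""Readers and writers for abundance tables and inferred networks.

Table dialect: TSV by default (CSV auto-detected from the extension),
OTUs as rows, first column = OTU id, header row = time labels.  Network
writers emit an adjacency matrix, an edge list and a growth-rate table;
the edge-list orientation is source = acting OTU (column index of A),
target = affected OTU (row index).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .glv import GLVParameters
from .profiles import AbundanceProfile

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_min",
    "write_min",
    "write_solution_set",
    "RunManifest",
]

_FLOAT_FMT = "%.12g"


def _delimiter_for(path: Path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(path, otus_as: str = "rows",
                         delimiter: str | None = None) -> AbundanceProfile:
    """Read an OTU table and return a per-time-point-normalised profile.

    The file must be a rectangular numeric table with OTU ids in the
    first column (or first row with ``otus_as='columns'``).  Counts or
    proportions are accepted; every time point is normalised to sum 1.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if otus_as == "columns":
        df = df.T
    elif otus_as != "rows":
        raise ValueError("otus_as must be 'rows' or 'columns'")
    ids = list(map(str, df.index))
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        lines = [k + 2 for k, i in enumerate(ids) if i in dup]
        raise ValueError(f"{path}: duplicate OTU ids {sorted(dup)} "
                         f"(lines {lines})")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for k, row in enumerate(df.itertuples(index=False)):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} on line {k + 2}"
                    ) from exc
        raise
    profile = AbundanceProfile(ids, list(df.columns), values)
    return profile.normalized()


def write_abundance_table(profile: AbundanceProfile, path,
                          delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    profile.to_dataframe().to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def write_min(params: GLVParameters, otu_ids, path_prefix) -> dict:
    """Write an inferred network as adjacency, edge-list and growth tables.

    Emits ``<prefix>_adjacency.tsv`` (A with OTU ids as headers),
    ``<prefix>_edges.tsv`` (source = acting OTU j, target = affected OTU
    i, weight = A[i, j], sign) and ``<prefix>_growth.tsv``.  Values keep
    12 significant digits, so a read-back round-trips.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    otu_ids = list(map(str, otu_ids))
    L = params.n_otus
    if len(otu_ids) != L:
        raise ValueError(f"{len(otu_ids)} OTU ids for {L} OTUs")

    adjacency = prefix.with_name(prefix.name + "_adjacency.tsv")
    pd.DataFrame(params.A, index=otu_ids, columns=otu_ids).to_csv(
        adjacency, sep="\t", float_format=_FLOAT_FMT)

    edges = prefix.with_name(prefix.name + "_edges.tsv")
    with open(edges, "w") as fh:
        fh.write("# A[i, j] is the effect OF source OTU j ON target OTU i\n")
        fh.write("source_otu\ttarget_otu\tweight\tsign\n")
        for i in range(L):
            for j in range(L):
                w = params.A[i, j]
                if w != 0.0:
                    sign = "+" if w > 0 else "-"
                    fh.write(f"{otu_ids[j]}\t{otu_ids[i]}\t"
                             f"{_FLOAT_FMT % w}\t{sign}\n")

    growth = prefix.with_name(prefix.name + "_growth.tsv")
    pd.Series(params.r, index=otu_ids, name="growth_rate").to_csv(
        growth, sep="\t", float_format=_FLOAT_FMT, header=True)
    return {"adjacency": adjacency, "edges": edges, "growth": growth}


def read_min(path_prefix) -> GLVParameters:
    """Read back a network written by :func:`write_min`."""
    prefix = Path(path_prefix)
    adjacency = prefix.with_name(prefix.name + "_adjacency.tsv")
    growth = prefix.with_name(prefix.name + "_growth.tsv")
    A = pd.read_csv(adjacency, sep="\t", index_col=0).to_numpy(dtype=float)
    r = pd.read_csv(growth, sep="\t", index_col=0)["growth_rate"].to_numpy(dtype=float)
    return GLVParameters(A=A, r=r)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one inference run: enough to re-run bit-identically."""

    config: dict
    seed: int
    input_checksum: str | None
    solutions: list
    clusters: list
    versions: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def _library_versions() -> dict:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {"mininfer": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}


def write_solution_set(sol_set, otu_ids, out_dir, config=None,
                       input_checksum: str | None = None) -> Path:
    """Materialise a solution set: one subdirectory per retained network.

    Writes ``solution_000/``... via :func:`write_min`, a cluster
    assignment table and a JSON run manifest with config, seeds and
    library versions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not sol_set.solutions:
        raise ValueError("empty solution set")
    for idx, sol in enumerate(sol_set.solutions):
        write_min(sol.params, otu_ids, out / f"solution_{idx:03d}" / "min")

    with open(out / "clusters.tsv", "w") as fh:
        fh.write("solution\tcluster\n")
        for cl, members in enumerate(sol_set.clusters):
            for idx in sorted(members):
                fh.write(f"solution_{idx:03d}\t{cl}\n")

    from dataclasses import is_dataclass

    cfg_dict = asdict(config) if is_dataclass(config) else (config or {})
    manifest = RunManifest(
        config=cfg_dict,
        seed=cfg_dict.get("seed", 0) if isinstance(cfg_dict, dict) else 0,
        input_checksum=input_checksum,
        solutions=[{"index": i, "seed": s.seed, "f1": s.f1, "f2": s.f2,
                    "fitness": s.fitness, "accuracy": s.accuracy}
                   for i, s in enumerate(sol_set.solutions)],
        clusters=[list(map(int, members)) for members in sol_set.clusters],
        versions=_library_versions())
    (out / "manifest.json").write_text(manifest.to_json())
    return out
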