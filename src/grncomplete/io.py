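"""File formats: expression TSV, edge-list / SIF networks, JSON results.

Expression files are tab-separated with gene identifiers in the first column
and sample identifiers in the header row.  Networks come in two dialects:
a two-column ``source<TAB>target`` edge list (optional header) and the SIF
dialect ``source<TAB>interaction<TAB>target`` (the interaction label is
written as ``regulates`` and ignored on read).  Results are JSON with floats
serialized to 12 significant digits.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "write_results",
    "round_floats",
]

Dialect = Literal["edge-list", "sif"]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column genes, first row samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty expression file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no expression data (need >= 1 gene and >= 1 sample)")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from None
    if pd.isna(values).any():
        raise ValueError(f"{path}: missing or non-finite expression values")
    return ExpressionMatrix(values, [str(g) for g in df.index], [str(s) for s in df.columns])


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.to_dataframe()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def _infer_dialect(path: Path, dialect: Dialect | None) -> Dialect:
    if dialect is not None:
        return dialect
    return "sif" if path.suffix.lower() == ".sif" else "edge-list"


def read_network(
    path: str | Path,
    dialect: Dialect | None = None,
    genes: Sequence[str] | None = None,
) -> GeneNetwork:
    """Read a directed network; genes not in ``genes`` are declared implicitly.

    ``dialect`` defaults to SIF for ``.sif`` files and edge-list otherwise.
    An empty file yields an edgeless network (a valid inference seed).
    Duplicate edges are deduplicated with a warning; edges over genes missing
    from ``genes`` (when given) trigger a warning and extend the gene list.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "sif":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF needs source, interaction, target")
                edges.append((fields[0].strip(), fields[2].strip()))
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: edge list needs source and target")
                u, v = fields[0].strip(), fields[1].strip()
                if lineno == 1 and (u.lower(), v.lower()) == ("source", "target"):
                    continue  # optional header
                edges.append((u, v))
    seen = set()
    unique_edges = []
    for e in edges:
        if e in seen:
            warnings.warn(f"{path}: duplicate edge {e} deduplicated", stacklevel=2)
        else:
            seen.add(e)
            unique_edges.append(e)
    if genes is None:
        gene_list: list[str] = []
        known: set[str] = set()
    else:
        gene_list = list(genes)
        known = set(gene_list)
    for u, v in unique_edges:
        for g in (u, v):
            if g not in known:
                if genes is not None:
                    warnings.warn(
                        f"{path}: gene {g!r} not in the declared gene list; declared implicitly",
                        stacklevel=2,
                    )
                known.add(g)
                gene_list.append(g)
    return GeneNetwork(gene_list, unique_edges)


def write_network(
    network: GeneNetwork, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write a network so that :func:`read_network` reproduces it exactly."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    order = {g: i for i, g in enumerate(network.genes)}
    edges = sorted(network.edges, key=lambda e: (order[e[0]], order[e[1]]))
    with open(path, "w") as fh:
        if dialect == "sif":
            for u, v in edges:
                fh.write(f"{u}\tregulates\t{v}\n")
        else:
            fh.write("source\ttarget\n")
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")


def round_floats(obj, sig: int = 12):
    """Recursively round floats to ``sig`` significant digits for stable JSON."""
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return round_floats(obj.tolist(), sig)
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def write_results(results: dict, path: str | Path) -> None:
    """Serialize a result dictionary as JSON (12 significant digits)."""
    with open(path, "w") as fh:
        json.dump(round_floats(results), fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_gene_list(edges: Iterable[tuple[str, str]]) -> list[str]:
    """Genes in order of first appearance across an edge iterable."""
    seen: list[str] = []
    known: set[str] = set()
    for u, v in edges:
        for g in (u, v):
            if g not in known:
                known.add(g)
                seen.append(g)
    return seen
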