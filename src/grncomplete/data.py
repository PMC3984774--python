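"""Core containers: directed gene networks and steady-state expression matrices.

A :class:`GeneNetwork` is a directed graph over named genes in which an edge
``(u, v)`` means "u directly regulates v"; self-loops (autoregulation) are
permitted.  A :class:`ExpressionMatrix` holds one expression value per gene per
sample, interpreted as repeated observations of a stationary regulatory state
rather than as a time course.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneNetwork", "ExpressionMatrix"]

#: relative singular-value cutoff used by every least-squares solve
RCOND = 1e-10


class GeneNetwork:
    """A directed graph over an ordered set of genes, self-loops allowed.

    Parameters
    ----------
    genes : sequence of str
        Ordered, unique gene identifiers.
    edges : iterable of (str, str), optional
        Directed edges ``(source, target)``.  Both endpoints must be listed
        genes.  Duplicate pairs collapse to a single edge.
    """

    def __init__(self, genes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        genes = tuple(genes)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers in network")
        self._genes = genes
        self._gene_set = frozenset(genes)
        edge_set = set()
        for u, v in edges:
            if u not in self._gene_set or v not in self._gene_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unlisted gene")
            edge_set.add((u, v))
        self._edges = frozenset(edge_set)
        self._parents: dict[str, tuple[str, ...]] = {}
        order = {g: i for i, g in enumerate(genes)}
        for g in genes:
            ps = sorted((u for (u, v) in self._edges if v == g), key=order.__getitem__)
            self._parents[g] = tuple(ps)

    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    @property
    def n(self) -> int:
        return len(self._genes)

    def parents(self, gene: str) -> tuple[str, ...]:
        """Sources of edges into ``gene`` (the parent set e⁻(v)), in gene order."""
        try:
            return self._parents[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def indegree(self, gene: str) -> int:
        """Number of incoming edges deg⁻(v), counting a self-loop."""
        return len(self.parents(gene))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._edges

    def with_modifications(
        self,
        added: Iterable[tuple[str, str]] = (),
        deleted: Iterable[tuple[str, str]] = (),
    ) -> "GeneNetwork":
        """Return a new network with ``added`` edges inserted and ``deleted`` removed.

        Added edges must be absent, deleted edges present; the two sets must be
        disjoint.
        """
        added = set(added)
        deleted = set(deleted)
        if added & deleted:
            raise ValueError("added and deleted edge sets must be disjoint")
        if added & self._edges:
            raise ValueError(f"edges already present: {sorted(added & self._edges)}")
        if not deleted <= self._edges:
            raise ValueError(f"edges not present: {sorted(deleted - self._edges)}")
        return GeneNetwork(self._genes, (self._edges | added) - deleted)

    def reordered(self, genes: Sequence[str]) -> "GeneNetwork":
        """Same edge set with genes listed in a different order (a permutation)."""
        if set(genes) != self._gene_set or len(genes) != self.n:
            raise ValueError("reordered gene list must be a permutation")
        return GeneNetwork(genes, self._edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self._genes)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, graph) -> "GeneNetwork":
        return cls([str(v) for v in graph.nodes], [(str(u), str(v)) for u, v in graph.edges])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self._gene_set == other._gene_set and self._edges == other._edges

    def __hash__(self):
        return hash((self._gene_set, self._edges))

    def __repr__(self) -> str:
        return f"GeneNetwork(n={self.n}, edges={len(self._edges)})"


class ExpressionMatrix:
    """Steady-state expression values, genes × samples.

    Column ``s`` holds one observed sample ⟨y_1(s), …, y_n(s)⟩.  The matrix also
    owns the machinery shared by every per-node quadratic fit: the design-column
    universe ``[1, x_1..x_n, x_i·x_j (i ≤ j)]`` and its one-off QR compression
    (see :meth:`compressed_design`), which makes the cost of a single candidate
    fit independent of the number of samples.
    """

    def __init__(self, values, genes: Sequence[str], samples: Sequence[str] | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes × samples array")
        n, m = values.shape
        if m < 1:
            raise ValueError("at least one sample is required")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must all be finite")
        genes = tuple(genes)
        if len(genes) != n:
            raise ValueError("gene list length does not match row count")
        if len(set(genes)) != n:
            raise ValueError("duplicate gene identifiers")
        if samples is None:
            samples = tuple(f"s{i + 1}" for i in range(m))
        else:
            samples = tuple(samples)
            if len(samples) != m:
                raise ValueError("sample list length does not match column count")
        self._values = values
        self._genes = genes
        self._samples = samples
        self._index = {g: i for i, g in enumerate(genes)}
        self._design_r: np.ndarray | None = None

    # ------------------------------------------------------------------ basics
    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    @property
    def samples(self) -> tuple[str, ...]:
        return self._samples

    @property
    def n_genes(self) -> int:
        return self._values.shape[0]

    @property
    def n_samples(self) -> int:
        return self._values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def row(self, gene: str) -> np.ndarray:
        return self._values[self.gene_index(gene)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(g) for g in df.index], [str(s) for s in df.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=list(self._genes), columns=list(self._samples))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(self._values[idx], genes, self._samples)

    # ------------------------------------------------- design-column universe
    # Column layout (fixed): 0 → intercept, 1+i → gene i, then products
    # x_i·x_j for i ≤ j in row-major order (0,0),(0,1),…,(0,n−1),(1,1),… .
    @property
    def n_design_columns(self) -> int:
        n = self.n_genes
        return 1 + n + n * (n + 1) // 2

    def _product_column(self, i: int, j: int) -> int:
        n = self.n_genes
        if i > j:
            i, j = j, i
        return 1 + n + i * n - i * (i - 1) // 2 + (j - i)

    def design_column_indices(self, parent_rows: Sequence[int]) -> list[int]:
        """Design-universe columns for an (ascending) parent row-index list.

        Order matches :func:`grncomplete.quadmodel.design_row`: intercept,
        linear terms, then products (j ≤ k) over the given parent order.
        """
        cols = [0] + [1 + i for i in parent_rows]
        for a in range(len(parent_rows)):
            for b in range(a, len(parent_rows)):
                cols.append(self._product_column(parent_rows[a], parent_rows[b]))
        return cols

    def full_design(self) -> np.ndarray:
        """The m × (1 + n + n(n+1)/2) matrix of all design columns."""
        n, m = self.n_genes, self.n_samples
        out = np.empty((m, self.n_design_columns))
        out[:, 0] = 1.0
        out[:, 1 : 1 + n] = self._values.T
        col = 1 + n
        for i in range(n):
            block = self._values[i][:, None] * self._values[i:].T
            out[:, col : col + n - i] = block
            col += n - i
        return out

    def compressed_design(self) -> np.ndarray:
        """R factor of a reduced QR of :meth:`full_design` (cached).

        With A = QR (Q orthonormal), any candidate design X = A[:, S] equals
        Q·R[:, S], and every response y (a gene column, hence a column of A)
        lies in range(Q).  Singular values, minimum-norm solutions and residual
        norms of the m-row problem therefore coincide exactly with those of the
        min(m, C)-row problem on R, so all fits are done on R.
        """
        if self._design_r is None:
            self._design_r = np.linalg.qr(self.full_design(), mode="r")
        return self._design_r

    def __repr__(self) -> str:
        return f"ExpressionMatrix(n_genes={self.n_genes}, n_samples={self.n_samples})"
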