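"""Network completion by dynamic programming over least-squares errors.

Given steady-state expression data and an initial directed network, completion
means spending an exact budget of k edge additions and h edge deletions so
that the sum over genes of the per-node least-squares error (see
:mod:`grncomplete.quadmodel`) is minimal.  Two facts make this tractable:

* the total error decomposes over nodes, because each node's fit depends only
  on its own parent set;
* per-node modification counts can be capped by small constants K and H, so
  the per-node minimum over modified parent sets (the σ table) is a modest
  exhaustive enumeration.

A dynamic program over nodes then distributes the global budgets optimally:
``D[k', h', i]`` is the minimal total error over the first i nodes using
exactly k' additions and h' deletions, and the final cell ``D[k, h, n]`` is
the optimum regardless of node order.  Starting from an edgeless network with
h = H = 0 the same machinery performs network inference.

The user-facing surface follows the statsmodels idiom: build a
:class:`NetworkCompletion` model from data, call :meth:`~NetworkCompletion.fit`,
inspect the returned :class:`CompletionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneNetwork
from .quadmodel import FitResult, fit_node, node_error

__all__ = [
    "INFEASIBLE",
    "CompletionSpec",
    "SigmaEntry",
    "SigmaTable",
    "DPTable",
    "CompletionResults",
    "NetworkCompletion",
    "candidate_parents",
    "sigma",
    "dp_add",
    "dp_add_del",
    "traceback",
    "complete_network",
    "infer_network",
]

#: sentinel for infeasible table entries; compares greater than any finite
#: error and propagates through min() without special-casing.
INFEASIBLE = float("inf")

#: per-node caps above this require an explicit override — the σ enumeration
#: is C(n, K)·C(deg, H) per node and blows up combinatorially.
_CAP_GUARD = 3


@dataclass(frozen=True)
class CompletionSpec:
    """Budgets for one completion run.

    k, h: exact total numbers of edges to add / delete.
    K, H: per-node caps on additions / deletions.
    """

    k: int
    h: int
    K: int = 2
    H: int = 2

    def __post_init__(self):
        for name in ("k", "h", "K", "H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def candidate_parents(
    network: GeneNetwork, node: str, allow_self_loops: bool = False
) -> set[str]:
    """Genes eligible to become new parents of ``node``.

    Everything except current parents, and except the node itself unless
    ``allow_self_loops`` — note that a self-loop parent makes the identity fit
    x_i = x_i available, driving the node's error to zero on any data, which
    is why self-loop additions are excluded by default.
    """
    out = set(network.genes) - set(network.parents(node))
    if not allow_self_loops:
        out.discard(node)
    return out


@dataclass(frozen=True)
class SigmaEntry:
    """One σ value: minimal error for a (node, k_j, h_j) budget, with argmin."""

    value: float
    added: tuple[str, ...]  # new parents, index-sorted
    deleted: tuple[str, ...]  # removed parents, index-sorted

    @property
    def feasible(self) -> bool:
        return self.value != INFEASIBLE


class SigmaTable:
    """Per-node minimal least-squares errors over modification budgets.

    ``entry(node, k_j, h_j)`` enumerates every way to delete h_j current
    parents and add k_j candidate parents (added and deleted sets are disjoint
    by construction, since candidates exclude current parents), fits each
    resulting parent set, and memoizes the minimum with its argmin edge sets.
    Entries are independent of one another, so the table is safe to fill in
    any order (or in parallel).

    An entry is +∞ exactly when k_j > K, h_j > H, k_j − h_j + deg⁻ ≥ n,
    k_j − h_j + deg⁻ < 0, or the enumeration is empty (h_j > deg⁻ or
    k_j > number of candidates).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        network: GeneNetwork,
        spec: CompletionSpec,
        allow_self_loops: bool = False,
    ):
        missing = set(network.genes) - set(expr.genes)
        if missing:
            raise ValueError(f"network genes absent from expression data: {sorted(missing)}")
        self.expr = expr
        self.network = network
        self.spec = spec
        self.allow_self_loops = allow_self_loops
        self.fit_count = 0  # least-squares fits performed (for diagnostics)
        self._order = {g: i for i, g in enumerate(network.genes)}
        self._cache: dict[tuple[str, int, int], SigmaEntry] = {}

    def candidates(self, node: str) -> tuple[str, ...]:
        cand = candidate_parents(self.network, node, self.allow_self_loops)
        return tuple(sorted(cand, key=self._order.__getitem__))

    def entry(self, node: str, k_j: int, h_j: int) -> SigmaEntry:
        key = (node, k_j, h_j)
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = self._compute(node, k_j, h_j)
        return hit

    def _compute(self, node: str, k_j: int, h_j: int) -> SigmaEntry:
        spec, net = self.spec, self.network
        deg = net.indegree(node)
        n = net.n
        if (
            k_j > spec.K
            or h_j > spec.H
            or k_j - h_j + deg >= n
            or k_j - h_j + deg < 0
        ):
            return SigmaEntry(INFEASIBLE, (), ())
        parents = net.parents(node)
        cand = self.candidates(node)
        if h_j > deg or k_j > len(cand):
            return SigmaEntry(INFEASIBLE, (), ())
        best: SigmaEntry | None = None
        # combinations() over index-sorted pools yields lexicographic order;
        # strict improvement keeps the lexicographically smallest tie-winner
        # (deleted set major, added set minor).
        for dels in combinations(parents, h_j):
            kept = [p for p in parents if p not in dels]
            for adds in combinations(cand, k_j):
                err = node_error(self.expr, node, kept + list(adds))
                self.fit_count += 1
                if best is None or err < best.value:
                    best = SigmaEntry(err, adds, dels)
        assert best is not None
        return best

    def compute_all(self) -> None:
        """Eagerly fill the full (K+1) × (H+1) grid for every node."""
        for g in self.network.genes:
            for k_j in range(self.spec.K + 1):
                for h_j in range(self.spec.H + 1):
                    self.entry(g, k_j, h_j)


def sigma(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    node: str,
    k_j: int,
    h_j: int,
    spec: CompletionSpec,
    allow_self_loops: bool = False,
) -> tuple[float, tuple[str, ...], tuple[str, ...]]:
    """One-off σ evaluation; see :class:`SigmaTable` for the table form."""
    e = SigmaTable(expr, network, spec, allow_self_loops).entry(node, k_j, h_j)
    return e.value, e.added, e.deleted


@dataclass
class DPTable:
    """Cumulative-minimum table D with split records for traceback.

    ``D[k', h', i]`` is the minimal total error over the first i+1 nodes (in
    ``sigma.network.genes`` order) spending exactly k' additions and h'
    deletions; ``split[k', h', i]`` is the (k_j, h_j) budget the optimum gives
    to node i at that cell.  The final value ``D[k, h, n−1]`` is invariant to
    the node ordering.
    """

    D: np.ndarray  # (k+1, h+1, n)
    split: np.ndarray  # (k+1, h+1, n, 2) int
    sigma: SigmaTable

    @property
    def optimum(self) -> float:
        return float(self.D[-1, -1, -1])


def dp_add_del(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    spec: CompletionSpec,
    allow_self_loops: bool = False,
    sigma_table: SigmaTable | None = None,
) -> DPTable:
    """Two-budget dynamic program over nodes.

    Recurrence: D[k', h', 1] = σ_{k',h',1} and
    D[k', h', j+1] = min over k_j ≤ k', h_j ≤ h' of
    D[k'−k_j, h'−h_j, j] + σ_{k_j,h_j,j+1}.  Ties prefer the smallest node
    budget k_j, then the smallest h_j.
    """
    st = sigma_table or SigmaTable(expr, network, spec, allow_self_loops)
    genes = st.network.genes
    n, k, h = len(genes), spec.k, spec.h
    D = np.full((k + 1, h + 1, n), INFEASIBLE)
    split = np.zeros((k + 1, h + 1, n, 2), dtype=int)
    for i, g in enumerate(genes):
        kmax, hmax = min(k, spec.K), min(h, spec.H)
        for kp in range(k + 1):
            for hp in range(h + 1):
                best = INFEASIBLE
                best_split = (0, 0)
                for kj in range(min(kp, kmax) + 1):
                    for hj in range(min(hp, hmax) + 1):
                        s = st.entry(g, kj, hj).value
                        if s == INFEASIBLE:
                            continue
                        if i == 0:
                            if kj != kp or hj != hp:
                                continue
                            total = s
                        else:
                            prev = D[kp - kj, hp - hj, i - 1]
                            if prev == INFEASIBLE:
                                continue
                            total = prev + s
                        if total < best:
                            best = total
                            best_split = (kj, hj)
                D[kp, hp, i] = best
                split[kp, hp, i] = best_split
    return DPTable(D, split, st)


def dp_add(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    k: int,
    spec: CompletionSpec | None = None,
    allow_self_loops: bool = False,
) -> DPTable:
    """Addition-only dynamic program (H = 0); a special case of :func:`dp_add_del`."""
    if spec is None:
        spec = CompletionSpec(k=k, h=0, K=2, H=0)
    if spec.H != 0 or spec.h != 0:
        raise ValueError("dp_add requires h = H = 0")
    if spec.k != k:
        spec = CompletionSpec(k=k, h=0, K=spec.K, H=0)
    return dp_add_del(expr, network, spec, allow_self_loops)


def traceback(table: DPTable, sigma_table: SigmaTable | None = None) -> "CompletionResults":
    """Recover the optimal edge modifications from a filled DP table.

    Walks the recorded splits from the final cell down to the first node,
    collects each node's argmin added/deleted parent sets, and applies them to
    the initial network.  If the optimum is +∞ the instance is infeasible and
    no network is produced.
    """
    st = sigma_table or table.sigma
    spec, net = st.spec, st.network
    if table.optimum == INFEASIBLE:
        return CompletionResults(
            spec=spec,
            initial=net,
            completed=None,
            per_node={},
            total_error=INFEASIBLE,
            feasible=False,
            dp=table,
            expr=st.expr,
        )
    genes = net.genes
    kp, hp = spec.k, spec.h
    per_node: dict[str, SigmaEntry] = {}
    for i in range(len(genes) - 1, -1, -1):
        kj, hj = table.split[kp, hp, i]
        per_node[genes[i]] = st.entry(genes[i], kj, hj)
        kp -= kj
        hp -= hj
    assert kp == 0 and hp == 0
    added = {(p, g) for g, e in per_node.items() for p in e.added}
    deleted = {(p, g) for g, e in per_node.items() for p in e.deleted}
    completed = net.with_modifications(added, deleted)
    total = float(sum(e.value for e in per_node.values()))
    return CompletionResults(
        spec=spec,
        initial=net,
        completed=completed,
        per_node=per_node,
        total_error=total,
        feasible=True,
        dp=table,
        expr=st.expr,
    )


@dataclass
class CompletionResults:
    """Results of one completion (or inference) fit.

    Attributes
    ----------
    completed : GeneNetwork or None
        The modified network (None when infeasible).
    per_node : dict
        Gene → :class:`SigmaEntry` giving that node's added/deleted parents
        and its minimal error under the optimum.
    total_error : float
        Σ_j node error of the completed parent sets; equals the DP optimum.
    """

    spec: CompletionSpec
    initial: GeneNetwork
    completed: GeneNetwork | None
    per_node: dict[str, SigmaEntry]
    total_error: float
    feasible: bool
    dp: DPTable
    expr: ExpressionMatrix
    model: "NetworkCompletion | None" = field(default=None, repr=False)

    @property
    def added_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, g) for g, e in self.per_node.items() for p in e.added)

    @property
    def deleted_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, g) for g, e in self.per_node.items() for p in e.deleted)

    @property
    def fit_count(self) -> int:
        return self.dp.sigma.fit_count

    @cached_property
    def node_models(self) -> dict[str, FitResult]:
        """Refitted quadratic models for every gene on its final parent set."""
        if not self.feasible:
            raise ValueError("infeasible result has no completed network")
        assert self.completed is not None
        return {
            g: fit_node(self.expr, g, self.completed.parents(g))
            for g in self.completed.genes
        }

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = []
        lines.append("Network completion results")
        lines.append("=" * 70)
        lines.append(
            f"genes: {self.initial.n}    samples: {self.expr.n_samples}    "
            f"budgets: k={self.spec.k} h={self.spec.h} (caps K={self.spec.K} H={self.spec.H})"
        )
        status = "feasible" if self.feasible else "INFEASIBLE"
        lines.append(f"status: {status}    total error: {self.total_error:.6g}")
        lines.append("-" * 70)
        lines.append(f"{'gene':<10}{'added parents':<22}{'deleted parents':<22}{'error':>14}")
        for g in self.initial.genes:
            e = self.per_node.get(g)
            if e is None:
                continue
            lines.append(
                f"{g:<10}{', '.join(e.added) or '-':<22}"
                f"{', '.join(e.deleted) or '-':<22}{e.value:>14.6g}"
            )
        lines.append("=" * 70)
        return "\n".join(lines)


class NetworkCompletion:
    """Model object: completion/inference of a gene network from static data.

    Parameters
    ----------
    expr : ExpressionMatrix or pandas.DataFrame
        Genes × samples steady-state expression values.
    network : GeneNetwork, iterable of edges, or None
        Initial network.  ``None`` (or an empty edge set) starts from an
        edgeless network over the expression genes, which turns completion
        into network inference.
    allow_self_loops : bool
        Permit self-loop additions.  Off by default: a self-loop makes the
        trivial identity fit available, so leaving this off matches the
        candidate rule the method is built around.

    Examples
    --------
    >>> model = NetworkCompletion(expr, network)
    >>> res = model.fit(k=1, h=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        expr: ExpressionMatrix | pd.DataFrame,
        network: GeneNetwork | Sequence[tuple[str, str]] | None = None,
        allow_self_loops: bool = False,
    ):
        if isinstance(expr, pd.DataFrame):
            expr = ExpressionMatrix.from_dataframe(expr)
        if network is None:
            network = GeneNetwork(expr.genes)
        elif not isinstance(network, GeneNetwork):
            edges = list(network)
            genes = list(expr.genes)
            network = GeneNetwork(genes, edges)
        missing = set(network.genes) - set(expr.genes)
        if missing:
            raise ValueError(f"network genes absent from expression data: {sorted(missing)}")
        if set(network.genes) != set(expr.genes):
            expr = expr.subset_genes(network.genes)
        self.expr = expr
        self.network = network
        self.allow_self_loops = allow_self_loops

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        network: GeneNetwork | Sequence[tuple[str, str]] | None = None,
        allow_self_loops: bool = False,
    ) -> "NetworkCompletion":
        return cls(ExpressionMatrix.from_dataframe(df), network, allow_self_loops)

    def fit(
        self,
        k: int = 0,
        h: int = 0,
        K: int = 2,
        H: int = 2,
        allow_large_caps: bool = False,
    ) -> CompletionResults:
        """Find the error-minimal network at exactly k additions / h deletions."""
        if max(K, H) > _CAP_GUARD and not allow_large_caps:
            raise ValueError(
                f"per-node caps K={K}, H={H} exceed {_CAP_GUARD}; the enumeration "
                "is combinatorial in the caps — pass allow_large_caps=True to force"
            )
        spec = CompletionSpec(k=k, h=h, K=K, H=H)
        table = dp_add_del(self.expr, self.network, spec, self.allow_self_loops)
        res = traceback(table)
        res.model = self
        return res


def complete_network(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    spec: CompletionSpec,
    allow_self_loops: bool = False,
) -> CompletionResults:
    """Functional form of :meth:`NetworkCompletion.fit`."""
    return NetworkCompletion(expr, network, allow_self_loops).fit(
        k=spec.k, h=spec.h, K=spec.K, H=spec.H
    )


def infer_network(
    expr: ExpressionMatrix,
    k: int,
    K: int = 2,
    allow_self_loops: bool = False,
) -> CompletionResults:
    """Network inference: completion of the edgeless network with h = H = 0."""
    return NetworkCompletion(expr, None, allow_self_loops).fit(k=k, h=0, K=K, H=0)
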