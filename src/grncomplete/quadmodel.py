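"""Per-node quadratic regulation model and its least-squares fit.

The steady-state value of a gene with parents x_{i1}, …, x_{ih} is modelled as

    x_i = a_0 + Σ_j a_j x_{ij} + Σ_{j ≤ k} a_{jk} x_{ij} x_{ik} + noise,

i.e. an intercept, linear effects, and pairwise (including squared)
interaction effects of its regulators; positive coefficients read as
activation, negative as inhibition.  The noise term is never estimated — it is
absorbed into the least-squares residual.  Fitting a node given a candidate
parent set means minimising

    S = Σ_s ( y_i(s) − model(y_parents(s)) )²

over the m samples; S is the quantity the completion layer compares across
candidate parent sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import RCOND, ExpressionMatrix

__all__ = ["NodeModel", "FitResult", "design_row", "fit_node", "node_error"]


def design_row(parent_values: Sequence[float]) -> np.ndarray:
    """Expand parent values into one design row of the quadratic model.

    The fixed ordering is: intercept 1, then the linear terms in the given
    parent order, then products ``x_j · x_k`` for j ≤ k in row-major order
    ((1,1), (1,2), …, (1,h), (2,2), (2,3), …, (h,h)).  An empty input yields
    the intercept-only row ``[1]``.
    """
    x = np.asarray(parent_values, dtype=float)
    h = x.size
    out = np.empty(1 + h + h * (h + 1) // 2)
    out[0] = 1.0
    out[1 : 1 + h] = x
    pos = 1 + h
    for j in range(h):
        out[pos : pos + h - j] = x[j] * x[j:]
        pos += h - j
    return out


@dataclass(frozen=True)
class NodeModel:
    """Fitted quadratic regulation rule for one gene.

    ``linear[j]`` multiplies parent j; ``quadratic[p]`` multiplies the p-th
    product term in :func:`design_row` order over ``parents``.
    """

    node: str
    parents: tuple[str, ...]
    intercept: float
    linear: np.ndarray
    quadratic: np.ndarray

    def __post_init__(self):
        h = len(self.parents)
        if self.linear.shape != (h,) or self.quadratic.shape != (h * (h + 1) // 2,):
            raise ValueError("coefficient shapes inconsistent with parent count")

    @property
    def n_parameters(self) -> int:
        h = len(self.parents)
        return 1 + h + h * (h + 1) // 2

    def coefficients(self) -> np.ndarray:
        """All coefficients in :func:`design_row` order."""
        return np.concatenate(([self.intercept], self.linear, self.quadratic))

    def predict(self, parent_values: Sequence[float]) -> float:
        """Model value for one sample's parent expression values."""
        return float(design_row(parent_values) @ self.coefficients())

    def predict_matrix(self, expr: ExpressionMatrix) -> np.ndarray:
        """Model values for every sample of ``expr``."""
        rows = np.array([expr.row(p) for p in self.parents], dtype=float)
        coef = self.coefficients()
        out = np.full(expr.n_samples, coef[0])
        h = len(self.parents)
        if h:
            out += coef[1 : 1 + h] @ rows
            pos = 1 + h
            for j in range(h):
                out += (coef[pos : pos + h - j] @ (rows[j] * rows[j:]))
                pos += h - j
        return out


@dataclass(frozen=True)
class FitResult:
    """A fitted :class:`NodeModel` plus the achieved objective value S.

    ``rank_deficient`` is set when the design matrix has deficient column rank
    (for example on replicated noiseless solutions); the coefficients are then
    the minimum-norm solution and the residual is still the global minimum.
    """

    model: NodeModel
    residual_error: float
    rank_deficient: bool


def _fit_canonical(expr: ExpressionMatrix, node: str, parent_rows: list[int]):
    """Least-squares fit with parents given as ascending row indices.

    Operates on the QR-compressed design (see
    :meth:`ExpressionMatrix.compressed_design`); solution and residual are
    identical to solving on the raw m-row design matrix.
    """
    r = expr.compressed_design()
    cols = expr.design_column_indices(parent_rows)
    x = r[:, cols]
    y = r[:, 1 + expr.gene_index(node)]
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=RCOND)
    resid = y - x @ beta
    return beta, float(resid @ resid), rank < len(cols)


def fit_node(expr: ExpressionMatrix, node: str, parents: Sequence[str]) -> FitResult:
    """Fit the quadratic model of ``node`` on the given parent set.

    Parents may be listed in any order: the fit is performed in a canonical
    (row-index-sorted) order and the coefficients are relabelled back, so the
    residual error is exactly invariant to parent-list permutation.
    """
    parents = tuple(parents)
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parents")
    node_idx = expr.gene_index(node)  # also validates presence
    rows = [expr.gene_index(p) for p in parents]
    order = np.argsort(rows, kind="stable")
    canonical_rows = [rows[i] for i in order]
    beta, err, deficient = _fit_canonical(expr, node, canonical_rows)

    h = len(parents)
    # invert the permutation: position of given parent j in canonical order
    pos_of = np.empty(h, dtype=int)
    pos_of[order] = np.arange(h)
    linear = np.empty(h)
    for j in range(h):
        linear[j] = beta[1 + pos_of[j]]

    def tri(a: int, b: int) -> int:
        # offset of product (a, b), a <= b, within the j<=k block for h parents
        return a * h - a * (a - 1) // 2 + (b - a)

    quadratic = np.empty(h * (h + 1) // 2)
    pos = 0
    for j in range(h):
        for k in range(j, h):
            a, b = sorted((pos_of[j], pos_of[k]))
            quadratic[pos] = beta[1 + h + tri(a, b)]
            pos += 1
    model = NodeModel(node, parents, float(beta[0]), linear, quadratic)
    return FitResult(model, err, deficient)


def node_error(expr: ExpressionMatrix, node: str, parents: Sequence[str]) -> float:
    """Minimal objective value S for ``node`` on the given parent set.

    Skips the coefficient-relabelling bookkeeping of :func:`fit_node`, which
    matters in the completion layer where millions of candidate errors may be
    evaluated.  Never returns +∞ — infeasible configurations are signalled by
    the completion layer, not here.
    """
    parents = tuple(parents)
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parents")
    rows = sorted(expr.gene_index(p) for p in parents)
    _, err, _ = _fit_canonical(expr, node, rows)
    return err
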