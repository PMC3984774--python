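"""Synthetic quadratic fixed-point systems with enumerable exact solutions.

Simulating steady-state expression data by integrating kinetic models is
awkward; instead we build systems of nonlinear equations whose exact solutions
are enumerable and treat each solution as one noiseless sample of a stationary
regulatory state.  Two rule kinds are used:

* **source** genes satisfy x = x² − c with c = r(r−1), giving the two integer
  roots r and 1 − r (the self-quadratic induces a self-loop in the gold
  network);
* **derived** genes are degree-≤2 polynomials in one or two *lower-indexed*
  genes (triangular structure), so every choice of source roots extends to
  exactly one full solution and the system has 2^(#sources) exact solutions.

A worked 3-gene exemplar (see :func:`three_gene_example`):

    x1 = x1² − 2,   x2 = x2² − 6,   x3 = x1·x2 − 1

with the four solutions (2,3,5), (2,−2,−5), (−1,3,−4), (−1,−2,1) and a gold
network of 3 genes and 4 edges including two self-loops.

Expression matrices are made by replicating each exact solution with
independent uniform noise on [−0.5, 0.5] per gene per replicate (400
replicates per solution by default, exact solutions kept alongside).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ExpressionMatrix, GeneNetwork
from .quadmodel import node_error

__all__ = [
    "SourceRule",
    "DerivedRule",
    "EquationSystem",
    "SolutionSet",
    "PerturbationConfig",
    "three_gene_example",
    "generate_system",
    "enumerate_solutions",
    "perturb",
    "modify_network",
]


@dataclass(frozen=True)
class SourceRule:
    """Self-quadratic rule x = x² − c with roots ``r`` and ``1 − r`` (c = r(r−1))."""

    gene: str
    r: int

    @property
    def c(self) -> int:
        return self.r * (self.r - 1)

    @property
    def roots(self) -> tuple[int, int]:
        return (self.r, 1 - self.r)

    @property
    def parents(self) -> tuple[str, ...]:
        return (self.gene,)

    def evaluate(self, values: dict[str, float]) -> float:
        x = values[self.gene]
        return x * x - self.c


@dataclass(frozen=True)
class DerivedRule:
    """Degree-≤2 polynomial rule in one or two parent genes.

    value = intercept + Σ_j linear[j]·x_pj + Σ_{j≤k} quadratic[(j,k)]·x_pj·x_pk
    """

    gene: str
    parents: tuple[str, ...]
    intercept: int
    linear: tuple[int, ...]
    quadratic: dict[tuple[int, int], int] = field(hash=False)

    def __post_init__(self):
        if not 1 <= len(self.parents) <= 2:
            raise ValueError("derived rules take 1 or 2 parents")
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parents in rule")
        if len(self.linear) != len(self.parents):
            raise ValueError("one linear coefficient per parent required")
        for j, k in self.quadratic:
            if not 0 <= j <= k < len(self.parents):
                raise ValueError("quadratic term indices out of range")

    def evaluate(self, values: dict[str, float]) -> float:
        x = [values[p] for p in self.parents]
        out = float(self.intercept)
        for a, xi in zip(self.linear, x):
            out += a * xi
        for (j, k), a in self.quadratic.items():
            out += a * x[j] * x[k]
        return out


@dataclass(frozen=True)
class EquationSystem:
    """A triangular quadratic fixed-point system and its induced gold network."""

    genes: tuple[str, ...]
    rules: tuple[SourceRule | DerivedRule, ...]

    def __post_init__(self):
        if len(self.rules) != len(self.genes):
            raise ValueError("one rule per gene required")
        seen: set[str] = set()
        for g, rule in zip(self.genes, self.rules):
            if rule.gene != g:
                raise ValueError("rules must be listed in gene order")
            if isinstance(rule, DerivedRule):
                bad = [p for p in rule.parents if p not in seen]
                if bad:
                    raise ValueError(
                        f"rule for {g} references non-lower-indexed genes {bad}"
                    )
            seen.add(g)

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(r.gene for r in self.rules if isinstance(r, SourceRule))

    def rule(self, gene: str) -> SourceRule | DerivedRule:
        return self.rules[self.genes.index(gene)]

    @property
    def network(self) -> GeneNetwork:
        """Gold-standard network: parent → gene edges, self-loops on sources."""
        edges = [(p, r.gene) for r in self.rules for p in r.parents]
        return GeneNetwork(self.genes, edges)

    def to_dict(self) -> dict:
        """YAML/JSON-serializable description of the system."""
        rules = []
        for r in self.rules:
            if isinstance(r, SourceRule):
                rules.append({"gene": r.gene, "kind": "source", "r": r.r, "c": r.c})
            else:
                rules.append(
                    {
                        "gene": r.gene,
                        "kind": "derived",
                        "parents": list(r.parents),
                        "intercept": r.intercept,
                        "linear": list(r.linear),
                        "quadratic": [[j, k, a] for (j, k), a in sorted(r.quadratic.items())],
                    }
                )
        return {"genes": list(self.genes), "rules": rules}

    @classmethod
    def from_dict(cls, d: dict) -> "EquationSystem":
        rules: list[SourceRule | DerivedRule] = []
        for r in d["rules"]:
            if r["kind"] == "source":
                rules.append(SourceRule(r["gene"], int(r["r"])))
            else:
                rules.append(
                    DerivedRule(
                        r["gene"],
                        tuple(r["parents"]),
                        int(r["intercept"]),
                        tuple(int(a) for a in r["linear"]),
                        {(int(j), int(k)): int(a) for j, k, a in r["quadratic"]},
                    )
                )
        return cls(tuple(d["genes"]), tuple(rules))


@dataclass(frozen=True)
class SolutionSet:
    """Exact fixed points of an :class:`EquationSystem`, one row per solution."""

    genes: tuple[str, ...]
    values: np.ndarray  # (n_solutions, n_genes)

    @property
    def n_solutions(self) -> int:
        return self.values.shape[0]

    def as_tuples(self) -> list[tuple[float, ...]]:
        return [tuple(float(v) for v in row) for row in self.values]


@dataclass(frozen=True)
class PerturbationConfig:
    """How exact solutions are replicated into noisy samples.

    Defaults are the study conditions: 400 replicates per solution, uniform
    noise on [−0.5, 0.5] added independently per gene per replicate, exact
    solutions kept in the matrix alongside the replicates.
    """

    replicates_per_solution: int = 400
    noise_half_width: float = 0.5
    include_exact_solutions: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.replicates_per_solution < 0:
            raise ValueError("replicates_per_solution must be nonnegative")
        if self.noise_half_width < 0:
            raise ValueError("noise_half_width must be nonnegative")


def three_gene_example() -> EquationSystem:
    """The 3-gene exemplar system (x1 = x1²−2, x2 = x2²−6, x3 = x1·x2−1)."""
    return EquationSystem(
        genes=("g1", "g2", "g3"),
        rules=(
            SourceRule("g1", 2),  # roots 2, −1
            SourceRule("g2", 3),  # roots 3, −2
            DerivedRule("g3", ("g1", "g2"), -1, (0, 0), {(0, 1): 1}),
        ),
    )


def enumerate_solutions(system: EquationSystem) -> SolutionSet:
    """All exact fixed points: Cartesian product over source roots.

    Derived genes are evaluated in index order (the system is triangular), and
    every returned vector is verified against every rule.
    """
    sources = [r for r in system.rules if isinstance(r, SourceRule)]
    sols = []
    for roots in itertools.product(*(s.roots for s in sources)):
        values: dict[str, float] = {
            s.gene: float(root) for s, root in zip(sources, roots)
        }
        for rule in system.rules:
            if isinstance(rule, DerivedRule):
                values[rule.gene] = rule.evaluate(values)
        vec = np.array([values[g] for g in system.genes])
        for rule in system.rules:
            resid = values[rule.gene] - rule.evaluate(values)
            if abs(resid) > 1e-12:
                raise AssertionError(
                    f"solution fails rule for {rule.gene} (residual {resid})"
                )
        sols.append(vec)
    return SolutionSet(system.genes, np.array(sols))


def perturb(
    solutions: SolutionSet, config: PerturbationConfig = PerturbationConfig()
) -> ExpressionMatrix:
    """Replicate exact solutions into a noisy expression matrix.

    Sample layout: for each solution, the exact vector first (if kept), then
    its replicates; every entry lies within ``noise_half_width`` of its source
    coordinate.  Deterministic given ``config.seed``.
    """
    if solutions.n_solutions == 0:
        raise ValueError("empty solution set")
    rng = np.random.default_rng(config.seed)
    cols: list[np.ndarray] = []
    names: list[str] = []
    reps = config.replicates_per_solution
    for i, sol in enumerate(solutions.values):
        if config.include_exact_solutions:
            cols.append(sol)
            names.append(f"sol{i + 1}")
        if reps:
            noise = rng.uniform(
                -config.noise_half_width,
                config.noise_half_width,
                size=(reps, len(solutions.genes)),
            )
            cols.extend(sol + noise)
            names.extend(f"sol{i + 1}_r{j + 1}" for j in range(reps))
    if not cols:
        raise ValueError("config keeps neither exact solutions nor replicates")
    return ExpressionMatrix(np.array(cols).T, solutions.genes, names)


# --------------------------------------------------------------- generation
_ROOT_CHOICES = (2, 3, 4, 5)
_MAX_ABS_VALUE = 30.0  # keep solution magnitudes at the worked-exemplar scale

#: variance of the uniform(−0.5, 0.5) observation noise
_NOISE_VAR = 1.0 / 12.0

#: cap on Σ_p (∂rule/∂x_p)² at every solution — bounds how much parent noise
#: a true rule propagates into its node's fitted residual
_DERIV_CAP = 60.0

#: upper bound on any node's per-sample noise-propagation variance under the
#: caps above: σ² · (1 + Σ ∂²)
_NP_CAP = _NOISE_VAR * (1.0 + _DERIV_CAP)


def _draw_derived_rule(
    rng: np.random.Generator,
    gene: str,
    pool: Sequence[str],
    supports: dict[str, frozenset[str]] | None = None,
) -> DerivedRule:
    """Draw one candidate rule for ``gene`` over the lower-indexed ``pool``.

    When ``supports`` maps pool genes to their source-gene ancestries, the
    draw is constrained so the rule's combined ancestry spans at least two
    sources whenever the pool allows it: a gene whose value is a function of a
    single source takes only two distinct values across the solution set and
    is affinely interchangeable with every other such gene, destroying
    identifiability of the gold structure.
    """
    n_par = 1 if (len(pool) == 1 or rng.random() < 0.25) else 2
    if supports is not None:
        wide = [g for g in pool if len(supports[g]) >= 2]
        distinct = len({supports[g] for g in pool if len(supports[g]) == 1}) >= 2
        if n_par == 1 and not wide and distinct and len(pool) >= 2:
            n_par = 2  # single-parent rule cannot span two sources here
        if n_par == 1 and wide:
            parent = wide[int(rng.integers(len(wide)))]
            par_tuple: tuple[str, ...] = (parent,)
        else:
            for _ in range(20):
                idx = sorted(rng.choice(len(pool), size=min(n_par, len(pool)), replace=False))
                par_tuple = tuple(pool[i] for i in idx)
                span = frozenset().union(*(supports[p] for p in par_tuple))
                if len(span) >= 2 or not (wide or distinct):
                    break
    else:
        idx = sorted(rng.choice(len(pool), size=n_par, replace=False))
        par_tuple = tuple(pool[i] for i in idx)
    parents = par_tuple
    n_par = len(parents)
    intercept = int(rng.integers(-6, 7))
    if n_par == 2 and rng.random() < 0.4:
        # plain product of parents, plus intercept
        return DerivedRule(gene, parents, intercept, (0, 0), {(0, 1): 1})
    nonzero = [a for a in range(-2, 3) if a != 0]
    linear = tuple(int(rng.integers(-2, 3)) for _ in range(n_par))
    if n_par == 1:
        quad = {(0, 0): int(rng.choice(nonzero))}
    else:
        quad = {(0, 1): int(rng.choice(nonzero))}
        if rng.random() < 0.3:
            quad[(0, 0)] = int(rng.integers(-1, 2))
    return DerivedRule(gene, parents, intercept, linear, quad)


def _noise_propagation(rule: SourceRule | DerivedRule, sols: SolutionSet) -> float:
    """Per-sample noise-propagation variance of the true fit of ``rule``.

    With y = x + ε (ε uniform, variance σ²), the residual of a node fitted
    with its true rule on its true parents is ε_node minus the rule's
    first-order response to the parent noises, giving a per-sample variance of
    about σ² · (1 + mean_s Σ_p (∂f/∂x_p)²).  Source nodes keep a self-loop,
    so the identity fit x = x makes their true residual exactly zero.
    """
    if isinstance(rule, SourceRule):
        return 0.0
    gi = {g: i for i, g in enumerate(sols.genes)}
    x = [sols.values[:, gi[p]] for p in rule.parents]
    total = np.zeros(sols.n_solutions)
    for j in range(len(rule.parents)):
        deriv = np.full(sols.n_solutions, float(rule.linear[j]))
        for (a, b), coef in rule.quadratic.items():
            if a == b == j:
                deriv = deriv + 2.0 * coef * x[j]
            elif a == j:
                deriv = deriv + coef * x[b]
            elif b == j:
                deriv = deriv + coef * x[a]
        total = total + deriv**2
    return float(_NOISE_VAR * (1.0 + np.mean(total)))


def _max_sq_gradient(rule: DerivedRule, sols: SolutionSet) -> float:
    """max over solutions of Σ_p (∂rule/∂x_p)²."""
    gi = {g: i for i, g in enumerate(sols.genes)}
    x = [sols.values[:, gi[p]] for p in rule.parents]
    total = np.zeros(sols.n_solutions)
    for j in range(len(rule.parents)):
        deriv = np.full(sols.n_solutions, float(rule.linear[j]))
        for (a, b), coef in rule.quadratic.items():
            if a == b == j:
                deriv = deriv + 2.0 * coef * x[j]
            elif a == j:
                deriv = deriv + coef * x[b]
            elif b == j:
                deriv = deriv + coef * x[a]
        total = total + deriv**2
    return float(np.max(total))


def _margin(rule: SourceRule | DerivedRule, sols: SolutionSet) -> float:
    """Required mean per-sample misfit for any alternative parent set.

    An alternative set beats the truth only if its structural misfit is below
    the truth's noise-propagation variance (minus the alternative's own, plus
    sampling fluctuation); an extra "proxy" parent on another node can gain at
    most about half that node's propagation variance.  Requiring every
    alternative to misfit by the node's own propagation variance plus the
    worst-case propagation bound (plus one) therefore keeps exact structure
    recovery the strict optimum under the ±0.5 replicate noise.

    A source node's true fit is the exact identity through its self-loop
    (residual 0), so any clearly positive misfit suffices there.
    """
    if isinstance(rule, SourceRule):
        return 0.25
    return _noise_propagation(rule, sols) + _NP_CAP + 1.0


def _identifiable(system: EquationSystem, solutions: SolutionSet) -> bool:
    """True when the solution set pins down every node's parent set.

    For each node with true parent set P (size d), every alternative parent
    set Q ≠ P with |Q| ≤ d drawn from the other genes must leave a mean
    per-sample squared error of at least :func:`_margin` of the node's
    noise-propagation variance.  This excludes systems in which regulators are
    interchangeable (affinely dependent value vectors, invertible product
    chains, duplicated rules), which would make structure recovery from noisy
    replicates a coin flip.
    """
    expr = ExpressionMatrix(solutions.values.T, system.genes)
    m = solutions.n_solutions
    for rule in system.rules:
        node = rule.gene
        true_set = frozenset(rule.parents)
        d = len(true_set)
        theta = _margin(rule, solutions)
        others = [g for g in system.genes if g != node]
        for size in range(d + 1):
            for q in itertools.combinations(others, size):
                qset = frozenset(q)
                if qset == true_set:
                    continue
                if node_error(expr, node, q) / m < theta:
                    return False
    return True


def generate_system(
    n: int,
    n_sources: int,
    max_parents: int = 2,
    seed: int | None = None,
    max_attempts: int = 200,
) -> EquationSystem:
    """Draw a random triangular system with ``n`` genes and enumerable solutions.

    The first ``n_sources`` genes are self-quadratic sources (integer roots r
    and 1 − r, r drawn from {2,…,5}); the rest draw 1–2 lower-indexed parents
    and an integer-coefficient degree-≤2 rule with intercept in [−6, 6].
    Candidate systems whose solution values explode, or whose solutions do not
    uniquely identify the structure (see :func:`_identifiable`), are rejected
    and redrawn.  Deterministic given ``seed``.
    """
    if not 1 <= n_sources <= n:
        raise ValueError("need 1 <= n_sources <= n")
    if n > n_sources and n_sources == 0:
        raise ValueError("derived genes need a nonempty parent pool")
    if not 1 <= max_parents <= 2:
        raise ValueError("max_parents must be 1 or 2")
    genes = tuple(f"g{i + 1}" for i in range(n))
    root_rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        rng = np.random.default_rng(root_rng.integers(0, 2**31))
        rules: list[SourceRule | DerivedRule] = [
            SourceRule(genes[i], int(rng.choice(_ROOT_CHOICES)))
            for i in range(n_sources)
        ]
        supports: dict[str, frozenset[str]] = {
            genes[i]: frozenset((genes[i],)) for i in range(n_sources)
        }
        ok = True
        for i in range(n_sources, n):
            pool = genes[:i]
            rule = None
            for _ in range(80):
                cand = _draw_derived_rule(rng, genes[i], pool, supports)
                if max_parents == 1 and len(cand.parents) > 1:
                    continue
                if _rule_acceptable(genes[: i + 1], tuple(rules), cand):
                    rule = cand
                    break
            if rule is None:
                ok = False
                break
            rules.append(rule)
            supports[genes[i]] = frozenset().union(
                *(supports[p] for p in rule.parents)
            )
        if not ok:
            continue
        system = EquationSystem(genes, tuple(rules))
        if _identifiable(system, enumerate_solutions(system)):
            return system
    raise RuntimeError(
        f"no identifiable system found in {max_attempts} attempts "
        f"(n={n}, n_sources={n_sources})"
    )


def _rule_acceptable(
    genes: tuple[str, ...],
    rules: tuple[SourceRule | DerivedRule, ...],
    cand: DerivedRule,
) -> bool:
    """Incrementally accept one candidate rule during generation.

    Checks, on the exact solutions of the partial system extended by ``cand``:
    magnitude and gradient caps; identifiability of the new node against all
    alternative parent sets of its size or smaller; and that the new gene does
    not make any *earlier* node's parent set substitutable (every alternative
    set containing the new gene must stay above that node's margin).
    """
    trial = EquationSystem(genes, rules + (cand,))
    try:
        sols = enumerate_solutions(trial)
    except AssertionError:
        return False
    vals = sols.values
    if np.max(np.abs(vals)) > _MAX_ABS_VALUE:
        return False
    if _max_sq_gradient(cand, sols) > _DERIV_CAP:
        return False
    expr = ExpressionMatrix(vals.T, genes)
    m = sols.n_solutions
    node = cand.gene
    true_set = frozenset(cand.parents)
    d = len(true_set)
    theta = _margin(cand, sols)
    others = [g for g in genes if g != node]
    for size in range(d + 1):
        for q in itertools.combinations(others, size):
            if frozenset(q) == true_set:
                continue
            if node_error(expr, node, q) / m < theta:
                return False
    # does the new gene break an earlier node's identifiability?
    for rule in rules:
        t = rule.gene
        d_t = len(rule.parents)
        theta_t = _margin(rule, sols)
        rest = [g for g in genes if g not in (t, node)]
        for extra in range(d_t):
            for c in itertools.combinations(rest, extra):
                q = (node,) + c
                if frozenset(q) == frozenset(rule.parents):
                    continue
                if node_error(expr, t, q) / m < theta_t:
                    return False
    return True


def modify_network(
    network: GeneNetwork,
    k_add: int,
    h_del: int,
    seed: int | None = None,
    recoverable_only: bool = True,
) -> tuple[GeneNetwork, frozenset[tuple[str, str]], frozenset[tuple[str, str]]]:
    """Randomly damage a network: add ``k_add`` absent edges, delete ``h_del``.

    With ``recoverable_only`` (the default) the damage stays reversible by the
    completion procedure's candidate rules: deletions avoid self-loops (a
    deleted self-loop could never be re-added) and additions avoid self-loops
    (an added self-loop would make the node's fit trivially exact).  Returns
    the damaged network together with the ground-truth added and deleted edge
    sets.  Deterministic given ``seed``.
    """
    if k_add < 0 or h_del < 0:
        raise ValueError("modification counts must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = network.genes
    present = sorted(network.edges)
    absent = [
        (u, v)
        for u in genes
        for v in genes
        if (u, v) not in network.edges and (not recoverable_only or u != v)
    ]
    deletable = [
        (u, v) for (u, v) in present if not (recoverable_only and u == v)
    ]
    if k_add > len(absent):
        raise ValueError(f"cannot add {k_add} edges: only {len(absent)} candidates")
    if h_del > len(deletable):
        raise ValueError(f"cannot delete {h_del} edges: only {len(deletable)} deletable")
    added_idx = rng.choice(len(absent), size=k_add, replace=False) if k_add else []
    deleted_idx = rng.choice(len(deletable), size=h_del, replace=False) if h_del else []
    added = frozenset(absent[i] for i in added_idx)
    deleted = frozenset(deletable[i] for i in deleted_idx)
    return network.with_modifications(added, deleted), added, deleted
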