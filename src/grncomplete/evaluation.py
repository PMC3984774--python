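"""Accuracy metrics and the averaged synthetic benchmark harness.

Two accuracy notions are used throughout:

* **completion accuracy** compares the completed network against the original
  (pre-damage) network given the modification budgets k and h:

      acc = (h + k + |E_org ∩ E_cmp| − |E_org|) / (h + k)

  which is 1 when every added and deleted edge is correct and 0 when none are;

* **inference accuracy** is the fraction of original edges recovered,
  |E_org ∩ E_inf| / |E_org| in directed mode; in undirected mode an inferred
  pair counts as correct if either orientation is an original edge, each
  unordered original pair creditable at most once (the scoring used for
  correlation-based tools, whose output is undirected).

The benchmark harness generates a synthetic system once, perturbs its exact
solutions into an expression matrix, then for a set of damage seeds randomly
modifies the gold network, runs completion (or inference from the edgeless
network), and reports per-run and mean accuracies.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .completion import CompletionSpec, NetworkCompletion
from .data import ExpressionMatrix, GeneNetwork
from .synthetic import (
    EquationSystem,
    PerturbationConfig,
    enumerate_solutions,
    generate_system,
    modify_network,
    perturb,
)

__all__ = [
    "AccuracyReport",
    "completion_accuracy",
    "inference_accuracy",
    "run_benchmark",
]

Mode = Literal["directed", "undirected"]


def completion_accuracy(
    e_org: set[tuple[str, str]],
    e_cmp: set[tuple[str, str]],
    k: int,
    h: int,
) -> float:
    """Completion accuracy (h + k + |E_org ∩ E_cmp| − |E_org|) / (h + k).

    Requires k + h ≥ 1.  A negative value indicates the inputs violate the
    modification-budget assumptions (the completed network differs from the
    original by more than k + h edges); a warning is attached in that case.
    """
    if k + h < 1:
        raise ValueError("completion accuracy is undefined for k + h = 0")
    e_org = set(e_org)
    e_cmp = set(e_cmp)
    acc = (h + k + len(e_org & e_cmp) - len(e_org)) / (h + k)
    if acc < 0:
        warnings.warn(
            f"completion accuracy {acc:.3f} < 0: the completed network differs "
            f"from the original by more than k + h = {k + h} edges",
            stacklevel=2,
        )
    return acc


def inference_accuracy(
    e_org: set[tuple[str, str]],
    e_inf: set[tuple[str, str]],
    mode: Mode = "directed",
) -> float:
    """Fraction of original edges correctly inferred.

    Directed mode counts exact ordered matches.  Undirected mode credits an
    inferred pair when either orientation is in the original edge set, with
    each unordered original pair creditable at most once (so the value never
    exceeds 1).
    """
    e_org = set(e_org)
    if not e_org:
        raise ValueError("original edge set must be nonempty")
    if mode == "directed":
        return len(e_org & set(e_inf)) / len(e_org)
    if mode != "undirected":
        raise ValueError(f"unknown matching mode {mode!r}")
    org_pairs = {frozenset((u, v)) for u, v in e_org}
    inf_pairs = {frozenset((u, v)) for u, v in e_inf}
    return len(org_pairs & inf_pairs) / len(org_pairs)


@dataclass
class RunRecord:
    """One benchmark run: its seed, damage, score and wall time."""

    seed: int | None
    accuracy: float
    added: tuple[tuple[str, str], ...]
    deleted: tuple[tuple[str, str], ...]
    matched_edges: tuple[tuple[str, str], ...]
    unmatched_edges: tuple[tuple[str, str], ...]
    wall_time_s: float
    feasible: bool


@dataclass
class AccuracyReport:
    """Per-run accuracies and their mean for one benchmark configuration."""

    task: Literal["completion", "inference"]
    matching_mode: Mode
    spec: CompletionSpec
    runs: list[RunRecord] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        if not self.runs:
            raise ValueError("no runs recorded")
        return float(np.mean([r.accuracy for r in self.runs]))

    @property
    def accuracies(self) -> list[float]:
        return [r.accuracy for r in self.runs]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "matching_mode": self.matching_mode,
            "spec": {
                "k": self.spec.k,
                "h": self.spec.h,
                "K": self.spec.K,
                "H": self.spec.H,
            },
            "mean_accuracy": self.mean_accuracy,
            "runs": [
                {
                    "seed": r.seed,
                    "accuracy": r.accuracy,
                    "added": sorted(map(list, r.added)),
                    "deleted": sorted(map(list, r.deleted)),
                    "matched_edges": sorted(map(list, r.matched_edges)),
                    "unmatched_edges": sorted(map(list, r.unmatched_edges)),
                    "wall_time_s": r.wall_time_s,
                    "feasible": r.feasible,
                }
                for r in self.runs
            ],
        }


def run_benchmark(
    system: EquationSystem | None,
    spec: CompletionSpec,
    n_runs: int = 5,
    seeds: Sequence[int] | None = None,
    *,
    task: Literal["completion", "inference"] = "completion",
    matching_mode: Mode = "directed",
    perturbation: PerturbationConfig | None = None,
    expr: ExpressionMatrix | None = None,
    n: int | None = None,
    n_sources: int | None = None,
    system_seed: int | None = None,
    inference_k: int | None = None,
    allow_self_loops: bool = False,
) -> AccuracyReport:
    """Run the averaged synthetic benchmark.

    Completion task, per run seed: damage the gold network by deleting
    ``spec.k`` true (non-self-loop) edges and adding ``spec.h`` spurious
    edges, complete the damaged network with budgets (k, h) and caps (K, H),
    and score with :func:`completion_accuracy` against the gold network.

    Inference task: complete the edgeless network with ``inference_k``
    additions (default: the number of gold edges) and H = 0, scoring with
    :func:`inference_accuracy`; the run seeds only label the runs, as the
    expression data are generated once.

    Either pass a ready ``system`` (optionally with a precomputed ``expr``) or
    ``n``/``n_sources``/``system_seed`` to generate one.  Wall time per run is
    informational only.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if task == "completion" and spec.k + spec.h < 1:
        raise ValueError("completion benchmark needs k + h >= 1")
    if system is None:
        if n is None or n_sources is None:
            raise ValueError("pass a system or n and n_sources")
        system = generate_system(n, n_sources, seed=system_seed)
    if expr is None:
        expr = perturb(enumerate_solutions(system), perturbation or PerturbationConfig())
    gold = system.network
    if seeds is None:
        root = np.random.default_rng(system_seed)
        seeds = [int(s) for s in root.integers(0, 2**31, size=n_runs)]
    else:
        seeds = list(seeds)
        if len(seeds) != n_runs:
            raise ValueError("len(seeds) must equal n_runs")

    report = AccuracyReport(task=task, matching_mode=matching_mode, spec=spec)
    for seed in seeds:
        t0 = time.perf_counter()
        if task == "completion":
            damaged, dmg_added, dmg_deleted = modify_network(
                gold, k_add=spec.h, h_del=spec.k, seed=seed
            )
            res = NetworkCompletion(expr, damaged, allow_self_loops).fit(
                k=spec.k, h=spec.h, K=spec.K, H=spec.H
            )
            if res.feasible:
                assert res.completed is not None
                acc = completion_accuracy(
                    set(gold.edges), set(res.completed.edges), spec.k, spec.h
                )
                result_edges = set(res.completed.edges)
            else:
                acc = 0.0
                result_edges = set()
            record_damage = (tuple(sorted(dmg_added)), tuple(sorted(dmg_deleted)))
        elif task == "inference":
            k_inf = inference_k if inference_k is not None else len(gold.edges)
            res = NetworkCompletion(expr, None, allow_self_loops).fit(
                k=k_inf, h=0, K=spec.K, H=0
            )
            if res.feasible:
                assert res.completed is not None
                acc = inference_accuracy(
                    set(gold.edges), set(res.completed.edges), matching_mode
                )
                result_edges = set(res.completed.edges)
            else:
                acc = 0.0
                result_edges = set()
            record_damage = ((), ())
        else:
            raise ValueError(f"unknown task {task!r}")
        matched = tuple(sorted(set(gold.edges) & result_edges))
        unmatched = tuple(sorted(result_edges - set(gold.edges)))
        report.runs.append(
            RunRecord(
                seed=seed,
                accuracy=acc,
                added=record_damage[0],
                deleted=record_damage[1],
                matched_edges=matched,
                unmatched_edges=unmatched,
                wall_time_s=time.perf_counter() - t0,
                feasible=res.feasible,
            )
        )
    return report
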