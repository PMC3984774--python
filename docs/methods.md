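# Methods

## Model and assumptions

Each gene's stationary expression is a full quadratic in its regulators'
expression: intercept, linear terms, and all pairwise products including
squares (for *h* parents, 1 + h + h(h+1)/2 coefficients).  The observation
noise enters additively and is never estimated — it is absorbed into the
least-squares residual.  Samples are treated as independent observations of
the same stationary state; no standardisation, centring or log transform is
applied (any preprocessing is the caller's responsibility), and the model is
fitted to raw values.

Two structural consequences matter in practice:

* **Nested parent sets.**  Enlarging a parent set can never increase the
  minimal residual, so raw error comparisons are only meaningful between
  parent sets reachable under the same modification budget — which is exactly
  what the budgeted search enforces.
* **Self-loops are self-certifying.**  If a gene is its own parent, the
  identity assignment (unit linear coefficient on itself) reproduces every
  sample exactly, so a node with a self-loop always has residual zero.  This
  is why candidate parents for *additions* exclude the gene itself by
  default: an addable self-loop would make every node's error vanish and the
  search degenerate.  The `allow_self_loops` flag lifts the exclusion for
  users who accept that behaviour; note it raises the attainable-error floor
  question for inference, where no self-loop can otherwise ever be recovered.

## Completion search

σ_{k_j,h_j,j} enumerates every disjoint choice of h_j deleted current parents
and k_j added candidate parents (deleted ⊆ current parents and added ⊆
non-parents, so disjointness is structural), fitting each resulting parent
set.  Entries are +∞ when k_j > K, h_j > H, k_j − h_j + deg⁻ ≥ n,
k_j − h_j + deg⁻ < 0, or the enumeration is empty.  The per-node tables feed
a dynamic program over genes whose final cell is the exact optimum for the
global budgets; a recorded-split traceback reconstructs the edge sets.  σ
entries have no cross-dependencies (they are memoized lazily and could be
filled in parallel).

Caps above K = 3 or H = 3 are refused without an explicit override because
the enumeration is C(n, K)-combinatorial; completion should start from sparse
networks, not dense ones.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| k, h | — | exact numbers of edges to add / delete (budgets, not maxima) |
| K, H | 2, 2 | per-node caps on additions / deletions; K = 2, H = 0 for inference |
| allow_self_loops | off | permit self-loop additions (see above) |
| replicates_per_solution | 400 | noisy replicates per exact solution |
| noise_half_width | 0.5 | uniform observation noise support is ±this |
| include_exact_solutions | on | keep the exact solutions in the matrix |

## Numerical choices

* Every fit solves min-norm least squares with a singular-value cutoff of
  1e-10 relative to the largest singular value; rank deficiency (e.g.
  replicated noiseless solutions) is flagged, not fatal.
* All candidate fits of one expression matrix are solved on a shared
  QR-compressed design: the column universe [1, x_i, x_i·x_j (i ≤ j)] is
  QR-factorised once, and each candidate design is a column slice of the R
  factor.  Because every response is itself a column of the universe (hence
  in range(Q)), singular values, min-norm solutions and residuals are
  *identical* to solving on the raw m-row design; the per-fit cost becomes
  independent of the sample count.  This is what keeps the ~10⁴ fits of a
  20-gene completion run in seconds.
* Residuals are computed explicitly as squared norms, so exact fits report
  ~1e-25 rather than relying on the solver's residual output.
* +∞ is the IEEE infinity, propagated through min() only; no arithmetic is
  performed on infeasible entries beyond addition with finite values.
* Ties among equal-error edge sets resolve to the lexicographically smallest
  (sorted deleted set, then added set, in gene order); ties among DP splits
  prefer the smallest per-node addition budget, then deletion budget.  Both
  exist purely for determinism; the *optimal value* never depends on them.
* Fitting is invariant to parent-list permutation: parents are canonicalised
  to gene order internally and coefficients relabelled back, so the residual
  is bitwise identical across orderings.

## Synthetic data

Steady-state data are hard to simulate kinetically, so benchmark systems are
triangular quadratic fixed-point systems with enumerable exact solutions:
source genes obey x = x² − c with c = r(r−1) (integer roots r and 1 − r,
r ∈ {2,…,5}, giving a self-loop), and each derived gene is an
integer-coefficient degree-≤2 rule in 1–2 lower-indexed genes (intercept in
[−6, 6]).  A system with s sources has exactly 2^s solutions; each solution
is replicated with independent uniform(±0.5) noise per gene.

Random rule drawing is filtered by three acceptance checks, applied
incrementally per gene and once more on the finished system:

1. **Magnitude cap** (|x| ≤ 30 at every solution): keeps values at the
   worked-exemplar scale so the ±0.5 noise is neither negligible nor
   overwhelming.
2. **Gradient cap** (Σ_p (∂rule/∂x_p)² ≤ 60 at every solution): bounds how
   much parent noise the true rule propagates into its node's residual.
3. **Identifiability margin**: on the exact solutions, every alternative
   parent set of a node (of its true size or smaller, over all other genes)
   must leave a mean per-sample error of at least the node's own
   noise-propagation variance plus the worst-case propagation bound (plus
   one); for sources, whose true residual is exactly zero, any clearly
   positive misfit (0.25) suffices.  This rejects systems in which
   regulators are interchangeable — duplicated rules, genes whose ancestry
   collapses to a single two-valued source (their value vectors are affinely
   dependent), and invertible product chains where a child and a co-parent
   reconstruct a parent exactly.  Without the filter, structure recovery on
   such systems is a coin flip no method could win; with it, the true
   network is the strict optimum of the budgeted search under the stated
   noise, which is the regime the completion benchmark is meant to probe.

One further practical consequence of the margin: identifiable systems need at
least two source genes (a single source makes every descendant a two-valued
affine clone of it), and generation is easiest when derived rules span two or
more sources — the generator tracks each gene's source ancestry and biases
draws accordingly.

Random damage (`modify_network`) deletes present edges and adds absent ones
uniformly; with `recoverable_only` (default) both avoid self-loops, since a
deleted self-loop could never be re-added under the candidate rule and an
added one would be self-certifying.  Damage is *not* constrained by the
per-node caps K and H: three spurious edges can land on one node and exceed
what an H = 2 completion can delete there, occasionally costing one edge of
accuracy at the largest budgets — visible as rare 0.975 run means in the
k = h = 4 cell, and consistent with accuracy decaying only at the largest
damage sizes.

**What the generator does not emulate:** kinetic/ODE dynamics, measurement
models of real microarrays (probe effects, heteroscedastic noise,
normalisation artefacts), unobserved regulators, and rule forms outside
degree-2 polynomials.  Passing benchmarks therefore demonstrate that the
search recovers planted structure exactly when the data-generating family
matches the model class and the structure is identifiable — not that the
method attains similar accuracy on real expression data.

## Study conditions used by tests and the acceptance script

* 10-gene systems: 5 sources → 32 exact solutions, m = 32·401 = 12,832
  samples; benchmark cells k = h = 1 and k = h = 4.
* 20-gene systems: 8 sources → 256 exact solutions, m = 256·401 = 102,656
  samples; benchmark cell k = h = 2.  Eight sources (rather than the minimum
  that still identifies) are used because twenty genes need a diverse pool of
  source pairs for distinct identifiable rules.
* Five damage seeds per cell; the reported number is the mean of the five
  per-run accuracies (h + k + |E_org ∩ E_cmp| − |E_org|)/(h + k).
* Completion caps K = H = 2 throughout; inference uses K = 2, H = 0.

## Known limitations

* The per-node enumeration is exponential in the caps; K, H ≤ 2 is the
  practical regime, and dense initial networks (deg⁻ comparable to n) are out
  of scope.
* Exactly-k/exactly-h budgets mean the user must know (or scan) the
  modification counts; the method does not select k and h itself.
* Directed-edge scoring is the default for the method's own output; the
  undirected mode exists for comparing against correlation-based tools whose
  output has no orientation.
* Wall-clock time is reported in benchmark records but is never part of any
  assertion — it is hardware-dependent.
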