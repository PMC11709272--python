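# Methods

## Model and assumptions

The learner targets a linear Gaussian structural equation model on an
unknown DAG G = (V, E), |V| = p:

    Y_j = Σ_{k ∈ pa(j)} β_jk Y_k + U_j,     U_j ~ N(0, σ²) i.i.d.

with one common error variance σ². Equal error variances are what make the
*exact* DAG identifiable from the observational distribution — without
this (or an ordering among the noise variances, or non-Gaussianity, or
nonlinearity) only the Markov equivalence class is identifiable. The key
consequence exploited here: the full conditional variance
var(Y_j | Y_{−j}) = 1/ω_jj is maximal at sink nodes, so the diagonal of
the precision matrix Ω = Σ⁻¹ reveals a terminal vertex, and peeling
terminals backwards yields a topological order.

Edge convention throughout: a stored pair (k, j) means k → j, the
coefficient β_jk attaches to that edge, and all matrices are laid out rows
= source k, columns = target j.

## Stage 1: ordering

**Knowledge-based.** A prior graph (e.g. a curated pathway) is first
restricted to the nodes present in the data, then converted to a DAG:
self-loops are removed and a depth-first traversal, started from nodes in
ascending label order, deletes every back edge as encountered. Any
deterministic cycle-breaking rule would do; DFS back-edge deletion is used
because it touches the minimum needed to destroy each cycle found and is
reproducible bit-for-bit. An already-acyclic prior passes through
unchanged. The vertex order is the lexicographic topological sort (ties by
label, for determinism); the layer order is the unique partition
L0 = sources, Lj = sources of the subgraph after removing L0..L(j−1),
computed by iterative leaf removal on the transposed graph (leaves of the
transpose are exactly the sources of the original). Note that leaf removal
on the *untransposed* graph groups nodes by distance-to-sink, which is a
different partition (e.g. on {a→b→c, d→c} it puts d beside b rather than
in the source layer); only the transpose-side peeling satisfies the
recursive definition, and that is what `layer_decomposition` returns.

**Bottom-up (data-driven).** Iteratively: form the second-moment matrix of
the remaining columns (centered; divided by n), estimate Ω̂ by the
graphical lasso with off-diagonal penalty λ, select the node with minimal
ω̂_jj (vertex mode; label order breaks exact ties) or the set
{j : ω̂_jj ≤ min ω̂ + η} (layer mode), append to the reversed ordering,
drop those columns, repeat until one node (or the top layer) remains, then
reverse. Re-estimation happens from the reduced data matrix at each
iteration rather than by matrix down-dating — it follows the loop as
stated and is easier to verify; at these problem sizes the cost is
negligible. A covariance-input variant (`bottomup_order_from_covariance`)
runs the identical loop on a fixed matrix by sub-setting it, which lets
tests feed the exact population covariance and check the population-level
behaviour with no sampling noise.

*Covariance, not correlation, by default.* Standardising each variable to
unit variance rescales the precision diagonal by the marginal variances
(diag of the correlation-scale precision is ω_jj·σ_jj), which destroys the
equal-variance ordering signal: for the 3-chain with β = 0.8 the
correlation-scale diagonals are (1.64, 2.69, 2.05), putting the *minimum
at the source* and inverting the sweep. The default is therefore the
covariance scale; `scale=True` remains available for pipelines that demand
scale invariance, with the caveat that ordering consistency is then no
longer guaranteed by the theory.

*Graphical-lasso penalty.* λ = 0.001 when n > p, and sqrt(log p / n) when
n ≤ p. The square-root rate is the standard high-dimensional choice for
sparse inverse-covariance estimation; a flat log(p)/n variant is exposed
(`hd_rule="flat"`). The default is computed once from the full matrix
dimensions and held fixed across iterations of the sweep, so the penalty
does not drift as columns are removed. The solver is scikit-learn's
graphical-lasso coordinate descent (penalty on off-diagonals only,
matching the objective); at near-zero penalties the dual gap can stall at
a tiny, even slightly negative, value — the estimate is still usable, so
that alone does not raise. The coordinate-descent solver can also fail
outright ("non-SPD result") on some comfortably invertible matrices at
near-zero penalties; because the penalised optimum then differs from the
MLE S⁻¹ by at most O(λ), λ ≤ 0.01 falls back to the exact inverse with a
warning, while larger penalties — where the L1 term genuinely shapes the
solution — or an effectively singular S still raise.

*Layer tolerance η.* Default 0.05 when layer mode is requested without a
value. η = 0 collapses layer mode to vertex mode on noiseless input (up to
tie handling). An adaptive variant estimates η as the mean absolute
difference between split-half precision diagonals — a direct gauge of the
sampling noise on ω̂_jj, hence of how large a diagonal gap must be to be
taken seriously. It requires n > 100 (each half must support a stable
precision estimate); the split is a seeded shuffle by default, with a
deterministic first-half/second-half option under which duplicated data
give exactly 0. This estimator is one reasonable realisation of
"adaptively from half the sample"; it is deliberately simple and its
construction, not any claimed optimality, is what is documented and
tested.

## Stage 2: parent learning

Each node j with a non-empty candidate set S_j (all strictly earlier
nodes, or the union of strictly earlier layers — same-layer edges are
never considered) is fit by weighted LASSO on centred data, no intercept:

    β̂_j ∈ argmin ‖Y_j − Σ_{k∈S_j} β_jk Y_k‖²/(2n) + λ_j Σ_k w_jk |β_jk|.

Vertex mode fits exactly p − 1 regressions, layer mode exactly p − |L0|.

**Penalty factors.** With a prior graph and `penalty=True`, known edges get
w = 0 and everything else w = 1, so known edges are never shrunk (and
therefore always retained at β = 0) while new edges must earn their way in
against the penalty. Candidates are *all* ordering-preceding nodes, not
just known parents — otherwise no new connection could ever be discovered.
The w = 0 block is handled exactly by profiling: minimising over the
unpenalised coefficients first reduces the problem to an ordinary LASSO on
the response and penalised columns projected off the span of the
unpenalised columns (QR-based), after which the unpenalised coefficients
are recovered by least squares on the partial residual. This is
algebraically identical to solving the weighted objective directly and was
cross-checked against R glmnet with matching penalty factors (agreement to
~1e-7 on a fixture).

**Standardisation.** Columns are standardised inside each nodewise
regression (penalty comparability across genes with different variances)
and coefficients are reported back on the original scale. This is internal
to stage 2 and unrelated to the stage-1 covariance/correlation choice.

**Choosing λ_j.** The default (`auto`) uses 10-fold cross-validation for
p ≤ 100 and BIC (n·log(RSS/n) + log(n)·df, df = nonzero count) above, over
a 100-point log-spaced path from the KKT zero threshold max|Xᵀy|/n down to
a 1e-4 (n > k) or 1e-2 fraction of it. CV uses the **one-standard-error
rule**: the largest λ whose mean held-out error is within one SE of the
minimum. The CV-*minimum* is prediction-optimal but systematically
over-selects for support recovery — under the recovery benchmark below it
yields a false-discovery rate around 0.66 (BIC: 0.33), versus ≈ 0.15 for
the 1-SE rule at unchanged true-positive rate 1.0. `cv_rule="min"`
restores the minimiser. Fold assignment is a seeded shuffle, making runs
bit-reproducible. A tuning-free closed form λ = z(1 − α/(2p(j−1)))/n
(j = 1-based ordering position; α default 0.05) is available, implemented
with divisor n as printed in the tuning-free literature it follows, with a
sqrt(n) divisor exposed; a user-supplied λ vector is scored per node by
the same CV/BIC criterion and the best value kept.

**Thresholding.** Edge (k, j) survives iff |β̂_jk| > β, strict, so the
default β = 0 removes exact zeros only. Acyclicity is guaranteed by
construction (all candidate edges point forward in the ordering). The
result is split into `dag_new` (not in the prior) and `dag_old` (present
in the prior), a disjoint partition of the estimated edge set.

## Simulator

`random_dag` draws a uniform node permutation and includes each forward
pair independently with probability `edge_prob`; `draw_weights` assigns
each edge a coefficient uniform on ±[0.5, 1.0] (fair sign coin) and σ = 1.
Magnitudes bounded away from zero keep every edge identifiable at moderate
n; sign balance prevents variance blow-up along long paths; σ = 1 is the
equal-variance regime the method assumes (a per-node override exists only
to demonstrate assumption violation). The closed-form population
covariance Σ = (I − Bᵀ)⁻¹ σ² (I − Bᵀ)⁻ᵀ serves as an exact oracle.

The generator emulates exactly the assumed data-generating process:
linear, Gaussian, homoscedastic, no hidden confounders, no measurement
error, i.i.d. rows. Passing tests therefore certify correctness *under
the model*, not robustness to the ways real expression data deviate from
it (heavy tails, batch structure, unequal noise, feedback loops, latent
drivers). The correlation-scale option and the per-node σ override are the
two hooks provided for probing such deviations.

## Evaluation metrics

SHD counts differing directed adjacency entries, so one reversed edge
costs 2 (a deletion plus an addition). The normalised variant divides by
the number of ordered pairs p(p−1), which guarantees [0, 1]; division by
p alone is available but can exceed 1. MCC is computed from the edge
confusion counts with the 0-on-degenerate-margins convention. Graph
descriptives use total (in + out) degree and directed, unnormalised,
unit-weight shortest-path betweenness. Path coefficients are per-node OLS
of each child on its parents (the Gaussian MLE given the structure);
prediction applies the train-set column means to test data — no
information flows from test to fit.

## Numerical choices and degenerate inputs

- All tie-breaks (topological sort roots, terminal selection, output
  listings) are by ascending node label; all randomness (CV folds,
  adaptive-η split, simulators) flows from explicit integer seeds.
- Zero-variance columns error out when correlations are requested; a
  rank-deficient parent matrix in the OLS refit errors naming the node; a
  response with zero variance cannot drive λ selection.
- Two-column data yield at most one edge, oriented by the bottom-up sweep;
  an edgeless or single-layer prior makes stage 2 trivially empty.
- LASSO solves use coordinate descent at tolerance 1e-8; the λ-path floor
  means "noiseless" fits leave residuals at the shrinkage scale of the
  smallest path value, not machine zero.

## Problem sizes used in the shipped checks

The acceptance script and test suite measure: layer decomposition against
an independent peeling oracle on 200 random DAGs (p ≤ 15); population
ordering on 100 random SEMs (p ≤ 10, λ = 1e-8, exact Σ); backward-edge
rates at p = 10 over n ∈ {100, 500, 5000} (20 seeds); end-to-end recovery
at p = 20, edge probability 0.1, n = 5000 (20 seeds; observed mean TPR
1.0, FDR ≈ 0.11–0.16 across seeds); structural invariants over 100 fuzzed
runs; the penalty contract over 10 seeds; simulator fidelity on 10⁶ rows
of a fixed 5-node SEM (empirical vs closed-form covariance within 1e-2
entrywise). These sizes keep a full run around one minute on a single CPU
while leaving the stochastic margins comfortable.

## Known limitations

- Identifiability rests on equal (or nearly ordered) error variances; with
  strongly heterogeneous noise the bottom-up sweep can invert parts of the
  order, and nothing in the procedure detects this.
- The ordering is estimated once and then conditioned on; uncertainty in
  the ordering is not propagated into the parent-selection stage.
- LASSO coefficients are biased toward zero by design; refit the selected
  structure with `fit_path_coefficients` when unbiased effect sizes
  matter.
- The DFS cycle-breaking rule for cyclic priors is one deterministic
  choice among many; different rules can yield different (all valid)
  DAGs from the same cyclic prior.
- The adaptive-η rule is a pragmatic stability estimate, not derived from
  any optimality criterion.
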