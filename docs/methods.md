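# Methods

## The chain model

St. Nicolas House Analysis treats the correlation matrix as the object of
inference. For each start variable a greedy walk ranks absolute
correlations in descending order: from the current variable it moves to
the unvisited variable with the largest |r|, stopping when the best
candidate has |r| below an absolute floor, is insignificant at the chosen
alpha, or no variable remains. A sequence of at least three members is an
*association chain* only if the walk restarted from its last member
retraces exactly the reversed sequence — neither diverging to another
variable nor extending past the original start. Reversibility is the
method's core filter: a greedy walk always produces *some* ordering, but
only orderings that are hierarchic from both ends are taken as evidence
of serial dependence. The union of consecutive pairs over all accepted
chains, signed by the correlation coefficient, is the final graph;
variables in no chain remain isolated nodes.

The walk's candidate set is the *unvisited* variables, so a walk can
never revisit its start or form a cycle. Arg-max ties are broken toward
the variable earliest in column order; ties have probability zero on
real-valued data but the rule makes every output deterministic and the
brute-force comparison in the test suite exact.

Failing the reversal check discards the whole sequence; no reversible
prefix is salvaged. A strongly correlated but isolated *pair* therefore
yields no edge — a 2-member sequence carries no ordering information —
and this is intended behavior.

### Ordering-consistency filter

An ordering of two variables established by one chain predetermines their
ordering in any other chain. Because a chain equals its reversal,
"ordering" is only defined up to orientation: two chains are judged
inconsistent when the induced sequence of their shared variables in one
matches neither the induced sequence in the other nor its reverse (with
fewer than three shared variables this can always be reconciled by
flipping one chain). Conflicts are resolved by dropping the shorter
chain; equal lengths drop the chain whose canonical form is
lexicographically larger. The filter is on by default and can be disabled
(`consistency_filter=False`) for exploration, since one can also read the
consistency property as a diagnostic rather than a constraint.

## Likelihood-ratio validation

A chain of k members asserts the factorization of the joint density into
first-order conditionals: each member normal given only its predecessor.
This is the only reading under which the degrees of freedom equal
C(k,2) − (k−1) = (k−1)(k−2)/2 — conditioning each member on *all*
predecessors would leave no restriction at all — so the restricted model
is the first-order Gaussian Markov chain: all non-adjacent partial
correlations vanish.

That model is decomposable (cliques are the adjacent pairs, separators
the interior singletons), so its MLE is closed-form and the deviance
against the saturated multivariate normal is

    chi2 = n * ( sum_adjacent log(1 - r_ab^2) - log det R ),

with R the sample correlation submatrix of the members. Natural
logarithms and the MLE multiplier n (not n−1) are used; likelihoods are
evaluated on the correlation scale, where means and variances cancel in
the ratio. The determinant-maximizing property of the Markov completion
guarantees chi2 ≥ 0; values more negative than −1e−6 raise an error,
smaller negative rounding noise is clamped to 0. Chains with a singular
submatrix or an adjacent |r| = 1 are rejected with a singularity error
rather than reported with infinite deviance; n ≤ k is an error. The
p-value is the right-tail chi-square probability; *small* p flags a chain
that fails to capture its members' dependencies. The test suite verifies
the closed form against an independent numeric maximizer of the
restricted likelihood and checks the asymptotic chi-square calibration
(empirical type-I error ≈ 0.05 at n = 200) on simulated Markov data.

## Model variance

Each node is regressed by OLS (with intercept) on its graph neighbors;
the *unadjusted* R² is recorded — unadjusted keeps the OLS nesting
property (adding a neighbor never lowers a node's R²) that the tests
assert. Isolated nodes count as 0 and the global score is the arithmetic
mean over *all* nodes, isolated ones included: the graph is scored
against the total variance of the variable set, and the convention keeps
the score comparable across alpha values that connect different node
subsets. Collinear neighbor sets fall back to the minimum-norm fit with a
warning. Binary 0/1 variables go through the same OLS definition.

## Tunable parameters

| parameter       | default    | meaning |
|-----------------|------------|---------|
| `abs_threshold` | 0.1        | minimal \|r\| for a walk step; the classical stopping floor of the algorithm |
| `alpha`         | 0.05       | significance level a correlation must reach to be ranked; graphs are typically stable for alpha in 0.05–0.20 |
| `method`        | `spearman` | rank correlations by default (robust to outliers and monotone transforms); `pearson` selectable and used where Gaussian likelihood calibration is itself under study |
| `consistency_filter` | on    | cross-chain ordering filter, see above |

Defaults for the baseline builders: threshold networks use strict
\|r\| > r_min; forward selection accepts a predictor only if the R²
increase is at least the R² floor *and* the partial F-test is significant
at alpha (both conditions simultaneously); selected target–predictor
pairs are symmetrized into undirected edges.

## Synthetic data

The generators emulate the three validation settings: (a) column
scrambling of a real table — independent permutation of each column,
destroying all cross-variable association while preserving marginals
exactly; (b) iid normal columns matched to a template's per-column mean
and variance; (c) linear-Gaussian acyclic systems (`PlantedStructure`)
with known ground truth, simulated in topological order with roots
standard normal and children coefficient-weighted parent sums plus
N(0, noise_sd²) noise. The closed-form implied covariance
Σ = (I−B)⁻¹D(I−B)⁻ᵀ of the same system serves as an independent oracle
for the generator.

The planted Markov path used throughout the recovery and calibration
experiments has 5 variables, unit coefficients, noise SD 0.5 and n = 500
(n = 200 for calibration), giving adjacent population correlations of
0.89–0.94 — strong serial structure a chain detector should recover
essentially always; the recovery experiment uses 100 seeded replicates,
the calibration experiment 2000. The null experiment follows the
20-scrambled + 20-random design at the 33×10 shape of the motivating
dataset, with a two-block hub template standing in for real data (for
edge counting on nulls only the shape matters: scrambling and resampling
destroy the template's correlation structure either way).

What these simulations do *not* emulate: non-Gaussian marginals,
nonlinear or non-monotone dependence, ordinal measurement, missingness
mechanisms, and latent confounding beyond what an acyclic linear system
expresses. Passing tests therefore demonstrate correctness of the
algorithmic and distributional machinery under the stated model, not
performance on arbitrary real data.

## Numerical choices and degenerate inputs

- p-values from r: two-sided t with n−2 df for both Pearson and Spearman
  (large-sample approximation for Spearman, mid-rank ties); |r| = 1 maps
  to p = 0, r = 0 to p = 1. Two-sided because chains rank |r|, making
  sign irrelevant to eligibility.
- Complete-case missing-data handling (`drop_rows`): the LR test and the
  OLS R² need one consistent n; pairwise-complete correlations are
  deliberately not offered on the core path.
- Correlation matrices read from file must be symmetric to 1e−8, have
  unit diagonal and entries in [−1, 1], and carry identical names in
  header and first column; they are then symmetrized exactly.
- Graph writers sort nodes and edges lexicographically; repeated runs are
  byte-identical. Weights are serialized at 17 significant digits so
  read/write round-trips are lossless to 1e−12.
- Zero-variance columns are an error wherever a correlation or a moment
  match is required, naming the offending column.

## Known limitations

- Edge sets are **not monotone** in the thresholds: raising the |r| floor
  or lowering alpha truncates walks earlier, and a truncated walk can
  pass the reversibility check where the longer walk failed, so a
  *stricter* setting can add edges. Empirically this affects roughly
  5–10% of random matrices. Alpha sweeps should therefore be read as a
  robustness display, not as a nested family.
- Chains are undirected; no causal orientation is attempted.
- No bootstrap-based chain significance; the LR test conditions on the
  detected chain and does not account for the selection step.
- The combinatorial candidate count I!/(I−k−1)!/2 grows fast; the greedy
  walk examines only I starts and is O(I²) per start, which is the
  method's practical appeal but also means it finds at most I chains per
  run.
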