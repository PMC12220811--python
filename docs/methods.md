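# Methods

## The model

`pmmtree` models a CRISPR dynamic lineage-tracing experiment: `N` sequenced
cells, `K` engineered target sites, and an observed character matrix `D`
whose entry for cell `w` and site `k` is the recorded edit state -- `0`
(unedited), a positive integer (one of the site's `M(k)` possible edit
outcomes), or `?` (missing). The generative model has two layers.

**Layer 1 (editing along the tree).** Cells descend from a single unedited
progenitor at the root of a rooted tree `T`; the root has exactly one child
(the progenitor needs time to divide) and all other internal nodes have two.
Each site evolves independently down `T` under an irreversible continuous-
time Markov chain over `{0, 1..M(k), -1}`: state `0` mutates to outcome `m`
at rate `q_m^(k)` (the *indel priors*, hyperparameters normalized to sum to
1) and silences to the absorbing state `-1` at rate `nu`; edited states can
only silence, also at rate `nu`. Edge `e` has a duration `t_e` in time
units; with shared editing rate `lambda` its length in *mutation units* is
`delta_e = lambda * t_e`, and the edge transition matrix is the matrix
exponential of the generator, available in closed form:

    P(0 -> 0)  = exp(-delta (1 + nu))
    P(0 -> m)  = q_m exp(-nu delta) (1 - exp(-delta))
    P(0 -> -1) = 1 - exp(-nu delta)
    P(m -> m)  = exp(-nu delta)
    P(m -> -1) = 1 - exp(-nu delta)

The closed form is verified against `scipy.linalg.expm` in the test suite.
A silenced site is *heritably missing*: all descendants read `?`.

**Layer 2 (sequencing).** At the leaves only, any non-silent state drops
out to `?` with probability `phi`; silent states always read `?`. Dropout
and heritable missing are indistinguishable in `D`; distinguishing them
statistically is the point of the model.

The likelihood of a column sums over all latent edit histories and is
computed by Felsenstein pruning with per-node, per-site renormalization
(log-scale accumulators), so matrices with hundreds of cells pose no
underflow problem. Sites are independent given the tree, so the total
log-likelihood is the sum over sites.

## Estimation

**EM on a fixed topology.** The complete-data log-likelihood depends on the
latent history only through five grouped transition counts per edge
(`0->0`, `0->edited`, `0->silent`, `edited->same`, `edited->silent`) and,
per leaf, the number of non-missing entries `B` and the expected number of
dropout entries `B~`. The E-step computes these by an inside-outside pass
that exploits the sparsity of the transition matrix (first row, diagonal,
silent column), costing `O(NK)` per iteration up to the alphabet-bounded
constant; a dense reference E-step that forms every joint edge posterior
explicitly is shipped alongside and tested for equality.

The M-step maximizes the expected complete-data log-likelihood subject to
the molecular clock `sum_{e in path(root, leaf)} delta_e = lambda * tau`
for every leaf, where `tau` is the user-supplied experiment duration. With
`nu = 0` and the clock disabled the update is the closed form
`rho_e = Czz/(Czz + Cza)`, `delta_e = -log rho_e`,
`phi = N_missing/(NK)` (computed once, outside the loop). In general the
package cycles three blocks until improvement falls below `solver_tol`:

1. `phi`: closed form `B~ / (B + B~)` aggregated over leaves;
2. `{delta_e, lambda}`: the objective is concave and separable per edge and
   the clock constraints are linear. The block is solved by projected
   gradient ascent on *node heights* (mutation-unit depths; leaves pinned
   at `lambda*tau`, so the clock holds structurally), preceded and followed
   by two exact one-dimensional line searches -- along the global scaling
   direction `(s*heights, s*lambda)` and along `lambda` alone -- which are
   the poorly conditioned modes of plain gradient ascent;
3. `nu`: a one-dimensional concave problem, solved by bounded scalar
   minimization.

Each block move only improves the surrogate, so this is a generalized EM:
the data log-likelihood is non-decreasing across iterations, which the
fitter asserts at run time (a decrease beyond numerical tolerance is a hard
error). Branch lengths are floored at `1e-8` and capped at `50` mutation
units to keep logarithms finite; edges with no informative transitions are
reported at the floor with a warning.

Defaults: convergence at `1e-6` absolute log-likelihood change, at most
1000 iterations, one initialization (more restarts jitter the warm start
with seeds derived from the master seed). The warm start scales per-edge
parsimony mutation counts (plus one pseudocount) to height `lambda0*tau`
with `lambda0 = -log(fraction unmutated)/tau`, and sets `nu0 = 0.01`,
`phi0 = N_missing/(NK)`.

**Topology search.** Nearest-neighbor interchange over the unrooted
topology induced by the leaves (the root pendant keeps its edge), giving
the standard `2*(n-3)` neighborhood; each proposal is refit by EM and
accepted by the simulated-annealing rule with temperature
`max(eps, (alpha^t - alpha^c)/(1 - alpha^c))` and acceptance probability
`min(1, exp(dll - eps)/Temp)`; improving moves are always accepted.
Defaults `eps = 1e-12`, `c = 20`, `alpha = 0.9`; proposals are tried in a
seeded random order, rejection does not advance the clock, and the best
tree ever seen is returned. When no starting tree is given, neighbor
joining on normalized Hamming distances (missing entries skipped pairwise)
provides one.

**Imputation.** Marginal posteriors for every node and site come from the
same inside-outside pass. A missing entry is called *heritable* when the
posterior silent mass at the leaf exceeds 0.5 (ties go to dropout -- the
threshold is a convention, not estimated), dropout entries are imputed with
the argmax non-silent state, and ancestral sequences are per-(node, site)
marginal MAP states; a joint MAP is deliberately not attempted.

**Multi-progenitor extension.** Progenitor labels are immutable and
heritable, so a literal single-root chain would assign probability zero to
any dataset with two distinct observed labels. The label character is
therefore factorized over *founder clades*: the minimal clade covering each
observed label (monophyly is checked and violations reported with a
witnessing triplet) plus maximal clades of entirely unlabeled cells. Each
founder draws its label uniformly from the observed labels plus one spare
slot for never-recovered founders; within a clade the label evolves under
the shared silencing rate and dropout probability. Unlabeled cells inside a
labeled clade inherit its label at imputation time; maximal all-`?` clades
outside every labeled clade are reported as missing-label progenitors.
During topology search, moves that would break a labeled clade are skipped.

## Simulator

The generator emulates the standard benchmark for this class of methods: a
complete binary tree of `2^g` leaves beneath a single root edge (default
`g = 10`, 1024 leaves), every branch duration i.i.d. lognormal with mean 1
and standard deviation 0.1 *on the natural scale* (`mu`, `sigma` solved
accordingly), `K = 30` sites, editing rate `lambda = 0.095`, and five named
`(nu, phi)` conditions (`h0d100` ... `h100d0`) that hold total missingness
near 25% while sweeping the heritable share from 0% to 100%. The root edge
also receives a lognormal duration and carries editing, making the expected
root-to-leaf depth `g + 1` time units; at `lambda = 0.095` this calibrates
to roughly 64% edited entries *among non-missing observations* (the
simulator reports the all-entries statistic as well). Per-site alphabets
draw `M ~ U{5..30}` outcomes with symmetric Dirichlet(1) priors -- a stand-in
for empirically estimated indel priors, which are dataset-specific. Cells
are subsampled uniformly without replacement (default 250) and the tree is
restricted accordingly, suppressing unary nodes with lengths adding.

What the simulator does *not* emulate: cell death and non-uniform sampling,
site-specific silencing rates, editing-rate variation across branches or
time, sequence-level indel structure, or coupled gene-expression readouts.
Passing recovery tests on these data therefore demonstrates correctness of
the estimator under the model's own assumptions, not robustness to real
single-cell artifacts.

## Evaluation metrics

Normalized Robinson-Foulds error `(FN+FP)` over the total internal-edge
count of both unrooted trees; RMSE of `(phi, nu)` across replicates;
Sankoff parsimony branch lengths under the irreversible state space
(`0 -> m` costs 1, edited states immutable, `?` free, root pinned at 0);
migration graphs/costs from unit-cost Sankoff with the root fixed to the
primary anatomical site (this orientation is required for reseeding to be
meaningful); triplet-based progenitor discordance (fraction of
label-resolved triplets whose induced topology does not place the odd
label as outgroup; 0 by convention when no triplet is resolved); and
developmental cost against a directed cell-type tree (transition cost =
directed path length, infinite when unreachable). All Sankoff tracebacks
break ties toward the lexicographically smallest state, which fixes the
reported labeling but never the cost.

## Replication harness and problem sizes

`pmmtree.benchmark.run_study` regenerates the calibrated study and measures
the headline quantities; `scripts/acceptance.py` wraps it. Problem sizes
are the package's defaults for a desk-scale run: 10-generation trees,
`K = 30`, 250-cell subsamples, three replicates per condition (a full study
would use 50), EM capped at 150 iterations with a `1e-3` convergence
threshold -- parameter estimates move by less than their replicate-to-
replicate spread beyond that point.

Two measurement conventions matter when comparing branch lengths. First,
Sankoff counts are summed over the `K` sites while `lambda` is a per-site
rate, so conversion to time units divides by `K * lambda`. Second, *both*
ML and parsimony mutation-unit lengths are converted to time with the
*true* editing rate, so the branch-length comparison is not confounded by
error in `lambda`-hat; per-branch ratios are then averaged over branches
and replicates. At `K = 30` roughly a tenth of the edges of a 250-cell
tree carry no edits at all; their maximum-likelihood length is (correctly)
the floor, which is why the per-branch ratio under the *estimated*-rate
conversion sits visibly below 1 while the true-rate conversion centers
near 1. The editing-rate estimate itself carries a small positive
finite-`K` (Jensen-type) bias of a few percent at `K = 30`.

## Known limitations

* The constrained M-step is a first-order method; it trades exactness per
  iteration for speed and relies on the outer EM loop (and its line
  searches) for polish. Likelihoods agree with brute-force enumeration to
  `1e-8`, but the final parameter vector can differ from a second-order
  optimum in its last digits.
* `lambda` is identified only through `tau`; without `tau` the package
  reports mutation-unit lengths only.
* The annealing acceptance rule follows the published formula, under which
  the acceptance probability for worsening moves *grows* as the temperature
  decays; the returned optimum is protected by best-so-far tracking.
* Triplet discordance enumerates pairs x labeled leaves (`O(n^2)` memory,
  `O(n^3)` time in the worst case); fine for hundreds of labeled cells,
  not for tens of thousands.
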