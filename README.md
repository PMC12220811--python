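# pmmtree

Maximum-likelihood, time-resolved cell lineage trees from CRISPR dynamic
lineage-tracing data, under a model that treats the two kinds of missing
data — heritable silencing and sequencing dropout — as what they are:
different processes with different phylogenetic meaning.

## The problem

In dynamic lineage tracing, engineered target sites accumulate irreversible
edits as cells divide; single-cell sequencing then reads out an `N x K`
character matrix of edit states. A large fraction of entries (often ~25%)
is missing, for two reasons that look identical in the data: the site was
*heritably silenced* in an ancestral cell (e.g. by a large deletion or
transcriptional silencing — every descendant is missing it, which is itself
lineage signal), or it *dropped out* during sequencing of that one cell
(noise). Parsimony-based tree builders discard or conflate this signal and
systematically underestimate branch lengths away from the root.

## The model

Each site `k` evolves down a rooted tree under an irreversible CTMC on
`{0, 1..M(k), -1}`: the unedited state 0 mutates to outcome `m` at rate
`q_m` (indel priors) and silences to the absorbing state −1 at rate `nu`;
edited states silence at the same rate. Edge `e` has length
`delta_e = lambda * t_e` in mutation units (`lambda` = editing rate, `t_e`
= time). At the leaves, any non-silent state is read as `?` with dropout
probability `phi`; silent states always read `?`. Parameters
`({delta_e}, lambda, nu, phi)` are estimated by maximum likelihood under
the clock constraint `sum_path delta_e = lambda * tau` (`tau` = experiment
duration), via an EM algorithm with grouped expected counts and a
block-coordinate M-step; tree topology is optimized by NNI moves with
simulated annealing. Posterior decoding then imputes every `?` as dropout
or heritable and reconstructs ancestral sequences. A multi-progenitor
extension handles experiments started from several labeled founder cells.

See `docs/methods.md` for the full model, estimation details, and the
simulator's assumptions.

## Worked example

```python
import numpy as np
from pmmtree import PMMModel, EMConfig
from pmmtree.simulate import SimConfig, simulate_dataset, subsample

# simulate a calibrated benchmark dataset: 6 generations, 30 sites,
# mixed heritable/dropout missing data, 48 cells kept
cfg = SimConfig.condition("h50d50", generations=6, K=30, lam=0.15,
                          subsample_n=48, seed=7)
ds = simulate_dataset(cfg)
(tree, latent, observed, causes), = subsample(
    ds.tree, (ds.latent, ds.observed, ds.causes), 48, seed=7)

model = PMMModel(observed, tree=tree, tau=7.0)
result = model.fit(em_config=EMConfig(max_iter=200, eps_em=1e-4))
print(result.summary())
```

prints

```
Mixed-type missing lineage model
================================================
Cells: 48    Sites: 30    Missing: 23.2%
Log-likelihood: -1668.4260
EM iterations:  28    converged: True
------------------------------------------------
editing rate lambda : 0.177583
silencing rate nu   : 0.0624643
dropout prob phi    : 0.175533
branch delta range  : [1e-08, 0.4057]
tree height         : 1.243 mutation units over tau = 7
```

The editing rate (0.178 vs the simulated 0.15), silencing rate (0.062 vs
0.134) and dropout probability (0.176 vs 0.143) are recovered only roughly
at this deliberately small size — 48 cells and 30 sites carry limited
information; the full-scale study below (250 cells, replicated) pins them
down much more tightly. `result.tree` carries branch lengths in both time
and mutation units, and

```python
imputed, calls, ancestors = result.impute()
print(calls["call"].value_counts())
```

```
call
dropout      252
heritable     82
```

splits the 334 missing entries into dropout (imputed with the most probable
edit state) and heritable missing — against the simulator's recorded
ground-truth causes, 79% of these calls are correct on this small dataset.

A command-line interface wraps the same pipeline:

```bash
pmmtree simulate --condition h50d50 --generations 6 --seed 7 -o sim/
pmmtree fit sim/character_matrix.csv --tree sim/true_tree.nwk --tau 7 -o fit/
pmmtree evaluate fit/tree.nwk --true-tree sim/true_tree.nwk
```

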