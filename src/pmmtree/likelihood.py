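"""Tree likelihood under the mixed-type missing model.

The probability of one site's observed column is a sum over all latent edit
histories on the tree; it is computed in linear time by Felsenstein's pruning
algorithm (an upward pass of conditional likelihoods), with a downward pass
added when posterior marginals or expected transition counts are needed.

All sites are processed together: states are packed into a common slot layout
``[0, mutated slot 1..Mmax, silent]`` where sites with fewer than Mmax
outcomes carry zero prior mass on the padding slots (those slots are then
unreachable and contribute nothing).  Messages are renormalized per node and
site, with the log of the normalizer accumulated, so likelihoods of trees
with hundreds of cells stay finite.
"""

from __future__ import annotations

import numpy as np

from .data import MISSING, CharacterMatrix, PMMParams
from .tree import LineageTree


class LikelihoodError(ValueError):
    """The observed data has probability zero under the current parameters."""


class PruningContext:
    """Compiled (tree, matrix) pair ready for repeated likelihood evaluation.

    Compilation resolves tree traversal order, slot encoding of the observed
    matrix, and per-site priors once; parameter-dependent quantities are
    recomputed on every call, so the same context serves a whole EM run.
    """

    def __init__(self, tree: LineageTree, matrix: CharacterMatrix):
        self.tree = tree
        self.matrix = matrix
        self.nodes = list(tree.postorder())          # root is last
        self.index = {n.name: i for i, n in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("node names must be unique")
        self.n_nodes = len(self.nodes)
        self.children = [
            [self.index[c.name] for c in n.children] for n in self.nodes
        ]
        self.leaf_idx = [i for i, n in enumerate(self.nodes) if n.is_leaf]

        K = matrix.n_sites
        self.K = K
        self.Mmax = max(a.n_mutated for a in matrix.alphabets)
        self.S = self.Mmax + 2                        # slots: 0, 1..Mmax, silent
        self.q = np.zeros((K, self.Mmax))
        self.slot_to_state = []                       # per site: slot j -> state
        self.state_to_slot = []
        for k, alpha in enumerate(matrix.alphabets):
            states = alpha.mutated_states
            self.q[k, : len(states)] = [alpha.priors[s] for s in states]
            self.slot_to_state.append({j + 1: s for j, s in enumerate(states)})
            self.state_to_slot.append({s: j + 1 for j, s in enumerate(states)})

        cells = set(matrix.cell_names)
        df = matrix.to_frame()
        self.leaf_codes = {}                          # node index -> (K,) slot codes
        for i in self.leaf_idx:
            name = self.nodes[i].name
            if name not in cells:
                raise LikelihoodError(f"leaf {name!r} absent from character matrix")
            row = df.loc[name]
            codes = np.empty(K, dtype=int)
            for k in range(K):
                v = row.iloc[k]
                if v == MISSING:
                    codes[k] = -1
                elif int(v) == 0:
                    codes[k] = 0
                else:
                    codes[k] = self.state_to_slot[k][int(v)]
            self.leaf_codes[i] = codes

    # -- parameter unpacking --------------------------------------------
    def edge_deltas(self, params: PMMParams) -> np.ndarray:
        """Per-node delta (mutation units) of the edge above each node."""
        d = np.zeros(self.n_nodes)
        for i, n in enumerate(self.nodes[:-1]):       # root has no edge
            try:
                d[i] = params.delta[n.name]
            except KeyError:
                raise KeyError(f"no delta for edge above node {n.name!r}") from None
            if d[i] < 0:
                raise ValueError(f"negative delta on edge {n.name!r}")
        return d

    def _edge_scalars(self, deltas: np.ndarray, nu: float):
        keep = np.exp(-nu * deltas)                   # P(no silencing on edge)
        stay0 = np.exp(-deltas * (1.0 + nu))
        gain = keep * (1.0 - np.exp(-deltas))         # total 0 -> mutated mass
        return keep, stay0, gain

    def leaf_likelihoods(self, phi: float) -> dict[int, np.ndarray]:
        """Observation likelihood P(D(w) | X(w)=state) per leaf, (K, S)."""
        out = {}
        for i in self.leaf_idx:
            codes = self.leaf_codes[i]
            L = np.zeros((self.K, self.S))
            obs = codes >= 0
            L[np.nonzero(obs)[0], codes[obs]] = 1.0 - phi
            L[~obs, : self.S - 1] = phi               # dropout of any non-silent
            L[~obs, self.S - 1] = 1.0                 # silent always reads "?"
            out[i] = L
        return out

    # -- upward (pruning) pass -------------------------------------------
    def up_pass(self, params: PMMParams):
        """Conditional likelihoods, normalized, with per-site log-scales.

        Returns ``(up, logn, msg, site_loglik)`` where ``up[i]`` is the
        normalized conditional likelihood of the data below node i given its
        state, ``msg[i]`` the message node i sends to its parent, and
        ``site_loglik`` the (K,) vector of per-site log-likelihoods.
        """
        deltas = self.edge_deltas(params)
        keep, stay0, gain = self._edge_scalars(deltas, params.nu)
        leafL = self.leaf_likelihoods(params.phi)
        S = self.S
        up = np.zeros((self.n_nodes, self.K, S))
        logn = np.zeros((self.n_nodes, self.K))
        msg = np.zeros((self.n_nodes, self.K, S))

        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                up[i] = leafL[i]
            else:
                up[i] = 1.0
                for c in self.children[i]:
                    up[i] *= msg[c]
                    logn[i] += logn[c]
            norm = up[i].sum(axis=1)
            bad = norm <= 0.0
            if np.any(bad):
                self._raise_zero(np.nonzero(bad)[0], node)
            up[i] /= norm[:, None]
            logn[i] += np.log(norm)
            if node.parent is not None:
                U = up[i]
                m = np.empty_like(U)
                m[:, 0] = (
                    stay0[i] * U[:, 0]
                    + gain[i] * (self.q * U[:, 1 : S - 1]).sum(axis=1)
                    + (1.0 - keep[i]) * U[:, S - 1]
                )
                m[:, 1 : S - 1] = keep[i] * U[:, 1 : S - 1] + (
                    (1.0 - keep[i]) * U[:, S - 1]
                )[:, None]
                m[:, S - 1] = U[:, S - 1]
                msg[i] = m

        top = self.children[-1][0]                    # root's single child
        root_val = msg[top][:, 0]                     # root state fixed to 0
        if np.any(root_val <= 0.0):
            self._raise_zero(np.nonzero(root_val <= 0.0)[0], self.nodes[-1])
        site_loglik = np.log(root_val) + logn[top]
        return up, logn, msg, site_loglik

    def _raise_zero(self, sites, node):
        names = [self.matrix.site_names[k] for k in sites[:5]]
        leaves = [n.name for n in LineageTree(node).leaves()][:10]
        raise LikelihoodError(
            f"site(s) {names} have zero likelihood under the current "
            f"parameters (subtree cells include {leaves})"
        )

    # -- downward pass -----------------------------------------------------
    def down_pass(self, params: PMMParams, up, msg):
        """Outside probabilities, normalized per node and site.

        Returns ``(down, down_excl)``: ``down[i]`` is proportional to
        P(X(i)=state, data outside the subtree of i); ``down_excl[i]`` the
        same quantity at the *parent* of i excluding i's own subtree (the
        outside factor entering edge posteriors for the edge above i).
        """
        deltas = self.edge_deltas(params)
        keep, stay0, gain = self._edge_scalars(deltas, params.nu)
        S = self.S
        down = np.zeros((self.n_nodes, self.K, S))
        down_excl = np.zeros((self.n_nodes, self.K, S))
        root = self.n_nodes - 1
        down[root][:, 0] = 1.0
        for node in self.tree.preorder():
            i = self.index[node.name]
            for c in self.children[i]:
                F = down[i].copy()
                for sib in self.children[i]:
                    if sib != c:
                        F *= msg[sib]
                norm = F.sum(axis=1)
                norm[norm <= 0] = 1.0                 # degenerate; posteriors 0
                F /= norm[:, None]
                down_excl[c] = F
                D = np.empty_like(F)
                D[:, 0] = F[:, 0] * stay0[c]
                D[:, 1 : S - 1] = F[:, 0, None] * gain[c] * self.q + keep[c] * F[:, 1 : S - 1]
                D[:, S - 1] = (1.0 - keep[c]) * F[:, : S - 1].sum(axis=1) + F[:, S - 1]
                norm = D.sum(axis=1)
                norm[norm <= 0] = 1.0
                down[c] = D / norm[:, None]
        return down, down_excl

    def node_posteriors(self, up, down) -> np.ndarray:
        """Marginal posterior P(X(i)=state | D) per node and site, (n, K, S)."""
        post = up * down
        Z = post.sum(axis=2, keepdims=True)
        Z[Z <= 0] = 1.0
        return post / Z


def _context(tree: LineageTree, matrix: CharacterMatrix) -> PruningContext:
    return PruningContext(tree, matrix)


def site_log_likelihood(
    tree: LineageTree, params: PMMParams, matrix: CharacterMatrix, site: int | str = 0
) -> float:
    """Log-probability of one site's observed column, by pruning."""
    single = matrix.single_site(site)
    ctx = PruningContext(tree, single)
    _, _, _, site_ll = ctx.up_pass(params)
    return float(site_ll[0])


def log_likelihood(
    tree: LineageTree, params: PMMParams, matrix: CharacterMatrix
) -> float:
    """Total log-likelihood: the sum of independent per-site terms."""
    if matrix.n_sites == 0:
        return 0.0
    ctx = PruningContext(tree, matrix)
    _, _, _, site_ll = ctx.up_pass(params)
    return float(site_ll.sum())
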