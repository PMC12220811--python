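"""EM estimation of branch lengths and missing-data parameters on a fixed tree.

The E-step reduces all edge transitions to five grouped expected counts per
edge -- 0->0, 0->mutated, 0->silent, mutated->same, mutated->silent -- plus,
per leaf, the number of non-missing entries B and the expected number of
dropout entries B~.  The grouping works because the chain is irreversible and
the edge transition matrix has non-zero entries only in its first row, its
diagonal and its silent column, so the complete-data log-likelihood depends
on the latent history only through these totals.

The M-step maximizes the resulting objective.  With no silencing (nu = 0) and
the ultrametric constraint switched off it has the closed form
rho_e = Czz/(Czz+Cza), delta_e = -log rho_e, phi = N_missing/(N K).  In
general the objective is maximized by block coordinate ascent over phi,
{delta_e, lambda} (a concave problem with linear clock constraints
sum_path delta_e = lambda tau, solved by projected gradient ascent on node
heights), and nu (one-dimensional, concave).  Partial maximization suffices:
every block move increases the EM surrogate, so the data log-likelihood is
non-decreasing across iterations (a generalized EM scheme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .data import MISSING, CharacterMatrix, PMMParams
from .likelihood import PruningContext
from .tree import LineageTree

DELTA_FLOOR = 1e-8
DELTA_CAP = 50.0


class EMError(RuntimeError):
    """The EM contract (monotone log-likelihood) was violated."""


@dataclass
class ExpectedCounts:
    """Grouped posterior expectations from one E-step.

    Edge-level dictionaries are keyed by the child node of the edge; leaf
    dictionaries by cell name.
    """

    czz: dict[str, float]
    cza: dict[str, float]
    czm: dict[str, float]
    caa: dict[str, float]
    cam: dict[str, float]
    B: dict[str, int]
    Btilde: dict[str, float]

    def edge_total(self, edge: str) -> float:
        return (
            self.czz[edge] + self.cza[edge] + self.czm[edge]
            + self.caa[edge] + self.cam[edge]
        )


@dataclass
class EMConfig:
    eps_em: float = 1e-6          # absolute log-likelihood change at convergence
    max_iter: int = 1000
    nu_zero_mode: bool = False    # use the closed-form M-step (forces nu = 0)
    solver_tol: float = 1e-6      # inner block-ascent convergence tolerance
    seed: int | None = None
    n_restarts: int = 1
    inner_iters: int = 100        # projected-gradient steps per delta/lambda block
    max_cycles: int = 6           # block cycles per M-step (partial M-steps
                                  # suffice: the outer EM loop iterates anyway)

    def __post_init__(self):
        if self.eps_em <= 0:
            raise ValueError("eps_em must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class EMResult:
    params: PMMParams
    loglik: float
    n_iter: int
    converged: bool
    trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def e_step(
    tree: LineageTree,
    params: PMMParams,
    matrix: CharacterMatrix,
    ctx: PruningContext | None = None,
) -> ExpectedCounts:
    """Grouped expected transition counts under the posterior given D.

    Exploits the sparsity of the edge transition matrix so each edge costs
    O(M) per site; the full quadratic-in-M joint posterior is never formed.
    """
    if ctx is None:
        ctx = PruningContext(tree, matrix)
    up, logn, msg, site_ll = ctx.up_pass(params)
    down, down_excl = ctx.down_pass(params, up, msg)
    deltas = ctx.edge_deltas(params)
    keep, stay0, gain = ctx._edge_scalars(deltas, params.nu)
    S = ctx.S
    czz, cza, czm, caa, cam = {}, {}, {}, {}, {}
    for i, node in enumerate(ctx.nodes[:-1]):
        F, U = down_excl[i], up[i]
        t_zz = F[:, 0] * stay0[i] * U[:, 0]
        t_za = F[:, 0] * gain[i] * (ctx.q * U[:, 1 : S - 1]).sum(axis=1)
        t_zm = F[:, 0] * (1.0 - keep[i]) * U[:, S - 1]
        t_aa = keep[i] * (F[:, 1 : S - 1] * U[:, 1 : S - 1]).sum(axis=1)
        t_am = (1.0 - keep[i]) * F[:, 1 : S - 1].sum(axis=1) * U[:, S - 1]
        t_ss = F[:, S - 1] * U[:, S - 1]
        Z = t_zz + t_za + t_zm + t_aa + t_am + t_ss
        czz[node.name] = float((t_zz / Z).sum())
        cza[node.name] = float((t_za / Z).sum())
        czm[node.name] = float((t_zm / Z).sum())
        caa[node.name] = float((t_aa / Z).sum())
        cam[node.name] = float((t_am / Z).sum())
    post = ctx.node_posteriors(up, down)
    B, Btilde = {}, {}
    for i in ctx.leaf_idx:
        name = ctx.nodes[i].name
        codes = ctx.leaf_codes[i]
        miss = codes < 0
        B[name] = int((~miss).sum())
        Btilde[name] = float((1.0 - post[i][miss, S - 1]).sum())
    return ExpectedCounts(czz, cza, czm, caa, cam, B, Btilde)


def e_step_dense(
    tree: LineageTree, params: PMMParams, matrix: CharacterMatrix
) -> ExpectedCounts:
    """Reference E-step via explicit per-site joint edge posteriors.

    Builds the full transition matrix on every edge and sums the joint
    posterior P(X(u)=a, X(v)=b | D) entry by entry -- quadratic in the
    alphabet size, independent of the grouped fast path above.
    """
    from .transitions import dropout_matrix, transition_matrix

    nodes = list(tree.postorder())
    czz = {n.name: 0.0 for n in nodes[:-1]}
    cza, czm, caa, cam = (dict(czz) for _ in range(4))
    B: dict[str, int] = {}
    Btilde: dict[str, float] = {}
    df = matrix.to_frame()
    for leaf in tree.leaves():
        row = df.loc[leaf.name]
        B[leaf.name] = int((row != MISSING).sum())
        Btilde[leaf.name] = 0.0
    for k, alpha in enumerate(matrix.alphabets):
        M = alpha.n_mutated
        Sk = M + 2
        sidx = Sk - 1
        state_pos = {0: 0, **{s: j + 1 for j, s in enumerate(alpha.mutated_states)}}
        Psi = {
            n.name: transition_matrix(params.delta[n.name], params.nu, alpha)
            for n in nodes[:-1]
        }
        Phi = dropout_matrix(params.phi, alpha)
        inside: dict[str, np.ndarray] = {}
        for n in nodes:
            if n.is_leaf:
                obs = df.loc[n.name].iloc[k]
                col = sidx if obs == MISSING else state_pos[int(obs)]
                inside[n.name] = Phi[:, col].copy()
            else:
                v = np.ones(Sk)
                for c in n.children:
                    v *= Psi[c.name] @ inside[c.name]
                inside[n.name] = v
        outside = {nodes[-1].name: np.eye(Sk)[0]}
        for n in tree.preorder():
            for c in n.children:
                F = outside[n.name].copy()
                for sib in n.children:
                    if sib is not c:
                        F = F * (Psi[sib.name] @ inside[sib.name])
                outside[c.name] = F @ Psi[c.name]
                # store the pre-transition outside factor for the edge above c
                outside[("excl", c.name)] = F
        L = float(inside[nodes[-1].name][0])
        for n in nodes[:-1]:
            F = outside[("excl", n.name)]
            J = (F[:, None] * Psi[n.name] * inside[n.name][None, :]) / L
            czz[n.name] += J[0, 0]
            cza[n.name] += J[0, 1 : Sk - 1].sum()
            czm[n.name] += J[0, sidx]
            caa[n.name] += np.diag(J)[1 : Sk - 1].sum()
            cam[n.name] += J[1 : Sk - 1, sidx].sum()
        for leaf in tree.leaves():
            obs = df.loc[leaf.name].iloc[k]
            if obs == MISSING:
                marg = outside[("excl", leaf.name)] @ Psi[leaf.name] * inside[leaf.name]
                marg = marg / marg.sum()
                Btilde[leaf.name] += 1.0 - marg[sidx]
    return ExpectedCounts(czz, cza, czm, caa, cam, B, Btilde)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def m_step_closed_form(
    counts: ExpectedCounts,
    matrix: CharacterMatrix,
    floor: float = DELTA_FLOOR,
    cap: float = DELTA_CAP,
) -> tuple[dict[str, float], float]:
    """Closed-form M-step for nu = 0 with the clock constraint ignored."""
    delta = {}
    for e in counts.czz:
        denom = counts.czz[e] + counts.cza[e]
        if denom <= 0:
            warnings.warn(f"edge {e}: no informative transitions; delta floored")
            delta[e] = floor
            continue
        rho = counts.czz[e] / denom
        if rho <= 0:
            delta[e] = cap
        else:
            delta[e] = float(np.clip(-np.log(rho), floor, cap))
    phi = matrix.n_missing / (matrix.n_cells * matrix.n_sites)
    return delta, phi


def _edge_objective(d, nu, czz, cza, czm, cam, caa, floor=DELTA_FLOOR):
    """Eq.-14-style expected complete-data log-likelihood, delta terms only."""
    d = np.maximum(d, floor)
    out = -czz * (1.0 + nu) * d - cza * nu * d - caa * nu * d
    # -inf * 0 inside the unselected where-branch is intentional and masked
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log1p(-np.exp(-d))
        out = out + np.where(cza > 0, cza * la, 0.0)
        if nu > 0:
            lm = np.log1p(-np.exp(-d * nu))
            out = out + np.where(czm + cam > 0, (czm + cam) * lm, 0.0)
        else:
            # silent transitions are impossible; positive counts mean -inf
            if np.any(czm + cam > 1e-12):
                return -np.inf
    return float(out.sum())


def _edge_gradient(d, nu, czz, cza, czm, cam, caa, floor=DELTA_FLOOR):
    d = np.maximum(d, floor)
    g = -czz * (1.0 + nu) - cza * nu - caa * nu
    g = g + np.where(cza > 0, cza / np.expm1(d), 0.0)
    if nu > 0:
        g = g + np.where(czm + cam > 0, (czm + cam) * nu / np.expm1(d * nu), 0.0)
    return g


class _TreeArrays:
    """Postorder-indexed arrays of a tree plus count vectors, for the M-step.

    All traversals are grouped by depth level so repairs and conversions run
    as a handful of vectorized passes rather than per-node Python loops.
    """

    def __init__(self, tree: LineageTree, counts: ExpectedCounts):
        self.nodes = list(tree.postorder())
        self.idx = {n.name: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.full(n, -1)
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                self.parent[i] = self.idx[node.parent.name]
        self.is_leaf = np.array([node.is_leaf for node in self.nodes])
        self.root = n - 1
        self.edge_nodes = np.arange(n - 1)            # all but root have an edge
        names = [self.nodes[i].name for i in self.edge_nodes]
        self.names = names
        self.czz = np.array([counts.czz[e] for e in names])
        self.cza = np.array([counts.cza[e] for e in names])
        self.czm = np.array([counts.czm[e] for e in names])
        self.caa = np.array([counts.caa[e] for e in names])
        self.cam = np.array([counts.cam[e] for e in names])
        self.internal_vars = np.array(
            [i for i in range(n - 1) if not self.is_leaf[i]], dtype=int
        )  # height variables: internal non-root nodes
        self.leaf_edge = self.is_leaf[self.edge_nodes]
        # depth levels (root at level 0), each an index array
        depth = np.zeros(n, dtype=int)
        order = []
        for node in tree.preorder():
            i = self.idx[node.name]
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + 1
            order.append(i)
        self.levels = [
            np.nonzero(depth == d)[0] for d in range(depth.max() + 1)
        ]

    def heights_from_deltas(self, delta: np.ndarray) -> np.ndarray:
        H = np.zeros(len(self.nodes))
        for ids in self.levels[1:]:
            H[ids] = H[self.parent[ids]] + delta[ids]
        return H

    def deltas_from_heights(self, H: np.ndarray, lam: float, tau: float) -> np.ndarray:
        Hfull = H.copy()
        Hfull[self.is_leaf] = lam * tau
        Hfull[self.root] = 0.0
        return Hfull[self.edge_nodes] - Hfull[self.parent[self.edge_nodes]]

    def repair(self, H: np.ndarray, lam: float, tau: float, floor: float) -> np.ndarray:
        """Clamp heights to (approximately) satisfy 0 <= ... <= lam*tau ordering."""
        A = lam * tau
        H = H.copy()
        H[self.is_leaf] = A
        H[self.root] = 0.0
        for ids in self.levels[1:]:                   # top-down: above parent
            sub = ids[~self.is_leaf[ids]]
            H[sub] = np.maximum(H[sub], H[self.parent[sub]] + floor)
        cap = np.full(len(self.nodes), np.inf)
        for ids in reversed(self.levels[1:]):         # bottom-up: below children
            sub = ids[~self.is_leaf[ids]]
            H[sub] = np.minimum(H[sub], cap[sub])
            np.minimum.at(cap, self.parent[ids], H[ids] - floor)
        return H


def _maximize_delta_lambda(
    ta: _TreeArrays,
    delta0: np.ndarray,
    lam0: float,
    nu: float,
    tau: float,
    floor: float = DELTA_FLOOR,
    max_steps: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Projected gradient ascent on node heights + lambda under the clock."""
    # heights indexed like nodes; edge i sits above node i
    H = ta.heights_from_deltas(np.append(delta0, 0.0))
    lam = lam0
    f = lambda d: _edge_objective(d, nu, ta.czz, ta.cza, ta.czm, ta.cam, ta.caa, floor)
    d = ta.deltas_from_heights(H, lam, tau)
    best = f(d)

    def line_searches(H, lam, d, best):
        # exact 1-D search along the global scaling direction (s*H, s*lam):
        # the clock constraint is scale-invariant, and this is the poorly
        # conditioned mode of plain gradient ascent
        res = minimize_scalar(lambda s: -f(np.exp(s) * d),
                              bounds=(-3.0, 3.0), method="bounded",
                              options={"xatol": 1e-10})
        s = float(np.exp(res.x))
        if -res.fun > best:
            H, lam, d, best = H * s, lam * s, d * s, -res.fun
        # 1-D search over lambda alone (moves only the leaf edges)
        leaf_d = d[ta.leaf_edge]
        lam_min = max(lam - (leaf_d.min() - floor) / tau, 1e-8)
        lam_max = max(lam * 4, lam_min * 2)
        if lam_min < lam_max:
            def with_lam(lam2):
                d2 = d.copy()
                d2[ta.leaf_edge] = leaf_d + (lam2 - lam) * tau
                return d2
            res = minimize_scalar(lambda l: -f(with_lam(l)),
                                  bounds=(lam_min, lam_max),
                                  method="bounded", options={"xatol": 1e-12})
            if -res.fun > best:
                lam, best = float(res.x), -res.fun
                d = with_lam(lam)
        return H, lam, d, best

    H, lam, d, best = line_searches(H, lam, d, best)
    step = 1.0
    for _ in range(max_steps):
        g_d = _edge_gradient(d, nu, ta.czz, ta.cza, ta.czm, ta.cam, ta.caa, floor)
        grad_H = np.zeros(len(ta.nodes))
        np.add.at(grad_H, ta.edge_nodes[~ta.leaf_edge], g_d[~ta.leaf_edge])
        np.subtract.at(grad_H, ta.parent[ta.edge_nodes], g_d)
        grad_lam = tau * g_d[ta.leaf_edge].sum()
        gnorm = np.sqrt((grad_H[ta.internal_vars] ** 2).sum() + grad_lam**2)
        if gnorm < 1e-14:
            break
        improved = False
        while step > 1e-13:
            Hc = H.copy()
            Hc[ta.internal_vars] += step * grad_H[ta.internal_vars]
            lamc = max(lam + step * grad_lam, 1e-8)
            Hc = ta.repair(Hc, lamc, tau, floor)
            dc = ta.deltas_from_heights(Hc, lamc, tau)
            val = f(dc)
            if val > best:
                gain = val - best
                H, lam, d, best = Hc, lamc, dc, val
                step *= 1.6
                improved = True
                if gain < tol * max(1.0, abs(best)):
                    return d, lam
                break
            step *= 0.5
        if not improved:
            break
    H, lam, d, best = line_searches(H, lam, d, best)
    return d, lam


def _maximize_delta_separable(
    delta0: np.ndarray, nu: float, ta: _TreeArrays,
    floor: float = DELTA_FLOOR, cap: float = DELTA_CAP,
) -> np.ndarray:
    """Per-edge 1-D maximization when no clock constraint couples the edges."""
    out = np.empty_like(delta0)
    for i in range(len(delta0)):
        czz, cza = ta.czz[i], ta.cza[i]
        czm, cam, caa = ta.czm[i], ta.cam[i], ta.caa[i]
        if nu == 0:
            denom = czz + cza
            out[i] = floor if denom <= 0 or cza <= 0 else np.clip(
                -np.log(czz / denom) if czz > 0 else cap, floor, cap
            )
            continue
        neg = lambda x: -_edge_objective(
            np.array([x]), nu,
            np.array([czz]), np.array([cza]), np.array([czm]),
            np.array([cam]), np.array([caa]), floor,
        )
        res = minimize_scalar(neg, bounds=(floor, cap), method="bounded",
                              options={"xatol": 1e-10})
        out[i] = res.x
    return out


def _maximize_nu(deltas: np.ndarray, ta: _TreeArrays, nu_max: float = 10.0) -> float:
    silent_mass = (ta.czm + ta.cam).sum()
    if silent_mass <= 1e-12:
        return 0.0

    def neg(nu):
        return -_edge_objective(deltas, nu, ta.czz, ta.cza, ta.czm, ta.cam, ta.caa)

    res = minimize_scalar(neg, bounds=(1e-10, nu_max), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def _phi_update(counts: ExpectedCounts) -> float:
    B = sum(counts.B.values())
    Bt = sum(counts.Btilde.values())
    if Bt <= 0:
        return 0.0
    return float(np.clip(Bt / (B + Bt), 1e-10, 1 - 1e-10))


def m_step_constrained(
    tree: LineageTree,
    counts: ExpectedCounts,
    params: PMMParams,
    tau: float | None,
    config: EMConfig | None = None,
) -> PMMParams:
    """Block coordinate ascent on the M-step objective.

    Cycles phi | {delta_e, lambda} | nu until the objective improvement drops
    below ``config.solver_tol``.  With ``tau`` given, the clock constraint
    (every root-to-leaf path sums to lambda*tau in mutation units) is enforced
    structurally through a node-height parameterization; without ``tau`` the
    delta block is separable and solved edge by edge.
    """
    config = config or EMConfig()
    if tau is not None and tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    ta = _TreeArrays(tree, counts)
    delta = np.array([params.delta[e] for e in ta.names])
    nu = params.nu
    lam = params.lam if params.lam is not None else (
        delta.max() / tau if tau else None
    )
    new = params.copy()
    new.phi = _phi_update(counts)

    def total(d, nu_):
        return _edge_objective(d, nu_, ta.czz, ta.cza, ta.czm, ta.cam, ta.caa)

    prev = total(delta, nu)
    for _ in range(config.max_cycles):
        if tau is not None:
            delta, lam = _maximize_delta_lambda(
                ta, delta, lam, nu, tau, max_steps=config.inner_iters,
                tol=config.solver_tol,
            )
        else:
            delta = _maximize_delta_separable(delta, nu, ta)
        if not config.nu_zero_mode:
            nu = _maximize_nu(delta, ta)
        else:
            nu = 0.0
        cur = total(delta, nu)
        if cur - prev < config.solver_tol * max(1.0, abs(cur)):
            break
        prev = cur
    new.delta = {e: float(max(d, DELTA_FLOOR)) for e, d in zip(ta.names, delta)}
    new.nu = float(nu)
    new.lam = float(lam) if lam is not None else None
    new.tau = tau
    return new


# ---------------------------------------------------------------------------
# Initialization and the outer EM loop
# ---------------------------------------------------------------------------

def default_init(
    tree: LineageTree,
    matrix: CharacterMatrix,
    tau: float | None,
    rng: np.random.Generator | None = None,
    nu_zero: bool = False,
) -> PMMParams:
    """Warm start: parsimony-scaled branch lengths, empirical phi, small nu.

    Per-edge parsimony mutation counts (plus one pseudocount) give relative
    branch lengths; they are rescaled so the mean root-to-leaf path equals
    lambda0*tau with lambda0 = -log(fraction unmutated)/tau.
    """
    from .metrics import mp_branch_lengths

    df = matrix.to_frame().to_numpy()
    n_obs = (df != MISSING).sum()
    frac0 = ((df == 0).sum() / n_obs) if n_obs else 0.5
    frac0 = float(np.clip(frac0, 1e-3, 1 - 1e-3))
    phi0 = float(np.clip(matrix.missing_fraction, 1e-6, 0.5))
    nu0 = 0.0 if nu_zero else 0.01
    counts = mp_branch_lengths(tree, matrix)
    raw = {e: c + 1.0 for e, c in counts.items()}
    if rng is not None:
        for e in raw:
            raw[e] *= float(np.exp(rng.normal(0.0, 0.3)))
        if not nu_zero:
            nu0 = float(rng.uniform(0.0, 0.1))
    if tau is None:
        K = matrix.n_sites
        delta = {e: max(c / max(K, 1), DELTA_FLOOR) for e, c in raw.items()}
        return PMMParams(delta=delta, lam=None, nu=nu0, phi=phi0, tau=None)
    lam0 = max(-np.log(frac0) / tau, 1e-4)
    A = lam0 * tau
    # cumulative raw heights, scaled so the mean leaf depth is A
    H: dict[str, float] = {tree.root.name: 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            H[node.name] = H[node.parent.name] + raw[node.name]
    leaf_mean = np.mean([H[l.name] for l in tree.leaves()])
    scale = A / leaf_mean
    for n in H:
        H[n] *= scale
    # clamp to a valid height assignment with leaves exactly at A
    for node in tree.postorder():
        if node.is_leaf:
            H[node.name] = A
        elif node.children:
            H[node.name] = min(
                H[node.name], min(H[c.name] for c in node.children) - DELTA_FLOOR
            )
    H[tree.root.name] = 0.0
    for node in tree.preorder():
        if node.parent is not None and not node.is_leaf:
            H[node.name] = max(H[node.name], H[node.parent.name] + DELTA_FLOOR)
    delta = {}
    for node in tree.preorder():
        if node.parent is not None:
            delta[node.name] = max(H[node.name] - H[node.parent.name], DELTA_FLOOR)
    return PMMParams(delta=delta, lam=lam0, nu=nu0, phi=phi0, tau=tau)


def em_fit(
    tree: LineageTree,
    matrix: CharacterMatrix,
    tau: float | None = None,
    config: EMConfig | None = None,
    init: PMMParams | None = None,
) -> EMResult:
    """Algorithm-1-style EM loop on a fixed topology, with optional restarts."""
    from .likelihood import log_likelihood

    config = config or EMConfig()
    rng = np.random.default_rng(config.seed)
    best: EMResult | None = None
    for r in range(max(config.n_restarts, 1)):
        if init is not None and r == 0:
            start = init.copy()
        else:
            start = default_init(
                tree, matrix, tau, rng=rng if r > 0 else None,
                nu_zero=config.nu_zero_mode,
            )
        res = _em_single(tree, matrix, tau, config, start)
        if best is None or res.loglik > best.loglik:
            best = res
    return best


def _em_single(tree, matrix, tau, config: EMConfig, params: PMMParams) -> EMResult:
    ctx = PruningContext(tree, matrix)
    if config.nu_zero_mode:
        params.nu = 0.0
        phi_hat = matrix.n_missing / (matrix.n_cells * matrix.n_sites)
        params.phi = float(np.clip(phi_hat, 0.0, 1 - 1e-10))
    _, _, _, site_ll = ctx.up_pass(params)
    ll = float(site_ll.sum())
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        counts = e_step(tree, params, matrix, ctx=ctx)
        if config.nu_zero_mode and tau is None:
            delta, _ = m_step_closed_form(counts, matrix)
            params = params.copy()
            params.delta = delta
        else:
            params = m_step_constrained(tree, counts, params, tau, config)
            if config.nu_zero_mode:
                params.phi = float(
                    np.clip(matrix.n_missing / (matrix.n_cells * matrix.n_sites),
                            0.0, 1 - 1e-10)
                )
        _, _, _, site_ll = ctx.up_pass(params)
        ll_new = float(site_ll.sum())
        if ll_new < ll - 1e-6 * max(1.0, abs(ll)):
            raise EMError(
                f"log-likelihood decreased at iteration {it}: {ll:.8f} -> {ll_new:.8f}"
            )
        trace.append(ll_new)
        if abs(ll_new - ll) < config.eps_em:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if tau is not None and params.lam:
        tree.set_deltas(params.delta)
        tree.times_from_deltas(params.lam)
    return EMResult(params=params, loglik=ll, n_iter=it, converged=converged,
                    trace=trace)
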