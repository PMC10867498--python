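"""Maximum-likelihood molecular clock test.

Likelihood-ratio comparison of two nested branch-length models on a
fixed topology under TN93 with discrete-gamma rate heterogeneity:

* free model — one branch-length parameter per edge;
* clock model — the tree is ultrametric, parameterized by the root
  height and one height proportion per internal node.

The statistic 2(lnL_free - lnL_clock) is referred to a chi-square
distribution with n - 2 degrees of freedom for n leaves. Likelihoods
are computed by Felsenstein's pruning algorithm with site-pattern
compression; gapped or ambiguous tip states are marginalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from ._tn93 import TN93Model, TN93Params, discrete_gamma_rates, empirical_frequencies, encode
from .alignment import Alignment
from .distances import DistanceMatrix, tn93_distances
from .errors import OptimizationError, TreeError
from .trees import nj_tree, root_tree, to_newick

__all__ = ["ClockTestResult", "tree_loglik", "clock_lrt", "nj_tree"]

_TIP_PARTIALS = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing data
_MIN_BLEN, _MAX_BLEN = 1e-8, 3.0


class _IndexedTree:
    """Array view of a dendropy tree for fast pruning.

    Leaves are numbered by their position in ``leaf_order``; internal
    nodes follow in postorder. Every non-root node owns one branch.
    """

    def __init__(self, tree: dendropy.Tree, leaf_order: list[str]):
        index_of = {label: i for i, label in enumerate(leaf_order)}
        n = len(leaf_order)
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if labels != set(leaf_order):
            raise TreeError(
                f"tree leaves do not match alignment IDs; "
                f"only_in_tree={sorted(labels - set(leaf_order))}, "
                f"only_in_alignment={sorted(set(leaf_order) - labels)}"
            )
        self.n_leaves = n
        self._id_of: dict[int, int] = {}
        next_internal = n
        post_internal: list[tuple[int, list[int]]] = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._id_of[id(node)] = index_of[node.taxon.label]
            else:
                nid = next_internal
                next_internal += 1
                self._id_of[id(node)] = nid
                post_internal.append((nid, [self._id_of[id(c)] for c in node.child_nodes()]))
        self.n_nodes = next_internal
        self.postorder_internal = post_internal
        self.root_id = self._id_of[id(tree.seed_node)]
        # branch parameter per non-root node
        self.edge_of = np.full(self.n_nodes, -1, dtype=int)
        self.parent_of = np.full(self.n_nodes, -1, dtype=int)
        lengths = []
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            nid = self._id_of[id(node)]
            self.edge_of[nid] = len(lengths)
            self.parent_of[nid] = self._id_of[id(node.parent_node)]
            lengths.append(node.edge.length if node.edge.length is not None else 0.0)
        self.branch_lengths = np.asarray(lengths, float)
        self.n_edges = len(lengths)
        # preorder internal non-root nodes, for clock height parameters
        self.preorder_internal_nonroot = [
            self._id_of[id(node)]
            for node in tree.preorder_node_iter()
            if (not node.is_leaf()) and node.parent_node is not None
        ]
        self.children_of: dict[int, list[int]] = {nid: kids for nid, kids in post_internal}


def _compress(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (npat, n_seq) and their weights."""
    codes = np.stack([encode(r.residues) for r in aln.records]).T  # (L, n)
    patterns, weights = np.unique(codes, axis=0, return_counts=True)
    return patterns, weights.astype(float)


def _loglik(
    idx: _IndexedTree,
    patterns: np.ndarray,
    weights: np.ndarray,
    blens: np.ndarray,
    model: TN93Model,
    rates: np.ndarray,
) -> float:
    k = len(rates)
    t = np.multiply.outer(np.clip(blens, 0.0, None), rates)  # (E, k)
    pmats = model.transition_probs(t)  # (E, k, 4, 4)
    partials: list[np.ndarray | None] = [None] * idx.n_nodes
    for leaf in range(idx.n_leaves):
        partials[leaf] = _TIP_PARTIALS[patterns[:, leaf]]  # (npat, 4)
    for nid, children in idx.postorder_internal:
        acc = None
        for c in children:
            p_c = pmats[idx.edge_of[c]]  # (k, 4, 4)
            child = partials[c]
            if child.ndim == 2:  # leaf child, no category axis
                msg = np.einsum("kij,pj->pki", p_c, child)
            else:
                msg = np.einsum("kij,pkj->pki", p_c, child)
            acc = msg if acc is None else acc * msg
        partials[nid] = acc
    root = partials[idx.root_id]
    if root.ndim == 2:  # degenerate: root is a leaf
        root = root[:, None, :]
    site_like = np.einsum("j,pkj->pk", model.pi, root).mean(axis=1)
    if np.any(site_like <= 0):
        return -np.inf
    return float(weights @ np.log(site_like))


def tree_loglik(
    aln: Alignment,
    tree: dendropy.Tree,
    params: TN93Params,
    gamma_categories: int = 4,
) -> float:
    """Log-likelihood of an alignment on a tree with fixed branch lengths.

    ``params.gamma_shape`` of ``None`` means rate homogeneity (a single
    unit-rate category).
    """
    idx = _IndexedTree(tree, aln.ids)
    patterns, weights = _compress(aln)
    model = TN93Model(params)
    if params.gamma_shape is None:
        rates = np.ones(1)
    else:
        rates = discrete_gamma_rates(params.gamma_shape, gamma_categories)
    return _loglik(idx, patterns, weights, idx.branch_lengths, model, rates)


@dataclass(frozen=True)
class ClockTestResult:
    """Likelihood-ratio clock test on a fixed topology."""

    lnL_free: float
    lnL_clock: float
    df: int
    alpha_shape: float | None
    kappa1: float
    kappa2: float
    free_tree: str  # Newick with optimized free branch lengths
    clock_tree: str  # Newick, ultrametric

    @property
    def lr_stat(self) -> float:
        return max(0.0, 2.0 * (self.lnL_free - self.lnL_clock))

    @property
    def p_value(self) -> float:
        return float(chi2.sf(self.lr_stat, self.df))

    def to_json(self) -> str:
        return json.dumps(
            {
                "lnL_free": self.lnL_free,
                "lnL_clock": self.lnL_clock,
                "lr_stat": self.lr_stat,
                "df": self.df,
                "p_value": self.p_value,
                "alpha_shape": self.alpha_shape,
                "kappa1": self.kappa1,
                "kappa2": self.kappa2,
            },
            indent=2,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _clock_heights_init(idx: _IndexedTree) -> np.ndarray:
    """Mean distance to descendant leaves, per node (from current blens)."""
    heights = np.zeros(idx.n_nodes)
    for nid, children in idx.postorder_internal:
        vals = [heights[c] + idx.branch_lengths[idx.edge_of[c]] for c in children]
        heights[nid] = float(np.mean(vals))
    return heights


def _clock_blens(idx: _IndexedTree, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Height parameters -> branch lengths (root height + proportions)."""
    heights = np.zeros(idx.n_nodes)
    heights[idx.root_id] = np.exp(x[0])
    for pos, nid in enumerate(idx.preorder_internal_nonroot):
        heights[nid] = heights[idx.parent_of[nid]] * expit(x[1 + pos])
    blens = np.zeros(idx.n_edges)
    for nid in range(idx.n_nodes):
        e = idx.edge_of[nid]
        if e >= 0:
            blens[e] = heights[idx.parent_of[nid]] - heights[nid]
    return blens, heights


def _fit_free(
    idx: _IndexedTree,
    patterns: np.ndarray,
    weights: np.ndarray,
    pi: np.ndarray,
    gamma_categories: int,
    estimate_alpha: bool,
    x0_blens: np.ndarray,
    x0_model: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    n_e = idx.n_edges

    def unpack(x):
        blens = np.exp(x[:n_e])
        k1, k2 = np.exp(x[n_e]), np.exp(x[n_e + 1])
        alpha = np.exp(x[n_e + 2]) if estimate_alpha else None
        return blens, k1, k2, alpha

    def nll(x):
        blens, k1, k2, alpha = unpack(x)
        model = TN93Model(TN93Params(tuple(pi), k1, k2))
        rates = (
            discrete_gamma_rates(alpha, gamma_categories)
            if alpha is not None
            else np.ones(1)
        )
        ll = _loglik(idx, patterns, weights, blens, model, rates)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.concatenate([np.log(np.clip(x0_blens, _MIN_BLEN, _MAX_BLEN)), x0_model])
    bounds = [(np.log(_MIN_BLEN), np.log(_MAX_BLEN))] * n_e
    bounds += [(np.log(0.05), np.log(200.0))] * 2
    if estimate_alpha:
        bounds += [(np.log(0.05), np.log(50.0))]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-10})
    blens, k1, k2, alpha = unpack(res.x)
    model_x = res.x[n_e:]
    return -res.fun, blens, model_x


def clock_lrt(
    aln: Alignment,
    topology: dendropy.Tree | None = None,
    *,
    outgroup: str | None = None,
    gamma_categories: int = 4,
    estimate_alpha: bool = True,
    seed: int = 0,
    n_restarts: int = 1,
) -> ClockTestResult:
    """Likelihood-ratio test of the strict molecular clock.

    Branch lengths are optimized under the free and clock models with
    shared TN93 parameters; the gamma shape (and rate ratios) are
    estimated under the free model and held fixed for the clock model.
    ``topology`` defaults to neighbor joining on TN93 distances. The
    root for the clock model sits on the outgroup edge when one is
    named, otherwise at the midpoint.
    """
    if len(aln) < 3:
        raise TreeError("clock test needs at least 3 sequences")
    rng = np.random.default_rng(seed)
    if topology is None:
        topology = nj_tree(tn93_distances(aln))
    patterns, weights = _compress(aln)
    pi = empirical_frequencies(np.stack([encode(r.residues) for r in aln.records]),
                               pseudocount=1.0)

    # ---- free model -------------------------------------------------
    idx_free = _IndexedTree(topology, aln.ids)
    x0_model = np.log([4.0, 4.0, 1.0])[: 3 if estimate_alpha else 2]
    best = _fit_free(idx_free, patterns, weights, pi, gamma_categories,
                     estimate_alpha, idx_free.branch_lengths, x0_model)
    for _ in range(max(0, n_restarts - 1)):
        jitter = np.exp(rng.normal(0.0, 0.5, idx_free.n_edges))
        cand = _fit_free(idx_free, patterns, weights, pi, gamma_categories,
                         estimate_alpha, idx_free.branch_lengths * jitter + 1e-6,
                         x0_model + rng.normal(0.0, 0.3, len(x0_model)))
        if cand[0] > best[0]:
            best = cand
    lnl_free, free_blens, model_x = best
    kappa1, kappa2 = float(np.exp(model_x[0])), float(np.exp(model_x[1]))
    alpha = float(np.exp(model_x[2])) if estimate_alpha else None
    model = TN93Model(TN93Params(tuple(pi), kappa1, kappa2))
    rates = discrete_gamma_rates(alpha, gamma_categories) if alpha else np.ones(1)

    # write optimized lengths back for the clock initialization / report
    for node in topology.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(free_blens[idx_free.edge_of[idx_free._id_of[id(node)]]])

    # ---- clock model ------------------------------------------------
    rooted = root_tree(topology, outgroup=outgroup)
    idx_clock = _IndexedTree(rooted, aln.ids)

    def clock_nll(x):
        blens, _ = _clock_blens(idx_clock, x)
        ll = _loglik(idx_clock, patterns, weights, blens, model, rates)
        return -ll if np.isfinite(ll) else 1e12

    heights0 = _clock_heights_init(idx_clock)
    h_root0 = max(heights0[idx_clock.root_id], 10 * _MIN_BLEN)
    x0 = [np.log(h_root0)]
    for nid in idx_clock.preorder_internal_nonroot:
        parent_h = max(heights0[idx_clock.parent_of[nid]], 10 * _MIN_BLEN)
        prop = np.clip(heights0[nid] / parent_h, 0.02, 0.98)
        x0.append(float(logit(prop)))
    x0 = np.asarray(x0)
    bounds = [(np.log(_MIN_BLEN), np.log(2 * _MAX_BLEN))] + [(-14.0, 14.0)] * (len(x0) - 1)

    def _fit_clock(x_start):
        res = minimize(clock_nll, x_start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10})
        return -res.fun, res.x

    lnl_clock, x_clock = _fit_clock(x0)
    for _ in range(max(1, n_restarts) - 1):
        cand = _fit_clock(x0 + rng.normal(0.0, 0.5, len(x0)))
        if cand[0] > lnl_clock:
            lnl_clock, x_clock = cand

    # nesting guard: the clock optimum is a feasible free configuration,
    # so polishing the free model from it guarantees lnL_free >= lnL_clock
    if lnl_clock > lnl_free - 1e-6:
        clock_blens_rooted, _ = _clock_blens(idx_clock, x_clock)
        for node in rooted.postorder_node_iter():
            if node.parent_node is not None:
                nid = idx_clock._id_of[id(node)]
                node.edge.length = float(clock_blens_rooted[idx_clock.edge_of[nid]])
        idx_free2 = _IndexedTree(rooted, aln.ids)
        cand = _fit_free(idx_free2, patterns, weights, pi, gamma_categories,
                         estimate_alpha, np.clip(idx_free2.branch_lengths, _MIN_BLEN, None),
                         model_x)
        if cand[0] > lnl_free:
            lnl_free = cand[0]
    if lnl_free < lnl_clock - 1e-4:
        raise OptimizationError(
            f"free-model likelihood ({lnl_free:.6f}) below clock likelihood "
            f"({lnl_clock:.6f}); optimization failed"
        )
    lnl_free = max(lnl_free, lnl_clock)

    clock_blens_final, _ = _clock_blens(idx_clock, x_clock)
    for node in rooted.postorder_node_iter():
        if node.parent_node is not None:
            nid = idx_clock._id_of[id(node)]
            node.edge.length = float(clock_blens_final[idx_clock.edge_of[nid]])

    return ClockTestResult(
        lnL_free=float(lnl_free),
        lnL_clock=float(lnl_clock),
        df=len(aln) - 2,
        alpha_shape=alpha,
        kappa1=kappa1,
        kappa2=kappa2,
        free_tree=to_newick(topology),
        clock_tree=to_newick(rooted),
    )
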