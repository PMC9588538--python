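"""Sum-of-trees regression machinery (BART).

A forest of H shallow binary trees approximates an unknown regression function
f(a, x).  Each MCMC sweep performs Bayesian backfitting: for every tree, a
structural Metropolis-Hastings move (grow / prune / change) is proposed against
the branching-process tree prior of Chipman, George & McCulloch, accepted with
the integrated-likelihood ratio (leaf values marginalized out under their
conjugate normal prior), after which all leaf values are redrawn from their
normal conditionals.

Splits are discrete: a split value is drawn uniformly from the observed unique
values of the chosen covariate within the node, excluding the maximum so both
children are non-empty by construction; the split variable is drawn uniformly
over covariates with at least two distinct values in the node.  The treatment
label enters as an unordered categorical predictor via indicator columns
appended to the covariate block (see :mod:`riaftbart.model`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_LEAF = -1
_DEAD = -2

# grow / prune / change move probabilities (swap omitted)
MOVE_PROBS = (0.25, 0.25, 0.50)


def leaf_prior_sd(sigma_hat_aft: float, H: int, k: float) -> float:
    """SD of the N(0, xi^2/(4 H k^2)) leaf prior, with xi = 4 sigma_hat_aft.

    Summing H independent leaves induces a N(0, 4 sigma_hat_aft^2 / k^2) prior
    on f, so k = 2 places ~95% prior mass on [-2 sigma_hat_aft, 2 sigma_hat_aft].
    """
    if sigma_hat_aft <= 0 or H < 1 or k <= 0:
        raise ValueError("sigma_hat_aft, H and k must be positive")
    xi = 4.0 * sigma_hat_aft
    return xi / (2.0 * k * np.sqrt(H))


@dataclass
class BARTHyperparams:
    """Hyperparameters of the sum-of-trees prior.

    H : number of trees (200 by default).
    k : leaf-prior shrinkage; the induced prior on f has SD 2*sigma_hat_aft/k.
    xi : leaf-prior scale, 4*sigma_hat_aft (set at centering time).
    nu, lam : IG(nu/2, nu*lam/2) prior on the residual variance sigma^2; lam is
        calibrated at initialization so that P(sigma < sigma^(0)) = 0.9.
    base, power : branching prior, P(split at depth d) = base*(1+d)^-power.
    """

    H: int = 200
    k: float = 2.0
    xi: float = 4.0
    nu: float = 3.0
    lam: float = 1.0
    base: float = 0.95
    power: float = 2.0

    def __post_init__(self) -> None:
        if self.H < 1 or self.k <= 0 or self.nu <= 0 or self.lam <= 0 or self.xi <= 0:
            raise ValueError("invalid BART hyperparameters")

    @property
    def leaf_sd(self) -> float:
        return self.xi / (2.0 * self.k * np.sqrt(self.H))


class Tree:
    """A single binary regression tree over a fixed training design.

    Nodes live in parallel arrays; ``var[i] == -1`` marks a leaf, ``-2`` a
    freed slot.  ``node_of`` maps each training row to its leaf node id, which
    makes per-sweep sufficient statistics a pair of ``bincount`` calls.
    """

    __slots__ = ("var", "cut", "left", "right", "parent", "depth", "leaf_val", "node_of")

    def __init__(self, n_rows: int):
        self.var = [_LEAF]
        self.cut = [0.0]
        self.left = [-1]
        self.right = [-1]
        self.parent = [-1]
        self.depth = [0]
        self.leaf_val = [0.0]
        self.node_of = np.zeros(n_rows, dtype=np.int64)

    # -- structure queries ----------------------------------------------------
    def leaves(self) -> list[int]:
        return [i for i, v in enumerate(self.var) if v == _LEAF]

    def internal(self) -> list[int]:
        return [i for i, v in enumerate(self.var) if v >= 0]

    def prunable(self) -> list[int]:
        """Internal nodes whose two children are both leaves."""
        return [i for i, v in enumerate(self.var)
                if v >= 0 and self.var[self.left[i]] == _LEAF and self.var[self.right[i]] == _LEAF]

    def n_nodes(self) -> int:
        return sum(1 for v in self.var if v != _DEAD)

    def fit(self) -> np.ndarray:
        vals = np.asarray(self.leaf_val)
        return vals[self.node_of]

    def _new_node(self, parent: int) -> int:
        self.var.append(_LEAF)
        self.cut.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.parent.append(parent)
        self.depth.append(self.depth[parent] + 1)
        self.leaf_val.append(0.0)
        return len(self.var) - 1

    # -- prediction -----------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Route rows of X through the tree and return leaf values."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        todo = [0]
        while todo:
            i = todo.pop()
            if self.var[i] == _LEAF:
                continue
            mask = node == i
            go_left = X[mask, self.var[i]] <= self.cut[i]
            idx = np.flatnonzero(mask)
            node[idx[go_left]] = self.left[i]
            node[idx[~go_left]] = self.right[i]
            todo.extend((self.left[i], self.right[i]))
        return np.asarray(self.leaf_val)[node]

    def subtree_leaves(self, i: int) -> list[int]:
        out, todo = [], [i]
        while todo:
            j = todo.pop()
            if self.var[j] == _LEAF:
                out.append(j)
            elif self.var[j] >= 0:
                todo.extend((self.left[j], self.right[j]))
        return out

    def to_dict(self) -> dict:
        return {k: (getattr(self, k) if k != "node_of" else None)
                for k in ("var", "cut", "left", "right", "parent", "depth", "leaf_val")}


def _log_marg(n: np.ndarray, s: np.ndarray, sigma2: float, leaf_var: float) -> np.ndarray:
    """Log integrated likelihood contribution of leaves with counts n, residual
    sums s (terms constant across tree structures dropped)."""
    denom = sigma2 + n * leaf_var
    return 0.5 * np.log(sigma2 / denom) + leaf_var * s * s / (2.0 * sigma2 * denom)


class Forest:
    """State of the sum-of-trees fit on a fixed training design.

    ``X`` is the (n, p) training design *including* the treatment indicator
    columns.  ``total_fit`` caches sum_h g_h(row) for every training row and is
    maintained incrementally; :meth:`cache_drift` reports its error.
    """

    def __init__(self, X: np.ndarray, H: int):
        self.X = np.ascontiguousarray(np.asarray(X, dtype=float))
        self.n, self.p = self.X.shape
        self.trees = [Tree(self.n) for _ in range(H)]
        self.total_fit = np.zeros(self.n)

    # -- invariants -----------------------------------------------------------
    def recompute_fit(self) -> np.ndarray:
        out = np.zeros(self.n)
        for t in self.trees:
            out += t.fit()
        return out

    def cache_drift(self) -> float:
        return float(np.max(np.abs(self.total_fit - self.recompute_fit()))) if self.n else 0.0

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.p:
            raise ValueError(f"expected design with {self.p} columns, got {X_new.shape}")
        out = np.zeros(X_new.shape[0])
        for t in self.trees:
            out += t.predict(X_new)
        return out

    def mean_depth(self) -> float:
        d = [t.depth[leaf] for t in self.trees for leaf in t.leaves()]
        return float(np.mean(d))

    def to_json(self) -> str:
        return json.dumps([t.to_dict() for t in self.trees])

    # -- MH moves -------------------------------------------------------------
    def _split_prob(self, depth: int, hyper: BARTHyperparams) -> float:
        return hyper.base * (1.0 + depth) ** (-hyper.power)

    def _try_grow(self, tree: Tree, R: np.ndarray, sigma2: float,
                  hyper: BARTHyperparams, rng: np.random.Generator) -> None:
        leaves = tree.leaves()
        L = leaves[rng.integers(len(leaves))]
        mask = tree.node_of == L
        rows = np.flatnonzero(mask)
        if rows.size < 2:
            return
        sub = self.X[rows]
        spread = sub.max(axis=0) > sub.min(axis=0)
        valid = np.flatnonzero(spread)
        if valid.size == 0:
            return
        v = valid[rng.integers(valid.size)]
        u = np.unique(sub[:, v])
        cut = u[rng.integers(u.size - 1)]
        go_left = sub[:, v] <= cut

        r_node = R[rows]
        s_all = r_node.sum()
        s_left = r_node[go_left].sum()
        n_all = rows.size
        n_left = int(go_left.sum())
        lv = hyper.leaf_sd ** 2
        loglik = (_log_marg(np.array(n_left), np.array(s_left), sigma2, lv)
                  + _log_marg(np.array(n_all - n_left), np.array(s_all - s_left), sigma2, lv)
                  - _log_marg(np.array(n_all), np.array(s_all), sigma2, lv))

        d = tree.depth[L]
        p_d = self._split_prob(d, hyper)
        p_d1 = self._split_prob(d + 1, hyper)
        log_prior = np.log(p_d) + 2.0 * np.log1p(-p_d1) - np.log1p(-p_d)

        par = tree.parent[L]
        sibling_leaf = (par >= 0 and
                        tree.var[tree.left[par] if tree.right[par] == L else tree.right[par]] == _LEAF)
        n_prunable_new = len(tree.prunable()) + 1 - (1 if sibling_leaf else 0)
        log_q = (np.log(MOVE_PROBS[1]) - np.log(MOVE_PROBS[0])
                 + np.log(len(leaves)) - np.log(n_prunable_new))

        if np.log(rng.random()) < float(log_prior + log_q + loglik):
            l = tree._new_node(L)
            r = tree._new_node(L)
            tree.var[L] = int(v)
            tree.cut[L] = float(cut)
            tree.left[L], tree.right[L] = l, r
            tree.node_of[rows[go_left]] = l
            tree.node_of[rows[~go_left]] = r

    def _try_prune(self, tree: Tree, R: np.ndarray, sigma2: float,
                   hyper: BARTHyperparams, rng: np.random.Generator) -> None:
        prunable = tree.prunable()
        if not prunable:
            return
        P = prunable[rng.integers(len(prunable))]
        l, r = tree.left[P], tree.right[P]
        mask = (tree.node_of == l) | (tree.node_of == r)
        rows = np.flatnonzero(mask)
        r_node = R[rows]
        s_left = r_node[tree.node_of[rows] == l].sum()
        s_all = r_node.sum()
        n_left = int((tree.node_of[rows] == l).sum())
        n_all = rows.size
        lv = hyper.leaf_sd ** 2
        loglik_split = (_log_marg(np.array(n_left), np.array(s_left), sigma2, lv)
                        + _log_marg(np.array(n_all - n_left), np.array(s_all - s_left), sigma2, lv)
                        - _log_marg(np.array(n_all), np.array(s_all), sigma2, lv))

        d = tree.depth[P]
        p_d = self._split_prob(d, hyper)
        p_d1 = self._split_prob(d + 1, hyper)
        log_prior = np.log(p_d) + 2.0 * np.log1p(-p_d1) - np.log1p(-p_d)
        n_leaves_after = len(tree.leaves()) - 1
        log_q_grow = (np.log(MOVE_PROBS[1]) - np.log(MOVE_PROBS[0])
                      + np.log(n_leaves_after) - np.log(len(prunable)))

        log_alpha = -(float(log_prior) + float(log_q_grow) + float(loglik_split))
        if np.log(rng.random()) < log_alpha:
            tree.node_of[rows] = P
            tree.var[P] = _LEAF
            tree.var[l] = tree.var[r] = _DEAD
            tree.left[P] = tree.right[P] = -1

    def _try_change(self, tree: Tree, R: np.ndarray, sigma2: float,
                    hyper: BARTHyperparams, rng: np.random.Generator) -> None:
        internal = tree.internal()
        if not internal:
            return
        C = internal[rng.integers(len(internal))]
        old_leaves = tree.subtree_leaves(C)
        mask = np.isin(tree.node_of, old_leaves)
        rows = np.flatnonzero(mask)
        sub = self.X[rows]
        spread = sub.max(axis=0) > sub.min(axis=0)
        valid = np.flatnonzero(spread)
        if valid.size == 0:
            return
        v = valid[rng.integers(valid.size)]
        u = np.unique(sub[:, v])
        cut = u[rng.integers(u.size - 1)]

        # re-route subtree rows under the proposed rule at C
        new_node_of = np.full(rows.size, C, dtype=np.int64)
        stack = [(C, int(v), float(cut))]
        ok = True
        while stack:
            i, vi, ci = stack.pop()
            m = new_node_of == i
            idx = np.flatnonzero(m)
            if idx.size == 0:
                ok = False
                break
            if tree.var[i] == _LEAF:
                continue
            go_left = sub[idx, vi] <= ci
            new_node_of[idx[go_left]] = tree.left[i]
            new_node_of[idx[~go_left]] = tree.right[i]
            for child in (tree.left[i], tree.right[i]):
                if tree.var[child] == _LEAF:
                    if not (new_node_of == child).any():
                        ok = False
                        stack.clear()
                        break
                else:
                    stack.append((child, tree.var[child], tree.cut[child]))
            if not ok:
                break
        if not ok:
            return

        lv = hyper.leaf_sd ** 2
        r_node = R[rows]
        nbins = len(tree.var)
        old_ids = tree.node_of[rows]
        n_old = np.bincount(old_ids, minlength=nbins)[old_leaves]
        s_old = np.bincount(old_ids, weights=r_node, minlength=nbins)[old_leaves]
        n_new = np.bincount(new_node_of, minlength=nbins)[old_leaves]
        s_new = np.bincount(new_node_of, weights=r_node, minlength=nbins)[old_leaves]
        if np.any(n_new == 0):
            return
        loglik = (_log_marg(n_new, s_new, sigma2, lv).sum()
                  - _log_marg(n_old, s_old, sigma2, lv).sum())
        if np.log(rng.random()) < float(loglik):
            tree.var[C] = int(v)
            tree.cut[C] = float(cut)
            tree.node_of[rows] = new_node_of

    def _draw_leaves(self, tree: Tree, R: np.ndarray, sigma2: float,
                     hyper: BARTHyperparams, rng: np.random.Generator) -> None:
        nbins = len(tree.var)
        n = np.bincount(tree.node_of, minlength=nbins)
        s = np.bincount(tree.node_of, weights=R, minlength=nbins)
        lv = hyper.leaf_sd ** 2
        leaves = tree.leaves()
        for leaf in leaves:
            post_var = 1.0 / (n[leaf] / sigma2 + 1.0 / lv)
            post_mean = post_var * s[leaf] / sigma2
            tree.leaf_val[leaf] = post_mean + np.sqrt(post_var) * rng.standard_normal()


def update_forest(forest: Forest, response: np.ndarray, sigma2: float,
                  hyper: BARTHyperparams, rng: np.random.Generator) -> Forest:
    """One Bayesian-backfitting sweep over all trees (in place).

    ``response`` is the partial response the forest should fit (complete-data
    centered log times minus the cluster intercepts).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    response = np.asarray(response, dtype=float)
    if response.shape[0] != forest.n:
        raise ValueError("response length does not match training size")
    for tree in forest.trees:
        old_fit = tree.fit()
        R = response - (forest.total_fit - old_fit)
        move = rng.random()
        if move < MOVE_PROBS[0]:
            forest._try_grow(tree, R, sigma2, hyper, rng)
        elif move < MOVE_PROBS[0] + MOVE_PROBS[1]:
            forest._try_prune(tree, R, sigma2, hyper, rng)
        else:
            forest._try_change(tree, R, sigma2, hyper, rng)
        forest._draw_leaves(tree, R, sigma2, hyper, rng)
        forest.total_fit += tree.fit() - old_fit
    return forest


def update_sigma2(residuals: np.ndarray, nu: float, lam: float,
                  rng: np.random.Generator) -> float:
    """Conjugate residual-variance draw.

    Under the IG(nu/2, nu*lam/2) prior and normal residuals the conditional is
    IG((nu + n)/2, (nu*lam + sum r^2)/2).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("residuals must be non-empty")
    shape = 0.5 * (nu + residuals.size)
    scale = 0.5 * (nu * lam + float(residuals @ residuals))
    return scale / rng.gamma(shape)
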