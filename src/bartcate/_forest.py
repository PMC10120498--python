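"""Sum-of-trees sampler internals.

Implements the backfitting Metropolis-within-Gibbs sampler over an ensemble
of binary regression trees with the depth-penalizing structure prior
P(split at depth d) = alpha * (1 + d)^(-beta), conjugate Normal(0, sigma_mu^2)
leaf values, and grow / prune / change structure proposals.  Proposals that
would create an empty leaf, or nodes with no valid cutpoint, are rejected.

The sampler supports optional per-observation precision weights (used by the
logit link's scale-mixture augmentation) and maintains incremental fits on
both the training matrix and an optional test matrix so that counterfactual
predictions cost O(n_test) per tree update instead of a full re-evaluation.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["split_probability", "CutpointGrid", "TreeSampler", "eval_frozen_tree"]


def split_probability(depth: int, base: float, power: float) -> float:
    """Prior probability that a node at ``depth`` is internal: alpha*(1+d)^-beta."""
    if not (0.0 < base < 1.0):
        raise ValueError("base (alpha) must lie in (0, 1)")
    if power < 0:
        raise ValueError("power (beta) must be >= 0")
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    return base * (1.0 + depth) ** (-power)


class CutpointGrid:
    """Per-variable cutpoint grids: midpoints of adjacent unique observed
    values, thinned to at most ``max_cuts`` quantile-spaced cutpoints."""

    def __init__(self, X: np.ndarray, max_cuts: int = 100):
        self.grids: list[np.ndarray] = []
        for j in range(X.shape[1]):
            uniq = np.unique(X[:, j])
            if len(uniq) < 2:
                self.grids.append(np.empty(0))
                continue
            mids = 0.5 * (uniq[:-1] + uniq[1:])
            if len(mids) > max_cuts:
                qs = np.quantile(mids, np.linspace(0, 1, max_cuts))
                mids = np.unique(qs)
            self.grids.append(mids)

    def valid_range(self, j: int, xlo: float, xhi: float) -> tuple[int, int]:
        """Index range [i0, i1) of cutpoints c with xlo <= c < xhi; a cut c
        sends points with x <= c left, so this range is exactly the cuts that
        leave both children nonempty."""
        g = self.grids[j]
        i0 = int(np.searchsorted(g, xlo, side="left"))
        i1 = int(np.searchsorted(g, xhi, side="left"))
        return i0, i1


class _Node:
    __slots__ = ("var", "cut", "left", "right", "mu", "idx", "tidx", "depth", "parent")

    def __init__(self, idx, tidx, depth, parent=None):
        self.var = -1
        self.cut = 0.0
        self.left = None
        self.right = None
        self.mu = 0.0
        self.idx = idx            # training row indices reaching this node
        self.tidx = tidx          # test row indices (may be None)
        self.depth = depth
        self.parent = parent

    @property
    def is_leaf(self) -> bool:
        return self.var < 0


def _leaves(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            out.append(nd)
        else:
            stack.append(nd.left)
            stack.append(nd.right)
    return out


def _nog_nodes(root: _Node) -> list[_Node]:
    """Internal nodes whose both children are leaves ('no grandchildren')."""
    out, stack = [], [root]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf:
            if nd.left.is_leaf and nd.right.is_leaf:
                out.append(nd)
            else:
                stack.append(nd.left)
                stack.append(nd.right)
    return out


def freeze_tree(root: _Node) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Serialize a tree to flat parallel arrays (preorder); var = -1 at leaves."""
    var, cut, left, right, mu = [], [], [], [], []

    def rec(nd: _Node) -> int:
        i = len(var)
        var.append(nd.var)
        cut.append(nd.cut)
        mu.append(nd.mu)
        left.append(-1)
        right.append(-1)
        if not nd.is_leaf:
            left[i] = rec(nd.left)
            right[i] = rec(nd.right)
        return i

    rec(root)
    return (
        np.asarray(var, dtype=np.int32),
        np.asarray(cut, dtype=np.float64),
        np.asarray(left, dtype=np.int32),
        np.asarray(right, dtype=np.int32),
        np.asarray(mu, dtype=np.float64),
    )


def eval_frozen_tree(frozen, X: np.ndarray) -> np.ndarray:
    """Vectorized evaluation of a frozen tree on rows of X."""
    var, cut, left, right, mu = frozen
    n = X.shape[0]
    out = np.empty(n)
    stack = [(0, np.arange(n))]
    while stack:
        i, rows = stack.pop()
        if var[i] < 0:
            out[rows] = mu[i]
        else:
            mask = X[rows, var[i]] <= cut[i]
            stack.append((int(left[i]), rows[mask]))
            stack.append((int(right[i]), rows[~mask]))
    return out


class TreeSampler:
    """State and single-sweep updates for one chain's forest.

    Works on an internal standardized response scale; the caller owns any
    outcome rescaling.  ``sigma2`` is the residual variance on that scale
    (fixed to 1 for latent-variable binary models).
    """

    def __init__(
        self,
        X: np.ndarray,
        m: int,
        base: float,
        power: float,
        sigma_mu: float,
        rng: np.random.Generator,
        X_test: np.ndarray | None = None,
        p_grow: float = 0.25,
        p_prune: float = 0.25,
        p_change: float = 0.50,
        max_cuts: int = 100,
    ):
        if not math.isclose(p_grow + p_prune + p_change, 1.0, abs_tol=1e-9):
            raise ValueError("proposal probabilities must sum to 1")
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.X_test = None if X_test is None else np.ascontiguousarray(X_test, dtype=np.float64)
        self.n, self.p = self.X.shape
        self.m = m
        self.base = base
        self.power = power
        self.sigma_mu2 = sigma_mu * sigma_mu
        self.rng = rng
        self.p_grow, self.p_prune, self.p_change = p_grow, p_prune, p_change
        self.grid = CutpointGrid(self.X, max_cuts=max_cuts)

        all_idx = np.arange(self.n)
        all_tidx = None if self.X_test is None else np.arange(self.X_test.shape[0])
        self.trees = [_Node(all_idx, all_tidx, 0) for _ in range(m)]
        self.fits = np.zeros((m, self.n))
        self.total = np.zeros(self.n)
        self.tfits = None if self.X_test is None else np.zeros((m, self.X_test.shape[0]))
        self.ttotal = None if self.X_test is None else np.zeros(self.X_test.shape[0])
        self.accept = {"grow": 0, "prune": 0, "change": 0}
        self.propose = {"grow": 0, "prune": 0, "change": 0}

    # -- likelihood helpers -------------------------------------------------

    def _node_stats(self, idx, R, w):
        if w is None:
            return float(len(idx)), float(R[idx].sum())
        wi = w[idx]
        return float(wi.sum()), float((wi * R[idx]).sum())

    def _log_marg(self, Sw, Swr, sigma2):
        A = Sw / sigma2
        B = Swr / sigma2
        P = 1.0 / self.sigma_mu2 + A
        return -0.5 * math.log1p(self.sigma_mu2 * A) + 0.5 * B * B / P

    def _psplit(self, depth):
        return self.base * (1.0 + depth) ** (-self.power)

    # -- structure proposals -------------------------------------------------

    def _pick_rule(self, node):
        """Uniformly pick a (var, cut) valid at this node; returns None if the
        node's data admit no split.  Also returns the count of valid vars and
        cuts for the chosen var (needed nowhere after cancellation, but the
        node may have no valid rule at all)."""
        xs = self.X[node.idx]
        valid = []
        for j in range(self.p):
            col = xs[:, j]
            i0, i1 = self.grid.valid_range(j, col.min(), col.max())
            if i1 > i0:
                valid.append((j, i0, i1))
        if not valid:
            return None
        j, i0, i1 = valid[self.rng.integers(len(valid))]
        cut = float(self.grid.grids[j][i0 + self.rng.integers(i1 - i0)])
        return j, cut

    def _split_idx(self, node, j, cut):
        mask = self.X[node.idx, j] <= cut
        li, ri = node.idx[mask], node.idx[~mask]
        if node.tidx is not None:
            tmask = self.X_test[node.tidx, j] <= cut
            lt, rt = node.tidx[tmask], node.tidx[~tmask]
        else:
            lt = rt = None
        return li, ri, lt, rt

    def _grow(self, root, R, sigma2, w):
        leaves = _leaves(root)
        node = leaves[self.rng.integers(len(leaves))]
        rule = self._pick_rule(node)
        if rule is None:
            return False
        j, cut = rule
        li, ri, lt, rt = self._split_idx(node, j, cut)
        if len(li) == 0 or len(ri) == 0:
            return False

        d = node.depth
        ps, ps1 = self._psplit(d), self._psplit(d + 1)
        log_prior = math.log(ps) + 2.0 * math.log1p(-ps1) - math.log1p(-ps)

        Swp, Srp = self._node_stats(node.idx, R, w)
        Swl, Srl = self._node_stats(li, R, w)
        ll_new = self._log_marg(Swl, Srl, sigma2) + self._log_marg(Swp - Swl, Srp - Srl, sigma2)
        ll_old = self._log_marg(Swp, Srp, sigma2)

        nog_after = len(_nog_nodes(root)) + 1
        if node.parent is not None:
            sib = node.parent.left if node.parent.right is node else node.parent.right
            if sib.is_leaf:
                nog_after -= 1
        log_trans = math.log(self.p_prune * len(leaves)) - math.log(self.p_grow * nog_after)

        if math.log(self.rng.random()) < log_prior + log_trans + ll_new - ll_old:
            node.var, node.cut = j, cut
            node.left = _Node(li, lt, d + 1, node)
            node.right = _Node(ri, rt, d + 1, node)
            node.idx = node.idx  # retained for prune restores
            return True
        return False

    def _prune(self, root, R, sigma2, w):
        nogs = _nog_nodes(root)
        if not nogs:
            return False
        node = nogs[self.rng.integers(len(nogs))]
        d = node.depth
        ps, ps1 = self._psplit(d), self._psplit(d + 1)
        log_prior = math.log1p(-ps) - (math.log(ps) + 2.0 * math.log1p(-ps1))

        Swp, Srp = self._node_stats(node.idx, R, w)
        Swl, Srl = self._node_stats(node.left.idx, R, w)
        ll_new = self._log_marg(Swp, Srp, sigma2)
        ll_old = self._log_marg(Swl, Srl, sigma2) + self._log_marg(Swp - Swl, Srp - Srl, sigma2)

        n_leaves_after = len(_leaves(root)) - 1
        log_trans = math.log(self.p_grow * len(nogs)) - math.log(self.p_prune * n_leaves_after)

        if math.log(self.rng.random()) < log_prior + log_trans + ll_new - ll_old:
            node.var = -1
            node.left = node.right = None
            return True
        return False

    def _change(self, root, R, sigma2, w):
        nogs = _nog_nodes(root)
        if not nogs:
            return False
        node = nogs[self.rng.integers(len(nogs))]
        rule = self._pick_rule(node)
        if rule is None:
            return False
        j, cut = rule
        li, ri, lt, rt = self._split_idx(node, j, cut)
        if len(li) == 0 or len(ri) == 0:
            return False

        Swp, Srp = self._node_stats(node.idx, R, w)
        Swl_new, Srl_new = self._node_stats(li, R, w)
        Swl_old, Srl_old = self._node_stats(node.left.idx, R, w)
        ll_new = self._log_marg(Swl_new, Srl_new, sigma2) + self._log_marg(
            Swp - Swl_new, Srp - Srl_new, sigma2
        )
        ll_old = self._log_marg(Swl_old, Srl_old, sigma2) + self._log_marg(
            Swp - Swl_old, Srp - Srl_old, sigma2
        )
        if math.log(self.rng.random()) < ll_new - ll_old:
            node.var, node.cut = j, cut
            node.left.idx, node.right.idx = li, ri
            node.left.tidx, node.right.tidx = lt, rt
            return True
        return False

    # -- Gibbs steps ----------------------------------------------------------

    def _draw_leaf_values(self, root, R, sigma2, w):
        for leaf in _leaves(root):
            Sw, Swr = self._node_stats(leaf.idx, R, w)
            P = 1.0 / self.sigma_mu2 + Sw / sigma2
            mean = (Swr / sigma2) / P
            leaf.mu = mean + self.rng.standard_normal() / math.sqrt(P)

    def _refresh_fit(self, t, root):
        newfit = np.empty(self.n)
        if self.tfits is not None:
            newtfit = np.empty(self.tfits.shape[1])
        for leaf in _leaves(root):
            newfit[leaf.idx] = leaf.mu
            if self.tfits is not None:
                newtfit[leaf.tidx] = leaf.mu
        self.total += newfit - self.fits[t]
        self.fits[t] = newfit
        if self.tfits is not None:
            self.ttotal += newtfit - self.tfits[t]
            self.tfits[t] = newtfit

    def sweep(self, y: np.ndarray, sigma2: float, w: np.ndarray | None = None) -> None:
        """One backfitting sweep: update every tree's structure and leaves."""
        moves = (self._grow, self._prune, self._change)
        probs = (self.p_grow, self.p_prune, self.p_change)
        names = ("grow", "prune", "change")
        for t in range(self.m):
            root = self.trees[t]
            R = y - (self.total - self.fits[t])
            k = self.rng.choice(3, p=probs)
            self.propose[names[k]] += 1
            if moves[k](root, R, sigma2, w):
                self.accept[names[k]] += 1
            self._draw_leaf_values(root, R, sigma2, w)
            self._refresh_fit(t, root)

    def snapshot_forest(self):
        return [freeze_tree(root) for root in self.trees]

    def sum_of_trees(self, fits=None) -> np.ndarray:
        """Sequential sum over per-tree fit vectors (fixed association order so
        stored draws and frozen-forest re-evaluation agree bit-for-bit)."""
        fits = self.fits if fits is None else fits
        out = np.zeros(fits.shape[1])
        for t in range(fits.shape[0]):
            out = out + fits[t]
        return out
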