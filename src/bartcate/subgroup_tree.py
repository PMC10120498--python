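"""Stage 2: "fit-the-fit" subgroup discovery.

A depth-limited CART regression tree is fitted greedily to the per-individual
posterior-mean CATEs, exposing covariate-defined subgroups.  Each node
carries the subgroup's mean effect (in original outcome units), the
proportion of the sample it contains, and — once draws are attached — a 95%
credible interval for the subgroup *mean* effect obtained by averaging the
CATE draws over the subgroup's members within each posterior draw.

Splits minimize the sum of squared errors of the CATE response.  Continuous
cutpoints are evaluated at midpoints of adjacent sorted unique values and
reported in original units (split search is invariant to the affine
standardization, so fitting on original-unit covariates is equivalent to
fitting standardized and back-translating the cutpoints).  The 3-level
respiratory-support factor is split by level subsets (3 levels admit 3
binary partitions).  Determinism: the best split maximizes SSE reduction
with ties broken toward the smaller cutpoint, then the lower variable index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cate import CateResult
from .trial_data import CovariateSchema, TrialDataset

__all__ = ["SubgroupNode", "SubgroupTree", "fit_cart", "build_feature_frame",
           "attach_subgroup_intervals", "render_tree", "parse_tree_json", "tree_depth"]

_TIE_TOL = 1e-12


@dataclass
class SubgroupNode:
    value: float                       # mean CATE of members
    proportion: float                  # fraction of the whole sample
    member_rows: np.ndarray            # row positions into the fitting frame
    depth: int
    var: str | None = None             # split covariate (internal nodes)
    kind: str | None = None            # "numeric" | "categorical"
    cut: float | None = None           # numeric threshold: left if x <= cut
    left_levels: tuple[str, ...] | None = None  # categorical: left if level in set
    left: "SubgroupNode | None" = None
    right: "SubgroupNode | None" = None
    cri_lower: float | None = None
    cri_upper: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class SubgroupTree:
    root: SubgroupNode
    n: int
    scale: str = "days"
    ids: np.ndarray | None = None      # record ids aligned with member_rows

    def leaves(self) -> list[SubgroupNode]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.append(nd.right)
                stack.append(nd.left)
        return out[::-1]

    def nodes(self) -> list[SubgroupNode]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            if not nd.is_leaf:
                stack.append(nd.right)
                stack.append(nd.left)
        return out

    def split_variables(self) -> list[str]:
        return [nd.var for nd in self.nodes() if not nd.is_leaf]


def tree_depth(tree: SubgroupTree) -> int:
    def rec(nd: SubgroupNode) -> int:
        if nd.is_leaf:
            return 0
        return 1 + max(rec(nd.left), rec(nd.right))

    return rec(tree.root)


def build_feature_frame(ds: TrialDataset) -> pd.DataFrame:
    """Covariate frame for tree fitting, continuous values in original units."""
    from .trial_data import destandardize_dataset

    if ds.standardized:
        ds = destandardize_dataset(ds)
    return ds.df[list(ds.schema.names)].copy()


def _best_numeric_split(x: np.ndarray, t: np.ndarray, min_leaf: int):
    """Best SSE-reducing threshold for one numeric column, O(n log n).

    Returns (gain, cut) or None.  Gain is the reduction in SSE relative to
    leaving the node unsplit; since total SSE = const - sum_child (S_c^2/n_c),
    maximizing sum of child (sum^2/count) maximizes the gain.
    """
    order = np.argsort(x, kind="stable")
    xs, ts = x[order], t[order]
    n = len(xs)
    # candidate boundaries: positions where the value changes
    change = np.flatnonzero(xs[1:] > xs[:-1]) + 1  # left child size candidates
    if len(change) == 0:
        return None
    valid = change[(change >= min_leaf) & (n - change >= min_leaf)]
    if len(valid) == 0:
        return None
    csum = np.cumsum(ts)
    total = csum[-1]
    ls = csum[valid - 1]
    score = ls**2 / valid + (total - ls) ** 2 / (n - valid)
    base = total**2 / n
    gains = score - base
    best = int(np.argmax(gains))
    # tie-break toward the smaller cutpoint: scan candidates in increasing x
    for i in range(len(valid)):
        if gains[i] > gains[best] - _TIE_TOL:
            best = i
            break
    k = valid[best]
    cut = 0.5 * (xs[k - 1] + xs[k])
    return float(gains[best]), float(cut)


def _best_categorical_split(x: np.ndarray, t: np.ndarray, levels: tuple[str, ...], min_leaf: int):
    """Best binary partition of the level set; returns (gain, left_levels)."""
    n = len(x)
    total = t.sum()
    base = total**2 / n
    present = [lev for lev in levels if np.any(x == lev)]
    if len(present) < 2:
        return None
    best = None
    # all nonempty proper subsets, canonicalized to exclude complements
    for size in range(1, len(present)):
        from itertools import combinations

        for combo in combinations(present, size):
            if present[0] not in combo:  # fix first level on the left: kills complements
                continue
            mask = np.isin(x, combo)
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            sl = t[mask].sum()
            gain = sl**2 / nl + (total - sl) ** 2 / (n - nl) - base
            if best is None or gain > best[0] + _TIE_TOL:
                best = (float(gain), tuple(combo))
    return best


def fit_cart(
    features: pd.DataFrame,
    t: np.ndarray,
    schema: CovariateSchema,
    max_depth: int = 3,
    min_leaf: int = 20,
    cp: float = 0.01,
    scale: str = "days",
    ids: np.ndarray | None = None,
) -> SubgroupTree:
    """Greedy depth-limited regression tree on posterior-mean CATEs.

    A split is kept only if it reduces the total SSE by at least
    ``cp * root SSE``.  Datasets too small to split return a root-only tree.
    """
    t = np.asarray(t, dtype=float)
    if len(t) != len(features):
        raise ValueError("response length does not match feature rows")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    n = len(t)
    root_sse = float(np.sum((t - t.mean()) ** 2))
    threshold = cp * root_sse

    cols = {name: features[name].to_numpy() for name in schema.names}

    def grow(rows: np.ndarray, depth: int) -> SubgroupNode:
        tm = t[rows]
        node = SubgroupNode(value=float(tm.mean()), proportion=len(rows) / n,
                            member_rows=rows, depth=depth)
        if depth >= max_depth or len(rows) < 2 * min_leaf or root_sse <= 0:
            return node
        best = None  # (gain, var_idx, kind, cut_or_levels)
        for vi, entry in enumerate(schema.entries):
            xv = cols[entry.name][rows]
            if entry.kind == "categorical":
                res = _best_categorical_split(np.asarray(xv, dtype=object), tm, entry.levels, min_leaf)
                if res is None:
                    continue
                gain, payload = res
                kind = "categorical"
            else:
                res = _best_numeric_split(np.asarray(xv, dtype=float), tm, min_leaf)
                if res is None:
                    continue
                gain, payload = res
                kind = "numeric"
            if best is None or gain > best[0] + _TIE_TOL:
                best = (gain, vi, kind, payload)
        if best is None or best[0] < threshold:
            return node
        gain, vi, kind, payload = best
        entry = schema.entries[vi]
        xv = cols[entry.name][rows]
        if kind == "numeric":
            mask = np.asarray(xv, dtype=float) <= payload
            node.cut = float(payload)
        else:
            mask = np.isin(np.asarray(xv, dtype=object), payload)
            node.left_levels = tuple(payload)
        node.var = entry.name
        node.kind = kind
        node.left = grow(rows[mask], depth + 1)
        node.right = grow(rows[~mask], depth + 1)
        return node

    root = grow(np.arange(n), 0)
    return SubgroupTree(root=root, n=n, scale=scale, ids=ids)


def fit_subgroup_tree(
    ds: TrialDataset,
    cate: CateResult,
    max_depth: int = 3,
    min_leaf: int = 20,
    cp: float = 0.01,
) -> SubgroupTree:
    """Convenience wrapper: build the feature frame, fit, attach intervals."""
    feats = build_feature_frame(ds)
    tree = fit_cart(
        feats, cate.mean, ds.schema, max_depth=max_depth, min_leaf=min_leaf,
        cp=cp, scale=cate.scale, ids=ds.df["id"].to_numpy(),
    )
    return attach_subgroup_intervals(tree, cate)


def attach_subgroup_intervals(tree: SubgroupTree, cate: CateResult) -> SubgroupTree:
    """95% credible intervals for every node's subgroup-mean effect.

    Within each posterior draw the CATE draws are averaged over the node's
    members; the 2.5/97.5 percentiles of those averages form the interval.
    """
    if tree.n != cate.draws.shape[1]:
        raise ValueError("tree and CATE result cover different individuals")
    if tree.ids is not None and not np.array_equal(tree.ids, cate.ids):
        raise ValueError("tree ids do not match CATE result ids")
    for nd in tree.nodes():
        gd = cate.draws[:, nd.member_rows].mean(axis=1)
        nd.cri_lower = float(np.percentile(gd, 2.5))
        nd.cri_upper = float(np.percentile(gd, 97.5))
    return tree


# ---------------------------------------------------------------------------
# Rendering


def _split_label(nd: SubgroupNode) -> str:
    if nd.kind == "numeric":
        return f"{nd.var} <= {nd.cut:g}"
    return f"{nd.var} in {{{', '.join(nd.left_levels)}}}"


def _node_dict(nd: SubgroupNode) -> dict:
    d: dict = {
        "estimate": nd.value,
        "proportion": nd.proportion,
        "n": int(len(nd.member_rows)),
    }
    if nd.cri_lower is not None:
        d["cri"] = [nd.cri_lower, nd.cri_upper]
    if not nd.is_leaf:
        d["split"] = {
            "var": nd.var,
            "kind": nd.kind,
            "cut": nd.cut,
            "left_levels": list(nd.left_levels) if nd.left_levels else None,
        }
        d["left"] = _node_dict(nd.left)
        d["right"] = _node_dict(nd.right)
    return d


def render_tree(tree: SubgroupTree, format: str = "text") -> str:
    """Render the subgroup tree as indented text, JSON, or DOT.

    Every box shows the subgroup effect estimate (days or risk difference,
    original scale) and the proportion of the trial sample in the subgroup.
    """
    if format == "json":
        return json.dumps({"n": tree.n, "scale": tree.scale, "root": _node_dict(tree.root)},
                          indent=2)
    if format == "text":
        lines: list[str] = []

        def rec(nd: SubgroupNode, prefix: str, label: str) -> None:
            ci = f" CrI ({nd.cri_lower:.2f}, {nd.cri_upper:.2f})" if nd.cri_lower is not None else ""
            lines.append(f"{prefix}{label}estimate {nd.value:.2f}{ci}  prop {nd.proportion:.2f}")
            if not nd.is_leaf:
                rec(nd.left, prefix + "  ", f"[{_split_label(nd)}] ")
                rec(nd.right, prefix + "  ", f"[not {_split_label(nd)}] ")

        rec(tree.root, "", "")
        return "\n".join(lines)
    if format == "dot":
        lines = ["digraph subgroups {", '  node [shape=box];']
        counter = [0]

        def rec(nd: SubgroupNode) -> int:
            i = counter[0]
            counter[0] += 1
            lines.append(f'  n{i} [label="{nd.value:.2f}\\nprop {nd.proportion:.2f}"];')
            if not nd.is_leaf:
                li, ri = rec(nd.left), rec(nd.right)
                lines.append(f'  n{i} -> n{li} [label="{_split_label(nd)}"];')
                lines.append(f'  n{i} -> n{ri} [label="otherwise"];')
            return i

        rec(tree.root)
        lines.append("}")
        return "\n".join(lines)
    raise ValueError("format must be 'text', 'json', or 'dot'")


def parse_tree_json(text: str) -> SubgroupTree:
    """Rebuild a SubgroupTree from its JSON rendering (structure round-trip).

    Member rows are not serialized; parsed nodes carry empty member sets and
    keep estimates, proportions, intervals and split rules.
    """
    doc = json.loads(text)

    def rec(d: dict, depth: int) -> SubgroupNode:
        # member identities are not serialized; a placeholder index array
        # preserves the subgroup size so re-rendering is faithful
        nd = SubgroupNode(
            value=d["estimate"], proportion=d["proportion"],
            member_rows=np.zeros(int(d["n"]), dtype=int), depth=depth,
        )
        if "cri" in d:
            nd.cri_lower, nd.cri_upper = d["cri"]
        if "split" in d:
            s = d["split"]
            nd.var, nd.kind, nd.cut = s["var"], s["kind"], s["cut"]
            nd.left_levels = tuple(s["left_levels"]) if s["left_levels"] else None
            nd.left = rec(d["left"], depth + 1)
            nd.right = rec(d["right"], depth + 1)
        return nd

    return SubgroupTree(root=rec(doc["root"], 0), n=doc["n"], scale=doc["scale"])
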