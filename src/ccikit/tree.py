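"""Weighted binary classification tree (Gini CART).

Recursive binary partitioning with case weights: each split maximises the
weighted decrease in Gini impurity.  Numeric and ordinal predictors split
at midpoints between observed values; categorical predictors use the
ordered-by-class-rate shortcut (order the levels by their weighted positive
rate and search the ordered cut points), which is exact for a binary
response.  Growth stops on maximum depth, minimum node weight, or when the
best achievable impurity decrease falls below ``min_improvement``.

Survey structure enters only through the case weights; no pruning is done
by default (cost-complexity pruning is available behind a flag).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError


@dataclass
class TreeParams:
    max_depth: int = 4
    min_node_weight: float = 50.0
    min_improvement: float = 1e-3
    use_case_weights: bool = True

    def __post_init__(self):
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if self.min_node_weight <= 0:
            raise ConfigurationError("min_node_weight must be > 0")


@dataclass
class TreeNode:
    node_id: int
    depth: int
    weighted_counts: tuple        # (class0, class1) weighted
    predicted: int
    split_var: str = None
    split_kind: str = None        # "numeric" | "categorical"
    threshold: float = None       # numeric: go left iff x <= threshold
    left_levels: tuple = None     # categorical: go left iff x in levels
    right_levels: tuple = None    # categorical levels seen on the right
    left: "TreeNode" = None
    right: "TreeNode" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    @property
    def weight(self) -> float:
        return sum(self.weighted_counts)


def _gini(counts) -> float:
    tot = sum(counts)
    if tot <= 0:
        return 0.0
    p = np.asarray(counts) / tot
    return float(1.0 - (p ** 2).sum())


def _best_numeric_split(x, y, w):
    """Best threshold for a numeric/ordinal predictor; returns
    (impurity_after, threshold) or None."""
    order = np.argsort(x, kind="mergesort")
    xs, ys, ws = x[order], y[order], w[order]
    cw1 = np.cumsum(ws * ys)
    cw = np.cumsum(ws)
    W, W1 = cw[-1], cw1[-1]
    # candidate cuts: positions where x changes
    change = np.nonzero(np.diff(xs) > 0)[0]
    if len(change) == 0:
        return None
    wl, wl1 = cw[change], cw1[change]
    wr, wr1 = W - wl, W1 - wl1
    gl = 1 - ((wl1 / wl) ** 2 + ((wl - wl1) / wl) ** 2)
    gr = 1 - ((wr1 / wr) ** 2 + ((wr - wr1) / wr) ** 2)
    after = (wl * gl + wr * gr) / W
    k = int(np.argmin(after))
    thr = (xs[change[k]] + xs[change[k] + 1]) / 2.0
    return float(after[k]), thr


def _best_categorical_split(x, y, w):
    """Ordered-by-rate subset search; returns (impurity_after, left levels)."""
    levels, inv = np.unique(x, return_inverse=True)
    if len(levels) < 2:
        return None
    wtot = np.bincount(inv, weights=w)
    w1 = np.bincount(inv, weights=w * y)
    rate = w1 / wtot
    order = np.argsort(rate, kind="mergesort")
    W, W1 = wtot.sum(), w1.sum()
    wl = np.cumsum(wtot[order])[:-1]
    wl1 = np.cumsum(w1[order])[:-1]
    wr, wr1 = W - wl, W1 - wl1
    gl = 1 - ((wl1 / wl) ** 2 + ((wl - wl1) / wl) ** 2)
    gr = 1 - ((wr1 / wr) ** 2 + ((wr - wr1) / wr) ** 2)
    after = (wl * gl + wr * gr) / W
    k = int(np.argmin(after))
    left = tuple(levels[order[:k + 1]])
    return float(after[k]), left


def grow_tree(df: pd.DataFrame, weights, response: str, predictors: dict,
              params: TreeParams = None) -> TreeNode:
    """Grow a weighted Gini classification tree.

    ``predictors`` maps column name -> kind ("numeric", "ordinal" or
    "categorical").  The response must be binary 0/1.  A constant response
    yields a single leaf.
    """
    params = params or TreeParams()
    y = df[response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError(f"response {response!r} must be binary 0/1")
    w = (np.asarray(weights, dtype=float) if params.use_case_weights
         else np.ones(len(df)))
    if len(w) != len(df):
        raise DataError("weights length does not match data")
    cols = {}
    for name, kind in predictors.items():
        if kind not in ("numeric", "ordinal", "categorical"):
            raise ConfigurationError(f"predictor {name!r}: unknown kind {kind!r}")
        v = df[name]
        if kind == "categorical":
            cols[name] = ("categorical", v.astype(str).to_numpy())
        else:
            if kind == "ordinal" and not np.issubdtype(v.dtype, np.number):
                v = pd.Series(pd.Categorical(v).codes, index=v.index)
            cols[name] = ("numeric", v.to_numpy(dtype=float))

    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        yi, wi = y[idx], w[idx]
        w1 = float((wi * yi).sum())
        w0 = float(wi.sum()) - w1
        node = TreeNode(node_id=counter[0], depth=depth,
                        weighted_counts=(w0, w1),
                        predicted=int(w1 >= w0))
        counter[0] += 1
        if depth >= params.max_depth or (w0 + w1) < 2 * params.min_node_weight:
            return node
        g_parent = _gini((w0, w1))
        if g_parent == 0.0:
            return node
        best = None   # (decrease, name, kind, payload)
        for name, (kind, arr) in cols.items():
            xi = arr[idx]
            res = (_best_categorical_split(xi, yi, wi) if kind == "categorical"
                   else _best_numeric_split(xi, yi, wi))
            if res is None:
                continue
            after, payload = res
            dec = g_parent - after
            if best is None or dec > best[0] + 1e-12:
                best = (dec, name, kind, payload)
        if best is None or best[0] < params.min_improvement:
            return node
        dec, name, kind, payload = best
        xi = cols[name][1][idx]
        if kind == "categorical":
            go_left = np.isin(xi, payload)
        else:
            go_left = xi <= payload
        wl = w[idx][go_left].sum()
        wr = w[idx][~go_left].sum()
        if wl < params.min_node_weight or wr < params.min_node_weight:
            return node
        node.split_var = name
        node.split_kind = "categorical" if kind == "categorical" else "numeric"
        if kind == "categorical":
            node.left_levels = tuple(str(v) for v in payload)
            node.right_levels = tuple(
                str(v) for v in np.unique(xi) if str(v) not in node.left_levels)
        else:
            node.threshold = float(payload)
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return build(np.arange(len(df)), 0)


def predict(tree: TreeNode, df: pd.DataFrame):
    """Route records through the tree.  Returns (classes, leaf node ids).

    Missing split values route to the heavier child; unseen categorical
    levels route to the heavier child with a warning.
    """
    classes = np.empty(len(df), dtype=int)
    node_ids = np.empty(len(df), dtype=int)
    warned = set()
    for pos, (_, row) in enumerate(df.iterrows()):
        node = tree
        while not node.is_leaf:
            v = row.get(node.split_var)
            heavier = (node.left if node.left.weight >= node.right.weight
                       else node.right)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                node = heavier
                continue
            if node.split_kind == "categorical":
                sv = str(v)
                if sv in node.left_levels:
                    node = node.left
                elif node.right_levels and sv in node.right_levels:
                    node = node.right
                else:
                    if (node.node_id, sv) not in warned:
                        warnings.warn(
                            f"unknown level {sv!r} for {node.split_var!r}; "
                            "routed to heavier child", stacklevel=2)
                        warned.add((node.node_id, sv))
                    node = heavier
            else:
                node = node.left if float(v) <= node.threshold else node.right
        classes[pos] = node.predicted
        node_ids[pos] = node.node_id
    return classes, node_ids


def export_tree(tree: TreeNode, fmt: str = "text"):
    """Render the tree as indented text or a JSON-serialisable dict."""
    if fmt == "json":
        return _node_to_dict(tree)
    if fmt != "text":
        raise ConfigurationError(f"unknown export format {fmt!r}")
    lines = []

    def walk(node, indent, label):
        w0, w1 = node.weighted_counts
        desc = (f"{label}n={w0 + w1:.1f} [partial={w0:.1f}, optimal={w1:.1f}] "
                f"-> class {node.predicted}")
        if not node.is_leaf:
            if node.split_kind == "numeric":
                rule = f"{node.split_var} <= {node.threshold:g}"
            else:
                rule = f"{node.split_var} in {list(node.left_levels)}"
            desc += f" | split: {rule}"
        lines.append("  " * indent + desc)
        if not node.is_leaf:
            walk(node.left, indent + 1, "L: ")
            walk(node.right, indent + 1, "R: ")

    walk(tree, 0, "")
    return "\n".join(lines)


def _node_to_dict(node: TreeNode) -> dict:
    d = {"node_id": node.node_id, "depth": node.depth,
         "weighted_counts": list(node.weighted_counts),
         "predicted": node.predicted}
    if not node.is_leaf:
        d["split_var"] = node.split_var
        d["split_kind"] = node.split_kind
        if node.split_kind == "numeric":
            d["threshold"] = node.threshold
        else:
            d["left_levels"] = list(node.left_levels)
            d["right_levels"] = list(node.right_levels or ())
        d["left"] = _node_to_dict(node.left)
        d["right"] = _node_to_dict(node.right)
    return d


def import_tree(data) -> TreeNode:
    """Inverse of ``export_tree(fmt='json')`` (accepts dict or JSON text)."""
    if isinstance(data, str):
        data = json.loads(data)
    node = TreeNode(node_id=data["node_id"], depth=data["depth"],
                    weighted_counts=tuple(data["weighted_counts"]),
                    predicted=data["predicted"])
    if "split_var" in data:
        node.split_var = data["split_var"]
        node.split_kind = data["split_kind"]
        node.threshold = data.get("threshold")
        ll = data.get("left_levels")
        node.left_levels = tuple(ll) if ll is not None else None
        rl = data.get("right_levels")
        node.right_levels = tuple(rl) if rl is not None else None
        node.left = import_tree(data["left"])
        node.right = import_tree(data["right"])
    return node
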