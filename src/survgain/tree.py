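"""Binary-outcome classification tree (CART) built from scratch.

Greedy recursive partitioning with Gini impurity, surrogate splits for
missing values, weakest-link cost-complexity pruning and k-fold
cross-validated complexity selection.  Conventions follow the classic CART
formulation:

* numeric splits test ``value <= t`` with t at midpoints of consecutive
  distinct observed values;
* categorical splits send a subset of levels left, found by ordering levels
  by response fraction and scanning them as if ordinal (optimal for a binary
  outcome);
* split gain is computed on rows where the variable is observed and scaled
  by the observed fraction, so heavily missing variables are penalized;
* rows with a missing primary value are routed by the highest-agreement
  surrogate split, falling back to the node's majority direction;
* pruning risk is misclassification count; cp values are normalized by the
  root risk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Split",
    "TreeNode",
    "GrowthParams",
    "ClassificationTree",
    "FeatureSchema",
    "gini",
    "best_split",
    "find_surrogates",
    "grow_tree",
    "prune_cv",
    "predict_proba",
    "render_text",
]

_EPS = 1e-12


def gini(class_counts) -> float:
    """Gini impurity 1 - p0^2 - p1^2 of a two-class count pair."""
    c0, c1 = class_counts
    n = c0 + c1
    if n <= 0:
        raise ValueError("class counts sum to zero")
    p0, p1 = c0 / n, c1 / n
    return 1.0 - p0 * p0 - p1 * p1


def _impurity_arrays(n1, n, criterion: str):
    """Vectorized impurity for arrays of positive counts."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n > 0, n1 / n, 0.0)
    if criterion == "gini":
        return 2.0 * p1 * (1.0 - p1)  # = 1 - p0^2 - p1^2 for two classes
    if criterion == "misclassification":
        return np.minimum(p1, 1.0 - p1)
    raise ValueError(f"unknown criterion {criterion!r}")


def _impurity_pair(c0, c1, criterion: str) -> float:
    return float(_impurity_arrays(np.array([c1], float), np.array([c0 + c1], float),
                                  criterion)[0])


@dataclass(frozen=True)
class Split:
    """One binary split.

    ``direction`` gives the routing rule: ``"le"`` — go left iff
    value <= threshold (all primary splits); ``"gt"`` — go left iff
    value > threshold (reversed-orientation surrogates only); ``"in"`` —
    go left iff value in ``subset`` (categorical).
    """

    variable: str
    kind: str                      # "numeric" | "categorical"
    threshold: Optional[float] = None
    subset: Optional[tuple] = None  # level labels routed left
    gain: float = 0.0
    direction: str = "le"

    def goes_left(self, value) -> Optional[bool]:
        """True/False for an observed value, None when it cannot route."""
        if self.kind == "numeric":
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return None
            le = value <= self.threshold
            return le if self.direction == "le" else not le
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return value in self.subset

    def describe(self) -> str:
        if self.kind == "numeric":
            op = "<=" if self.direction == "le" else ">"
            return f"{self.variable} {op} {self.threshold:g}"
        return f"{self.variable} in {{{','.join(map(str, self.subset))}}}"


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n_train: int
    class_counts: tuple          # (n_nonresponse, n_response)
    probability_response: float
    primary_split: Optional[Split] = None
    surrogates: list = field(default_factory=list)  # [(Split, agreement)]
    majority_direction: str = "left"
    children: Optional[tuple] = None  # (left TreeNode, right TreeNode)

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class GrowthParams:
    """Stopping and search parameters for tree growth (classic defaults)."""

    min_split: int = 20
    min_bucket: int = 7
    max_depth: int = 30
    cp_grow: float = 0.01
    criterion: str = "gini"   # "gini" | "misclassification"


@dataclass
class FeatureSchema:
    """Ordered feature names with kinds; order defines split tie-breaking."""

    names: list
    kinds: dict                      # name -> "numeric" | "categorical"
    levels: dict                     # name -> ordered level labels (categorical)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureSchema":
        names, kinds, levels = list(frame.columns), {}, {}
        for name in names:
            if frame[name].dtype == object:
                kinds[name] = "categorical"
                levels[name] = sorted(frame[name].dropna().unique().tolist())
            else:
                kinds[name] = "numeric"
        return cls(names=names, kinds=kinds, levels=levels)

    def encode(self, frame: pd.DataFrame) -> np.ndarray:
        """Feature matrix as floats; categorical values become level codes,
        missing values NaN."""
        cols = []
        for name in self.names:
            col = frame[name]
            if self.kinds[name] == "categorical":
                codes = pd.Categorical(col, categories=self.levels[name]).codes.astype(float)
                codes[codes < 0] = np.nan  # missing or unseen level
                cols.append(codes)
            else:
                cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(frame), 0))


@dataclass
class ClassificationTree:
    root: TreeNode
    params: GrowthParams
    schema: FeatureSchema
    cp_table: list = field(default_factory=list)  # dicts: cp, n_leaves, train_error, cv_error, cv_se
    selected_cp: Optional[float] = None

    def leaves(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return out

    def internal_nodes(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def split_variables(self) -> list:
        """Variables used by primary splits, in breadth-first order."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            if not node.is_leaf:
                out.append(node.primary_split.variable)
                queue.extend(node.children)
        return out

    def to_dict(self) -> dict:
        def _node(nd: TreeNode) -> dict:
            d = {
                "node_id": nd.node_id,
                "n_train": nd.n_train,
                "class_counts": list(nd.class_counts),
                "probability_response": nd.probability_response,
            }
            if not nd.is_leaf:
                sp = nd.primary_split
                d["primary_split"] = {
                    "variable": sp.variable, "kind": sp.kind, "threshold": sp.threshold,
                    "subset": list(sp.subset) if sp.subset else None,
                    "gain": sp.gain, "direction": sp.direction,
                }
                d["surrogates"] = [
                    {"variable": s.variable, "kind": s.kind, "threshold": s.threshold,
                     "subset": list(s.subset) if s.subset else None,
                     "direction": s.direction, "agreement": agr}
                    for s, agr in nd.surrogates
                ]
                d["majority_direction"] = nd.majority_direction
                d["children"] = [_node(c) for c in nd.children]
            return d

        return {
            "params": vars(self.params),
            "selected_cp": self.selected_cp,
            "cp_table": self.cp_table,
            "root": _node(self.root),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# Split search


def _scan_numeric(x, y, min_bucket, criterion):
    """Best ``value <= t`` split on observed (x, y); returns (gain_obs,
    threshold) or None.  First maximum wins, so among tied gains the smallest
    threshold is chosen."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    nobs = len(xs)
    boundaries = np.flatnonzero(xs[:-1] < xs[1:])
    if len(boundaries) == 0:
        return None
    cum1 = np.cumsum(ys)
    nl = boundaries + 1.0
    nr = nobs - nl
    n1l = cum1[boundaries].astype(float)
    n1r = cum1[-1] - n1l
    valid = (nl >= min_bucket) & (nr >= min_bucket)
    if not valid.any():
        return None
    parent = _impurity_pair(nobs - int(cum1[-1]), int(cum1[-1]), criterion)
    gains = parent - (nl / nobs) * _impurity_arrays(n1l, nl, criterion) \
        - (nr / nobs) * _impurity_arrays(n1r, nr, criterion)
    gains[~valid] = -np.inf
    best = int(np.argmax(gains))
    thr = 0.5 * (xs[boundaries[best]] + xs[boundaries[best] + 1])
    return float(gains[best]), float(thr)


def _scan_categorical(codes, y, levels, min_bucket, criterion):
    """Best subset split on observed (codes, y).  Levels are ordered by
    response fraction and scanned as ordinal — optimal for binary outcomes;
    tied gains resolve to the lexicographically smallest left subset."""
    nobs = len(codes)
    present = np.unique(codes).astype(int)
    if len(present) < 2:
        return None
    n_by = np.array([(codes == c).sum() for c in present], dtype=float)
    n1_by = np.array([y[codes == c].sum() for c in present], dtype=float)
    frac = n1_by / n_by
    # order by response fraction, then code, for a deterministic scan
    order = np.lexsort((present, frac))
    n_ord, n1_ord = n_by[order], n1_by[order]
    parent = _impurity_pair(int(nobs - y.sum()), int(y.sum()), criterion)
    cum_n = np.cumsum(n_ord)[:-1]
    cum_n1 = np.cumsum(n1_ord)[:-1]
    nl, nr = cum_n, nobs - cum_n
    n1l, n1r = cum_n1, y.sum() - cum_n1
    gains = parent - (nl / nobs) * _impurity_arrays(n1l, nl, criterion) \
        - (nr / nobs) * _impurity_arrays(n1r, nr, criterion)
    gains[(nl < min_bucket) | (nr < min_bucket)] = -np.inf
    if np.all(np.isinf(gains)):
        return None
    best_gain = gains.max()
    if not np.isfinite(best_gain):
        return None
    candidates = []
    for m in np.flatnonzero(gains >= best_gain - _EPS):
        left_codes = present[order[: m + 1]]
        subset = tuple(sorted(levels[c] for c in left_codes))
        candidates.append(subset)
    return float(best_gain), min(candidates)


def best_split(X: np.ndarray, y: np.ndarray, schema: FeatureSchema,
               params: GrowthParams,
               candidate_variables: Sequence[str] | None = None) -> Optional[Split]:
    """Exhaustive greedy search over all admissible splits of a node.

    Gain is the impurity decrease among observed rows, scaled by the
    fraction of node rows with the variable observed.  Ties break by schema
    variable order, then smaller threshold / lexicographically smaller
    subset.  Returns None when no admissible split has positive gain.
    """
    n_node = len(y)
    names = schema.names if candidate_variables is None else [
        n for n in schema.names if n in set(candidate_variables)]
    best: Optional[Split] = None
    for name in names:
        j = schema.names.index(name)
        col = X[:, j]
        obs = ~np.isnan(col)
        nobs = int(obs.sum())
        if nobs < 2 * params.min_bucket:
            continue
        f_obs = nobs / n_node
        xo, yo = col[obs], y[obs]
        if schema.kinds[name] == "numeric":
            res = _scan_numeric(xo, yo, params.min_bucket, params.criterion)
            if res is None:
                continue
            gain_obs, thr = res
            cand = Split(variable=name, kind="numeric", threshold=thr,
                         gain=gain_obs * f_obs)
        else:
            res = _scan_categorical(xo.astype(int), yo, schema.levels[name],
                                    params.min_bucket, params.criterion)
            if res is None:
                continue
            gain_obs, subset = res
            cand = Split(variable=name, kind="categorical", subset=subset,
                         gain=gain_obs * f_obs)
        if best is None or cand.gain > best.gain + _EPS:
            best = cand
    if best is None or best.gain <= _EPS:
        return None
    return best


# ---------------------------------------------------------------------------
# Surrogates


def _surrogate_numeric(x, d):
    """Best threshold (either orientation) mimicking primary direction d
    (0=left, 1=right) on rows where both variables are observed.  Returns
    (agree_count, Split-args) or None."""
    order = np.argsort(x, kind="stable")
    xs, ds = x[order], d[order]
    boundaries = np.flatnonzero(xs[:-1] < xs[1:])
    if len(boundaries) == 0:
        return None
    n = len(xs)
    n_left_total = int((ds == 0).sum())
    cum_left = np.cumsum(ds == 0)
    left_prefix = cum_left[boundaries]            # primary-left rows with value <= t
    nl = boundaries + 1
    # orientation "le": <=t goes left
    agree_le = left_prefix + ((n - nl) - (n_left_total - left_prefix))
    # orientation "gt": <=t goes right
    agree_gt = (nl - left_prefix) + (n_left_total - left_prefix)
    best_le, best_gt = int(agree_le.max()), int(agree_gt.max())
    if best_le >= best_gt:
        i = int(np.argmax(agree_le))
        direction, agree = "le", best_le
    else:
        i = int(np.argmax(agree_gt))
        direction, agree = "gt", best_gt
    thr = 0.5 * (xs[boundaries[i]] + xs[boundaries[i] + 1])
    return agree, {"kind": "numeric", "threshold": float(thr), "direction": direction}


def _surrogate_categorical(codes, d, levels):
    """Each level goes to its majority primary direction."""
    present = np.unique(codes).astype(int)
    if len(present) < 2:
        return None
    subset = []
    agree = 0
    for c in present:
        mask = codes == c
        n_left = int((d[mask] == 0).sum())
        n_right = int(mask.sum()) - n_left
        if n_left >= n_right:
            subset.append(levels[c])
            agree += n_left
        else:
            agree += n_right
    if not subset or len(subset) == len(present):
        return None
    return agree, {"kind": "categorical", "subset": tuple(sorted(subset)),
                   "direction": "in"}


#: one-sided z bound on the agreement excess over the majority baseline; a
#: surrogate whose advantage is compatible with pure chance (the optimised
#: agreement of an independent variable always creeps above the baseline) is
#: discarded rather than used for routing.
SURROGATE_Z = 2.33


def find_surrogates(X: np.ndarray, schema: FeatureSchema, primary: Split,
                    go_left: np.ndarray, observed_primary: np.ndarray) -> list:
    """Rank alternative splits by how well they reproduce the primary
    split's left/right routing.

    Agreement is the fraction of rows (with both the primary and the
    candidate variable observed) sent to the same side.  A surrogate is kept
    only if it strictly beats the blind majority-direction baseline on those
    rows AND the excess exceeds ``SURROGATE_Z`` binomial standard deviations
    (guarding against chance agreement from threshold optimisation on an
    independent variable).  Returned ordered by agreement descending (ties:
    schema order).
    """
    out = []
    d_all = np.where(go_left, 0, 1)
    for name in schema.names:
        if name == primary.variable:
            continue
        j = schema.names.index(name)
        col = X[:, j]
        both = observed_primary & ~np.isnan(col)
        n_both = int(both.sum())
        if n_both < 2:
            continue
        d = d_all[both]
        base = max(int((d == 0).sum()), int((d == 1).sum()))
        if schema.kinds[name] == "numeric":
            res = _surrogate_numeric(col[both], d)
        else:
            res = _surrogate_categorical(col[both].astype(int), d, schema.levels[name])
        if res is None:
            continue
        agree_count, kwargs = res
        p0 = base / n_both
        chance_sd = np.sqrt(n_both * p0 * (1.0 - p0))
        if agree_count > base and agree_count - base > SURROGATE_Z * chance_sd:
            out.append((Split(variable=name, **kwargs), agree_count / n_both))
    out.sort(key=lambda t: -t[1])
    return out


# ---------------------------------------------------------------------------
# Growth


def _route(X: np.ndarray, schema: FeatureSchema, node: TreeNode) -> np.ndarray:
    """Boolean go-left for every row of X through one internal node,
    using primary split, then surrogates in order, then majority."""
    sp = node.primary_split
    j = schema.names.index(sp.variable)
    col = X[:, j]
    go_left = np.empty(len(X), dtype=bool)
    decided = ~np.isnan(col)
    if sp.kind == "numeric":
        le = col <= sp.threshold
        go_left[decided] = le[decided] if sp.direction == "le" else ~le[decided]
    else:
        codes_in = np.isin(col, [schema.levels[sp.variable].index(lv) for lv in sp.subset])
        go_left[decided] = codes_in[decided]
    for surr, _agr in node.surrogates:
        if decided.all():
            break
        js = schema.names.index(surr.variable)
        cols = X[:, js]
        usable = ~decided & ~np.isnan(cols)
        if not usable.any():
            continue
        if surr.kind == "numeric":
            le = cols <= surr.threshold
            go_left[usable] = le[usable] if surr.direction == "le" else ~le[usable]
        else:
            codes_in = np.isin(cols, [schema.levels[surr.variable].index(lv)
                                      for lv in surr.subset])
            go_left[usable] = codes_in[usable]
        decided |= usable
    go_left[~decided] = node.majority_direction == "left"
    return go_left


def grow_tree(frame: pd.DataFrame, y, params: GrowthParams | None = None,
              schema: FeatureSchema | None = None) -> ClassificationTree:
    """Grow an unpruned tree by recursive partitioning.

    ``frame`` holds the covariates (numeric columns and object-dtype
    categoricals, NaN = missing); ``y`` the binary response labels.  The
    cp_table of the growth sequence is attached (cv columns empty until
    :func:`prune_cv`)."""
    params = params or GrowthParams()
    schema = schema or FeatureSchema.from_frame(frame)
    X = schema.encode(frame)
    y = np.asarray(y, dtype=int)
    if len(y) != len(X):
        raise ValueError("frame and y length mismatch")

    n_root = len(y)
    root_imp = _impurity_pair(int((y == 0).sum()), int((y == 1).sum()), params.criterion)
    counter = [0]

    def _node(idx: np.ndarray, depth: int) -> TreeNode:
        ys = y[idx]
        c1 = int(ys.sum())
        c0 = len(ys) - c1
        node = TreeNode(node_id=counter[0], depth=depth, n_train=len(ys),
                        class_counts=(c0, c1),
                        probability_response=c1 / len(ys))
        counter[0] += 1
        if depth >= params.max_depth or len(ys) < params.min_split or c0 == 0 or c1 == 0:
            return node
        Xs = X[idx]
        split = best_split(Xs, ys, schema, params)
        if split is None:
            return node
        if root_imp > 0 and (split.gain * len(ys)) / (root_imp * n_root) < params.cp_grow:
            return node

        j = schema.names.index(split.variable)
        col = Xs[:, j]
        observed = ~np.isnan(col)
        if split.kind == "numeric":
            prim_left = np.where(split.direction == "le", col <= split.threshold,
                                 col > split.threshold)
        else:
            prim_left = np.isin(col, [schema.levels[split.variable].index(lv)
                                      for lv in split.subset])
        n_left_obs = int((prim_left & observed).sum())
        n_right_obs = int(observed.sum()) - n_left_obs
        node.majority_direction = "left" if n_left_obs >= n_right_obs else "right"
        node.primary_split = split
        node.surrogates = find_surrogates(Xs, schema, split, prim_left, observed)

        go_left = _route(Xs, schema, node)
        left = _node(idx[go_left], depth + 1)
        right = _node(idx[~go_left], depth + 1)
        node.children = (left, right)
        return node

    root = _node(np.arange(n_root), 0)
    tree = ClassificationTree(root=root, params=params, schema=schema)
    tree.cp_table = _cp_table(tree)
    return tree


# ---------------------------------------------------------------------------
# Cost-complexity pruning


def _collect(root: TreeNode, collapsed: set):
    """Leaves of the subtree obtained by collapsing the given node ids."""
    leaves, stack = [], [root]
    while stack:
        nd = stack.pop()
        if nd.is_leaf or nd.node_id in collapsed:
            leaves.append(nd)
        else:
            stack.extend(nd.children)
    return leaves


def _risk(node: TreeNode) -> int:
    return min(node.class_counts)


def _prune_sequence(root: TreeNode) -> list:
    """Weakest-link sequence [(alpha_count, collapsed_ids)] from the full
    tree (alpha 0) to the root-only tree.  alpha is in misclassification
    counts; nested by construction."""
    collapsed: set = set()
    seq = [(0.0, set())]

    def _stats(nd: TreeNode):
        # (leaf risk sum, leaf count) of nd's current subtree
        lv = _collect(nd, collapsed)
        return sum(_risk(x) for x in lv), len(lv)

    while len(_collect(root, collapsed)) > 1:
        g_best, targets = np.inf, []
        stack = [root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf or nd.node_id in collapsed:
                continue
            r_sub, n_leaves = _stats(nd)
            g = (_risk(nd) - r_sub) / (n_leaves - 1)
            if g < g_best - _EPS:
                g_best, targets = g, [nd]
            elif g <= g_best + _EPS:
                targets.append(nd)
            stack.extend(nd.children)
        for nd in targets:
            collapsed.add(nd.node_id)
        seq.append((float(g_best), set(collapsed)))
    return seq


def _cp_table(tree: ClassificationTree) -> list:
    n = tree.root.n_train
    r_root = max(_risk(tree.root), 1)
    rows = []
    for alpha, collapsed in _prune_sequence(tree.root):
        leaves = _collect(tree.root, collapsed)
        rows.append({
            "cp": alpha / r_root,
            "n_leaves": len(leaves),
            "train_error": sum(_risk(x) for x in leaves) / n,
            "cv_error": None,
            "cv_se": None,
        })
    return rows


def _apply_collapse(tree: ClassificationTree, collapsed: set) -> ClassificationTree:
    import copy

    new_root = copy.deepcopy(tree.root)
    stack = [new_root]
    while stack:
        nd = stack.pop()
        if nd.node_id in collapsed:
            nd.children = None
            nd.primary_split = None
            nd.surrogates = []
        elif not nd.is_leaf:
            stack.extend(nd.children)
    return ClassificationTree(root=new_root, params=tree.params, schema=tree.schema,
                              cp_table=[dict(r) for r in tree.cp_table],
                              selected_cp=tree.selected_cp)


def _subtree_for_penalty(seq: list, beta: float) -> set:
    """Collapsed set of the cost-complexity-optimal subtree at penalty beta:
    the sequence element with the largest alpha <= beta."""
    chosen = seq[0][1]
    for alpha, collapsed in seq:
        if alpha <= beta + _EPS:
            chosen = collapsed
        else:
            break
    return chosen


def _predict_leaf_values(root: TreeNode, schema: FeatureSchema, X: np.ndarray,
                         collapsed: set) -> np.ndarray:
    """Leaf response probability per row, treating ``collapsed`` node ids as
    leaves.  Vectorized by recursive row partitioning."""
    out = np.empty(len(X))

    def _rec(nd: TreeNode, idx: np.ndarray):
        if len(idx) == 0:
            return
        if nd.is_leaf or nd.node_id in collapsed:
            out[idx] = nd.probability_response
            return
        go_left = _route(X[idx], schema, nd)
        _rec(nd.children[0], idx[go_left])
        _rec(nd.children[1], idx[~go_left])

    _rec(root, np.arange(len(X)))
    return out


def _predict_classes(root: TreeNode, schema: FeatureSchema, X: np.ndarray,
                     collapsed: set) -> np.ndarray:
    return (_predict_leaf_values(root, schema, X, collapsed) > 0.5).astype(int)


def prune_cv(tree: ClassificationTree, frame: pd.DataFrame, y,
             n_folds: int = 10, seed: int = 0, rule: str = "min") -> ClassificationTree:
    """Select the complexity parameter by k-fold cross-validation and return
    the pruned tree.

    For each candidate cp of the full tree's weakest-link sequence, each
    fold's tree (grown on the fold complement) is pruned at the geometric-
    mean penalty and scored on the held-out fold; the cp minimizing CV
    misclassification error is selected (``rule="1se"``: largest cp within
    one standard error of the minimum; ties always resolve to the larger cp,
    i.e. the simpler tree).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = np.asarray(y, dtype=int)
    n = len(y)
    seq = _prune_sequence(tree.root)
    r_root = max(_risk(tree.root), 1)
    # penalties are compared on the cp scale (alpha / root risk) so that
    # fold trees, grown on fewer rows, are pruned at commensurate strength
    alphas = np.array([a for a, _ in seq]) / r_root
    betas = np.empty_like(alphas)
    betas[:-1] = np.sqrt(np.maximum(alphas[:-1], 0.0) * alphas[1:])
    betas[-1] = np.inf

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[f::n_folds] for f in range(n_folds)]
    # a fold whose training complement is single-class cannot grow a tree
    merged, i = [], 0
    while i < len(folds):
        fold = folds[i]
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if len(np.unique(y[mask])) < 2 and merged:
            warnings.warn("single-class CV fold merged into neighbor")
            merged[-1] = np.concatenate([merged[-1], fold])
        else:
            merged.append(fold)
        i += 1
    folds = merged

    X_all = tree.schema.encode(frame)
    errors = np.zeros(len(seq))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        sub = grow_tree(frame.iloc[mask].reset_index(drop=True), y[mask],
                        params=tree.params, schema=tree.schema)
        sub_r_root = max(_risk(sub.root), 1)
        sub_seq = [(a / sub_r_root, c) for a, c in _prune_sequence(sub.root)]
        X_fold = X_all[fold]
        for s, beta in enumerate(betas):
            collapsed = _subtree_for_penalty(sub_seq, beta)
            pred = _predict_classes(sub.root, tree.schema, X_fold, collapsed)
            errors[s] += int((pred != y[fold]).sum())

    cv_err = errors / n
    cv_se = np.sqrt(np.maximum(cv_err * (1 - cv_err), 0.0) / n)
    best_err = cv_err.min()
    if rule == "1se":
        ok = cv_err <= best_err + cv_se[int(np.argmin(cv_err))]
    elif rule == "min":
        ok = cv_err <= best_err + _EPS
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    sel = int(np.flatnonzero(ok)[-1])  # largest qualifying cp = simplest tree

    pruned = _apply_collapse(tree, seq[sel][1])
    pruned.selected_cp = float(alphas[sel])
    table = _cp_table(tree)
    for row, e, se in zip(table, cv_err, cv_se):
        row["cv_error"] = float(e)
        row["cv_se"] = float(se)
    pruned.cp_table = table
    return pruned


# ---------------------------------------------------------------------------
# Prediction & rendering


def predict_proba(tree: ClassificationTree, records: pd.DataFrame) -> np.ndarray:
    """Leaf response probability for each record, routing missing values by
    surrogates then majority direction.  Unknown categorical levels route by
    majority direction with a warning (they encode as missing)."""
    for name in tree.schema.names:
        if tree.schema.kinds[name] == "categorical":
            col = records[name]
            unknown = col.notna() & ~col.isin(tree.schema.levels[name])
            if unknown.any():
                warnings.warn(
                    f"unknown level {col[unknown].iloc[0]!r} for {name!r}; "
                    "routing by majority direction")
    X = tree.schema.encode(records[tree.schema.names])
    return _predict_leaf_values(tree.root, tree.schema, X, collapsed=set())


def render_text(tree: ClassificationTree) -> str:
    """Human-readable rendering: one line per node with split, size and
    response probability."""
    lines = []

    def _walk(nd: TreeNode, indent: int, label: str):
        tag = "leaf" if nd.is_leaf else nd.primary_split.describe()
        lines.append(f"{'  ' * indent}{label}{tag}  [n={nd.n_train}, "
                     f"p(response)={nd.probability_response:.3f}]")
        if not nd.is_leaf:
            _walk(nd.children[0], indent + 1, "yes: ")
            _walk(nd.children[1], indent + 1, "no:  ")

    _walk(tree.root, 0, "")
    return "\n".join(lines)
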