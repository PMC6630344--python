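"""Binary least-squares regression trees on mixed binary/continuous cohorts.

The model is a standard CART-style regression tree: recursive axis-aligned
binary splits of the form ``x_i <= c`` (left) / ``x_i > c`` (right) chosen
to minimise the children's residual sum of squares, with leaf predictions
equal to the mean training target in the leaf.  Equivalently the fitted
tree is T(x) = sum_m mu_m * B_m(x) where B_m is the indicator of the m-th
leaf's path conditions and mu_m its training mean, so the leaves partition
the predictor space and every subject lands in exactly one leaf.

Candidate cut points are midpoints between consecutive distinct observed
values within the node; a node stops splitting when its residual error is
zero, it is smaller than ``min_node_size``, no split strictly reduces the
residual sum of squares, or the depth safeguard is reached.  Ties between
equally good splits break to the lowest column index, then the smallest
threshold, so fits are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

BINARY = "binary"
CONTINUOUS = "continuous"

# relative slack used when comparing sums of squares; splits must beat the
# parent by more than this to count as an improvement
_SSE_RTOL = 1e-9


@dataclass(frozen=True)
class GrowthConfig:
    """Stopping rules for tree growth.

    ``min_node_size`` is the smallest node that may still be split (nodes
    with fewer subjects become leaves); ``max_depth`` is a hard safeguard
    on recursion depth (a stump has depth 0).
    """

    min_node_size: int = 5
    max_depth: int = 12

    def __post_init__(self) -> None:
        if self.min_node_size < 2:
            raise ValueError("min_node_size must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class CohortTable:
    """An n x p numeric predictor matrix with typed columns and an integer target.

    Binary columns hold only {0, 1}; continuous columns are in natural
    units (years, hours/day).  Missing values are rejected — imputation or
    row dropping belongs upstream.
    """

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one row and one column")
        if self.y.shape != (n,):
            raise ValueError("y length must match the number of rows")
        self.columns = tuple(self.columns)
        self.kinds = tuple(self.kinds)
        if len(self.columns) != p or len(self.kinds) != p:
            raise ValueError("column metadata length must match p")
        bad = set(self.kinds) - {BINARY, CONTINUOUS}
        if bad:
            raise ValueError(f"unknown column kinds: {sorted(bad)}")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("missing values are not allowed in a cohort table")
        bin_idx = [j for j, k in enumerate(self.kinds) if k == BINARY]
        if bin_idx:
            vals = self.X[:, bin_idx]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("binary columns may only contain 0 and 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "CohortTable":
        rows = np.asarray(rows, dtype=np.intp)
        return CohortTable(self.X[rows], self.y[rows], self.columns, self.kinds)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        target: str,
        kinds: dict[str, str] | None = None,
    ) -> "CohortTable":
        """Build a table from a DataFrame, inferring column kinds if absent.

        A column whose observed values are a subset of {0, 1} is inferred
        binary; everything else continuous.
        """
        if target not in frame.columns:
            raise ValueError(f"target column {target!r} not in frame")
        if frame.isna().any().any():
            raise ValueError("missing cells in cohort data")
        predictors = [c for c in frame.columns if c != target]
        if not predictors:
            raise ValueError("no predictor columns")
        X = frame[predictors].to_numpy(dtype=np.float64)
        y = frame[target].to_numpy(dtype=np.float64)
        resolved = []
        for j, c in enumerate(predictors):
            if kinds is not None and c in kinds:
                resolved.append(kinds[c])
            else:
                resolved.append(BINARY if np.isin(X[:, j], (0.0, 1.0)).all() else CONTINUOUS)
        return cls(X, y, tuple(predictors), tuple(resolved))

    def to_dataframe(self, target: str = "cvsq_score") -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.columns))
        frame[target] = self.y
        return frame


def read_cohort(path, meta_path=None, target: str = "cvsq_score") -> CohortTable:
    """Read a delimited cohort table, optionally with a YAML/JSON sidecar.

    The sidecar declares ``target`` and a ``kinds`` mapping of column name
    to ``binary``/``continuous``; unlisted columns get inferred kinds.
    """
    frame = pd.read_csv(path)
    kinds = None
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        target = meta.get("target", target)
        kinds = meta.get("kinds")
    return CohortTable.from_dataframe(frame, target=target, kinds=kinds)


def write_cohort(table: CohortTable, path, meta_path=None, target: str = "cvsq_score") -> None:
    table.to_dataframe(target).to_csv(path, index=False)
    if meta_path is not None:
        meta = {"target": target, "kinds": dict(zip(table.columns, table.kinds))}
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


@dataclass(frozen=True)
class SplitRule:
    """An axis-aligned split: rows with x[variable] <= threshold go left."""

    variable: int
    threshold: float


@dataclass
class Node:
    value: float
    n: int
    rule: Optional[SplitRule] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclass
class RegressionTree:
    root: Node
    columns: tuple[str, ...]
    n_train: int

    @property
    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            if node.is_leaf:
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node: Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def required_variables(self) -> set[int]:
        out: set[int] = set()

        def walk(node: Node) -> None:
            if not node.is_leaf:
                out.add(node.rule.variable)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out


def _node_sse(y: np.ndarray) -> float:
    s = y.sum()
    return float((y * y).sum() - s * s / y.size)


def _best_split_arrays(
    X: np.ndarray,
    y: np.ndarray,
    bin_cols: np.ndarray,
    cont_cols: np.ndarray,
) -> tuple[int, float, float] | None:
    """Best (column, threshold, child SSE) over the given rows/columns.

    Binary columns admit the single candidate threshold 0.5 and are scored
    in one vectorised pass; continuous columns are scanned over midpoints
    of consecutive distinct sorted values.  Returns None when no column has
    two distinct values.
    """
    n = y.size
    sy = y.sum()
    yy = y * y
    syy = float(yy.sum())
    tol = _SSE_RTOL * max(1.0, syy)

    # per-kind best candidates: (column, threshold, child SSE); binary
    # columns contribute at most one (exact ties resolved to the lowest
    # column index by the first-minimum rule), continuous columns one each
    cands: list[tuple[int, float, float]] = []

    if bin_cols.size:
        Xb = X[:, bin_cols]
        n1 = Xb.sum(axis=0)
        s1 = y @ Xb
        ss1 = yy @ Xb
        n0 = n - n1
        valid = (n1 > 0) & (n0 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = (ss1 - s1 * s1 / n1) + (syy - ss1 - (sy - s1) ** 2 / n0)
        sse = np.where(valid, sse, np.inf)
        j = int(np.argmin(sse))  # first minimum -> lowest column index
        if np.isfinite(sse[j]):
            cands.append((int(bin_cols[j]), 0.5, float(sse[j])))

    if cont_cols.size:
        # all continuous columns scored in one vectorised pass: sort each
        # column, prefix sums of y along the sorted order, candidate cuts
        # only where consecutive sorted values differ
        Xc = X[:, cont_cols]
        order = np.argsort(Xc, axis=0, kind="stable")
        xs = np.take_along_axis(Xc, order, axis=0)
        yo = y[order]
        cs = np.cumsum(yo, axis=0)[:-1]
        css = np.cumsum(yo * yo, axis=0)[:-1]
        nl = np.arange(1, n, dtype=np.float64)[:, None]
        sse = (css - cs * cs / nl) + (syy - css - (sy - cs) ** 2 / (n - nl))
        sse[xs[1:] <= xs[:-1]] = np.inf  # not a boundary between distinct values
        jmin = np.argmin(sse, axis=0)  # first minimum -> smallest threshold
        col_idx = np.arange(cont_cols.size)
        best_per_col = sse[jmin, col_idx]
        for k in np.flatnonzero(np.isfinite(best_per_col)):
            j = int(jmin[k])
            thr = float((xs[j, k] + xs[j + 1, k]) / 2.0)
            cands.append((int(cont_cols[k]), thr, float(best_per_col[k])))

    if not cands:
        return None
    # ties within tolerance break to the lowest column index
    best_sse = min(s for _, _, s in cands)
    col, thr, sse = min(
        (cand for cand in cands if cand[2] <= best_sse + tol), key=lambda cand: cand[0]
    )
    return col, thr, max(sse, 0.0)


def best_split(
    table: CohortTable,
    rows: Sequence[int] | np.ndarray | None = None,
    allowed_columns: Sequence[int] | np.ndarray | None = None,
) -> Optional[SplitRule]:
    """Exhaustively best split of the given rows over the allowed columns.

    Returns None when no allowed column has two distinct values within the
    rows, or when no split strictly reduces the residual sum of squares
    (as happens for a constant target).
    """
    rows = np.arange(table.n) if rows is None else np.asarray(rows, dtype=np.intp)
    if rows.size < 2:
        raise ValueError("need at least two rows to split")
    cols = (
        np.arange(table.p)
        if allowed_columns is None
        else np.sort(np.asarray(allowed_columns, dtype=np.intp))
    )
    if cols.size == 0:
        raise ValueError("allowed_columns must be non-empty")
    kinds = np.asarray(table.kinds)
    bin_cols = cols[kinds[cols] == BINARY]
    cont_cols = cols[kinds[cols] == CONTINUOUS]
    ysub = table.y[rows]
    found = _best_split_arrays(table.X[rows], ysub, bin_cols, cont_cols)
    if found is None:
        return None
    col, thr, child_sse = found
    parent = _node_sse(ysub)
    if parent - child_sse <= _SSE_RTOL * max(1.0, parent):
        return None
    return SplitRule(variable=col, threshold=thr)


def fit_tree(
    table: CohortTable,
    mask: Sequence[int] | np.ndarray | None = None,
    config: GrowthConfig | None = None,
) -> RegressionTree:
    """Grow a regression tree on the table restricted to the masked columns.

    ``mask`` is a length-p 0/1 vector (the feature-selection chromosome);
    None means all columns.  At least one column must be selected.
    """
    config = config or GrowthConfig()
    if mask is None:
        cols = np.arange(table.p)
    else:
        mask = np.asarray(mask)
        if mask.shape != (table.p,):
            raise ValueError("mask length must equal the number of predictors")
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            raise ValueError("feature mask must select at least one column")
    if table.n < 2:
        raise ValueError("need at least two training rows")

    # restrict to the masked columns once; the compiled kernel grows the
    # whole tree and returns it as flat arrays with local column indices
    from ._fast_tree import grow_tree_arrays

    feature, threshold, left, right, value, count = grow_tree_arrays(
        table.X[:, cols], table.y, config.min_node_size, config.max_depth
    )

    def build(i: int) -> Node:
        node = Node(value=float(value[i]), n=int(count[i]))
        if feature[i] >= 0:
            node.rule = SplitRule(
                variable=int(cols[feature[i]]), threshold=float(threshold[i])
            )
            node.left = build(int(left[i]))
            node.right = build(int(right[i]))
        return node

    return RegressionTree(root=build(0), columns=table.columns, n_train=table.n)


def predict(tree: RegressionTree, x) -> float | np.ndarray:
    """Route one row (1-D) or a matrix of rows (2-D) through the tree.

    Every variable referenced by a split rule must be present (the row must
    be at least long enough to index it); a shorter row raises naming the
    first missing variable.
    """
    arr = np.asarray(x, dtype=np.float64)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    needed = tree.required_variables()
    if needed and arr.shape[1] <= max(needed):
        j = min(v for v in needed if v >= arr.shape[1])
        name = tree.columns[j] if j < len(tree.columns) else f"x{j}"
        raise ValueError(f"input row is missing variable {name!r} (index {j})")

    out = np.empty(arr.shape[0], dtype=np.float64)

    def route(node: Node, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.value
            return
        go_left = arr[idx, node.rule.variable] <= node.rule.threshold
        route(node.left, idx[go_left])
        route(node.right, idx[~go_left])

    route(tree.root, np.arange(arr.shape[0], dtype=np.intp))
    return float(out[0]) if single else out


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error between two equal-length vectors."""
    a = np.asarray(y_true, dtype=np.float64)
    b = np.asarray(y_pred, dtype=np.float64)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def render_tree(tree: RegressionTree) -> str:
    """Deterministic indented outline: one line per split or leaf.

    The first child under a split line is the <= branch, the second the >
    branch.
    """
    lines: list[str] = []

    def walk(node: Node, depth: int) -> None:
        pad = "  " * depth
        if node.is_leaf:
            lines.append(f"{pad}leaf: mean={node.value:.6f} n={node.n}")
        else:
            name = tree.columns[node.rule.variable]
            lines.append(f"{pad}split: {name} <= {node.rule.threshold:g}")
            walk(node.left, depth + 1)
            walk(node.right, depth + 1)

    walk(tree.root, 0)
    return "\n".join(lines)
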