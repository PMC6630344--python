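import numpy as np
import pytest

from cvstree.tree import BINARY, CONTINUOUS, CohortTable


@pytest.fixture
def four_row_table() -> CohortTable:
    """Single binary predictor perfectly separating y = [1,1,5,5]."""
    return CohortTable(
        X=np.array([[0.0], [0.0], [1.0], [1.0]]),
        y=np.array([1, 1, 5, 5]),
        columns=("flag",),
        kinds=(BINARY,),
    )


def random_micro_table(rng: np.random.Generator, n: int, p: int) -> CohortTable:
    """Small mixed-kind table with integer targets for oracle comparisons."""
    kinds = tuple(rng.choice([BINARY, CONTINUOUS]) for _ in range(p))
    cols = []
    for k in kinds:
        if k == BINARY:
            cols.append(rng.integers(0, 2, size=n).astype(float))
        else:
            cols.append(np.round(rng.normal(10, 4, size=n), 2))
    X = np.column_stack(cols)
    y = rng.integers(0, 33, size=n)
    return CohortTable(X=X, y=y, columns=tuple(f"v{j}" for j in range(p)), kinds=kinds)


def brute_force_best_split(table: CohortTable, tol: float = 1e-9):
    """Independent exhaustive enumeration of every (column, midpoint) split.

    Scans columns in ascending index and thresholds in ascending order,
    accepting a candidate only when it strictly beats the incumbent, which
    reproduces the lowest-column / smallest-threshold tie-break.  Returns
    (variable, threshold, child_sse) or None.
    """
    X, y = table.X, table.y
    parent_sse = float(((y - y.mean()) ** 2).sum())
    best = None
    for j in range(table.p):
        values = np.unique(X[:, j])
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            sse = float(((left - left.mean()) ** 2).sum()) + float(
                ((right - right.mean()) ** 2).sum()
            )
            if best is None or sse < best[2] - tol:
                best = (j, thr, sse)
    if best is None or parent_sse - best[2] <= tol * max(1.0, parent_sse):
        return None
    return best
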