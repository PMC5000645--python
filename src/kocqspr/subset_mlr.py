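"""Subset multivariable linear regression and the Replacement Method search.

The Replacement Method (RM) finds a near-optimal d-descriptor subset in a
large pool without exhaustive enumeration: starting from a random subset it
repeatedly replaces the descriptor whose coefficient carries the largest
relative standard error with the pool descriptor that most reduces the
residual standard deviation S, iterating to a fixed point.  An exhaustive
search over all C(D, d) subsets is provided as the correctness oracle for
small pools, and a dimension sweep reproduces the d-selection tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptor_pool import DescriptorMatrix


@dataclass
class LinearModel:
    """OLS fit ``y_hat = intercept + sum_i coef_i * descriptor_i``."""

    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    n_train: int
    r2_train: float
    rms_train: float  # sqrt(RSS / n)
    s_train: float    # sqrt(RSS / (n - d - 1))
    coef_se: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def d(self) -> int:
        return len(self.descriptor_names)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.descriptor_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing descriptor column(s): {missing}")
            X = X[list(self.descriptor_names)].to_numpy(dtype=float)
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


@dataclass
class SearchResult:
    model: LinearModel
    n_restarts: int
    visited_models: int
    converged: list[bool]
    seed: int
    step_log: pd.DataFrame


def fit_mlr(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    names: tuple[str, ...] | None = None,
) -> LinearModel:
    """Ordinary least squares with the diagnostics the pipeline reports.

    R^2 is the squared correlation of fitted vs observed; RMS divides the
    residual sum of squares by n, S by n - d - 1 (the residual standard
    deviation that RM minimizes).
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(d))
    if n <= d + 1:
        raise ValueError(f"need more than d+1={d + 1} rows, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in design matrix or response")

    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < d + 1:
        bad = [names[j] for j in range(d)
               if np.linalg.matrix_rank(np.delete(A, j + 1, axis=1)) == rank]
        raise ValueError(f"rank-deficient descriptor subset; involved: {bad}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    s2 = rss / (n - d - 1)
    cov = s2 * np.linalg.inv(A.T @ A)
    return LinearModel(
        descriptor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        n_train=n,
        r2_train=1.0 - rss / tss if tss > 0 else 0.0,
        rms_train=math.sqrt(rss / n),
        s_train=math.sqrt(s2),
        coef_se=np.sqrt(np.diag(cov))[1:],
    )


def _s_of_subset(A: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    """Residual standard deviation of the OLS fit on columns ``cols``.

    Returns inf for (numerically) rank-deficient subsets so the search
    simply skips them.
    """
    n = A.shape[0]
    d = len(cols)
    M = A[:, (0, *[c + 1 for c in cols])]
    beta, res, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < d + 1:
        return math.inf
    resid = y - M @ beta
    return math.sqrt(float(resid @ resid) / (n - d - 1))


def rm_search(
    pool: DescriptorMatrix,
    y: np.ndarray,
    d: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_passes: int = 200,
) -> SearchResult:
    """Replacement Method search for the best d-descriptor subset.

    Each restart starts from a seeded random subset and iterates full
    passes: positions are taken in order of decreasing relative coefficient
    standard error; the descriptor at a position is swapped against every
    pool column outside the subset and the swap minimizing S is kept if it
    strictly improves.  A pass with no accepted swap terminates the restart.
    """
    Xdf = pool.train_rows()
    names = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, D = X.shape
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > D:
        raise ValueError(f"d={d} exceeds pool size D={D}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    A = np.column_stack([np.ones(n), X])

    if d == D:
        model = fit_mlr(Xdf, y)
        return SearchResult(model, 0, 1, [True], seed,
                            pd.DataFrame(columns=["restart", "step", "position",
                                                  "old", "new", "s_train"]))

    rng = np.random.default_rng(seed)
    best_subset: tuple[int, ...] | None = None
    best_s = math.inf
    visited = 0
    converged = []
    log_rows = []

    for r in range(n_restarts):
        subset = list(rng.choice(D, size=d, replace=False))
        s = _s_of_subset(A, y, tuple(subset))
        visited += 1
        # restart from a fresh random subset if the draw is degenerate
        tries = 0
        while not math.isfinite(s) and tries < 50:
            subset = list(rng.choice(D, size=d, replace=False))
            s = _s_of_subset(A, y, tuple(subset))
            tries += 1
        step = 0
        done = False
        for _ in range(max_passes):
            improved_in_pass = False
            order = _positions_by_relative_se(A, y, subset)
            for pos in order:
                incumbent = subset[pos]
                out = set(subset)
                best_repl, best_repl_s = incumbent, s
                for cand in range(D):
                    if cand in out:
                        continue
                    trial = subset.copy()
                    trial[pos] = cand
                    s_new = _s_of_subset(A, y, tuple(trial))
                    visited += 1
                    if s_new < best_repl_s:
                        best_repl, best_repl_s = cand, s_new
                if best_repl != incumbent and best_repl_s < s:
                    subset[pos] = best_repl
                    step += 1
                    log_rows.append({
                        "restart": r, "step": step, "position": pos,
                        "old": names[incumbent], "new": names[best_repl],
                        "s_train": best_repl_s,
                    })
                    s = best_repl_s
                    improved_in_pass = True
            if not improved_in_pass:
                done = True
                break
        converged.append(done)
        if s < best_s:
            best_s, best_subset = s, tuple(subset)

    assert best_subset is not None
    model = fit_mlr(Xdf.iloc[:, list(best_subset)], y)
    return SearchResult(
        model=model,
        n_restarts=n_restarts,
        visited_models=visited,
        converged=converged,
        seed=seed,
        step_log=pd.DataFrame(
            log_rows, columns=["restart", "step", "position", "old", "new", "s_train"]
        ),
    )


def _positions_by_relative_se(
    A: np.ndarray, y: np.ndarray, subset: list[int]
) -> list[int]:
    """Subset positions ordered by decreasing |SE(coef) / coef|."""
    n = A.shape[0]
    d = len(subset)
    M = A[:, (0, *[c + 1 for c in subset])]
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    s2 = float(resid @ resid) / max(n - d - 1, 1)
    try:
        cov = s2 * np.linalg.inv(M.T @ M)
    except np.linalg.LinAlgError:
        return list(range(d))
    se = np.sqrt(np.abs(np.diag(cov)))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(beta[1:] != 0, se / np.abs(beta[1:]), np.inf)
    return list(np.argsort(-rel, kind="stable"))


def exhaustive_search(
    pool: DescriptorMatrix,
    y: np.ndarray,
    d: int,
    cap: int = 200_000,
) -> LinearModel:
    """Global optimum of S over all d-subsets; the oracle for RM."""
    Xdf = pool.train_rows()
    X = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, D = X.shape
    n_subsets = math.comb(D, d)
    if n_subsets > cap:
        raise ValueError(
            f"C({D},{d}) = {n_subsets} exceeds the cap ({cap}); use rm_search"
        )
    A = np.column_stack([np.ones(n), X])
    best_s = math.inf
    best: tuple[int, ...] | None = None
    for cols in itertools.combinations(range(D), d):
        s = _s_of_subset(A, y, cols)
        if s < best_s:
            best_s, best = s, cols
    if best is None:
        raise ValueError("no full-rank subset of the requested size exists")
    return fit_mlr(Xdf.iloc[:, list(best)], y)


def dimension_sweep(
    pool: DescriptorMatrix,
    y_train: np.ndarray,
    y_test: np.ndarray | None = None,
    d_range: range | list[int] = range(1, 7),
    n_restarts: int = 10,
    seed: int = 0,
    margin: float = 0.01,
) -> pd.DataFrame:
    """One RM search per dimension d, tabulated like the model-selection tables.

    Returns a table of (d, descriptors, r2_train, r2_test, rms_train,
    rms_test, selected) where ``selected`` flags the smallest d after which
    the test RMS stops improving by more than ``margin``.
    """
    rows = []
    X_test = pool.test_rows()
    for i, d in enumerate(d_range):
        res = rm_search(pool, y_train, d, n_restarts=n_restarts, seed=seed + i)
        m = res.model
        row = {
            "d": d,
            "descriptors": " ".join(m.descriptor_names),
            "r2_train": m.r2_train,
            "rms_train": m.rms_train,
            "r2_test": np.nan,
            "rms_test": np.nan,
        }
        if y_test is not None and len(X_test):
            pred = m.predict(X_test)
            yt = np.asarray(y_test, dtype=float)
            resid = yt - pred
            row["rms_test"] = float(np.sqrt(np.mean(resid ** 2)))
            if np.ptp(yt) > 0 and np.ptp(pred) > 0:
                row["r2_test"] = float(np.corrcoef(pred, yt)[0, 1] ** 2)
        rows.append(row)
    table = pd.DataFrame(rows)

    table["selected"] = False
    if table["rms_test"].notna().all() and len(table) > 0:
        chosen = table["d"].iloc[-1]
        for i in range(len(table) - 1):
            future_best = table["rms_test"].iloc[i + 1:].min()
            if table["rms_test"].iloc[i] - future_best <= margin:
                chosen = table["d"].iloc[i]
                break
        table.loc[table["d"] == chosen, "selected"] = True
    return table
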