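"""Model validation battery: LOO, Y-randomization, outliers, external
criteria and the leverage applicability domain.

Conventions follow common QSPR practice: RMS statistics divide by n,
R^2-type statistics are squared Pearson correlations unless a criterion's
own definition says otherwise, and the warning leverage is
h* = 3(d + 1) / n_train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .subset_mlr import LinearModel, fit_mlr


@dataclass
class ValidationReport:
    r2_train: float = np.nan
    rms_train: float = np.nan
    r2_test: float = np.nan
    rms_test: float = np.nan
    r2_loo: float = np.nan
    rms_loo: float = np.nan
    rms_rand_mean: float = np.nan
    n_rand_cases: int = 0
    y_rand_pass: bool | None = None
    o2_5: int = 0
    rij_max: float = np.nan
    external_criteria: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "external_criteria"}
        out.update(self.external_criteria)
        return out


@dataclass
class ADReport:
    """Leverage-based applicability domain for a fitted subset model."""

    leverages: pd.Series
    h_star: float
    outside_ad: list

    @property
    def n_outside(self) -> int:
        return len(self.outside_ad)


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, np.asarray(y, dtype=float)


def loo_cv(X, y) -> tuple[float, float, np.ndarray]:
    """Leave-one-out cross-validation by explicit refits.

    Each compound is excluded in turn, the model refitted on the remaining
    n-1 and the excluded compound predicted; returns (r2_loo, rms_loo,
    per-compound held-out predictions).  r2_loo is the classic
    Q^2 = 1 - PRESS / TSS.
    """
    X, y = _as_xy(X, y)
    n, d = X.shape
    if n < d + 3:
        raise ValueError(f"need n >= d+3 = {d + 3} compounds for LOO, got {n}")
    A = np.column_stack([np.ones(n), X])
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Ai, yi = A[mask], y[mask]
        beta, _, rank, _ = np.linalg.lstsq(Ai, yi, rcond=None)
        if rank < d + 1:
            raise ValueError(f"rank-deficient refit when excluding compound {i}")
        preds[i] = A[i] @ beta
    press = float(((y - preds) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2_loo = 1.0 - press / tss if tss > 0 else np.nan
    rms_loo = float(np.sqrt(press / n))
    return r2_loo, rms_loo, preds


def loo_cv_hat(X, y) -> tuple[float, float, np.ndarray]:
    """Hat-matrix (PRESS) shortcut for LOO; equals :func:`loo_cv` exactly."""
    X, y = _as_xy(X, y)
    n, d = X.shape
    A = np.column_stack([np.ones(n), X])
    H = A @ np.linalg.inv(A.T @ A) @ A.T
    resid = y - H @ y
    loo_resid = resid / (1.0 - np.diag(H))
    preds = y - loo_resid
    press = float((loo_resid ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss, float(np.sqrt(press / n)), preds


def y_randomization(
    X, y, n_cases: int = 10_000, seed: int = 0
) -> tuple[float, np.ndarray, bool]:
    """Scramble the property vector ``n_cases`` times and refit each time.

    Returns (mean scrambled training RMS, all per-case RMS values, PASS
    flag).  PASS means the mean scrambled RMS exceeds the true training
    RMS, i.e. the model is not a chance correlation.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    X, y = _as_xy(X, y)
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    # QR once: the design never changes, only the permuted response
    Q, _ = np.linalg.qr(A)
    rms_true = float(np.sqrt(np.mean((y - Q @ (Q.T @ y)) ** 2)))
    rng = np.random.default_rng(seed)
    all_rms = np.empty(n_cases)
    for c in range(n_cases):
        yp = y[rng.permutation(n)]
        resid = yp - Q @ (Q.T @ yp)
        all_rms[c] = np.sqrt(np.mean(resid ** 2))
    mean_rms = float(all_rms.mean())
    return mean_rms, all_rms, mean_rms > rms_true


def count_outliers(model: LinearModel, X, y, k: float = 2.5) -> int:
    """Number of compounds with |residual| > k * RMStrain (the o2.5 count)."""
    X, y = _as_xy(X, y)
    resid = y - model.predict(X)
    return int((np.abs(resid) > k * model.rms_train).sum())


def max_pairwise_correlation(X) -> float:
    """Maximum squared Pearson correlation over descriptor pairs (Rijmax^2)."""
    X, _ = _as_xy(X, np.zeros(len(X)))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 descriptors")
    corr = np.corrcoef(X, rowvar=False)
    mask = ~np.eye(X.shape[1], dtype=bool)
    return float(np.nanmax(corr[mask] ** 2))


def external_stats(
    model: LinearModel, X_test, y_test
) -> tuple[float, float, np.ndarray]:
    """Squared predicted-observed correlation and RMS on an external set."""
    if isinstance(X_test, pd.DataFrame):
        pred = model.predict(X_test)
    else:
        X_arr, _ = _as_xy(X_test, y_test)
        pred = model.predict(X_arr)
    y_test = np.asarray(y_test, dtype=float)
    rms = float(np.sqrt(np.mean((y_test - pred) ** 2)))
    if np.ptp(y_test) == 0:
        raise ValueError(f"constant test property; RMS alone is {rms:.6g}")
    r2 = float(np.corrcoef(pred, y_test)[0, 1] ** 2)
    return r2, rms, pred


def external_criteria(
    model: LinearModel, X_train, y_train, X_test, y_test
) -> dict:
    """Standard external-validation battery for a QSPR model.

    Computes Q2F1, Q2F2, Q2F3, the concordance correlation coefficient and
    the regression-through-origin checks (k, k', |r2_0 - r2_0'|), each with
    its conventional pass threshold.
    """
    _, y_tr = _as_xy(X_train, y_train)
    if isinstance(X_test, pd.DataFrame):
        pred = model.predict(X_test)
    else:
        pred = model.predict(_as_xy(X_test, y_test)[0])
    y = np.asarray(y_test, dtype=float)
    n_ext = len(y)
    ss_err = float(((y - pred) ** 2).sum())

    q2f1 = 1.0 - ss_err / float(((y - y_tr.mean()) ** 2).sum())
    q2f2 = 1.0 - ss_err / float(((y - y.mean()) ** 2).sum())
    q2f3 = 1.0 - (ss_err / n_ext) / float(((y_tr - y_tr.mean()) ** 2).mean())

    sy, sp = y - y.mean(), pred - pred.mean()
    ccc = float(
        2.0 * (sy * sp).sum()
        / ((sy ** 2).sum() + (sp ** 2).sum() + n_ext * (y.mean() - pred.mean()) ** 2)
    )

    r2 = float(np.corrcoef(pred, y)[0, 1] ** 2) if np.ptp(pred) > 0 else 1.0
    k = float((y * pred).sum() / (pred ** 2).sum())
    k_prime = float((y * pred).sum() / (y ** 2).sum())
    # r^2 of regressions through the origin (observed-vs-predicted and back)
    r2_0 = 1.0 - float(((y - k * pred) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    r2_0p = 1.0 - float(((pred - k_prime * y) ** 2).sum()
                        / ((pred - pred.mean()) ** 2).sum())
    return {
        "q2_f1": q2f1,
        "q2_f2": q2f2,
        "q2_f3": q2f3,
        "ccc": ccc,
        "k": k,
        "k_prime": k_prime,
        "abs_r20_diff": abs(r2_0 - r2_0p),
        "thresholds": {
            "q2_f1": ">= 0.70", "q2_f2": ">= 0.70", "q2_f3": ">= 0.70",
            "ccc": ">= 0.85", "k": "0.85 <= k <= 1.15",
            "k_prime": "0.85 <= k' <= 1.15", "abs_r20_diff": "<= 0.10",
        },
    }


def leverage_ad(X_train, X_query, query_ids=None) -> ADReport:
    """Leverage applicability domain with warning leverage h* = 3(d+1)/n.

    Leverages are h_i = x_i (X'X)^-1 x_i' on intercept-augmented descriptor
    rows; query compounds with h_i > h* sit outside the domain and their
    predictions are flagged as extrapolations.
    """
    Xt, _ = _as_xy(X_train, np.zeros(len(X_train)))
    if isinstance(X_query, pd.DataFrame):
        if query_ids is None:
            query_ids = list(X_query.index)
        Xq = X_query.to_numpy(dtype=float)
    else:
        Xq, _ = _as_xy(X_query, np.zeros(len(X_query)))
    if query_ids is None:
        query_ids = list(range(len(Xq)))
    n, d = Xt.shape
    At = np.column_stack([np.ones(n), Xt])
    gram = At.T @ At
    if np.linalg.matrix_rank(gram) < d + 1:
        raise ValueError("singular X'X: training design is rank deficient")
    inv = np.linalg.inv(gram)
    Aq = np.column_stack([np.ones(len(Xq)), Xq])
    lev = np.einsum("ij,jk,ik->i", Aq, inv, Aq)
    h_star = warning_leverage(d, n)
    lev_s = pd.Series(lev, index=query_ids, name="leverage")
    outside = [i for i, h in lev_s.items() if h > h_star]
    return ADReport(leverages=lev_s, h_star=h_star, outside_ad=outside)


def warning_leverage(d: int, n_train: int) -> float:
    """h* = 3(d + 1) / n_train."""
    return 3.0 * (d + 1) / n_train


def validate_model(
    model: LinearModel,
    X_train, y_train,
    X_test=None, y_test=None,
    n_rand_cases: int = 10_000,
    outlier_k: float = 2.5,
    seed: int = 0,
) -> ValidationReport:
    """Full diagnostic battery for a fitted subset model."""
    if isinstance(X_train, pd.DataFrame):
        X_train = X_train[list(model.descriptor_names)]
    if isinstance(X_test, pd.DataFrame):
        X_test = X_test[list(model.descriptor_names)]
    rep = ValidationReport(
        r2_train=model.r2_train,
        rms_train=model.rms_train,
        o2_5=count_outliers(model, X_train, y_train, k=outlier_k),
    )
    if model.d >= 2:
        Xsub = X_train[list(model.descriptor_names)] \
            if isinstance(X_train, pd.DataFrame) else X_train
        rep.rij_max = max_pairwise_correlation(Xsub)
    rep.r2_loo, rep.rms_loo, _ = loo_cv_hat(X_train, y_train)
    rep.rms_rand_mean, _, rep.y_rand_pass = y_randomization(
        X_train, y_train, n_cases=n_rand_cases, seed=seed
    )
    rep.n_rand_cases = n_rand_cases
    if X_test is not None and y_test is not None and len(y_test):
        rep.r2_test, rep.rms_test, _ = external_stats(model, X_test, y_test)
        rep.external_criteria = external_criteria(
            model, X_train, y_train, X_test, y_test
        )
    return rep
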