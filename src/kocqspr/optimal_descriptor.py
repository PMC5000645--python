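"""CORAL-style optimal descriptor: correlation weights fitted by Monte Carlo.

The optimal descriptor DCW of a molecule is the multiplicity-weighted sum of
per-attribute correlation weights (CW) over its structural-attribute profile.
Weights are fitted on a training set by a seeded greedy Monte Carlo search
that only ever accepts moves increasing the squared training correlation
r^2(DCW, y).  Attributes occurring in fewer than ``T`` training compounds are
"rare" and carry no weight; ``T`` and the number of optimization epochs are
the two hyperparameters of the method (the sorption models use T=1,
Nepochs=7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .molgraph import ATTR_CLASSES, AttributeProfile

logger = logging.getLogger(__name__)


@dataclass
class CorrelationWeights:
    """Fitted attribute -> weight map with its activity bookkeeping."""

    weights: dict[str, float]
    threshold_T: int
    n_epochs: int
    active_keys: frozenset[str]
    rng_seed: int
    attr_classes: tuple[str, ...] = ATTR_CLASSES
    r2_trajectory: list[float] = field(default_factory=list)
    unseen_key_count: int = 0

    @property
    def n_active(self) -> int:
        return len(self.active_keys)


@dataclass
class DcwModel:
    """One-descriptor linear model ``y_hat = slope * DCW + intercept``."""

    cw: CorrelationWeights
    slope: float
    intercept: float
    r2_train: float
    rms_train: float

    def predict(self, profiles: Sequence[AttributeProfile]) -> np.ndarray:
        return self.slope * np.array([dcw(p, self.cw) for p in profiles]) \
            + self.intercept


def build_vocabulary(
    profiles: Sequence[AttributeProfile], T: int
) -> tuple[set[str], set[str]]:
    """Split observed attribute keys into active and blocked (rare) sets.

    A key is blocked iff it occurs in fewer than ``T`` training compounds,
    so T=0 and T=1 both activate every observed key.
    """
    if not profiles:
        raise ValueError("empty profile list")
    if T < 0:
        raise ValueError("threshold T must be non-negative")
    freq: dict[str, int] = {}
    for p in profiles:
        for key in p.counts:
            freq[key] = freq.get(key, 0) + 1
    active = {k for k, n in freq.items() if n >= T}
    blocked = set(freq) - active
    return active, blocked


def dcw(profile: AttributeProfile, cw: CorrelationWeights | Mapping[str, float]) -> float:
    """Multiplicity-weighted sum of correlation weights over a profile.

    Keys without a weight (rare or unseen at prediction time) contribute 0;
    unseen keys are counted on the weight object when one is supplied.
    """
    if isinstance(cw, CorrelationWeights):
        table = cw.weights
        unseen = sum(
            n for k, n in profile.counts.items() if k not in cw.active_keys
        )
        if unseen:
            cw.unseen_key_count += unseen
            logger.debug(
                "%s: %d attribute occurrence(s) outside the active vocabulary",
                profile.molecule_id, unseen,
            )
    else:
        table = cw
    return float(
        sum(n * table.get(k, 0.0) for k, n in profile.counts.items())
    )


def _count_matrix(
    profiles: Sequence[AttributeProfile], keys: Sequence[str]
) -> np.ndarray:
    idx = {k: j for j, k in enumerate(keys)}
    C = np.zeros((len(profiles), len(keys)))
    for i, p in enumerate(profiles):
        for k, n in p.counts.items():
            j = idx.get(k)
            if j is not None:
                C[i, j] = n
    return C


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    if denom == 0:
        return 0.0
    return float(((sx * sy).sum() / denom) ** 2)


def mc_optimize(
    profiles: Sequence[AttributeProfile],
    y: Sequence[float],
    T: int = 1,
    n_epochs: int = 7,
    seed: int = 0,
    max_steps_per_key: int = 60,
    init_weights: Mapping[str, float] | None = None,
) -> CorrelationWeights:
    """Fit correlation weights by greedy Monte Carlo hill climbing.

    All active weights start at 1.0 (or at ``init_weights`` where given,
    which the stepwise class search uses to warm-start from the previous
    step's optimum).  Each epoch visits the active keys in a
    seeded-random order; for each key a step size delta ~ U(0.01, 0.1) is
    drawn, both signed directions are evaluated, and the weight keeps moving
    in an improving direction while the training r^2(DCW, y) strictly
    increases (capped at ``max_steps_per_key`` moves per key per epoch).
    The accept/reject trajectory is fully reproducible from ``seed``.
    """
    y = np.asarray(y, dtype=float)
    if len(profiles) != len(y):
        raise ValueError("profiles and y must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 training molecules")
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("property vector has zero variance")

    active, _blocked = build_vocabulary(profiles, T)
    if not active:
        raise ValueError(f"no active attribute keys at T={T}")
    keys = sorted(active)
    C = _count_matrix(profiles, keys)

    rng = np.random.default_rng(seed)
    if init_weights is None:
        w = np.ones(len(keys))
    else:
        w = np.array([init_weights.get(k, 1.0) for k in keys])
    dcw_vec = C @ w
    best_r2 = _r2(dcw_vec, y)
    trajectory = [best_r2]

    for _epoch in range(n_epochs):
        order = rng.permutation(len(keys))
        for j in order:
            delta = rng.uniform(0.01, 0.1)
            col = C[:, j]
            if not col.any():
                continue
            for _ in range(max_steps_per_key):
                r2_up = _r2(dcw_vec + delta * col, y)
                r2_dn = _r2(dcw_vec - delta * col, y)
                if r2_up >= r2_dn:
                    cand_r2, step = r2_up, delta
                else:
                    cand_r2, step = r2_dn, -delta
                if cand_r2 > best_r2:
                    w[j] += step
                    dcw_vec += step * col
                    best_r2 = cand_r2
                    trajectory.append(best_r2)
                else:
                    break

    return CorrelationWeights(
        weights={k: float(w[j]) for j, k in enumerate(keys)},
        threshold_T=T,
        n_epochs=n_epochs,
        active_keys=frozenset(keys),
        rng_seed=seed,
        r2_trajectory=trajectory,
    )


def fit_dcw_model(
    profiles: Sequence[AttributeProfile],
    y: Sequence[float],
    cw: CorrelationWeights,
) -> DcwModel:
    """Ordinary least squares of the property on DCW."""
    y = np.asarray(y, dtype=float)
    x = np.array([dcw(p, cw) for p in profiles])
    if np.ptp(x) == 0:
        raise ValueError("DCW has zero variance on the training set")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return DcwModel(
        cw=cw,
        slope=float(slope),
        intercept=float(intercept),
        r2_train=_r2(x, y),
        rms_train=float(np.sqrt(np.mean(resid ** 2))),
    )


def stepwise_class_search(
    profiles_by_class: Mapping[str, Sequence[AttributeProfile]],
    y_train: Sequence[float],
    test_profiles_by_class: Mapping[str, Sequence[AttributeProfile]] | None = None,
    y_test: Sequence[float] | None = None,
    T: int = 1,
    n_epochs: int = 7,
    seed: int = 0,
) -> list[dict]:
    """Greedy forward selection over structural-attribute classes.

    At each step every remaining class is tried in combination with the
    classes already selected; weights are re-fitted by Monte Carlo,
    warm-started from the previous step's optimum (keys new to the
    vocabulary start at 1.0), and the candidate with the highest training
    r^2 is kept.  Warm starting makes the training r^2 non-decreasing — and
    hence the training RMS non-increasing — across accepted steps.
    Selection stops once adding a class degrades the test-set RMS (when
    test data is supplied), mirroring the published stopping rule.  Returns
    one report row per accepted step with Rtrain^2, Rtest^2, RMStrain,
    RMStest, Nact and the fitted model.
    """
    candidates = list(profiles_by_class)
    if not candidates:
        raise ValueError("at least one candidate attribute class is required")
    y_train = np.asarray(y_train, dtype=float)

    def merged(classes: list[str], by_class) -> list[AttributeProfile]:
        base = [
            AttributeProfile(p.molecule_id, p.counts.copy())
            for p in by_class[classes[0]]
        ]
        for cls in classes[1:]:
            for acc, p in zip(base, by_class[cls]):
                acc.counts = acc.counts + p.counts
        return base

    selected: list[str] = []
    rows: list[dict] = []
    prev_rms_test = np.inf
    prev_weights: dict[str, float] | None = None
    while candidates:
        best = None
        for cls in candidates:
            trial = selected + [cls]
            prof = merged(trial, profiles_by_class)
            init = None
            if prev_weights is not None:
                # new keys start at 0 so the starting DCW reproduces the
                # previous step's optimum exactly; the climb can only improve
                init = {k: prev_weights.get(k, 0.0)
                        for p in prof for k in p.counts}
            cw = mc_optimize(prof, y_train, T=T, n_epochs=n_epochs, seed=seed,
                             init_weights=init)
            model = fit_dcw_model(prof, y_train, cw)
            row = {
                "classes": tuple(trial),
                "model": model,
                "r2_train": model.r2_train,
                "rms_train": model.rms_train,
                "n_active": cw.n_active,
                "r2_test": np.nan,
                "rms_test": np.nan,
            }
            if test_profiles_by_class is not None and y_test is not None:
                tp = merged(trial, test_profiles_by_class)
                pred = model.predict(tp)
                yt = np.asarray(y_test, dtype=float)
                row["r2_test"] = _r2(pred, yt)
                row["rms_test"] = float(np.sqrt(np.mean((yt - pred) ** 2)))
            if best is None or row["r2_train"] > best["r2_train"]:
                best = row
        assert best is not None
        has_test = np.isfinite(best["rms_test"])
        if has_test and best["rms_test"] > prev_rms_test:
            break  # predictive capability on the test set starts to degrade
        rows.append(best)
        if has_test:
            prev_rms_test = best["rms_test"]
        prev_weights = dict(best["model"].cw.weights)
        new_cls = best["classes"][-1]
        selected.append(new_cls)
        candidates.remove(new_cls)
    return rows
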