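"""Descriptor-table loading, merging and collinearity filtering.

Descriptor matrices arrive as CSV exports (PaDEL-style wide tables, EPI
Suite two-column tables, or a DCW column produced by this package) and are
merged into a single compound x descriptor pool.  Before subset search the
pool is sanitized: constant columns and effectively identical
(linearly-dependent) column pairs are dropped, keeping the first of each
pair, with every removal logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Effectively exact duplicates up to affine transformation and float noise.
DEFAULT_CORR_TOL = 0.999999


@dataclass
class DescriptorMatrix:
    """Named compound x descriptor table with a train/test split."""

    values: pd.DataFrame  # index = compound ids, columns = descriptor names
    split_labels: pd.Series  # per-compound "train" / "test"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate descriptor names: {list(dupes)}")
        if not self.split_labels.index.equals(self.values.index):
            self.split_labels = self.split_labels.reindex(self.values.index)
        bad = set(self.split_labels.dropna()) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def compound_ids(self) -> list:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def train_rows(self) -> pd.DataFrame:
        return self.values.loc[self.split_labels == "train"]

    def test_rows(self) -> pd.DataFrame:
        return self.values.loc[self.split_labels == "test"]


def load_table(
    path,
    id_column: str,
    property_column: str | None = None,
    split_column: str | None = None,
) -> tuple[DescriptorMatrix, pd.Series | None]:
    """Load a descriptor CSV into a matrix plus an optional property vector.

    Non-numeric descriptor cells are coerced to missing and logged; rows or
    columns with unresolvable gaps are handled later by the caller (the
    matrix keeps NaN so the removal is explicit).
    """
    df = pd.read_csv(path)
    for col in filter(None, (id_column, property_column, split_column)):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if df[id_column].duplicated().any():
        dupes = df[id_column][df[id_column].duplicated()].tolist()
        raise ValueError(f"duplicate compound ids: {dupes}")
    df = df.set_index(id_column)

    y = None
    if property_column is not None:
        y = pd.to_numeric(df.pop(property_column), errors="coerce")
    if split_column is not None:
        split = df.pop(split_column).astype(str).str.lower()
    else:
        split = pd.Series("train", index=df.index)

    values = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int(values.isna().sum().sum() - df.isna().sum().sum())
    if n_bad:
        logger.warning("%s: %d non-numeric cell(s) coerced to missing", path, n_bad)
    return DescriptorMatrix(values=values, split_labels=split), y


def merge(tables: list[DescriptorMatrix]) -> DescriptorMatrix:
    """Column-wise concatenation of descriptor tables over identical compounds.

    Descriptor-name collisions are resolved by prefixing with the table's
    position (``t0.``, ``t1.``, ...) and logged; compound sets and split
    labels must agree exactly.
    """
    if not tables:
        raise ValueError("no tables to merge")
    base = tables[0]
    for k, t in enumerate(tables[1:], start=1):
        missing = set(base.compound_ids) ^ set(t.compound_ids)
        if missing:
            raise ValueError(
                f"table {k} compound set differs from table 0: {sorted(missing)[:10]}"
            )
        if not t.split_labels.reindex(base.values.index).equals(base.split_labels):
            raise ValueError(f"table {k} split labels disagree with table 0")

    seen: set[str] = set()
    frames = []
    for k, t in enumerate(tables):
        df = t.values.reindex(base.values.index)
        rename = {c: f"t{k}.{c}" for c in df.columns if c in seen}
        if rename:
            logger.warning("merge: prefixing colliding names %s", sorted(rename))
            df = df.rename(columns=rename)
        seen.update(df.columns)
        frames.append(df)
    return DescriptorMatrix(
        values=pd.concat(frames, axis=1), split_labels=base.split_labels.copy()
    )


def remove_degenerate(
    m: DescriptorMatrix, corr_tol: float = DEFAULT_CORR_TOL
) -> tuple[DescriptorMatrix, pd.DataFrame]:
    """Drop constant and pairwise linearly-dependent descriptor columns.

    Constant columns (on the training rows) go first; then for every pair
    with |Pearson r| >= ``corr_tol`` on the *training* rows the later column
    in the current order is dropped, so exactly one member of each dependent
    group survives.  Returns the filtered matrix and a removal log with one
    row per dropped descriptor (descriptor, reason, partner, abs_r).

    The filter looks only at training rows to keep the test set out of
    every modelling decision.
    """
    if not 0 < corr_tol <= 1:
        raise ValueError("corr_tol must be in (0, 1]")
    X = m.train_rows()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training rows to assess collinearity")

    log_rows = []
    nan_cols = X.columns[X.isna().any()]
    for c in nan_cols:
        log_rows.append({"descriptor": c, "reason": "missing_values",
                         "partner": "", "abs_r": np.nan})
    X = X.drop(columns=nan_cols)

    const = X.columns[X.std(ddof=0) == 0]
    for c in const:
        log_rows.append({"descriptor": c, "reason": "constant",
                         "partner": "", "abs_r": np.nan})
    X = X.drop(columns=const)

    keep = list(X.columns)
    if len(keep) >= 2:
        arr = X.to_numpy(dtype=float)
        arr = arr - arr.mean(axis=0)
        norms = np.linalg.norm(arr, axis=0)
        corr = np.abs((arr / norms).T @ (arr / norms))
        np.fill_diagonal(corr, 0.0)
        dropped = np.zeros(len(keep), dtype=bool)
        for j in range(len(keep)):
            if dropped[j]:
                continue
            partners = np.where((corr[j] >= corr_tol) & ~dropped)[0]
            for p in partners[partners > j]:
                dropped[p] = True
                log_rows.append({
                    "descriptor": keep[p], "reason": "collinear",
                    "partner": keep[j], "abs_r": float(corr[j, p]),
                })
        keep = [c for c, d in zip(keep, dropped) if not d]

    log = pd.DataFrame(log_rows, columns=["descriptor", "reason", "partner", "abs_r"])
    filtered = DescriptorMatrix(
        values=m.values[keep].copy(), split_labels=m.split_labels.copy()
    )
    return filtered, log
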