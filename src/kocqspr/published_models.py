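"""The three published logKoc predictors, packaged as ready-to-use models.

Each model is a fixed linear equation over named descriptor values:

* ``eq1`` — four PaDEL descriptors (SP3, CrippenLogP, gmax, XLogP);
* ``eq2`` — the single optimal descriptor DCW (T=1, Nepochs=7);
* ``eq3`` — MLFER.E, the SubFP302 rotatable-bond fingerprint bit and the
  EPI Suite logKow estimate; the recommended model, with warning leverage
  h* = 0.13 for applicability-domain gating.

Descriptor values are user-supplied (PaDEL/EPI Suite exports, or the
``optimal_descriptor`` module for DCW); coefficients are stored exactly as
published, rounded to two significant figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PublishedModel:
    name: str
    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    h_star: float | None = None
    provenance: str = ""
    binary_descriptors: tuple[str, ...] = ()

    def predict_row(self, row: Mapping[str, float]) -> float:
        missing = [d for d in self.descriptor_names if d not in row]
        if missing:
            raise ValueError(f"{self.name}: missing descriptor(s) {missing}")
        vals = np.array([row[d] for d in self.descriptor_names], dtype=float)
        if not np.isfinite(vals).all():
            bad = [d for d, v in zip(self.descriptor_names, vals)
                   if not np.isfinite(v)]
            raise ValueError(f"{self.name}: non-finite value(s) for {bad}")
        for d in self.binary_descriptors:
            if row[d] not in (0, 1):
                warnings.warn(
                    f"{self.name}: {d} is a 0/1 fingerprint bit but got "
                    f"{row[d]!r}; the linear combination is computed anyway",
                    stacklevel=2,
                )
        return float(vals @ np.array(self.coefficients) + self.intercept)

    def interpret(self) -> pd.DataFrame:
        """Signed-contribution summary: which descriptors raise logKoc."""
        return pd.DataFrame({
            "descriptor": self.descriptor_names,
            "coefficient": self.coefficients,
            "sign": ["positive" if c > 0 else "negative"
                     for c in self.coefficients],
        })


EQ1 = PublishedModel(
    name="eq1",
    descriptor_names=("SP3", "CrippenLogP", "gmax", "XLogP"),
    coefficients=(0.18, 0.30, -0.090, 0.16),
    intercept=1.18,
    provenance="four-descriptor PaDEL model (93 train / 550 test compounds)",
)

EQ2 = PublishedModel(
    name="eq2",
    descriptor_names=("DCW",),
    coefficients=(0.073,),
    intercept=0.31,
    provenance="single optimal-descriptor model, T=1, Nepochs=7",
)

EQ3 = PublishedModel(
    name="eq3",
    descriptor_names=("MLFER.E", "SubFP302", "logKowEpi"),
    coefficients=(0.60, -0.36, 0.48),
    intercept=0.72,
    h_star=0.13,
    provenance="recommended PaDEL + EPI Suite model",
    binary_descriptors=("SubFP302",),
)

MODELS: dict[str, PublishedModel] = {m.name: m for m in (EQ1, EQ2, EQ3)}

#: Correlation-weight table of the published worked example: formaldehyde's
#: nine structural attributes and their fitted CW values (DCW = -0.64892).
FORMALDEHYDE_CW: dict[str, float] = {
    "EC0-O...1...": 0.12508,
    "EC0-C...3...": 1.00094,
    "EC0-H...1...": -0.18254,
    "NNC-O...101.": 0.24867,
    "NNC-C...303.": -0.75284,
    "NNC-H...101.": -0.07978,
    "NOSP01000000": -0.74613,
}


def predict(
    model: PublishedModel | str,
    descriptor_row: Mapping[str, float],
    train_leverage_stats: tuple[np.ndarray, float] | None = None,
) -> tuple[float, bool | None]:
    """Predict logKoc for one compound; AD flag when leverage stats exist.

    ``train_leverage_stats`` is an optional ``(inv_gram, h_star)`` pair from
    the training design; without it the in-domain flag is None (unknown).
    """
    if isinstance(model, str):
        try:
            model = MODELS[model]
        except KeyError:
            raise ValueError(
                f"unknown model {model!r}; choose from {sorted(MODELS)}"
            ) from None
    value = model.predict_row(descriptor_row)
    in_ad: bool | None = None
    if train_leverage_stats is not None:
        inv_gram, h_star = train_leverage_stats
        x = np.concatenate(
            [[1.0], [descriptor_row[d] for d in model.descriptor_names]]
        )
        in_ad = bool(x @ inv_gram @ x <= h_star)
    return value, in_ad


def predict_table(
    model: PublishedModel | str, table: pd.DataFrame
) -> pd.Series:
    """Vectorized prediction over a descriptor DataFrame."""
    if isinstance(model, str):
        model = MODELS[model]
    return pd.Series(
        [model.predict_row(row) for _, row in table.iterrows()],
        index=table.index,
        name="logKoc_pred",
    )
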