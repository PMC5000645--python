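"""Synthetic fixtures with known ground truth for the whole pipeline.

Two families of fixtures mirror the statistical structure the analysis
assumes:

* planted-subset descriptor matrices — i.i.d. standard-normal (or, in
  fingerprint mode, Bernoulli 0/1) descriptor columns, a handful of exact
  duplicate columns, and a property built as a sparse linear combination of
  a known true subset plus homoscedastic Gaussian noise;
* molecule sets from a small fragment grammar — single-fragment, non-ionic
  organic SMILES whose property is an affine function of a known-weight DCW
  plus noise, the recovery target for the Monte Carlo weight fit.

All generators are pure functions of their seed.  The default train:test
split follows the study design these fixtures emulate: a small training set
and a roughly six-fold larger test set (93:550).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptor_pool import DescriptorMatrix
from .molgraph import ATTR_CLASSES, AttributeProfile, attribute_profile, parse_smiles
from .optimal_descriptor import dcw

#: Train:test proportions of the emulated study (93 train, 550 test).
TRAIN_TEST_RATIO = 93 / (93 + 550)


@dataclass
class SyntheticSpec:
    """Parameters of a planted-subset descriptor fixture."""

    n_train: int = 93
    n_test: int = 550
    n_descriptors: int = 50
    true_subset: tuple[int, ...] = (3, 7)
    beta: tuple[float, ...] = (1.5, -2.0)
    sigma: float = 0.1
    n_duplicates: int = 0
    binary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_subset) != len(self.beta):
            raise ValueError("true_subset and beta must have equal length")
        if max(self.true_subset, default=-1) >= self.n_descriptors:
            raise ValueError("true_subset index outside the descriptor pool")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def gen_planted_linear(spec: SyntheticSpec) -> tuple[DescriptorMatrix, pd.Series]:
    """Descriptor matrix with a planted sparse linear property.

    y = X[:, true_subset] @ beta + N(0, sigma^2); ``n_duplicates`` exact
    copies of randomly chosen columns are appended (named ``dup_k_of_<col>``)
    so the collinearity filter has known work to do.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_train + spec.n_test
    if spec.binary:
        X = rng.binomial(1, 0.1, size=(n, spec.n_descriptors)).astype(float)
    else:
        X = rng.standard_normal((n, spec.n_descriptors))
    names = [f"desc{j:03d}" for j in range(spec.n_descriptors)]
    cols = [X]
    dup_names = []
    if spec.n_duplicates:
        src = rng.choice(spec.n_descriptors, size=spec.n_duplicates, replace=False)
        cols.append(X[:, src])
        dup_names = [f"dup{k}_of_{names[j]}" for k, j in enumerate(src)]
    full = np.hstack(cols)
    ids = [f"cpd{i:04d}" for i in range(n)]
    y = full[:, list(spec.true_subset)] @ np.array(spec.beta) \
        + rng.normal(0.0, spec.sigma, size=n)
    split = pd.Series(
        ["train"] * spec.n_train + ["test"] * spec.n_test, index=ids, name="split"
    )
    values = pd.DataFrame(full, index=ids, columns=names + dup_names)
    return (
        DescriptorMatrix(values=values, split_labels=split),
        pd.Series(y, index=ids, name="y"),
    )


# Fragment grammar for small organic, single-fragment, non-ionic molecules:
# an alkyl backbone decorated with at most a few heteroatom/halogen
# fragments and optionally one carbocycle.
_BACKBONES = ["C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCCCCC"]
_SUBSTITUENTS = ["O", "N", "S", "Cl", "Br", "F", "C=O", "C(=O)O", "C#N", "OC"]
_SUBSTITUENT_P = [0.18, 0.12, 0.06, 0.12, 0.06, 0.10, 0.12, 0.10, 0.06, 0.08]
_RINGS = ["C1CCCCC1", "c1ccccc1", "C1CCCC1"]


def gen_molecule_set(n: int, seed: int = 0) -> list[str]:
    """Reproducible small-organic SMILES from a fixed fragment grammar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        # Concatenation can violate valence (e.g. a nitrile followed by a
        # halogen); draw candidates until one parses.  The rng stream keeps
        # the whole procedure a pure function of the seed.
        for _attempt in range(100):
            parts = [str(rng.choice(_BACKBONES))]
            if rng.random() < 0.3:
                parts.append(str(rng.choice(_RINGS)))
            for _ in range(rng.integers(0, 3)):
                parts.append(str(rng.choice(_SUBSTITUENTS, p=_SUBSTITUENT_P)))
            smiles = "".join(parts)
            try:
                parse_smiles(smiles)
            except ValueError:
                continue
            out.append(smiles)
            break
        else:  # pragma: no cover - the grammar always yields a valid draw
            raise RuntimeError("fragment grammar failed to produce a molecule")
    return out


def gen_cw_property(
    molecules: list[str] | list[AttributeProfile],
    true_cw: dict[str, float],
    slope: float = 1.0,
    intercept: float = 0.0,
    sigma: float = 0.05,
    seed: int = 0,
    classes: tuple[str, ...] = ATTR_CLASSES,
) -> pd.Series:
    """Property built from a known-weight DCW: y = slope*DCW_true + b + noise.

    Attribute keys absent from ``true_cw`` contribute 0, exactly as unseen
    keys do at prediction time.
    """
    profiles = [
        m if isinstance(m, AttributeProfile)
        else attribute_profile(parse_smiles(m), classes)
        for m in molecules
    ]
    rng = np.random.default_rng(seed)
    y = np.array([
        slope * dcw(p, true_cw) + intercept for p in profiles
    ]) + rng.normal(0.0, sigma, size=len(profiles))
    return pd.Series(y, index=[p.molecule_id for p in profiles], name="y")


def gen_true_cw(
    profiles: list[AttributeProfile], seed: int = 0, scale: float = 0.5
) -> dict[str, float]:
    """A random ground-truth weight table over the keys a set of molecules
    actually exhibits, drawn N(0, scale^2) — the span of published
    correlation-weight tables (roughly -0.8 to 1.0)."""
    keys = sorted({k for p in profiles for k in p.counts})
    rng = np.random.default_rng(seed)
    return {k: float(w) for k, w in zip(keys, rng.normal(0.0, scale, len(keys)))}
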