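# kocqspr

Conformation-independent QSPR modelling of the soil sorption coefficient
(logKoc) for organic non-ionic compounds.

The soil sorption coefficient Koc — the ratio of a chemical's
concentration sorbed to soil organic carbon to its concentration in water —
governs the environmental fate of pesticides and organic pollutants, and is
slow and costly to measure. This package builds and validates linear
structure–property models for logKoc using only 2D-graph information (no
conformers, no geometry optimization). It is aimed at QSAR/QSPR
practitioners who have descriptor tables (e.g. PaDEL or EPI Suite exports)
and SMILES, and want a reproducible, fully seeded pipeline.

Two modelling routes are implemented end to end:

* **Replacement Method (RM) subset MLR** — for a pool of D descriptors,
  find the d-descriptor ordinary-least-squares model (d ≪ D) minimizing
  the residual standard deviation S_train, by iteratively replacing the
  descriptor whose coefficient has the largest relative standard error.
  Includes an exhaustive-search oracle, a collinearity pre-filter, and a
  dimension sweep for choosing d.
* **Optimal descriptor (DCW)** — per-molecule sum of correlation weights
  over structural attributes of the hydrogen-filled graph (NNC
  nearest-neighbour codes, EC0 zeroth-order Morgan extended connectivity,
  NOSP heteroatom flags), with weights fitted by seeded Monte Carlo hill
  climbing to maximize r²(DCW, logKoc) on the training set, then
  logKoc = a·DCW + b by OLS.

Every model runs through the same validation battery — leave-one-out
cross-validation, Y-randomization, the o2.5 outlier count, the maximum
pairwise descriptor correlation Rijmax², external-set statistics and
criteria (Q²F1/F2/F3, CCC, regression-through-origin checks) — and a
leverage applicability domain with warning leverage h* = 3(d+1)/n.

The three published logKoc equations ship as ready-to-use predictors:

```
eq1: logKoc = 0.18·SP3 + 0.30·CrippenLogP − 0.090·gmax + 0.16·XLogP + 1.18
eq2: logKoc = 0.073·DCW + 0.31                      (T=1, Nepochs=7)
eq3: logKoc = 0.60·MLFER.E − 0.36·SubFP302 + 0.48·logKowEpi + 0.72
```

## Worked example

The classic hand-checkable calculation is the optimal descriptor of
formaldehyde. Its hydrogen-filled graph (SMILES `C=O`) has four atoms and
yields nine attribute occurrences over seven distinct keys; summing the
published correlation weights with multiplicity gives the DCW, and eq2
turns it into a prediction:

```python
>>> from kocqspr import parse_smiles, attribute_profile, dcw
>>> from kocqspr.published_models import FORMALDEHYDE_CW, predict
>>> profile = attribute_profile(parse_smiles("C=O"))
>>> sorted(profile.counts.items())
[('EC0-C...3...', 1), ('EC0-H...1...', 2), ('EC0-O...1...', 1),
 ('NNC-C...303.', 1), ('NNC-H...101.', 2), ('NNC-O...101.', 1),
 ('NOSP01000000', 1)]
>>> round(dcw(profile, FORMALDEHYDE_CW), 5)
-0.64892
>>> predict("eq2", {"DCW": -0.64892})[0]
0.26262884
```

The carbonyl carbon has degree 3 in the hydrogen-filled graph (`EC0-C...3...`,
nearest-neighbour code 303), the two hydrogens count twice, and the NOSP
key `NOSP01000000` records "oxygen present, no N/S/P". The weighted sum
−0.64892 maps through eq2 to a predicted logKoc of 0.263.

## Analysis scripts

The `analysis/` drivers run the full pipeline on synthetic data with known
ground truth and write their tables under `results/`:

```sh
python analysis/01_assemble_pool.py        # pool + collinearity filter
python analysis/02_rm_model_selection.py   # RM dimension sweep, d selection
python analysis/03_optimal_descriptor.py   # stepwise NNC/EC0/NOSP search
python analysis/04_validation_battery.py   # LOO, Y-rand, AD, Williams data
```

Step 02, for instance, prints the model-selection table (93 train / 550
test compounds, 120-column pool, planted two-descriptor truth):

```
 d                     descriptors  r2_train  rms_train  r2_test  rms_test  selected
 1                         desc007     0.652      1.421    0.664     1.540     False
 2                 desc007 desc003     0.987      0.275    0.987     0.293      True
 3         desc003 desc007 desc091     0.988      0.267    0.987     0.298     False
 4 desc007 desc091 desc040 desc003     0.989      0.258    0.986     0.307     False
```

Training RMS keeps improving with d while test RMS does not — so d = 2 is
selected, and it is exactly the planted subset (the exhaustive oracle
agrees).

There is also a CLI for the individual steps:
`kocqspr attributes|dcw-fit|fit|predict|synth` (see `kocqspr --help`).

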