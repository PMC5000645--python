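# Methods

## Problem and scope

The soil sorption coefficient Koc is the ratio of a chemical's
concentration sorbed to soil organic carbon to its concentration dissolved
in water; logKoc spans more than six log units across common pesticides and
organic pollutants, and measuring it is slow and expensive. The package
implements a conformation-independent QSPR workflow for logKoc: all
structural information comes from the 2D molecular graph, never from 3D
geometry. Two complementary modelling routes are covered:

1. **Subset multivariable linear regression (MLR)** over a large pool of
   precomputed descriptors (PaDEL/EPI-Suite-style CSV exports), with the
   Replacement Method for variable selection.
2. **An optimal descriptor (DCW)** built from graph structural attributes
   whose per-attribute correlation weights are fitted to the training
   property by Monte Carlo search — the CORAL family of methods.

Both routes end in the same validation battery and leverage-based
applicability domain. The three published equations are also packaged as
fixed predictors (`published_models`): a four-descriptor PaDEL model, the
one-descriptor DCW model (logKoc = 0.073·DCW + 0.31), and the recommended
three-descriptor PaDEL + EPI Suite model.

Computing PaDEL's descriptor and fingerprint blocks, or EPI Suite's
KOWWIN/WATERNT estimates, is out of scope: those arrive as CSV columns.
Only the three graph-attribute classes below are computed natively.

## Structural representation and attributes

A molecule is parsed from SMILES (via RDKit) into its **hydrogen-filled
graph**: every hydrogen implied by the valence model is an explicit vertex.
Multi-fragment SMILES (salts) and formally charged species are rejected —
the method targets single-fragment, non-ionic organics.

Three attribute classes are extracted:

* **EC0** (zeroth-order Morgan extended connectivity): element symbol plus
  vertex degree, one key per atom, formatted `EC0-<El>...<deg>...`.
* **NNC** (nearest-neighbouring code): element symbol plus a three-digit
  code of the first-shell environment, one key per atom, formatted
  `NNC-<El>...<ddd>.`. The code digits are **(vertex degree, number of
  incident ring bonds, number of neighbours)**. Only one worked example of
  the original encoding is public (formaldehyde: O→101, C→303, H→101), and
  this mapping reproduces it; the learning pipeline only needs a
  deterministic, locally computed label, but byte-compatibility with CORAL
  output for arbitrary molecules is not guaranteed. Any digit exceeding 9
  raises an explicit overflow error rather than wrapping; organic molecules
  in scope never reach it.
* **NOSP**: one whole-molecule key, four 0/1 presence flags for N, O, S, P
  followed by four zero-padding characters (`NOSP01000000` for
  formaldehyde). The trailing characters are treated as pure padding.

A molecule's **attribute profile** is the multiset of keys over the chosen
classes; EC0 and NNC multiplicities each sum to the atom count and NOSP
contributes exactly one key. Profiles are invariant under atom re-ordering.

Note that NNC is an information refinement of EC0: every EC0 key splits
into one or more NNC keys, so any signal expressible through EC0 counts is
also expressible through NNC counts. This matters when interpreting the
stepwise class search — classes are correlated by construction, and the
search ranks them by fitted training correlation, not by disjoint signal.

## The optimal descriptor

DCW(molecule) = Σ over attribute occurrences (with multiplicity) of
CW(key). Keys occurring in fewer than **T** training compounds are "rare"
and carry no weight; unseen keys at prediction time contribute 0 and are
counted on the weight object so the leakage is visible, never silent.
T = 1 (the default, matching the published models) blocks nothing that
occurs at least once; T is meaningful from 2 up.

**Monte Carlo fit.** The original method states only that weights are
obtained by Monte Carlo simulation maximizing the training correlation; the
scheme here is a reproducible greedy hill climb:

* all active weights start at 1.0 (or at supplied warm-start values);
* each epoch visits the active keys in a seeded-random order;
* per key, a step size δ ~ U(0.01, 0.1) is drawn once, both signed
  directions are evaluated, and the weight keeps stepping in an improving
  direction while the squared training correlation r²(DCW, y) strictly
  increases (capped at 60 moves per key per epoch);
* rejected proposals leave the weight unchanged; there is no annealing.

The repeated-step line search (rather than a single proposal per key per
epoch) is what lets 7 epochs traverse weight scales of order 1 — published
weight tables span roughly −0.8 to 1.0 — while remaining a pure
"accept-only-improvements" climb. The full accepted-r² trajectory is stored
and is monotone by construction; the same seed and inputs give bit-identical
weight tables. Only the direction of the weight vector matters for the
final model (the OLS step absorbs scale and offset).

**Stepwise class search.** Classes are added greedily: at each step every
remaining class is tried in combination with the already-selected ones and
the candidate with the highest training r² is kept; selection stops when
the test-set RMS degrades, the published stopping signal. Each step's fit
is warm-started from the previous optimum with new keys initialized at 0,
so the starting DCW of the enlarged vocabulary reproduces the previous
model exactly and training r² is non-decreasing (hence training RMS
non-increasing) across accepted steps. A from-scratch refit at each step is
the other admissible reading; it was not used because it provides no such
guarantee — the monotone statistics seen in published step tables then hold
only by accident of optimization quality.

The final one-descriptor model is plain OLS of y on DCW, reported with the
same statistics as any subset model.

## Descriptor pool and collinearity filter

Descriptor tables are merged column-wise over identical compound sets
(name collisions get a positional prefix and a logged warning). The
degeneracy filter first drops columns with missing or constant training
values, then removes, for every pair with |Pearson r| ≥ `corr_tol` on the
**training rows only**, the later column in the current order. The default
`corr_tol = 0.999999` removes only effectively exact duplicates (identical
columns up to affine transformation and float noise): the published models
retain moderately correlated descriptors (a reported pairwise R² of 0.58),
so an aggressive cut would be wrong. Keep-first tie-breaking makes the
filter deterministic and idempotent. Restricting to training rows keeps the
test set out of every modelling decision.

## Replacement Method (RM)

For a pool of D descriptors and a target dimension d, each restart begins
at a seeded random d-subset and iterates passes: positions are visited in
order of decreasing relative standard error of their coefficient
(|SE/coef|, the least-reliable variable first); the descriptor at a
position is swapped against every pool column outside the subset and the
swap minimizing the residual standard deviation S = √(RSS/(n−d−1)) is
accepted if it strictly improves. A pass with no accepted swap is a fixed
point. The best model over restarts (default 10) is returned, along with
the full step log; accepted steps strictly decrease S, which guarantees
termination. Ties keep the incumbent. Rank-deficient candidate subsets are
skipped (their S is treated as infinite).

S is the search criterion; RMS = √(RSS/n) is reported alongside. At fixed
d they are monotonically related, so the choice only matters across
dimensions, where the dimension sweep compares like-for-like columns
(training and test RMS per d) and flags the smallest d after which the test
RMS stops improving by more than a configurable margin (default 0.01).

`exhaustive_search` enumerates all C(D, d) subsets (capped, default
200,000) and is the independent optimality oracle for RM on small pools.

## Validation battery

* **LOO**: naive per-compound refits by default; a PRESS/hat-matrix fast
  path is provided and tested equal to 1e-10. R²loo is Q² = 1 − PRESS/TSS.
* **Y-randomization**: the property vector is permuted n_cases times
  (convention 10,000; reduced in the bundled analyses), the model refitted
  (one QR factorization reused — only the response changes) and the mean
  scrambled RMS compared with the true training RMS; the model passes when
  the scrambled mean is larger. The mean is used (full distribution
  returned) as the most stable single summary.
* **o2.5**: the count of training compounds with |raw residual| >
  2.5·RMStrain.
* **Rijmax**: the maximum squared pairwise Pearson correlation among the
  model's descriptors.
* **External criteria**: Q²F1, Q²F2, Q²F3, the concordance correlation
  coefficient, and the regression-through-origin checks (k, k′,
  |r²0 − r′²0|), each reported with its conventional pass threshold
  (0.70 / 0.85 / 0.85–1.15 / 0.10). The exact criterion list behind the
  published "external validation criteria" citation is not public; this is
  the field-standard battery.
* **Applicability domain**: leverages h_i = x_i(XᵀX)⁻¹x_iᵀ on
  intercept-augmented rows; warning leverage h* = 3(d+1)/n_train (0.129 →
  printed 0.13 for d = 3, n = 93). Training leverages lie in [1/n, 1] and
  sum to d+1. Williams-plot data (leverage vs standardized residual) is
  exported as CSV.

RMS statistics divide by n throughout; S (divide by n−d−1) is reported
separately. This is required for a single convention to serve both the
"RMS" and "S" columns of the published tables.

## Synthetic data

The generators define the test conditions; they are statistical stand-ins,
not Koc chemistry.

* `gen_planted_linear`: i.i.d. standard-normal descriptor columns (or
  Bernoulli(0.1) 0/1 columns in fingerprint mode), optional exact duplicate
  columns, y = Xβ over a known subset + N(0, σ²), and a 93:550-style
  train:test split mirroring the unusual 1:6 design of the emulated study.
  Defaults: 93 train / 550 test, two-descriptor truth β = (1.5, −2.0),
  σ = 0.1 (bundled analyses use σ = 0.3 for a realistically noisy fit).
* `gen_molecule_set`: single-fragment, non-ionic SMILES from a fixed
  fragment grammar (alkyl backbones, N/O/S/halogen substituents, one
  optional ring), parse-validated with a seeded retry so every output is a
  valid molecule.
* `gen_true_cw` / `gen_cw_property`: a ground-truth weight table drawn
  N(0, 0.5²) over the keys the molecule set actually exhibits — matching
  the span of published weight tables — and y = slope·DCW_true + intercept
  + N(0, σ²).

What passing on these fixtures shows: the algorithms recover planted
structure under the stated noise. What it does not show: performance on
real descriptor pools, whose columns are neither independent nor Gaussian
and whose property noise is not homoscedastic.

## Numerical choices and problem sizes

OLS uses `numpy.linalg.lstsq` with an explicit rank check (rank-deficient
subsets raise, naming the involved columns); coefficient covariances come
from s²(XᵀX)⁻¹. The RM-vs-exhaustive checks run on 20 seeded fixtures with
n = 60, D ≤ 15 (d = 2–3); Monte Carlo recovery on ten 100-molecule sets
with ~30-key vocabularies; the bundled analyses use a 130-column pool over
643 compounds and 1,000 Y-randomization cases. These sizes keep every
bundled run in seconds while exercising all code paths; all knobs scale up
through the public interfaces.

## Known limitations

* The NNC encoding reproduces the only published worked example but may not
  byte-match CORAL output for arbitrary molecules.
* The Monte Carlo scheme is one admissible reading of "fitted by Monte
  Carlo simulation"; different schemes give different (equally valid)
  weight tables.
* Published coefficients are rounded to two significant figures, so
  per-compound predictions of the original study cannot be reproduced
  exactly from the packaged equations.
* The full 643-compound statistics require the original supplementary
  descriptor tables, which are not packaged; user-supplied tables in the
  same CSV dialect run through the identical pipeline.
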