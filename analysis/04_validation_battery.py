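#!/usr/bin/env python
"""Full validation battery and applicability domain for the selected model.

Reloads the pool and the subset chosen in step 02, then computes every
diagnostic the pipeline reports: training/test statistics, leave-one-out
cross-validation, Y-randomization (a reduced 1,000 cases here; the method's
convention is 10,000), the o2.5 outlier count, Rijmax, the external
validation criteria (Q2F1/F2/F3, CCC, regression-through-origin checks) and
leverage-based applicability-domain flags with h* = 3(d+1)/n.

Writes:  results/validation.json, results/williams.csv
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from kocqspr.app import _jsonable
from kocqspr.descriptor_pool import load_table
from kocqspr.subset_mlr import fit_mlr
from kocqspr.validation import leverage_ad, validate_model, warning_leverage

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main(seed: int = 0) -> None:
    matrix, y = load_table(SCRATCH / "pool.csv", "id", "logKoc", "split")
    with open(RESULTS / "rm_model.json") as fh:
        chosen = json.load(fh)
    names = chosen["descriptors"]

    tr = matrix.split_labels == "train"
    X_train, X_test = matrix.train_rows()[names], matrix.test_rows()[names]
    y_train, y_test = y[tr].to_numpy(), y[~tr].to_numpy()

    model = fit_mlr(X_train, y_train)
    rep = validate_model(model, X_train, y_train, X_test, y_test,
                         n_rand_cases=1000, seed=seed)
    print(f"model ({', '.join(names)}): "
          f"R2train={rep.r2_train:.3f} RMStrain={rep.rms_train:.3f} "
          f"R2test={rep.r2_test:.3f} RMStest={rep.rms_test:.3f}")
    print(f"LOO: R2loo={rep.r2_loo:.3f} RMSloo={rep.rms_loo:.3f}")
    print(f"Y-randomization ({rep.n_rand_cases} cases): "
          f"RMSrand={rep.rms_rand_mean:.3f} "
          f"{'>' if rep.y_rand_pass else '<='} RMStrain -> "
          f"{'PASS' if rep.y_rand_pass else 'FAIL'}")
    print(f"o2.5={rep.o2_5}, Rijmax^2={rep.rij_max:.3f}")

    ad = leverage_ad(X_train, X_test)
    d = len(names)
    print(f"applicability domain: h*=3({d}+1)/{len(X_train)}="
          f"{warning_leverage(d, len(X_train)):.3f}; "
          f"{ad.n_outside} of {len(X_test)} test compounds outside")

    resid = y_test - model.predict(X_test)
    std_resid = resid / rep.rms_train
    pd.DataFrame({
        "id": X_test.index, "leverage": ad.leverages.to_numpy(),
        "std_residual": std_resid,
        "outside_ad": [i in set(ad.outside_ad) for i in X_test.index],
    }).to_csv(RESULTS / "williams.csv", index=False)

    payload = {"seed": seed, "descriptors": names,
               "validation": _jsonable(rep.to_dict()),
               "h_star": ad.h_star, "n_outside_ad": ad.n_outside}
    with open(RESULTS / "validation.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"wrote {RESULTS / 'validation.json'} and {RESULTS / 'williams.csv'}")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=0)
    main(**vars(p.parse_args()))
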