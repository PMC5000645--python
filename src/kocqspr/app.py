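"""Command-line interface tying the pipeline together.

Thin wrappers over the library: every subcommand reads/writes plain CSV or
JSON, embeds the seeds it used in its output, and defaults to the study's
published hyperparameters (T=1, Nepochs=7, 10,000 Y-randomization cases,
outlier threshold 2.5).
"""

from __future__ import annotations

import json
import sys

import click
import numpy as np
import pandas as pd

from . import __version__
from .descriptor_pool import DEFAULT_CORR_TOL, load_table, remove_degenerate
from .molgraph import ATTR_CLASSES, SmilesParseError, attribute_profile, parse_smiles
from .optimal_descriptor import dcw, fit_dcw_model, mc_optimize
from .published_models import MODELS, predict_table
from .subset_mlr import dimension_sweep, rm_search
from .synthetic_data import SyntheticSpec, gen_molecule_set, gen_planted_linear
from .validation import leverage_ad, validate_model


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Conformation-independent QSPR toolkit for logKoc."""


def _read_smiles(path: str) -> list[tuple[str, str]]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append((mol_id, smiles))
    if not records:
        raise click.ClickException(f"no SMILES records in {path}")
    return records


@main.command()
@click.argument("smiles_file", type=click.Path(exists=True))
@click.option("--classes", default=",".join(ATTR_CLASSES),
              help="Comma-separated attribute classes (NNC,EC0,NOSP).")
@click.option("--out", type=click.Path(), required=True)
@click.option("--skip-invalid", is_flag=True,
              help="Skip unparseable SMILES instead of aborting.")
def attributes(smiles_file, classes, out, skip_invalid):
    """Extract structural-attribute profiles into a sparse CSV."""
    cls = tuple(c.strip() for c in classes.split(",") if c.strip())
    rows = []
    for mol_id, smiles in _read_smiles(smiles_file):
        try:
            profile = attribute_profile(parse_smiles(smiles), cls, mol_id)
        except SmilesParseError as exc:
            if skip_invalid:
                click.echo(f"skipping {mol_id}: {exc}", err=True)
                continue
            raise click.ClickException(str(exc)) from exc
        for key, n in sorted(profile.counts.items()):
            rows.append({"molecule_id": mol_id, "attribute_key": key, "count": n})
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"wrote {len(rows)} attribute rows to {out}")


@main.command("dcw-fit")
@click.argument("smiles_file", type=click.Path(exists=True))
@click.argument("property_csv", type=click.Path(exists=True))
@click.option("--id-column", default="id")
@click.option("--property-column", default="logKoc")
@click.option("--threshold", "-T", default=1, show_default=True)
@click.option("--n-epochs", default=7, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def dcw_fit(smiles_file, property_csv, id_column, property_column,
            threshold, n_epochs, seed, out):
    """Fit correlation weights on SMILES + property data; write a CW table."""
    records = _read_smiles(smiles_file)
    props = pd.read_csv(property_csv).set_index(id_column)[property_column]
    profiles = [attribute_profile(parse_smiles(s), ATTR_CLASSES, i)
                for i, s in records]
    y = props.loc[[i for i, _ in records]].to_numpy()
    cw = mc_optimize(profiles, y, T=threshold, n_epochs=n_epochs, seed=seed)
    model = fit_dcw_model(profiles, y, cw)
    freq = {}
    for p in profiles:
        for k in p.counts:
            freq[k] = freq.get(k, 0) + 1
    with open(out, "w") as fh:
        fh.write(f"# kocqspr {__version__}; T={threshold}; "
                 f"n_epochs={n_epochs}; seed={seed}; "
                 f"nnc_encoding=degree,ring_bonds,neighbors; "
                 f"slope={model.slope:.6g}; intercept={model.intercept:.6g}\n")
        pd.DataFrame({
            "attribute_key": sorted(cw.weights),
            "CW": [cw.weights[k] for k in sorted(cw.weights)],
            "frequency": [freq.get(k, 0) for k in sorted(cw.weights)],
            "active": [k in cw.active_keys for k in sorted(cw.weights)],
        }).to_csv(fh, index=False)
    click.echo(
        f"r2_train={model.r2_train:.4f} rms_train={model.rms_train:.4f} "
        f"n_active={cw.n_active} -> {out}"
    )


@main.command("fit")
@click.argument("descriptor_csv", type=click.Path(exists=True))
@click.option("--id-column", default="id")
@click.option("--property-column", default="logKoc")
@click.option("--split-column", default="split")
@click.option("--d-min", default=1, show_default=True)
@click.option("--d-max", default=4, show_default=True)
@click.option("--restarts", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--corr-tol", default=DEFAULT_CORR_TOL, show_default=True)
@click.option("--n-rand-cases", default=10_000, show_default=True)
@click.option("--out-prefix", required=True)
def fit(descriptor_csv, id_column, property_column, split_column,
        d_min, d_max, restarts, seed, corr_tol, n_rand_cases, out_prefix):
    """Filter the pool, run the RM dimension sweep, validate the chosen model."""
    matrix, y = load_table(descriptor_csv, id_column, property_column, split_column)
    matrix, removal_log = remove_degenerate(matrix, corr_tol=corr_tol)
    removal_log.to_csv(f"{out_prefix}_removals.csv", index=False)
    train_mask = matrix.split_labels == "train"
    y_train = y[train_mask].to_numpy()
    y_test = y[~train_mask].to_numpy()
    sweep = dimension_sweep(
        matrix, y_train, y_test if len(y_test) else None,
        d_range=range(d_min, d_max + 1), n_restarts=restarts, seed=seed,
    )
    sweep.to_csv(f"{out_prefix}_sweep.csv", index=False)
    d_star = int(sweep.loc[sweep["selected"], "d"].iloc[0]) \
        if sweep["selected"].any() else d_max
    res = rm_search(matrix, y_train, d_star, n_restarts=restarts, seed=seed)
    model = res.model
    rep = validate_model(
        model, matrix.train_rows(), y_train,
        matrix.test_rows() if len(y_test) else None,
        y_test if len(y_test) else None,
        n_rand_cases=n_rand_cases, seed=seed,
    )
    if not len(y_test):
        click.echo("no test rows: external statistics skipped", err=True)
    ad = leverage_ad(
        matrix.train_rows()[list(model.descriptor_names)],
        matrix.test_rows()[list(model.descriptor_names)]
        if len(y_test) else matrix.train_rows()[list(model.descriptor_names)],
    )
    payload = {
        "package_version": __version__,
        "seed": seed,
        "model": {
            "descriptors": list(model.descriptor_names),
            "coefficients": list(map(float, model.coefficients)),
            "intercept": model.intercept,
            "n_train": model.n_train,
        },
        "validation": _jsonable(rep.to_dict()),
        "applicability_domain": {
            "h_star": ad.h_star,
            "n_outside": ad.n_outside,
            "outside_ad": list(map(str, ad.outside_ad)),
        },
    }
    with open(f"{out_prefix}_model.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    click.echo(f"selected d={d_star}: {' '.join(model.descriptor_names)}")


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _jsonable(v)
        elif isinstance(v, (np.floating, float)):
            out[k] = None if not np.isfinite(v) else float(v)
        elif isinstance(v, (np.integer, np.bool_)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


@main.command()
@click.option("--model", "model_name", required=True,
              type=click.Choice(sorted(MODELS)))
@click.option("--input", "input_csv", type=click.Path(exists=True), required=True)
@click.option("--id-column", default="id")
@click.option("--output", type=click.Path(), required=True)
def predict(model_name, input_csv, id_column, output):
    """Predict logKoc with a published equation over a descriptor CSV."""
    df = pd.read_csv(input_csv)
    if id_column in df.columns:
        df = df.set_index(id_column)
    model = MODELS[model_name]
    missing = [c for c in model.descriptor_names if c not in df.columns]
    if missing:
        raise click.ClickException(
            f"{model_name} needs column(s) {missing} absent from {input_csv}"
        )
    preds = predict_table(model, df)
    out_df = pd.DataFrame({"logKoc_pred": preds})
    out_df.index.name = id_column
    out_df.to_csv(output)
    click.echo(f"wrote {len(out_df)} predictions to {output}")


@main.command()
@click.option("--kind", type=click.Choice(["pool", "molecules"]), default="pool")
@click.option("--n", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def synth(kind, n, seed, out):
    """Generate synthetic fixtures (descriptor pool CSV or SMILES list)."""
    if kind == "pool":
        spec = SyntheticSpec(n_train=max(n // 7, 5), n_test=n - max(n // 7, 5),
                             seed=seed)
        matrix, y = gen_planted_linear(spec)
        df = matrix.values.copy()
        df["logKoc"] = y
        df["split"] = matrix.split_labels
        df.index.name = "id"
        df.to_csv(out)
    else:
        smiles = gen_molecule_set(n, seed=seed)
        with open(out, "w") as fh:
            for i, s in enumerate(smiles):
                fh.write(f"{s}\tmol{i}\n")
    click.echo(f"wrote {n} {kind} records to {out}")


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
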