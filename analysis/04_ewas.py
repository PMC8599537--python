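#!/usr/bin/env python
"""Epigenome-wide association studies of age, rapamycin and sex.

Age: per-species correlation screens combined across species with
Stouffer's method (sqrt-n weights).  Rapamycin: OLS contrast of treated
vs control test-cohort animals with chronological age as covariate.
Sex: same model on untreated animals only (treated animals excluded).
Top CpGs are selected at p < 0.005, up to 500 per direction by |z|, and
the overlap between the three hit sets is counted upset-style.

Writes full tables, top tables and the overlap counts to results/ewas/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from methclock.ewas import (
    ewas_covariate,
    screen_numeric_trait,
    select_top_cpgs,
    set_overlap,
    stouffer_meta,
)
from methclock.io import read_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data/two_species"))
    parser.add_argument("--outdir", type=Path, default=Path("results/ewas"))
    parser.add_argument("--p-threshold", type=float, default=0.005)
    parser.add_argument("--max-per-direction", type=int, default=500)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ds = read_dataset(args.data / "betas.tsv", args.data / "sample_sheet.csv")
    sheet = ds.sheet
    tables = {}

    # -- age: per-species screen, Stouffer meta across species ----------
    z_cols, ns = {}, []
    for sp, grp in sheet.groupby("species"):
        mask = (sheet["species"] == sp).to_numpy()
        z_cols[sp] = screen_numeric_trait(ds.betas.loc[:, mask], grp["age_years"])["z"]
        ns.append(int(mask.sum()))
    age = screen_numeric_trait(ds.betas, sheet["age_years"])
    age["meta_z"] = stouffer_meta(pd.DataFrame(z_cols), weights=np.sqrt(ns))
    tables["age"] = age

    # -- rapamycin: treated vs control, age-adjusted --------------------
    test = sheet["treatment"].isin(["rapamycin", "control"]).to_numpy()
    grp = (sheet.loc[test, "treatment"] == "rapamycin").astype(int)
    tables["rapamycin"] = ewas_covariate(
        ds.betas.loc[:, test], grp,
        covariates=sheet.loc[test, ["age_years"]].reset_index(drop=True),
    )

    # -- sex: females vs males among untreated animals, age-adjusted ----
    untreated = (sheet["treatment"] != "rapamycin").to_numpy()
    sex_grp = (sheet.loc[untreated, "sex"] == "F").astype(int)
    tables["sex"] = ewas_covariate(
        ds.betas.loc[:, untreated], sex_grp,
        covariates=sheet.loc[untreated, ["age_years"]].reset_index(drop=True),
    )

    top_sets = {}
    for name, table in tables.items():
        table.to_csv(args.outdir / f"ewas_{name}.tsv", sep="\t")
        top = select_top_cpgs(table, args.p_threshold, args.max_per_direction)
        top.to_csv(args.outdir / f"ewas_{name}_top.tsv", sep="\t")
        top_sets[name] = set(top.index)
        print(f"{name}: {len(top)} CpGs at p < {args.p_threshold} "
              f"({int((top['direction'] > 0).sum())} hyper, "
              f"{int((top['direction'] < 0).sum())} hypo)")

    overlap = set_overlap(top_sets)
    serializable = {"+".join(sorted(k)): v for k, v in overlap.items()}
    (args.outdir / "overlap_counts.json").write_text(json.dumps(serializable, indent=2))
    print(f"exclusive overlap counts: {serializable}")


if __name__ == "__main__":
    main()
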