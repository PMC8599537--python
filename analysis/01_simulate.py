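#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Produces two datasets under results/data/:

* ``two_species/`` — the default world: 60 marmoset blood samples
  (0.5-15.5 y, including an older treated/control test cohort) plus 40
  human-like samples spanning the same relative-age range, 2,000 CpGs.
* ``three_species/`` — the same world extended with 30 macaque-like
  samples (maxLifespan 40 y) used only as a held-out transfer target.

Each dataset ships with its sample sheet and the generator truth table.
"""

import argparse
from pathlib import Path

from methclock.io import Dataset, write_dataset
from methclock.simdata import SimConfig, SpeciesSpec, simulate_dataset

TWO_SPECIES = SimConfig()
THREE_SPECIES = SimConfig(
    species_specs=(
        SpeciesSpec("marmoset", 22.8, (0.5, 15.5), 50),
        SpeciesSpec("human", 122.5, (2.7, 83.3), 50),
        SpeciesSpec("macaque", 40.0, (1.0, 27.0), 30),
    ),
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    for name, cfg in [("two_species", TWO_SPECIES), ("three_species", THREE_SPECIES)]:
        betas, sheet, truth = simulate_dataset(cfg.with_seed(args.seed))
        out = args.outdir / name
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(Dataset(betas, sheet), out / "betas.tsv", out / "sample_sheet.csv")
        truth.to_csv(out / "truth.csv", index=False)
        n_test = (sheet["study"] == "test").sum()
        print(f"{name}: {betas.shape[0]} CpGs x {betas.shape[1]} samples "
              f"({n_test} in the treated/control test cohort) -> {out}")


if __name__ == "__main__":
    main()
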