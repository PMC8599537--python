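"""End-to-end orchestration: clock CV -> EWAS -> treatment test -> sex OOB.

``run_pipeline`` consumes a :class:`RunConfig`, runs every analysis stage
on one dataset, writes machine-readable tables under the output
directory, and finishes with a manifest (seed, input hashes, package
version) from which the whole run is reproducible.  A stage failure
aborts the run with the stage name; outputs already written are moved
under a ``failed/`` prefix.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import CVResult, loocv, kfold_cv, predict_age, train_clock
from .downstream import sex_predictor_oob, treatment_effect
from .errors import ConfigError, PipelineStageError
from .ewas import ewas_covariate, screen_numeric_trait, select_top_cpgs, stouffer_meta
from .io import Dataset, read_dataset, write_clock
from .transforms import AgeTransform


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    matrix_path: str
    sheet_path: str
    out_dir: str
    annotation_path: Optional[str] = None
    transform: str = "identity"
    max_lifespan_years: dict = field(default_factory=dict)
    adult_age_years: dict = field(default_factory=dict)
    alpha: float = 0.5
    folds: int = 10
    cv_scheme: str = "loocv"  # loocv | kfold
    seed: int = 0
    p_threshold: float = 0.005
    max_per_direction: int = 500
    treated_label: str = "rapamycin"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def build_transform(self) -> AgeTransform:
        kwargs = {}
        if self.max_lifespan_years:
            kwargs["max_lifespan_years"] = dict(self.max_lifespan_years)
        if self.adult_age_years:
            kwargs["adult_age_years"] = dict(self.adult_age_years)
        return AgeTransform(kind=self.transform, **kwargs)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _cv_to_files(cv: CVResult, out: Path, stem: str, seed: int) -> dict:
    cv.predictions.assign(seed=seed).to_csv(out / f"{stem}_predictions.csv", index=False)
    summary = {
        "scheme": cv.scheme,
        "r": cv.r,
        "mae_years": cv.mae,
        "n": cv.n,
        "per_stratum": cv.per_stratum,
        "seed": seed,
    }
    (out / f"{stem}_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one dataset; returns the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {}
    stage = "setup"
    try:
        stage = "read"
        ds = read_dataset(config.matrix_path, config.sheet_path, config.annotation_path)
        sheet = ds.sheet
        transform = config.build_transform()

        stage = "cv"
        if config.cv_scheme == "loocv":
            cv = loocv(ds.betas, sheet, transform, alpha=config.alpha, seed=config.seed)
        elif config.cv_scheme == "kfold":
            cv = kfold_cv(ds.betas, sheet, transform, k=config.folds,
                          alpha=config.alpha, seed=config.seed)
        else:
            raise ConfigError(f"unknown cv_scheme {config.cv_scheme!r}")
        report["cv"] = _cv_to_files(cv, out, "cv", config.seed)
        written += [out / "cv_predictions.csv", out / "cv_summary.json"]

        stage = "ewas_age"
        strata = sorted(sheet["species"].unique())
        z_cols, ns = {}, []
        for sp in strata:
            mask = (sheet["species"] == sp).to_numpy()
            if mask.sum() >= 4 and np.ptp(sheet.loc[mask, "age_years"]) > 0:
                tab = screen_numeric_trait(
                    ds.betas.loc[:, mask], sheet.loc[mask, "age_years"]
                )
                z_cols[sp] = tab["z"]
                ns.append(mask.sum())
        age_z = pd.DataFrame(z_cols)
        meta_z = stouffer_meta(age_z, weights=np.sqrt(ns))
        age_table = screen_numeric_trait(ds.betas, sheet["age_years"])
        age_table["meta_z"] = meta_z
        age_table.to_csv(out / "ewas_age.tsv", sep="\t")
        written.append(out / "ewas_age.tsv")
        top_age = select_top_cpgs(age_table, config.p_threshold, config.max_per_direction)
        top_age.to_csv(out / "ewas_age_top.tsv", sep="\t")
        written.append(out / "ewas_age_top.tsv")
        report["ewas_age"] = {
            "n_top": int(len(top_age)),
            "n_hyper": int((top_age["direction"] > 0).sum()),
            "n_hypo": int((top_age["direction"] < 0).sum()),
        }

        stage = "treatment"
        test_mask = sheet["treatment"].isin([config.treated_label, "control"])
        if test_mask.any():
            # the intervention clock is trained on untreated animals of the
            # test cohort's own species only
            test_species = sheet.loc[test_mask, "species"].unique()
            train_mask = ~test_mask & sheet["species"].isin(test_species)
            train_sheet = sheet.loc[train_mask]
            model = train_clock(
                ds.betas.loc[:, train_mask.to_numpy()],
                train_sheet["age_years"],
                transform,
                species=train_sheet["species"].tolist(),
                alpha=config.alpha,
                seed=config.seed,
            )
            write_clock(model, out / "clock_training_cohort.csv")
            written.append(out / "clock_training_cohort.csv")
            test_sheet = sheet.loc[test_mask]
            dnam = predict_age(
                model,
                ds.betas.loc[:, test_mask.to_numpy()],
                species=test_sheet["species"].tolist(),
            )
            dnam = pd.Series(dnam, index=test_sheet["sample_id"])
            dnam.rename("dnam_age_years").to_csv(out / "dnam_age_test.csv")
            written.append(out / "dnam_age_test.csv")
            rep = treatment_effect(
                dnam, sheet, training_sample_ids=train_sheet["sample_id"],
                treated_label=config.treated_label,
            )
            rep.terms.to_csv(out / "treatment_regression.tsv", sep="\t")
            written.append(out / "treatment_regression.tsv")
            report["treatment"] = {
                "r_squared": rep.r_squared,
                "n": rep.n,
                "treatment_estimate": float(rep.terms.loc["treatment", "estimate"]),
                "treatment_p": float(rep.terms.loc["treatment", "p"]),
            }

            stage = "ewas_treatment"
            grp = (test_sheet["treatment"] == config.treated_label).astype(int)
            trt_table = ewas_covariate(
                ds.betas.loc[:, test_mask.to_numpy()],
                grp,
                covariates=test_sheet[["age_years"]].reset_index(drop=True),
            )
            trt_table.to_csv(out / "ewas_treatment.tsv", sep="\t")
            written.append(out / "ewas_treatment.tsv")
            top_trt = select_top_cpgs(trt_table, config.p_threshold, config.max_per_direction)
            report["ewas_treatment"] = {
                "n_top": int(len(top_trt)),
                "n_hyper": int((top_trt["direction"] > 0).sum()),
                "n_hypo": int((top_trt["direction"] < 0).sum()),
            }

        stage = "sex"
        # treated animals excluded from sex analyses
        untreated = ~(sheet["treatment"] == config.treated_label)
        sex_sheet = sheet.loc[untreated]
        if sex_sheet["sex"].nunique() == 2 and untreated.sum() >= 20:
            oob = sex_predictor_oob(
                ds.betas.loc[:, untreated.to_numpy()],
                sex_sheet["sex"].tolist(),
                seed=config.seed,
            )
            sex_report = {
                "oob_accuracy": oob.oob_accuracy,
                "n_trees": oob.n_trees,
                "n": int(untreated.sum()),
                "seed": config.seed,
            }
            (out / "sex_oob.json").write_text(json.dumps(sex_report, indent=2))
            written.append(out / "sex_oob.json")
            report["sex_oob"] = sex_report

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "inputs": {
                "matrix": _sha256(config.matrix_path),
                "sheet": _sha256(config.sheet_path),
            },
        }
        if config.annotation_path:
            manifest["inputs"]["annotation"] = _sha256(config.annotation_path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        report["manifest"] = manifest
        return report
    except Exception as e:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for path in written:
            if path.exists():
                shutil.move(str(path), str(failed / path.name))
        raise PipelineStageError(stage, e) from e
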