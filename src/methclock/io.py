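"""On-disk formats: beta matrices, sample sheets, annotations, clock models.

Conventions (fixed, validated on read):

* beta matrix — TSV, CpG rows x sample columns, first column ``cpg_id``;
* sample sheet — CSV with header
  ``sample_id,age_years,sex,species,tissue,treatment[,study]``;
* probe annotation — TSV with columns
  ``chrom,pos,cpg_id,gene,tss_distance,region_class`` (1-based positions,
  signed TSS distance, negative = upstream);
* clock model — CSV with a commented ``# key=value`` header block
  (transform spec + training provenance) followed by rows
  ``cpg_id,weight,training_mean``; the first data row is the reserved id
  ``__intercept__``.

Betas outside [0, 1] by more than 1e-6 are rejected; tiny excursions are
clipped with a logged warning.  Matrix columns are harmonised to sample-
sheet order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .clock import INTERCEPT_ID, ClockModel
from .errors import FormatError, ValidationError
from .transforms import AgeTransform

logger = logging.getLogger("methclock")

BETA_TOLERANCE = 1e-6
SHEET_COLUMNS = ["sample_id", "age_years", "sex", "species", "tissue", "treatment"]
ANNOTATION_COLUMNS = ["chrom", "pos", "cpg_id", "gene", "tss_distance", "region_class"]


@dataclass
class Dataset:
    """A beta matrix joined to its sample sheet (and optional annotation)."""

    betas: pd.DataFrame
    sheet: pd.DataFrame
    annotation: Optional[pd.DataFrame] = None


def _validate_betas(betas: pd.DataFrame) -> pd.DataFrame:
    if betas.index.duplicated().any():
        dups = betas.index[betas.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate cpg_id values: {dups[:10]}")
    vals = betas.to_numpy(dtype=float)
    if np.nanmin(vals) < -BETA_TOLERANCE or np.nanmax(vals) > 1 + BETA_TOLERANCE:
        bad = vals[(vals < -BETA_TOLERANCE) | (vals > 1 + BETA_TOLERANCE)]
        raise ValidationError(
            f"{bad.size} beta values outside [0, 1] beyond tolerance "
            f"(e.g. {bad.flat[0]!r})"
        )
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        logger.warning("clipped beta values within %.0e of [0, 1] bounds", BETA_TOLERANCE)
        betas = betas.clip(0.0, 1.0)
    return betas


def read_dataset(matrix_path, sheet_path, annotation_path=None) -> Dataset:
    """Load and cross-validate a beta matrix + sample sheet (+ annotation)."""
    betas = pd.read_csv(matrix_path, sep="\t", index_col=0)
    betas.index.name = "cpg_id"
    sheet = pd.read_csv(sheet_path)
    missing_cols = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise FormatError(f"sample sheet missing columns: {missing_cols}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")

    matrix_samples = set(betas.columns)
    sheet_samples = set(sheet["sample_id"])
    if matrix_samples != sheet_samples:
        only_matrix = sorted(matrix_samples - sheet_samples)
        only_sheet = sorted(sheet_samples - matrix_samples)
        raise ValidationError(
            "matrix/sheet sample mismatch; only in matrix: "
            f"{only_matrix[:10]}, only in sheet: {only_sheet[:10]}"
        )
    betas = _validate_betas(betas[sheet["sample_id"].tolist()])

    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
        if missing_cols:
            raise FormatError(f"annotation missing columns: {missing_cols}")
        if annotation["cpg_id"].duplicated().any():
            raise ValidationError("duplicate cpg_id in annotation")
    return Dataset(betas=betas, sheet=sheet, annotation=annotation)


def write_dataset(dataset: Dataset, matrix_path, sheet_path, annotation_path=None) -> None:
    dataset.betas.to_csv(matrix_path, sep="\t")
    dataset.sheet.to_csv(sheet_path, index=False)
    if annotation_path is not None and dataset.annotation is not None:
        dataset.annotation.to_csv(annotation_path, sep="\t", index=False)


# -- clock model files ----------------------------------------------------

def write_clock(model: ClockModel, path) -> None:
    """Serialise a clock (header block + intercept row + weight rows)."""
    lines = []
    for key, value in model.transform.to_header_items():
        lines.append(f"# {key}={value}")
    for key, value in sorted(model.training_meta.items()):
        if key == "species":
            value = ",".join(value)
        lines.append(f"# meta.{key}={value}")
    lines.append("cpg_id,weight,training_mean")
    lines.append(f"{INTERCEPT_ID},{model.intercept!r},")
    for cpg in sorted(model.weights):
        lines.append(f"{cpg},{model.weights[cpg]!r},{model.training_means[cpg]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clock(path) -> ClockModel:
    """Parse a clock file; raises FormatError (with line number) on damage."""
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(text):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" not in body:
            raise FormatError(f"{path}:{i + 1}: malformed header line {line!r}")
        key, value = body.split("=", 1)
        if key.startswith("meta."):
            meta[key[5:]] = value
        else:
            header[key] = value
    if i >= len(text) or text[i].strip() != "cpg_id,weight,training_mean":
        raise FormatError(f"{path}:{i + 1}: expected column header after header block")
    try:
        transform = AgeTransform.from_header_items(header)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from e

    intercept = None
    weights: dict[str, float] = {}
    means: dict[str, float] = {}
    for lineno, line in enumerate(text[i + 1 :], start=i + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        cpg, weight, mean = parts
        try:
            if cpg == INTERCEPT_ID:
                intercept = float(weight)
            else:
                weights[cpg] = float(weight)
                means[cpg] = float(mean)
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: {e}") from e
    if intercept is None:
        raise FormatError(f"{path}: truncated model file (no {INTERCEPT_ID} row)")

    typed_meta: dict = {}
    for key, value in meta.items():
        if key == "species":
            typed_meta[key] = [s for s in value.split(",") if s]
        else:
            try:
                typed_meta[key] = int(value)
            except ValueError:
                try:
                    typed_meta[key] = float(value)
                except ValueError:
                    typed_meta[key] = value
    return ClockModel(
        intercept=intercept,
        weights=weights,
        transform=transform,
        training_means=means,
        training_meta=typed_meta,
    )
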