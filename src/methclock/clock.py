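"""Sparse elastic-net epigenetic clocks and their unbiased evaluation.

A clock is a penalized linear regression of transformed age on CpG beta
values.  The mixing fraction between L1 and L2 penalties is fixed at 0.5
(midpoint of ridge and lasso; it is not tuned), and the penalty strength
is chosen by tenfold internal cross-validation over a descending
log-spaced path, taking the penalty that minimises internal-CV MSE with
ties broken toward the sparser (larger-penalty) model.

Predictors are standardised internally before penalization; stored
weights are reported back on the original beta scale.  Evaluation uses
leave-one-out or stratified k-fold cross-validation, re-selecting the
penalty inside every outer fold so that no held-out sample influences
the model that predicts it.  Accuracy is summarised the way this
literature does: Pearson correlation R between DNAm age and
chronological age, and the median absolute error (MAE) in years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import ComputationError, ConfigError, DomainError, ValidationError
from .transforms import AgeTransform

INTERCEPT_ID = "__intercept__"

#: number of penalty values on the internal cross-validation path
N_PENALTIES = 60
#: hard cap on the fraction of model CpGs that may be mean-imputed
MAX_MISSING_FRACTION = 0.2


@dataclass
class ClockModel:
    """A fitted clock: intercept + sparse CpG weights on the beta scale."""

    intercept: float
    weights: dict[str, float]
    transform: AgeTransform
    training_means: dict[str, float]
    training_meta: dict = field(default_factory=dict)
    fitted_years: Optional[pd.Series] = None  # in-memory only, not serialized

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.weights)

    def linear_score(self, betas: pd.DataFrame) -> np.ndarray:
        """Regression-scale score per sample, mean-imputing missing CpGs."""
        cpgs = self.cpg_ids
        if not cpgs:
            return np.full(betas.shape[1], self.intercept)
        missing = [c for c in cpgs if c not in betas.index]
        if len(missing) > MAX_MISSING_FRACTION * len(cpgs):
            raise ValidationError(
                f"{len(missing)}/{len(cpgs)} model CpGs absent from the input "
                f"matrix (> {MAX_MISSING_FRACTION:.0%}); refusing to extrapolate"
            )
        X = np.empty((betas.shape[1], len(cpgs)))
        for j, c in enumerate(cpgs):
            if c in betas.index:
                X[:, j] = betas.loc[c].to_numpy(dtype=float)
            else:
                X[:, j] = self.training_means[c]
        w = np.array([self.weights[c] for c in cpgs])
        return self.intercept + X @ w


@dataclass
class CVResult:
    """Cross-validated predictions with overall and per-stratum accuracy."""

    predictions: pd.DataFrame  # sample_id, true_age_years, predicted_age_years, fold
    r: float
    mae: float
    n: int
    per_stratum: dict[str, dict] = field(default_factory=dict)
    scheme: str = ""
    seed: Optional[int] = None


def performance(true_age_years, pred_age_years):
    """(Pearson R, median absolute error in years, n)."""
    true = np.asarray(true_age_years, dtype=float)
    pred = np.asarray(pred_age_years, dtype=float)
    if true.shape != pred.shape:
        raise ValidationError("true and predicted age vectors differ in length")
    if true.size < 3:
        raise ValidationError("need at least 3 samples to assess performance")
    if np.ptp(true) == 0:
        raise ComputationError("correlation undefined for constant true ages")
    r = float(stats.pearsonr(true, pred).statistic) if np.ptp(pred) > 0 else 0.0
    mae = float(np.median(np.abs(pred - true)))
    return r, mae, int(true.size)


def _fit_elastic_net(X: np.ndarray, y: np.ndarray, alpha: float,
                     n_internal_folds: int, seed: int):
    """Standardise, fit ElasticNetCV along a descending penalty path, and
    return (intercept, coefficients) on the ORIGINAL predictor scale.

    glmnet's mixing parameter alpha maps to scikit-learn's l1_ratio; both
    parameterise the penalty as lam * (alpha*|w|_1 + (1-alpha)/2*|w|_2^2).
    The path is scanned largest-penalty first, so the first minimiser of
    mean internal-CV MSE is the sparsest among exact ties.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return float(y.mean()), np.zeros(X.shape[1])
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    cv = KFold(n_splits=n_internal_folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=alpha,
        alphas=N_PENALTIES,
        cv=cv,
        max_iter=2000,
        tol=1e-4,
        selection="cyclic",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(Z, y)
    coef = np.zeros(X.shape[1])
    coef[keep] = enet.coef_ / sd[keep]
    intercept = float(enet.intercept_ - np.sum(enet.coef_ * mu[keep] / sd[keep]))
    return intercept, coef


def train_clock(betas: pd.DataFrame, ages, transform: AgeTransform,
                species=None, alpha: float = 0.5,
                n_internal_folds: int = 10, seed: int = 0) -> ClockModel:
    """Fit a sparse elastic-net clock on a CpG-by-sample beta matrix.

    Parameters
    ----------
    betas : DataFrame, CpG rows x sample columns.
    ages : chronological ages in years, one per sample column.
    transform : the age transform defining the regression scale.
    species : per-sample species labels; required by species-aware transforms.
    alpha : L1 mixing fraction of the elastic net (0.5 by convention).
    n_internal_folds : folds of the internal penalty-selection CV.
    """
    ages = np.asarray(ages, dtype=float)
    n = betas.shape[1]
    if ages.size != n:
        raise ValidationError("ages length does not match number of samples")
    if n < n_internal_folds:
        raise ValidationError(
            f"need at least {n_internal_folds} samples for "
            f"{n_internal_folds}-fold internal CV (got {n})"
        )
    if np.ptp(ages) == 0:
        raise ComputationError("degenerate response: all ages identical")
    if not (0 < alpha <= 1):
        raise ConfigError("alpha must lie in (0, 1]")

    species_list = list(species) if species is not None else None
    y = np.asarray(transform.forward(ages, species_list), dtype=float)
    X = betas.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValidationError("beta matrix contains missing values; impute first")

    intercept, coef = _fit_elastic_net(X, y, alpha, n_internal_folds, seed)
    nz = np.flatnonzero(coef)
    cpg_index = betas.index.to_numpy()
    weights = {str(cpg_index[j]): float(coef[j]) for j in nz}
    means = X.mean(axis=0)
    training_means = {str(cpg_index[j]): float(means[j]) for j in nz}

    model = ClockModel(
        intercept=intercept,
        weights=weights,
        transform=transform,
        training_means=training_means,
        training_meta={
            "n_samples": int(n),
            "n_cpgs_input": int(betas.shape[0]),
            "alpha": float(alpha),
            "n_internal_folds": int(n_internal_folds),
            "seed": int(seed),
            "species": sorted(set(species_list)) if species_list else [],
        },
    )
    fitted = predict_age(model, betas, species=species_list)
    model.fitted_years = pd.Series(fitted, index=betas.columns)
    return model


def predict_age(model: ClockModel, betas: pd.DataFrame, species=None) -> np.ndarray:
    """DNAm age in years for each sample column of ``betas``."""
    score = model.linear_score(betas)
    species_list = list(species) if species is not None else None
    return np.asarray(model.transform.inverse(score, species_list), dtype=float)


def _collect_cv(preds: pd.DataFrame, sheet: pd.DataFrame, scheme: str,
                seed: Optional[int], stratify_by: str = "species") -> CVResult:
    r, mae, n = performance(preds["true_age_years"], preds["predicted_age_years"])
    per_stratum: dict[str, dict] = {}
    if stratify_by in sheet.columns:
        strata = sheet.set_index("sample_id").loc[preds["sample_id"], stratify_by]
        for name, grp in preds.groupby(strata.to_numpy()):
            if len(grp) >= 3 and np.ptp(grp["true_age_years"]) > 0:
                sr, smae, sn = performance(grp["true_age_years"], grp["predicted_age_years"])
                per_stratum[str(name)] = {"r": sr, "mae": smae, "n": sn}
    return CVResult(predictions=preds, r=r, mae=mae, n=n,
                    per_stratum=per_stratum, scheme=scheme, seed=seed)


def loocv(betas: pd.DataFrame, sheet: pd.DataFrame, transform: AgeTransform,
          alpha: float = 0.5, n_internal_folds: int = 10, seed: int = 0,
          stratify_by: str = "species") -> CVResult:
    """Leave-one-out cross-validation: each sample is predicted by a clock
    refit from scratch (including penalty re-selection) on the others."""
    n = betas.shape[1]
    if n < 12:
        raise ValidationError("LOOCV needs at least 12 samples")
    sheet = sheet.reset_index(drop=True)
    ages = sheet["age_years"].to_numpy(dtype=float)
    species = sheet["species"].tolist() if "species" in sheet.columns else None
    rows = []
    for i in range(n):
        rest = np.arange(n) != i
        sp_rest = [s for j, s in enumerate(species) if j != i] if species else None
        model = train_clock(
            betas.iloc[:, rest], ages[rest], transform,
            species=sp_rest, alpha=alpha,
            n_internal_folds=n_internal_folds, seed=seed,
        )
        sp_i = [species[i]] if species else None
        pred = predict_age(model, betas.iloc[:, [i]], species=sp_i)[0]
        rows.append(
            {
                "sample_id": sheet["sample_id"].iloc[i],
                "true_age_years": ages[i],
                "predicted_age_years": float(pred),
                "fold": i,
            }
        )
    preds = pd.DataFrame(rows)
    return _collect_cv(preds, sheet, "loocv", seed, stratify_by)


def _stratified_folds(sheet: pd.DataFrame, k: int, stratify_by: str,
                      rng: np.random.Generator) -> np.ndarray:
    """Deal samples round-robin into k folds within each stratum so every
    training fold sees every stratum; falls back to unstratified when a
    stratum is smaller than k."""
    n = len(sheet)
    folds = np.empty(n, dtype=int)
    if stratify_by in sheet.columns:
        sizes = sheet[stratify_by].value_counts()
        if (sizes < k).any():
            small = sizes[sizes < k].index.tolist()
            warnings.warn(
                f"strata {small} have fewer than {k} samples; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
        else:
            for _, idx in sheet.groupby(stratify_by).groups.items():
                idx = np.asarray(list(idx))
                order = rng.permutation(len(idx))
                folds[idx[order]] = np.arange(len(idx)) % k
            return folds
    order = rng.permutation(n)
    folds[order] = np.arange(n) % k
    return folds


def kfold_cv(betas: pd.DataFrame, sheet: pd.DataFrame, transform: AgeTransform,
             k: int = 10, stratify_by: str = "species", alpha: float = 0.5,
             n_internal_folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation (default: stratify by species so a
    dual-species clock sees both species in every training fold)."""
    n = betas.shape[1]
    if k < 2:
        raise ValidationError("k must be at least 2")
    if n < k:
        raise ValidationError(f"cannot make {k} folds from {n} samples")
    sheet = sheet.reset_index(drop=True)
    ages = sheet["age_years"].to_numpy(dtype=float)
    species = sheet["species"].tolist() if "species" in sheet.columns else None
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(sheet, k, stratify_by, rng)

    rows = []
    for f in range(k):
        train = folds != f
        test = ~train
        sp_train = [s for s, t in zip(species, train) if t] if species else None
        model = train_clock(
            betas.loc[:, train], ages[train], transform,
            species=sp_train, alpha=alpha,
            n_internal_folds=n_internal_folds, seed=seed,
        )
        sp_test = [s for s, t in zip(species, test) if t] if species else None
        preds = predict_age(model, betas.loc[:, test], species=sp_test)
        for sid, ta, pa in zip(sheet.loc[test, "sample_id"], ages[test], preds):
            rows.append(
                {
                    "sample_id": sid,
                    "true_age_years": float(ta),
                    "predicted_age_years": float(pa),
                    "fold": f,
                }
            )
    preds = pd.DataFrame(rows)
    # report in sheet order so results do not depend on fold layout
    preds = preds.set_index("sample_id").loc[sheet["sample_id"]].reset_index()
    return _collect_cv(preds, sheet, f"{k}-fold", seed, stratify_by)
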