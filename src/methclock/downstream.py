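"""Analyses downstream of the clock: intervention and sex effects.

``treatment_effect`` fits the multivariate model

    DNAmAge ~ intercept + Age + Female + Treatment

by ordinary least squares on test-cohort animals, with a mandatory check
that no test sample was seen during clock training (DNAm age must come
from a clock trained on disjoint animals, otherwise the treatment term
is biased toward zero residual).  ``age_acceleration`` returns residuals
of DNAmAge regressed on chronological age — positive means epigenetically
older than expected.  ``sex_predictor_oob`` measures how well methylation
predicts sex using a random forest evaluated out-of-bag; in blood from a
hematopoietic chimera this accuracy is expected to be barely above
chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .errors import ComputationError, LeakageError, ValidationError


@dataclass
class RegressionReport:
    """Per-term OLS estimates in the layout of an intervention table."""

    terms: pd.DataFrame  # index term; columns estimate, std_error, t, p
    r_squared: float
    n: int


@dataclass
class SexOobReport:
    """Out-of-bag accuracy of the random-forest sex predictor."""

    oob_accuracy: float
    votes: pd.Series  # per-sample OOB fraction of trees voting 'F'
    predicted: pd.Series
    n_trees: int
    seed: int


def _ols_report(y: np.ndarray, X: pd.DataFrame) -> RegressionReport:
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    terms.index = ["intercept" if t == "const" else t for t in terms.index]
    return RegressionReport(terms=terms, r_squared=float(fit.rsquared), n=int(len(y)))


def treatment_effect(dnam_age_years: pd.Series, sheet: pd.DataFrame,
                     training_sample_ids: Optional[Sequence[str]] = None,
                     treatment_col: str = "treatment",
                     treated_label: str = "rapamycin") -> RegressionReport:
    """OLS of DNAmAge on [Age, Female, Treatment] over the test cohort.

    ``dnam_age_years`` is indexed by sample_id and must cover exactly the
    samples to test; ``sheet`` supplies age, sex and treatment arm.
    ``training_sample_ids``, when given, triggers the leakage check.
    """
    sheet = sheet.set_index("sample_id").loc[dnam_age_years.index]
    if training_sample_ids is not None:
        overlap = sorted(set(sheet.index) & set(training_sample_ids))
        if overlap:
            raise LeakageError(
                f"test samples also present in clock training: {overlap[:10]}"
            )
    arms = sheet[treatment_col]
    treated = (arms == treated_label).astype(float)
    if treated.nunique() < 2:
        raise ValidationError("both treatment arms must be present")
    X = pd.DataFrame(
        {
            "age": sheet["age_years"].astype(float),
            "female": (sheet["sex"] == "F").astype(float),
            "treatment": treated,
        },
        index=sheet.index,
    )
    if len(X) < X.shape[1] + 1 + 3:
        raise ValidationError("need at least 3 more samples than model terms")
    return _ols_report(dnam_age_years.to_numpy(dtype=float), X)


def age_acceleration(dnam_age_years, age_years) -> np.ndarray:
    """Residuals of DNAmAge regressed on chronological age (mean zero)."""
    y = np.asarray(dnam_age_years, dtype=float)
    a = np.asarray(age_years, dtype=float)
    if y.size != a.size:
        raise ValidationError("DNAmAge and age vectors differ in length")
    if y.size < 3:
        raise ValidationError("need at least 3 samples")
    if np.ptp(a) == 0:
        raise ComputationError("constant age: acceleration undefined")
    X = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def sex_predictor_oob(betas: pd.DataFrame, sex: Sequence[str],
                      n_trees: int = 500, seed: int = 0) -> SexOobReport:
    """Random-forest sex prediction scored out-of-bag.

    Each sample is classified by the majority vote of the trees for which
    it was out-of-bag; accuracy is the fraction of correct votes.
    Defaults: 500 trees, sqrt(p) features per split, unlimited depth.
    """
    labels = pd.Series(sex, index=betas.columns, name="sex")
    if labels.nunique() < 2:
        raise ValidationError("both sexes must be present")
    X = betas.to_numpy(dtype=float).T
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, labels.to_numpy())
    proba = rf.oob_decision_function_
    classes = rf.classes_
    pred = pd.Series(classes[np.nanargmax(proba, axis=1)], index=betas.columns)
    f_col = int(np.where(classes == "F")[0][0]) if "F" in classes else 0
    votes = pd.Series(proba[:, f_col], index=betas.columns, name="oob_vote_F")
    acc = float((pred.to_numpy() == labels.to_numpy()).mean())
    return SexOobReport(
        oob_accuracy=acc, votes=votes, predicted=pred, n_trees=n_trees, seed=seed
    )
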