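"""Epigenome-wide association screening and meta-analysis.

Two per-CpG tests are provided: a Pearson-correlation screen against a
numeric trait (the standard screen for age), and an OLS group contrast
with numeric covariates (treatment vs control adjusting for age; sex
contrast adjusting for age).  Both report the statistic, a two-sided p
from the exact Student-t reference, and a standard-normal-scale score
z = sign(statistic) * Phi^{-1}(1 - p/2) so that results from different
strata can be combined with Stouffer's method,

    Z = sum_i w_i z_i / sqrt(sum_i w_i^2),

with weights defaulting to sqrt(n_i) per stratum.

Downstream helpers implement the directional top-CpG selection rule
(strict p < threshold, at most a cap per direction ranked by |z|),
genic-region distribution with hypergeometric enrichment, and exclusive
(upset-style) intersection counts between CpG sets.

No genome-wide multiple-testing correction is applied by default; a
Bonferroni column is emitted for reference.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError

REGION_CLASSES = (
    "promoter", "5'UTR", "exon", "intron", "3'UTR", "downstream", "intergenic",
)

_P_FLOOR = np.nextafter(0, 1)


def _z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed standard-normal score equivalent to a two-sided p-value."""
    return sign * stats.norm.isf(np.clip(p, _P_FLOOR, 1.0) / 2.0)


def _finish_table(cpg_ids, statistic, t, df, flagged) -> pd.DataFrame:
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _P_FLOOR, 1.0)
    p[flagged] = 1.0
    sign = np.sign(statistic)
    sign[flagged] = 0.0
    z = _z_from_p(p, np.where(sign == 0, 1.0, sign))
    z[flagged] = 0.0
    table = pd.DataFrame(
        {
            "statistic": statistic,
            "z": z,
            "p": p,
            "p_bonferroni": np.clip(p * len(p), 0.0, 1.0),
            "direction": sign.astype(int),
            "flagged": flagged,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    return table


def screen_numeric_trait(betas: pd.DataFrame, trait) -> pd.DataFrame:
    """Per-CpG Pearson correlation screen against a numeric trait.

    For each CpG: r, t = r*sqrt(n-2)/sqrt(1-r^2), two-sided p from the
    t(n-2) reference, and the signed z equivalent.  CpGs with zero
    variance are flagged (p = 1, z = 0).
    """
    y = np.asarray(trait, dtype=float)
    n = betas.shape[1]
    if y.size != n:
        raise ValidationError("trait length does not match sample count")
    if n < 4:
        raise ValidationError("need at least 4 samples for the screen")
    if np.ptp(y) == 0:
        raise ComputationError("trait is constant; correlation undefined")

    X = betas.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    flagged = sx < 1e-10  # constant probe (allow centering float dust)
    denom = np.where(flagged, 1.0, sx * sy)
    r = (Xc @ yc) / denom
    r[flagged] = 0.0
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(np.maximum(1.0 - r**2, 0.0))
    return _finish_table(betas.index, r, t, df, flagged)


def ewas_covariate(betas: pd.DataFrame, group, covariates: Optional[pd.DataFrame] = None
                   ) -> pd.DataFrame:
    """Per-CpG OLS of beta on [intercept, group, covariates].

    ``group`` is a binary indicator (treated/female = 1).  The reported
    statistic is the group coefficient; p and z follow the exact t
    reference at n - k degrees of freedom.
    """
    g = np.asarray(group, dtype=float)
    n = betas.shape[1]
    if g.size != n:
        raise ValidationError("group length does not match sample count")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError("group must take exactly two values")
    g = (g == levels.max()).astype(float)

    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        if len(cov) != n:
            raise ValidationError("covariate rows do not match sample count")
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    k = X.shape[1]
    if n < k + 1:
        raise ValidationError("too few samples for the design")
    if np.linalg.matrix_rank(X) < k:
        bad = [
            names[j]
            for j in range(1, k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")

    Y = betas.to_numpy(dtype=float).T  # n x p
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # k x p
    resid = Y - X @ B
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    flagged = betas.to_numpy(dtype=float).std(axis=1) < 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1] / np.where(se == 0, 1.0, se), 0.0)
    return _finish_table(betas.index, B[1].copy(), t, df, flagged | (se == 0))


def stouffer_meta(z_by_stratum: pd.DataFrame, weights: Optional[Sequence[float]] = None
                  ) -> pd.Series:
    """Combine per-stratum z-scores: Z = sum(w z) / sqrt(sum w^2).

    ``z_by_stratum`` is CpG x strata.  Weights default to equal; pass
    sqrt(n_i) per stratum for the sample-size-weighted convention.  A CpG
    missing a stratum's z drops that stratum with weight renormalisation.
    """
    Z = pd.DataFrame(z_by_stratum)
    if Z.shape[1] < 1:
        raise ValidationError("need at least one stratum")
    if weights is None:
        w = np.ones(Z.shape[1])
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != Z.shape[1]:
            raise ValidationError("one weight per stratum is required")
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
    vals = Z.to_numpy(dtype=float)
    valid = ~np.isnan(vals)  # dropped strata renormalise per CpG
    num = np.nansum(vals * w[None, :], axis=1)
    denom = np.sqrt((valid * w[None, :] ** 2).sum(axis=1))
    out = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), np.nan)
    return pd.Series(out, index=Z.index, name="meta_z")


def select_top_cpgs(table: pd.DataFrame, p_threshold: float = 0.005,
                    max_per_direction: int = 500, z_col: str = "z",
                    p_col: str = "p") -> pd.DataFrame:
    """Directional top-CpG selection: strict p < threshold, then at most
    ``max_per_direction`` per sign of z ranked by |z| descending (ties
    broken by cpg_id).  Output order is deterministic and independent of
    the input row order."""
    hits = table[table[p_col] < p_threshold].copy()
    if "direction" not in hits.columns:
        hits["direction"] = np.sign(hits[z_col]).astype(int)
    hits["_absz"] = hits[z_col].abs()
    parts = []
    for d in (1, -1):
        sub = hits[hits["direction"] == d]
        # cpg_id ascending first, then a stable sort by |z| descending,
        # so exact |z| ties resolve lexicographically
        sub = sub.sort_index().sort_values("_absz", ascending=False, kind="mergesort")
        parts.append(sub.head(max_per_direction))
    return pd.concat(parts).drop(columns="_absz")


def region_distribution(cpg_set: Sequence[str], annotation: pd.DataFrame,
                        background: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Genic-region distribution of a CpG set against a background.

    ``annotation`` must be indexed by (or contain) cpg_id with a
    ``region_class`` column.  Returns per-class foreground/background
    counts and proportions plus hypergeometric tail p-values
    (``p_enrichment`` = P(X >= k), ``p_depletion`` = P(X <= k))."""
    ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
    cpg_set = list(dict.fromkeys(cpg_set))
    missing = [c for c in cpg_set if c not in ann.index]
    if missing:
        raise ValidationError(f"unannotated CpGs in set: {missing[:10]}")
    bg = list(ann.index) if background is None else list(dict.fromkeys(background))
    N = len(bg)
    n = len(cpg_set)
    fg_classes = ann.loc[cpg_set, "region_class"]
    bg_classes = ann.loc[bg, "region_class"]
    rows = []
    for cls in REGION_CLASSES:
        k = int((fg_classes == cls).sum())
        K = int((bg_classes == cls).sum())
        row = {
            "region_class": cls,
            "foreground_count": k,
            "foreground_prop": k / n if n else 0.0,
            "background_count": K,
            "background_prop": K / N if N else 0.0,
        }
        if n:
            row["p_enrichment"] = float(stats.hypergeom.sf(k - 1, N, K, n))
            row["p_depletion"] = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append(row)
    return pd.DataFrame(rows).set_index("region_class")


def set_overlap(named_sets: Mapping[str, Sequence[str]]) -> dict[frozenset, int]:
    """Exclusive (upset-style) intersection counts for >= 2 named sets.

    Returns {frozenset of set names -> number of elements belonging to
    exactly those sets}; counts sum to the size of the union."""
    if len(named_sets) < 2:
        raise ValidationError("need at least two sets")
    sets = {name: set(v) for name, v in named_sets.items()}
    union = set().union(*sets.values())
    counts: dict[frozenset, int] = {}
    for el in union:
        key = frozenset(name for name, s in sets.items() if el in s)
        counts[key] = counts.get(key, 0) + 1
    return counts
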