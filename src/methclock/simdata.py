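"""Synthetic methylation-array data with known truth.

The generator emulates the statistical structure a conserved-CpG
methylation-array aging study assumes, at desk scale:

* a primary short-lived species (marmoset-like, maxLifespan 22.8 y,
  blood samples aged 0.5-15.5 y) and optionally further species sharing
  the SAME aging signal on the relative-age scale (human-like,
  maxLifespan 122.5 y);
* age-role CpGs whose mean beta moves linearly in relative age
  (clipped to [0.01, 0.99]), with a hypermethylation-biased direction mix;
* weak sex-offset CpGs (blood chimerism makes sex signals faint),
  treatment-offset CpGs whose default amplitude is zero (a null
  intervention), and null CpGs;
* Beta-distributed array noise parameterised by (mean, precision), which
  respects the [0, 1] support of beta values;
* a cohort split of the first species into a training cohort spanning
  the full age range and an older test cohort carrying the
  treated/control arms (the treated animals are middle-aged).

Everything is deterministic given (config, seed), and every dataset
ships with a truth table recording each CpG's role, direction,
amplitude and baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

CLIP_LO = 0.01
CLIP_HI = 0.99

#: probability that an age CpG gains methylation with age (promoter-style
#: hypermethylation dominates in blood aging)
HYPERMETHYLATION_FRACTION = 0.7


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated species: name, longevity and sampled age range."""

    name: str
    max_lifespan_years: float
    age_range_years: tuple[float, float]
    n_samples: int

    def __post_init__(self):
        if self.max_lifespan_years <= 0:
            raise ConfigError(f"{self.name}: max lifespan must be positive")
        lo, hi = self.age_range_years
        if not (0 <= lo < hi):
            raise ConfigError(f"{self.name}: age range must satisfy 0 <= lo < hi")
        if self.n_samples < 0:
            raise ConfigError(f"{self.name}: n_samples must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated world.

    Defaults are the scaled-down study design: 2,000 CpGs; 60 marmoset-like
    blood samples aged 0.5-15.5 y plus 40 human-like samples covering the
    same relative-age span; 20 age CpGs of amplitude 0.4 at noise precision
    100; weak sex CpGs; a nominally null treatment.
    """

    n_cpgs: int = 2000
    species_specs: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("marmoset", 22.8, (0.5, 15.5), 60),
        SpeciesSpec("human", 122.5, (2.7, 83.3), 40),
    )
    n_age_cpgs: int = 20
    n_sex_cpgs: int = 10
    n_treatment_cpgs: int = 10
    age_effect_size: float = 0.4
    sex_effect_size: float = 0.05
    treatment_effect_size: float = 0.0
    noise_precision: float = 100.0
    treated_fraction: float = 0.46
    test_fraction: float = 0.4
    test_age_range_years: tuple[float, float] = (5.5, 13.5)
    tissue: str = "blood"
    seed: int = 0

    def __post_init__(self):
        if self.n_cpgs <= 0:
            raise ConfigError("n_cpgs must be positive")
        if not self.species_specs or sum(s.n_samples for s in self.species_specs) <= 0:
            raise ConfigError("at least one species with samples is required")
        if self.n_age_cpgs + self.n_sex_cpgs + self.n_treatment_cpgs > self.n_cpgs:
            raise ConfigError("signal CpGs exceed n_cpgs")
        for name, amp in (
            ("age_effect_size", self.age_effect_size),
            ("sex_effect_size", self.sex_effect_size),
            ("treatment_effect_size", self.treatment_effect_size),
        ):
            if not (0 <= amp <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_precision <= 0:
            raise ConfigError("noise_precision must be positive")
        if not (0 <= self.treated_fraction <= 1):
            raise ConfigError("treated_fraction must lie in [0, 1]")
        if not (0 <= self.test_fraction <= 1):
            raise ConfigError("test_fraction must lie in [0, 1]")

    @property
    def lifespans(self) -> dict[str, float]:
        return {s.name: s.max_lifespan_years for s in self.species_specs}

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def single_species_config(**overrides) -> SimConfig:
    """The marmoset-only default world (60 blood samples)."""
    base = SimConfig(
        species_specs=(SpeciesSpec("marmoset", 22.8, (0.5, 15.5), 60),)
    )
    return replace(base, **overrides) if overrides else base


def trajectory_mean(relative_age, role_params, sex="F", treated=False):
    """Noise-free mean beta for one CpG at a given relative age.

    ``role_params`` is a truth-table row (mapping with ``role``,
    ``baseline``, ``direction``, ``amplitude``).  Age CpGs move linearly in
    relative age; sex/treatment CpGs are constant offsets applied to
    females / treated animals; null CpGs sit at their baseline.  The
    result is clipped to [0.01, 0.99] so Beta noise parameters stay finite.
    """
    rel = np.asarray(relative_age, dtype=float)
    if np.any(rel < 0) or np.any(rel > 1):
        raise DomainError("relative_age must lie in [0, 1]")
    role = role_params["role"]
    baseline = float(role_params["baseline"])
    direction = float(role_params["direction"])
    amplitude = float(role_params["amplitude"])
    mean = np.full_like(rel, baseline, dtype=float)
    if role == "age":
        mean = baseline + direction * amplitude * rel
    elif role == "sex":
        female = np.asarray(sex) == "F"
        mean = baseline + direction * amplitude * female
    elif role == "treatment":
        mean = baseline + direction * amplitude * np.asarray(treated, dtype=float)
    elif role != "null":
        raise ConfigError(f"unknown CpG role {role!r}")
    out = np.clip(mean, CLIP_LO, CLIP_HI)
    return float(out) if np.isscalar(relative_age) else out


def sample_beta(mean, precision, rng):
    """Draw array-style beta values from Beta(mean*prec, (1-mean)*prec).

    The expectation equals ``mean``; variance is mean(1-mean)/(precision+1),
    so precision -> infinity recovers the noise-free trajectory.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0) or np.any(mean >= 1):
        raise DomainError("mean must lie strictly inside (0, 1)")
    if precision <= 0:
        raise DomainError("precision must be positive")
    return rng.beta(mean * precision, (1.0 - mean) * precision)


def _make_truth_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = max(5, len(str(config.n_cpgs)))
    cpg_ids = np.array([f"cpg{i + 1:0{width}d}" for i in range(config.n_cpgs)])
    roles = np.array(["null"] * config.n_cpgs, dtype=object)
    n_a, n_s, n_t = config.n_age_cpgs, config.n_sex_cpgs, config.n_treatment_cpgs
    roles[:n_a] = "age"
    roles[n_a : n_a + n_s] = "sex"
    roles[n_a + n_s : n_a + n_s + n_t] = "treatment"

    directions = np.where(rng.random(config.n_cpgs) < 0.5, 1, -1)
    # age CpGs skew toward gain of methylation with age
    directions[:n_a] = np.where(
        rng.random(n_a) < HYPERMETHYLATION_FRACTION, 1, -1
    )

    amplitudes = np.zeros(config.n_cpgs)
    amplitudes[:n_a] = config.age_effect_size
    amplitudes[n_a : n_a + n_s] = config.sex_effect_size
    amplitudes[n_a + n_s : n_a + n_s + n_t] = config.treatment_effect_size

    # baselines leave headroom for the full signal excursion on either side
    lo = 0.05 + np.where(directions < 0, amplitudes, 0.0)
    hi = 0.95 - np.where(directions > 0, amplitudes, 0.0)
    baselines = rng.uniform(lo, hi)

    return pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "role": roles,
            "direction": directions,
            "amplitude": amplitudes,
            "baseline": baselines,
        }
    )


def _make_sample_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counter = 0
    for si, spec in enumerate(config.species_specs):
        n = spec.n_samples
        sexes = np.array(["F", "M"] * ((n + 1) // 2))[:n]
        rng.shuffle(sexes)
        if si == 0 and config.test_fraction > 0:
            n_test = int(round(n * config.test_fraction))
        else:
            n_test = 0
        n_train = n - n_test
        lo, hi = spec.age_range_years
        ages = np.concatenate(
            [
                rng.uniform(lo, hi, size=n_train),
                rng.uniform(*config.test_age_range_years, size=n_test),
            ]
        )
        study = np.array(["training"] * n_train + ["test"] * n_test, dtype=object)
        treatment = np.array(["none"] * n, dtype=object)
        if n_test:
            n_treated = int(round(n_test * config.treated_fraction))
            test_idx = np.arange(n_train, n)
            treated_idx = rng.permutation(test_idx)[:n_treated]
            treatment[n_train:] = "control"
            treatment[treated_idx] = "rapamycin"
        for j in range(n):
            counter += 1
            rows.append(
                {
                    "sample_id": f"s{counter:04d}",
                    "age_years": ages[j],
                    "sex": sexes[j],
                    "species": spec.name,
                    "tissue": config.tissue,
                    "treatment": treatment[j],
                    "study": study[j],
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig):
    """Generate (beta matrix, sample sheet, truth table) for a config.

    Returns
    -------
    betas : DataFrame, CpG rows x sample columns, values in [0, 1]
    sheet : DataFrame, one row per sample (age, sex, species, tissue,
        treatment arm, training/test cohort)
    truth : DataFrame, one row per CpG (role, direction, amplitude, baseline)
    """
    rng = np.random.default_rng(config.seed)
    truth = _make_truth_table(config, rng)
    sheet = _make_sample_sheet(config, rng)

    lifespans = sheet["species"].map(config.lifespans).to_numpy(dtype=float)
    rel_age = np.minimum(sheet["age_years"].to_numpy() / lifespans, 1.0)
    female = (sheet["sex"] == "F").to_numpy()
    treated = (sheet["treatment"] == "rapamycin").to_numpy()

    baseline = truth["baseline"].to_numpy()[:, None]
    direction = truth["direction"].to_numpy(dtype=float)[:, None]
    amplitude = truth["amplitude"].to_numpy()[:, None]
    role = truth["role"].to_numpy()

    means = np.broadcast_to(baseline, (config.n_cpgs, len(sheet))).copy()
    is_age = role == "age"
    is_sex = role == "sex"
    is_trt = role == "treatment"
    means[is_age] += (direction * amplitude)[is_age] * rel_age[None, :]
    means[is_sex] += (direction * amplitude)[is_sex] * female[None, :]
    means[is_trt] += (direction * amplitude)[is_trt] * treated[None, :]
    means = np.clip(means, CLIP_LO, CLIP_HI)

    values = sample_beta(means, config.noise_precision, rng)
    betas = pd.DataFrame(values, index=truth["cpg_id"].to_numpy(), columns=sheet["sample_id"])
    betas.index.name = "cpg_id"
    betas.columns.name = None
    return betas, sheet, truth
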