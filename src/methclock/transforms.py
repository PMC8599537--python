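"""Invertible maps between chronological age and the clock regression scale.

Three transforms are supported:

``identity``
    Regress directly on age in years (single-species clocks).
``loglinear``
    Piecewise map, logarithmic before an "adult age" knot and linear
    after it, continuous with matching slope at the knot, so that one
    regression covers both rapid development and slow adult aging:

        F(a) = log((a + c) / (m + c))   for a <= m
        F(a) = (a - m) / (m + c)        for a >  m

    with adult age ``m`` and offset ``c`` (both in years).  The knot may
    be per-species (a mapping) for single-species clocks, or one shared
    scalar — the "single formula" construction used for dual-species
    chronological clocks, which needs no species label at prediction
    time and can therefore be applied unchanged to a new species.
``relative``
    Relative age = age / maxLifespan, which places species of very
    different longevity on a common [0, 1] scale.  Neither direction is
    clipped: an animal may exceed its species' recorded maximum lifespan
    and a clock may predict beyond it.

Default maximum lifespans are 22.8 y (marmoset) and 122.5 y (human).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigError, DomainError, FormatError

DEFAULT_LIFESPANS: dict[str, float] = {"marmoset": 22.8, "human": 122.5}
DEFAULT_ADULT_AGES: dict[str, float] = {"marmoset": 2.0, "human": 15.0}
DEFAULT_OFFSET_YEARS: float = 1.0
#: shared knot of the single-formula dual-species chronological clock
DUAL_SPECIES_ADULT_AGE: float = 5.0

_KINDS = ("identity", "loglinear", "relative")


def to_relative_age(age_years, max_lifespan_years):
    """Relative age = age / maxLifespan (not clipped at 1)."""
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise DomainError("age_years must be non-negative")
    if np.any(np.asarray(max_lifespan_years, dtype=float) <= 0):
        raise DomainError("max_lifespan_years must be positive")
    out = age / max_lifespan_years
    return float(out) if np.isscalar(age_years) else out


def from_relative_age(fraction, max_lifespan_years):
    """Inverse of :func:`to_relative_age`: fraction * maxLifespan."""
    if np.any(np.asarray(max_lifespan_years, dtype=float) <= 0):
        raise DomainError("max_lifespan_years must be positive")
    out = np.asarray(fraction, dtype=float) * max_lifespan_years
    return float(out) if np.isscalar(fraction) else out


def loglinear_forward(age_years, adult_age_years, offset_years):
    """Piecewise log/linear forward map; strictly increasing, F(adult) = 0."""
    if adult_age_years <= 0 or offset_years <= 0:
        raise DomainError("adult_age_years and offset_years must be positive")
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise DomainError("age_years must be non-negative")
    denom = adult_age_years + offset_years
    out = np.where(
        age <= adult_age_years,
        np.log((age + offset_years) / denom),
        (age - adult_age_years) / denom,
    )
    return float(out) if np.isscalar(age_years) else out


def loglinear_inverse(value, adult_age_years, offset_years):
    """Exact inverse of :func:`loglinear_forward`."""
    if adult_age_years <= 0 or offset_years <= 0:
        raise DomainError("adult_age_years and offset_years must be positive")
    val = np.asarray(value, dtype=float)
    denom = adult_age_years + offset_years
    out = np.where(
        val <= 0,
        np.exp(val) * denom - offset_years,
        val * denom + adult_age_years,
    )
    return float(out) if np.isscalar(value) else out


@dataclass(frozen=True)
class AgeTransform:
    """Invertible map between age in years and the regression scale.

    Parameters are keyed by species name for the species-aware kinds;
    ``identity`` ignores species entirely.
    """

    kind: str = "identity"
    max_lifespan_years: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFESPANS)
    )
    adult_age_years: "Mapping[str, float] | float" = field(
        default_factory=lambda: dict(DEFAULT_ADULT_AGES)
    )
    offset_years: float = DEFAULT_OFFSET_YEARS

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown transform kind {self.kind!r}; expected one of {_KINDS}")
        if any(v <= 0 for v in self.max_lifespan_years.values()):
            raise ConfigError("all max lifespans must be positive")
        adult = self.adult_age_years
        if isinstance(adult, Mapping):
            if any(v <= 0 for v in adult.values()):
                raise ConfigError("all adult ages must be positive")
        elif adult <= 0:
            raise ConfigError("adult_age_years must be positive")
        if self.offset_years <= 0:
            raise ConfigError("offset_years must be positive")

    # -- per-sample parameter lookup ------------------------------------
    def _lifespans(self, species) -> np.ndarray:
        try:
            return np.asarray([self.max_lifespan_years[s] for s in species], dtype=float)
        except KeyError as e:
            raise ConfigError(f"no max lifespan configured for species {e.args[0]!r}") from e

    def _adult_ages(self, species, n: int) -> np.ndarray:
        if not isinstance(self.adult_age_years, Mapping):
            return np.full(n, float(self.adult_age_years))
        species = self._species_vector(species, n)
        try:
            return np.asarray([self.adult_age_years[s] for s in species], dtype=float)
        except KeyError as e:
            raise ConfigError(f"no adult age configured for species {e.args[0]!r}") from e

    @staticmethod
    def _species_vector(species, n: int):
        if species is None:
            raise ConfigError("species labels are required for a species-aware transform")
        if isinstance(species, str):
            return [species] * n
        species = list(species)
        if len(species) != n:
            raise ConfigError("species vector length does not match number of samples")
        return species

    # -- forward / inverse ----------------------------------------------
    def forward(self, age_years, species=None):
        """Map chronological age (years) to the regression scale."""
        scalar = np.isscalar(age_years)
        age = np.atleast_1d(np.asarray(age_years, dtype=float))
        if np.any(age < 0):
            raise DomainError("age_years must be non-negative")
        if self.kind == "identity":
            out = age
        elif self.kind == "relative":
            out = age / self._lifespans(self._species_vector(species, age.size))
        else:
            adult = self._adult_ages(species, age.size)
            denom = adult + self.offset_years
            out = np.where(
                age <= adult,
                np.log((age + self.offset_years) / denom),
                (age - adult) / denom,
            )
        return float(out[0]) if scalar else out

    def inverse(self, value, species=None):
        """Map a regression-scale value back to age in years."""
        scalar = np.isscalar(value)
        val = np.atleast_1d(np.asarray(value, dtype=float))
        if self.kind == "identity":
            out = val
        elif self.kind == "relative":
            out = val * self._lifespans(self._species_vector(species, val.size))
        else:
            adult = self._adult_ages(species, val.size)
            denom = adult + self.offset_years
            out = np.where(
                val <= 0,
                np.exp(val) * denom - self.offset_years,
                val * denom + adult,
            )
        return float(out[0]) if scalar else out

    # -- serialization ---------------------------------------------------
    def to_header_items(self) -> list[tuple[str, str]]:
        """Flatten to ``key=value`` pairs for the clock-file header block."""
        items: list[tuple[str, str]] = [("transform", self.kind)]
        if self.kind == "relative":
            for name in sorted(self.max_lifespan_years):
                items.append((f"max_lifespan.{name}", repr(self.max_lifespan_years[name])))
        elif self.kind == "loglinear":
            if isinstance(self.adult_age_years, Mapping):
                for name in sorted(self.adult_age_years):
                    items.append((f"adult_age.{name}", repr(self.adult_age_years[name])))
            else:
                items.append(("adult_age", repr(float(self.adult_age_years))))
            items.append(("offset_years", repr(self.offset_years)))
        return items

    @classmethod
    def from_header_items(cls, items: Mapping[str, str]) -> "AgeTransform":
        """Rebuild a transform from parsed ``key=value`` header pairs."""
        kind = items.get("transform")
        if kind not in _KINDS:
            raise FormatError(f"unknown transform kind {kind!r} in model header")
        lifespans: dict[str, float] = {}
        adult_ages: dict[str, float] = {}
        shared_adult: float | None = None
        offset = DEFAULT_OFFSET_YEARS
        for key, raw in items.items():
            if key.startswith("max_lifespan."):
                lifespans[key.split(".", 1)[1]] = float(raw)
            elif key.startswith("adult_age."):
                adult_ages[key.split(".", 1)[1]] = float(raw)
            elif key == "adult_age":
                shared_adult = float(raw)
            elif key == "offset_years":
                offset = float(raw)
        if shared_adult is not None:
            adult: "dict[str, float] | float" = shared_adult
        else:
            adult = adult_ages or dict(DEFAULT_ADULT_AGES)
        return cls(
            kind=kind,
            max_lifespan_years=lifespans or dict(DEFAULT_LIFESPANS),
            adult_age_years=adult,
            offset_years=offset,
        )
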