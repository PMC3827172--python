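"""Niche side of the model: per-cell persistence probability and competitive ability.

A species present in (or having just colonised) a cell stays there for the
next time step with probability ``P_E``, a function of the cell's environment
only.  Three functional forms cover the use cases: a constant probability
(appropriate when nearly every occupied cell stays occupied), a single-covariate
threshold rule (e.g. a climatic envelope edge) and a logistic response on named
covariates (the habitat-suitability form typically obtained from a binomial GLM
of occurrence on habitat descriptors).

Competitive ability ``C_j`` of species ``j`` is its maximal persistence
probability over the viable cells of the study area; it feeds the
competition–dispersal trade-off in :mod:`ndm.dispersal`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .landscape import Landscape

__all__ = [
    "PersistenceModel",
    "ConstantPersistence",
    "ThresholdPersistence",
    "LogisticPersistence",
    "SpeciesSpec",
    "persistence_prob",
    "persistence_field",
    "competitive_ability",
    "fit_logistic_persistence",
]


class PersistenceModel:
    """Base class: maps cell covariates to a persistence probability in [0, 1]."""

    variant: str = "abstract"

    def probability(self, covariates: Mapping[str, float | np.ndarray]):
        raise NotImplementedError

    def required_covariates(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class ConstantPersistence(PersistenceModel):
    """Environment-independent persistence probability."""

    p: float
    variant: str = field(default="constant", init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("persistence probability must be in [0, 1]")

    def probability(self, covariates: Mapping[str, float | np.ndarray]):
        return self.p


@dataclass(frozen=True)
class ThresholdPersistence(PersistenceModel):
    """Step response on one covariate: one probability below the cutoff, another at or above."""

    covariate: str
    cutoff: float
    p_below: float
    p_at_or_above: float
    variant: str = field(default="threshold", init=False)

    def __post_init__(self) -> None:
        for p in (self.p_below, self.p_at_or_above):
            if not 0.0 <= p <= 1.0:
                raise ValueError("threshold probabilities must be in [0, 1]")

    def required_covariates(self) -> set[str]:
        return {self.covariate}

    def probability(self, covariates: Mapping[str, float | np.ndarray]):
        if self.covariate not in covariates:
            raise KeyError(f"missing covariate {self.covariate!r}")
        x = np.asarray(covariates[self.covariate], dtype=float)
        out = np.where(x >= self.cutoff, self.p_at_or_above, self.p_below)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LogisticPersistence(PersistenceModel):
    """Logistic (logit-linear) response on named covariates.

    ``P = 1 / (1 + exp(-(intercept + sum_i beta_i * x_i)))`` with coefficients
    on the log-odds scale, as produced by a binomial GLM with logit link.
    """

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    variant: str = field(default="logistic", init=False)

    def required_covariates(self) -> set[str]:
        return set(self.coefficients)

    def probability(self, covariates: Mapping[str, float | np.ndarray]):
        eta = np.asarray(self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            if name not in covariates:
                raise KeyError(f"missing covariate {name!r}")
            eta = eta + beta * np.asarray(covariates[name], dtype=float)
        out = 1.0 / (1.0 + np.exp(-eta))
        return float(out) if out.ndim == 0 else out


@dataclass
class SpeciesSpec:
    """One species: dispersal parameters plus its persistence model.

    Exactly one of ``d_max`` (maximal dispersal distance, in cells) or
    ``d_min`` (trade-off distance at competitive ability 1, from which
    ``d_max`` is derived per landscape) must be given.
    """

    species_id: str
    p_max: float
    persistence: PersistenceModel
    d_max: int | None = None
    d_min: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError(f"{self.species_id}: p_max must be in [0, 1]")
        if (self.d_max is None) == (self.d_min is None):
            raise ValueError(
                f"{self.species_id}: exactly one of d_max or d_min must be given"
            )
        for name in ("d_max", "d_min"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 1):
                raise ValueError(f"{self.species_id}: {name} must be an integer >= 1")


def persistence_prob(m: PersistenceModel, covariates: Mapping[str, float]) -> float:
    """Persistence probability of model ``m`` under the given covariate values."""
    return float(m.probability(covariates))


def persistence_field(m: PersistenceModel, L: Landscape) -> np.ndarray:
    """Persistence probability of ``m`` evaluated at every cell of ``L``.

    Returns a ``(n_rows, n_cols)`` float array.  Non-viable cells are included
    (the niche is defined everywhere); the simulator zeroes them out.
    """
    out = np.asarray(m.probability(L.covariates), dtype=float)
    if out.ndim == 0:
        out = np.full(L.shape, float(out))
    return out


def competitive_ability(s: SpeciesSpec, L: Landscape) -> float:
    """Maximal persistence probability of ``s`` over the viable cells of ``L``."""
    if not L.viable.any():
        raise ValueError("landscape has no viable cells")
    field_ = persistence_field(s.persistence, L)
    return float(field_[L.viable].max())


def fit_logistic_persistence(
    presence: np.ndarray,
    covariates: Mapping[str, np.ndarray],
) -> LogisticPersistence:
    """Maximum-likelihood logistic fit of presence on the supplied covariates.

    A convenience for synthetic work: covariate choice is the caller's (no
    stepwise selection).  Under perfect separation the fit warns and returns
    clipped coefficients rather than diverging.
    """
    import statsmodels.api as sm

    y = np.asarray(presence, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("need at least one presence and one absence")
    names = list(covariates)
    X = np.column_stack([np.asarray(covariates[n], dtype=float).ravel() for n in names])
    X = sm.add_constant(X, has_constant="add")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params, dtype=float)
        except Exception:  # perfect separation can abort IRLS outright
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
            params = np.asarray(res.params, dtype=float)
    clip = 30.0  # |log-odds| beyond this is numerically saturated
    if np.any(np.abs(params) > clip):
        import logging

        logging.getLogger(__name__).warning(
            "logistic persistence fit near-separated; clipping coefficients"
        )
        params = np.clip(params, -clip, clip)
    return LogisticPersistence(
        intercept=float(params[0]),
        coefficients={n: float(b) for n, b in zip(names, params[1:])},
    )
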