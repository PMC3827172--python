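"""Dispersal kernel, immigration union, colonisation and the trade-off.

Per-source dispersal follows a linear kernel on chessboard distance: the
arrival probability is maximal (``p_max``) at distance 1 and declines
linearly, reaching ``p_max / d_max`` at the cutoff distance ``d_max`` and
zero beyond.  This discrete form keeps the kernel well defined at
``d_max = 1`` (a single ring at full strength), which species with
cell-scale dispersal require.

Arrivals from different occupied source cells are independent Bernoulli
events, so immigration into a cell is their union,
``P_I = 1 - prod_k (1 - p_k)``, and colonisation of an empty cell is the
product ``P_C = P_I * P_E`` of immigration and conditional persistence.

The competition–dispersal trade-off of patch-dynamics communities sets
``d_max = round(d_min / C_j)``: better competitors (higher maximal
persistence ``C_j``) disperse less far.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .landscape import CellCoord, Landscape, chebyshev_distance, neighbourhood
from .persistence import SpeciesSpec, competitive_ability

__all__ = [
    "dispersal_prob",
    "immigration_prob",
    "colonisation_prob",
    "tradeoff_d_max",
    "immigration_prob_at",
    "resolve_d_max",
    "log1m_kernel",
]


def dispersal_prob(d: int, p_max: float, d_max: int) -> float:
    """Probability of arriving from one source at chessboard distance ``d`` cells.

    ``p_max * (d_max - d + 1) / d_max`` for ``1 <= d <= d_max``, zero beyond.
    """
    if d < 1:
        raise ValueError("source and target cell coincide: distance must be >= 1")
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if d > d_max:
        return 0.0
    return p_max * (d_max - d + 1) / d_max


def immigration_prob(source_probs: Sequence[float]) -> float:
    """Union of independent per-source arrival events: ``1 - prod(1 - p_k)``."""
    p = np.asarray(source_probs, dtype=float)
    if p.size == 0:
        return 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("per-source probabilities must be in [0, 1]")
    if np.any(p == 1.0):
        return 1.0
    return float(-np.expm1(np.log1p(-p).sum()))


def colonisation_prob(p_i: float, p_e: float) -> float:
    """Colonisation = immigration x conditional persistence (independent events)."""
    for v in (p_i, p_e):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    return p_i * p_e


def tradeoff_d_max(d_min: int, c_j: float) -> int:
    """Trade-off dispersal cutoff ``round(d_min / C_j)``, half-up, floored at 1 cell."""
    if c_j <= 0:
        raise ValueError("competitive ability must be > 0")
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    return max(1, int(math.floor(d_min / c_j + 0.5)))


def resolve_d_max(s: SpeciesSpec, L: Landscape) -> int:
    """Species' dispersal cutoff: explicit ``d_max``, or derived from the trade-off."""
    if s.d_max is not None:
        return int(s.d_max)
    return tradeoff_d_max(int(s.d_min), competitive_ability(s, L))


def immigration_prob_at(
    species: SpeciesSpec,
    e: CellCoord,
    occupied: np.ndarray,
    L: Landscape,
) -> float:
    """Immigration probability into cell ``e`` given the species' occupancy grid.

    ``occupied`` is a boolean ``(n_rows, n_cols)`` presence grid for this
    species.  Every occupied cell within the dispersal cutoff contributes an
    independent arrival event at the kernel probability for its distance.
    """
    d_max = resolve_d_max(species, L)
    probs = [
        dispersal_prob(chebyshev_distance(k, e), species.p_max, d_max)
        for k in neighbourhood(e, d_max, L)
        if occupied[k.row, k.col]
    ]
    return immigration_prob(probs)


def log1m_kernel(p_max: float, d_max: int) -> np.ndarray:
    """Convolution kernel of ``log(1 - p)`` kernel values, centre zero.

    Summing this kernel over a species' occupancy indicator grid gives
    ``log prod_k (1 - p_k)``, from which the immigration union follows as
    ``-expm1``.  Values are clipped away from ``p = 1`` so the logarithm
    stays finite; the resulting immigration probability is 1 to within
    double precision.
    """
    size = 2 * d_max + 1
    k = np.zeros((size, size), dtype=float)
    for dr in range(-d_max, d_max + 1):
        for dc in range(-d_max, d_max + 1):
            d = max(abs(dr), abs(dc))
            if d >= 1:
                p = min(dispersal_prob(d, p_max, d_max), 1.0 - 1e-15)
                k[dr + d_max, dc + d_max] = np.log1p(-p)
    return k
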