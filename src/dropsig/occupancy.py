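"""Poisson statistics of cell and transcript encapsulation in droplets.

Cell loading into droplets is a Poisson process: with an average of
``lambda_`` cells per droplet, P(x cells) = lambda^x e^-lambda / x!.
The empty-droplet fraction therefore identifies lambda (lambda =
-ln P(0)), which is the basis both for estimating cell concentration and
for limiting-dilution quantification of transcripts.  Conditional on a
droplet containing cells, the model used downstream keeps only the
single-cell and doublet cases:

    p1 = P(1) / (P(1) + P(2)) = 2 / (2 + lambda)
    p2 = P(2) / (P(1) + P(2)) = lambda / (2 + lambda)

Droplets with more than two cells are deliberately not modelled here;
the simulator quantifies the bias this simplification costs at high
lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OccupancyModel",
    "poisson_pmf",
    "lambda_from_empty_fraction",
    "conditional_cell_probs",
    "multiplet_fraction",
    "concentration_from_negatives",
    "efficiency_from_slope",
    "droplet_diameter_um",
    "cells_per_microliter",
    "AboveQuantifiableRange",
]


class AboveQuantifiableRange(ValueError):
    """No negative droplets: the target is too concentrated to quantify."""


def poisson_pmf(x: int, lambda_: float) -> float:
    """P(x cells) = lambda^x e^-lambda / x! for mean occupancy lambda."""
    if lambda_ <= 0:
        raise ValueError(f"lambda must be positive, got {lambda_}")
    if x < 0 or x != int(x):
        raise ValueError(f"x must be a non-negative integer, got {x}")
    return float(stats.poisson.pmf(int(x), lambda_))


def lambda_from_empty_fraction(p0: float) -> float:
    """Invert P(0) = e^-lambda: mean occupancy from the empty fraction.

    ``p0`` must lie strictly in (0, 1): p0 = 1 means no cells were loaded
    and p0 = 0 means every droplet is occupied (saturation), neither of
    which identifies lambda.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(
            f"empty fraction must be in (0, 1), got {p0} "
            "(1 means no cells; 0 means saturation)"
        )
    return -math.log(p0)


def conditional_cell_probs(lambda_: float) -> tuple[float, float]:
    """(p1, p2): P(1 or 2 cells) conditioned on the droplet holding 1 or 2.

    Closed form: p1 = 2/(2+lambda), p2 = lambda/(2+lambda).
    """
    if lambda_ <= 0:
        raise ValueError(f"lambda must be positive, got {lambda_}")
    p1 = 2.0 / (2.0 + lambda_)
    return p1, 1.0 - p1


def multiplet_fraction(lambda_: float, k: int = 2) -> float:
    """Fraction of droplets containing more than ``k`` cells.

    The default k=2 is the quantity relevant to the deconvolution model,
    which treats droplets with more than two cells as negligible
    (0.11% at lambda=0.2, 1.44% at lambda=0.5).
    """
    if lambda_ <= 0:
        raise ValueError(f"lambda must be positive, got {lambda_}")
    if k < 0 or k != int(k):
        raise ValueError(f"k must be a non-negative integer, got {k}")
    return float(stats.poisson.sf(int(k), lambda_))


def concentration_from_negatives(fraction_negative: float, droplet_volume_nl: float = 1.0) -> float:
    """Limiting-dilution estimate of transcript concentration (copies/nL).

    ``fraction_negative`` is the fraction of droplets not expressing the
    target gene; by Poisson statistics the mean copies per droplet is
    -ln(fraction_negative), applied independently per target.
    """
    if droplet_volume_nl <= 0:
        raise ValueError(f"droplet volume must be positive, got {droplet_volume_nl}")
    if fraction_negative == 0:
        raise AboveQuantifiableRange(
            "no negative droplets observed: concentration is above the quantifiable range"
        )
    if not 0.0 < fraction_negative < 1.0:
        raise ValueError(f"fraction_negative must be in (0, 1), got {fraction_negative}")
    return -math.log(fraction_negative) / droplet_volume_nl


def efficiency_from_slope(alpha: float) -> float:
    """PCR amplification efficiency from a standard-curve slope.

    ``alpha`` is the slope of C_T against log10 template amount (C_T per
    decade, negative for an amplifying reaction); E = 10^(-1/alpha) - 1,
    with E = 1 meaning perfect per-cycle doubling.
    """
    if alpha >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {alpha}")
    return 10.0 ** (-1.0 / alpha) - 1.0


def droplet_diameter_um(volume_nl: float) -> float:
    """Diameter (µm) of a spherical droplet of the given volume (nL)."""
    if volume_nl <= 0:
        raise ValueError(f"volume must be positive, got {volume_nl}")
    volume_um3 = volume_nl * 1e6  # 1 nL = 1e-6 cm³ = 1e6 µm³
    return (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def cells_per_microliter(lambda_: float, droplet_volume_nl: float = 1.0) -> float:
    """Cell concentration (cells/µL) implied by mean occupancy lambda.

    One cell per 1 nL droplet is equivalent to 1000 cells/µL, the lysate
    concentration scale relevant to reaction inhibition.
    """
    if lambda_ < 0:
        raise ValueError(f"lambda must be non-negative, got {lambda_}")
    if droplet_volume_nl <= 0:
        raise ValueError(f"droplet volume must be positive, got {droplet_volume_nl}")
    return lambda_ / droplet_volume_nl * 1000.0


@dataclass(frozen=True)
class OccupancyModel:
    """Mean occupancy lambda with the derived conditional probabilities."""

    lambda_: float

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError(f"lambda must be positive, got {self.lambda_}")

    @classmethod
    def from_empty_fraction(cls, p0: float) -> "OccupancyModel":
        return cls(lambda_from_empty_fraction(p0))

    @property
    def p1(self) -> float:
        return conditional_cell_probs(self.lambda_)[0]

    @property
    def p2(self) -> float:
        return conditional_cell_probs(self.lambda_)[1]

    @property
    def empty_fraction(self) -> float:
        return math.exp(-self.lambda_)

    def pmf(self, x: int) -> float:
        return poisson_pmf(x, self.lambda_)

    def multiplet_fraction(self, k: int = 2) -> float:
        return multiplet_fraction(self.lambda_, k)


def quantify_targets(fractions_negative: "np.ndarray | dict[str, float]",
                     droplet_volume_nl: float = 1.0) -> dict[str, float]:
    """Per-target copies/nL from per-target negative fractions (CLI helper)."""
    if isinstance(fractions_negative, dict):
        items = fractions_negative.items()
    else:
        arr = np.asarray(fractions_negative, dtype=float)
        items = ((str(i), float(v)) for i, v in enumerate(arr))
    return {
        name: concentration_from_negatives(frac, droplet_volume_nl)
        for name, frac in items
    }
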