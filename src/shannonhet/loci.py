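"""Estimating the number of loci L from allelism-free profiles.

A diploid individual can carry at most 2L distinct variants of an L-locus
gene family, so half the per-individual distinct-variant count bounds and
estimates L. Three aggregations are provided: ``one_individual`` (the
maximum over individuals — the single most variant-rich individual),
``mean`` and ``median``. An alternative basis estimates 2L per individual as
the reciprocal of the smallest within-individual read proportion (a variant
present as a single allele copy out of 2L should draw ~1/(2L) of the reads),
aggregated the same three ways; it can yield non-half-integer raw estimates.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .profiles import PopulationProfile

__all__ = [
    "LocusEstimationMethod",
    "LocusEstimate",
    "per_individual_variant_counts",
    "estimate_loci",
    "round_locus_estimate",
]


class LocusEstimationMethod(str, enum.Enum):
    ONE_INDIVIDUAL = "one_individual"
    MEAN = "mean"
    MEDIAN = "median"


@dataclass(frozen=True)
class LocusEstimate:
    """A locus-number estimate: raw (non-rounded) and rounded (half-up, >= 1)."""

    method: LocusEstimationMethod
    raw: float
    rounded: int

    def __post_init__(self) -> None:
        if self.raw <= 0:
            raise InvalidInputError(f"raw locus estimate must be > 0, got {self.raw}")


def per_individual_variant_counts(population: PopulationProfile) -> list[int]:
    """Number of distinct variants (count > 0) carried by each individual."""
    return [p.n_variants for p in population]


def round_locus_estimate(raw: float) -> int:
    """Round a raw locus estimate to the nearest integer, halves up, floor 1.

    The floor keeps the statistic defined even when the raw estimate drops
    below 0.5 (a population can't have a fractional locus count below one).
    """
    if raw <= 0:
        raise InvalidInputError(f"raw locus estimate must be > 0, got {raw}")
    return max(1, math.floor(raw + 0.5))


def estimate_loci(
    population: PopulationProfile,
    method: LocusEstimationMethod | str = LocusEstimationMethod.MEDIAN,
    proportion_based: bool = False,
) -> LocusEstimate:
    """Estimate L from variant profiles.

    Parameters
    ----------
    population
        Allelism-free variant profiles.
    method
        ``one_individual`` (max over individuals), ``mean`` or ``median``.
    proportion_based
        If true, each individual's 2L estimate is 1 / (smallest
        within-individual variant proportion) instead of its distinct-variant
        count. Useful when read proportions, not just presence, are reliable.
    """
    method = LocusEstimationMethod(method)
    if proportion_based:
        per_ind = [
            1.0 / min(p.proportions().values()) for p in population.profiles
        ]
    else:
        per_ind = [float(c) for c in per_individual_variant_counts(population)]
    agg = {
        LocusEstimationMethod.ONE_INDIVIDUAL: np.max,
        LocusEstimationMethod.MEAN: np.mean,
        LocusEstimationMethod.MEDIAN: np.median,
    }[method]
    raw = float(agg(per_ind)) / 2.0
    return LocusEstimate(method=method, raw=raw, rounded=round_locus_estimate(raw))
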