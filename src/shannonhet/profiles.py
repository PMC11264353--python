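"""Allelism-free variant profiles.

In a multi-locus gene family, short-read data identify which variant
sequences an individual carries and in what read proportions, but not which
locus each variant belongs to. These containers hold exactly that
information: per-individual variant counts (``VariantProfile``) and a
population of such individuals (``PopulationProfile``) with pooled variant
proportions P_i.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import InvalidInputError

__all__ = ["PoolingMode", "VariantProfile", "PopulationProfile"]


class PoolingMode(str, enum.Enum):
    """How population-level variant proportions P_i are formed.

    ``MEAN_OF_PROPORTIONS`` averages each individual's proportion vector
    (robust to unequal read depth between individuals); ``POOLED_COUNTS``
    sums raw counts before normalizing. For equal-depth data the two agree.
    """

    MEAN_OF_PROPORTIONS = "mean_of_proportions"
    POOLED_COUNTS = "pooled_counts"


@dataclass(frozen=True)
class VariantProfile:
    """One individual's variant read counts, allelism unknown.

    Parameters
    ----------
    individual_id
        Opaque label for the individual.
    counts
        Mapping variant ID -> nonnegative count (read count or allele-copy
        count; nonintegral values such as proportions are accepted since
        every downstream statistic depends only on proportions).
    """

    individual_id: str
    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for variant, count in self.counts.items():
            c = float(count)
            if not np.isfinite(c) or c < 0:
                raise InvalidInputError(
                    f"individual {self.individual_id!r}: count for variant "
                    f"{variant!r} must be a finite nonnegative number, got {count!r}"
                )
            if c > 0:
                clean[str(variant)] = c
        if not clean:
            raise InvalidInputError(
                f"individual {self.individual_id!r} has no variant with count > 0"
            )
        object.__setattr__(self, "counts", clean)

    @property
    def variants(self) -> tuple[str, ...]:
        """Variant IDs present (count > 0)."""
        return tuple(self.counts)

    @property
    def n_variants(self) -> int:
        """v, the number of distinct variants carried by this individual."""
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def proportions(self) -> dict[str, float]:
        """Within-individual variant proportions p_i (sum to 1)."""
        tot = self.total
        return {v: c / tot for v, c in self.counts.items()}


@dataclass(frozen=True)
class PopulationProfile:
    """An ordered collection of variant profiles plus pooled proportions."""

    profiles: tuple[VariantProfile, ...]
    pooling_mode: PoolingMode = PoolingMode.MEAN_OF_PROPORTIONS

    def __init__(
        self,
        profiles: Iterable[VariantProfile],
        pooling_mode: PoolingMode | str = PoolingMode.MEAN_OF_PROPORTIONS,
    ) -> None:
        profiles = tuple(profiles)
        if not profiles:
            raise InvalidInputError("population must contain at least one profile")
        ids = [p.individual_id for p in profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate individual IDs: {dupes}")
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "pooling_mode", PoolingMode(pooling_mode))

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @property
    def individual_ids(self) -> tuple[str, ...]:
        return tuple(p.individual_id for p in self.profiles)

    def population_proportions(self) -> dict[str, float]:
        """Population variant proportions P_i per the pooling mode (sum to 1)."""
        acc: dict[str, float] = {}
        if self.pooling_mode is PoolingMode.MEAN_OF_PROPORTIONS:
            n = len(self.profiles)
            for prof in self.profiles:
                for v, p in prof.proportions().items():
                    acc[v] = acc.get(v, 0.0) + p / n
        else:
            total = sum(p.total for p in self.profiles)
            for prof in self.profiles:
                for v, c in prof.counts.items():
                    acc[v] = acc.get(v, 0.0) + c / total
        return acc

    @property
    def n_variants(self) -> int:
        """V, the number of variants with population proportion > 0."""
        return len(self.population_proportions())
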