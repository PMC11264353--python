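"""From allelism-aware genotypes to NGS-like variant profiles, plus filters.

``genotypes_to_profiles`` deliberately throws away the locus labels,
producing the kind of data a real multi-locus gene-family study yields:
per-individual variant counts with no information on which variant sits at
which locus. ``sample_reads`` emulates finite sequencing depth;
the filters drop data where neither F_IS nor the Shannon statistic is
informative (no population variation, or no between-individual variation in
H_I¹ — the signature of locus-specific fixation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .genotypes import LocusGenotypeTable
from .profiles import PopulationProfile, VariantProfile
from .shannon import individual_shannon

__all__ = [
    "FilterReport",
    "genotypes_to_profiles",
    "sample_reads",
    "filter_low_proportion_variants",
    "degeneracy_reason",
    "exclude_degenerate_replicates",
]

REASON_NO_POPULATION_VARIATION = "no_population_variation"
REASON_ZERO_HI_VARIANCE = "zero_hi_variance"
REASON_LOW_PROPORTION_VARIANT = "low_proportion_variant"


@dataclass(frozen=True)
class FilterReport:
    """Partition of input labels into kept and dropped-with-reason."""

    kept: tuple = ()
    dropped: Mapping[object, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise InvalidInputError(f"labels both kept and dropped: {sorted(overlap)}")


def genotypes_to_profiles(table: LocusGenotypeTable) -> PopulationProfile:
    """Discard allelism: per individual, count allele copies of each variant.

    Every individual contributes exactly 2L copies, so within-individual
    proportions are allele-copy proportions and the population proportions
    match what perfectly depth-balanced sequencing would report.
    """
    profiles = []
    for i, ind in enumerate(table.individuals):
        values, counts = np.unique(table.alleles[i], return_counts=True)
        profiles.append(
            VariantProfile(ind, dict(zip(values.tolist(), counts.tolist())))
        )
    return PopulationProfile(profiles)


def sample_reads(
    profile: VariantProfile, depth: int, rng: np.random.Generator
) -> VariantProfile:
    """Resample a profile at finite read depth.

    Reads are drawn multinomially with the profile's proportions and a fixed
    total of ``depth``; variants drawn zero times disappear from the output,
    as they would from a real sequencing run.
    """
    if depth < 1:
        raise InvalidInputError(f"read depth must be >= 1, got {depth}")
    variants = list(profile.counts)
    props = np.array([profile.proportions()[v] for v in variants])
    draws = rng.multinomial(depth, props)
    return VariantProfile(
        profile.individual_id,
        {v: int(c) for v, c in zip(variants, draws) if c > 0},
    )


def filter_low_proportion_variants(
    profile: VariantProfile, min_prop: float
) -> VariantProfile:
    """Drop variants below a within-individual read-proportion threshold.

    A standard cleaning step for real amplicon data (e.g. requiring each
    retained variant to make up at least 10% of an individual's reads, which
    suppresses sequencing artefacts). The boundary is inclusive: a variant
    at exactly ``min_prop`` is kept. Counts of retained variants are left
    unchanged; proportions renormalize implicitly.
    """
    if not 0 <= min_prop < 1:
        raise InvalidInputError(f"min_prop must lie in [0, 1), got {min_prop}")
    props = profile.proportions()
    kept = {v: c for v, c in profile.counts.items() if props[v] >= min_prop}
    if not kept:
        raise InvalidInputError(
            f"individual {profile.individual_id!r}: no variant reaches "
            f"proportion {min_prop}"
        )
    return VariantProfile(profile.individual_id, kept)


def degeneracy_reason(
    population: PopulationProfile, hi_variance_tol: float = 1e-12
) -> str | None:
    """Why a replicate is uninformative, or None if it is usable.

    Checked in order: a single variant in the whole population (H_S¹ = 0,
    total fixation — nothing to measure), then between-individual variance
    of H_I¹ at or below tolerance (every individual has the same
    within-individual information, e.g. each locus fixed for its own
    variant, where the statistic would read maximal diversity).
    """
    if population.n_variants < 2:
        return REASON_NO_POPULATION_VARIATION
    h_i = [individual_shannon(p) for p in population]
    if float(np.var(h_i)) <= hi_variance_tol:
        return REASON_ZERO_HI_VARIANCE
    return None


def exclude_degenerate_replicates(
    replicates: Sequence[PopulationProfile] | Mapping[object, PopulationProfile],
    hi_variance_tol: float = 1e-12,
) -> FilterReport:
    """Partition replicate populations into kept and dropped-with-reason."""
    if hi_variance_tol < 0:
        raise InvalidInputError("hi_variance_tol must be >= 0")
    if isinstance(replicates, Mapping):
        items = list(replicates.items())
    else:
        items = list(enumerate(replicates))
    kept, dropped = [], {}
    for label, pop in items:
        reason = degeneracy_reason(pop, hi_variance_tol)
        if reason is None:
            kept.append(label)
        else:
            dropped[label] = reason
    return FilterReport(kept=tuple(kept), dropped=dropped)
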