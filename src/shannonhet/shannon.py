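"""The Shannon-information heterozygosity statistic ¹H_IS.

F_IS compares observed to Hardy–Weinberg-expected heterozygosity at a known
locus; it cannot be computed for multi-locus gene families where short-read
data do not reveal which variants are alleles of which locus. ¹H_IS is an
allelism-free analogue built from Shannon information (natural log, nats):

    H_I¹  = −Σ p_i ln p_i        within one individual,
    H̄_I¹ = mean of H_I¹ over individuals,
    H_S¹  = −Σ P_i ln P_i        over population variant proportions,
    EV    = H_S¹ / ln V          genetic evenness, V = number of variants,

and, with L the number of loci in the family,

    ¹H_IS = −( H̄_I¹ · (L + 1) / H_S¹ − L ) · EV.

Like F_IS it is positive under heterozygote deficit (inbreeding, positive
assortative mating, selection against heterozygotes) and negative under
heterozygote excess; stochasticity can push it slightly above +1, which may
optionally be clamped to +1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError, UndefinedEvennessError, UndefinedStatisticError
from .profiles import PopulationProfile, VariantProfile

__all__ = [
    "HisResult",
    "individual_shannon",
    "mean_individual_shannon",
    "population_shannon",
    "evenness",
    "his_prime",
    "his",
    "his_from_profiles",
]


@dataclass(frozen=True)
class HisResult:
    """All intermediate and final values of a ¹H_IS computation.

    ``his`` is the reported statistic; when ``clamped`` is true the raw
    value exceeded +1 and ``his`` was set to +1, with the raw value kept in
    ``his_raw``. Otherwise ``his == his_raw == his_prime * evenness``.
    """

    h_bar: float
    h_s: float
    evenness: float
    loci: int
    his_prime: float
    his: float
    his_raw: float
    clamped: bool


def _shannon(proportions) -> float:
    # 0·ln 0 = 0 by convention; proportions of zero never enter.
    return -sum(p * math.log(p) for p in proportions if p > 0)


def individual_shannon(profile: VariantProfile) -> float:
    """Shannon information H_I¹ of one individual's variant proportions, in nats.

    Bounded by 0 (a single variant) and ln v (v variants, equal proportions).
    """
    return _shannon(profile.proportions().values())


def mean_individual_shannon(population: PopulationProfile) -> float:
    """H̄_I¹: arithmetic mean of H_I¹ across all individuals."""
    return sum(individual_shannon(p) for p in population) / len(population)


def population_shannon(population: PopulationProfile) -> float:
    """H_S¹: Shannon information of the pooled population variant proportions."""
    return _shannon(population.population_proportions().values())


def evenness(population: PopulationProfile) -> float:
    """Genetic evenness EV = H_S¹ / ln V, in (0, 1].

    EV is 1 when all V variants are equally frequent. Undefined for V < 2,
    where ln V = 0.
    """
    v = population.n_variants
    if v < 2:
        raise UndefinedEvennessError(
            f"evenness needs at least 2 variants in the population, found {v}"
        )
    return population_shannon(population) / math.log(v)


def his_prime(h_bar: float, h_s: float, loci: int) -> float:
    """Uncorrected statistic −( H̄_I¹ · (L+1) / H_S¹ − L ).

    The mean within-individual information is weighted by (L+1)/H_S¹ so that
    the comparison with the population's information accounts for the ceiling
    ln(2L) that the number of loci puts on H_I¹; subtracting L returns the
    result to the F_IS-like −1..+1 scale.
    """
    if loci < 1 or int(loci) != loci:
        raise InvalidInputError(f"number of loci must be a positive integer, got {loci}")
    if h_bar < 0:
        raise InvalidInputError(f"mean individual Shannon information must be >= 0, got {h_bar}")
    if h_s == 0:
        raise UndefinedStatisticError(
            "population Shannon information is 0 (no variation in the population); "
            "the statistic is undefined"
        )
    if h_s < 0:
        raise InvalidInputError(f"population Shannon information must be >= 0, got {h_s}")
    return -(h_bar * (loci + 1) / h_s - loci)


def his(
    h_bar: float,
    h_s: float,
    loci: int,
    ev: float,
    clamp: bool = False,
) -> HisResult:
    """Evenness-corrected statistic ¹H_IS = his_prime × EV.

    With ``clamp=True``, values above +1 (possible through stochasticity)
    are reported as +1 and flagged; the raw value is always retained.
    """
    if not 0 < ev <= 1:
        raise InvalidInputError(f"evenness must lie in (0, 1], got {ev}")
    prime = his_prime(h_bar, h_s, loci)
    raw = prime * ev
    clamped = bool(clamp and raw > 1.0)
    return HisResult(
        h_bar=h_bar,
        h_s=h_s,
        evenness=ev,
        loci=int(loci),
        his_prime=prime,
        his=1.0 if clamped else raw,
        his_raw=raw,
        clamped=clamped,
    )


def his_from_profiles(
    population: PopulationProfile, loci: int, clamp: bool = False
) -> HisResult:
    """Compute H̄_I¹, H_S¹ and EV from variant profiles, then ¹H_IS.

    Raises :class:`UndefinedStatisticError` when the population carries a
    single variant (total fixation: H_S¹ = 0 and EV undefined).
    """
    h_bar = mean_individual_shannon(population)
    ev = evenness(population)  # raises for V < 2 (total fixation)
    h_s = population_shannon(population)
    return his(h_bar, h_s, loci, ev, clamp=clamp)
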