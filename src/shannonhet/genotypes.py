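"""Classical locus-aware statistics: He, Ho and F_IS.

These require allelism — knowing which variants segregate at which locus —
and serve both as the reference statistic the Shannon analogue is validated
against and as the representation the forward simulator produces.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "LocusGenotypeTable",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "fis_locus",
    "multiple_fis",
]


@dataclass(frozen=True)
class LocusGenotypeTable:
    """Diploid genotypes for an ordered set of individuals and loci.

    ``alleles`` has shape (n_individuals, n_loci, 2); each cell holds an
    allele ID (the pair is unordered; identical IDs mean a homozygote).
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles)
        if arr.shape != (len(self.individuals), len(self.loci), 2):
            raise InvalidInputError(
                f"allele array shape {arr.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise InvalidInputError("duplicate individual labels")
        if len(set(self.loci)) != len(self.loci):
            raise InvalidInputError("duplicate locus labels")
        object.__setattr__(self, "alleles", arr)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "LocusGenotypeTable":
        """Build from (individual, locus, allele1, allele2) records.

        Every individual must have exactly one genotype at every locus.
        """
        cells: dict[tuple[str, str], tuple[str, str]] = {}
        individuals: list[str] = []
        loci: list[str] = []
        for ind, locus, a1, a2 in records:
            key = (str(ind), str(locus))
            if key in cells:
                raise InvalidInputError(
                    f"duplicate genotype for individual {ind!r} at locus {locus!r}"
                )
            cells[key] = (str(a1), str(a2))
            if key[0] not in individuals:
                individuals.append(key[0])
            if key[1] not in loci:
                loci.append(key[1])
        missing = [
            (i, l) for i in individuals for l in loci if (i, l) not in cells
        ]
        if missing:
            raise InvalidInputError(f"missing genotypes for cells: {missing[:5]}")
        arr = np.empty((len(individuals), len(loci), 2), dtype=object)
        for i, ind in enumerate(individuals):
            for j, locus in enumerate(loci):
                arr[i, j, :] = cells[(ind, locus)]
        return cls(tuple(individuals), tuple(loci), arr)

    def to_records(self) -> list[tuple[str, str, str, str]]:
        return [
            (ind, locus, self.alleles[i, j, 0], self.alleles[i, j, 1])
            for i, ind in enumerate(self.individuals)
            for j, locus in enumerate(self.loci)
        ]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def _locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise InvalidInputError(f"unknown locus {locus!r}") from None

    def allele_proportions(self, locus: str) -> dict:
        """Sample allele proportions P̃_i at one locus (2N allele copies)."""
        j = self._locus_index(locus)
        values, counts = np.unique(self.alleles[:, j, :], return_counts=True)
        total = counts.sum()
        return {v: c / total for v, c in zip(values.tolist(), counts.tolist())}


def expected_heterozygosity(allele_proportions: Sequence[float]) -> float:
    """Hardy–Weinberg expected heterozygosity He = 1 − Σ P̃_i² at one locus."""
    props = np.asarray(list(allele_proportions), dtype=float)
    if props.size == 0 or (props < 0).any():
        raise InvalidInputError("allele proportions must be nonnegative and nonempty")
    if abs(props.sum() - 1.0) > 1e-9:
        raise InvalidInputError(
            f"allele proportions must sum to 1, got {props.sum():.12f}"
        )
    return float(1.0 - (props**2).sum())


def observed_heterozygosity(table: LocusGenotypeTable, locus: str) -> float:
    """Ho: fraction of individuals whose two allele IDs at the locus differ."""
    j = table._locus_index(locus)
    het = table.alleles[:, j, 0] != table.alleles[:, j, 1]
    return float(np.mean(het))


def fis_locus(he: float, ho: float) -> float:
    """Single-locus F_IS = (He − Ho) / He.

    +1 when no heterozygotes are observed despite allelic variation, −1 under
    complete heterozygote excess. Undefined for a monomorphic locus (He = 0).
    """
    if he < 0 or ho < 0:
        raise InvalidInputError("heterozygosities must be nonnegative")
    if he == 0:
        raise UndefinedStatisticError("He = 0 (monomorphic locus): F_IS is undefined")
    return (he - ho) / he


def multiple_fis(table: LocusGenotypeTable) -> float:
    """Multiple F_IS: per-locus F_IS averaged over polymorphic loci.

    Allele proportions are estimated from the sample itself. Loci that are
    monomorphic in the sample carry no heterozygosity information and are
    skipped; a fully monomorphic table has no defined value.
    """
    values = []
    for locus in table.loci:
        props = table.allele_proportions(locus)
        he = expected_heterozygosity(list(props.values()))
        if he == 0:
            continue
        values.append(fis_locus(he, observed_heterozygosity(table, locus)))
    if not values:
        raise UndefinedStatisticError(
            "all loci are monomorphic in the sample: multiple F_IS is undefined"
        )
    return float(np.mean(values))
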