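"""Forward-time diploid simulation of a multi-locus gene family.

Non-overlapping generations of constant size; unlinked loci (free
recombination); no mutation. Each offspring draws two distinct parents —
uniformly within its mating pool, accepted with a probability determined by
the selection scheme — and inherits one allele per locus from each parent.
Selection therefore acts only on who gets to be a parent, never on
offspring survival, so every censused generation is itself the product of a
round of random union of gametes from the (selection-weighted) parent pool.

Mating pools are either the whole population (``random`` mating) or closed
family groups (``inbred_small_family``), with offspring staying in their
parents' group; persistent small groups accumulate inbreeding at roughly
ΔF = 1/(2·(family_size + 1/2)) per generation.

Selection schemes give each locus a pass probability (p_hom for a
homozygous locus, p_het for heterozygous) and multiply across loci:
``mild_hom`` (0.60, 0.50), ``mild_het`` (0.20, 0.60), ``strong_het``
(0.00, 1.00), ``none`` (1, 1). Under ``strong_het`` a replicate fails if
fewer than two all-heterozygous candidates remain; failures are retried a
bounded number of times and otherwise reported as failed.

Ten variant types are allowed per locus and the ID space is shared across
loci — the same variant sequence can occur at any locus, which is exactly
why allelism cannot be recovered once locus labels are stripped. Initial
variant frequencies are either ``even`` (every variant at frequency 0.1 at
every locus) or ``uneven`` (per locus, integer weights drawn from a
unit-rate Poisson law, redrawn while all weights are zero, then normalized:
unequal proportions with the same mean proportion of 0.1, and usually a
few variants missing from a locus entirely).
"""
from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .genotypes import LocusGenotypeTable
from .loci import round_locus_estimate
from .preprocess import (
    REASON_NO_POPULATION_VARIATION,
    REASON_ZERO_HI_VARIANCE,
)

__all__ = [
    "MatingScheme",
    "Distribution",
    "SelectionScheme",
    "SELECTION_SCHEMES",
    "ScenarioConfig",
    "SimReplicate",
    "initial_frequencies",
    "init_population",
    "parent_acceptance_prob",
    "evolve",
    "full_grid",
    "run_sweep",
]

FLAG_OK = "ok"
FLAG_FAILED = "failed"

#: Rate of the integer-weight Poisson draws behind the uneven initial
#: variant distribution. Normalized weights keep a mean proportion of
#: 1/variants_per_locus whatever the rate; unit rate gives strongly unequal
#: proportions while leaving most loci polymorphic.
UNEVEN_POISSON_RATE = 1.0


class MatingScheme(str, enum.Enum):
    RANDOM = "random"
    INBRED_SMALL_FAMILY = "inbred_small_family"


class Distribution(str, enum.Enum):
    EVEN = "even"
    UNEVEN = "uneven"


@dataclass(frozen=True)
class SelectionScheme:
    """Per-locus reproduction pass probabilities, multiplied across loci."""

    name: str
    p_hom: float
    p_het: float


SELECTION_SCHEMES: dict[str, SelectionScheme] = {
    "none": SelectionScheme("none", 1.0, 1.0),
    "mild_hom": SelectionScheme("mild_hom", 0.60, 0.50),
    "mild_het": SelectionScheme("mild_het", 0.20, 0.60),
    "strong_het": SelectionScheme("strong_het", 0.00, 1.00),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``family_size`` only matters under ``inbred_small_family`` mating; the
    default of 8 makes persistent closed groups accumulate inbreeding at
    ΔF ≈ 1/17 per generation (1 − (1 − 1/17)^10 ≈ 0.45 after 10
    generations), and divides both default population sizes.
    """

    mating: MatingScheme = MatingScheme.RANDOM
    selection: str = "none"
    loci: int = 5
    distribution: Distribution = Distribution.EVEN
    generations: int = 10
    pop_size: int = 40
    variants_per_locus: int = 10
    family_size: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mating", MatingScheme(self.mating))
        object.__setattr__(self, "distribution", Distribution(self.distribution))
        if self.selection not in SELECTION_SCHEMES:
            raise InvalidInputError(
                f"unknown selection scheme {self.selection!r}; "
                f"choose from {sorted(SELECTION_SCHEMES)}"
            )
        if self.loci < 1:
            raise InvalidInputError("loci must be >= 1")
        if self.variants_per_locus < 2:
            raise InvalidInputError("variants_per_locus must be >= 2")
        if self.generations < 1:
            raise InvalidInputError("generations must be >= 1")
        if self.pop_size < 2:
            raise InvalidInputError("pop_size must be >= 2")
        if self.mating is MatingScheme.INBRED_SMALL_FAMILY:
            if self.selection != "none":
                raise InvalidInputError(
                    "inbred_small_family mating is not combined with selection"
                )
            if self.family_size < 2:
                raise InvalidInputError("family_size must be >= 2")
            if self.pop_size % self.family_size != 0:
                raise InvalidInputError(
                    f"pop_size {self.pop_size} must be divisible by "
                    f"family_size {self.family_size}"
                )

    @property
    def scheme(self) -> SelectionScheme:
        return SELECTION_SCHEMES[self.selection]


@dataclass(frozen=True)
class SimReplicate:
    """Outcome of one replicate: the final genotypes, or a failure flag."""

    config: ScenarioConfig
    replicate_index: int
    final_genotypes: LocusGenotypeTable | None
    failed: bool = False
    attempts: int = 1


class _ReplicateFailed(Exception):
    """Selection eliminated all candidate parent pairs in some mating pool."""


# ---------------------------------------------------------------------------
# initialization


def initial_frequencies(
    distribution: Distribution | str,
    variants_per_locus: int,
    rng: np.random.Generator,
    n_loci: int = 1,
) -> np.ndarray:
    """Per-locus initial variant frequency vectors, shape (n_loci, variants).

    ``even``: every variant at 1/variants_per_locus. ``uneven``: integer
    weights ~ Poisson(:data:`UNEVEN_POISSON_RATE`) per variant, a locus
    redrawn while all its weights are zero, then normalized — unequal
    proportions, often with some variants absent from a locus.
    """
    distribution = Distribution(distribution)
    if variants_per_locus < 2:
        raise InvalidInputError("variants_per_locus must be >= 2")
    if distribution is Distribution.EVEN:
        return np.full((n_loci, variants_per_locus), 1.0 / variants_per_locus)
    freqs = np.empty((n_loci, variants_per_locus))
    for j in range(n_loci):
        weights = rng.poisson(UNEVEN_POISSON_RATE, size=variants_per_locus)
        while not weights.any():
            weights = rng.poisson(UNEVEN_POISSON_RATE, size=variants_per_locus)
        freqs[j] = weights / weights.sum()
    return freqs


def _variant_labels(variants_per_locus: int) -> np.ndarray:
    """The shared variant ID space: ``V0`` .. ``V9`` at every locus."""
    return np.array(
        [f"V{k}" for k in range(variants_per_locus)], dtype=object
    )


def _init_alleles(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer allele array (N, L, 2); each copy drawn iid per locus."""
    freqs = initial_frequencies(
        config.distribution, config.variants_per_locus, rng, config.loci
    )
    n, L = config.pop_size, config.loci
    out = np.empty((n, L, 2), dtype=np.int64)
    for j in range(L):
        out[:, j, :] = rng.choice(
            config.variants_per_locus, size=(n, 2), p=freqs[j]
        )
    return out


def _to_table(config: ScenarioConfig, alleles: np.ndarray) -> LocusGenotypeTable:
    labels = _variant_labels(config.variants_per_locus)
    arr = labels[alleles]
    individuals = tuple(f"ind{i:04d}" for i in range(config.pop_size))
    loci = tuple(f"L{j:02d}" for j in range(config.loci))
    return LocusGenotypeTable(individuals, loci, arr)


def init_population(
    config: ScenarioConfig, rng: np.random.Generator
) -> LocusGenotypeTable:
    """Draw the founding generation from the initial frequency vectors."""
    return _to_table(config, _init_alleles(config, rng))


# ---------------------------------------------------------------------------
# selection and reproduction


def parent_acceptance_prob(
    genotypes: Sequence[tuple[object, object]] | np.ndarray,
    scheme: SelectionScheme,
) -> float:
    """Probability an individual is accepted as a parent when drawn.

    The product over loci of p_hom or p_het according to whether that locus
    is homozygous or heterozygous.
    """
    arr = np.asarray(genotypes)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("genotypes must be a sequence of allele pairs")
    het = arr[:, 0] != arr[:, 1]
    return float(
        np.prod(np.where(het, scheme.p_het, scheme.p_hom))
    )


def _acceptance_weights(alleles: np.ndarray, scheme: SelectionScheme) -> np.ndarray:
    het = alleles[:, :, 0] != alleles[:, :, 1]
    return np.prod(np.where(het, scheme.p_het, scheme.p_hom), axis=1)


def _draw_parent_pairs(
    weights: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
    offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two distinct parents per offspring, marginally ∝ acceptance weight.

    Drawing each parent independently with probability proportional to its
    acceptance weight, and redrawing pairs until the two differ, reproduces
    the distribution of rejection sampling (uniform draw, accept with the
    scheme's probability, distinct parents required).
    """
    total = weights.sum()
    if total == 0 or (weights > 0).sum() < 2:
        raise _ReplicateFailed
    p = weights / total
    n_pool = len(weights)
    fathers = rng.choice(n_pool, size=n_offspring, p=p)
    mothers = rng.choice(n_pool, size=n_offspring, p=p)
    clash = fathers == mothers
    while clash.any():
        mothers[clash] = rng.choice(n_pool, size=int(clash.sum()), p=p)
        clash = fathers == mothers
    return fathers + offset, mothers + offset


def _next_generation(
    alleles: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    n, L = alleles.shape[:2]
    if config.mating is MatingScheme.RANDOM:
        weights = _acceptance_weights(alleles, config.scheme)
        fathers, mothers = _draw_parent_pairs(weights, n, rng)
    else:
        # Persistent closed family groups: members i*fs..(i+1)*fs-1 form one
        # pool; each group produces its own replacement offspring.
        fs = config.family_size
        fathers = np.empty(n, dtype=np.int64)
        mothers = np.empty(n, dtype=np.int64)
        uniform = np.ones(fs)
        for g in range(n // fs):
            lo = g * fs
            f, m = _draw_parent_pairs(uniform, fs, rng, offset=lo)
            fathers[lo : lo + fs] = f
            mothers[lo : lo + fs] = m
    # One allele per locus from each parent, independently per locus
    # (unlinked loci, free recombination).
    pick_f = rng.integers(0, 2, size=(n, L))
    pick_m = rng.integers(0, 2, size=(n, L))
    loci_idx = np.arange(L)[None, :]
    out = np.empty_like(alleles)
    out[:, :, 0] = alleles[fathers[:, None], loci_idx, pick_f]
    out[:, :, 1] = alleles[mothers[:, None], loci_idx, pick_m]
    return out


def _evolve_alleles(
    config: ScenarioConfig, rng: np.random.Generator, max_attempts: int = 3
) -> tuple[np.ndarray | None, int]:
    """Run one replicate; returns (final alleles or None if failed, attempts)."""
    for attempt in range(1, max_attempts + 1):
        alleles = _init_alleles(config, rng)
        try:
            for _ in range(config.generations):
                alleles = _next_generation(alleles, config, rng)
        except _ReplicateFailed:
            continue
        return alleles, attempt
    return None, max_attempts


def evolve(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    max_attempts: int = 3,
) -> SimReplicate:
    """Simulate one replicate of a scenario.

    A replicate fails (after ``max_attempts`` fresh restarts) when selection
    leaves fewer than two acceptable parents in some mating pool — e.g.
    strong heterozygote selection once a locus has drifted to fixation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alleles, attempts = _evolve_alleles(config, rng, max_attempts)
    if alleles is None:
        return SimReplicate(config, 0, None, failed=True, attempts=attempts)
    return SimReplicate(config, 0, _to_table(config, alleles), attempts=attempts)


# ---------------------------------------------------------------------------
# fast per-replicate statistics on integer allele arrays


def _fis_int(alleles: np.ndarray) -> float:
    """Multiple F_IS from an integer allele array; NaN if all loci monomorphic."""
    n, L = alleles.shape[:2]
    values = []
    for j in range(L):
        copies = alleles[:, j, :].ravel()
        counts = np.bincount(copies)
        props = counts[counts > 0] / (2 * n)
        he = 1.0 - float((props**2).sum())
        if he == 0:
            continue
        ho = float(np.mean(alleles[:, j, 0] != alleles[:, j, 1]))
        values.append((he - ho) / he)
    return float(np.mean(values)) if values else float("nan")


def _profile_matrix(alleles: np.ndarray, variants_per_locus: int) -> np.ndarray:
    """Per-individual allele-copy counts over the shared variant ID space
    (copies of the same variant at different loci pool together);
    shape (N, variants_per_locus)."""
    n, L = alleles.shape[:2]
    flat = (np.arange(n)[:, None] * variants_per_locus
            + alleles.reshape(n, 2 * L)).ravel()
    return np.bincount(flat, minlength=n * variants_per_locus).reshape(
        n, variants_per_locus
    )


def _his_summary(counts: np.ndarray) -> dict:
    """H̄_I¹, H_S¹, V, EV, one-individual L estimate and ¹H_IS (raw) from a
    per-individual count matrix; mirrors the public profile-based path
    (proportion-based one-individual estimator: L̂ is the largest
    1/(2·smallest within-individual proportion), which recovers the true L
    whenever some individual carries a single copy of some variant)."""
    row_tot = counts.sum(axis=1, keepdims=True)
    p_ind = counts / row_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p_ind > 0, -p_ind * np.log(p_ind), 0.0)
    h_i = terms.sum(axis=1)
    h_bar = float(h_i.mean())
    p_pop = p_ind.mean(axis=0)
    pos = p_pop[p_pop > 0]
    h_s = float(-(pos * np.log(pos)).sum())
    v = int(pos.size)
    out = {
        "h_bar": h_bar,
        "h_s": h_s,
        "n_variants": v,
        "hi_variance": float(np.var(h_i)),
    }
    if v >= 2:
        ev = h_s / np.log(v)
        min_pos = np.where(counts > 0, counts, np.inf).min(axis=1)
        raw = float((counts.sum(axis=1) / (2.0 * min_pos)).max())
        loci_est = round_locus_estimate(raw)
        out["evenness"] = ev
        out["loci_est"] = loci_est
        out["his"] = float(-(h_bar * (loci_est + 1) / h_s - loci_est) * ev)
    else:
        out["evenness"] = float("nan")
        out["loci_est"] = 0
        out["his"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# the scenario sweep


def full_grid(
    loci: Sequence[int] = (3, 5, 10),
    distributions: Sequence[str] = ("even", "uneven"),
    generations: Sequence[int] = (10, 30, 50),
    pop_sizes: Sequence[int] = (40, 400),
) -> list[ScenarioConfig]:
    """The full scenario grid: 5 mating/selection schemes (random or inbred
    small-family mating without selection, plus the three selection schemes
    under random mating) × loci × distributions × generations × population
    sizes — 180 scenarios at the default axes."""
    schemes = [
        (MatingScheme.RANDOM, "none"),
        (MatingScheme.INBRED_SMALL_FAMILY, "none"),
        (MatingScheme.RANDOM, "mild_hom"),
        (MatingScheme.RANDOM, "mild_het"),
        (MatingScheme.RANDOM, "strong_het"),
    ]
    grid = []
    for (mating, selection), L, dist, gens, n in itertools.product(
        schemes, loci, distributions, generations, pop_sizes
    ):
        grid.append(
            ScenarioConfig(
                mating=mating,
                selection=selection,
                loci=L,
                distribution=dist,
                generations=gens,
                pop_size=n,
            )
        )
    return grid


def run_sweep(
    grid: Sequence[ScenarioConfig] | None = None,
    replicates: int = 10,
    seed: int = 0,
    hi_variance_tol: float = 1e-12,
    max_attempts: int = 3,
) -> pd.DataFrame:
    """Simulate every scenario × replicate and pair F_IS with ¹H_IS.

    For each replicate the classical multiple F_IS is computed from the true
    allelism, the genotypes are stripped of locus information, the number of
    loci is re-estimated by the one-individual method, and ¹H_IS is computed
    from the resulting variant profiles. Degenerate replicates (no
    population variation, or no between-individual H_I¹ variance) and failed
    replicates are carried with flags, not dropped.

    One independent random stream is derived per (scenario, replicate) from
    the master seed, so results are reproducible and order-independent.
    """
    if grid is None:
        grid = full_grid()
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    rows = []
    for si, config in enumerate(grid):
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(si, rep))
            )
            alleles, attempts = _evolve_alleles(config, rng, max_attempts)
            row = {
                "mating": config.mating.value,
                "selection": config.selection,
                "loci": config.loci,
                "distribution": config.distribution.value,
                "generations": config.generations,
                "pop_size": config.pop_size,
                "replicate": rep,
                "fis": float("nan"),
                "his": float("nan"),
                "h_bar": float("nan"),
                "h_s": float("nan"),
                "evenness": float("nan"),
                "loci_est": 0,
                "flag": FLAG_OK,
                "attempts": attempts,
            }
            if alleles is None:
                row["flag"] = FLAG_FAILED
            else:
                counts = _profile_matrix(alleles, config.variants_per_locus)
                summary = _his_summary(counts)
                row["h_bar"] = summary["h_bar"]
                row["h_s"] = summary["h_s"]
                row["evenness"] = summary["evenness"]
                row["loci_est"] = summary["loci_est"]
                row["his"] = summary["his"]
                row["fis"] = _fis_int(alleles)
                if summary["n_variants"] < 2:
                    row["flag"] = REASON_NO_POPULATION_VARIATION
                elif summary["hi_variance"] <= hi_variance_tol:
                    row["flag"] = REASON_ZERO_HI_VARIANCE
            rows.append(row)
    return pd.DataFrame(rows)
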