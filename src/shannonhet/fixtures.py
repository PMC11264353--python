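"""Deterministic toy datasets exercising the package's edge behaviours.

Each kind writes small delimited-text files (genotypes and/or variant
counts, or a sweep configuration) to a directory:

- ``hw_equilibrium``: genotypes drawn under Hardy–Weinberg equilibrium.
- ``all_hom_distinct``: every individual homozygous, different individuals
  fixed for different variants (heterozygote deficit: F_IS = +1, ¹H_IS > 0).
- ``identical_het``: every individual the same A/B heterozygote
  (heterozygote excess: F_IS = −1, ¹H_IS = −1).
- ``locus_specific_fixation``: each of four loci fixed for its own variant
  (C1C1;C2C2;C3C3;C4C4) — F_IS undefined, ¹H_IS = −1.
- ``sweep_mini``: a 2-scenario, 5-replicate YAML sweep configuration.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .genotypes import LocusGenotypeTable
from .io import write_genotypes, write_variant_counts
from .preprocess import genotypes_to_profiles

__all__ = ["FIXTURE_KINDS", "generate_fixtures"]

FIXTURE_KINDS = (
    "hw_equilibrium",
    "all_hom_distinct",
    "identical_het",
    "locus_specific_fixation",
    "sweep_mini",
)

_SWEEP_MINI = """\
# A tiny sweep: one neutral and one inbred scenario, 5 replicates each.
replicates: 5
seed: {seed}
scenarios:
  - {{mating: random, selection: none, loci: 5, distribution: even,
     generations: 10, pop_size: 40}}
  - {{mating: inbred_small_family, selection: none, loci: 5, distribution: even,
     generations: 10, pop_size: 40}}
"""


def _table_from_grid(alleles: np.ndarray) -> LocusGenotypeTable:
    n, L = alleles.shape[:2]
    return LocusGenotypeTable(
        tuple(f"ind{i:03d}" for i in range(n)),
        tuple(f"L{j}" for j in range(L)),
        alleles.astype(object),
    )


def generate_fixtures(kind: str, seed: int = 0, out_dir: str | Path = ".") -> list[Path]:
    """Write the fixture files for ``kind``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"fixture_kind": kind, "seed": seed}
    if kind == "sweep_mini":
        path = out_dir / "sweep_mini.yaml"
        path.write_text(_SWEEP_MINI.format(seed=seed))
        return [path]

    if kind == "hw_equilibrium":
        rng = np.random.default_rng(seed)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        alleles = np.empty((24, 3, 2), dtype=object)
        for j in range(3):
            draws = rng.choice(4, size=(24, 2), p=freqs)
            alleles[:, j, :] = np.array(
                [[f"L{j}.A{a}" for a in pair] for pair in draws], dtype=object
            )
        table = _table_from_grid(alleles)
    elif kind == "all_hom_distinct":
        # one locus; individual i homozygous for variant A{i % 4}
        alleles = np.array(
            [[[f"A{i % 4}", f"A{i % 4}"]] for i in range(12)], dtype=object
        )
        table = _table_from_grid(alleles)
    elif kind == "identical_het":
        alleles = np.array([[["A", "B"]] for _ in range(12)], dtype=object)
        table = _table_from_grid(alleles)
    elif kind == "locus_specific_fixation":
        alleles = np.array(
            [[[f"C{j + 1}", f"C{j + 1}"] for j in range(4)] for _ in range(10)],
            dtype=object,
        )
        table = _table_from_grid(alleles)
    else:
        raise InvalidInputError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )

    geno_path = out_dir / f"{kind}.genotypes.tsv"
    counts_path = out_dir / f"{kind}.counts.tsv"
    write_genotypes(table, geno_path, meta)
    write_variant_counts(genotypes_to_profiles(table), counts_path, meta)
    return [geno_path, counts_path]
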