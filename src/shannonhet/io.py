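"""Delimited-text input and output.

Variant counts travel as TSV/CSV in wide form (row = individual, column =
variant ID, cell = count) or long form (individual, variant, count);
genotypes as four columns (individual, locus, allele1, allele2); scenario
grids as YAML. Output tables are TSV with ``#``-prefixed metadata lines
(version, seed, parameters) ahead of the header. Readers reject malformed
input with file/line context rather than coercing it.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParseError
from .genotypes import LocusGenotypeTable
from .profiles import PoolingMode, PopulationProfile, VariantProfile
from .simulate import ScenarioConfig

__all__ = [
    "read_variant_counts",
    "write_variant_counts",
    "read_genotypes",
    "write_genotypes",
    "read_scenario_grid",
    "write_table",
    "read_table",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


def _parse_count(raw: str, path: Path, line: int, what: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"{path}:{line}: {what} {raw!r} is not a number") from None
    if not np.isfinite(value) or value < 0:
        raise ParseError(f"{path}:{line}: {what} must be nonnegative, got {raw!r}")
    return value


def read_variant_counts(
    path: str | Path,
    dialect: str = "wide",
    pooling_mode: PoolingMode | str = PoolingMode.MEAN_OF_PROPORTIONS,
) -> PopulationProfile:
    """Read a variant-count table into a population of profiles.

    ``wide``: first column holds individual IDs, remaining columns are
    variant IDs. ``long``: columns individual, variant, count; duplicate
    (individual, variant) rows are an error. Zero and empty cells drop out.
    """
    path = Path(path)
    frame = _read_frame(path)
    if dialect not in {"wide", "long"}:
        raise ParseError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    profiles: list[VariantProfile] = []
    if dialect == "wide":
        if frame.shape[1] < 2:
            raise ParseError(f"{path}: wide table needs an ID column plus variants")
        id_col = frame.columns[0]
        for row_no, row in enumerate(frame.itertuples(index=False), start=2):
            counts = {}
            for variant, raw in zip(frame.columns[1:], row[1:]):
                if pd.isna(raw) or raw == "":
                    continue
                value = _parse_count(raw, path, row_no, f"count for {variant!r}")
                if value > 0:
                    counts[variant] = value
            if not counts:
                raise ParseError(
                    f"{path}:{row_no}: individual {row[0]!r} has no positive count"
                )
            profiles.append(VariantProfile(str(row[0]), counts))
    else:
        needed = {"individual", "variant", "count"}
        if not needed.issubset(frame.columns):
            raise ParseError(
                f"{path}: long table needs columns {sorted(needed)}, "
                f"found {list(frame.columns)}"
            )
        seen: dict[str, dict[str, float]] = {}
        order: list[str] = []
        for row_no, row in enumerate(frame.itertuples(index=False), start=2):
            ind, variant = str(row.individual), str(row.variant)
            value = _parse_count(row.count, path, row_no, "count")
            bucket = seen.setdefault(ind, {})
            if ind not in order:
                order.append(ind)
            if variant in bucket:
                raise ParseError(
                    f"{path}:{row_no}: duplicate entry for ({ind!r}, {variant!r})"
                )
            if value > 0:
                bucket[variant] = value
        for ind in order:
            if not seen[ind]:
                raise ParseError(f"{path}: individual {ind!r} has no positive count")
            profiles.append(VariantProfile(ind, seen[ind]))
    return PopulationProfile(profiles, pooling_mode)


def write_variant_counts(
    population: PopulationProfile, path: str | Path, metadata: Mapping | None = None
) -> None:
    """Write a population as a wide TSV/CSV count table."""
    path = Path(path)
    variants = sorted({v for p in population for v in p.counts})
    rows = [
        {"individual": p.individual_id, **{v: p.counts.get(v, 0) for v in variants}}
        for p in population
    ]
    write_table(pd.DataFrame(rows), path, metadata)


def read_genotypes(path: str | Path) -> LocusGenotypeTable:
    """Read (individual, locus, allele1, allele2) records into a table."""
    path = Path(path)
    frame = _read_frame(path)
    needed = ["individual", "locus", "allele1", "allele2"]
    if list(frame.columns[:4]) != needed:
        raise ParseError(
            f"{path}: genotype table needs columns {needed}, found "
            f"{list(frame.columns)}"
        )
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}:{bad}: missing value in genotype row")
    try:
        return LocusGenotypeTable.from_records(
            frame[needed].itertuples(index=False, name=None)
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genotypes(
    table: LocusGenotypeTable, path: str | Path, metadata: Mapping | None = None
) -> None:
    frame = pd.DataFrame(
        table.to_records(), columns=["individual", "locus", "allele1", "allele2"]
    )
    write_table(frame, path, metadata)


def read_scenario_grid(path: str | Path) -> tuple[list[ScenarioConfig], dict]:
    """Read a YAML scenario grid: a list of scenario mappings plus top-level
    ``replicates`` and ``seed``. Returns (configs, {replicates, seed})."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, Mapping) or "scenarios" not in doc:
        raise ParseError(f"{path}: expected a mapping with a 'scenarios' list")
    configs = [ScenarioConfig(**sc) for sc in doc["scenarios"]]
    meta = {
        "replicates": int(doc.get("replicates", 10)),
        "seed": int(doc.get("seed", 0)),
    }
    return configs, meta


def write_table(
    frame: pd.DataFrame, path: str | Path, metadata: Mapping | None = None
) -> None:
    """Write a TSV/CSV with ``#`` metadata lines before the header."""
    path = Path(path)
    meta = {"shannonhet_version": __version__, **(metadata or {})}
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key} = {value}\n")
    frame.to_csv(buf, sep=_sep_for(path), index=False)
    path.write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (metadata skipped)."""
    return pd.read_csv(Path(path), sep=_sep_for(Path(path)), comment="#")
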