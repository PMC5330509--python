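"""Readers and writers for the pipeline's delimited-text interchange formats.

All tables are UTF-8 comma-separated files with a header row; per-mil values
are plain decimals.  Trees are Newick.  Every writer/reader pair round-trips
value-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CaptureRecords,
    DietTable,
    DistanceMatrix,
    IsotopeMeasurement,
    Phylogeny,
    TrapHabitatTable,
    TrophicCoding,
    validate_measurements,
)
from .errors import ParseError, SchemaError

__all__ = [
    "read_isotope_table",
    "write_isotope_table",
    "read_diet_table",
    "write_diet_table",
    "read_trophic_coding",
    "write_trophic_coding",
    "read_habitat_table",
    "write_habitat_table",
    "read_captures",
    "write_captures",
    "read_newick",
    "write_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_run_report",
]

#: default column names for isotope tables; override via ``schema``
DEFAULT_ISOTOPE_SCHEMA = {
    "specimen_id": "specimen_id",
    "species": "species",
    "site": "site",
    "d13C": "d13C",
    "d15N": "d15N",
}


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # parse with Python's float() for exact (correctly rounded) round-trips
    out = np.empty(len(df))
    for i, raw in enumerate(df[col]):
        try:
            v = float(raw)
        except (TypeError, ValueError):
            v = float("nan")
        if not np.isfinite(v):
            raise ParseError(
                f"{path}: column {col!r} has a non-numeric value {raw!r} "
                f"at line {i + 2}"  # 1-based + header row
            )
        out[i] = v
    return out


def read_isotope_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[IsotopeMeasurement]:
    """Read per-individual isotope measurements from CSV.

    ``schema`` maps the five required fields (specimen_id, species, site,
    d13C, d15N) to the file's actual column names, so field tables with
    arbitrary headers can be ingested without editing the file.
    """
    colmap = dict(DEFAULT_ISOTOPE_SCHEMA)
    if schema:
        unknown = set(schema) - set(colmap)
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, list(colmap.values()), path)
    d13C = _numeric_column(df, colmap["d13C"], path)
    d15N = _numeric_column(df, colmap["d15N"], path)
    records = [
        IsotopeMeasurement(
            specimen_id=str(df[colmap["specimen_id"]].iloc[i]).strip(),
            species=str(df[colmap["species"]].iloc[i]).strip(),
            site=str(df[colmap["site"]].iloc[i]).strip(),
            d13C=float(d13C[i]),
            d15N=float(d15N[i]),
        )
        for i in range(len(df))
    ]
    validate_measurements(records)
    return records


def write_isotope_table(measurements: Sequence[IsotopeMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "specimen_id": [m.specimen_id for m in measurements],
            "species": [m.species for m in measurements],
            "site": [m.site for m in measurements],
            "d13C": [repr(m.d13C) for m in measurements],
            "d15N": [repr(m.d15N) for m in measurements],
        }
    )
    df.to_csv(path, index=False)


def read_diet_table(path: str | Path) -> DietTable:
    """Wide CSV: species, n, then one column per prey category."""
    df = pd.read_csv(path)
    _require_columns(df, ["species"], path)
    df = df.set_index("species")
    return DietTable.from_frame(df)


def write_diet_table(table: DietTable, path: str | Path) -> None:
    table.to_frame().to_csv(path)


def read_trophic_coding(path: str | Path) -> TrophicCoding:
    df = pd.read_csv(path)
    _require_columns(df, ["category", "rank"], path)
    ranks = _numeric_column(df, "rank", path)
    return TrophicCoding(dict(zip(df["category"].astype(str).str.strip(), ranks)))


def write_trophic_coding(coding: TrophicCoding, path: str | Path) -> None:
    pd.DataFrame(
        {"category": list(coding.category_rank), "rank": list(coding.category_rank.values())}
    ).to_csv(path, index=False)


def read_habitat_table(path: str | Path) -> TrapHabitatTable:
    df = pd.read_csv(path, dtype={"trap_id": str})
    _require_columns(df, ["trap_id"], path)
    for col in df.columns:
        if col != "trap_id":
            _numeric_column(df, col, path)
    return TrapHabitatTable(df)


def write_habitat_table(table: TrapHabitatTable, path: str | Path) -> None:
    table.frame.to_csv(path)


def read_captures(path: str | Path) -> CaptureRecords:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["species", "trap_id"], path)
    return CaptureRecords(df)


def write_captures(captures: CaptureRecords, path: str | Path) -> None:
    captures.frame.to_csv(path, index=False)


def read_newick(path: str | Path) -> Phylogeny:
    """Read one Newick tree with branch lengths; ultrametricity is checked and
    reported via :meth:`Phylogeny.is_ultrametric`, not enforced."""
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylogeny.to_newick() + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def write_run_report(path: str | Path, *, config, seed: int, extra: dict | None = None) -> None:
    """Record seed, configuration and package version alongside results so a
    permutation p-value can always be regenerated."""
    from . import __version__

    report = {
        "package": "isotroph",
        "version": __version__,
        "seed": int(seed),
        "config": config.to_dict() if hasattr(config, "to_dict") else dict(config),
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
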