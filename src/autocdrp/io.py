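"""On-disk formats: SMILES drug tables, binary cell-feature matrices,
response tables, and JSON for descriptors, graphs and reports.

CSV is the canonical table dialect; TSV is accepted via the dialect flag.
All loaders raise typed errors on malformed input — there are no partial
silent results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .codec import ArchitectureGraph
from .model import (
    ATOM_SYMBOLS,
    DRUG_FEATURE_DIM,
    CellLineProfile,
    DrugGraph,
    ResponseRecord,
    pair_accounting,
)
from .space import ArchitectureDescriptor, SearchSpace

__all__ = [
    "TableDialect", "smiles_to_drug_graph", "load_drug_table",
    "load_response_table", "load_cell_matrix", "write_response_table",
    "write_cell_matrix", "write_drug_table", "load_descriptor",
    "save_descriptor", "save_graph",
]


class DataFormatError(ValueError):
    """Raised for any malformed on-disk input."""


@dataclass(frozen=True)
class TableDialect:
    delimiter: Literal[",", "\t"] = ","
    header: bool = True
    drug_id_column: str = "drug_id"
    cell_id_column: str = "cell_id"
    response_column: str = "ln_ic50"
    encoding: str = "utf-8"


DEFAULT_DIALECT = TableDialect()


# ---------------------------------------------------------------------------
# Molecular featurization


def _one_hot(value, choices: Sequence) -> list[float]:
    if value not in choices:
        value = choices[-1]
    return [1.0 if value == c else 0.0 for c in choices]


def _atom_features(atom: Chem.Atom) -> list[float]:
    return (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetTotalNumHs(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(11)))
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )


def smiles_to_drug_graph(smiles: str, drug_id: str | None = None) -> DrugGraph:
    """Parse a SMILES string into a molecular DrugGraph with the 78-D atom
    featurization (symbol, degree, total Hs, implicit valence, aromaticity)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataFormatError(f"unparsable SMILES: {smiles!r}")
    feats = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    if feats.size == 0:
        raise DataFormatError(f"SMILES {smiles!r} has no atoms")
    assert feats.shape[1] == DRUG_FEATURE_DIM
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges += [(i, j), (j, i)]
    return DrugGraph(drug_id=drug_id or smiles, node_features=feats, edges=edges)


# ---------------------------------------------------------------------------
# Tables


def _read(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=dialect.delimiter, encoding=dialect.encoding,
                           header=0 if dialect.header else None)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc


def load_drug_table(path: str | Path,
                    dialect: TableDialect = DEFAULT_DIALECT) -> list[DrugGraph]:
    """Load a (drug_id, smiles) CSV into DrugGraphs; duplicate or missing
    drug ids are rejected."""
    df = _read(path, dialect)
    for col in (dialect.drug_id_column, "smiles"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    if df[dialect.drug_id_column].isna().any():
        raise DataFormatError(f"{path}: missing drug id")
    ids = df[dialect.drug_id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise DataFormatError(f"{path}: duplicate drug ids {dupes}")
    return [
        smiles_to_drug_graph(str(row["smiles"]), str(row[dialect.drug_id_column]))
        for _, row in df.iterrows()
    ]


def load_response_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> tuple[list[ResponseRecord], dict]:
    """Load a (drug_id, cell_id, ln_ic50) table. Rows with missing response
    are dropped and counted; duplicate (drug, cell) pairs are an error.
    Returns the records plus an accounting summary (pairs observed/dropped,
    and the drug x cell pair accounting)."""
    df = _read(path, dialect)
    cols = (dialect.drug_id_column, dialect.cell_id_column, dialect.response_column)
    for col in cols:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    n_total = len(df)
    df = df.dropna(subset=[dialect.response_column])
    n_dropped = n_total - len(df)
    pairs = df[[dialect.drug_id_column, dialect.cell_id_column]].astype(str)
    dup_mask = pairs.duplicated()
    if dup_mask.any():
        first = pairs[dup_mask].iloc[0]
        raise DataFormatError(
            f"{path}: duplicate (drug, cell) pair "
            f"({first.iloc[0]!r}, {first.iloc[1]!r})"
        )
    records = [
        ResponseRecord(
            str(row[dialect.drug_id_column]),
            str(row[dialect.cell_id_column]),
            float(row[dialect.response_column]),
        )
        for _, row in df.iterrows()
    ]
    n_drugs = pairs[dialect.drug_id_column].nunique()
    n_cells = pairs[dialect.cell_id_column].nunique()
    summary = {
        "n_records": len(records),
        "n_dropped": n_dropped,
        "n_drugs": int(n_drugs),
        "n_cells": int(n_cells),
        **pair_accounting(int(n_drugs), int(n_cells), len(records)),
    }
    return records, summary


def load_cell_matrix(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[CellLineProfile]:
    """Load a cell-feature matrix (cell_id column + binary feature columns).
    Any non-binary entry is an error reported with its coordinates."""
    df = _read(path, dialect)
    if dialect.cell_id_column not in df.columns:
        raise DataFormatError(f"{path}: missing column {dialect.cell_id_column!r}")
    feature_cols = [c for c in df.columns if c != dialect.cell_id_column]
    if not feature_cols:
        raise DataFormatError(f"{path}: no feature columns")
    values = df[feature_cols].to_numpy()
    try:
        values = values.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: non-numeric feature entry: {exc}") from exc
    bad = ~np.isin(values, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataFormatError(
            f"{path}: non-binary entry {values[r, c]!r} at row "
            f"{df.index[r]}, column {feature_cols[c]!r}"
        )
    return [
        CellLineProfile(str(df.iloc[i][dialect.cell_id_column]), values[i])
        for i in range(len(df))
    ]


# ---------------------------------------------------------------------------
# Writers


def write_response_table(records: Sequence[ResponseRecord], path: str | Path,
                         dialect: TableDialect = DEFAULT_DIALECT) -> None:
    pd.DataFrame(
        {
            dialect.drug_id_column: [r.drug_id for r in records],
            dialect.cell_id_column: [r.cell_id for r in records],
            dialect.response_column: [r.ln_ic50 for r in records],
        }
    ).to_csv(path, sep=dialect.delimiter, index=False)


def write_cell_matrix(cells: Sequence[CellLineProfile], path: str | Path,
                      dialect: TableDialect = DEFAULT_DIALECT) -> None:
    dim = len(cells[0].features)
    df = pd.DataFrame(
        np.vstack([c.features for c in cells]).astype(int),
        columns=[f"f{i}" for i in range(dim)],
    )
    df.insert(0, dialect.cell_id_column, [c.cell_id for c in cells])
    df.to_csv(path, sep=dialect.delimiter, index=False)


def write_drug_table(drug_smiles: dict, path: str | Path,
                     dialect: TableDialect = DEFAULT_DIALECT) -> None:
    pd.DataFrame(
        {dialect.drug_id_column: list(drug_smiles), "smiles": list(drug_smiles.values())}
    ).to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# JSON objects


def save_descriptor(descriptor: ArchitectureDescriptor, path: str | Path) -> None:
    Path(path).write_text(json.dumps(descriptor.to_json(), indent=2))


def load_descriptor(path: str | Path, space: SearchSpace) -> ArchitectureDescriptor:
    return ArchitectureDescriptor.from_json(
        json.loads(Path(path).read_text()), space
    )


def save_graph(graph: ArchitectureGraph, path: str | Path) -> None:
    """JSON serialization; edge-list TSV and feature CSV siblings are written
    alongside for inspection."""
    p = Path(path)
    p.write_text(json.dumps(graph.to_json(), indent=2))
    edge_path = p.with_suffix(".edges.tsv")
    edge_path.write_text(
        "\n".join(f"{s}\t{d}" for s, d in graph.edges) + ("\n" if graph.edges else "")
    )
    np.savetxt(p.with_suffix(".features.csv"), graph.features, fmt="%d",
               delimiter=",")
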