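"""Text I/O: expression matrices, ranked-signature tables, config files.

File dialect: UTF-8, tab-delimited, '.' decimal separator.  An expression
matrix file has assay identifiers in the header row (the top-left header
cell is ignored) and gene identifiers in the first column.  Values are
serialized with 15 significant digits so a write/read round trip is
lossless at double precision for practical purposes.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ExpressionMatrix,
    ParseError,
    RunConfig,
    ShapeError,
    ValidationError,
)
from .signature import RankedSignature
from .simulate import SimulationConfig

FLOAT_FORMAT = "%.15g"


def read_expression_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Row 1 holds assay identifiers, column 1 gene identifiers; every other
    cell must parse as a finite real.  ``transpose=True`` swaps the roles
    (for files stored one assay per row).
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ShapeError(
            f"{path}: need at least 2 gene rows and 2 assay columns, got {df.shape}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate row identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate column identifier {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: cell ({df.index[i]!r}, {df.columns[j]!r}) = "
            f"{df.iat[i, j]!r} is not a finite number"
        )
    x = ExpressionMatrix(
        numeric.to_numpy(dtype=float), tuple(df.index), tuple(df.columns)
    )
    return x.transposed() if transpose else x


def write_expression_matrix(x: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the same tab-delimited dialect (header cell 'gene_id')."""
    df = pd.DataFrame(x.values, index=list(x.gene_ids), columns=list(x.assay_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_ranked_table(result: RankedSignature, path: str | Path) -> None:
    """Write rank, gene_id, statistic_value, in_signature (0/1) per gene."""
    m = result.m
    df = pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "gene_id": list(result.gene_order),
            "statistic_value": result.ranked_values,
            "in_signature": (np.arange(m) < result.cutoff).astype(int),
        }
    )
    if result.p_values is not None:
        df["p_value"] = result.p_values
        df["q_value"] = result.q_values
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    """Read a ranked-signature table back as a DataFrame (for round trips)."""
    return pd.read_csv(path, sep="\t")


def _config_from_mapping(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a plain-text key/value (YAML) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _config_from_mapping(RunConfig, data)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a plain-text key/value (YAML) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _config_from_mapping(SimulationConfig, data)
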