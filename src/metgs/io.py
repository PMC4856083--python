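"""Delimited-text readers and writers for phenotypes, genotypes and results.

Phenotype tables are CSV with header columns trial, line, block, row, col,
y (missing responses as empty cells or NA).  Genotype tables are CSV with
the line identifier in the first column and one column per marker, calls
coded 0 (homozygous minor), 2 (homozygous major), 1 (heterozygous) and
empty/NA for missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geno_prep import MarkerMatrix, RawGenotypes
from .met_design import REQUIRED_COLUMNS, MetDataset

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_marker_matrix",
]


def read_phenotypes(path) -> MetDataset:
    """Read an observation-level phenotype CSV into a MetDataset."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = pd.to_numeric(df["y"], errors="coerce").isna() & df["y"].notna()
    bad &= ~df["y"].astype(str).str.strip().str.upper().isin(("NA", "NAN", ""))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-numeric response at data line {i + 2}")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    return MetDataset(df[list(REQUIRED_COLUMNS)])


def write_phenotypes(data: MetDataset, path) -> None:
    data.records[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def read_genotypes(path) -> RawGenotypes:
    """Read a lines × markers genotype CSV into RawGenotypes."""
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    calls = df.to_numpy(dtype=float)
    return RawGenotypes(calls, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_marker_matrix(m: MarkerMatrix, path) -> None:
    pd.DataFrame(m.M.astype(int), index=m.line_ids, columns=m.marker_ids).to_csv(
        path, index_label="line"
    )


def read_marker_matrix(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )
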