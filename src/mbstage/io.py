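"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (genes as rows, header = sample ids) or as
MatrixMarket triplets with separate row/column index files; gene sets as GMT;
labels, arm-status and score tables as TSV; spatial sections as CSV with
``spot_id, x, y`` followed by one column per peak or metabolite.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


# ---------------------------------------------------------------- TSV tables

def write_expression_tsv(path: str, expression: pd.DataFrame) -> None:
    """Write a genes x samples matrix as TSV (genes as rows)."""
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels_tsv(path: str, labels: pd.Series, value_name: str = "label") -> None:
    labels.rename(value_name).to_csv(path, sep="\t", index_label="id")


def read_labels_tsv(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_arm_status_tsv(path: str, arm_status: pd.DataFrame) -> None:
    """Samples x chromosome arms, values in {loss, neutral, gain}."""
    arm_status.to_csv(path, sep="\t", index_label="sample")


def read_arm_status_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = set(np.unique(df.to_numpy())) - {"loss", "neutral", "gain"}
    if bad:
        raise ValueError(f"arm status values outside loss/neutral/gain: {sorted(bad)}")
    return df


# ----------------------------------------------------------------------- MTX

def write_cells_mtx(prefix: str, matrix: pd.DataFrame) -> None:
    """Write a cells x genes matrix as MTX plus row/column index files.

    Creates ``<prefix>.mtx``, ``<prefix>.rows.tsv`` (cell ids) and
    ``<prefix>.cols.tsv`` (gene names).
    """
    scipy.io.mmwrite(prefix + ".mtx", scipy.sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index).to_csv(prefix + ".rows.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.columns).to_csv(prefix + ".cols.tsv", sep="\t", index=False, header=False)


def read_cells_mtx(prefix: str) -> pd.DataFrame:
    mat = scipy.io.mmread(prefix + ".mtx").toarray()
    rows = pd.read_csv(prefix + ".rows.tsv", sep="\t", header=None).iloc[:, 0].tolist()
    cols = pd.read_csv(prefix + ".cols.tsv", sep="\t", header=None).iloc[:, 0].tolist()
    return pd.DataFrame(mat, index=rows, columns=cols)


# ----------------------------------------------------------------------- GMT

def write_gmt(path: str, sets: Mapping[str, Sequence[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = fields[2:]
    return sets


def read_gmt_descriptions(path: str) -> dict[str, str]:
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2:
                desc[fields[0]] = fields[1]
    return desc


def read_gene_list(path: str) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


# ------------------------------------------------------------- section CSVs

def write_section_csv(path: str, coords: pd.DataFrame, intensities: pd.DataFrame) -> None:
    """columns: spot_id, x, y, then one column per metabolite/peak."""
    if not coords.index.equals(intensities.index):
        raise ValueError("coords and intensities must share the spot index")
    out = pd.concat([coords[["x", "y"]], intensities], axis=1)
    out.to_csv(path, index_label="spot_id")


def read_section_csv(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, index_col=0)
    coords = df[["x", "y"]]
    intensities = df.drop(columns=["x", "y"])
    return coords, intensities


def read_metabolite_reference_csv(path: str) -> pd.DataFrame:
    """Metabolite reference list: columns ``name`` and ``mz``."""
    df = pd.read_csv(path)
    if not {"name", "mz"}.issubset(df.columns):
        raise ValueError("metabolite reference CSV needs 'name' and 'mz' columns")
    if df["name"].duplicated().any():
        raise ValueError("duplicate metabolite names in reference")
    if (df["mz"] <= 0).any():
        raise ValueError("theoretical m/z must be positive")
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
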