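"""Plain-text readers/writers for the pipeline's tabular formats.

Matrices are TSV with features as rows and a header row of sample ids;
designs and probe annotations are TSV; gene annotation is BED6 (0-based
half-open).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import DESIGN_COLUMNS

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design file {path} lacks columns {missing}")
    return design


def read_mask(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def read_probe_annot(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", index_col=0)
    if "location_class" not in annot.columns:
        raise ValueError(f"probe annotation {path} lacks a location_class column")
    return annot


def read_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return bed


def read_truth(path: str | Path) -> pd.DataFrame:
    """Long truth TSV (feature, day, effect) -> wide feature x day frame."""
    long = pd.read_csv(path, sep="\t")
    feature_col = long.columns[0]
    wide = long.pivot(index=feature_col, columns="day", values="effect")
    wide.columns = [int(c) for c in wide.columns]
    return wide
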