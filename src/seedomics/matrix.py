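"""Core containers: abundance matrices and the sample design table.

An :class:`AbundanceMatrix` is a features x samples table of numeric
abundances.  RNA matrices hold log2 gene-level abundances and must be
complete; protein matrices arrive on linear scale (summed peptide
intensities) and may contain missing cells.  The design table records,
per sample, the treatment arm (``seed`` vs ``control``), the day in
vitro (DIV), the biological replicate, the culture plate and the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TREATMENTS = ("seed", "control")

DESIGN_COLUMNS = ["sample_id", "treatment", "div", "replicate", "plate", "assay"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class AbundanceMatrix:
    """Features x samples abundance table with a scale tag.

    Parameters
    ----------
    data :
        DataFrame indexed by feature ID with sample IDs as columns.
        Values are numeric; NaN encodes a missing measurement.
    scale :
        ``"log2"`` or ``"linear"``.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError("abundance matrix contains non-finite (inf) values")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.loc[:, list(sample_ids)], self.scale)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path: str | Path, feature_col: str = "feature_id") -> None:
        out = self.data.copy()
        out.index.name = feature_col
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "log2") -> "AbundanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        return cls(frame, scale)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample design table and return it with normalized dtypes."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design table missing columns: {missing}")
    design = design.copy()
    design["div"] = design["div"].astype(int)
    design["replicate"] = design["replicate"].astype(int)
    for col in ("sample_id", "treatment", "plate", "assay"):
        design[col] = design[col].astype(str)
    if design["sample_id"].duplicated().any():
        raise ValidationError("design table contains duplicate sample IDs")
    bad = set(design["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatment levels: {sorted(bad)}")
    return design


def design_for_matrix(design: pd.DataFrame, m: AbundanceMatrix) -> pd.DataFrame:
    """Rows of ``design`` matching the matrix columns, in column order."""
    design = validate_design(design)
    indexed = design.set_index("sample_id")
    absent = [s for s in m.sample_ids if s not in indexed.index]
    if absent:
        raise ValidationError(f"samples absent from design table: {absent[:5]}")
    return indexed.loc[list(m.sample_ids)].reset_index()


def read_design(path: str | Path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path))


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design)[DESIGN_COLUMNS].to_csv(path, index=False)


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Two-column gene -> protein ID mapping table (TSV)."""
    mapping = pd.read_csv(path, sep="\t")
    if list(mapping.columns[:2]) != ["gene_id", "protein_id"]:
        mapping.columns = ["gene_id", "protein_id"] + list(mapping.columns[2:])
    return mapping[["gene_id", "protein_id"]]
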