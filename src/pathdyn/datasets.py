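"""Expression dataset container and plain-text I/O.

The central object is :class:`ExpressionDataset`: a genes x arrays matrix of
non-negative hybridization intensities together with per-array metadata
(phenotype group, cell line, sampling time in hours, and the index of the
duplicated experiment the array belongs to).  Everything downstream --
normalization, gene selection, clustering, networking -- consumes either this
object or matrices derived from it that share its labelling conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("control", "case")

META_COLUMNS = ("group", "line", "timepoint_h", "duplicate_idx")


class DatasetError(ValueError):
    """Raised when an expression matrix or its metadata is malformed."""


@dataclass
class ExpressionDataset:
    """Raw intensities plus per-array annotations.

    Parameters
    ----------
    values:
        DataFrame of shape (genes, arrays); index = gene ids, columns =
        array ids, entries finite and >= 0.
    meta:
        DataFrame indexed by array id with columns ``group`` (one of
        ``control``/``case``), ``line``, ``timepoint_h`` and
        ``duplicate_idx``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate gene ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise DatasetError("expression values must be finite")
        if (arr < 0).any():
            g, a = np.argwhere(arr < 0)[0]
            raise DatasetError(
                f"negative intensity for gene {v.index[g]!r} on array {v.columns[a]!r}"
            )
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise DatasetError(f"metadata missing columns: {missing_cols}")
        for col in v.columns:
            if col not in self.meta.index:
                raise DatasetError(f"array {col!r} absent from metadata")
        bad_groups = set(self.meta["group"]) - set(GROUPS)
        if bad_groups:
            raise DatasetError(f"unknown phenotype groups: {sorted(bad_groups)}")
        if self.meta.loc[list(v.columns)].isna().any().any():
            raise DatasetError("metadata contains missing entries")

    # -- convenience accessors ------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def array_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.meta["timepoint_h"].unique())

    def arrays_for(
        self,
        group: str | None = None,
        line=None,
        timepoint: float | None = None,
        duplicate: int | None = None,
    ) -> list:
        """Array ids matching the given metadata filters, in column order."""
        m = self.meta.loc[self.array_ids]
        mask = pd.Series(True, index=m.index)
        if group is not None:
            mask &= m["group"] == group
        if line is not None:
            mask &= m["line"] == line
        if timepoint is not None:
            mask &= m["timepoint_h"] == timepoint
        if duplicate is not None:
            mask &= m["duplicate_idx"] == duplicate
        return list(m.index[mask])

    def duplicates_in(self, group: str) -> list[int]:
        m = self.meta[self.meta["group"] == group]
        return sorted(m["duplicate_idx"].unique())


def read_dataset(matrix_path, metadata_path) -> ExpressionDataset:
    """Load a genes x arrays TSV matrix (first column = gene id) plus metadata.

    Arrays are sorted by (group, line, timepoint); duplicate gene ids and
    non-numeric cells are rejected with the offending location.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        values = raw.astype(float)
    except (TypeError, ValueError):
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                gene = raw.index[bad.to_numpy()][0]
                # +2: header line plus 1-based numbering
                line_no = int(np.argwhere(bad.to_numpy())[0][0]) + 2
                raise DatasetError(
                    f"non-numeric cell at gene {gene!r}, array {col!r} "
                    f"({matrix_path.name} line {line_no})"
                )
        raise
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [a for a in values.columns if a not in meta.index]
    if missing:
        raise DatasetError(f"array column {missing[0]!r} absent from metadata")
    order = meta.sort_values(["group", "line", "timepoint_h"]).index
    order = [a for a in order if a in values.columns]
    ds = ExpressionDataset(values[order], meta)
    return ds


def write_dataset(ds: ExpressionDataset, out_dir, prefix: str = "expression") -> dict:
    """Write matrix + metadata TSVs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = out_dir / f"{prefix}_matrix.tsv"
    metadata = out_dir / f"{prefix}_metadata.tsv"
    ds.values.to_csv(matrix, sep="\t", float_format="%.6g", index_label="gene_id")
    ds.meta.to_csv(metadata, sep="\t", index_label="array_id")
    return {"matrix": matrix, "metadata": metadata}


def profile_matrix(
    values: pd.DataFrame, meta: pd.DataFrame, group: str, duplicate: int
) -> pd.DataFrame:
    """Genes x timepoints profile for one duplicated experiment of a group.

    ``values`` may be raw, normalized or residual expressions sharing the
    dataset's array ids.  If the duplicate has several arrays per timepoint
    they are averaged.
    """
    m = meta[(meta["group"] == group) & (meta["duplicate_idx"] == duplicate)]
    if m.empty:
        raise DatasetError(f"no arrays for group={group!r} duplicate={duplicate!r}")
    cols = [a for a in m.index if a in values.columns]
    sub = values[cols]
    tps = m.loc[cols, "timepoint_h"]
    prof = sub.T.groupby(tps.values).mean().T
    prof.columns.name = "timepoint_h"
    return prof[sorted(prof.columns)]
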