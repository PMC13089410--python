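"""Uncollapsed allele and collapsed gene-burden matrices.

The uncollapsed matrix has one binary column per gene-disrupting variant;
collapsing ORs the columns of each gene into a single burden state, so an
accession scores 1 for a gene when it carries at least one of the gene's
LoF alleles.  Allelic heterogeneity — several independent knockout alleles
of the same gene segregating in different accessions — is exactly what the
collapsing step is designed to absorb.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import LoFCallSet

logger = logging.getLogger(__name__)


@dataclass
class AlleleMatrix:
    """Binary accession x column matrix with per-column gene/position metadata.

    ``values``: DataFrame, index = accession ids, columns = variant ids
    (uncollapsed) or gene ids (collapsed), entries in {0, 1}.
    ``column_meta``: DataFrame indexed by column id with ``gene_id``,
    ``chromosome``, ``midpoint`` where known.
    """

    values: pd.DataFrame
    column_meta: pd.DataFrame
    collapsed: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("allele matrix entries must be binary")

    @property
    def accessions(self) -> list:
        return list(self.values.index)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="accession")

    @classmethod
    def from_tsv(cls, path: str, column_meta: Optional[pd.DataFrame] = None,
                 collapsed: bool = False) -> "AlleleMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if column_meta is None:
            column_meta = pd.DataFrame(index=df.columns)
        return cls(values=df, column_meta=column_meta, collapsed=collapsed)


def build_uncollapsed(
    call_set: LoFCallSet,
    gene_coords: Optional[pd.DataFrame] = None,
) -> AlleleMatrix:
    """One binary column per gene-level LoF variant.

    Column ids are ``variant_id`` (suffixed with the gene id when a single
    structural deletion knocks out more than one gene).  Duplicate column
    ids raise.
    """
    cols: Dict[str, np.ndarray] = {}
    meta_rows = []
    variant_counts: Dict[str, int] = {}
    for (vid, _gid) in call_set.carriers:
        variant_counts[vid] = variant_counts.get(vid, 0) + 1
    for (vid, gid), carr in call_set.carriers.items():
        col_id = vid if variant_counts[vid] == 1 else f"{vid}@{gid}"
        if col_id in cols:
            raise ValueError(f"duplicate variant id {col_id}")
        cols[col_id] = carr.astype(np.int8)
        row = {"gene_id": gid, "chromosome": None, "midpoint": np.nan,
               "monomorphic": bool(carr.sum() == 0)}
        if gene_coords is not None and gid in gene_coords.index:
            row["chromosome"] = gene_coords.loc[gid, "chromosome"]
            row["midpoint"] = gene_coords.loc[gid, "midpoint"]
        meta_rows.append((col_id, row))
    values = pd.DataFrame(
        {cid: v for cid, v in cols.items()}, index=call_set.accessions, dtype=np.int8
    )
    meta = pd.DataFrame({cid: r for cid, r in meta_rows}).T
    if meta.empty:
        meta = pd.DataFrame(columns=["gene_id", "chromosome", "midpoint", "monomorphic"])
    n_mono = int(meta["monomorphic"].sum()) if len(meta) else 0
    if n_mono:
        logger.info("uncollapsed matrix: %d monomorphic variant columns", n_mono)
    return AlleleMatrix(values=values, column_meta=meta, collapsed=False)


def collapse(uncollapsed: AlleleMatrix) -> AlleleMatrix:
    """OR the variant columns of each gene into a single burden column."""
    if "gene_id" not in uncollapsed.column_meta.columns:
        raise ValueError("uncollapsed matrix lacks gene_id column metadata")
    gene_of = uncollapsed.column_meta["gene_id"]
    if uncollapsed.collapsed:
        # collapsing is idempotent: gene columns map to themselves
        gene_of = pd.Series(uncollapsed.values.columns,
                            index=uncollapsed.values.columns)
    burden = uncollapsed.values.T.groupby(gene_of.reindex(uncollapsed.values.columns)).max().T
    burden = burden.astype(np.int8)
    meta_rows = {}
    for col in burden.columns:
        members = gene_of[gene_of == col].index
        sub = uncollapsed.column_meta.loc[members]
        meta_rows[col] = {
            "gene_id": col,
            "chromosome": sub["chromosome"].dropna().iloc[0] if sub["chromosome"].notna().any() else None,
            "midpoint": sub["midpoint"].dropna().iloc[0] if sub["midpoint"].notna().any() else np.nan,
            "n_independent_alleles": int(len(members)),
        }
    meta = pd.DataFrame(meta_rows).T
    return AlleleMatrix(values=burden, column_meta=meta, collapsed=True)


def lof_frequency(matrix: AlleleMatrix) -> pd.DataFrame:
    """Per-column LoF frequency (column mean) and independent-allele count."""
    if matrix.values.shape[0] == 0:
        raise ValueError("matrix has zero accessions")
    freq = matrix.values.mean(axis=0)
    n_alleles = (
        matrix.column_meta["n_independent_alleles"]
        if "n_independent_alleles" in matrix.column_meta.columns
        else pd.Series(1, index=matrix.values.columns)
    )
    out = pd.DataFrame(
        {"lof_frequency": freq,
         "n_independent_alleles": n_alleles.reindex(matrix.values.columns).fillna(1).astype(int)}
    )
    out.attrs["n_zero_frequency"] = int((freq == 0).sum())
    return out


def frequency_filter(matrix: AlleleMatrix, maf: float = 0.05) -> AlleleMatrix:
    """Keep columns whose minor-allele-side frequency is at least ``maf``.

    A column with burden frequency f is retained iff min(f, 1-f) >= maf;
    the boundary is inclusive because only frequencies *below* the cutoff
    are excluded.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    f = matrix.values.mean(axis=0)
    keep = np.minimum(f, 1.0 - f) >= maf
    kept = matrix.values.loc[:, keep]
    logger.info("frequency filter (maf=%g): retained %d / %d columns",
                maf, int(keep.sum()), len(keep))
    out = AlleleMatrix(
        values=kept,
        column_meta=matrix.column_meta.loc[kept.columns],
        collapsed=matrix.collapsed,
    )
    out.values.attrs["n_dropped"] = int((~keep).sum())
    return out
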