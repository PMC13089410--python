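"""Candidate filtering cascade, association network, and diagnostics.

Association hits pass four stringent filters before being called
candidates: Benjamini–Hochberg FDR <= 0.05, a >1,000 kb same-chromosome
distance rule against linkage artefacts, removal of pairs involving
"hypothetical" genes, and retention of only rank-1 hits from the
frequency-preserving permutation null.  Survivors form a signed directed
network from LoF gene to associated expression gene.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def distance_filter(
    pairs: pd.DataFrame,
    gene_coords: pd.DataFrame,
    window_bp: int = 1_000_000,
    marker_col: str = "marker",
    pheno_col: str = "phenotype",
) -> pd.DataFrame:
    """Drop same-chromosome pairs whose gene midpoints are within the window.

    Pairs on different chromosomes are always retained; a pair with a
    missing coordinate is dropped with a warning.
    """
    def coord(gid):
        if gid in gene_coords.index:
            row = gene_coords.loc[gid]
            return row["chromosome"], float(row["midpoint"])
        return None, np.nan

    keep = []
    n_missing = 0
    for row in pairs.itertuples(index=False):
        c1, m1 = coord(getattr(row, marker_col))
        c2, m2 = coord(getattr(row, pheno_col))
        if c1 is None or c2 is None or not np.isfinite(m1) or not np.isfinite(m2):
            n_missing += 1
            keep.append(False)
            continue
        keep.append(c1 != c2 or abs(m1 - m2) > window_bp)
    if n_missing:
        warnings.warn(f"{n_missing} pairs dropped for missing gene coordinates")
    return pairs.loc[np.asarray(keep, dtype=bool)]


@dataclass
class FilteredAssociations:
    """Surviving candidate pairs with per-stage bookkeeping."""

    pairs: pd.DataFrame  # marker, phenotype, beta, p_value, p_adjusted, rank
    drop_counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def filter_candidates(
    assoc: pd.DataFrame,
    ranks: pd.DataFrame,
    gene_coords: pd.DataFrame,
    gene_annotations: Optional[pd.Series] = None,
    fdr: float = 0.05,
    window_bp: int = 1_000_000,
) -> FilteredAssociations:
    """The full cascade: FDR -> distance -> annotation -> rank 1.

    ``assoc`` needs columns marker/phenotype/beta/p_value; ``ranks`` needs
    marker/phenotype/rank.  ``gene_annotations`` maps gene id to a free-text
    class; any gene whose class contains "hypothetical" (case-insensitive)
    disqualifies its pairs.  Stage drop counts are recorded in cascade order.
    """
    df = assoc.dropna(subset=["p_value"]).copy()
    df["p_adjusted"] = fdr_adjust(df["p_value"].to_numpy())
    drops: Dict[str, int] = {}

    n0 = len(df)
    df = df[df["p_adjusted"] <= fdr]
    drops["fdr"] = n0 - len(df)

    n0 = len(df)
    df = distance_filter(df, gene_coords, window_bp=window_bp)
    drops["distance"] = n0 - len(df)

    n0 = len(df)
    if gene_annotations is not None:
        bad = {
            g for g, cls in gene_annotations.items()
            if isinstance(cls, str) and "hypothetical" in cls.lower()
        }
        df = df[~(df["marker"].isin(bad) | df["phenotype"].isin(bad))]
    drops["annotation"] = n0 - len(df)

    n0 = len(df)
    key_rank = ranks.set_index(["marker", "phenotype"])["rank"]
    idx = pd.MultiIndex.from_frame(df[["marker", "phenotype"]])
    missing = ~idx.isin(key_rank.index)
    if missing.any():
        lost = idx[missing].tolist()[:10]
        raise KeyError(f"pairs without permutation ranks, e.g. {lost}")
    df["rank"] = key_rank.loc[idx].to_numpy()
    df = df[df["rank"] == 1]
    drops["rank"] = n0 - len(df)

    return FilteredAssociations(pairs=df.reset_index(drop=True), drop_counts=drops)


def pos_neg_ratio(filtered: FilteredAssociations | pd.DataFrame) -> Tuple[int, int, float]:
    """Counts of positive/negative-beta survivors and their ratio.

    Zero-beta pairs are counted in neither class.  An empty negative class
    yields ``math.inf``.
    """
    df = filtered.pairs if isinstance(filtered, FilteredAssociations) else filtered
    betas = df["beta"].to_numpy(dtype=float)
    n_pos = int((betas > 0).sum())
    n_neg = int((betas < 0).sum())
    ratio = math.inf if n_neg == 0 else n_pos / n_neg
    return n_pos, n_neg, ratio


def build_network(filtered: FilteredAssociations | pd.DataFrame) -> nx.DiGraph:
    """Signed directed association network.

    One edge per surviving pair, LoF gene -> expression gene, with
    ``sign`` from the beta coefficient and ``weight`` = -log10(adjusted p).
    Self-loops are excluded with a warning.  Node attribute ``role`` is
    "LoF", "Exp", or "both".
    """
    df = filtered.pairs if isinstance(filtered, FilteredAssociations) else filtered
    G = nx.DiGraph()
    n_self = 0
    for row in df.itertuples(index=False):
        if row.marker == row.phenotype:
            n_self += 1
            continue
        padj = getattr(row, "p_adjusted", getattr(row, "p_value", np.nan))
        G.add_edge(
            row.marker,
            row.phenotype,
            sign="positive" if row.beta > 0 else "negative",
            weight=float(-np.log10(max(padj, np.finfo(float).tiny))),
        )
    if n_self:
        warnings.warn(f"{n_self} self-loop pairs excluded from the network")
    lof_nodes = set(df["marker"])
    exp_nodes = set(df["phenotype"])
    for node in G.nodes:
        if node in lof_nodes and node in exp_nodes:
            G.nodes[node]["role"] = "both"
        elif node in lof_nodes:
            G.nodes[node]["role"] = "LoF"
        else:
            G.nodes[node]["role"] = "Exp"
    return G


def write_edge_list(G: nx.DiGraph, path: str) -> None:
    rows = [
        {"source": u, "target": v, "sign": d["sign"], "weight": d["weight"]}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    G = nx.DiGraph()
    for row in df.itertuples(index=False):
        G.add_edge(row.source, row.target, sign=row.sign, weight=float(row.weight))
    return G


def spearman_coexpression(
    expr: pd.DataFrame, pairs: Iterable[Tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rho (average-rank ties) per gene pair over shared accessions."""
    rows = []
    for a, b in pairs:
        rho = np.nan
        if a in expr.columns and b in expr.columns:
            xa = expr[a].to_numpy(dtype=float)
            xb = expr[b].to_numpy(dtype=float)
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() >= 3 and np.std(xa[ok]) > 0 and np.std(xb[ok]) > 0:
                rho = stats.spearmanr(xa[ok], xb[ok]).statistic
        rows.append({"gene_a": a, "gene_b": b, "spearman_rho": rho})
    return pd.DataFrame(rows)


def tissue_jaccard(profile_a: Set[str] | Sequence, profile_b: Set[str] | Sequence) -> float:
    """Jaccard index |A∩B| / |A∪B| of two tissue-expression sets (0 if both empty)."""
    a, b = set(profile_a), set(profile_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def binarize_tissue_profile(mean_expr: pd.Series, threshold: float = 0.0) -> Set[str]:
    """Tissues in which a gene counts as expressed (mean expression > threshold)."""
    return set(mean_expr.index[mean_expr > threshold])
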