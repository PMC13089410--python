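"""End-to-end driver: annotate -> matrix -> associate -> permute -> filter.

The pipeline consumes a directory of standard files (SnpEff-annotated VCF,
deletion TSV, GFF3 gene models, expression TSV, kinship or genotype TSV) —
exactly what the synthetic generator writes — runs every stage in order,
and leaves TSV/JSON/GraphML outputs plus a manifest of content hashes,
accession intersections and per-stage drop counts in the run directory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotation, filtering, matrix as mx
from .assoc import BurdenScan, compute_kinship, compute_pcs, int_transform
from .genes import gene_coordinate_table, read_gff3
from .permutation import PermutationScan

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    vcf: str
    gff: str
    expression: str
    out_dir: str
    deletions: Optional[str] = None
    kinship: Optional[str] = None
    genotypes: Optional[str] = None
    model: str = "emmax"
    n_pcs: int = 5
    maf: float = 0.05
    fdr: float = 0.05
    window_kb: float = 1000.0
    end_exempt: float = 0.05
    cds_frac: float = 0.10
    n_perms: int = 101
    apply_int: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must be in [0, 0.5]")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")
        if self.n_perms < 101:
            raise ValueError("n_perms must be >= 101")
        if self.model in ("emmax", "emmax_pc") and not (self.kinship or self.genotypes):
            raise ValueError("mixed models need a kinship or genotype matrix")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


@dataclass
class RunManifest:
    """Per-stage bookkeeping: hashes, counts, wall-clock."""

    output_hashes: Dict[str, str] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    accession_intersection: int = 0
    completed_stages: List[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def intersect_accessions(*sources: Sequence[str]) -> Tuple[List[str], List[int]]:
    """Sorted intersection of accession panels plus per-source exclusions."""
    if len(sources) < 2:
        raise ValueError("need at least two accession sources")
    sets = [set(s) for s in sources]
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError("empty accession intersection")
    excluded = [len(s) - len(shared) for s in sets]
    return sorted(shared), excluded


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full study on one input set.

    Deterministic stages (calling, matrices, filtering) are reproducible by
    content hash; stochastic stages (permutations) by seed.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config_echo.yaml"))
    manifest = RunManifest()

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, *exc):
                manifest.stage_seconds[name] = time.perf_counter() - self_.t0
                if exc[0] is None:
                    manifest.completed_stages.append(name)
                return False

        return _Timer()

    def emit(fname: str) -> str:
        path = os.path.join(config.out_dir, fname)
        manifest.output_hashes[fname] = file_hash(path)
        return path

    with stage("annotate"):
        genes = read_gff3(config.gff)
        coords = gene_coordinate_table(genes)
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        from cyvcf2 import VCF

        vcf_accessions = list(VCF(config.vcf).samples)
        dels = (annotation.read_deletions_tsv(config.deletions, vcf_accessions)
                if config.deletions else None)
        calls = annotation.call_lof(
            config.vcf, dels, genes, vcf_accessions,
            exempt_frac=config.end_exempt, cds_frac=config.cds_frac,
        )
        calls.to_tsv(os.path.join(config.out_dir, "calls.tsv"))
        emit("calls.tsv")
        manifest.counts["lof_calls"] = int((calls.entries["verdict"] == "LoF").sum())
        manifest.counts["variant_gene_pairs"] = len(calls.entries)

    with stage("matrix"):
        uncollapsed = mx.build_uncollapsed(calls, coords)
        collapsed = mx.collapse(uncollapsed)
        filtered_burden = mx.frequency_filter(collapsed, maf=config.maf)
        for name, m in [("uncollapsed.tsv", uncollapsed),
                        ("collapsed.tsv", collapsed),
                        ("burden_filtered.tsv", filtered_burden)]:
            m.to_tsv(os.path.join(config.out_dir, name))
            emit(name)
        manifest.counts["genes_with_burden"] = collapsed.values.shape[1]
        manifest.counts["genes_after_maf"] = filtered_burden.values.shape[1]

    with stage("assoc"):
        kinship = None
        pcs = None
        if config.kinship:
            kinship = pd.read_csv(config.kinship, sep="\t", index_col=0)
            kinship.columns = kinship.index
        elif config.genotypes:
            kinship = compute_kinship(pd.read_csv(config.genotypes, sep="\t", index_col=0))
        if config.model.endswith("_pc"):
            if not config.genotypes:
                raise ValueError("PC models need the genotype matrix")
            pcs = compute_pcs(pd.read_csv(config.genotypes, sep="\t", index_col=0),
                              k=config.n_pcs)
        pheno = expr.copy()
        if config.apply_int:
            pheno = pheno.apply(lambda col: int_transform(col.to_numpy()), axis=0)
        shared, excluded = intersect_accessions(
            pheno.index, filtered_burden.values.index,
            *( [kinship.index] if kinship is not None else [] ),
        )
        manifest.accession_intersection = len(shared)
        manifest.counts["accessions_excluded_per_source"] = excluded
        scan = BurdenScan(pheno, filtered_burden.values, kinship=kinship,
                          pcs=pcs, model=config.model)
        results = scan.fit()
        results.frame.to_csv(os.path.join(config.out_dir, "assoc.tsv"),
                             sep="\t", index=False)
        emit("assoc.tsv")

    with stage("permute"):
        perms = PermutationScan(results, n_perms=config.n_perms,
                                seed=config.seed).run()
        perms.to_tsv(os.path.join(config.out_dir, "ranks.tsv"))
        emit("ranks.tsv")
        perms.enrichment().to_csv(os.path.join(config.out_dir, "rank_enrichment.tsv"),
                                  sep="\t", index=False)
        emit("rank_enrichment.tsv")

    with stage("filter"):
        annotations = pd.Series({g.gene_id: g.annotation_class for g in genes.values()})
        filtered = filtering.filter_candidates(
            results.frame, perms.rank_frame, coords,
            gene_annotations=annotations, fdr=config.fdr,
            window_bp=int(config.window_kb * 1000),
        )
        filtered.pairs.to_csv(os.path.join(config.out_dir, "candidates.tsv"),
                              sep="\t", index=False)
        emit("candidates.tsv")
        manifest.counts.update({f"dropped_{k}": v for k, v in filtered.drop_counts.items()})
        manifest.counts["survivors"] = len(filtered)
        n_pos, n_neg, _ = filtering.pos_neg_ratio(filtered)
        manifest.counts["positive_beta"] = n_pos
        manifest.counts["negative_beta"] = n_neg

    with stage("network"):
        G = filtering.build_network(filtered)
        filtering.write_edge_list(G, os.path.join(config.out_dir, "network_edges.tsv"))
        emit("network_edges.tsv")
        import networkx as nx

        nx.write_graphml(G, os.path.join(config.out_dir, "network.graphml"))
        emit("network.graphml")
        manifest.counts["network_edges"] = G.number_of_edges()

    manifest.to_json(os.path.join(config.out_dir, "manifest.json"))
    return manifest
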