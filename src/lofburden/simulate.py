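"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a natural inbred-accession panel:
fully homozygous diploid accessions drawn from a small number of diverged
subpopulations, non-overlapping gene models, per-gene allelic heterogeneity
of loss-of-function alleles (several independent knockout alleles at
modest frequencies), expression phenotypes with a polygenic background
whose covariance follows the realized kinship, and per-gene feature tables
with a class-conditional signal.  Every generated artefact carries its
ground truth, so the annotation, collapsing, association, permutation and
prediction stages can all be checked end to end.
"""
from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import GeneModel, GeneSet, TranscriptModel, write_gff3

# effect-class mix for emitted LoF annotations; the frameshift and premature
# stop shares dominate, as they do in natural LoF spectra
DEFAULT_CLASS_PROPORTIONS = {
    "frameshift_variant": 0.4459,
    "stop_gained": 0.2498,
    "stop_lost": 0.05,
    "start_lost": 0.05,
    "splice_donor_variant": 0.05,
    "splice_acceptor_variant": 0.05,
    "deletion_frameshift": 0.05,
    "deletion_gt10pct": 0.0543,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with field-realistic defaults."""

    n_accessions: int = 300
    n_subpops: int = 2
    fst_like_divergence: float = 0.15
    n_snps: int = 1000
    n_genes: int = 400
    n_chromosomes: int = 5
    transcripts_per_gene: Dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    lof_alleles_per_gene: Dict[int, float] = field(default_factory=lambda: {0: 0.2, 1: 0.4, 2: 0.25, 3: 0.15})
    lof_freq_beta: Tuple[float, float] = (0.6, 6.0)  # beta-shaped, mass below 0.1
    class_proportions: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    decoy_rate: float = 0.5
    hypothetical_frac: float = 0.05
    gene_spacing: Tuple[int, int] = (20_000, 40_000)
    n_expressed_genes: int = 100
    h2: float = 0.3
    n_effects: int = 10
    effect_size: float = 2.0  # in residual-SD units
    effect_table: Optional[List[Tuple[str, str, float]]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_genes < 1 or self.n_snps < 1:
            raise ValueError("counts must be >= 1")
        if self.n_subpops < 1 or self.n_subpops > self.n_accessions:
            raise ValueError("n_subpops must be in [1, n_accessions]")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise ValueError("fst_like_divergence must be in [0, 1)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.n_expressed_genes > self.n_genes:
            raise ValueError("n_expressed_genes cannot exceed n_genes")
        for d in (self.transcripts_per_gene, self.lof_alleles_per_gene):
            if any(k < 0 for k in d) or abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError("count distributions must be proper")

    def rng(self, *stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stage]))


@dataclass
class SyntheticVariant:
    """Internal record of one emitted variant with its truth verdict."""

    variant_id: str
    gene_id: str
    chromosome: str
    position: int  # 0-based
    ref: str
    alt: str
    kind: str  # small | deletion
    ann_entries: List[Tuple[str, str, str]]  # (effect, impact, feature_id)
    carriers: np.ndarray
    end: Optional[int] = None
    is_lof_truth: bool = False
    truth_note: str = ""


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    true_burden: pd.DataFrame  # accession x gene, binary
    variant_carriers: Dict[str, np.ndarray]
    variant_truth: pd.DataFrame  # variant_id, gene_id, is_lof, note
    true_effects: List[Tuple[str, str, float]]
    variance_components: Dict[str, Tuple[float, float]]  # phenotype -> (s2g, s2e)
    realized_h2: Dict[str, float]
    subpop_labels: pd.Series


# ---------------------------------------------------------------------------
# population

def simulate_population(config: SimulationConfig):
    """Inbred 0/2 genotypes under a Balding–Nichols-style subpopulation model.

    Ancestral allele frequencies are uniform on (0.05, 0.95); each
    subpopulation draws its own frequency from a beta distribution whose
    spread is governed by ``fst_like_divergence`` (0 = panmictic).  Returns
    (genotypes, subpop labels, realized centered kinship).
    """
    config.validate()
    rng = config.rng(1)
    n, m, k = config.n_accessions, config.n_snps, config.n_subpops
    d = config.fst_like_divergence
    labels = np.sort(rng.integers(0, k, size=n))
    p0 = rng.uniform(0.05, 0.95, size=m)
    if d > 0 and k > 1:
        a = p0 * (1 - d) / d
        b = (1 - p0) * (1 - d) / d
        psub = np.clip(rng.beta(a, b, size=(k, m)), 0.01, 0.99)
    else:
        psub = np.tile(p0, (k, 1))
    geno = 2 * (rng.random((n, m)) < psub[labels, :]).astype(np.int8)
    acc = [f"acc{i:04d}" for i in range(n)]
    G = pd.DataFrame(geno, index=acc, columns=[f"snp{j:05d}" for j in range(m)])
    from .assoc import compute_kinship

    K = compute_kinship(G)
    return G, pd.Series(labels, index=acc, name="subpop"), K


# ---------------------------------------------------------------------------
# gene models

def simulate_gene_annotation(config: SimulationConfig) -> GeneSet:
    """Non-overlapping gene models with 2–3 CDS exons per transcript.

    Spliced CDS lengths are multiples of 3 between 300 and 1500 bp; all
    transcripts of a gene share the same CDS intervals (alternative models
    are exercised through annotation coverage, not exon structure).
    """
    config.validate()
    rng = config.rng(2)
    tx_counts = sorted(config.transcripts_per_gene)
    tx_probs = [config.transcripts_per_gene[c] for c in tx_counts]
    cursors = {f"chr{c + 1}": 10_000 for c in range(config.n_chromosomes)}
    genes: GeneSet = {}
    for gi in range(config.n_genes):
        chrom = f"chr{gi % config.n_chromosomes + 1}"
        L = int(3 * rng.integers(100, 501))  # spliced CDS length, 300..1503
        n_exons = int(rng.integers(2, 4))
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
        exon_lens = np.diff(np.concatenate([[0], cuts, [L]]))
        start = cursors[chrom]
        intervals = []
        pos = start
        for j, el in enumerate(exon_lens):
            intervals.append((pos, pos + int(el)))
            pos += int(el) + int(rng.integers(50, 201))  # intron
        gene_id = f"g{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.choice(tx_counts, p=tx_probs))
        txs = [
            TranscriptModel(f"{gene_id}.t{t + 1}", list(intervals))
            for t in range(max(1, n_tx))
        ]
        klass = "hypothetical" if rng.random() < config.hypothetical_frac else "protein_coding"
        genes[gene_id] = GeneModel(gene_id, chrom, strand, txs, klass)
        cursors[chrom] = intervals[-1][1] + int(rng.integers(*config.gene_spacing))
    return genes


# ---------------------------------------------------------------------------
# variants

def _cds_window_to_genomic(
    t: TranscriptModel, strand: str, c0: int, length: int
) -> Optional[Tuple[int, int]]:
    """Map a spliced-CDS window (single-exon-contained) to genomic coords."""
    acc = 0
    exons = t.cds_intervals if strand == "+" else t.cds_intervals[::-1]
    for (s, e) in exons:
        el = e - s
        if c0 >= acc and c0 + length <= acc + el:
            off = c0 - acc
            if strand == "+":
                return (s + off, s + off + length)
            return (e - off - length, e - off)
        acc += el
    return None


def _interior_slot(
    t: TranscriptModel, strand: str, length: int, rng: np.random.Generator
) -> Optional[Tuple[int, int]]:
    """Genomic window whose CDS footprint avoids the terminal 5% zones."""
    L = t.spliced_cds_length
    head = int(np.ceil(0.05 * L))
    tail = int(np.floor(0.95 * L))
    feasible = []
    acc = 0
    exons = t.cds_intervals if strand == "+" else t.cds_intervals[::-1]
    for (s, e) in exons:
        el = e - s
        lo = max(acc, head)
        hi = min(acc + el, tail)
        if hi - lo >= length:
            feasible.append((lo, hi))
        acc += el
    if not feasible:
        return None
    lo, hi = feasible[int(rng.integers(len(feasible)))]
    c0 = int(rng.integers(lo, hi - length + 1))
    return _cds_window_to_genomic(t, strand, c0, length)


def _terminal_slot(
    t: TranscriptModel, strand: str, length: int, rng: np.random.Generator
) -> Optional[Tuple[int, int]]:
    """Genomic window fully inside the first or last 5% of the CDS."""
    L = t.spliced_cds_length
    head = int(np.ceil(0.05 * L))
    tail = int(np.floor(0.95 * L))
    zones = []
    if head >= length:
        zones.append((0, head))
    if L - tail >= length:
        zones.append((tail, L))
    rng.shuffle(zones)
    for lo, hi in zones:
        c0 = int(rng.integers(lo, hi - length + 1))
        g = _cds_window_to_genomic(t, strand, c0, length)
        if g is not None:
            return g
    return None


def _draw_carriers(n: int, freq: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(freq * n))
    carriers = np.zeros(n, dtype=bool)
    if k >= 1:
        carriers[rng.choice(n, size=k, replace=False)] = True
    return carriers


def simulate_lof_variants(
    genes: GeneSet, accessions: Sequence[str], config: SimulationConfig
) -> Tuple[List[SyntheticVariant], GroundTruth]:
    """Plant LoF alleles (with heterogeneity) and rule-exercising decoys.

    Each gene draws its number of independent LoF alleles and per-allele
    frequencies from the configured distributions; variant classes follow
    ``class_proportions``.  Decoys (MODERATE-impact annotations, terminal-5%
    HIGH variants, in-frame sub-10% deletions, and partial-transcript
    annotations) are emitted but excluded from the truth burden.  A
    requested frequency rounding to zero carriers triggers a warning and a
    monomorphic-reference variant outside the truth.
    """
    rng = config.rng(3)
    n = len(accessions)
    alle_counts = sorted(config.lof_alleles_per_gene)
    alle_probs = [config.lof_alleles_per_gene[c] for c in alle_counts]
    classes = list(config.class_proportions)
    class_probs = np.array([config.class_proportions[c] for c in classes], dtype=float)
    class_probs = class_probs / class_probs.sum()
    variants: List[SyntheticVariant] = []
    burden = np.zeros((n, len(genes)), dtype=np.int8)
    gene_ids = list(genes)
    vid = 0

    def all_tx_ann(g: GeneModel, effect: str) -> List[Tuple[str, str, str]]:
        return [(effect, "HIGH", t.transcript_id) for t in g.transcripts]

    for gcol, gid in enumerate(gene_ids):
        g = genes[gid]
        t0 = g.transcripts[0]
        L = t0.spliced_cds_length
        k_alleles = int(rng.choice(alle_counts, p=alle_probs))
        for _ in range(k_alleles):
            freq = float(np.clip(rng.beta(*config.lof_freq_beta), 1e-4, 0.5))
            carriers = _draw_carriers(n, freq, rng)
            klass = classes[int(rng.choice(len(classes), p=class_probs))]
            var = _make_true_variant(g, t0, klass, carriers, f"v{vid:05d}", rng)
            if var is None:
                continue
            vid += 1
            if not var.carriers.any():
                warnings.warn(
                    f"{var.variant_id}: requested frequency {freq:.4f} rounds to "
                    "zero carriers; emitted monomorphic and excluded from truth"
                )
                var.is_lof_truth = False
                var.truth_note = f"monomorphic:{var.truth_note}"
            variants.append(var)
            if var.is_lof_truth:
                burden[:, gcol] |= var.carriers.astype(np.int8)
        if rng.random() < config.decoy_rate:
            dv = _make_decoy(g, t0, f"d{vid:05d}",
                             _draw_carriers(n, 0.1, rng), rng)
            if dv is not None:
                vid += 1
                variants.append(dv)

    truth_rows = [
        {"variant_id": v.variant_id, "gene_id": v.gene_id,
         "is_lof": v.is_lof_truth, "note": v.truth_note}
        for v in variants
    ]
    truth = GroundTruth(
        true_burden=pd.DataFrame(burden, index=list(accessions), columns=gene_ids),
        variant_carriers={v.variant_id: v.carriers.copy() for v in variants if v.is_lof_truth},
        variant_truth=pd.DataFrame(truth_rows),
        true_effects=[],
        variance_components={},
        realized_h2={},
        subpop_labels=pd.Series(dtype=int),
    )
    return variants, truth


def _make_true_variant(
    g: GeneModel, t: TranscriptModel, klass: str, carriers: np.ndarray,
    vid: str, rng: np.random.Generator,
) -> Optional[SyntheticVariant]:
    L = t.spliced_cds_length
    chrom = g.chromosome
    if klass.startswith("deletion"):
        if klass == "deletion_frameshift":
            o = int(rng.choice([4, 5, 7, 8, 10, 11]))
        else:  # smallest in-frame overlap exceeding 10% of the CDS
            o = 3 * (int(np.floor(0.10 * L / 3)) + 1)
        slot = _interior_slot(t, g.strand, o, rng)
        if slot is None:  # exon too short; fall back to a premature stop
            return _make_true_variant(g, t, "stop_gained", carriers, vid, rng)
        s, e = slot
        return SyntheticVariant(
            variant_id=vid, gene_id=g.gene_id, chromosome=chrom, position=s,
            ref="N", alt="<DEL>", kind="deletion", ann_entries=[],
            carriers=carriers, end=e, is_lof_truth=True, truth_note=klass,
        )
    if klass.startswith("splice"):
        # first intron base flanking an internal exon junction
        iv = t.cds_intervals
        if len(iv) < 2:
            return _make_true_variant(g, t, "stop_gained", carriers, vid, rng)
        pos = iv[0][1] if klass == "splice_donor_variant" else iv[1][0] - 1
        ann = [(klass, "HIGH", tx.transcript_id) for tx in g.transcripts]
        return SyntheticVariant(
            variant_id=vid, gene_id=g.gene_id, chromosome=chrom, position=pos,
            ref="A", alt="T", kind="small", ann_entries=ann,
            carriers=carriers, is_lof_truth=True, truth_note=klass,
        )
    length = 1
    slot = _interior_slot(t, g.strand, length, rng)
    if slot is None:
        return None
    pos = slot[0]
    ref, alt = ("A", "AT") if klass == "frameshift_variant" else ("A", "T")
    ann = [(klass, "HIGH", tx.transcript_id) for tx in g.transcripts]
    return SyntheticVariant(
        variant_id=vid, gene_id=g.gene_id, chromosome=chrom, position=pos,
        ref=ref, alt=alt, kind="small", ann_entries=ann,
        carriers=carriers, is_lof_truth=True, truth_note=klass,
    )


def _make_decoy(
    g: GeneModel, t: TranscriptModel, vid: str, carriers: np.ndarray,
    rng: np.random.Generator,
) -> Optional[SyntheticVariant]:
    kinds = ["moderate", "exempt_high", "inframe_del"]
    if len(g.transcripts) > 1:
        kinds.append("partial_tx")
    kind = kinds[int(rng.integers(len(kinds)))]
    L = t.spliced_cds_length
    if kind == "moderate":
        slot = _interior_slot(t, g.strand, 1, rng)
        if slot is None:
            return None
        ann = [("missense_variant", "MODERATE", tx.transcript_id) for tx in g.transcripts]
        return SyntheticVariant(vid, g.gene_id, g.chromosome, slot[0], "A", "G",
                                "small", ann, carriers, None, False, "decoy_moderate")
    if kind == "exempt_high":
        slot = _terminal_slot(t, g.strand, 1, rng)
        if slot is None:
            return None
        ann = [("stop_gained", "HIGH", tx.transcript_id) for tx in g.transcripts]
        return SyntheticVariant(vid, g.gene_id, g.chromosome, slot[0], "A", "T",
                                "small", ann, carriers, None, False, "decoy_exempt")
    if kind == "inframe_del":
        o = 3 * int(np.floor(0.09 * L / 3))
        if o < 3:
            return None
        slot = _interior_slot(t, g.strand, o, rng)
        if slot is None:
            return None
        return SyntheticVariant(vid, g.gene_id, g.chromosome, slot[0], "N", "<DEL>",
                                "deletion", [], carriers, slot[1], False,
                                "decoy_inframe_del")
    # partial_tx: HIGH annotation covering only the first transcript
    slot = _interior_slot(t, g.strand, 1, rng)
    if slot is None:
        return None
    ann = [("stop_gained", "HIGH", g.transcripts[0].transcript_id)]
    return SyntheticVariant(vid, g.gene_id, g.chromosome, slot[0], "A", "T",
                            "small", ann, carriers, None, False, "decoy_partial_tx")


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    truth: GroundTruth,
    kinship: pd.DataFrame,
    config: SimulationConfig,
    expressed_genes: Sequence[str],
    effect_table: Sequence[Tuple[str, str, float]],
) -> pd.DataFrame:
    """Phenotypes y = sum(x * beta * sd_e) + u + e with u ~ N(0, s2g K).

    The kinship matrix is trace-normalized so that the average marginal
    variance of u equals s2g; with s2g = h2 and s2e = 1 - h2, the realized
    variance ratio var(u) / (var(u) + var(e)) targets the configured
    heritability.  Effect sizes are in residual-SD units.  Raises when
    h2 = 1 is requested (the model always carries a residual term).
    """
    if config.h2 >= 1.0:
        raise ValueError("h2 = 1 with a nonzero residual term is contradictory")
    rng = config.rng(4)
    acc = list(truth.true_burden.index)
    n = len(acc)
    K = kinship.loc[acc, acc].to_numpy()
    Ks = K * (n / max(np.trace(K), 1e-12))
    # Cholesky with jitter for the PSD-but-singular centered kinship
    jitter = 1e-8 * np.eye(n)
    Lc = np.linalg.cholesky(Ks + jitter)
    s2g, s2e = config.h2, 1.0 - config.h2
    effects_by_target: Dict[str, List[Tuple[str, float]]] = {}
    for causal, target, beta in effect_table:
        if causal not in truth.true_burden.columns:
            raise ValueError(f"effect table references unknown gene {causal}")
        effects_by_target.setdefault(target, []).append((causal, beta))
    out = {}
    for gid in expressed_genes:
        u = np.sqrt(s2g) * (Lc @ rng.standard_normal(n))
        e = np.sqrt(s2e) * rng.standard_normal(n)
        y = u + e
        for causal, beta in effects_by_target.get(gid, []):
            x = truth.true_burden[causal].to_numpy(dtype=float)
            y = y + beta * np.sqrt(s2e) * x
        out[gid] = y
        vu, ve = float(np.var(u, ddof=1)), float(np.var(e, ddof=1))
        truth.variance_components[gid] = (s2g, s2e)
        truth.realized_h2[gid] = vu / (vu + ve)
    truth.true_effects = list(effect_table)
    return pd.DataFrame(out, index=acc)


def plant_effects(
    genes: GeneSet,
    truth: GroundTruth,
    expressed_genes: Sequence[str],
    config: SimulationConfig,
) -> List[Tuple[str, str, float]]:
    """Choose (causal gene, target phenotype, beta) triples with known truth.

    Causal genes need a common burden (frequency in [0.05, 0.45] so the
    minor-allele filter keeps them); targets sit on a different chromosome
    and neither member is annotated hypothetical, so planted pairs are not
    removed by the linkage or annotation filters by construction.
    """
    rng = config.rng(5)
    freq = truth.true_burden.mean(axis=0)
    ok_causal = [
        gid for gid in truth.true_burden.columns
        if 0.05 <= freq[gid] <= 0.45 and genes[gid].annotation_class != "hypothetical"
    ]
    ok_target = [
        gid for gid in expressed_genes if genes[gid].annotation_class != "hypothetical"
    ]
    rng.shuffle(ok_causal)
    table: List[Tuple[str, str, float]] = []
    used_targets: set = set()
    for causal in ok_causal:
        if len(table) >= config.n_effects:
            break
        cands = [
            t for t in ok_target
            if t not in used_targets and t != causal
            and genes[t].chromosome != genes[causal].chromosome
        ]
        if not cands:
            continue
        target = cands[int(rng.integers(len(cands)))]
        used_targets.add(target)
        sign = 1.0 if rng.random() < 0.7 else -1.0  # knockouts mostly up-regulate targets here
        table.append((causal, target, sign * config.effect_size))
    return table


@dataclass
class HeterogeneityStudy:
    """A focused allelic-heterogeneity fixture for power comparisons."""

    collapsed: pd.DataFrame  # accession x causal gene burden
    uncollapsed: pd.DataFrame  # accession x allele carriers
    phenotypes: pd.DataFrame  # one phenotype per causal gene
    kinship: pd.DataFrame
    planted: List[Tuple[str, str]]  # (gene, phenotype) pairs
    allele_of: Dict[str, str]  # allele column -> gene


def simulate_heterogeneity_study(
    seed: int,
    n_accessions: int = 300,
    n_causal: int = 5,
    k_alleles: int = 4,
    allele_freq: float = 0.02,
    beta: float = 1.0,
    h2: float = 0.3,
    n_snps: int = 300,
) -> HeterogeneityStudy:
    """Causal genes carried by several rare, mutually exclusive LoF alleles.

    Each causal gene receives ``k_alleles`` independent alleles at frequency
    ``allele_freq`` with disjoint carrier sets, so the collapsed burden
    frequency is exactly ``k_alleles * allele_freq``.  One phenotype per
    gene carries the burden effect (``beta`` residual-SD units) on top of a
    kinship-structured polygenic background.  This is the regime where
    single-allele tests are underpowered but the collapsed burden is not.
    """
    cfg = SimulationConfig(n_accessions=n_accessions, n_snps=n_snps,
                           seed=seed, h2=h2)
    G, labels, K = simulate_population(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    acc = list(G.index)
    n = len(acc)
    k_carriers = max(1, int(round(allele_freq * n)))
    collapsed: Dict[str, np.ndarray] = {}
    uncoll: Dict[str, np.ndarray] = {}
    allele_of: Dict[str, str] = {}
    for i in range(n_causal):
        gid = f"causal{i:02d}"
        pool = rng.permutation(n)[: k_alleles * k_carriers]
        b = np.zeros(n, dtype=np.int8)
        for a in range(k_alleles):
            carr = np.zeros(n, dtype=np.int8)
            carr[pool[a * k_carriers:(a + 1) * k_carriers]] = 1
            aid = f"{gid}_allele{a}"
            uncoll[aid] = carr
            allele_of[aid] = gid
            b |= carr
        collapsed[gid] = b
    burden_df = pd.DataFrame(collapsed, index=acc)
    Kn = K.to_numpy()
    Ks = Kn * (n / np.trace(Kn))
    Lc = np.linalg.cholesky(Ks + 1e-8 * np.eye(n))
    s2g, s2e = h2, 1.0 - h2
    ph = {}
    planted = []
    for gid in burden_df.columns:
        u = np.sqrt(s2g) * (Lc @ rng.standard_normal(n))
        e = np.sqrt(s2e) * rng.standard_normal(n)
        pid = f"expr_{gid}"
        ph[pid] = u + e + beta * np.sqrt(s2e) * burden_df[gid].to_numpy()
        planted.append((gid, pid))
    return HeterogeneityStudy(
        collapsed=burden_df,
        uncollapsed=pd.DataFrame(uncoll, index=acc),
        phenotypes=pd.DataFrame(ph, index=acc),
        kinship=K,
        planted=planted,
        allele_of=allele_of,
    )


# ---------------------------------------------------------------------------
# feature tables

def simulate_feature_table(
    n_genes: int,
    signal: float,
    seed: int,
    n_features: int = 10,
    pos_fraction: float = 0.5,
    informative: int = 1,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-gene features with a class-conditional mean shift on some columns.

    The first ``informative`` features differ between classes by ``signal``
    standard deviations; the rest are pure noise.  ``pos_fraction`` sets the
    label imbalance, which is preserved exactly in the output.
    """
    if signal < 0:
        raise ValueError("signal must be >= 0")
    rng = np.random.default_rng(seed)
    n_pos = int(round(pos_fraction * n_genes))
    labels = np.zeros(n_genes, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    X = rng.standard_normal((n_genes, n_features))
    X[:, :informative] += signal * labels[:, None]
    idx = [f"gene{i:05d}" for i in range(n_genes)]
    cols = [f"feat{j:02d}" for j in range(n_features)]
    return (pd.DataFrame(X, index=idx, columns=cols),
            pd.Series(labels, index=idx, name="label"))


# ---------------------------------------------------------------------------
# writers & the dataset bundle

def write_vcf(
    variants: Sequence[SyntheticVariant],
    accessions: Sequence[str],
    path: str,
    small_only: bool = True,
) -> None:
    """VCF v4.2 with SnpEff-style ANN INFO and homozygous GT fields."""
    chroms = sorted({v.chromosome for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
                 "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
                 "Feature_Type | Feature_ID'\">\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for v in sorted(variants, key=lambda v: (v.chromosome, v.position)):
            if small_only and v.kind != "small":
                continue
            if v.kind == "small":
                ann = ",".join(
                    f"{v.alt}|{eff}|{imp}|{v.gene_id}|{v.gene_id}|transcript|{feat}"
                    for eff, imp, feat in v.ann_entries
                )
                info = f"ANN={ann}" if ann else "."
            else:
                info = f"SVTYPE=DEL;END={v.end}"
            gts = "\t".join("1/1" if c else "0/0" for c in v.carriers)
            fh.write(f"{v.chromosome}\t{v.position + 1}\t{v.variant_id}\t{v.ref}\t"
                     f"{v.alt}\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_deletions_tsv(
    variants: Sequence[SyntheticVariant], accessions: Sequence[str], path: str
) -> None:
    acc = np.asarray(accessions)
    with open(path, "w") as fh:
        for v in variants:
            if v.kind != "deletion":
                continue
            carr = ",".join(acc[v.carriers])
            fh.write(f"{v.chromosome}\t{v.position}\t{v.end}\t{v.variant_id}\t{carr}\n")


def write_deletions_vcf(
    variants: Sequence[SyntheticVariant], accessions: Sequence[str], path: str
) -> None:
    write_vcf([v for v in variants if v.kind == "deletion"], accessions, path,
              small_only=False)


@dataclass
class SyntheticDataset:
    """The full synthetic study, in memory plus (optionally) on disk."""

    config: SimulationConfig
    genotypes: pd.DataFrame
    subpops: pd.Series
    kinship: pd.DataFrame
    genes: GeneSet
    variants: List[SyntheticVariant]
    truth: GroundTruth
    expression: pd.DataFrame
    expressed_genes: List[str]


def simulate_dataset(config: SimulationConfig, out_dir: Optional[str] = None) -> SyntheticDataset:
    """Generate the complete study and optionally write all artefacts.

    Files written: annotated small-variant VCF, deletions (TSV and symbolic
    VCF), GFF3 gene models, genotype/kinship/expression/burden-truth TSVs,
    and a JSON echoing the config plus the planted effect table.
    """
    config.validate()
    G, subpops, K = simulate_population(config)
    genes = simulate_gene_annotation(config)
    variants, truth = simulate_lof_variants(genes, list(G.index), config)
    truth.subpop_labels = subpops
    rng = config.rng(6)
    expressed = list(rng.choice(list(genes), size=config.n_expressed_genes, replace=False))
    effect_table = (config.effect_table if config.effect_table is not None
                    else plant_effects(genes, truth, expressed, config))
    expression = simulate_expression(truth, K, config, expressed, effect_table)
    ds = SyntheticDataset(config, G, subpops, K, genes, variants, truth,
                          expression, expressed)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        acc = list(G.index)
        write_vcf(variants, acc, os.path.join(out_dir, "variants.vcf"))
        write_deletions_tsv(variants, acc, os.path.join(out_dir, "deletions.tsv"))
        write_deletions_vcf(variants, acc, os.path.join(out_dir, "deletions.vcf"))
        write_gff3(genes.values(), os.path.join(out_dir, "genes.gff3"))
        G.to_csv(os.path.join(out_dir, "genotypes.tsv"), sep="\t", index_label="accession")
        K.to_csv(os.path.join(out_dir, "kinship.tsv"), sep="\t", index_label="accession")
        expression.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t",
                          index_label="accession")
        truth.true_burden.to_csv(os.path.join(out_dir, "true_burden.tsv"), sep="\t",
                                 index_label="accession")
        meta = {
            "config": {k: v for k, v in asdict(config).items() if k != "effect_table"},
            "effect_table": [list(t) for t in (effect_table or [])],
            "realized_h2": truth.realized_h2,
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
    return ds
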