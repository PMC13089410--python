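"""Rule-based loss-of-function (LoF) calling.

A variant knocks a gene out when it disrupts *every* transcript of the gene:

* small variants: SnpEff HIGH-impact effects of the six disruptive classes
  (stop gained/lost, start lost, frameshift, splice donor/acceptor);
* structural deletions: the deletion removes a stretch of spliced CDS whose
  length is not divisible by three (frameshift) or more than 10% of the
  transcript's coding sequence;
* terminal exemption: a variant whose entire CDS footprint lies in the first
  or last 5% of the coding sequence is assumed rescuable by an alternative
  start/stop codon and is never counted as LoF.

Verdicts carry the rule that fired, so a call set is auditable.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import GeneModel, GeneSet, TranscriptModel

logger = logging.getLogger(__name__)

HIGH_IMPACT_TERMS = frozenset(
    {
        "stop_lost",
        "stop_gained",
        "start_lost",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
    }
)

RULE_SNPEFF = "snpeff_high"
RULE_DEL_FRAMESHIFT = "deletion_frameshift"
RULE_DEL_GT10 = "deletion_gt10pct"
RULE_EXEMPT = "end_exempt"
RULE_PARTIAL = "partial_transcripts"
RULE_NONE = "none"

LOF_RULES = (RULE_SNPEFF, RULE_DEL_FRAMESHIFT, RULE_DEL_GT10)


def _normalize_effect(term: str) -> str:
    term = term.strip().lower()
    if term.endswith("_variant"):
        term = term[: -len("_variant")]
    if term.endswith("_variants"):
        term = term[: -len("_variants")]
    return term


def is_lof_effect(term: str) -> bool:
    """True for the six disruptive SnpEff effect classes (suffix-tolerant)."""
    return any(_normalize_effect(t) in HIGH_IMPACT_TERMS for t in term.split("&"))


@dataclass
class VariantRecord:
    """One alternate allele of one site, with per-accession carrier states."""

    variant_id: str
    chromosome: str
    position: int  # 0-based
    ref: str
    alt: str
    variant_class: str  # snv | indel | deletion_sv
    carriers: np.ndarray  # bool per accession
    end: Optional[int] = None  # 0-based half-open end, deletions only
    snpeff_annotations: List[Tuple[str, str, str]] = field(default_factory=list)
    n_missing: int = 0

    @property
    def interval(self) -> Tuple[int, int]:
        if self.variant_class == "deletion_sv":
            if self.end is None:
                raise ValueError(f"{self.variant_id}: deletion without END")
            return (self.position, self.end)
        return (self.position, self.position + max(1, len(self.ref)))


def classify_deletion(
    deletion: Tuple[int, int],
    transcript: TranscriptModel,
    cds_frac: float = 0.10,
) -> Tuple[str, str]:
    """Classify a deletion against one transcript.

    Returns ``(verdict, rule)`` where verdict is ``"LoF"`` or ``"not_LoF"``.
    The overlap ``o`` is summed over CDS exons only; introns do not count.
    LoF iff ``o > 0 and o % 3 != 0`` (frameshift) or ``o / L > cds_frac``.
    """
    start, end = deletion
    if end <= start:
        raise ValueError(f"zero-length deletion interval ({start},{end})")
    L = transcript.spliced_cds_length
    if L <= 0:
        raise ValueError(f"{transcript.transcript_id}: empty CDS")
    o = transcript.cds_overlap(start, end)
    if o > 0 and o % 3 != 0:
        return "LoF", RULE_DEL_FRAMESHIFT
    if o / L > cds_frac:
        return "LoF", RULE_DEL_GT10
    return "not_LoF", RULE_NONE


def end_exemption(
    cds_footprint: Optional[Tuple[int, int]],
    transcript: TranscriptModel,
    exempt_frac: float = 0.05,
) -> bool:
    """Terminal-CDS exemption for one (variant, transcript) pair.

    ``cds_footprint`` is the variant's spliced-CDS window, 0-based half-open
    (``None`` when the variant does not touch the CDS, e.g. splice-site
    variants — those are never exempt).  With 1-based CDS positions and
    length L, the exempt windows are [1, ceil(f*L)] and [floor((1-f)*L)+1, L];
    a variant is exempt only when its whole footprint sits inside one window.
    """
    if cds_footprint is None:
        return False
    L = transcript.spliced_cds_length
    lo, hi = cds_footprint  # 0-based half-open
    head = int(np.ceil(exempt_frac * L))  # first `head` bases exempt
    tail_start = int(np.floor((1.0 - exempt_frac) * L))  # 0-based
    return hi <= head or lo >= tail_start


def _transcript_verdict(
    variant: VariantRecord,
    transcript: TranscriptModel,
    strand: str,
    snpeff_hit: bool,
    exempt_frac: float,
    cds_frac: float,
) -> Tuple[str, str]:
    """Verdict and rule for one (variant, transcript) pair."""
    start, end = variant.interval
    footprint = transcript.cds_footprint(start, end, strand)
    if variant.variant_class == "deletion_sv":
        verdict, rule = classify_deletion((start, end), transcript, cds_frac)
        if verdict == "LoF" and end_exemption(footprint, transcript, exempt_frac):
            return "not_LoF", RULE_EXEMPT
        return verdict, rule
    if not snpeff_hit:
        return "not_LoF", RULE_NONE
    if end_exemption(footprint, transcript, exempt_frac):
        return "not_LoF", RULE_EXEMPT
    return "LoF", RULE_SNPEFF


def gene_level_verdict(
    variant: VariantRecord,
    gene: GeneModel,
    snpeff_transcripts: Optional[set] = None,
    exempt_frac: float = 0.05,
    cds_frac: float = 0.10,
) -> Tuple[str, str]:
    """Aggregate per-transcript verdicts: LoF only if every transcript is hit.

    For small variants, ``snpeff_transcripts`` holds the transcript ids with a
    HIGH-impact disruptive annotation; transcripts without one veto the call.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    rules = []
    for t in gene.transcripts:
        hit = snpeff_transcripts is None or t.transcript_id in snpeff_transcripts
        verdict, rule = _transcript_verdict(
            variant, t, gene.strand, hit, exempt_frac, cds_frac
        )
        if verdict != "LoF":
            reason = RULE_EXEMPT if rule == RULE_EXEMPT else RULE_PARTIAL
            return "not_LoF", reason
        rules.append(rule)
    return "LoF", rules[0]


@dataclass
class LoFCallSet:
    """Per (variant, gene) verdicts plus carrier vectors for LoF calls."""

    accessions: List[str]
    entries: pd.DataFrame  # variant_id, gene_id, verdict, rule_fired, n_carriers
    carriers: Dict[Tuple[str, str], np.ndarray]  # (variant, gene) -> bool vector

    @property
    def lof_entries(self) -> pd.DataFrame:
        return self.entries[self.entries["verdict"] == "LoF"]

    def rule_counts(self) -> pd.Series:
        return self.entries.groupby("rule_fired").size()

    def to_tsv(self, path: str) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def parse_snpeff_candidates(vcf_path: str) -> List[VariantRecord]:
    """Read a SnpEff-annotated VCF, keeping HIGH-impact disruptive candidates.

    Multi-allelic sites are decomposed per alternate allele.  Records whose
    annotations are all below HIGH impact (or not of the six classes) are
    dropped.  Raises a format error when no record in the file carries an
    ANN/EFF field.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    out: List[VariantRecord] = []
    saw_ann = False
    for rec in vcf:
        ann_entries = _parse_ann_info(rec)
        if ann_entries is None:
            continue
        saw_ann = True
        gts = np.asarray(rec.genotypes, dtype=object)
        for alt_idx, alt in enumerate(rec.ALT):
            allele_num = alt_idx + 1
            keep = [
                (eff, imp, feat)
                for allele, eff, imp, feat in ann_entries
                if (allele in ("", alt)) and imp.upper() == "HIGH" and is_lof_effect(eff)
            ]
            if not keep:
                continue
            carriers = np.zeros(len(samples), dtype=bool)
            n_missing = 0
            for i, g in enumerate(rec.genotypes):
                alleles = [a for a in g[:-1]]
                if all(a < 0 for a in alleles):
                    n_missing += 1  # missing genotype treated as functional
                elif allele_num in alleles:
                    carriers[i] = True
            vid = rec.ID or f"{rec.CHROM}_{rec.POS}_{rec.REF}_{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}_alt{allele_num}"
            vclass = "snv" if len(rec.REF) == 1 and len(alt) == 1 else "indel"
            out.append(
                VariantRecord(
                    variant_id=vid,
                    chromosome=rec.CHROM,
                    position=rec.POS - 1,
                    ref=rec.REF,
                    alt=alt,
                    variant_class=vclass,
                    carriers=carriers,
                    snpeff_annotations=keep,
                    n_missing=n_missing,
                )
            )
    if not saw_ann:
        raise ValueError(f"no ANN/EFF annotations found in any record of {vcf_path}")
    return out


def _parse_ann_info(rec) -> Optional[List[Tuple[str, str, str, str]]]:
    """Extract (allele, effect, impact, feature_id) tuples from ANN or EFF."""
    try:
        ann = rec.INFO.get("ANN")
    except Exception:
        ann = None
    entries: List[Tuple[str, str, str, str]] = []
    if ann:
        for sub in str(ann).split(","):
            fields = sub.split("|")
            if len(fields) < 7:
                warnings.warn(f"malformed ANN subfield at {rec.CHROM}:{rec.POS}: {sub!r}")
                continue
            # SnpEff ANN: Allele|Annotation|Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID
            entries.append((fields[0], fields[1], fields[2], fields[6]))
        return entries
    try:
        eff = rec.INFO.get("EFF")
    except Exception:
        eff = None
    if eff:
        for sub in str(eff).split(","):
            if "(" not in sub or not sub.endswith(")"):
                warnings.warn(f"malformed EFF subfield at {rec.CHROM}:{rec.POS}: {sub!r}")
                continue
            effect, rest = sub.split("(", 1)
            fields = rest[:-1].split("|")
            if len(fields) < 9:
                warnings.warn(f"malformed EFF subfield at {rec.CHROM}:{rec.POS}: {sub!r}")
                continue
            # EFF: Impact|FunClass|Codon|AA|AA_len|Gene|BioType|Coding|Transcript
            entries.append(("", effect, fields[0], fields[8]))
        return entries
    return None


def read_deletions_tsv(path: str, accessions: Sequence[str]) -> List[VariantRecord]:
    """Read deletions from a BED-like TSV.

    Columns: chrom, start (0-based), end, variant_id, carriers
    (comma-separated accession ids; empty string for none).
    """
    idx = {a: i for i, a in enumerate(accessions)}
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "variant_id", "carriers"],
        header=None,
        comment="#",
        dtype={"carriers": str},
    )
    out = []
    for row in df.itertuples(index=False):
        carriers = np.zeros(len(accessions), dtype=bool)
        if isinstance(row.carriers, str) and row.carriers:
            for a in row.carriers.split(","):
                carriers[idx[a]] = True
        out.append(
            VariantRecord(
                variant_id=str(row.variant_id),
                chromosome=str(row.chrom),
                position=int(row.start),
                ref="N",
                alt="<DEL>",
                variant_class="deletion_sv",
                end=int(row.end),
                carriers=carriers,
            )
        )
    return out


def read_deletions_vcf(path: str) -> List[VariantRecord]:
    """Read symbolic ``<DEL>`` records (with INFO END) from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    out = []
    for rec in vcf:
        if not rec.ALT or rec.ALT[0] != "<DEL>":
            continue
        end = rec.INFO.get("END")
        if end is None:
            raise ValueError(f"<DEL> without END at {rec.CHROM}:{rec.POS}")
        carriers = np.zeros(len(samples), dtype=bool)
        n_missing = 0
        for i, g in enumerate(rec.genotypes):
            alleles = g[:-1]
            if all(a < 0 for a in alleles):
                n_missing += 1
            elif 1 in alleles:
                carriers[i] = True
        out.append(
            VariantRecord(
                variant_id=rec.ID or f"{rec.CHROM}_{rec.POS}_DEL",
                chromosome=rec.CHROM,
                position=rec.POS - 1,
                ref=rec.REF,
                alt="<DEL>",
                variant_class="deletion_sv",
                end=int(end),
                carriers=carriers,
                n_missing=n_missing,
            )
        )
    return out


def call_lof(
    vcf_path: Optional[str],
    deletions: Optional[Sequence[VariantRecord]],
    genes: GeneSet,
    accessions: Sequence[str],
    exempt_frac: float = 0.05,
    cds_frac: float = 0.10,
) -> LoFCallSet:
    """Run the full rule cascade and return the audited call set.

    Small-variant candidates come from the annotated VCF; deletions are
    matched to genes by CDS-span overlap.  A gene referenced in an
    annotation but absent from the gene set is skipped with a warning.
    """
    accessions = list(accessions)
    feature_to_gene: Dict[str, str] = {}
    for g in genes.values():
        for t in g.transcripts:
            feature_to_gene[t.transcript_id] = g.gene_id
    rows = []
    carriers: Dict[Tuple[str, str], np.ndarray] = {}
    n_skipped_unknown_gene = 0

    small = parse_snpeff_candidates(vcf_path) if vcf_path else []
    for var in small:
        hit_by_gene: Dict[str, set] = {}
        for eff, imp, feat in var.snpeff_annotations:
            gene_id = feature_to_gene.get(feat)
            if gene_id is None:
                n_skipped_unknown_gene += 1
                continue
            hit_by_gene.setdefault(gene_id, set()).add(feat)
        for gene_id, feats in hit_by_gene.items():
            gene = genes[gene_id]
            verdict, rule = gene_level_verdict(
                var, gene, snpeff_transcripts=feats,
                exempt_frac=exempt_frac, cds_frac=cds_frac,
            )
            rows.append((var.variant_id, gene_id, verdict, rule,
                         int(var.carriers.sum())))
            if verdict == "LoF":
                carriers[(var.variant_id, gene_id)] = var.carriers.copy()

    for var in deletions or []:
        start, end = var.interval
        for g in genes.values():
            if g.chromosome != var.chromosome:
                continue
            gs, ge = g.span
            if end <= gs or start >= ge:
                continue
            verdict, rule = gene_level_verdict(
                var, g, snpeff_transcripts=None,
                exempt_frac=exempt_frac, cds_frac=cds_frac,
            )
            rows.append((var.variant_id, g.gene_id, verdict, rule,
                         int(var.carriers.sum())))
            if verdict == "LoF":
                carriers[(var.variant_id, g.gene_id)] = var.carriers.copy()

    if n_skipped_unknown_gene:
        warnings.warn(
            f"{n_skipped_unknown_gene} annotation entries referenced features "
            "absent from the gene set and were skipped"
        )
    entries = pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "verdict", "rule_fired", "n_carriers"]
    ).drop_duplicates(subset=["variant_id", "gene_id"])
    logger.info("LoF calling: %d (variant, gene) pairs, %d LoF",
                len(entries), int((entries["verdict"] == "LoF").sum()))
    return LoFCallSet(accessions=accessions, entries=entries, carriers=carriers)
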