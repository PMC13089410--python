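"""Gene and transcript models with GFF3 input/output.

Internally all intervals are 0-based half-open ``[start, end)``.  GFF3 is
1-based inclusive; the conversion happens only at the file boundary.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import gffutils

Interval = Tuple[int, int]  # 0-based half-open genomic interval


@dataclass
class TranscriptModel:
    """One transcript: an ordered set of CDS intervals on a chromosome.

    ``cds_intervals`` are stored sorted by genomic coordinate; transcript
    orientation (5'->3') is resolved through the parent gene's strand when
    mapping genomic positions to spliced-CDS coordinates.
    """

    transcript_id: str
    cds_intervals: List[Interval]

    def __post_init__(self) -> None:
        self.cds_intervals = sorted((int(s), int(e)) for s, e in self.cds_intervals)
        for (s, e) in self.cds_intervals:
            if e <= s:
                raise ValueError(f"empty CDS interval ({s},{e}) in {self.transcript_id}")
        for (_, e0), (s1, _) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping CDS intervals in {self.transcript_id}")

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> Interval:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    def genomic_to_cds(self, pos: int, strand: str) -> int | None:
        """Map a 0-based genomic position to a 0-based spliced-CDS offset.

        Returns ``None`` for intronic/outside positions.  Position 0 of the
        spliced CDS is the first base of the start codon, so on the minus
        strand counting runs from the rightmost interval leftwards.
        """
        acc = 0
        if strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos < e:
                    return acc + (pos - s)
                acc += e - s
            return None
        acc = 0
        for s, e in reversed(self.cds_intervals):
            if s <= pos < e:
                return acc + (e - 1 - pos)
            acc += e - s
        return None

    def cds_overlap(self, start: int, end: int) -> int:
        """Total spliced-CDS bases overlapped by genomic interval [start, end)."""
        o = 0
        for s, e in self.cds_intervals:
            o += max(0, min(e, end) - max(s, start))
        return o

    def cds_footprint(self, start: int, end: int, strand: str) -> Tuple[int, int] | None:
        """Spliced-CDS footprint (0-based half-open) of a genomic interval.

        Returns the smallest CDS-coordinate window containing every
        overlapped CDS base, or ``None`` when the interval misses the CDS.
        """
        hits: List[int] = []
        for s, e in self.cds_intervals:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                a = self.genomic_to_cds(lo, strand)
                b = self.genomic_to_cds(hi - 1, strand)
                hits.extend((a, b))
        if not hits:
            return None
        return (min(hits), max(hits) + 1)


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chromosome and strand."""

    gene_id: str
    chromosome: str
    strand: str
    transcripts: List[TranscriptModel]
    annotation_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))

    @property
    def midpoint(self) -> float:
        s, e = self.span
        return (s + (e - 1)) / 2.0 + 1  # midpoint of 1-based start/end

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


GeneSet = Dict[str, GeneModel]


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Write a gene->mRNA->CDS hierarchy as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.span[0])):
            gs, ge = g.span
            attrs = f"ID={g.gene_id};annotation_class={g.annotation_class}"
            fh.write(
                f"{g.chromosome}\tlofburden\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                fh.write(
                    f"{g.chromosome}\tlofburden\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(t.cds_intervals):
                    fh.write(
                        f"{g.chromosome}\tlofburden\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID=cds-{t.transcript_id}-{i};Parent={t.transcript_id}\n"
                    )


def read_gff3(path: str) -> GeneSet:
    """Parse a GFF3 with gene->mRNA->CDS hierarchy into GeneModel objects."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: GeneSet = {}
    for gene in db.features_of_type("gene"):
        transcripts: List[TranscriptModel] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [
                (c.start - 1, c.end)  # GFF3 1-based inclusive -> 0-based half-open
                for c in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            if cds:
                transcripts.append(TranscriptModel(mrna.id, cds))
        if not transcripts:
            continue
        klass = gene.attributes.get("annotation_class", ["protein_coding"])[0]
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            transcripts=transcripts,
            annotation_class=klass,
        )
    return genes


def gene_coordinate_table(genes: GeneSet):
    """Per-gene chromosome and midpoint, used for distance filtering/plots."""
    import pandas as pd

    rows = [
        {"gene_id": g.gene_id, "chromosome": g.chromosome, "midpoint": g.midpoint}
        for g in genes.values()
    ]
    return pd.DataFrame(rows).set_index("gene_id")
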