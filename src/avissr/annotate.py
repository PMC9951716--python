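"""Genomic-compartment assignment of SSR loci from GFF3 annotation.

Loci are labelled CDS, exon_noncoding, intron or intergenic by the position
of their midpoint, with precedence CDS > exon_noncoding > intron >
intergenic.  Introns are always derived as the gaps between consecutive
exons of one transcript, never read from the file; for multi-transcript
genes the transcript with the largest summed exon length represents the
gene.  Exon/intron ranks are counted from both gene ends honouring strand,
so rank r from the 5' end and rank r' from the 3' end of an n-exon gene
satisfy r + r' = n + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .detect import SSRLocus

logger = logging.getLogger(__name__)

REGION_LABELS = ("CDS", "exon_noncoding", "intron", "intergenic")


@dataclass
class GeneRecord:
    """One gene reduced to its representative transcript (0-based half-open)."""

    gene_id: str
    seq_id: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]     # genomic order
    introns: list[tuple[int, int]]   # genomic order
    cds: list[tuple[int, int]]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def rank_from_5p(self, genomic_index: int, feature: str) -> int:
        """5'->3' rank (1-based) of the exon/intron at *genomic_index*."""
        n = self.n_exons if feature == "exon" else self.n_introns
        return genomic_index + 1 if self.strand == "+" else n - genomic_index


@dataclass
class AnnotationIndex:
    """Interval structures for region queries over one annotation set."""

    genes: dict[str, GeneRecord]
    cds_tree: dict[str, IntervalTree]
    exon_tree: dict[str, IntervalTree]      # data: (gene_id, genomic_index)
    intron_tree: dict[str, IntervalTree]    # data: (gene_id, genomic_index)
    skipped_features: int = 0

    def seq_ids(self):
        return set(self.exon_tree) | set(self.cds_tree) | set(self.intron_tree)


def _derive_introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def build_annotation_index(gff3_path) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GFF3 file.

    Expects gene features with mRNA/transcript children carrying exon (and
    optionally CDS) grandchildren; exons attached directly to a gene are
    also accepted.  Exons extending outside their gene span are clamped with
    a warning; features without a resolvable parent are skipped and counted.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    genes: dict[str, GeneRecord] = {}
    skipped = 0

    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        gspan = (gene.start - 1, gene.end)  # to 0-based half-open
        transcripts = [
            t for t in db.children(gene, level=1)
            if t.featuretype in ("mRNA", "transcript")
        ]
        best_exons: list[tuple[int, int]] = []
        best_cds: list[tuple[int, int]] = []
        candidates = transcripts if transcripts else [gene]
        for tr in candidates:
            exons = sorted(
                (f.start - 1, f.end)
                for f in db.children(tr, level=1, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end)
                for f in db.children(tr, level=1, featuretype="CDS")
            )
            if not exons and cds:
                exons = list(cds)
            if sum(e - s for s, e in exons) > sum(e - s for s, e in best_exons):
                best_exons, best_cds = exons, cds
        if not best_exons:
            skipped += 1
            continue
        clamped = []
        for s, e in best_exons:
            if s < gspan[0] or e > gspan[1]:
                logger.warning("exon %s-%s outside gene %s span; clamped",
                               s, e, gene_id)
                s, e = max(s, gspan[0]), min(e, gspan[1])
            clamped.append((s, e))
        genes[gene_id] = GeneRecord(
            gene_id=gene_id, seq_id=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=clamped, introns=_derive_introns(clamped), cds=best_cds,
        )

    cds_tree: dict[str, IntervalTree] = {}
    exon_tree: dict[str, IntervalTree] = {}
    intron_tree: dict[str, IntervalTree] = {}
    for rec in genes.values():
        for s, e in rec.cds:
            cds_tree.setdefault(rec.seq_id, IntervalTree()).addi(s, e, rec.gene_id)
        for i, (s, e) in enumerate(rec.exons):
            exon_tree.setdefault(rec.seq_id, IntervalTree()).addi(
                s, e, (rec.gene_id, i))
        for i, (s, e) in enumerate(rec.introns):
            intron_tree.setdefault(rec.seq_id, IntervalTree()).addi(
                s, e, (rec.gene_id, i))
    if skipped:
        logger.warning("skipped %d gene(s) without exon features", skipped)
    return AnnotationIndex(genes, cds_tree, exon_tree, intron_tree, skipped)


def _point_hits(tree: dict[str, IntervalTree], seq_id: str, point: int):
    t = tree.get(seq_id)
    return sorted(t[point], key=lambda iv: (iv.begin, iv.end)) if t else []


def assign_region(locus: SSRLocus, index: AnnotationIndex) -> str:
    """Region label for one locus, decided at its midpoint.

    Precedence CDS > exon_noncoding > intron > intergenic; a locus on a
    sequence absent from the annotation is intergenic.
    """
    mid = (locus.start + locus.end) // 2
    if _point_hits(index.cds_tree, locus.seq_id, mid):
        return "CDS"
    if _point_hits(index.exon_tree, locus.seq_id, mid):
        return "exon_noncoding"
    if _point_hits(index.intron_tree, locus.seq_id, mid):
        return "intron"
    return "intergenic"


def assign_regions(loci, index: AnnotationIndex) -> list[str]:
    """Vector of :func:`assign_region` labels, one per locus."""
    return [assign_region(l, index) for l in loci]


def locate_feature(locus: SSRLocus, index: AnnotationIndex):
    """(feature, gene, genomic_index) of the exon/intron holding the midpoint.

    Returns None for intergenic loci.  Exonic hits (CDS or not) resolve to
    the containing exon; ties between overlapping genes break on the
    earliest interval, then gene id.
    """
    mid = (locus.start + locus.end) // 2
    hits = _point_hits(index.exon_tree, locus.seq_id, mid)
    if hits:
        gene_id, idx = min(h.data for h in hits)
        return "exon", index.genes[gene_id], idx
    hits = _point_hits(index.intron_tree, locus.seq_id, mid)
    if hits:
        gene_id, idx = min(h.data for h in hits)
        return "intron", index.genes[gene_id], idx
    return None


def positional_profile(loci, index: AnnotationIndex, top_n: int = 30) -> pd.DataFrame:
    """Gene-end positional profile of SSR counts.

    For every locus falling in an exon or intron, the 5'->3' rank r and the
    3'->5' rank n - r + 1 of that feature are computed, and the locus
    increments both the 5'-indexed and the 3'-indexed profile at its rank,
    provided the rank does not exceed *top_n*.  Returns a DataFrame indexed
    by rank 1..top_n with columns exon_5p, exon_3p, intron_5p, intron_3p.
    """
    cols = ["exon_5p", "exon_3p", "intron_5p", "intron_3p"]
    prof = pd.DataFrame(
        0, index=pd.RangeIndex(1, top_n + 1, name="rank"), columns=cols
    )
    for locus in loci:
        hit = locate_feature(locus, index)
        if hit is None:
            continue
        feature, gene, idx = hit
        n = gene.n_exons if feature == "exon" else gene.n_introns
        r5 = gene.rank_from_5p(idx, feature)
        r3 = n - r5 + 1
        if r5 <= top_n:
            prof.loc[r5, f"{feature}_5p"] += 1
        if r3 <= top_n:
            prof.loc[r3, f"{feature}_3p"] += 1
    return prof
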