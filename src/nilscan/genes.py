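"""Candidate-gene intersection and codon-level variant effect annotation.

A gene "hits" an introgression region when their intervals overlap by at
least one base (1-based inclusive coordinates on both sides).  SNP effects
inside coding sequence are annotated by extracting the affected codon in
coding orientation (reverse-complement for minus-strand genes) and
translating with the standard genetic code; a substitution is synonymous
iff the amino acid is unchanged.

When a gene model carries no exon structure (the published candidate table
gives gene spans only), the whole span is treated as a single CDS starting
at the span's 5' end.  That approximation is adequate for first-exon SNPs
such as the three annotated flesh-colour variants, and hits derived from it
are flagged ``approximate``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

PSY1_GENE_ID = "ClCG01G008470"
#: 1-based offset of the flesh-colour SNP within the PSY1 gene span
#: (position 10,040,402 minus gene start 10,039,958): codon 149, position 1
PSY1_SNP_GENE_OFFSET = 444

CDS, INTRON, UPSTREAM, INTERGENIC = "CDS", "intron", "upstream", "intergenic"
SYNONYMOUS, NON_SYNONYMOUS, NON_CODING = "synonymous", "non_synonymous", "non_coding"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    #: True when the CDS is approximated by the whole gene span
    approximate_cds: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = e

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Genomic CDS intervals in ascending coordinate order."""
        return self.exons if self.exons else ((self.start, self.end),)


@dataclass(frozen=True)
class VariantEffect:
    gene_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    region: str  # CDS / intron / upstream / intergenic
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None  # 3-letter code
    aa_after: str | None = None
    effect_class: str = NON_CODING
    codon_number: int | None = None  # 1-based position in the protein

    def __str__(self) -> str:
        if self.effect_class == NON_CODING:
            return f"{self.ref}>{self.alt} ({self.region})"
        tag = "Syn" if self.effect_class == SYNONYMOUS else "Non-syn"
        return f"{self.ref}>{self.alt} ({tag}) {self.aa_before} > {self.aa_after}"


# --------------------------------------------------------------------------
# gene tables

def load_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a candidate-gene TSV (name, gene_id, chromosome, start, end,
    strand; '#' comments) into gene models without exon structure."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [GeneModel(gene_id=row.gene_id, name=row.name_, chromosome=row.chromosome,
                      start=int(row.start), end=int(row.end), strand=row.strand)
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)]


def carotenoid_genes() -> list[GeneModel]:
    """The 13 watermelon carotenoid-pathway genes (18 loci) shipped with the
    package, on real Charleston Gray coordinates."""
    ref = importlib.resources.files("nilscan.data") / "carotenoid_genes.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_gene_table(path)


def scaled_gene_models(config) -> list[GeneModel]:
    """The packaged carotenoid genes rescaled into a synthetic genome.

    Gene starts are scaled by (simulated length / 35 Mb assumed real
    chromosome); gene lengths are kept so in-gene offsets, and hence codon
    arithmetic, survive the scaling.  Genes on absent chromosomes or not
    fitting the scaled chromosome are dropped.
    """
    from .simulate import REAL_CHROM_BP

    out = []
    for gene in carotenoid_genes():
        if gene.chromosome not in config.chromosome_names:
            continue
        length = config.length_of(gene.chromosome)
        start = max(1, round(gene.start * length / REAL_CHROM_BP))
        end = start + (gene.end - gene.start)
        if end > length:
            continue
        out.append(GeneModel(gene.gene_id, gene.name, gene.chromosome,
                             start, end, gene.strand))
    return out


# --------------------------------------------------------------------------
# region intersection

def genes_in_regions(genes: Sequence[GeneModel], regions: Iterable) -> pd.DataFrame:
    """Genes overlapping introgression regions by >= 1 bp.

    Returns one row per (gene, region) hit with the region's NIL and
    shared/nil-specific category.  Raises if the two tables use disjoint
    chromosome naming systems.
    """
    regions = list(regions)
    gene_chroms = {g.chromosome for g in genes}
    region_chroms = {r.chromosome for r in regions}
    if genes and regions and not (gene_chroms & region_chroms):
        raise ValueError(
            "chromosome names do not match between gene and region tables: "
            f"genes use {sorted(gene_chroms)}, regions use {sorted(region_chroms)}")
    rows = []
    for gene in genes:
        for region in regions:
            if (gene.chromosome == region.chromosome
                    and gene.start <= region.end and region.start <= gene.end):
                rows.append({
                    "gene_id": gene.gene_id, "name": gene.name,
                    "chromosome": gene.chromosome,
                    "gene_start": gene.start, "gene_end": gene.end,
                    "strand": gene.strand,
                    "region_start": region.start, "region_end": region.end,
                    "nil_id": region.nil_id, "category": region.category,
                })
    return pd.DataFrame(rows, columns=["gene_id", "name", "chromosome",
                                       "gene_start", "gene_end", "strand",
                                       "region_start", "region_end",
                                       "nil_id", "category"])


# --------------------------------------------------------------------------
# codon effects

def _slice(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a genome (dict of str or pyfaidx.Fasta)."""
    return str(genome[chrom][start - 1:end]).upper()


def annotate_variant(
    snp: tuple[str, int, str, str],
    gene: GeneModel,
    genome: Mapping[str, object],
    upstream_bp: int = 2_000,
) -> VariantEffect:
    """Codon-level effect of a SNP (chromosome, 1-based position, ref, alt)
    on a gene model.

    The reference allele is checked against the genome (guarding coordinate
    bugs).  Positions inside the gene but outside its exons annotate as
    intron; within ``upstream_bp`` of the transcription start as upstream;
    elsewhere as intergenic.
    """
    chrom, pos, ref, alt = snp
    genome_base = _slice(genome, chrom, pos, pos)
    if not genome_base:
        raise IndexError(f"{chrom}:{pos} outside genome bounds")
    if genome_base != ref.upper():
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: genome has "
            f"{genome_base}, variant says {ref}")
    base_effect = dict(gene_id=gene.gene_id, chromosome=chrom, position=pos,
                       ref=ref, alt=alt)

    if chrom != gene.chromosome or not gene.start <= pos <= gene.end:
        if chrom == gene.chromosome:
            if gene.strand == "+" and gene.start - upstream_bp <= pos < gene.start:
                return VariantEffect(**base_effect, region=UPSTREAM)
            if gene.strand == "-" and gene.end < pos <= gene.end + upstream_bp:
                return VariantEffect(**base_effect, region=UPSTREAM)
        return VariantEffect(**base_effect, region=INTERGENIC)

    interval = next(((s, e) for s, e in gene.cds_intervals if s <= pos <= e), None)
    if interval is None:
        return VariantEffect(**base_effect, region=INTRON)

    # CDS coordinate of the SNP in coding orientation
    intervals = list(gene.cds_intervals)
    if gene.strand == "+":
        cds_pos = sum(e - s + 1 for s, e in intervals if e < pos) + (pos - interval[0])
    else:
        cds_pos = sum(e - s + 1 for s, e in intervals if s > pos) + (interval[1] - pos)

    cds_seq = "".join(_slice(genome, chrom, s, e) for s, e in intervals)
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        alt_coding = str(Seq(alt).complement())
    else:
        alt_coding = alt.upper()

    ci = cds_pos // 3
    codon_before = cds_seq[ci * 3:ci * 3 + 3]
    if len(codon_before) < 3:
        return VariantEffect(**base_effect, region=CDS)
    within = cds_pos % 3
    codon_after = codon_before[:within] + alt_coding + codon_before[within + 1:]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    return VariantEffect(
        **base_effect, region=CDS,
        codon_before=codon_before, codon_after=codon_after,
        aa_before=seq3(aa_before), aa_after=seq3(aa_after),
        effect_class=SYNONYMOUS if aa_before == aa_after else NON_SYNONYMOUS,
        codon_number=ci + 1)
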