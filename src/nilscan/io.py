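"""Readers and writers for the standard formats the pipeline speaks.

Internal coordinates are 1-based inclusive throughout; BED output is
converted to 0-based half-open on disk (and back on reading).  Per-line
VCFs carry allele read depths (AD) and total depth (DP) per record;
no-call loci are written as GT ./. with DP retained, which is how the
matrix builder recovers consensus fill-in depth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genes import GeneModel
from .introgression import IntrogressionRegion
from .snp_matrix import SnpMatrix

BASES = "ACGT"


# --------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path):
    """Indexed FASTA access (pyfaidx); slices are 0-based like strings."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


# --------------------------------------------------------------------------
# VCF

def write_vcf(calls: pd.DataFrame, path: str | Path, sample: str,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a per-line call table (columns chromosome, position, ref,
    A/C/G/T counts, depth, missing) as a single-sample VCF 4.2.

    Genotypes come from the truth columns when present (the upstream
    caller's call), otherwise from the majority alleles.  No-call rows are
    written GT ./. with DP only.
    """
    lines = ["##fileformat=VCFv4.2", "##source=nilscan"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in pd.unique(calls["chromosome"]):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    has_truth = "truth_allele1" in calls.columns
    for row in calls.itertuples(index=False):
        ref = row.ref
        counts = {b: int(getattr(row, b)) for b in BASES}
        alts = [b for b in BASES if b != ref and counts[b] > 0]
        if has_truth:
            for allele in (row.truth_allele1, row.truth_allele2):
                if allele != ref and allele not in alts:
                    alts.append(allele)
        alt_field = ",".join(alts) if alts else "."
        idx = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        missing = bool(getattr(row, "missing", False))
        if missing:
            fmt = f"./.:.:{int(row.depth)}"
        else:
            ad = ",".join(str(counts[a]) for a in [ref, *alts])
            if has_truth:
                gt = "/".join(str(idx[a]) for a in
                              sorted([row.truth_allele1, row.truth_allele2],
                                     key=lambda a: idx[a]))
            else:
                top = sorted(counts, key=counts.get, reverse=True)[:2]
                a1 = top[0]
                a2 = top[1] if counts[top[1]] >= 0.2 * max(row.depth, 1) else a1
                gt = "/".join(str(i) for i in sorted((idx.get(a1, 0), idx.get(a2, 0))))
            fmt = f"{gt}:{ad}:{int(row.depth)}"
        lines.append(f"{row.chromosome}\t{int(row.position)}\t.\t{ref}\t"
                     f"{alt_field}\t.\t.\t.\tGT:AD:DP\t{fmt}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> dict[str, pd.DataFrame]:
    """Read a VCF into per-sample call tables (per-base counts, depth,
    missing flag); multi-allelic records fold their allele depths into the
    per-base counts, conserving the total.

    Raises if a called record lacks allele depths (AD), naming the field.
    """
    vcf = VCF(str(path))
    names = list(vcf.samples)
    wanted = list(samples) if samples is not None else names
    unknown = set(wanted) - set(names)
    if unknown:
        raise KeyError(f"samples {sorted(unknown)} not in VCF {path}")
    cols: dict[str, list] = {s: [] for s in wanted}
    for i, variant in enumerate(vcf):
        ref = variant.REF.upper()
        alts = [a.upper() for a in variant.ALT]
        ad = variant.format("AD")
        dp = variant.format("DP")
        for s in wanted:
            j = names.index(s)
            gt = variant.genotypes[j]
            missing = gt[0] == -1
            counts = {b: 0 for b in BASES}
            if missing:
                depth = int(dp[j][0]) if dp is not None and dp[j][0] >= 0 else 0
            else:
                if ad is None:
                    raise KeyError(
                        f"record {variant.CHROM}:{variant.POS} (line {i + 1}) "
                        "has no allele-depth (AD) field")
                row_ad = np.atleast_1d(ad[j])
                alleles = [ref, *alts]
                for allele, depth_a in zip(alleles, row_ad):
                    if allele in counts and depth_a >= 0:
                        counts[allele] += int(depth_a)
                depth = int(dp[j][0]) if dp is not None and dp[j][0] >= 0 else sum(counts.values())
            cols[s].append((variant.CHROM, variant.POS, ref,
                            counts["A"], counts["C"], counts["G"], counts["T"],
                            depth, missing))
    out = {}
    for s in wanted:
        out[s] = pd.DataFrame(
            cols[s], columns=["chromosome", "position", "ref",
                              "A", "C", "G", "T", "depth", "missing"])
    return out


def read_call_sets(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read one single-sample VCF per line id."""
    out = {}
    for line_id, path in paths.items():
        frames = read_vcf(path)
        if line_id in frames:
            out[line_id] = frames[line_id]
        elif len(frames) == 1:
            out[line_id] = next(iter(frames.values()))
        else:
            raise KeyError(f"sample {line_id!r} not in {path}")
    return out


def decompose_multiallelic(calls: pd.DataFrame) -> pd.DataFrame:
    """Expand per-base count rows into biallelic (ref, alt) records, one
    per observed non-reference allele; counts are conserved."""
    rows = []
    for row in calls.itertuples(index=False):
        counts = {b: int(getattr(row, b)) for b in BASES}
        for alt in BASES:
            if alt != row.ref and counts[alt] > 0:
                rows.append((row.chromosome, row.position, row.ref, alt,
                             counts[row.ref], counts[alt], int(row.depth)))
    return pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt",
                                       "ref_count", "alt_count", "depth"])


# --------------------------------------------------------------------------
# GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};Name={g.name}"
        lines.append("\t".join([g.chromosome, "nilscan", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]))
        for s, e in g.cds_intervals:
            lines.append("\t".join([g.chromosome, "nilscan", "CDS", str(s),
                                    str(e), ".", g.strand, "0",
                                    f"ID={g.gene_id}.cds;Parent={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feature in db.features_of_type("gene"):
        cds = sorted((c.start, c.end) for c in db.children(feature, featuretype="CDS"))
        whole_span = cds == [(feature.start, feature.end)] or not cds
        genes.append(GeneModel(
            gene_id=feature.id,
            name=feature.attributes.get("Name", [feature.id])[0],
            chromosome=feature.seqid, start=feature.start, end=feature.end,
            strand=feature.strand,
            exons=() if whole_span else tuple(cds),
        ))
    return genes


# --------------------------------------------------------------------------
# BED (0-based half-open on disk, 1-based inclusive in memory)

def write_truth_bed(truth: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in truth.itertuples(index=False):
            name = f"{row.line_id}:{row.origin}:{row.zygosity}:{row.source}"
            fh.write(f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{name}\n")


def read_truth_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, name = line.split("\t")[:4]
        line_id, origin, zygosity, source = name.split(":")
        rows.append((line_id, chrom, int(start) + 1, int(end), origin,
                     zygosity, source))
    return pd.DataFrame(rows, columns=["line_id", "chromosome", "start", "end",
                                       "origin", "zygosity", "source"])


def write_regions_bed(regions: Iterable[IntrogressionRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.nil_id}:{r.donor_id}:{r.category}"
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{name}\t{r.snp_count}\n")


def read_regions_bed(path: str | Path) -> list[IntrogressionRegion]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, name, score = line.split("\t")[:5]
        nil_id, donor_id, category = name.split(":")
        out.append(IntrogressionRegion(
            chromosome=chrom, start=int(start) + 1, end=int(end),
            snp_count=int(score), nil_id=nil_id, donor_id=donor_id,
            category=category))
    return out


# --------------------------------------------------------------------------
# matrix TSV

_CELL_NONE = "."


def write_matrix_tsv(matrix: SnpMatrix, path: str | Path) -> None:
    """Locus rows x line columns; each cell is
    genotype|zygosity|depth|fill_source|ambiguous.  Header names the
    conventions."""
    with open(path, "w") as fh:
        fh.write("# positions 1-based inclusive; cell = "
                 "genotype|zygosity|depth|fill_source|ambiguous\n")
        fh.write("\t".join(["chromosome", "position", "ref", *matrix.lines]) + "\n")
        for i in range(matrix.n_loci):
            locus = matrix.loci.iloc[i]
            cells = []
            for line in matrix.lines:
                gt = matrix.genotype[line].iloc[i] or _CELL_NONE
                cells.append("|".join([
                    gt, matrix.zygosity[line].iloc[i],
                    str(int(matrix.depth[line].iloc[i])),
                    matrix.fill_source[line].iloc[i],
                    "1" if matrix.ambiguous[line].iloc[i] else "0"]))
            fh.write("\t".join([locus["chromosome"], str(int(locus["position"])),
                                locus["ref"], *cells]) + "\n")


def read_matrix_tsv(path: str | Path) -> SnpMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    lines = [c for c in df.columns if c not in ("chromosome", "position", "ref")]
    zyg, gt, dp, fill, amb = ({} for _ in range(5))
    for line in lines:
        parts = df[line].str.split("|", expand=True)
        gt[line] = parts[0].where(parts[0] != _CELL_NONE, None)
        zyg[line], fill[line] = parts[1], parts[3]
        dp[line] = parts[2].astype(np.int64)
        amb[line] = parts[4] == "1"
    return SnpMatrix(
        loci=df[["chromosome", "position", "ref"]].copy(),
        lines=lines,
        zygosity=pd.DataFrame(zyg), genotype=pd.DataFrame(gt),
        depth=pd.DataFrame(dp), fill_source=pd.DataFrame(fill),
        ambiguous=pd.DataFrame(amb))
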