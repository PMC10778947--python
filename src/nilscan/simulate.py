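"""Synthetic backcross-breeding simulator.

Generates truth-tagged founder genomes, BC2F4 near-isogenic lines (NILs),
F2 populations and noisy per-line SNP call sets, so every downstream stage
of the pipeline can be tested against known ground truth.

The breeding scheme mirrors NIL development by marker-free phenotypic
selection: an F1 between donor and recurrent parent is backcrossed twice to
the recurrent parent (keeping only gametes that carry the donor allele at
the selected trait locus), then selfed for three generations with selection
for the homozygous donor genotype at that locus.  The final selection step
resolves residual heterozygous background segments to fixation, modelling
the breeder's choice of a genetically fixed line.

Crossovers per chromosome per meiosis are Poisson with uniform breakpoint
positions and no interference.  Read depth is negative-binomial
(overdispersed, as in real resequencing); each read reports the wrong base
with probability ``error_rate``; whole loci drop out of the call table with
probability ``missing_rate`` (no genotype call, depth retained, emulating a
consensus-covered no-call).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _stable_hash(text: str) -> int:
    """Process-independent 31-bit hash for seeding per-line RNG streams."""
    return zlib.crc32(text.encode()) & 0x7FFFFFFF

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
# for each base index, the three other base indices (error targets)
_OTHER_IDX = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])

DEFAULT_RECURRENT = "DAH"
DEFAULT_DONORS = ("NB5410", "OTO9491")

#: physical size assumed for a real watermelon chromosome when scaling the
#: published carotenoid-gene coordinates into a smaller synthetic genome
REAL_CHROM_BP = 35_000_000


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and breeding scheme.

    Defaults give a desk-scale watermelon-like genome: the real karyotype
    of 11 chromosomes, each scaled to 3 Mb (~1/10 of a real ~35 Mb
    chromosome) so whole-genome runs stay fast; parental divergence of
    4e-4 SNPs/bp (the published parents differ at ~147k homozygous SNPs
    over a 350 Mb genome, i.e. ~4.2e-4/bp); ~15x mean depth as in the
    published resequencing; and 1.5 crossovers/chromosome/meiosis.
    Keeping all 11 chromosomes matters for the breeding background: with
    few chromosomes the donor-genome fraction after BC2 drifts wildly.
    """

    n_chromosomes: int = 11
    chromosome_lengths: tuple[int, ...] = (3_000_000,) * 11
    snp_density: float = 4e-4
    crossover_rate: float = 1.5
    #: (chromosome, 1-based position) of the selected trait locus; None
    #: resolves to the scaled phytoene-synthase (PSY1) first-exon SNP
    target_locus: tuple[str, int] | None = None
    depth_mean: float = 15.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.005
    missing_rate: float = 0.02
    seed: int = 0
    #: reference codon embedded around the target locus (the donor SNP then
    #: converts AAG/Lys into GAG/Glu at codon position ``target_codon_offset``)
    target_codon: str | None = "AAG"
    target_codon_offset: int = 0
    target_alt: str = "G"

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigError("chromosome_lengths must have n_chromosomes entries")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ConfigError("chromosome lengths must be positive")
        for name, value in [
            ("error_rate", self.error_rate),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.snp_density < 0 or self.crossover_rate < 0:
            raise ConfigError("rates must be non-negative")
        if self.depth_mean < 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth model parameters must be positive")
        if self.target_locus is not None:
            chrom, pos = self.target_locus
            if chrom not in self.chromosome_names:
                raise ConfigError(f"target chromosome {chrom} not in genome")
            if not 1 <= pos <= self.chromosome_lengths[self.chromosome_names.index(chrom)]:
                raise ConfigError("target_locus outside its chromosome")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def length_of(self, chrom: str) -> int:
        return self.chromosome_lengths[self.chromosome_names.index(chrom)]


def resolve_target_locus(config: SimConfig) -> tuple[str, int]:
    """The configured target locus, or the scaled PSY1 first-exon SNP.

    The published trait SNP sits 444 bp into the PSY1 gene span (codon 149,
    first codon position); the gene start is scaled into the synthetic
    chromosome and the in-gene offset kept unscaled so codon arithmetic
    survives the scaling.
    """
    if config.target_locus is not None:
        return config.target_locus
    from .genes import scaled_gene_models, PSY1_GENE_ID, PSY1_SNP_GENE_OFFSET

    for gene in scaled_gene_models(config):
        if gene.gene_id == PSY1_GENE_ID:
            pos = gene.start + PSY1_SNP_GENE_OFFSET
            if pos <= config.length_of(gene.chromosome):
                return (gene.chromosome, pos)
    # genome too small to host the scaled gene: fall back to mid-chromosome 1
    return (config.chromosome_names[0], config.chromosome_lengths[0] // 2)


# --------------------------------------------------------------------------
# founders

@dataclass
class Founders:
    config: SimConfig
    recurrent_id: str
    #: chromosome -> uint8 base codes (0..3); the recurrent genome equals this
    reference: dict[str, np.ndarray]
    #: donor -> DataFrame(chromosome, position, ref, alt) of divergent SNPs
    donor_snps: dict[str, pd.DataFrame]
    target_locus: tuple[str, int] = ("", 0)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.donor_snps)

    def reference_base(self, chrom: str, pos: int) -> str:
        return BASES[self.reference[chrom][pos - 1]]

    def reference_seq(self, chrom: str) -> str:
        return self.reference[chrom].tobytes().translate(
            bytes.maketrans(bytes(range(4)), b"ACGT")).decode()


def simulate_founders(
    config: SimConfig,
    recurrent_id: str = DEFAULT_RECURRENT,
    donor_ids: Sequence[str] = DEFAULT_DONORS,
    shared_segments: Sequence[tuple[str, int, int]] | None = None,
) -> Founders:
    """Draw a random reference genome and donor SNP truth lists.

    Each donor diverges from the recurrent parent at Poisson(density x
    length) uniformly placed positions, with alternate alleles uniform over
    the three non-reference bases.  Every donor additionally carries the
    forced trait SNP at the target locus (with the reference codon patched
    in so the variant has a defined codon effect).  Within
    ``shared_segments`` intervals all donors carry one common SNP set
    (an ancestral haplotype shared between donors), so shared-introgression
    detection can be exercised.
    """
    rng = np.random.default_rng([config.seed, 0xF0])
    reference = {
        chrom: rng.integers(0, 4, size=length, dtype=np.uint8)
        for chrom, length in zip(config.chromosome_names, config.chromosome_lengths)
    }

    target = resolve_target_locus(config)
    tchrom, tpos = target
    if config.target_codon is not None:
        codon_start = tpos - config.target_codon_offset  # 1-based
        if codon_start >= 1 and codon_start + 2 <= config.length_of(tchrom):
            for k, base in enumerate(config.target_codon):
                reference[tchrom][codon_start - 1 + k] = BASES.index(base)

    def draw_snps(chrom: str, length: int, local_rng) -> pd.DataFrame:
        n = min(local_rng.poisson(config.snp_density * length), length)
        pos = np.sort(local_rng.choice(length, size=n, replace=False)) + 1
        ref_codes = reference[chrom][pos - 1]
        alt_codes = (ref_codes + local_rng.integers(1, 4, size=n)) % 4
        return pd.DataFrame({
            "chromosome": chrom,
            "position": pos.astype(np.int64),
            "ref": [BASES[c] for c in ref_codes],
            "alt": [BASES[c] for c in alt_codes],
        })

    shared_segments = list(shared_segments or [])
    shared_pool = []
    for chrom, start, end in shared_segments:
        seg = draw_snps(chrom, config.length_of(chrom), rng)
        seg = seg[(seg["position"] >= start) & (seg["position"] <= end)]
        shared_pool.append(seg)

    def in_shared(snps: pd.DataFrame) -> pd.Series:
        mask = pd.Series(False, index=snps.index)
        for chrom, start, end in shared_segments:
            mask |= ((snps["chromosome"] == chrom)
                     & (snps["position"] >= start) & (snps["position"] <= end))
        return mask

    donor_snps: dict[str, pd.DataFrame] = {}
    for donor in donor_ids:
        frames = [draw_snps(chrom, length, rng)
                  for chrom, length in zip(config.chromosome_names,
                                           config.chromosome_lengths)]
        snps = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chromosome", "position", "ref", "alt"])
        if shared_segments:
            snps = pd.concat([snps[~in_shared(snps)], *shared_pool],
                             ignore_index=True)
        # force the trait SNP
        mask = (snps["chromosome"] == tchrom) & (snps["position"] == tpos)
        snps = snps[~mask]
        forced = pd.DataFrame({
            "chromosome": [tchrom],
            "position": [tpos],
            "ref": [founders_ref_base(reference, tchrom, tpos)],
            "alt": [config.target_alt],
        })
        snps = pd.concat([snps, forced], ignore_index=True)
        snps = snps.sort_values(["chromosome", "position"], ignore_index=True)
        donor_snps[donor] = snps

    return Founders(config=config, recurrent_id=recurrent_id,
                    reference=reference, donor_snps=donor_snps,
                    target_locus=target)


def founders_ref_base(reference: Mapping[str, np.ndarray], chrom: str, pos: int) -> str:
    return BASES[reference[chrom][pos - 1]]


# --------------------------------------------------------------------------
# genomes as origin-labelled segment mosaics

Segment = tuple[int, int, str]          # start, end (1-based inclusive), founder id
Haplotype = list[Segment]


@dataclass
class LineGenome:
    line_id: str
    #: chromosome -> (haplotype A, haplotype B)
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    def origin_at(self, chrom: str, pos: int) -> tuple[str, str]:
        return (_origin_at(self.haplotypes[chrom][0], pos),
                _origin_at(self.haplotypes[chrom][1], pos))


def _origin_at(hap: Haplotype, pos: int) -> str:
    for start, end, origin in hap:
        if start <= pos <= end:
            return origin
    raise ValueError(f"position {pos} outside haplotype span")


def _founder_genome(line_id: str, origin: str, config: SimConfig) -> LineGenome:
    haps = {
        chrom: ([(1, length, origin)], [(1, length, origin)])
        for chrom, length in zip(config.chromosome_names, config.chromosome_lengths)
    }
    return LineGenome(line_id, haps)


def _slice_hap(hap: Haplotype, start: int, end: int) -> Haplotype:
    out = []
    for s, e, o in hap:
        if e < start or s > end:
            continue
        out.append((max(s, start), min(e, end), o))
    return out


def _merge_adjacent(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for seg in hap:
        if out and out[-1][2] == seg[2] and out[-1][1] + 1 == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def _gamete_chrom(hapA: Haplotype, hapB: Haplotype, length: int,
                  rate: float, rng: np.random.Generator) -> Haplotype:
    """One meiotic product: Poisson crossovers, uniform breakpoints."""
    k = rng.poisson(rate)
    breaks = np.sort(rng.integers(2, length + 1, size=k)) if k else np.empty(0, int)
    cur = int(rng.integers(0, 2))
    haps = (hapA, hapB)
    out: Haplotype = []
    start = 1
    for b in breaks:
        b = int(b)
        if b <= start:
            cur ^= 1
            continue
        out.extend(_slice_hap(haps[cur], start, b - 1))
        start = b
        cur ^= 1
    out.extend(_slice_hap(haps[cur], start, length))
    return _merge_adjacent(out)


def _gamete(genome: LineGenome, config: SimConfig, rng: np.random.Generator) -> dict[str, Haplotype]:
    return {
        chrom: _gamete_chrom(*genome.haplotypes[chrom], config.length_of(chrom),
                             config.crossover_rate, rng)
        for chrom in genome.haplotypes
    }


def _cross(line_id: str, mother: LineGenome, father: LineGenome,
           config: SimConfig, rng: np.random.Generator) -> LineGenome:
    gm, gf = _gamete(mother, config, rng), _gamete(father, config, rng)
    return LineGenome(line_id, {c: (gm[c], gf[c]) for c in gm})


# --------------------------------------------------------------------------
# breeding schemes

SCHEMES = ("F1", "F2", "BC2F1", "BC2F4_selected")


def simulate_breeding(
    founders: Founders,
    scheme: str,
    config: SimConfig | None = None,
    donor_id: str | None = None,
    n_individuals: int = 1,
    selfing_generations: int = 3,
    line_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LineGenome], pd.DataFrame]:
    """Breed from the founders and return genomes plus truth blocks.

    Schemes: ``F1`` (donor x recurrent), ``F2`` (selfed F1, ``n_individuals``
    plants, no selection), ``BC2F1`` (two backcrosses, before selfing) and
    ``BC2F4_selected`` (the NIL scheme: BC2 then ``selfing_generations``
    selfs with selection for the homozygous donor genotype at the target
    locus, residual heterozygosity fixed at the end).
    """
    config = config or founders.config
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    donor_id = donor_id or founders.donor_ids[0]
    if donor_id == founders.recurrent_id:
        raise ConfigError("donor and recurrent parent must differ")
    tchrom, tpos = founders.target_locus
    snps = founders.donor_snps[donor_id]
    has_target = ((snps["chromosome"] == tchrom) & (snps["position"] == tpos)).any()
    if scheme in ("BC2F1", "BC2F4_selected") and not has_target:
        raise ConfigError(f"donor {donor_id} carries no allele at the target locus")
    if rng is None:
        rng = np.random.default_rng([config.seed, SCHEMES.index(scheme), _stable_hash(donor_id)])

    recurrent = _founder_genome(founders.recurrent_id, founders.recurrent_id, config)
    donor = _founder_genome(donor_id, donor_id, config)

    def f1(lid: str) -> LineGenome:
        return _cross(lid, donor, recurrent, config, rng)

    genomes: list[LineGenome] = []
    if scheme == "F1":
        for i in range(n_individuals):
            genomes.append(f1(line_id or f"F1_{i + 1:04d}" if n_individuals > 1 else (line_id or "F1")))
    elif scheme == "F2":
        parent = f1("F1")
        for i in range(n_individuals):
            lid = line_id or f"F2_{i + 1:04d}"
            if n_individuals > 1:
                lid = f"F2_{i + 1:04d}"
            genomes.append(_cross(lid, parent, parent, config, rng))
    else:
        for i in range(n_individuals):
            lid = line_id or (f"NIL-{donor_id}" if n_individuals == 1 else f"NIL-{donor_id}_{i + 1}")
            cur = f1("F1")
            for _ in range(2):  # two backcrosses, gamete selected for donor allele
                gam = _select_gamete(cur, tchrom, tpos, donor_id, config, rng)
                rec = _gamete(recurrent, config, rng)
                cur = LineGenome(lid, {c: (gam[c], rec[c]) for c in gam})
            if scheme == "BC2F1":
                genomes.append(cur)
                continue
            for _ in range(selfing_generations):  # selfing, target fixed homozygous
                while True:
                    g1, g2 = _gamete(cur, config, rng), _gamete(cur, config, rng)
                    if (_origin_at(g1[tchrom], tpos) == donor_id
                            and _origin_at(g2[tchrom], tpos) == donor_id):
                        break
                cur = LineGenome(lid, {c: (g1[c], g2[c]) for c in g1})
            genomes.append(_fix_residual_heterozygosity(cur, rng))

    truth = pd.concat([truth_blocks(g, founders.recurrent_id) for g in genomes],
                      ignore_index=True)
    return genomes, truth


def _select_gamete(genome: LineGenome, tchrom: str, tpos: int, donor_id: str,
                   config: SimConfig, rng: np.random.Generator) -> dict[str, Haplotype]:
    while True:
        g = _gamete(genome, config, rng)
        if _origin_at(g[tchrom], tpos) == donor_id:
            return g


def _fix_residual_heterozygosity(genome: LineGenome, rng: np.random.Generator) -> LineGenome:
    """Resolve origin-heterozygous tiles to homozygosity (either side, p=1/2)."""
    haps = {}
    for chrom, (a, b) in genome.haplotypes.items():
        tiles = _overlay(a, b)
        new: Haplotype = []
        for start, end, oa, ob in tiles:
            origin = oa if oa == ob else (oa, ob)[int(rng.integers(0, 2))]
            new.append((start, end, origin))
        new = _merge_adjacent(new)
        haps[chrom] = (new, list(new))
    return LineGenome(genome.line_id, haps)


def _overlay(a: Haplotype, b: Haplotype) -> list[tuple[int, int, str, str]]:
    """Tile the chromosome by the union of breakpoints of two haplotypes."""
    bounds = sorted({s for s, _, _ in a} | {s for s, _, _ in b}
                    | {e + 1 for _, e, _ in a} | {e + 1 for _, e, _ in b})
    out = []
    for start, nxt in zip(bounds[:-1], bounds[1:]):
        end = nxt - 1
        out.append((start, end, _origin_at(a, start), _origin_at(b, start)))
    return out


def truth_blocks(genome: LineGenome, recurrent_id: str) -> pd.DataFrame:
    """Tile each chromosome into origin/zygosity blocks (ground truth)."""
    rows = []
    for chrom, (a, b) in genome.haplotypes.items():
        for start, end, oa, ob in _overlay(a, b):
            donor_a, donor_b = oa != recurrent_id, ob != recurrent_id
            if donor_a and donor_b:
                origin, zyg = "donor", "homozygous"
            elif donor_a or donor_b:
                origin, zyg = "donor", "heterozygous"
            else:
                origin, zyg = "recurrent", "homozygous"
            rows.append((genome.line_id, chrom, start, end, origin, zyg,
                         oa if donor_a else (ob if donor_b else recurrent_id)))
    df = pd.DataFrame(rows, columns=["line_id", "chromosome", "start", "end",
                                     "origin", "zygosity", "source"])
    # merge adjacent tiles with identical labels
    merged = []
    for _, row in df.iterrows():
        if (merged and merged[-1][0] == row["line_id"]
                and merged[-1][1] == row["chromosome"]
                and merged[-1][3] + 1 == row["start"]
                and merged[-1][4:] == [row["origin"], row["zygosity"], row["source"]]):
            merged[-1][3] = row["end"]
        else:
            merged.append([row["line_id"], row["chromosome"], row["start"],
                           row["end"], row["origin"], row["zygosity"], row["source"]])
    return pd.DataFrame(merged, columns=df.columns)


def donor_genome_fraction(truth: pd.DataFrame, config: SimConfig,
                          line_id: str | None = None) -> float:
    """Fraction of the diploid genome of donor origin (het counts half)."""
    df = truth if line_id is None else truth[truth["line_id"] == line_id]
    total = 2 * sum(config.chromosome_lengths) * df["line_id"].nunique()
    span = df["end"] - df["start"] + 1
    weight = np.where(df["origin"] == "recurrent", 0.0,
                      np.where(df["zygosity"] == "homozygous", 2.0, 1.0))
    return float((span * weight).sum() / total)


# --------------------------------------------------------------------------
# noisy call sets

def union_loci(founders: Founders) -> pd.DataFrame:
    """Union of all donors' divergent loci: chromosome, position, ref, and
    one alt column per donor (NaN where that donor is reference)."""
    pieces = []
    for donor, snps in founders.donor_snps.items():
        piece = snps.rename(columns={"alt": f"alt_{donor}"})
        pieces.append(piece.set_index(["chromosome", "position", "ref"]))
    merged = pd.concat(pieces, axis=1, join="outer").reset_index()
    return merged.sort_values(["chromosome", "position"], ignore_index=True)


def _hap_origin_codes(hap: Haplotype, positions: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _, _ in hap])
    origins = np.array([o for _, _, o in hap], dtype=object)
    idx = np.searchsorted(starts, positions, side="right") - 1
    return origins[idx]


def simulate_call_set(
    genome: LineGenome,
    founders: Founders,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy per-line SNP call table over the union of divergent loci.

    Columns: chromosome, position, ref, A/C/G/T read counts, depth, missing
    flag, and the truth genotype/zygosity for recovery tests.  ``missing``
    rows represent loci with coverage but no genotype call.
    """
    config = config or founders.config
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xCA11, _stable_hash(genome.line_id)])
    loci = union_loci(founders)
    frames = []
    for chrom, sub in loci.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy()
        n = len(pos)
        ref_codes = np.array([BASES.index(b) for b in sub["ref"]], dtype=np.int64)
        # per-haplotype allele codes
        allele_codes = []
        for hap in genome.haplotypes[chrom]:
            origins = _hap_origin_codes(hap, pos)
            codes = ref_codes.copy()
            for donor in founders.donor_ids:
                col = f"alt_{donor}"
                if col not in sub:
                    continue
                alt = sub[col]
                mask = (origins == donor) & alt.notna().to_numpy()
                if mask.any():
                    codes[mask] = [BASES.index(b) for b in alt[mask]]
            allele_codes.append(codes)
        a1, a2 = allele_codes

        depth = rng.negative_binomial(
            config.depth_dispersion,
            config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
            size=n) if config.depth_mean > 0 else np.zeros(n, dtype=np.int64)
        n1 = rng.binomial(depth, 0.5)
        counts = np.zeros((n, 4), dtype=np.int64)
        rows = np.arange(n)
        for a, m in ((a1, n1), (a2, depth - n1)):
            correct = rng.binomial(m, 1.0 - config.error_rate)
            err = m - correct
            np.add.at(counts, (rows, a), correct)
            if err.any():
                spread = rng.multinomial(err, [1 / 3] * 3)
                np.add.at(counts, (rows[:, None], _OTHER_IDX[a]), spread)
        missing = rng.random(n) < config.missing_rate

        frames.append(pd.DataFrame({
            "chromosome": chrom,
            "position": pos,
            "ref": sub["ref"].to_numpy(),
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3],
            "depth": depth,
            "missing": missing,
            "truth_allele1": [BASES[c] for c in a1],
            "truth_allele2": [BASES[c] for c in a2],
        }))
    calls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chromosome", "position", "ref", "A", "C", "G", "T",
                 "depth", "missing", "truth_allele1", "truth_allele2"])
    hom = calls["truth_allele1"] == calls["truth_allele2"]
    ref_gt = hom & (calls["truth_allele1"] == calls["ref"])
    calls["truth_zygosity"] = np.where(
        ref_gt, "reference", np.where(hom, "homozygous", "heterozygous"))
    # zero all counts at missing loci: no call was emitted there
    calls.loc[calls["missing"], ["A", "C", "G", "T"]] = 0
    return calls


# --------------------------------------------------------------------------
# whole-study bundle and fixture export

@dataclass
class SimBundle:
    config: SimConfig
    founders: Founders
    genomes: dict[str, LineGenome]
    call_sets: dict[str, pd.DataFrame]
    truth: pd.DataFrame

    @property
    def recurrent_id(self) -> str:
        return self.founders.recurrent_id

    @property
    def nil_ids(self) -> list[str]:
        return [f"NIL-{d}" for d in self.founders.donor_ids]


def simulate_study(
    config: SimConfig,
    recurrent_id: str = DEFAULT_RECURRENT,
    donor_ids: Sequence[str] = DEFAULT_DONORS,
    shared_segments: Sequence[tuple[str, int, int]] | None = None,
) -> SimBundle:
    """Founders, one BC2F4 NIL per donor, and call sets for every line."""
    founders = simulate_founders(config, recurrent_id, donor_ids, shared_segments)
    genomes: dict[str, LineGenome] = {
        recurrent_id: _founder_genome(recurrent_id, recurrent_id, config)}
    for donor in donor_ids:
        genomes[donor] = _founder_genome(donor, donor, config)
    truth_frames = []
    for donor in donor_ids:
        nils, truth = simulate_breeding(founders, "BC2F4_selected", config,
                                        donor_id=donor, line_id=f"NIL-{donor}")
        genomes[f"NIL-{donor}"] = nils[0]
        truth_frames.append(truth)
    call_sets = {lid: simulate_call_set(g, founders, config)
                 for lid, g in genomes.items()}
    founder_truth = pd.concat(
        [truth_blocks(genomes[lid], recurrent_id) for lid in [recurrent_id, *donor_ids]],
        ignore_index=True)
    truth = pd.concat([founder_truth, *truth_frames], ignore_index=True)
    return SimBundle(config, founders, genomes, call_sets, truth)


def export_fixture(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated study to disk as standard-format files.

    reference.fa, one VCF per line (AD/DP per record, GT ./. at no-call
    loci), genes.gff3 with the published carotenoid-pathway gene spans
    scaled into the synthetic genome, truth_blocks.bed and config.yaml.
    """
    from . import io as nio
    from .genes import scaled_gene_models

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = out / "reference.fa"
    nio.write_fasta({c: bundle.founders.reference_seq(c)
                     for c in bundle.config.chromosome_names}, paths["reference"])
    for lid, calls in bundle.call_sets.items():
        p = out / f"{lid}.vcf"
        nio.write_vcf(calls, p, sample=lid)
        paths[f"vcf:{lid}"] = p
    paths["genes"] = out / "genes.gff3"
    nio.write_gff3(scaled_gene_models(bundle.config), paths["genes"])
    paths["truth"] = out / "truth_blocks.bed"
    nio.write_truth_bed(bundle.truth, paths["truth"])
    paths["config"] = out / "config.yaml"
    import yaml

    cfg = asdict(bundle.config)
    cfg["chromosome_lengths"] = list(cfg["chromosome_lengths"])
    if cfg["target_locus"] is not None:
        cfg["target_locus"] = list(cfg["target_locus"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths
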