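"""CAPS/dCAPS marker design: IUPAC site scanning, in-silico digestion,
fragment-size prediction and mismatch-primer construction.

A CAPS marker exploits a SNP that creates or destroys a restriction site,
so that digesting the PCR amplicon yields allele-distinguishing fragment
patterns.  When no natural site differs between alleles, a dCAPS marker
engineers one: a mismatch is introduced into a PCR primer ending near the
SNP such that the primer-rewritten amplicon completes a recognition site
together with one SNP allele but not the other.

Cut coordinates are reported on the top strand, 0-based (the number of
bases before the cut).  Non-palindromic recognitions are scanned on both
strands; for a bottom-strand site starting at top position ``p`` the top
strand is severed at ``p + len(site) - cut_bottom``.
"""

from __future__ import annotations

import importlib.resources
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values, ambiguous_dna_complement

_IUPAC = {k.upper(): v.upper() for k, v in ambiguous_dna_values.items()}
_COMPLEMENT = str.maketrans(
    {k: v for k, v in ambiguous_dna_complement.items()})
_VALID_SEQ = re.compile(r"^[ACGT]*$")


def revcomp_iupac(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: IUPAC recognition plus cut offsets measured
    from the 5' start of the recognition on its own strand (``cut_top``)
    and, along the same axis, on the complement (``cut_bottom``).  Offsets
    may exceed the recognition length for downstream cutters."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(_IUPAC)
        if bad or not self.recognition:
            raise ValueError(f"{self.name}: invalid IUPAC recognition {self.recognition!r}")

    @property
    def length(self) -> int:
        return len(self.recognition)

    @property
    def palindromic(self) -> bool:
        return revcomp_iupac(self.recognition) == self.recognition.upper()


def load_enzymes(path: str | Path | None = None) -> list[EnzymeSpec]:
    """The shipped enzyme catalogue (or a user TSV with the same columns)."""
    if path is None:
        ref = importlib.resources.files("nilscan.data") / "enzymes.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_enzymes(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    return [EnzymeSpec(r.name, r.recognition, int(r.cut_top), int(r.cut_bottom))
            for r in df.itertuples(index=False)]


def enzyme_by_name(name: str, enzymes: Iterable[EnzymeSpec] | None = None) -> EnzymeSpec:
    for enz in enzymes or load_enzymes():
        if enz.name.lower() == name.lower():
            return enz
    raise KeyError(f"enzyme {name!r} not in catalogue")


# --------------------------------------------------------------------------
# scanning and digestion

def _pattern(recognition: str) -> re.Pattern:
    body = "".join(ch if len(_IUPAC[ch]) == 1 else f"[{_IUPAC[ch]}]"
                   for ch in recognition.upper())
    return re.compile(f"(?=({body}))")


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains invalid bases {bad}")
    return seq


def site_matches(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All recognition matches as (0-based start, strand '+'/'-'); the
    reverse complement is scanned only for non-palindromic recognitions."""
    seq = _check_sequence(sequence)
    hits = [(m.start(), "+") for m in _pattern(enzyme.recognition).finditer(seq)]
    if not enzyme.palindromic:
        hits += [(m.start(), "-")
                 for m in _pattern(revcomp_iupac(enzyme.recognition)).finditer(seq)]
    return sorted(hits)


def scan_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Top-strand cut coordinates of all sites in ``sequence``.

    Cuts falling outside the molecule (possible for downstream cutters near
    an end) are dropped; coordinates are unique and ascending.
    """
    seq = _check_sequence(sequence)
    cuts = set()
    for start, strand in site_matches(seq, enzyme):
        cut = (start + enzyme.cut_top if strand == "+"
               else start + enzyme.length - enzyme.cut_bottom)
        if 0 < cut < len(seq):
            cuts.add(cut)
    return sorted(cuts)


def digest(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Fragment lengths (descending) after complete digestion; the multiset
    always sums to the sequence length."""
    seq = _check_sequence(sequence)
    bounds = [0, *scan_sites(seq, enzyme), len(seq)]
    return sorted((b - a for a, b in zip(bounds[:-1], bounds[1:])), reverse=True)


# --------------------------------------------------------------------------
# amplicons and CAPS

@dataclass(frozen=True)
class AmpliconPair:
    """Allele-specific PCR amplicon sequences differing at the SNP offset
    (plus any engineered dCAPS mismatch offsets, which are shared)."""

    allele_a: str
    allele_b: str
    snp_offset: int  # 0-based
    forward_primer: str = ""
    reverse_primer: str = ""

    def __post_init__(self) -> None:
        a, b = self.allele_a.upper(), self.allele_b.upper()
        if len(a) != len(b):
            raise ValueError("allele sequences must have equal length")
        if not 0 <= self.snp_offset < len(a):
            raise ValueError("snp_offset outside amplicon")
        diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        if diffs and diffs != [self.snp_offset]:
            raise ValueError(
                f"alleles differ at {diffs}, expected only at {self.snp_offset}")

    @property
    def length(self) -> int:
        return len(self.allele_a)

    @property
    def identical(self) -> bool:
        return self.allele_a.upper() == self.allele_b.upper()


@dataclass(frozen=True)
class DigestResult:
    enzyme: EnzymeSpec
    fragments: dict  # allele label -> descending fragment lengths (tuple)
    discriminating: bool
    heterozygote_bands: tuple[int, ...]  # union, one band per length

    def bands(self, allele: str) -> tuple[int, ...]:
        return self.fragments[allele]


def digest_pair(pair: AmpliconPair, enzyme: EnzymeSpec) -> DigestResult:
    fr_a = tuple(digest(pair.allele_a, enzyme))
    fr_b = tuple(digest(pair.allele_b, enzyme))
    return DigestResult(
        enzyme=enzyme,
        fragments={"A": fr_a, "B": fr_b},
        discriminating=sorted(fr_a) != sorted(fr_b),
        heterozygote_bands=tuple(sorted(set(fr_a) | set(fr_b), reverse=True)),
    )


def _diagnostic_min(result: DigestResult) -> int:
    from collections import Counter

    ca, cb = Counter(result.fragments["A"]), Counter(result.fragments["B"])
    diag = list((ca - cb) + (cb - ca))
    return min(diag) if diag else 0


def find_caps(
    pair: AmpliconPair,
    enzymes: Sequence[EnzymeSpec] | None = None,
    min_fragment: int = 30,
) -> list[DigestResult]:
    """Enzymes whose digestion discriminates the two alleles.

    Ranked with designs whose shortest diagnostic fragment resolves on a
    gel (>= ``min_fragment``) first, then by fewest total cuts, then by the
    largest shortest-diagnostic fragment.
    """
    if pair.identical:
        raise ValueError("alleles are identical: no SNP to assay")
    enzymes = list(enzymes) if enzymes is not None else load_enzymes()
    hits = [r for r in (digest_pair(pair, e) for e in enzymes) if r.discriminating]

    def key(r: DigestResult):
        cuts = len(r.fragments["A"]) + len(r.fragments["B"]) - 2
        dmin = _diagnostic_min(r)
        return (dmin < min_fragment, cuts, -dmin, r.enzyme.name)

    return sorted(hits, key=key)


def predict_gel(result: DigestResult, genotype: str) -> tuple[int, ...]:
    """Expected band lengths for genotype AA, BB or AB (heterozygote bands
    are the additive union with duplicate lengths collapsed)."""
    if genotype == "AA":
        return result.fragments["A"]
    if genotype == "BB":
        return result.fragments["B"]
    if genotype == "AB":
        return result.heterozygote_bands
    raise ValueError(f"genotype must be AA, BB or AB, got {genotype!r}")


# --------------------------------------------------------------------------
# dCAPS design

@dataclass(frozen=True)
class DcapsDesign:
    enzyme: EnzymeSpec
    primer: str            # edited primer sequence, 5'->3' on the top strand
    primer_start: int      # 0-based offset of the primer in the flank
    mismatch_offsets: tuple[int, ...]  # absolute offsets of engineered edits
    cut_allele: str        # 'A' or 'B': the allele carrying the new site
    amplicons: AmpliconPair
    digest: DigestResult = field(compare=False)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_offsets)


def _site_overlapping_snp(seq: str, enzyme: EnzymeSpec, snp_offset: int) -> bool:
    return any(start <= snp_offset < start + enzyme.length
               for start, _ in site_matches(seq, enzyme))


def design_dcaps(
    flank_a: str,
    flank_b: str,
    snp_offset: int,
    enzymes: Sequence[EnzymeSpec] | None = None,
    max_mismatches: int = 1,
    primer_len: int = 20,
) -> list[DcapsDesign]:
    """Search mismatch-primer designs that create an allele-specific site.

    For every enzyme, forward-primer placements ending within one
    recognition length upstream of the SNP are enumerated; for each, up to
    ``max_mismatches`` single-base primer edits (never at the 3'-terminal
    base) are tried.  A design is kept when the primer-rewritten amplicon
    contains a recognition site overlapping the SNP for exactly one allele.
    The zero-mismatch case degenerates to a plain CAPS assay.  Returns an
    empty list when nothing is found.
    """
    a, b = _check_sequence(flank_a), _check_sequence(flank_b)
    if len(a) != len(b):
        raise ValueError("flanks must have equal length")
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if diffs != [snp_offset]:
        raise ValueError("flanks must be identical except at the SNP offset")
    enzymes = list(enzymes) if enzymes is not None else load_enzymes()

    designs: dict[tuple, DcapsDesign] = {}
    for enzyme in enzymes:
        lo = max(snp_offset - enzyme.length, primer_len - 1)
        for end in range(lo, snp_offset):  # 3' end position, before the SNP
            start = end - primer_len + 1
            if start < 0:
                continue
            editable = [j for j in range(start, end)]  # 3' base excluded
            for k in range(0, max_mismatches + 1):
                for positions in itertools.combinations(editable, k):
                    for bases in itertools.product("ACGT", repeat=k):
                        if any(a[j] == nb for j, nb in zip(positions, bases)):
                            continue
                        ra, rb = list(a), list(b)
                        for j, nb in zip(positions, bases):
                            ra[j] = rb[j] = nb
                        ra, rb = "".join(ra), "".join(rb)
                        hit_a = _site_overlapping_snp(ra, enzyme, snp_offset)
                        hit_b = _site_overlapping_snp(rb, enzyme, snp_offset)
                        if hit_a == hit_b:
                            continue
                        primer = ra[start:end + 1]
                        pair = AmpliconPair(ra, rb, snp_offset,
                                            forward_primer=primer)
                        design = DcapsDesign(
                            enzyme=enzyme, primer=primer, primer_start=start,
                            mismatch_offsets=tuple(positions),
                            cut_allele="A" if hit_a else "B",
                            amplicons=pair,
                            digest=digest_pair(pair, enzyme))
                        designs.setdefault(
                            (enzyme.name, primer, start), design)
    return sorted(designs.values(),
                  key=lambda d: (d.n_mismatches, d.enzyme.name, d.primer_start))
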