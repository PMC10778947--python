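"""Synthetic fixture amplicons for the three published flesh-colour markers.

The genomic coordinates of the published PCR products are not public, so
these amplicons are synthetic constructs: random sequences with the
marker's restriction sites planted so that digestion reproduces the
published allele band multisets exactly:

* PSY1-A>G   (BcoDI, 381 bp):  A -> 338/43,   G -> 175/163/43
* LCYB-G>T   (BsaHI, 1594 bp): T -> 1594,     G -> 1180/414
* LCYB-G>C   (AflII, 210 bp):  C -> 210,      G -> 182/28

Each builder scrubs accidental recognition sites of the marker's enzyme
from both alleles, then plants the intended sites, so the band patterns
are exact by construction and serve as ground truth for the digestion
engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import (
    AmpliconPair,
    EnzymeSpec,
    enzyme_by_name,
    revcomp_iupac,
    site_matches,
)


@dataclass(frozen=True)
class MarkerFixture:
    marker: str
    enzyme: EnzymeSpec
    pair: AmpliconPair
    allele_labels: dict  # 'A'/'B' -> flesh-colour genotype description
    expected_bands: dict  # 'A'/'B' -> descending band tuple


def _random_seq(n: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _scrub_pair(seq: list[str], snp_offset: int, alt: str, enzyme: EnzymeSpec,
                rng: np.random.Generator, protected: set[int]) -> None:
    """Mutate shared bases until neither allele carries a recognition match
    (either strand) outside the planted, protected windows."""
    for _ in range(10_000):
        cut = "".join(seq)
        uncut = cut[:snp_offset] + alt + cut[snp_offset + 1:]
        bad: list[tuple[int, int]] = []
        for allele in (cut, uncut):
            for s, _ in site_matches(allele, enzyme):
                window = (s, s + enzyme.length)
                ok = all(i in protected for i in range(*window))
                if allele is uncut and snp_offset in range(*window):
                    ok = False  # the SNP must destroy the allele-specific site
                if not ok:
                    bad.append(window)
        if not bad:
            return
        s, e = bad[0]
        free = [i for i in range(s, e) if i not in protected]
        i = free[int(rng.integers(len(free)))]
        seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    raise RuntimeError("could not scrub recognition sites")


def _build(marker: str, enzyme_name: str, length: int, sites: list[tuple[int, str]],
           snp_offset: int, ref: str, alt: str, labels: dict, bands: dict,
           seed: int = 20) -> MarkerFixture:
    """Construct an allele pair of ``length`` bp where ``sites`` (start,
    concrete motif) exist on the cut allele and the SNP at ``snp_offset``
    (ref on the cut allele) toggles the allele-specific one."""
    enzyme = enzyme_by_name(enzyme_name)
    rng = np.random.default_rng(seed)
    seq = _random_seq(length, rng)
    protected: set[int] = set()
    for at, motif in sites:
        for k, ch in enumerate(motif):
            seq[at + k] = ch
        protected |= set(range(at, at + len(motif)))
    protected.add(snp_offset)
    assert seq[snp_offset] == ref
    _scrub_pair(seq, snp_offset, alt, enzyme, rng, protected)

    cut = "".join(seq)
    uncut = cut[:snp_offset] + alt + cut[snp_offset + 1:]
    # the SNP must destroy the planted allele-specific site on the other allele
    pair = AmpliconPair(allele_a=cut, allele_b=uncut, snp_offset=snp_offset,
                        forward_primer=cut[:20], reverse_primer=revcomp_iupac(cut[-20:]))
    return MarkerFixture(marker=marker, enzyme=enzyme, pair=pair,
                         allele_labels=labels, expected_bands=bands)


def psy1_a_g() -> MarkerFixture:
    """PSY1-A>G CAPS fixture: a constant BcoDI site cutting at 43 and a
    G-allele-specific site cutting at 206 (43 + 163)."""
    # BcoDI GTCTC cuts 1 nt downstream: sense site at p cuts at p + 6
    return _build(
        marker="PSY1-A>G", enzyme_name="BcoDI", length=381,
        sites=[(37, "GTCTC"), (200, "GTCTC")],
        snp_offset=200, ref="G", alt="A",
        labels={"A": "orange-beta (G)", "B": "canary-yellow / red (A)"},
        bands={"A": (175, 163, 43), "B": (338, 43)})


def lcyb_g_t() -> MarkerFixture:
    """LCYB-G>T CAPS fixture: a G-allele (red flesh) BsaHI site cutting
    at 414 of a 1594 bp product."""
    # BsaHI GR^CGYC: sense site at p cuts at p + 2; planted as GACGTC
    return _build(
        marker="LCYB-G>T", enzyme_name="BsaHI", length=1594,
        sites=[(412, "GACGTC")],
        snp_offset=415, ref="G", alt="T",
        labels={"A": "red (G)", "B": "canary-yellow / orange-beta (T)"},
        bands={"A": (1180, 414), "B": (1594,)})


def lcyb_g_c() -> MarkerFixture:
    """LCYB-G>C dCAPS fixture: the AflII site completed by the G allele
    (with the engineered primer mismatch) cuts a 210 bp product at 182."""
    # AflII C^TTAAG: sense site at p cuts at p + 1
    return _build(
        marker="LCYB-G>C", enzyme_name="AflII", length=210,
        sites=[(181, "CTTAAG")],
        snp_offset=186, ref="G", alt="C",
        labels={"A": "red (G)", "B": "canary-yellow / orange-beta (C)"},
        bands={"A": (182, 28), "B": (210,)})


def published_marker_fixtures() -> list[MarkerFixture]:
    return [psy1_a_g(), lcyb_g_t(), lcyb_g_c()]
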