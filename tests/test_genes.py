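"""Gene-region intersection and codon-level effect annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from nilscan.genes import (
    CDS,
    INTRON,
    NON_SYNONYMOUS,
    SYNONYMOUS,
    UPSTREAM,
    GeneModel,
    VariantEffect,
    annotate_variant,
    carotenoid_genes,
    genes_in_regions,
)
from nilscan.introgression import IntrogressionRegion

# the standard genetic code, hard-coded as an independent reference
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA3 = {"F": "Phe", "L": "Leu", "I": "Ile", "M": "Met", "V": "Val",
       "S": "Ser", "P": "Pro", "T": "Thr", "A": "Ala", "Y": "Tyr",
       "H": "His", "Q": "Gln", "N": "Asn", "K": "Lys", "D": "Asp",
       "E": "Glu", "C": "Cys", "W": "Trp", "R": "Arg", "G": "Gly",
       "*": "Ter"}


def region(chrom, start, end, nil="NIL"):
    return IntrogressionRegion(chrom, start, end, 10, nil, "donor")


class TestGenesInRegions:
    def test_containment_and_boundary_overlap(self):
        gene = GeneModel("G1", "PSY", "Chr01", 10_039_958, 10_042_905, "+")
        inside = genes_in_regions([gene], [region("Chr01", 9_000_000, 11_000_000)])
        assert list(inside["gene_id"]) == ["G1"]
        # region abutting the gene end with exactly one base of overlap
        edge = genes_in_regions([gene], [region("Chr01", 10_042_905, 10_050_000)])
        assert len(edge) == 1
        miss = genes_in_regions([gene], [region("Chr01", 10_042_906, 10_050_000)])
        assert miss.empty

    def test_gene_outside_regions_not_hit(self):
        chyb = GeneModel("G2", "CHYB", "Chr01", 2_378_461, 2_381_614, "+")
        hits = genes_in_regions([chyb], [region("Chr01", 9_000_000, 11_000_000)])
        assert hits.empty

    def test_chromosome_naming_mismatch_raises(self):
        gene = GeneModel("G1", "PSY", "chr1", 100, 200, "+")
        with pytest.raises(ValueError, match="chromosome names"):
            genes_in_regions([gene], [region("Chr01", 1, 1_000)])

    def test_monotone_under_region_growth(self):
        genes = [GeneModel(f"G{i}", "x", "Chr01", s, s + 999, "+")
                 for i, s in enumerate(range(1, 50_000, 7_000))]
        small = genes_in_regions(genes, [region("Chr01", 5_000, 20_000)])
        large = genes_in_regions(genes, [region("Chr01", 1_000, 40_000)])
        assert set(small["gene_id"]) <= set(large["gene_id"])

    def test_packaged_gene_table_loads(self):
        genes = carotenoid_genes()
        assert len(genes) == 18
        psy1 = next(g for g in genes if g.gene_id == "ClCG01G008470")
        assert (psy1.chromosome, psy1.start, psy1.end) == ("Chr01", 10_039_958, 10_042_905)


def make_gene(genome_len=60, cds=(10, 39), strand="+", seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), genome_len))
    gene = GeneModel("G", "g", "Chr01", cds[0], cds[1], strand)
    return {"Chr01": seq}, gene


class TestAnnotateVariant:
    def test_published_flesh_colour_substitutions(self):
        """The three annotated non-synonymous changes: AAG>GAG Lys>Glu,
        GTC>TTC Val>Phe and AAG>AAC Lys>Asn."""
        genome = {"Chr01": "TT" + "AAGGTCAAG" + "TT"}
        gene = GeneModel("G", "g", "Chr01", 3, 11, "+")
        cases = [
            (3, "A", "G", "AAG", "GAG", "Lys", "Glu"),
            (6, "G", "T", "GTC", "TTC", "Val", "Phe"),
            (11, "G", "C", "AAG", "AAC", "Lys", "Asn"),
        ]
        for pos, ref, alt, cb, ca, ab, aa in cases:
            eff = annotate_variant(("Chr01", pos, ref, alt), gene, genome)
            assert (eff.codon_before, eff.codon_after) == (cb, ca)
            assert (eff.aa_before, eff.aa_after) == (ab, aa)
            assert eff.effect_class == NON_SYNONYMOUS

    def test_wobble_synonymous(self):
        genome = {"Chr01": "GCAGCA"}
        gene = GeneModel("G", "g", "Chr01", 1, 6, "+")
        eff = annotate_variant(("Chr01", 3, "A", "G"), gene, genome)
        assert eff.codon_after == "GCG"
        assert eff.effect_class == SYNONYMOUS

    def test_reference_mismatch_guards_coordinates(self):
        genome, gene = make_gene()
        pos = 12
        wrong = "A" if genome["Chr01"][pos - 1] != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            annotate_variant(("Chr01", pos, wrong, "G"), gene, genome)

    def test_intron_and_upstream_and_intergenic(self):
        genome = {"Chr01": "A" * 100}
        gene = GeneModel("G", "g", "Chr01", 40, 80, "+",
                         exons=((40, 51), (70, 80)))
        assert annotate_variant(("Chr01", 60, "A", "G"), gene, genome).region == INTRON
        assert annotate_variant(("Chr01", 39, "A", "G"), gene, genome).region == UPSTREAM
        assert annotate_variant(("Chr01", 5, "A", "G"), gene, genome,
                                upstream_bp=10).region == "intergenic"

    def test_minus_strand_upstream_is_downstream_in_genome_coordinates(self):
        genome = {"Chr01": "A" * 100}
        gene = GeneModel("G", "g", "Chr01", 10, 50, "-")
        assert annotate_variant(("Chr01", 55, "A", "G"), gene, genome).region == UPSTREAM

    @pytest.mark.parametrize("seed", range(8))
    def test_strand_symmetry(self, seed):
        """Annotating a minus-strand gene equals annotating the mirrored
        plus-strand gene on the reverse-complemented genome."""
        rng = np.random.default_rng(seed)
        n = 90
        seq = "".join(rng.choice(list("ACGT"), n))
        start, end = 20, 20 + 3 * rng.integers(5, 15) - 1
        pos = int(rng.integers(start, end + 1))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))

        minus = GeneModel("G", "g", "Chr01", start, end, "-")
        eff_minus = annotate_variant(("Chr01", pos, ref, alt), minus, {"Chr01": seq})

        rc = str(Seq(seq).reverse_complement())
        plus = GeneModel("G", "g", "Chr01", n - end + 1, n - start + 1, "+")
        pos_rc = n - pos + 1
        ref_rc, alt_rc = str(Seq(ref).complement()), str(Seq(alt).complement())
        eff_plus = annotate_variant(("Chr01", pos_rc, ref_rc, alt_rc), plus, {"Chr01": rc})

        assert eff_minus.codon_before == eff_plus.codon_before
        assert eff_minus.codon_after == eff_plus.codon_after
        assert eff_minus.effect_class == eff_plus.effect_class
        assert eff_minus.codon_number == eff_plus.codon_number

    def test_translation_covers_all_codons(self):
        """Every codon of a CDS containing all 64 codons translates to the
        hard-coded standard-code reference, for a substitution at each
        codon position."""
        codons = sorted(STANDARD_CODE)
        seq = "".join(codons)
        gene = GeneModel("G", "g", "Chr01", 1, len(seq), "+")
        genome = {"Chr01": seq}
        for ci, codon in enumerate(codons):
            pos = ci * 3 + 1  # first base of the codon
            ref = codon[0]
            alt = "A" if ref != "A" else "G"
            eff = annotate_variant(("Chr01", pos, ref, alt), gene, genome)
            assert eff.aa_before == AA3[STANDARD_CODE[codon]]
            mutated = alt + codon[1:]
            assert eff.aa_after == AA3[STANDARD_CODE[mutated]]
            assert eff.effect_class == (
                SYNONYMOUS if STANDARD_CODE[codon] == STANDARD_CODE[mutated]
                else NON_SYNONYMOUS)


def test_effect_string_rendering():
    eff = VariantEffect("G", "Chr01", 5, "A", "G", CDS, "AAG", "GAG",
                        "Lys", "Glu", NON_SYNONYMOUS, 149)
    assert "Non-syn" in str(eff) and "Lys > Glu" in str(eff)
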