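"""Restriction-site scanning, digestion, CAPS/dCAPS design, gel bands."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nilscan.amplicons import published_marker_fixtures
from nilscan.markers import (
    AmpliconPair,
    EnzymeSpec,
    design_dcaps,
    digest,
    digest_pair,
    enzyme_by_name,
    find_caps,
    load_enzymes,
    predict_gel,
    revcomp_iupac,
    scan_sites,
)
from nilscan.validation import naive_digest

ENZYMES = load_enzymes()


class TestScanAndDigest:
    def test_aflii_toy_sequence(self):
        """C^TTAAG inside AAAACTTAAGT...: one cut after the fifth base."""
        afl = enzyme_by_name("AflII")
        seq = "AAAACTTAAGTTTTTTTTTT"
        assert scan_sites(seq, afl) == [5]
        assert digest(seq, afl) == [15, 5]

    def test_sequence_without_motif(self):
        assert scan_sites("ACGT" * 10, enzyme_by_name("AflII")) == []
        assert digest("ACGT" * 10, enzyme_by_name("AflII")) == [40]

    @pytest.mark.parametrize("core,hit", [
        ("GACGTC", True), ("GGCGCC", True), ("GTCGTC", False)])
    def test_bsahi_degeneracy(self, core, hit):
        """GR^CGYC matches GACGTC and GGCGCC but not GTCGTC."""
        sites = scan_sites("AAAA" + core + "AAAA", enzyme_by_name("BsaHI"))
        assert bool(sites) == hit

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            scan_sites("ACGTN", enzyme_by_name("AflII"))

    def test_downstream_cutter_offsets(self):
        """BcoDI (GTCTC 1/5) cuts one base past the recognition on the top
        strand, and five on the bottom for an antisense site."""
        bco = enzyme_by_name("BcoDI")
        assert scan_sites("AAAAGTCTCAAAAAAAAA", bco) == [10]
        #        GAGAC antisense site at 4..8: top cut at 4 + 5 - 10 < 0 -> also
        #        check an internal placement
        assert scan_sites("AAAAAAAAAAGAGACAAAA", bco) == [5]

    def test_palindromic_sites_strand_independent(self):
        """A palindromic recognition is found at mirrored positions on the
        reverse complement: the site set is strand-independent (cut
        coordinates mirror only for blunt cutters, so compare sites)."""
        from nilscan.markers import site_matches

        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 400))
        for enz in ENZYMES:
            if not enz.palindromic:
                continue
            fwd = [p for p, _ in site_matches(seq, enz)]
            rev = [p for p, _ in site_matches(revcomp_iupac(seq), enz)]
            assert sorted(len(seq) - p - enz.length for p in fwd) == rev

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=30, max_size=200),
           idx=st.integers(0, len(ENZYMES) - 1))
    def test_fragment_conservation(self, seq, idx):
        fragments = digest(seq, ENZYMES[idx])
        assert sum(fragments) == len(seq)
        assert all(f >= 1 for f in fragments)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=30, max_size=150),
           idx=st.integers(0, len(ENZYMES) - 1))
    def test_digest_matches_naive_oracle(self, seq, idx):
        assert digest(seq, ENZYMES[idx]) == naive_digest(seq, ENZYMES[idx])

    def test_bad_recognition_rejected(self):
        with pytest.raises(ValueError):
            EnzymeSpec("X", "ACGTQ", 1, 3)


class TestPublishedMarkerFixtures:
    @pytest.mark.parametrize("fixture", published_marker_fixtures(),
                             ids=lambda f: f.marker)
    def test_band_patterns_reproduced(self, fixture):
        """Digesting each allele reproduces the published band multisets
        and the per-allele fragment sums agree (the amplicon length)."""
        res = digest_pair(fixture.pair, fixture.enzyme)
        assert res.fragments["A"] == fixture.expected_bands["A"]
        assert res.fragments["B"] == fixture.expected_bands["B"]
        assert sum(res.fragments["A"]) == sum(res.fragments["B"]) == fixture.pair.length
        assert res.discriminating

    def test_heterozygote_bands_are_additive_union(self):
        psy1 = published_marker_fixtures()[0]
        res = digest_pair(psy1.pair, psy1.enzyme)
        assert predict_gel(res, "AB") == (338, 175, 163, 43)
        assert predict_gel(res, "AA") == res.fragments["A"]


class TestFindCaps:
    def test_constructed_extra_site(self):
        """Allele B completes one extra EcoRI site: the enzyme is found
        and the fragments differ by exactly one split."""
        seq_a = "A" * 30 + "GTATTC" + "A" * 30
        seq_b = "A" * 30 + "GAATTC" + "A" * 30
        pair = AmpliconPair(seq_a, seq_b, 31)
        hits = find_caps(pair, ENZYMES, min_fragment=0)
        eco = next(h for h in hits if h.enzyme.name == "EcoRI")
        assert len(eco.fragments["B"]) == len(eco.fragments["A"]) + 1

    def test_snp_outside_any_recognition_window(self):
        seq_a = "ACGTAC" * 20
        seq_b = seq_a[:60] + "T" + seq_a[61:]
        pair = AmpliconPair(seq_a, seq_b, 60)
        only = {"AflII", "NotI"}  # motifs absent from the repeat
        hits = find_caps(pair, [e for e in ENZYMES if e.name in only])
        assert hits == []

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            find_caps(AmpliconPair("ACGT" * 10, "ACGT" * 10, 5), ENZYMES)

    def test_equals_bruteforce_on_random_amplicons(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 120))
            offset = int(rng.integers(10, 110))
            ref = seq[offset]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            other = seq[:offset] + alt + seq[offset + 1:]
            found = {r.enzyme.name
                     for r in find_caps(AmpliconPair(seq, other, offset),
                                        ENZYMES, min_fragment=0)}
            brute = {e.name for e in ENZYMES
                     if naive_digest(seq, e) != naive_digest(other, e)}
            assert found == brute


class TestDesignDcaps:
    def test_zero_mismatch_degenerates_to_caps(self):
        """When the SNP already completes a site, a 0-mismatch design is
        returned whose digestion equals the plain CAPS digestion."""
        seq_a = "C" * 25 + "CTTAA" + "G" + "C" * 29
        seq_b = "C" * 25 + "CTTAA" + "T" + "C" * 29
        designs = design_dcaps(seq_a, seq_b, 30, [enzyme_by_name("AflII")])
        zero = [d for d in designs if d.n_mismatches == 0]
        assert zero
        caps = digest_pair(AmpliconPair(seq_a, seq_b, 30), enzyme_by_name("AflII"))
        assert zero[0].digest.fragments == caps.fragments

    def test_mismatch_never_at_three_prime_terminus(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 60))
        fa, fb = seq, seq[:30] + ("A" if seq[30] != "A" else "C") + seq[31:]
        for d in design_dcaps(fa, fb, 30, ENZYMES[:15]):
            three_prime = d.primer_start + len(d.primer) - 1
            assert three_prime not in d.mismatch_offsets

    def test_published_style_uncut_vs_cut_pattern(self):
        """A 210 bp product cut into 182/28 for one allele and left whole
        for the other: the fragment sums agree."""
        fx = published_marker_fixtures()[2]
        res = digest_pair(fx.pair, fx.enzyme)
        assert res.fragments["A"] == (182, 28)
        assert res.fragments["B"] == (210,)

    def test_flank_validation(self):
        with pytest.raises(ValueError):
            design_dcaps("ACGT" * 10, "ACGT" * 10, 5, ENZYMES[:3])


class TestPredictGel:
    def test_uncut_both_alleles_single_band(self):
        pair = AmpliconPair("A" * 50, "A" * 49 + "C", 49)
        res = digest_pair(pair, enzyme_by_name("EcoRI"))
        assert predict_gel(res, "AA") == (50,)
        assert predict_gel(res, "AB") == (50,)

    def test_unknown_genotype_rejected(self):
        pair = AmpliconPair("A" * 50, "A" * 49 + "C", 49)
        res = digest_pair(pair, enzyme_by_name("EcoRI"))
        with pytest.raises(ValueError):
            predict_gel(res, "AC")
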