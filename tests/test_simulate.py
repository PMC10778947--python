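"""Breeding simulator: founder divergence, meiosis, schemes, call noise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nilscan.simulate import (
    ConfigError,
    SimConfig,
    donor_genome_fraction,
    simulate_breeding,
    simulate_call_set,
    simulate_founders,
    _founder_genome,
)


def small_config(**kw):
    base = dict(n_chromosomes=2, chromosome_lengths=(3_000_000, 3_000_000),
                seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_chromosomes=1, chromosome_lengths=(0,))

    def test_target_outside_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            small_config(target_locus=("Chr01", 4_000_000))

    @pytest.mark.parametrize("field", ["error_rate", "missing_rate"])
    def test_probabilities_bounded(self, field):
        with pytest.raises(ConfigError):
            small_config(**{field: 1.5})


class TestFounders:
    def test_zero_density_leaves_only_forced_trait_snp(self):
        """With snp_density 0 the donors match the recurrent genome except
        for the deliberately forced trait SNP at the target locus."""
        f = simulate_founders(small_config(snp_density=0.0), donor_ids=("D1",))
        snps = f.donor_snps["D1"]
        assert len(snps) == 1
        assert (snps["chromosome"].iloc[0], snps["position"].iloc[0]) == f.target_locus

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        for donor in a.donor_ids:
            pd.testing.assert_frame_equal(a.donor_snps[donor], b.donor_snps[donor])
        for chrom in a.reference:
            assert np.array_equal(a.reference[chrom], b.reference[chrom])

    def test_snp_count_matches_poisson_expectation(self):
        """10 Mb at density 1e-4: the divergent-SNP count sits within 4
        sigma of the Poisson mean of 1000."""
        cfg = SimConfig(n_chromosomes=1, chromosome_lengths=(10_000_000,),
                        snp_density=1e-4, seed=3)
        f = simulate_founders(cfg, donor_ids=("D1",))
        n = len(f.donor_snps["D1"])
        assert abs(n - 1000) <= 4 * np.sqrt(1000) + 1  # +1 for the forced SNP

    def test_alt_alleles_never_equal_reference(self):
        f = simulate_founders(small_config())
        for snps in f.donor_snps.values():
            assert (snps["ref"] != snps["alt"]).all()

    def test_shared_segments_give_identical_donor_snps(self):
        cfg = small_config()
        seg = [("Chr02", 1, 1_500_000)]
        f = simulate_founders(cfg, donor_ids=("D1", "D2"), shared_segments=seg)

        def inside(snps):
            m = (snps["chromosome"] == "Chr02") & (snps["position"] <= 1_500_000)
            return snps[m].reset_index(drop=True)

        pd.testing.assert_frame_equal(inside(f.donor_snps["D1"]),
                                      inside(f.donor_snps["D2"]))


class TestBreeding:
    def test_f1_heterozygous_everywhere(self):
        f = simulate_founders(small_config())
        genomes, truth = simulate_breeding(f, "F1")
        assert (truth["origin"] == "donor").all()
        assert (truth["zygosity"] == "heterozygous").all()

    def test_no_recombination_limit(self):
        """With crossover_rate 0 chromosomes segregate whole: the target
        chromosome is fully homozygous donor, every other chromosome is
        fully one parent."""
        cfg = SimConfig(n_chromosomes=3, chromosome_lengths=(2_000_000,) * 3,
                        crossover_rate=0.0, seed=9)
        f = simulate_founders(cfg, donor_ids=("D1",))
        genomes, truth = simulate_breeding(f, "BC2F4_selected", donor_id="D1")
        tchrom = f.target_locus[0]
        per_chrom = truth.groupby("chromosome")
        for chrom, sub in per_chrom:
            assert len(sub) == 1, "whole-chromosome blocks expected"
            assert (sub["zygosity"] == "homozygous").all()
            if chrom == tchrom:
                assert (sub["origin"] == "donor").all()

    def test_nil_target_block_homozygous_donor(self, study):
        for nil in study.nil_ids:
            truth = study.truth[study.truth["line_id"] == nil]
            tchrom, tpos = study.founders.target_locus
            block = truth[(truth["chromosome"] == tchrom)
                          & (truth["start"] <= tpos) & (truth["end"] >= tpos)]
            assert block["origin"].iloc[0] == "donor"
            assert block["zygosity"].iloc[0] == "homozygous"

    def test_bc2f4_blocks_all_homozygous(self, study):
        """The NIL scheme selfs and then fixes residual heterozygosity, so
        every reported truth block is homozygous."""
        for nil in study.nil_ids:
            truth = study.truth[study.truth["line_id"] == nil]
            assert (truth["zygosity"] == "homozygous").all()

    def test_truth_blocks_tile_chromosomes(self, study):
        cfg = study.config
        for (line, chrom), sub in study.truth.groupby(["line_id", "chromosome"]):
            sub = sub.sort_values("start")
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == cfg.length_of(chrom)
            assert (sub["start"].iloc[1:].to_numpy()
                    == sub["end"].iloc[:-1].to_numpy() + 1).all()

    def test_f2_segregates_one_two_one(self):
        """2000 F2 plants: target-locus genotype counts inside the 99%
        chi-square band of 1:2:1."""
        cfg = small_config(seed=17)
        f = simulate_founders(cfg, donor_ids=("D1",))
        genomes, _ = simulate_breeding(f, "F2", donor_id="D1", n_individuals=2000)
        tchrom, tpos = f.target_locus
        counts = {0: 0, 1: 0, 2: 0}
        for g in genomes:
            origins = g.origin_at(tchrom, tpos)
            counts[sum(o == "D1" for o in origins)] += 1
        obs = np.array([counts[2], counts[1], counts[0]])
        exp = 2000 * np.array([0.25, 0.5, 0.25])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_bc2_background_heterozygosity_near_quarter(self):
        """Before selfing, the non-target genome of a BC2 individual is
        heterozygous donor at an expected fraction of 1/4 (two backcross
        halvings of the F1); the replicate mean sits within 3 SE."""
        fracs = []
        cfg0 = SimConfig(seed=0)
        for i in range(50):
            cfg = SimConfig(seed=300 + i)
            f = simulate_founders(cfg, donor_ids=("D1",))
            _, truth = simulate_breeding(f, "BC2F1", donor_id="D1")
            tchrom = f.target_locus[0]
            bg = truth[truth["chromosome"] != tchrom]
            span = bg["end"] - bg["start"] + 1
            het = span[bg["zygosity"] == "heterozygous"].sum()
            total = sum(length for c, length in
                        zip(cfg.chromosome_names, cfg.chromosome_lengths)
                        if c != tchrom)
            fracs.append(het / total)
        mean, se = np.mean(fracs), np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.25) <= 3 * se

    def test_scheme_without_target_in_donor_errors(self):
        cfg = small_config(snp_density=0.0)
        f = simulate_founders(cfg, donor_ids=("D1",))
        f.donor_snps["D1"] = f.donor_snps["D1"].iloc[0:0]  # drop the trait SNP
        with pytest.raises(ConfigError):
            simulate_breeding(f, "BC2F4_selected", donor_id="D1")


class TestCallSets:
    def test_noiseless_homozygous_donor_reads_all_alternate(self):
        cfg = small_config(error_rate=0.0, missing_rate=0.0, depth_mean=30)
        f = simulate_founders(cfg, donor_ids=("D1",))
        donor = _founder_genome("D1", "D1", cfg)
        calls = simulate_call_set(donor, f, cfg)
        snp_keys = set(zip(f.donor_snps["D1"]["chromosome"],
                           f.donor_snps["D1"]["position"]))
        at_snps = calls[[k in snp_keys for k in
                         zip(calls["chromosome"], calls["position"])]]
        ref_counts = np.array([row[row_ref] for row_ref, row in
                               zip(at_snps["ref"], at_snps[list("ACGT")].to_dict("records"))])
        assert (ref_counts == 0).all()
        alt_total = at_snps[list("ACGT")].sum(axis=1) - ref_counts
        assert (alt_total == at_snps["depth"]).all()

    def test_heterozygous_read_rate_near_half_at_high_depth(self):
        """Depth ~1000, no error: the alternate-allele read rate of every
        heterozygous locus falls in [0.4, 0.6] (binomial concentration)."""
        cfg = small_config(error_rate=0.0, missing_rate=0.0,
                           depth_mean=1000.0, depth_dispersion=200.0)
        f = simulate_founders(cfg, donor_ids=("D1",))
        genomes, _ = simulate_breeding(f, "F1", donor_id="D1")
        calls = simulate_call_set(genomes[0], f, cfg)
        het = calls[calls["truth_zygosity"] == "heterozygous"]
        ref_counts = np.array([rec[r] for r, rec in
                               zip(het["ref"], het[list("ACGT")].to_dict("records"))])
        rate = (het["depth"].to_numpy() - ref_counts) / het["depth"].to_numpy()
        assert len(het) > 500
        assert ((rate >= 0.4) & (rate <= 0.6)).all()

    def test_missing_rate_one_drops_every_call(self):
        cfg = small_config(missing_rate=1.0)
        f = simulate_founders(cfg, donor_ids=("D1",))
        calls = simulate_call_set(_founder_genome("D1", "D1", cfg), f, cfg)
        assert calls["missing"].all()
        assert (calls[list("ACGT")].to_numpy() == 0).all()

    def test_call_sets_deterministic_under_seed(self):
        cfg = small_config()
        f = simulate_founders(cfg, donor_ids=("D1",))
        g = _founder_genome("D1", "D1", cfg)
        pd.testing.assert_frame_equal(simulate_call_set(g, f, cfg),
                                      simulate_call_set(g, f, cfg))


def test_donor_fraction_of_founders():
    cfg = small_config()
    f = simulate_founders(cfg, donor_ids=("D1",))
    from nilscan.simulate import truth_blocks

    donor_truth = truth_blocks(_founder_genome("D1", "D1", cfg), "DAH")
    recurrent_truth = truth_blocks(_founder_genome("DAH", "DAH", cfg), "DAH")
    assert donor_genome_fraction(donor_truth, cfg) == 1.0
    assert donor_genome_fraction(recurrent_truth, cfg) == 0.0
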