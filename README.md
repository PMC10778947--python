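# nilscan

Introgression mapping in near-isogenic lines (NILs), built around the
comparative-genomics workflow used to localize the orange-flesh
(high-β-carotene) gene of watermelon: whole-genome SNP calls of a
recurrent parent, one or more donor parents and the NILs bred from them
are classified, consolidated into a multi-line SNP matrix, and mined for
donor-derived chromosome blocks; candidate genes inside those blocks are
annotated at codon level and turned into CAPS/dCAPS genotyping markers
with in-silico restriction digestion.

The package is for plant breeders and genome analysts who have per-line
VCFs from an upstream aligner/caller and want the downstream analysis —
zygosity classification, pairwise polymorphism accounting, region
detection, candidate-gene effects, marker design and segregation
statistics — as tested, scriptable components rather than a one-off
pipeline. A synthetic backcross-breeding simulator generates truth-tagged
founders, BC₂F₄ NILs, F₂ populations and noisy call sets, so every stage
is testable without external data.

## The method

**Zygosity from read rates.** At each locus the read rate *r* is the
fraction of reads supporting the majority non-reference allele:
homozygous if *r* ≥ 0.90, heterozygous if 0.40 ≤ *r* ≤ 0.60, otherwise
"other" (unclassifiable) for *r* ≥ 0.20 and reference-like below; loci
with depth outside [3, 257] are missing. Calls within 30 bp of a
gap/indel or of another call are filtered.

**Consolidated matrix and comparison taxonomy.** The union of
post-filter candidate loci over all lines forms the matrix; lines without
a call at a union locus are filled in from consensus coverage
(reference-like) when depth permits. Each locus between two lines falls
in exactly one of six classes — homozygous-polymorphic,
heterozygous-polymorphic, non-polymorphic, insufficient-depth, unknown,
ambiguous — with data-quality classes taking precedence over biological
ones.

**Introgression regions.** A NIL's introgression SNPs are homozygous,
adequate-depth loci that equal the donor allele and are
homozygous-polymorphic to the recurrent parent. Counting them in 1 Mb
windows, windows with ≥ 10 SNPs are seeded, runs bridging ≤ 1 empty
window are merged, and region bounds are reported at the outermost
supporting SNPs. Regions of two NILs can be intersected (shared donor
blocks, with a between-NIL polymorphism check) or subtracted
(NIL-specific blocks).

**Candidate genes and markers.** Genes overlapping a region by ≥ 1 bp are
candidates; SNP effects in coding sequence are annotated by codon
(standard genetic code, strand-aware), e.g. the phytoene-synthase
substitution AAG→GAG (Lys→Glu, codon 149). For a marker, each enzyme of a
~50-enzyme IUPAC catalogue digests both allele amplicons in silico; an
enzyme whose fragment multisets differ is a CAPS assay, and when none
exists a dCAPS search enumerates single-base primer mismatches that
complete a recognition site together with exactly one allele.

**Segregation.** F₂ phenotype counts are tested against Mendelian ratios
by χ² = Σ(O−E)²/E; for an incompletely dominant gene both the unpooled
1:2:1 test (df = 2) and the dominant-pooled 3:1 test (df = 1) are
available, and marker–phenotype co-segregation is summarized as a
concordance table.

## Worked example

Simulate a study (11 scaled chromosomes, two donors, two BC₂F₄ NILs),
export it as FASTA/VCF/GFF3/BED, and run the full pipeline:

```sh
nilscan simulate --out fixture --seed 7
nilscan segregate --counts 22,47,20 --pool dominant
```

The segregation command prints

```
chi2 = 0.3034, df = 1, p = 0.5818
```

— the observed 22:47:20 flesh-colour classes pooled to 69:20 fit 3:1
(and hence single-gene incomplete dominance) comfortably. In Python,
the same study end to end:

```python
from nilscan.simulate import SimConfig, simulate_study, export_fixture
from nilscan.pipeline import PipelineConfig, run_pipeline

bundle = simulate_study(SimConfig(seed=7, depth_mean=20, error_rate=0.005))
export_fixture(bundle, "fixture")
results = run_pipeline(PipelineConfig(
    vcf_paths={lid: f"fixture/{lid}.vcf" for lid in bundle.call_sets},
    reference="fixture/reference.fa", genes="fixture/genes.gff3",
    out_dir="out", recurrent="DAH",
    donors=["NB5410", "OTO9491"], nils=["NIL-NB5410", "NIL-OTO9491"]))
print(results["gene_hits"][["gene_id", "name", "chromosome", "nil_id"]])
print(results["effects"][["gene_id", "change", "codon", "aa", "codon_number"]])
```

prints, among the candidate hits,

```
      gene_id   name chromosome      nil_id
ClCG01G008470    PSY      Chr01  NIL-NB5410
```

```
      gene_id change   codon        aa  codon_number
ClCG01G008470    A>G AAG>GAG Lys > Glu           149
```

i.e. the phytoene-synthase gene placed inside the simulated donor block
is recovered as a candidate, and the trait SNP annotates as the
non-synonymous Lys→Glu change at codon 149. `out/` additionally holds
the matrix TSV, pairwise summary, region BEDs, window densities, marker
designs and a manifest of every threshold used.

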