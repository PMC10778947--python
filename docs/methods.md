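# Methods

This note documents the models, defaults and design choices behind
nilscan, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Breeding and genome model

The simulator represents a diploid genome as two haplotypes per
chromosome, each a mosaic of origin-labelled segments (founder
identifiers). Meiosis draws a Poisson number of crossovers per
chromosome (default 1.5, configurable; chromosome-scale linkage maps are
out of scope, so physical positions are uniform and interference is
ignored) and alternates parental segments at the breakpoints.

The NIL scheme mirrors marker-free phenotypic selection: donor ×
recurrent F₁, two backcrosses to the recurrent parent keeping only
gametes that carry the donor allele at the target locus, then three
selfing generations keeping individuals homozygous donor at that locus.
Selection acts on the target genotype only; the background is neutral.
After the final selfing, residual heterozygous segments are resolved to
homozygosity (either side with probability 1/2). Biologically, a
heterozygous background segment survives three selfings with probability
1/8; the forced resolution models the breeder's deliberate selection of
a genetically fixed line, and it is what makes "every truth block is
homozygous" an exact invariant rather than a statistical one. Reduce
`selfing_generations` and skip fixation to study partially fixed
material.

Default genome: the real watermelon karyotype of 11 chromosomes, each
scaled to 3 Mb (about a tenth of a real chromosome). The chromosome
*number* matters more than the length: the donor-genome fraction left
after BC₂ is an average over independently segregating chromosomes, and
with very few chromosomes it drifts so wildly between realizations that
region calling sees either almost no background or a half-donor genome.
Eleven scaled chromosomes keep that variance realistic at desk-scale
cost. Parental divergence defaults to 4 × 10⁻⁴ SNPs/bp (the published
parent pair differs at ~147k homozygous SNPs over a ~350 Mb genome);
alternate alleles are uniform over the three non-reference bases.

The published candidate-gene coordinates are rescaled into the synthetic
genome by scaling gene *starts* (assuming 35 Mb real chromosomes) while
keeping gene *lengths*, so in-gene offsets — and hence codon arithmetic
such as the Lys→Glu substitution at codon 149 of phytoene synthase —
survive the scaling. The reference codon at the target locus is patched
to AAG and every donor carries the forced A→G trait SNP, so the full
chain (region → gene hit → codon effect → marker) is exercised by
construction.

## Read-count noise model

Per-locus depth is negative binomial (mean 15, dispersion 5 by default;
overdispersion is typical of resequencing and stresses the depth
filters). Reads split binomially between haplotypes; each read reports a
uniform wrong base with probability `error_rate` (default 0.5%). Whole
loci become no-calls with probability `missing_rate` (default 2%): the
record keeps its depth but no genotype, emulating a consensus-covered
position without a SNP call — which is exactly the information the
matrix builder needs for consensus fill-in. What the generator does
*not* emulate: mapping artifacts, allele-specific bias, indels and
structural variants, GC-dependent coverage, and duplicated regions.
Passing tests therefore demonstrate correctness of the downstream
arithmetic under a clean error model, not robustness to alignment
pathology.

## Matrix construction details

Zygosity classes follow the read-rate rule (homozygous ≥ 90%,
heterozygous 40–60%, other 20–90%, reference-like < 20%, missing outside
depth [3, 257]). The published rate ranges overlap; precedence
homozygous → heterozygous → other makes "other" the residual
could-not-classify class, matching its use in the published SNP-type
accounting. Multi-allelic cells keep the two highest-count alleles and
are flagged ambiguous when a third allele exceeds 20% of reads. One
published section says depth > 3 where another says minimum depth 3; the
default is depth ≥ 3 with a `strict_gt3` switch for the stricter
reading.

The dense-SNP filter removes every call whose nearest neighbour lies
within the 30 bp window (the source states the window size only; the
any-window-with-≥2-calls reading makes the filter idempotent). The union
of candidate loci is taken over post-filter calls with any non-reference
read evidence; after consensus fill-in, loci reference-like in every
line (miscalls) are dropped. A call removed by a filter is treated as
missing rather than fillable: its evidence was judged unreliable, so
promoting it to a confident reference call would manufacture certainty.

## Comparison and region calling

The six comparison classes are ordered so that data-quality failures are
never reported as biology: insufficient depth, then missing, then
ambiguous, then identity, then homozygous/heterozygous polymorphism.
Heterozygous-vs-heterozygous contrasts with different allele pairs fall
in "ambiguous" (the published class definitions never cover them).

Region calling counts introgression SNPs in 1 Mb windows anchored at
position 1, seeds windows with ≥ 10 SNPs, merges runs bridging at most
one empty window, and reports boundaries at the outermost supporting
SNPs (window edges overstate precision inconsistently across window
phases). The seed threshold was designed as a fixed floor rather than
the initially considered adaptive quantile rule: at the stated
divergence a genuinely introgressed window carries ~400 homozygous donor
SNPs while the miscall background contributes at most a few, so any
threshold in the wide gap between works, whereas a quantile of the
window-count distribution is captured by the signal itself whenever
introgression covers a large genome fraction — which desk-scale genomes
regularly produce. Recovery experiments score boundaries against the
*chained* truth interval (donor-homozygous blocks merged across gaps the
caller bridges by design), since that is the object a gap-bridging
windowed caller estimates.

## Candidate genes, effects, markers

When a gene model lacks exon structure (the shipped candidate table
gives spans only), the whole span is treated as a single CDS from the 5′
end — adequate for first-exon SNPs like the three annotated here, and
flagged approximate. Translation uses the standard genetic code via
Biopython; minus-strand genes are handled by reverse-complementing the
CDS, and a reference-allele check against the genome guards coordinate
bugs. The cis-regulatory check is a configurable upstream window
(default 2 kb) scanned for SNP presence only; no motif analysis.

Enzyme recognition data ship as an editable TSV of ~50 common enzymes
with IUPAC sites and top/bottom cut offsets (REBASE-style public data;
the source paper names enzymes but not sites). Non-palindromic
recognitions are scanned on both strands; for a bottom-strand site at
top position *p* the top strand is severed at *p* + *L* − *cut_bottom*.
Fragment lengths are consecutive differences of top-strand cut
coordinates — the convention restriction-mapping tools print. The
heterozygote gel model is additive banding (duplicate lengths collapse
to one band); heteroduplex artifacts are ignored. CAPS candidates are
ranked resolvable-first (shortest diagnostic fragment ≥ 30 bp, matching
3% agarose; the smallest published diagnostic band is 28 bp, and the
floor is configurable down to 20), then by fewest cuts. The dCAPS search
enumerates primer placements ending within one recognition length of the
SNP and ≤ 1 primer edits, never at the 3′-terminal base; the
zero-mismatch case degenerates to plain CAPS.

The three published marker amplicons cannot be reconstructed from
public text (their genomic coordinates are not printed), so
`nilscan.amplicons` builds *synthetic* amplicons with the sites planted
to reproduce the published band multisets exactly (338/43 vs 175/163/43
summing 381; 1594 vs 1180/414; 210 vs 182/28); they serve as ground
truth for the digestion engine, not as genomic sequence.

## Segregation statistics

χ² = Σ(O−E)²/E with p from the χ² survival function. The published
statistic for the F₂ counts (22, 47, 20) carries one degree of freedom,
which a three-class 1:2:1 comparison cannot produce; pooling the
dominant classes to (69, 20) against 3:1 reproduces it, so both modes
are implemented and the pooled mode is documented as the published one.
Yates continuity correction is available behind a flag, default off
(the published value is reproduced without it). Intermediate-phenotype
plants are excluded from co-segregation via an explicit exclusion list,
and genotypes mapped to no phenotype (heterozygotes) are reported
separately rather than counted discordant. Coverage arithmetic divides
summed trimmed read lengths by the 350 Mb genome estimate the published
table uses (the assembly-size figure of 424 Mb is retained as a named
constant).

## Problem sizes and numerical choices

The test suite and acceptance script run whole studies at 11 × 3 Mb
(≈ 26k union loci, five lines) in seconds, 20-seed recovery experiments
at depth 20 and 1% error, 1000-amplicon CAPS oracle comparisons, 20
60-bp dCAPS exhaustive enumerations, and a 10,000-replicate null
calibration — sizes chosen so a complete run stays desk-scale while
each statistic retains enough replicates to be meaningful. All
randomness flows through explicit integer seeds (numpy Generator
streams keyed by seed plus a stable per-line hash), so fixed seeds give
byte-identical fixtures and pipeline outputs. Known limitations: no
haplotype phasing or HMM ancestry inference (the rule-based method
only), no indel genotyping (indels act only as gap positions for
filtering), no primer thermodynamics (amplicons are user- or
simulator-supplied), and the single-CDS approximation above.
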