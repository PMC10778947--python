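"""End-to-end pipeline: matrix -> compare -> introgression -> genes ->
markers -> segregation, with a manifest logging every threshold used.

The pipeline consumes per-line VCFs (the output of an upstream aligner and
SNP caller, which is out of scope) plus a reference FASTA, gene models and
an enzyme catalogue, and writes the tables a mapping study reports: the
pairwise polymorphism summary, per-NIL introgression regions (BED) and
window densities, candidate-gene hits, codon effects, CAPS/dCAPS marker
designs and (optionally) segregation statistics.  Identical config and
seed produce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as nio
from .compare import compare_lines, window_density, COMPARISON_CLASSES
from .genes import (annotate_variant, genes_in_regions, load_gene_table,
                    CDS, NON_SYNONYMOUS)
from .introgression import (RegionCallConfig, call_regions,
                            detect_introgression_snps, distinct_regions,
                            shared_regions)
from .markers import AmpliconPair, design_dcaps, find_caps, load_enzymes, predict_gel
from .segregation import chisq_segregation
from .snp_matrix import FilterConfig, build_consolidated_matrix


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf_paths: dict[str, str]          # line id -> per-line VCF
    reference: str
    genes: str                         # GFF3 or candidate-gene TSV
    out_dir: str
    recurrent: str = ""
    donors: list[str] = field(default_factory=list)
    nils: list[str] = field(default_factory=list)  # nils[i] bred from donors[i]
    enzymes: str | None = None
    phenotype_counts: dict[str, int] | None = None  # class -> F2 count
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    region_config: RegionCallConfig = field(default_factory=RegionCallConfig)
    amplicon_flank: int = 170
    seed: int = 0

    def validate(self) -> None:
        roles = [self.recurrent, *self.donors, *self.nils]
        if not self.recurrent or not self.donors or not self.nils:
            raise PipelineError("config", "recurrent, donors and nils must all be set")
        if len(roles) != len(set(roles)):
            raise PipelineError("config", "line roles must be distinct")
        if len(self.donors) != len(self.nils):
            raise PipelineError("config", "donors and nils must pair up")
        absent = [r for r in roles if r not in self.vcf_paths]
        if absent:
            raise PipelineError("config", f"roles without a VCF: {absent}")
        for name in ("reference", "genes"):
            if not Path(getattr(self, name)).exists():
                raise PipelineError("config", f"{name} path does not exist")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the in-memory results keyed by stage.  Any stage failure
    aborts with the stage name and context.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "filters": asdict(config.filter_config),
        "region_calling": asdict(config.region_config),
        "roles": {"recurrent": config.recurrent, "donors": config.donors,
                  "nils": config.nils},
        "counts": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError(name, str(exc)) from exc
        return deco

    @stage("matrix")
    def _matrix():
        calls = nio.read_call_sets(config.vcf_paths)
        matrix = build_consolidated_matrix(calls, config.filter_config)
        nio.write_matrix_tsv(matrix, out / "matrix.tsv")
        pd.DataFrame(matrix.filter_logs).T.to_csv(out / "filter_log.tsv", sep="\t")
        results["matrix"] = matrix
        manifest["counts"]["matrix_loci"] = matrix.n_loci
        return matrix

    matrix = _matrix

    @stage("compare")
    def _compare():
        pairs = [(config.recurrent, d) for d in config.donors]
        pairs += [(config.recurrent, n) for n in config.nils]
        if len(config.donors) > 1:
            pairs.append(tuple(config.donors[:2]))
        if len(config.nils) > 1:
            pairs.append(tuple(config.nils[:2]))
        rows = []
        for a, b in pairs:
            res = compare_lines(matrix, a, b, config.filter_config)
            rows.append({"pair": f"{a} vs {b}", **res.counts})
        summary = pd.DataFrame(rows, columns=["pair", *COMPARISON_CLASSES])
        summary.to_csv(out / "pairwise_summary.tsv", sep="\t", index=False)
        results["pairwise"] = summary
        return summary

    _compare

    @stage("introgression")
    def _introgression():
        regions_by_nil, snps_by_nil = {}, {}
        for donor, nil in zip(config.donors, config.nils):
            snps = detect_introgression_snps(matrix, nil, donor,
                                             config.recurrent, config.region_config)
            snps.to_csv(out / f"introgression_snps_{nil}.tsv", sep="\t", index=False)
            density = window_density(snps, config.region_config.window_bp)
            density.to_csv(out / f"windows_{nil}.tsv", sep="\t", index=False)
            regions = call_regions(snps, config.region_config, nil_id=nil,
                                   donor_id=donor)
            nio.write_regions_bed(regions, out / f"regions_{nil}.bed")
            regions_by_nil[nil], snps_by_nil[nil] = regions, snps
            manifest["counts"][f"introgression_snps_{nil}"] = len(snps)
            manifest["counts"][f"regions_{nil}"] = len(regions)
        results["regions"] = regions_by_nil
        results["introgression_snps"] = snps_by_nil

        if len(config.nils) > 1:
            a, b = config.nils[:2]
            shared = shared_regions(regions_by_nil[a], regions_by_nil[b],
                                    matrix, a, b, snps_by_nil[a], snps_by_nil[b],
                                    config.region_config)
            nio.write_regions_bed(shared.regions, out / "shared_regions.bed")
            shared.polymorphism.to_csv(out / "shared_polymorphism.tsv",
                                       sep="\t", index=False)
            only_a, only_b = distinct_regions(regions_by_nil[a], regions_by_nil[b],
                                              snps_by_nil[a], snps_by_nil[b])
            nio.write_regions_bed(only_a, out / f"distinct_regions_{a}.bed")
            nio.write_regions_bed(only_b, out / f"distinct_regions_{b}.bed")
            results["shared"] = shared
            results["distinct"] = {a: only_a, b: only_b}
        return regions_by_nil

    regions_by_nil = _introgression

    @stage("genes")
    def _genes():
        path = Path(config.genes)
        genes = (nio.read_gff3(path) if path.suffix.lower() in (".gff", ".gff3")
                 else load_gene_table(path))
        all_regions = [r for regs in regions_by_nil.values() for r in regs]
        hits = genes_in_regions(genes, all_regions)
        hits.to_csv(out / "gene_hits.tsv", sep="\t", index=False)
        results["gene_hits"] = hits

        genome = nio.read_fasta(config.reference)
        effects = []
        for _, hit in hits.iterrows():
            gene = next(g for g in genes if g.gene_id == hit["gene_id"])
            nil = hit["nil_id"]
            snps = results["introgression_snps"].get(nil)
            if snps is None:
                continue
            inside = snps[(snps["chromosome"] == gene.chromosome)
                          & (snps["position"] >= gene.start)
                          & (snps["position"] <= gene.end)]
            for _, snp in inside.iterrows():
                alt = snp["genotype"].split("/")[0]
                if alt == snp["ref"]:
                    continue
                eff = annotate_variant(
                    (snp["chromosome"], int(snp["position"]), snp["ref"], alt),
                    gene, genome)
                effects.append({
                    "gene_id": gene.gene_id, "gene": gene.name, "nil_id": nil,
                    "chromosome": eff.chromosome, "position": eff.position,
                    "change": f"{eff.ref}>{eff.alt}", "region": eff.region,
                    "effect": eff.effect_class,
                    "codon": (f"{eff.codon_before}>{eff.codon_after}"
                              if eff.codon_before else ""),
                    "aa": (f"{eff.aa_before} > {eff.aa_after}"
                           if eff.aa_before else ""),
                    "codon_number": eff.codon_number or "",
                })
        effects_df = pd.DataFrame(effects, columns=[
            "gene_id", "gene", "nil_id", "chromosome", "position", "change",
            "region", "effect", "codon", "aa", "codon_number"])
        effects_df.to_csv(out / "variant_effects.tsv", sep="\t", index=False)
        results["effects"] = effects_df
        return effects_df

    effects_df = _genes

    @stage("markers")
    def _markers():
        enzymes = load_enzymes(config.enzymes)
        genome = nio.read_fasta(config.reference)
        rows = []
        targets = effects_df[(effects_df["region"] == CDS)
                             & (effects_df["effect"] == NON_SYNONYMOUS)]
        for _, eff in targets.iterrows():
            chrom, pos = eff["chromosome"], int(eff["position"])
            ref_base, alt_base = eff["change"].split(">")
            flank = config.amplicon_flank
            start = max(1, pos - flank)
            seq = str(genome[chrom][start - 1:pos + flank]).upper()
            offset = pos - start
            allele_ref = seq
            allele_alt = seq[:offset] + alt_base + seq[offset + 1:]
            name = f"{eff['gene']}-{ref_base}>{alt_base}"
            caps = find_caps(AmpliconPair(allele_ref, allele_alt, offset),
                             enzymes)
            if caps:
                best = caps[0]
                rows.append(_marker_row(name, "CAPS", best, eff))
                continue
            short = 30
            lo, hi = offset - short, offset + short
            designs = design_dcaps(allele_ref[lo:hi], allele_alt[lo:hi],
                                   short, enzymes, primer_len=20)
            designs = [d for d in designs if d.n_mismatches > 0]
            if designs:
                best = designs[0]
                rows.append(_marker_row(name, "dCAPS", best.digest, eff,
                                        primer=best.primer))
        markers_df = pd.DataFrame(rows, columns=[
            "marker", "type", "enzyme", "bands_ref_allele", "bands_alt_allele",
            "bands_het", "primer", "gene_id", "position"])
        markers_df.to_csv(out / "markers.tsv", sep="\t", index=False)
        results["markers"] = markers_df
        return markers_df

    _markers

    @stage("segregation")
    def _segregation():
        if config.phenotype_counts is None:
            return None
        test = chisq_segregation(config.phenotype_counts, (1, 2, 1), "dominant")
        report = pd.DataFrame([{
            "observed": "/".join(f"{k}:{v}" for k, v in test.observed.items()),
            "pooled": "/".join(f"{k}:{v}" for k, v in test.pooled_observed.items()),
            "ratio": ":".join(str(int(r)) for r in test.ratio),
            "chi_square": round(test.chi_square, 4), "df": test.df,
            "p_value": round(test.p_value, 4)}])
        report.to_csv(out / "segregation.tsv", sep="\t", index=False)
        results["segregation"] = test
        return test

    _segregation

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results


def _marker_row(name: str, kind: str, digest_result, eff, primer: str = "") -> dict:
    return {
        "marker": name, "type": kind, "enzyme": digest_result.enzyme.name,
        "bands_ref_allele": "/".join(map(str, digest_result.fragments["A"])),
        "bands_alt_allele": "/".join(map(str, digest_result.fragments["B"])),
        "bands_het": "/".join(map(str, predict_gel(digest_result, "AB"))),
        "primer": primer, "gene_id": eff["gene_id"], "position": eff["position"],
    }
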