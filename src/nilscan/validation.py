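"""Recovery and calibration experiments against independent oracles.

These routines quantify how well the pipeline recovers simulated ground
truth (target-block detection across seeds), how the digestion-based
marker search compares with brute-force re-computation, and whether the
segregation test is calibrated under the null.  The brute-force helpers
here are deliberately naive re-implementations (plain nested loops, no
shared code with the engine) so they can serve as independent oracles.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .compare import compare_lines, NON_POLYMORPHIC, HOM_POLY
from .introgression import RegionCallConfig, call_regions, detect_introgression_snps
from .markers import AmpliconPair, EnzymeSpec, design_dcaps, find_caps, load_enzymes
from .simulate import SimConfig, simulate_breeding, simulate_call_set, simulate_founders
from .snp_matrix import build_consolidated_matrix


# --------------------------------------------------------------------------
# target-block recovery across seeded breeding simulations

def run_target_recovery(
    n_runs: int = 20,
    base_seed: int = 1,
    config: SimConfig | None = None,
    region_config: RegionCallConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_runs`` BC2F4 NILs and measure target-block detection.

    Per run: one donor/recurrent/NIL trio is simulated (mean depth 20,
    error rate 1 % unless overridden), the matrix is built, introgression
    SNPs are detected and regions called; the run scores as detected when
    a region contains the target locus.  Boundary errors are measured
    against the *chained* truth interval: the donor-homozygous truth
    blocks around the target merged across recurrent gaps the caller
    bridges by design (up to ``merge_gap_windows + 1`` windows), since a
    windowed caller with gap bridging reports that chained span, not the
    single recombination-delimited block.
    """
    base = config or SimConfig(depth_mean=20.0, error_rate=0.01)
    region_config = region_config or RegionCallConfig()
    rows = []
    for i in range(n_runs):
        cfg = replace(base, seed=(base_seed + 1000 * i) % 2**31)
        founders = simulate_founders(cfg, donor_ids=("NB5410",))
        nils, truth = simulate_breeding(founders, "BC2F4_selected", cfg,
                                        donor_id="NB5410", line_id="NIL")
        genomes = {"DAH": None, "NB5410": None, "NIL": nils[0]}
        from .simulate import _founder_genome  # founders as trivial genomes

        genomes["DAH"] = _founder_genome("DAH", "DAH", cfg)
        genomes["NB5410"] = _founder_genome("NB5410", "NB5410", cfg)
        calls = {lid: simulate_call_set(g, founders, cfg)
                 for lid, g in genomes.items()}
        matrix = build_consolidated_matrix(calls)
        snps = detect_introgression_snps(matrix, "NIL", "NB5410", "DAH",
                                         region_config)
        regions = call_regions(snps, region_config, nil_id="NIL",
                               donor_id="NB5410")
        tchrom, tpos = founders.target_locus
        t_start, t_end = _chained_truth_interval(
            truth, tchrom, tpos,
            region_config.window_bp, region_config.merge_gap_windows)
        hit = next((r for r in regions
                    if r.chromosome == tchrom and r.start <= tpos <= r.end), None)
        rows.append({
            "seed": cfg.seed,
            "detected": hit is not None,
            "truth_start": t_start,
            "truth_end": t_end,
            "region_start": hit.start if hit else np.nan,
            "region_end": hit.end if hit else np.nan,
            "start_error": abs(hit.start - t_start) if hit else np.nan,
            "end_error": abs(hit.end - t_end) if hit else np.nan,
        })
    return pd.DataFrame(rows)


def _chained_truth_interval(truth: pd.DataFrame, chrom: str, pos: int,
                            window_bp: int, merge_gap_windows: int) -> tuple[int, int]:
    """Span of donor-homozygous truth blocks chained around the block
    containing ``pos``, merging across gaps of up to
    (merge_gap_windows + 1) windows of recurrent genome."""
    blocks = truth[(truth["chromosome"] == chrom)
                   & (truth["origin"] == "donor")
                   & (truth["zygosity"] == "homozygous")]
    blocks = blocks.sort_values("start").reset_index(drop=True)
    idx = blocks.index[(blocks["start"] <= pos) & (blocks["end"] >= pos)][0]
    max_gap = (merge_gap_windows + 1) * window_bp
    start, end = int(blocks.loc[idx, "start"]), int(blocks.loc[idx, "end"])
    for i in range(idx - 1, -1, -1):
        if start - int(blocks.loc[i, "end"]) - 1 <= max_gap:
            start = int(blocks.loc[i, "start"])
        else:
            break
    for i in range(idx + 1, len(blocks)):
        if int(blocks.loc[i, "start"]) - end - 1 <= max_gap:
            end = int(blocks.loc[i, "end"])
        else:
            break
    return start, end


def recovery_summary(recovery: pd.DataFrame,
                     window_bp: int = 1_000_000) -> dict[str, float]:
    detected = recovery["detected"]
    within = (detected
              & (recovery["start_error"] <= window_bp)
              & (recovery["end_error"] <= window_bp))
    return {
        "n_runs": int(len(recovery)),
        "detection_rate": float(detected.mean()),
        "within_one_window_rate": float(within.mean()),
        "mean_boundary_error_bp": float(
            recovery.loc[detected, ["start_error", "end_error"]].to_numpy().mean())
        if detected.any() else float("nan"),
    }


def detection_invariants_hold(matrix, nil: str, donor: str, recurrent: str,
                              config: RegionCallConfig | None = None) -> bool:
    """Set containment: detected loci are homozygous-polymorphic between
    recurrent and NIL AND non-polymorphic between donor and NIL."""
    snps = detect_introgression_snps(matrix, nil, donor, recurrent, config)
    keys = set(zip(snps["chromosome"], snps["position"]))
    vs_rec = compare_lines(matrix, recurrent, nil).classes.to_numpy()
    vs_don = compare_lines(matrix, donor, nil).classes.to_numpy()
    locus_keys = list(zip(matrix.loci["chromosome"], matrix.loci["position"]))
    allowed = {k for k, a, b in zip(locus_keys, vs_rec, vs_don)
               if a == HOM_POLY and b == NON_POLYMORPHIC}
    return keys <= allowed


# --------------------------------------------------------------------------
# naive digestion oracle (independent of the regex engine)

_NAIVE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_NAIVE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
               "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
               "D": "H", "H": "D", "N": "N"}


def naive_digest(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Fragment lengths by brute force: check every start position of both
    strands against the IUPAC recognition, base by base."""
    seq = sequence.upper()
    rec = enzyme.recognition.upper()
    rc = "".join(_NAIVE_COMP[c] for c in rec)[::-1]
    L = len(rec)
    cuts = set()
    for p in range(len(seq) - L + 1):
        window = seq[p:p + L]
        if all(window[k] in _NAIVE_IUPAC[rec[k]] for k in range(L)):
            cuts.add(p + enzyme.cut_top)
        if rc != rec and all(window[k] in _NAIVE_IUPAC[rc[k]] for k in range(L)):
            cuts.add(p + L - enzyme.cut_bottom)
    cuts = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0, *cuts, len(seq)]
    return sorted((b - a for a, b in zip(bounds[:-1], bounds[1:])), reverse=True)


def caps_bruteforce_agreement(
    n_amplicons: int = 1000,
    seed: int = 1,
    amplicon_len: int = 160,
    enzymes: list[EnzymeSpec] | None = None,
) -> dict[str, float]:
    """Compare find_caps against brute-force digestion over the catalogue
    on random SNP-bearing amplicons; returns the agreement rate."""
    enzymes = enzymes or load_enzymes()
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_amplicons):
        seq = "".join(rng.choice(list("ACGT"), size=amplicon_len))
        offset = int(rng.integers(10, amplicon_len - 10))
        ref = seq[offset]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        allele_b = seq[:offset] + alt + seq[offset + 1:]
        pair = AmpliconPair(seq, allele_b, offset)
        found = {r.enzyme.name for r in find_caps(pair, enzymes, min_fragment=0)}
        brute = {e.name for e in enzymes
                 if naive_digest(seq, e) != naive_digest(allele_b, e)}
        agree += found == brute
    return {"n_amplicons": n_amplicons, "agreement_rate": agree / n_amplicons}


def dcaps_exhaustive_agreement(
    n_flanks: int = 30,
    seed: int = 2,
    flank_len: int = 60,
    primer_len: int = 20,
    enzymes: list[EnzymeSpec] | None = None,
) -> dict[str, float]:
    """Compare design_dcaps with an exhaustive independent enumeration of
    single-base primer edits on random flanks; returns the agreement rate
    over the (enzyme, primer, placement) design sets."""
    enzymes = enzymes or load_enzymes()
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_flanks):
        snp = flank_len // 2
        seq = "".join(rng.choice(list("ACGT"), size=flank_len))
        ref = seq[snp]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        fa, fb = seq, seq[:snp] + alt + seq[snp + 1:]
        found = {(d.enzyme.name, d.primer, d.primer_start)
                 for d in design_dcaps(fa, fb, snp, enzymes, 1, primer_len)}
        brute = _brute_dcaps(fa, fb, snp, enzymes, primer_len)
        agree += found == brute
    return {"n_flanks": n_flanks, "agreement_rate": agree / n_flanks}


def _overlapping_site_naive(seq: str, enzyme: EnzymeSpec, snp: int) -> bool:
    rec = enzyme.recognition.upper()
    rc = "".join(_NAIVE_COMP[c] for c in rec)[::-1]
    L = len(rec)
    for p in range(max(0, snp - L + 1), min(snp + 1, len(seq) - L + 1)):
        window = seq[p:p + L]
        if all(window[k] in _NAIVE_IUPAC[rec[k]] for k in range(L)):
            return True
        if rc != rec and all(window[k] in _NAIVE_IUPAC[rc[k]] for k in range(L)):
            return True
    return False


def _brute_dcaps(fa: str, fb: str, snp: int, enzymes, primer_len: int) -> set:
    out = set()
    for enzyme in enzymes:
        for end in range(primer_len - 1, snp):
            if snp - end > enzyme.length:
                continue
            start = end - primer_len + 1
            if start < 0:
                continue
            candidates = [((), ())]
            for j in range(start, end):
                for base in "ACGT":
                    if base != fa[j]:
                        candidates.append(((j,), (base,)))
            for positions, bases in candidates:
                ra, rb = list(fa), list(fb)
                for j, base in zip(positions, bases):
                    ra[j] = rb[j] = base
                ra, rb = "".join(ra), "".join(rb)
                hit_a = _overlapping_site_naive(ra, enzyme, snp)
                hit_b = _overlapping_site_naive(rb, enzyme, snp)
                if hit_a != hit_b:
                    out.add((enzyme.name, ra[start:end + 1], start))
    return out


# --------------------------------------------------------------------------
# segregation-test null calibration

def null_calibration(
    n_reps: int = 10_000,
    n_plants: int = 89,
    alpha: float = 0.05,
    seed: int = 3,
) -> dict[str, float]:
    """Rejection rate of the unpooled 1:2:1 chi-square test (df = 2) under
    the null, over multinomial draws of ``n_plants`` F2 plants."""
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_plants, [0.25, 0.5, 0.25], size=n_reps)
    expected = n_plants * np.array([0.25, 0.5, 0.25])
    chi2 = (((draws - expected) ** 2) / expected).sum(axis=1)
    pvals = stats.chi2.sf(chi2, df=2)
    return {"n_reps": n_reps, "alpha": alpha,
            "rejection_rate": float((pvals < alpha).mean())}
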