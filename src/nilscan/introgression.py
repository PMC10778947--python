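"""Donor-introgression detection in near-isogenic lines.

An introgression SNP is a matrix locus at which the NIL is homozygous with
adequate depth, carries the donor parent's allele (non-polymorphic to the
donor) and is homozygous-polymorphic to the recurrent parent.  Regions are
called from 1 Mb-window SNP densities: windows at or above a count
threshold are seeded, runs of qualifying windows (bridging at most
``merge_gap_windows`` empty ones) are merged, and region boundaries are
reported at the outermost supporting SNPs rather than window edges.
Regions of two NILs can be intersected (shared introgressions, with a
between-NIL polymorphism check inside) or subtracted (NIL-specific
introgressions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import Interval, IntervalTree

from .snp_matrix import SnpMatrix, FilterConfig, HOM_ALT, REF_LIKE
from .compare import compare_lines, window_density, NON_POLYMORPHIC, HOM_POLY


@dataclass
class RegionCallConfig:
    """Window size, seeding threshold and gap bridging for region calling.

    The seed threshold of 10 SNPs per 1 Mb window sits far below a true
    introgression window (parental divergence of 4e-4/bp implies ~400
    homozygous donor SNPs per Mb) and far above the miscall background
    (single spurious homozygous calls); it is configurable for divergence
    levels where that separation does not hold.  ``strict_gt3`` applies
    the stricter depth > 3 reading instead of depth >= 3.
    """

    window_bp: int = 1_000_000
    min_snps_per_window: int = 10
    merge_gap_windows: int = 1
    min_depth: int = 3
    strict_gt3: bool = False

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.min_depth < 0 or self.merge_gap_windows < 0:
            raise ValueError("region-call parameters must be positive")
        if self.min_snps_per_window is not None and self.min_snps_per_window < 1:
            raise ValueError("min_snps_per_window must be >= 1")


@dataclass(frozen=True)
class IntrogressionRegion:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    snp_count: int
    nil_id: str
    donor_id: str
    category: str = "nil_specific"  # or "shared"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")
        if self.snp_count < 1:
            raise ValueError("a region needs at least one supporting SNP")


def detect_introgression_snps(
    matrix: SnpMatrix,
    nil: str,
    donor: str,
    recurrent: str,
    config: RegionCallConfig | None = None,
) -> pd.DataFrame:
    """Loci in ``matrix`` showing the donor's homozygous allele in the NIL.

    Returns the supporting loci (chromosome, position, ref, genotype).  The
    result is a subset of the homozygous-polymorphic loci between recurrent
    and NIL, intersected with the non-polymorphic loci between donor and
    NIL; loci missing in the donor are excluded.
    """
    if len({nil, donor, recurrent}) != 3:
        raise ValueError("nil, donor and recurrent must be three distinct lines")
    config = config or RegionCallConfig()
    fcfg = FilterConfig(min_depth=config.min_depth)

    vs_recurrent = compare_lines(matrix, recurrent, nil, fcfg).classes.to_numpy()
    vs_donor = compare_lines(matrix, donor, nil, fcfg).classes.to_numpy()
    nil_zyg = matrix.zygosity[nil].to_numpy(object)
    nil_hom = np.isin(nil_zyg, (HOM_ALT, REF_LIKE))
    depth_ok = matrix.depth[nil].to_numpy() > config.min_depth \
        if config.strict_gt3 else matrix.depth[nil].to_numpy() >= config.min_depth

    mask = (nil_hom & depth_ok
            & (vs_recurrent == HOM_POLY) & (vs_donor == NON_POLYMORPHIC))
    out = matrix.loci[mask].reset_index(drop=True)
    out["genotype"] = matrix.genotype[nil].to_numpy(object)[mask]
    return out


def call_regions(
    snps: pd.DataFrame,
    config: RegionCallConfig | None = None,
    nil_id: str = "",
    donor_id: str = "",
) -> list[IntrogressionRegion]:
    """Call introgression regions from detected SNPs by windowed density."""
    config = config or RegionCallConfig()
    if snps.empty:
        return []
    density = window_density(snps, config.window_bp)
    threshold = config.min_snps_per_window

    regions: list[IntrogressionRegion] = []
    for chrom, sub in density.groupby("chromosome", sort=True):
        hot = sub.loc[sub["count"] >= threshold, "window_index"].to_numpy()
        if not len(hot):
            continue
        pos = np.sort(snps.loc[snps["chromosome"] == chrom, "position"].to_numpy())
        # merge runs of qualifying windows, bridging small gaps
        run_start = prev = hot[0]
        runs = []
        for w in hot[1:]:
            if w - prev <= config.merge_gap_windows + 1:
                prev = w
            else:
                runs.append((run_start, prev))
                run_start = prev = w
        runs.append((run_start, prev))
        for w0, w1 in runs:
            lo, hi = w0 * config.window_bp + 1, (w1 + 1) * config.window_bp
            inside = pos[(pos >= lo) & (pos <= hi)]
            if not len(inside):
                continue
            regions.append(IntrogressionRegion(
                chromosome=chrom, start=int(inside[0]), end=int(inside[-1]),
                snp_count=int(len(inside)), nil_id=nil_id, donor_id=donor_id))
    return regions


@dataclass
class SharedRegionReport:
    regions: list[IntrogressionRegion]
    #: per shared region: SNPs common to both NILs inside it, and how many
    #: of them are non-polymorphic vs polymorphic between the NILs
    polymorphism: pd.DataFrame


def shared_regions(
    regions_a: list[IntrogressionRegion],
    regions_b: list[IntrogressionRegion],
    matrix: SnpMatrix,
    nil_a: str,
    nil_b: str,
    snps_a: pd.DataFrame | None = None,
    snps_b: pd.DataFrame | None = None,
    config: RegionCallConfig | None = None,
) -> SharedRegionReport:
    """Interval intersections of two NILs' regions, with a between-NIL
    polymorphism check over the introgression SNPs common to both NILs."""
    fcfg = FilterConfig(min_depth=(config or RegionCallConfig()).min_depth)
    between = compare_lines(matrix, nil_a, nil_b, fcfg).classes.to_numpy()
    positions = matrix.loci["position"].to_numpy()
    chroms = matrix.loci["chromosome"].to_numpy()

    common: pd.DataFrame | None = None
    if snps_a is not None and snps_b is not None:
        key_a = set(zip(snps_a["chromosome"], snps_a["position"]))
        key_b = set(zip(snps_b["chromosome"], snps_b["position"]))
        keys = key_a & key_b
        common = pd.DataFrame(sorted(keys), columns=["chromosome", "position"]) \
            if keys else pd.DataFrame(columns=["chromosome", "position"])

    out: list[IntrogressionRegion] = []
    rows = []
    for chrom in sorted({r.chromosome for r in regions_a} & {r.chromosome for r in regions_b}):
        tree = IntervalTree(Interval(r.start, r.end + 1, r)
                            for r in regions_b if r.chromosome == chrom)
        for ra in (r for r in regions_a if r.chromosome == chrom):
            for hit in sorted(tree.overlap(ra.start, ra.end + 1)):
                lo, hi = max(ra.start, hit.begin), min(ra.end, hit.end - 1)
                on_chrom = (chroms == chrom) & (positions >= lo) & (positions <= hi)
                if common is not None:
                    ckeys = set(zip(common["chromosome"], common["position"]))
                    in_common = np.array(
                        [(c, p) in ckeys for c, p in zip(chroms, positions)]) \
                        if ckeys else np.zeros(len(positions), bool)
                    on_chrom = on_chrom & in_common
                n_inside = int(on_chrom.sum())
                non_poly = int((between[on_chrom] == NON_POLYMORPHIC).sum())
                poly = int(np.isin(between[on_chrom], (HOM_POLY, "heterozygous_polymorphic")).sum())
                out.append(IntrogressionRegion(
                    chromosome=chrom, start=lo, end=hi,
                    snp_count=max(n_inside, 1), nil_id=f"{nil_a}&{nil_b}",
                    donor_id=f"{ra.donor_id}&{hit.data.donor_id}",
                    category="shared"))
                rows.append({"chromosome": chrom, "start": lo, "end": hi,
                             "snps_compared": n_inside,
                             "non_polymorphic": non_poly, "polymorphic": poly})
    report = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                         "snps_compared", "non_polymorphic",
                                         "polymorphic"])
    return SharedRegionReport(out, report)


def distinct_regions(
    regions_a: list[IntrogressionRegion],
    regions_b: list[IntrogressionRegion],
    snps_a: pd.DataFrame | None = None,
    snps_b: pd.DataFrame | None = None,
) -> tuple[list[IntrogressionRegion], list[IntrogressionRegion]]:
    """Per-NIL exclusive regions: a \\ b and b \\ a, with supporting-SNP
    counts recomputed on the remainder intervals."""
    return (_subtract(regions_a, regions_b, snps_a),
            _subtract(regions_b, regions_a, snps_b))


def _subtract(keep: list[IntrogressionRegion], remove: list[IntrogressionRegion],
              snps: pd.DataFrame | None) -> list[IntrogressionRegion]:
    out: list[IntrogressionRegion] = []
    by_chrom: dict[str, IntervalTree] = {}
    for r in remove:
        by_chrom.setdefault(r.chromosome, IntervalTree()).add(
            Interval(r.start, r.end + 1))
    for r in keep:
        tree = IntervalTree([Interval(r.start, r.end + 1)])
        for other in by_chrom.get(r.chromosome, IntervalTree()):
            tree.chop(other.begin, other.end)
        for iv in sorted(tree):
            start, end = iv.begin, iv.end - 1
            if snps is not None:
                pos = snps.loc[snps["chromosome"] == r.chromosome, "position"].to_numpy()
                count = int(((pos >= start) & (pos <= end)).sum())
                if count == 0:
                    continue
            else:
                count = max(1, round(r.snp_count * (end - start + 1) / (r.end - r.start + 1)))
            out.append(replace(r, start=start, end=end, snp_count=count,
                               category="nil_specific"))
    return out
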