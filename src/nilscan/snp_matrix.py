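"""Post-call SNP filtering, zygosity classification, consolidated matrix.

Zygosity is classified from the allele read rate, the fraction of reads at
a locus supporting the majority non-reference allele:

* ``homozygous_alt``  -- read rate >= 90 %
* ``heterozygous``    -- 40 % <= read rate <= 60 %
* ``other``           -- 20 % <= read rate < 90 % and neither of the above
  (the residual "could not be classified" class)
* ``reference_like``  -- read rate < 20 %
* ``missing``         -- depth outside [min_depth, max_depth], or no call

The published rate ranges overlap (40-60 % is inside 20-90 %); precedence
homozygous > heterozygous > other makes ``other`` the residual class.

The consolidated matrix is the union of post-filter non-reference loci over
all lines; a line without a call at a union locus is filled in from its
consensus (reference-agreeing, ``consensus_fill``) when its depth there is
adequate, otherwise ``missing``.  Loci at which every line is
reference-like after fill-in were miscalls and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"

HOM_ALT = "homozygous_alt"
HET = "heterozygous"
OTHER = "other"
REF_LIKE = "reference_like"
MISSING = "missing"
ZYGOSITY_CLASSES = (HOM_ALT, HET, OTHER, REF_LIKE, MISSING)

DIRECT = "direct_call"
CONSENSUS = "consensus_fill"
FILL_MISSING = "missing"


@dataclass
class FilterConfig:
    """Post-call filter thresholds (defaults as used for the published SNP
    validation: depth in [3, 257], 30 bp gap exclusion and dense-SNP window,
    SNP quality 30, gap quality 15)."""

    min_depth: int = 3
    max_depth: int = 257
    gap_exclusion_bp: int = 30
    dense_window_bp: int = 30
    min_snp_quality: float = 30.0
    min_gap_quality: float = 15.0
    min_indel_score_near_snp: float = 30.0

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if min(self.min_depth, self.max_depth, self.gap_exclusion_bp,
               self.dense_window_bp) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class SnpCall:
    """One classified locus in one line."""

    chromosome: str
    position: int
    ref: str
    allele_counts: Mapping[str, int]
    depth: int
    zygosity: str
    genotype: str | None  # "A/G"-style, alphabetical
    ambiguous: bool = False


# --------------------------------------------------------------------------
# zygosity classification

def _classify_arrays(counts: np.ndarray, ref_idx: np.ndarray, depth: np.ndarray,
                     config: FilterConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector core: (zygosity, genotype, ambiguous) for an (n, 4) count
    matrix, reference-base indices and total depths."""
    n = len(depth)
    rows = np.arange(n)
    nonref = counts.copy().astype(float)
    nonref[rows, ref_idx] = -1.0
    alt_idx = nonref.argmax(axis=1)
    alt_count = counts[rows, alt_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)

    depth_ok = (depth >= config.min_depth) & (depth <= config.max_depth) & (depth > 0)
    zyg = np.select(
        [~depth_ok, rate >= 0.9, (rate >= 0.4) & (rate <= 0.6), rate >= 0.2],
        [MISSING, HOM_ALT, HET, OTHER],
        default=REF_LIKE,
    )

    # genotype: hom -> alt/alt; het -> two highest-count alleles; ref -> ref/ref
    order = np.argsort(-counts, axis=1, kind="stable")
    top1, top2, top3 = order[:, 0], order[:, 1], order[:, 2]
    third_count = counts[rows, top3]
    ambiguous = depth_ok & (third_count > 0.2 * depth)

    genotype = np.empty(n, dtype=object)
    for i in range(n):
        z = zyg[i]
        if z == HOM_ALT:
            a = BASES[alt_idx[i]]
            genotype[i] = f"{a}/{a}"
        elif z == HET:
            pair = sorted(BASES[top1[i]] + BASES[top2[i]])
            genotype[i] = f"{pair[0]}/{pair[1]}"
        elif z == REF_LIKE:
            r = BASES[ref_idx[i]]
            genotype[i] = f"{r}/{r}"
        elif z == OTHER:
            pair = sorted((BASES[ref_idx[i]], BASES[alt_idx[i]]))
            genotype[i] = f"{pair[0]}/{pair[1]}"
        else:
            genotype[i] = None
    return zyg, genotype, ambiguous


def classify_zygosity(
    allele_counts: Mapping[str, int],
    ref: str,
    depth: int | None = None,
    config: FilterConfig | None = None,
) -> SnpCall:
    """Classify one locus from its per-base read counts.

    ``depth`` defaults to the sum of the counts.  Total function: every
    valid (counts, depth) maps to exactly one zygosity class.
    """
    config = config or FilterConfig()
    if any(c < 0 for c in allele_counts.values()):
        raise ValueError("negative allele read count")
    if ref not in BASES:
        raise ValueError(f"invalid reference base {ref!r}")
    counts = np.array([[allele_counts.get(b, 0) for b in BASES]], dtype=np.int64)
    if depth is None:
        depth = int(counts.sum())
    if depth < 0:
        raise ValueError("negative depth")
    zyg, genotype, amb = _classify_arrays(
        counts, np.array([BASES.index(ref)]), np.array([depth]), config)
    return SnpCall("", 0, ref, dict(allele_counts), depth,
                   str(zyg[0]), genotype[0], bool(amb[0]))


def classify_calls(calls: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Classify a call table (columns A/C/G/T, ref, depth) in place-copy,
    adding ``zygosity``, ``genotype`` and ``ambiguous`` columns.  Rows
    flagged ``missing`` (no genotype call emitted) classify as missing."""
    config = config or FilterConfig()
    counts = calls[list(BASES)].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative allele read count")
    ref_idx = calls["ref"].map(BASES.index).to_numpy()
    depth = calls["depth"].to_numpy(dtype=np.int64)
    zyg, genotype, amb = _classify_arrays(counts, ref_idx, depth, config)
    out = calls.copy()
    out["zygosity"], out["genotype"], out["ambiguous"] = zyg, genotype, amb
    nonref = counts.copy()
    nonref[np.arange(len(out)), ref_idx] = 0
    out["alt_count"] = nonref.sum(axis=1)
    if "missing" in out.columns:
        nocall = out["missing"].to_numpy(bool)
        out.loc[nocall, "zygosity"] = MISSING
        out.loc[nocall, "genotype"] = None
    return out


# --------------------------------------------------------------------------
# positional filters

def apply_call_filters(
    calls: pd.DataFrame,
    config: FilterConfig | None = None,
    gap_positions: Mapping[str, Iterable[int]] | None = None,
) -> pd.DataFrame:
    """Remove calls near gaps/indels, in dense-SNP windows, or below quality.

    * gap rule: a call within ``gap_exclusion_bp`` of a supplied gap/indel
      position is removed (distance <= threshold).
    * dense rule: any ``dense_window_bp``-long window containing more than
      one call removes those calls, i.e. a call whose nearest neighbour is
      closer than the window length is removed.  Idempotent.
    * quality rule: applied when a ``snp_quality`` column is present.

    Input must be position-sorted per chromosome.  Rows flagged ``missing``
    (coverage-only, no call) pass through untouched and do not trigger the
    dense rule.  Dropped-row counts are recorded in ``.attrs['filter_log']``.
    """
    config = config or FilterConfig()
    by = calls.sort_values(["chromosome", "position"], kind="stable")
    if not by.index.equals(calls.index):
        raise ValueError("calls must be sorted by (chromosome, position)")

    log = {"input": len(calls), "quality": 0, "gap": 0, "dense": 0}
    keep = np.ones(len(calls), dtype=bool)
    called = (~calls["missing"].to_numpy(bool) if "missing" in calls.columns
              else np.ones(len(calls), dtype=bool))

    if "snp_quality" in calls.columns:
        bad = called & (calls["snp_quality"].to_numpy(float) < config.min_snp_quality)
        log["quality"] = int(bad.sum())
        keep &= ~bad

    pos = calls["position"].to_numpy(dtype=np.int64)
    chroms = calls["chromosome"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & keep & called)
        p = pos[sel]
        if gap_positions and chrom in gap_positions:
            gaps = np.sort(np.asarray(list(gap_positions[chrom]), dtype=np.int64))
            if len(gaps):
                idx = np.searchsorted(gaps, p)
                left = np.where(idx > 0, p - gaps[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
                right = np.where(idx < len(gaps), gaps[np.minimum(idx, len(gaps) - 1)] - p,
                                 np.iinfo(np.int64).max)
                near = np.minimum(left, right) <= config.gap_exclusion_bp
                log["gap"] += int(near.sum())
                keep[sel[near]] = False
                sel, p = sel[~near], p[~near]
        if len(p) > 1 and config.dense_window_bp > 1:
            gap_prev = np.diff(p, prepend=p[0] - config.dense_window_bp)
            gap_next = np.diff(p, append=p[-1] + config.dense_window_bp)
            dense = (gap_prev < config.dense_window_bp) | (gap_next < config.dense_window_bp)
            log["dense"] += int(dense.sum())
            keep[sel[dense]] = False

    out = calls[keep].reset_index(drop=True)
    log["output"] = len(out)
    out.attrs["filter_log"] = log
    return out


# --------------------------------------------------------------------------
# consolidated matrix

LOCUS_COLS = ["chromosome", "position", "ref"]


@dataclass
class SnpMatrix:
    """Union-of-loci x lines genotype matrix with fill-in provenance.

    All per-cell frames share one index (sorted loci) and one column order
    (lines): ``zygosity`` (class strings), ``genotype`` ("A/G" or None),
    ``depth``, ``fill_source`` ({direct_call, consensus_fill, missing}) and
    ``ambiguous``.
    """

    loci: pd.DataFrame
    lines: list[str]
    zygosity: pd.DataFrame
    genotype: pd.DataFrame
    depth: pd.DataFrame
    fill_source: pd.DataFrame
    ambiguous: pd.DataFrame
    filter_logs: dict[str, dict] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def line_frame(self, line: str) -> pd.DataFrame:
        """All per-cell attributes of one line as a flat frame."""
        if line not in self.lines:
            raise KeyError(f"unknown line {line!r}")
        return pd.DataFrame({
            "chromosome": self.loci["chromosome"].to_numpy(),
            "position": self.loci["position"].to_numpy(),
            "ref": self.loci["ref"].to_numpy(),
            "zygosity": self.zygosity[line].to_numpy(),
            "genotype": self.genotype[line].to_numpy(),
            "depth": self.depth[line].to_numpy(),
            "fill_source": self.fill_source[line].to_numpy(),
            "ambiguous": self.ambiguous[line].to_numpy(),
        })


def build_consolidated_matrix(
    call_sets: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    config: FilterConfig | None = None,
    gap_positions: Mapping[str, Iterable[int]] | None = None,
) -> SnpMatrix:
    """Filter and classify per-line calls, union the non-reference loci and
    fill in absentee lines from their consensus depth.

    A line lacking a call at a union locus becomes ``reference_like`` with
    ``fill_source='consensus_fill'`` when a coverage-only record shows depth
    >= min_depth there, else ``missing``.  Loci reference-like in every line
    after fill-in (miscalls) are dropped.
    """
    config = config or FilterConfig()
    items = list(call_sets.items()) if isinstance(call_sets, Mapping) else list(call_sets)
    ids = [lid for lid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate line ids")
    if len(ids) < 2:
        raise ValueError("need at least two lines")

    filter_logs: dict[str, dict] = {}
    per_line: dict[str, pd.DataFrame] = {}
    for lid, calls in items:
        filtered = apply_call_filters(calls, config, gap_positions)
        filter_logs[lid] = filtered.attrs.get("filter_log", {})
        per_line[lid] = classify_calls(filtered, config).set_index(LOCUS_COLS)

    # raw candidate loci: any line with non-reference read evidence in a
    # retained call (the paper's union of per-sample candidate loci)
    union = sorted(
        {idx for df in per_line.values()
         for idx in df.index[(df["alt_count"] > 0)
                             & ~df["zygosity"].eq(MISSING)]},
    )
    union_index = pd.MultiIndex.from_tuples(union, names=LOCUS_COLS) if union else \
        pd.MultiIndex.from_arrays([[], [], []], names=LOCUS_COLS)

    zyg, gt, dp, fill, amb = {}, {}, {}, {}, {}
    for lid in ids:
        df = per_line[lid].reindex(union_index)
        present = df["depth"].notna().to_numpy()
        nocall = present & df["zygosity"].eq(MISSING).to_numpy()
        depth = df["depth"].fillna(0).to_numpy(dtype=np.int64)
        fillable = nocall & (depth >= config.min_depth) & (depth <= config.max_depth)

        z = df["zygosity"].to_numpy(object)
        g = df["genotype"].to_numpy(object)
        refs = union_index.get_level_values("ref").to_numpy(object) if len(union_index) else np.array([], object)
        z = np.where(~present, MISSING, z)
        z = np.where(fillable, REF_LIKE, z)
        ref_gt = np.array([f"{r}/{r}" for r in refs], dtype=object)
        g = np.where(fillable, ref_gt, np.where(~present, None, g))
        src = np.where(fillable, CONSENSUS,
                       np.where(present & ~nocall, DIRECT, FILL_MISSING))
        zyg[lid], gt[lid], dp[lid], fill[lid] = z, g, depth, src
        amb[lid] = df["ambiguous"].eq(True).to_numpy(bool)

    loci = pd.DataFrame(
        {c: union_index.get_level_values(c) for c in LOCUS_COLS})
    mat = SnpMatrix(
        loci=loci, lines=list(ids),
        zygosity=pd.DataFrame(zyg, columns=ids),
        genotype=pd.DataFrame(gt, columns=ids),
        depth=pd.DataFrame(dp, columns=ids, dtype=np.int64),
        fill_source=pd.DataFrame(fill, columns=ids),
        ambiguous=pd.DataFrame(amb, columns=ids),
        filter_logs=filter_logs,
    )
    # miscall drop: loci reference-like (or unresolvable) in every line, with
    # no line retaining a non-reference call
    informative = mat.zygosity.isin([HOM_ALT, HET, OTHER]).any(axis=1).to_numpy()
    return _subset(mat, informative)


def _subset(mat: SnpMatrix, mask: np.ndarray) -> SnpMatrix:
    return SnpMatrix(
        loci=mat.loci[mask].reset_index(drop=True),
        lines=mat.lines,
        zygosity=mat.zygosity[mask].reset_index(drop=True),
        genotype=mat.genotype[mask].reset_index(drop=True),
        depth=mat.depth[mask].reset_index(drop=True),
        fill_source=mat.fill_source[mask].reset_index(drop=True),
        ambiguous=mat.ambiguous[mask].reset_index(drop=True),
        filter_logs=mat.filter_logs,
    )
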