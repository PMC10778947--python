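"""Six-way pairwise polymorphism taxonomy and windowed SNP density.

Every matrix locus compared between two lines falls in exactly one class:

* ``insufficient_depth``      -- either cell below the depth threshold
* ``unknown``                 -- either cell missing (no genotype)
* ``ambiguous``               -- either cell unclassifiable ("Etc." type),
                                 or a heterozygote/heterozygote contrast
* ``non_polymorphic``         -- identical genotypes
* ``homozygous_polymorphic``  -- both homozygous, different alleles
* ``heterozygous_polymorphic``-- one homozygous, one heterozygous, different

Precedence runs data-quality first (depth, then missing, then ambiguous) so
quality failures are never reported as biology.  Chromosome-window counts
use 1 Mb bins anchored at position 1 (1-based inclusive coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_matrix import SnpMatrix, FilterConfig, HOM_ALT, HET, OTHER, REF_LIKE, MISSING

INSUFFICIENT_DEPTH = "insufficient_depth"
UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"
NON_POLYMORPHIC = "non_polymorphic"
HOM_POLY = "homozygous_polymorphic"
HET_POLY = "heterozygous_polymorphic"

COMPARISON_CLASSES = (HOM_POLY, HET_POLY, NON_POLYMORPHIC,
                      INSUFFICIENT_DEPTH, UNKNOWN, AMBIGUOUS)


class ComparisonClass(str):
    """Comparison classes are plain strings; this alias names the domain."""


@dataclass(frozen=True)
class MatrixCell:
    """The per-line attributes of one locus needed for a comparison."""

    zygosity: str
    genotype: str | None
    depth: int
    ambiguous: bool = False


def compare_locus(cell_a: MatrixCell, cell_b: MatrixCell,
                  min_depth: int = 3) -> str:
    """Classify one locus between two lines (see module docstring for the
    precedence order)."""
    z = _compare_arrays(
        np.array([cell_a.zygosity], object), np.array([cell_b.zygosity], object),
        np.array([cell_a.genotype], object), np.array([cell_b.genotype], object),
        np.array([cell_a.depth]), np.array([cell_b.depth]),
        np.array([cell_a.ambiguous]), np.array([cell_b.ambiguous]),
        min_depth)
    return str(z[0])


def _compare_arrays(za, zb, ga, gb, da, db, aa, ab, min_depth: int) -> np.ndarray:
    hom = (HOM_ALT, REF_LIKE)
    a_hom, b_hom = np.isin(za, hom), np.isin(zb, hom)
    a_het, b_het = za == HET, zb == HET
    same = (ga == gb) & (ga != None)  # noqa: E711  (elementwise vs None)
    depth_bad = (da < min_depth) | (db < min_depth)
    missing = (za == MISSING) | (zb == MISSING)
    fuzzy = (za == OTHER) | (zb == OTHER) | aa | ab
    return np.select(
        [depth_bad, missing, fuzzy, same,
         a_hom & b_hom, (a_hom & b_het) | (a_het & b_hom)],
        [INSUFFICIENT_DEPTH, UNKNOWN, AMBIGUOUS, NON_POLYMORPHIC,
         HOM_POLY, HET_POLY],
        default=AMBIGUOUS,  # het vs het with differing allele pairs
    )


@dataclass
class CompareResult:
    line_a: str
    line_b: str
    counts: dict[str, int]
    classes: pd.Series  # per-locus class, aligned with the matrix loci
    loci: pd.DataFrame

    def loci_of(self, cls: str) -> pd.DataFrame:
        return self.loci[(self.classes == cls).to_numpy()].reset_index(drop=True)


def compare_lines(matrix: SnpMatrix, line_a: str, line_b: str,
                  config: FilterConfig | None = None) -> CompareResult:
    """Classify every matrix locus between two lines; counts sum to the
    matrix locus count and are symmetric in (a, b)."""
    for line in (line_a, line_b):
        if line not in matrix.lines:
            raise KeyError(f"unknown line {line!r}")
    min_depth = (config or FilterConfig()).min_depth
    classes = _compare_arrays(
        matrix.zygosity[line_a].to_numpy(object), matrix.zygosity[line_b].to_numpy(object),
        matrix.genotype[line_a].to_numpy(object), matrix.genotype[line_b].to_numpy(object),
        matrix.depth[line_a].to_numpy(), matrix.depth[line_b].to_numpy(),
        matrix.ambiguous[line_a].to_numpy(bool), matrix.ambiguous[line_b].to_numpy(bool),
        min_depth)
    series = pd.Series(classes, name="comparison_class")
    counts = {cls: int((classes == cls).sum()) for cls in COMPARISON_CLASSES}
    return CompareResult(line_a, line_b, counts, series, matrix.loci)


def window_density(loci: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Per-chromosome SNP counts in fixed windows.

    Window index = floor((position - 1) / window_bp), so positions 1 and
    window_bp share window 0.  Returns chromosome, window_index, count with
    counts conserved (empty windows inside the spanned range included as 0).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if loci.empty:
        return pd.DataFrame(columns=["chromosome", "window_index", "count"])
    df = loci.copy()
    df["window_index"] = (df["position"].astype(np.int64) - 1) // window_bp
    rows = []
    for chrom, sub in df.groupby("chromosome", sort=True):
        counts = sub.groupby("window_index").size()
        full = np.arange(0, counts.index.max() + 1)
        counts = counts.reindex(full, fill_value=0)
        rows.append(pd.DataFrame({"chromosome": chrom,
                                  "window_index": counts.index,
                                  "count": counts.to_numpy()}))
    return pd.concat(rows, ignore_index=True)
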