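"""Mendelian segregation tests, marker co-segregation and sequencing
summary arithmetic.

For an incompletely dominant single gene the F2 phenotypes segregate
1:2:1; published practice also tests the dominant pooling (class1 +
heterozygote) : class3 against 3:1 with one degree of freedom, which is
the mode that reproduces the published statistic for the flesh-colour
counts (22, 47, 20) -> chi-square 0.30, p 0.58.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: genome size used for the published coverage arithmetic (the genome
#: assembly itself is cited elsewhere at 424 Mb; 350 Mb is the estimate
#: the coverage table divides by)
COVERAGE_GENOME_SIZE = 350_000_000
ASSEMBLY_GENOME_SIZE = 424_000_000


@dataclass
class SegregationTest:
    observed: dict[str, int]
    pooled_observed: dict[str, int]
    expected: dict[str, float]
    ratio: tuple[float, ...]
    pooling: str
    chi_square: float
    df: int
    p_value: float
    yates: bool = False


def chisq_segregation(
    observed: Mapping[str, int] | Sequence[int],
    ratio: Sequence[float] = (1, 2, 1),
    pooling: str = "none",
    yates: bool = False,
) -> SegregationTest:
    """Goodness of fit of observed class counts to a Mendelian ratio.

    ``pooling='none'`` tests the classes as given (df = k - 1);
    ``pooling='dominant'`` pools all classes but the last into one
    dominant-phenotype class and tests against 3:1 (df = 1).  ``yates``
    applies the continuity correction (published value is reproduced
    without it).
    """
    if isinstance(observed, Mapping):
        labels, counts = list(observed), [int(v) for v in observed.values()]
    else:
        counts = [int(v) for v in observed]
        labels = [f"class{i + 1}" for i in range(len(counts))]
    if any(c < 0 for c in counts):
        raise ValueError("observed counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("no observations")

    if pooling == "dominant":
        pooled = {"dominant": sum(counts[:-1]), "recessive": counts[-1]}
        test_ratio = (3.0, 1.0)
    elif pooling == "none":
        pooled = dict(zip(labels, counts))
        test_ratio = tuple(float(r) for r in ratio)
    else:
        raise ValueError(f"unknown pooling rule {pooling!r}")
    if len(pooled) < 2:
        raise ValueError("need at least two classes after pooling")
    if len(test_ratio) != len(pooled):
        raise ValueError("ratio length must match the number of test classes")

    obs = np.array(list(pooled.values()), dtype=float)
    exp = total * np.array(test_ratio) / sum(test_ratio)
    if (exp == 0).any():
        raise ValueError("expected count of zero in some class")
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / exp).sum())
    df = len(pooled) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationTest(
        observed=dict(zip(labels, counts)), pooled_observed=pooled,
        expected=dict(zip(pooled, exp)), ratio=test_ratio, pooling=pooling,
        chi_square=chi2, df=df, p_value=p, yates=yates)


# --------------------------------------------------------------------------
# co-segregation

@dataclass
class CosegregationResult:
    contingency: pd.DataFrame  # genotype x phenotype counts
    concordance: float
    n_classified: int
    n_concordant: int
    n_excluded_phenotype: int
    #: plants whose genotype has no phenotype mapping (e.g. heterozygotes),
    #: reported separately and not counted as discordant
    unmapped: pd.DataFrame = field(default_factory=pd.DataFrame)


def cosegregation(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    genotype_to_phenotype: Mapping[str, str],
    exclude_phenotypes: Iterable[str] = (),
) -> CosegregationResult:
    """Concordance between marker genotypes and phenotype classes.

    Inputs are (plant_id, genotype) and (plant_id, phenotype) tables;
    plants with phenotypes in ``exclude_phenotypes`` (e.g. intermediates
    too ambiguous to score) are dropped with a logged count.  Genotypes
    absent from the mapping are tolerated only if declared by mapping them
    to None; any other code raises.
    """
    merged = genotypes.merge(phenotypes, on="plant_id", how="inner")
    excluded = merged["phenotype"].isin(set(exclude_phenotypes))
    kept = merged[~excluded]
    unknown = set(kept["genotype"]) - set(genotype_to_phenotype)
    if unknown:
        raise ValueError(f"unmapped genotype codes: {sorted(unknown)}")

    expect = kept["genotype"].map(genotype_to_phenotype)
    mapped = expect.notna()
    concordant = mapped & (expect == kept["phenotype"])
    table = pd.crosstab(kept["genotype"], kept["phenotype"])
    n_cls = int(mapped.sum())
    return CosegregationResult(
        contingency=table,
        concordance=float(concordant.sum() / n_cls) if n_cls else float("nan"),
        n_classified=n_cls,
        n_concordant=int(concordant.sum()),
        n_excluded_phenotype=int(excluded.sum()),
        unmapped=kept[~mapped].reset_index(drop=True),
    )


# --------------------------------------------------------------------------
# sequencing summary arithmetic

@dataclass
class CoverageSummary:
    per_line: pd.DataFrame
    means: dict[str, float]


def load_read_stats(path: str | Path | None = None) -> pd.DataFrame:
    """Per-read-file resequencing statistics (line, n_reads, trimmed_bases,
    trimmed_over_raw_pct); the shipped table carries the published values."""
    if path is None:
        ref = importlib.resources.files("nilscan.data") / "wgrs_read_stats.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_read_stats(p)
    return pd.read_csv(path, sep="\t", comment="#")


def load_snp_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Per-line SNP-type counts against the reference genome (line,
    total_snps, homozygous, heterozygous, other); the shipped table
    carries the published values."""
    if path is None:
        ref = importlib.resources.files("nilscan.data") / "snp_counts.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_snp_counts(p)
    return pd.read_csv(path, sep="\t", comment="#")


def coverage_summary(
    read_stats: pd.DataFrame,
    genome_size: int = COVERAGE_GENOME_SIZE,
    homozygous_snps: Mapping[str, int] | None = None,
) -> CoverageSummary:
    """Per-line genome coverage and cohort means.

    Coverage = (sum of a line's trimmed read-file totals) / genome size,
    rounded to 2 decimals.  Cohort means: reads per line, trimmed/raw
    percentage over all read files, and (when supplied) homozygous SNP
    counts per line.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if (read_stats["trimmed_bases"] <= 0).any():
        raise ValueError("trimmed base totals must be positive")
    per_line = (read_stats.groupby("line", sort=False)
                .agg(n_reads=("n_reads", "first"),
                     total_trimmed_bases=("trimmed_bases", "sum"))
                .reset_index())
    per_line["coverage"] = (per_line["total_trimmed_bases"] / genome_size).round(2)
    means = {
        "reads": float(per_line["n_reads"].mean()),
        "trimmed_over_raw_pct": float(read_stats["trimmed_over_raw_pct"].mean()),
        "coverage": float(per_line["coverage"].mean()),
    }
    if homozygous_snps is not None:
        means["homozygous_snps"] = float(np.mean(list(homozygous_snps.values())))
    return CoverageSummary(per_line=per_line, means=means)
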