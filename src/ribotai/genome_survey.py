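"""Genome-scale bottleneck survey, expression classes, and quadrant tests.

The survey scans every sufficiently long ORF for its bottleneck and asks
where, along the transcript, strong bottlenecks sit.  The transcript is cut
into four quadrants of relative location ([0, 0.25), [0.25, 0.5), [0.5, 0.75),
[0.75, 1]); genes whose bottleneck relative strength exceeds a threshold
(default 1.3) form the sample, and a one-sided hypergeometric test asks
whether the sample over- or under-represents a quadrant relative to the whole
surveyed population.  Expression classes take the top and bottom 500 genes by
mRNA level (unrecorded genes ignored), intersected with the length-filtered
survey table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .bottleneck import DEFAULT_WINDOW_N, find_bottleneck
from .codon_model import CodingSequence, CodonWeightTable, ExpressionLevelMap

__all__ = [
    "DEFAULT_MIN_LENGTH",
    "DEFAULT_STRENGTH_THRESHOLD",
    "QUADRANTS",
    "GeneBottleneckTable",
    "EnrichmentResult",
    "survey_genome",
    "quadrant_enrichment",
    "expression_classes",
]

DEFAULT_MIN_LENGTH = 101  # "longer than 100 codons"
DEFAULT_STRENGTH_THRESHOLD = 1.3

#: Half-open quadrant intervals of relative location; the last is closed at 1.
QUADRANTS: dict[str, tuple[float, float, bool]] = {
    "first": (0.0, 0.25, False),
    "second": (0.25, 0.5, False),
    "third": (0.5, 0.75, False),
    "fourth": (0.75, 1.0, True),
}


@dataclass
class GeneBottleneckTable:
    """Per-gene bottleneck parameters for all genes passing the length filter."""

    table: pd.DataFrame  # gene_id, length_l, window_n, location_k, relative_location, strength, relative_strength
    min_length: int
    window_n: int
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided hypergeometric enrichment/depletion of a quadrant.

    Population = all surveyed genes; successes = genes whose bottleneck lies
    in the quadrant; sample = strong-bottleneck genes; ``n_overlap`` of the
    sample fall in the quadrant.  ``p_enrichment`` = P(X >= n_overlap),
    ``p_depletion`` = P(X <= n_overlap), both including the observed point.
    """

    quadrant: str
    population_size: int
    n_success_in_population: int
    sample_size: int
    n_overlap: int
    fraction: float
    p_enrichment: float
    p_depletion: float


def survey_genome(
    orfs: Sequence[CodingSequence],
    weights: CodonWeightTable,
    n: int = DEFAULT_WINDOW_N,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> GeneBottleneckTable:
    """Scan every gene of at least ``min_length`` codons for its bottleneck.

    Shorter genes are skipped and reported in ``skipped`` (a gene of exactly
    100 codons fails the default "longer than 100 codons" filter).
    """
    if not orfs:
        raise ValueError("genome survey requires at least one ORF")
    rows = []
    skipped: list[str] = []
    seen: set[str] = set()
    for orf in orfs:
        if orf.id in seen:
            raise ValueError(f"duplicate gene id {orf.id!r} in ORF set")
        seen.add(orf.id)
        if orf.length_l < min_length:
            skipped.append(orf.id)
            continue
        bn = find_bottleneck(orf, weights, n=n)
        rows.append(
            dict(
                gene_id=orf.id,
                length_l=orf.length_l,
                window_n=n,
                location_k=bn.location_k,
                relative_location=bn.relative_location,
                strength=bn.strength,
                relative_strength=bn.relative_strength,
            )
        )
    columns = [
        "gene_id", "length_l", "window_n", "location_k",
        "relative_location", "strength", "relative_strength",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return GeneBottleneckTable(table=table, min_length=min_length, window_n=n, skipped=skipped)


def _in_quadrant(values: np.ndarray, quadrant: str) -> np.ndarray:
    lo, hi, closed = QUADRANTS[quadrant]
    upper = values <= hi if closed else values < hi
    return (values >= lo) & upper


def _tail_sum(pmf_support: np.ndarray, M: int, n: int, N: int) -> float:
    # direct pmf summation keeps tiny tails accurate
    return float(np.clip(hypergeom.pmf(pmf_support, M, n, N).sum(), 0.0, 1.0))


def hypergeom_tails(M: int, n: int, N: int, k: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) for a hypergeometric(M, n, N) variable."""
    k_min = max(0, n + N - M)
    k_max = min(n, N)
    upper = _tail_sum(np.arange(k, k_max + 1), M, n, N) if k <= k_max else 0.0
    lower = _tail_sum(np.arange(k_min, min(k, k_max) + 1), M, n, N) if k >= k_min else 0.0
    return upper, lower


def quadrant_enrichment(
    table: GeneBottleneckTable,
    strength_threshold: float = DEFAULT_STRENGTH_THRESHOLD,
    quadrant: str = "first",
) -> EnrichmentResult:
    """Test whether strong-bottleneck genes over/under-populate a quadrant.

    The sample is the genes with relative strength strictly above
    ``strength_threshold``; tail probabilities include the observed overlap.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}; expected one of {list(QUADRANTS)}")
    df = table.table
    if df.empty:
        raise ValueError("enrichment test requires a non-empty gene table")
    locations = df["relative_location"].to_numpy()
    strengths = df["relative_strength"].to_numpy()
    in_quad = _in_quadrant(locations, quadrant)
    strong = strengths > strength_threshold
    M = len(df)
    n_success = int(in_quad.sum())
    N = int(strong.sum())
    if N == 0:
        raise ValueError(
            f"no gene exceeds relative strength {strength_threshold}; lower the threshold"
        )
    k = int((in_quad & strong).sum())
    p_enr, p_dep = hypergeom_tails(M, n_success, N, k)
    return EnrichmentResult(
        quadrant=quadrant,
        population_size=M,
        n_success_in_population=n_success,
        sample_size=N,
        n_overlap=k,
        fraction=k / N,
        p_enrichment=p_enr,
        p_depletion=p_dep,
    )


def expression_classes(
    expr: ExpressionLevelMap,
    table: GeneBottleneckTable,
    top: int = 500,
    bottom: int = 500,
) -> tuple[list[str], list[str]]:
    """Highly/lowly expressed gene lists intersected with the survey table.

    Genes with no recorded mRNA level are ignored.  Ranking ties are resolved
    deterministically by (level descending, gene id ascending).  Returns the
    gene ids, in rank order, that also passed the survey's length filter.
    """
    if not expr.levels:
        raise ValueError("expression map is empty")
    recorded = sorted(expr.levels.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(recorded) < top + bottom:
        raise ValueError(
            f"only {len(recorded)} recorded genes; cannot take top {top} and bottom {bottom}"
        )
    in_table = set(table.table["gene_id"])
    high = [g for g, _ in recorded[:top] if g in in_table]
    low = [g for g, _ in recorded[-bottom:] if g in in_table]
    return high, low


def location_histogram(
    table: GeneBottleneckTable, n_bins: int = 20
) -> pd.DataFrame:
    """Histogram of relative bottleneck locations (default 20 bins on (0, 1])."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(table.table["relative_location"].to_numpy(), bins=edges)
    total = max(counts.sum(), 1)
    return pd.DataFrame(
        dict(bin_lo=edges[:-1], bin_hi=edges[1:], count=counts, fraction=counts / total)
    )
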