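"""Gene-level layer: genes per window, label-permutation enrichment test,
region annotation, and cross-group shared-candidate partitions.

The enrichment test asks whether a gene class (e.g. NLR-like disease
resistance genes) is denser in high-diversity windows than elsewhere. Each
smoothed window is represented as the interval ``center +/- sigma``; the
observed statistic is ``mean genes/window (high) - mean genes/window
(other)``. The window labels are then permuted without replacement
(preserving class sizes), giving a null distribution of differences, and
``p = (1 + #{null >= observed}) / (n_perm + 1)``. When the number of
distinct labelings is small the null is enumerated exhaustively instead
(the p-value is then an exact proportion over all labelings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneAnnotation
from .scan import windows_to_intervals

EXHAUSTIVE_LIMIT = 100_000

__all__ = [
    "EnrichmentResult",
    "gene_counts_per_window",
    "enrichment_permutation_test",
    "annotate_regions",
    "shared_candidates",
]


@dataclass
class EnrichmentResult:
    gene_class: str
    n_high_windows: int
    n_other_windows: int
    mean_count_high: float
    mean_count_other: float
    observed_diff: float
    n_permutations: int
    p_value: float
    null_mean: float
    null_sd: float
    null_max: float
    exhaustive: bool = False


def _gene_tree(
    genes: Sequence[GeneAnnotation], gene_class: Optional[str] = None
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if gene_class is not None and g.gene_class != gene_class:
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    return trees


def gene_counts_per_window(
    windows: pd.DataFrame,
    sigma: float,
    genes: Sequence[GeneAnnotation],
    gene_class: Optional[str] = None,
) -> np.ndarray:
    """Count class-member genes intersecting each window's +/- sigma interval.

    A gene spanning several window intervals is counted in each of them.
    """
    trees = _gene_tree(genes, gene_class)
    intervals = windows_to_intervals(windows, sigma)
    counts = np.zeros(len(intervals), dtype=int)
    for i, row in enumerate(intervals.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is not None:
            counts[i] = len(tree.overlap(row.start, row.end))
    return counts


def enrichment_permutation_test(
    counts: np.ndarray,
    is_high: np.ndarray,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    gene_class: str = "candidate",
    method: str = "auto",
) -> EnrichmentResult:
    """One-sided label-permutation test for class enrichment in high windows.

    ``method``: "auto" enumerates all labelings exhaustively when their
    number is <= 100,000 and falls back to Monte Carlo otherwise; "monte_carlo"
    and "exhaustive" force either route.
    """
    counts = np.asarray(counts, dtype=float)
    is_high = np.asarray(is_high, dtype=bool)
    if counts.shape != is_high.shape:
        raise ValueError("counts and labels must align")
    n = len(counts)
    k = int(is_high.sum())
    if k == 0 or k == n:
        raise ValueError("both label classes must be nonempty")
    obs = float(counts[is_high].mean() - counts[~is_high].mean())
    total_sum = counts.sum()

    def diff_from_high_sum(high_sum: np.ndarray) -> np.ndarray:
        return high_sum / k - (total_sum - high_sum) / (n - k)

    n_labelings = math.comb(n, k)
    exhaustive = method == "exhaustive" or (
        method == "auto" and n_labelings <= EXHAUSTIVE_LIMIT
    )
    tol = 1e-12 * max(1.0, abs(obs))
    if exhaustive:
        high_sums = np.fromiter(
            (counts[list(c)].sum() for c in combinations(range(n), k)),
            dtype=float,
            count=n_labelings,
        )
        null = diff_from_high_sum(high_sums)
        p = float(np.count_nonzero(null >= obs - tol)) / n_labelings
        n_perm = n_labelings
    else:
        rng = np.random.default_rng(seed)
        # permute labels by ranking uniform noise; rows are random subsets of size k
        u = rng.random((n_permutations, n))
        sel = np.argpartition(u, k - 1, axis=1)[:, :k]
        null = diff_from_high_sum(counts[sel].sum(axis=1))
        p = (1 + int(np.count_nonzero(null >= obs - tol))) / (n_permutations + 1)
        n_perm = n_permutations
    return EnrichmentResult(
        gene_class=gene_class,
        n_high_windows=k,
        n_other_windows=n - k,
        mean_count_high=float(counts[is_high].mean()),
        mean_count_other=float(counts[~is_high].mean()),
        observed_diff=obs,
        n_permutations=n_perm,
        p_value=float(p),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        null_max=float(null.max()),
        exhaustive=exhaustive,
    )


def annotate_regions(
    regions: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    candidate_class: str = "candidate",
    genome_length: Optional[float] = None,
) -> tuple[pd.DataFrame, dict]:
    """Gene inventory per merged region plus totals.

    Totals include the summed region length (Mbp), total genes, class-member
    counts and the class density per Mbp inside regions vs genome-wide.
    """
    trees = _gene_tree(genes)
    rows = []
    total_genes = 0
    total_candidates = 0
    for row in regions.itertuples(index=False):
        tree = trees.get(row.chrom, IntervalTree())
        hits = sorted(tree.overlap(row.start, row.end), key=lambda iv: iv.begin)
        gene_ids = [iv.data for iv in hits]
        by_id = {g.gene_id: g for g in genes}
        cand = [gid for gid in gene_ids if by_id[gid].gene_class == candidate_class]
        total_genes += len(gene_ids)
        total_candidates += len(cand)
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n_genes": len(gene_ids),
                "n_candidate": len(cand),
                "candidate_ids": cand,
            }
        )
    per_region = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_genes", "n_candidate", "candidate_ids"]
    )
    span = float((regions["end"] - regions["start"]).sum()) if len(regions) else 0.0
    n_class_total = sum(g.gene_class == candidate_class for g in genes)
    if genome_length is None:
        by_chrom: dict[str, int] = {}
        for g in genes:
            by_chrom[g.chrom] = max(by_chrom.get(g.chrom, 0), g.end)
        genome_length = float(sum(by_chrom.values()))
    span_mbp = span / 1e6
    genome_mbp = genome_length / 1e6 if genome_length else float("nan")
    totals = {
        "n_regions": len(regions),
        "total_span_bp": span,
        "total_span_mbp": span_mbp,
        "n_genes": total_genes,
        "n_candidate": total_candidates,
        "candidate_density_in_regions_per_mbp": (
            total_candidates / span_mbp if span_mbp > 0 else 0.0
        ),
        "candidate_density_genome_per_mbp": (
            n_class_total / genome_mbp if genome_mbp > 0 else float("nan")
        ),
    }
    return per_region, totals


def shared_candidates(candidate_sets: Mapping[str, set]) -> dict[str, list[str]]:
    """Exact Venn partition of per-group candidate gene-id sets.

    Cell keys are '&'-joined sorted group names; each gene appears in exactly
    one cell (the set of groups it belongs to), and the cells' union equals
    the union of the inputs.
    """
    groups = sorted(candidate_sets)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    partition: dict[str, list[str]] = {}
    for r in range(1, len(groups) + 1):
        for combo in combinations(groups, r):
            inside = set.intersection(*(set(candidate_sets[g]) for g in combo))
            outside = set.union(
                set(), *(set(candidate_sets[g]) for g in groups if g not in combo)
            )
            partition["&".join(combo)] = sorted(inside - outside)
    return partition
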