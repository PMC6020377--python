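"""Per-locus and per-window population-genetic estimators.

Haplotype-level statistics treat each 92-bp RAD haplotype as one allele of a
multi-allelic locus:

* nucleotide diversity ``pi`` — mean pairwise nucleotide differences over all
  unordered sequence pairs, divided by locus length;
* gene diversity ``H_e`` — ``(2n/(2n-1)) * (1 - sum p_k^2)`` over haplotype
  frequencies (unbiased correction configurable);
* observed heterozygosity ``H_o`` — fraction of genotyped individuals whose
  two haplotypes differ;
* AMOVA F_ST on allelic data — among/within population variance components
  (equivalent to the Weir–Cockerham theta for allelic data);
* Tajima's D from segregating sites and mean pairwise differences;
* isolation-by-distance: regression of F_ST/(1-F_ST) on great-circle
  distance with a matrix-permutation test.

Undefined statistics (too few sequences, fewer than two populations with
data, S = 0, ...) are returned as ``nan`` rather than raised.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypeMatrix

Call = Optional[tuple[str, str]]

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "TajimaConstants",
    "PairwiseFstMatrix",
    "IbdResult",
    "filter_loci_by_presence",
    "locus_pi",
    "locus_gene_diversity",
    "locus_observed_het",
    "individual_heterozygosity",
    "locus_amova_fst",
    "amova_components",
    "pairwise_population_fst",
    "tajima_constants",
    "tajima_d",
    "locus_stats_table",
    "group_summary",
    "haversine_km",
    "ibd_regression",
]


def _genotyped(calls: Sequence[Call]) -> list[tuple[str, str]]:
    return [c for c in calls if c is not None]


def _sequences(calls: Sequence[Call]) -> list[str]:
    seqs: list[str] = []
    for c in calls:
        if c is not None:
            seqs.extend(c)
    return seqs


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_loci_by_presence(
    matrix: HaplotypeMatrix,
    individuals: Optional[Sequence[str]] = None,
    max_missing_frac: float = 0.5,
):
    """Indices of loci genotyped in >= ceil((1-f) * n_group) group members.

    Returns ``(locus_indices, report)`` where report carries retained/dropped
    counts and the presence threshold used.
    """
    if individuals is None:
        individuals = list(matrix.samples["individual"])
    if len(individuals) == 0:
        raise ValueError("group of individuals must be nonempty")
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    cols = matrix.sample_indices(individuals)
    present = matrix.genotyped_mask()[:, cols].sum(axis=1)
    n = len(individuals)
    min_present = math.ceil((1.0 - max_missing_frac) * n - 1e-9)
    keep = np.flatnonzero(present >= min_present)
    report = {
        "n_loci": matrix.n_loci,
        "retained": int(keep.size),
        "dropped": int(matrix.n_loci - keep.size),
        "min_present": int(min_present),
        "group_size": n,
    }
    return keep, report


# ---------------------------------------------------------------------------
# per-locus diversity statistics
# ---------------------------------------------------------------------------


def locus_pi(calls: Sequence[Call], length: Optional[int] = None) -> float:
    """Per-bp nucleotide diversity over all unordered pairs of sequences."""
    seqs = _sequences(calls)
    total = len(seqs)
    if total < 2:
        return float("nan")
    if length is None:
        length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("haplotype length inconsistent with locus length")
    counts = Counter(seqs)
    uniq = list(counts)
    if len(uniq) == 1:
        return 0.0
    diff_sum = 0.0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            ham = sum(a != b for a, b in zip(uniq[i], uniq[j]))
            diff_sum += counts[uniq[i]] * counts[uniq[j]] * ham
    n_pairs = total * (total - 1) / 2
    return diff_sum / n_pairs / length


def locus_gene_diversity(calls: Sequence[Call], unbiased: bool = True) -> float:
    """Haplotype gene diversity H_e = (2n/(2n-1)) (1 - sum p_k^2)."""
    seqs = _sequences(calls)
    total = len(seqs)
    if total == 0:
        return float("nan")
    counts = np.array(list(Counter(seqs).values()), dtype=float)
    p = counts / total
    h = 1.0 - float(np.sum(p * p))
    if unbiased and total > 1:
        h *= total / (total - 1)
    return h


def locus_observed_het(calls: Sequence[Call]) -> float:
    """Fraction of genotyped individuals carrying two distinct haplotypes."""
    geno = _genotyped(calls)
    if not geno:
        return float("nan")
    return sum(a != b for a, b in geno) / len(geno)


def individual_heterozygosity(
    matrix: HaplotypeMatrix,
    individual: str,
    locus_indices: Optional[Sequence[int]] = None,
) -> float:
    """Heterozygous loci / genotyped loci for one individual.

    The locus set may (and for the per-individual summary should) include
    monomorphic loci.
    """
    (col,) = matrix.sample_indices([individual])
    calls = matrix.calls[:, col]
    if locus_indices is not None:
        calls = calls[np.asarray(locus_indices, dtype=int)]
    geno = [c for c in calls if c is not None]
    if not geno:
        return float("nan")
    return sum(a != b for a, b in geno) / len(geno)


# ---------------------------------------------------------------------------
# AMOVA / Weir-Cockerham F_ST on allelic data
# ---------------------------------------------------------------------------


def amova_components(counts: np.ndarray) -> tuple[float, float]:
    """Variance components of the allelic AMOVA from an allele-count table.

    Parameters
    ----------
    counts : (n_populations, n_alleles) integer array of gene-copy counts.

    Returns
    -------
    (sigma_among, sigma_within) summed over alleles; F_ST is their ratio to
    the total. Populations with zero copies are dropped. Returns (nan, nan)
    when fewer than two populations have data or degrees of freedom vanish.
    """
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    counts = counts[n_i > 0]
    n_i = n_i[n_i > 0]
    r = len(n_i)
    if r < 2:
        return float("nan"), float("nan")
    N = n_i.sum()
    if N - r <= 0:
        return float("nan"), float("nan")
    p = counts / n_i[:, None]
    pbar = counts.sum(axis=0) / N
    ssa = float(np.sum(n_i[:, None] * (p - pbar[None, :]) ** 2))
    ssw = float(np.sum(n_i[:, None] * p * (1.0 - p)))
    msa = ssa / (r - 1)
    msw = ssw / (N - r)
    n_c = (N - float(np.sum(n_i**2)) / N) / (r - 1)
    sigma_among = (msa - msw) / n_c
    return sigma_among, msw


def _allele_counts(calls_by_pop: Mapping[str, Sequence[Call]]) -> np.ndarray:
    alleles: dict[str, int] = {}
    rows = []
    for pop, calls in calls_by_pop.items():
        row: Counter = Counter(_sequences(calls))
        rows.append(row)
        for a in row:
            alleles.setdefault(a, len(alleles))
    table = np.zeros((len(rows), len(alleles)), dtype=float)
    for i, row in enumerate(rows):
        for a, c in row.items():
            table[i, alleles[a]] = c
    return table


def locus_amova_fst(calls_by_pop: Mapping[str, Sequence[Call]]) -> float:
    """AMOVA F_ST at one locus, haplotypes treated as unordered alleles.

    May be negative (returned unclipped); nan when undefined (fewer than two
    populations with data, or a monomorphic locus).
    """
    table = _allele_counts(calls_by_pop)
    if table.size == 0 or table.shape[1] < 2:
        return float("nan")
    sigma_a, sigma_w = amova_components(table)
    total = sigma_a + sigma_w
    if not np.isfinite(total) or total == 0:
        return float("nan")
    return sigma_a / total


@dataclass
class PairwiseFstMatrix:
    """Symmetric multi-locus Weir–Cockerham F_ST between populations."""

    populations: list[str]
    fst: pd.DataFrame
    standardized: pd.DataFrame  # F_ST / (1 - F_ST); inf where F_ST == 1


def pairwise_population_fst(
    matrix: HaplotypeMatrix,
    locus_indices: Optional[Sequence[int]] = None,
    populations: Optional[Sequence[str]] = None,
) -> PairwiseFstMatrix:
    """Multi-locus pairwise F_ST: ratio of summed per-locus components."""
    if locus_indices is None:
        locus_indices = np.arange(matrix.n_loci)
    pops_col = matrix.samples["population"].to_numpy()
    if populations is None:
        populations = list(pd.unique(pops_col))
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    cols_by_pop = {p: np.flatnonzero(pops_col == p) for p in populations}
    k = len(populations)
    fst = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            num = den = 0.0
            for li in locus_indices:
                calls_by_pop = {
                    populations[i]: matrix.calls[li, cols_by_pop[populations[i]]],
                    populations[j]: matrix.calls[li, cols_by_pop[populations[j]]],
                }
                table = _allele_counts(calls_by_pop)
                if table.size == 0 or table.shape[1] < 2:
                    continue
                sigma_a, sigma_w = amova_components(table)
                if np.isfinite(sigma_a):
                    num += sigma_a
                    den += sigma_a + sigma_w
            fst[i, j] = fst[j, i] = num / den if den > 0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(fst < 1.0, fst / (1.0 - fst), np.inf)
    np.fill_diagonal(std, 0.0)
    return PairwiseFstMatrix(
        populations=list(populations),
        fst=pd.DataFrame(fst, index=populations, columns=populations),
        standardized=pd.DataFrame(std, index=populations, columns=populations),
    )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Tajima (1989) normalizing constants for n sequences (n >= 2)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d(S: int, mean_pairwise_diffs: float, n: int) -> float:
    """Tajima's D = (pi_hat - S/a1) / sqrt(e1 S + e2 S (S-1)).

    ``mean_pairwise_diffs`` is the mean number of pairwise differences summed
    over the window's sites (pi_hat, in units of sites, not per bp). Returns
    nan for S = 0 or n < 4 (undefined / excluded windows).
    """
    if S < 1 or n < 4:
        return float("nan")
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (mean_pairwise_diffs - S / c.a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# per-locus stats table and group summary
# ---------------------------------------------------------------------------


def locus_stats_table(
    matrix: HaplotypeMatrix,
    individuals: Optional[Sequence[str]] = None,
    group_id: str = "all",
    fst_partition: Optional[Mapping[str, Sequence[str]]] = None,
    unbiased_he: bool = True,
) -> pd.DataFrame:
    """Per-locus pi, H_e, H_o (and optional AMOVA F_ST) within one group.

    ``fst_partition`` maps subpopulation labels to member individuals; when
    given, a per-locus among-subpopulation F_ST column is added.
    """
    if individuals is None:
        individuals = list(matrix.samples["individual"])
    cols = matrix.sample_indices(individuals)
    part_cols = None
    if fst_partition is not None:
        part_cols = {
            label: matrix.sample_indices(members)
            for label, members in fst_partition.items()
        }
    rows = []
    for li in range(matrix.n_loci):
        locus = matrix.loci.iloc[li]
        calls = matrix.calls[li, cols]
        geno = _genotyped(calls)
        n_geno = len(geno)
        seqs = _sequences(calls)
        n_alleles = len(set(seqs))
        if n_geno == 0:
            pi = he = ho = float("nan")
        else:
            pi = locus_pi(calls, length=int(locus["length"]))
            he = locus_gene_diversity(calls, unbiased=unbiased_he)
            ho = locus_observed_het(calls)
        fst = float("nan")
        if part_cols is not None:
            fst = locus_amova_fst(
                {label: matrix.calls[li, pc] for label, pc in part_cols.items()}
            )
        rows.append(
            {
                "locus_id": locus["locus_id"],
                "chrom": locus["chrom"],
                "pos": int(locus["pos"]),
                "group": group_id,
                "n": n_geno,
                "n_sequences": 2 * n_geno,
                "n_alleles": n_alleles,
                "pi": pi,
                "he": he,
                "ho": ho,
                "fst": fst,
                "is_polymorphic": n_alleles >= 2,
            }
        )
    return pd.DataFrame(rows)


def group_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Mean pi, H_e, H_o per group (the per-group summary table)."""
    return (
        stats.groupby("group")
        .agg(
            n_loci=("locus_id", "size"),
            n_polymorphic=("is_polymorphic", "sum"),
            mean_pi=("pi", "mean"),
            mean_he=("he", "mean"),
            mean_ho=("ho", "mean"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius * math.asin(min(1.0, math.sqrt(a)))


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n_pairs: int


def ibd_regression(
    genetic_dist: pd.DataFrame,
    coordinates: Mapping[str, tuple[float, float]],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> IbdResult:
    """Matrix regression of genetic distance on great-circle distance.

    Least squares on the vectorized upper triangles; significance from a
    permutation test in which rows and columns of the genetic matrix are
    permuted together, with p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    Degenerate geography (all distances equal) gives a flagged nan slope.
    """
    pops = list(genetic_dist.index)
    if len(pops) < 4:
        raise ValueError("need at least 4 populations")
    G = genetic_dist.to_numpy(dtype=float)
    if not np.allclose(G, G.T) or not np.allclose(np.diag(G), 0.0):
        raise ValueError("genetic distance matrix must be symmetric with zero diagonal")
    k = len(pops)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            lat1, lon1 = coordinates[pops[i]]
            lat2, lon2 = coordinates[pops[j]]
            D[i, j] = D[j, i] = haversine_km(lat1, lon1, lat2, lon2)
    iu = np.triu_indices(k, 1)
    x = D[iu]
    y = G[iu]
    m = len(x)
    if np.allclose(x, x[0]):
        return IbdResult(float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), m)

    def _fit(yv: np.ndarray) -> tuple[float, float, float, float]:
        xc = x - x.mean()
        slope = float(np.dot(xc, yv - yv.mean()) / np.dot(xc, xc))
        intercept = float(yv.mean() - slope * x.mean())
        resid = yv - (intercept + slope * x)
        sse = float(np.dot(resid, resid))
        sst = float(np.dot(yv - yv.mean(), yv - yv.mean()))
        ssr = sst - sse
        if sse <= 0:
            f = math.inf if ssr > 0 else 0.0
        else:
            f = (ssr / 1.0) / (sse / (m - 2))
        r2 = ssr / sst if sst > 0 else float("nan")
        return slope, intercept, r2, f

    slope, intercept, r2, f_obs = _fit(y)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        y_perm = G[np.ix_(perm, perm)][iu]
        _, _, _, f_perm = _fit(y_perm)
        if f_perm >= f_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_permutations + 1)
    return IbdResult(slope, intercept, r2, f_obs, p, m)
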