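"""Kernel-smoothed window scan, bootstrap significance, and window selection.

The scan follows the kernel-smoothing approach of Hohenlohe et al. (2010):
each window is centred on a polymorphic RAD locus and spans 3 sigma either
side; contributing loci are weighted by a Gaussian kernel
``w = exp(-d^2 / (2 sigma^2))`` so loci near the centre dominate. Bootstrap
pseudoreplicates draw the same number of per-locus values from the
genome-wide pool (reusing the window's weight vector) to test whether a
window's diversity exceeds the genome-wide expectation. Adjacent significant
windows whose centres are separated by less than sigma merge into regions.

Tajima's D uses a separate fixed grid of windows (default 120 kbp wide,
stepped by 12 kbp, anchored at coordinate 0), since D is computed from
individual SNPs rather than from per-locus statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import SnpTable
from .popgen import tajima_d

KERNEL_RADIUS_SIGMAS = 3.0

__all__ = [
    "smooth_statistic",
    "bootstrap_window_pvalues",
    "single_locus_outliers",
    "merge_windows_to_regions",
    "quantile_windows",
    "sliding_tajima_d",
    "top_d_windows",
    "interval_overlap",
    "windows_to_intervals",
    "sigma_for_target_loci",
    "OverlapResult",
]


def _tolerant_ceil(x: float) -> int:
    return int(math.ceil(x - 1e-9))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _window_members(
    pos: np.ndarray, center: int, sigma: float
) -> tuple[int, int, np.ndarray]:
    """Slice (lo, hi) of sorted positions within 3 sigma of center, plus
    the Gaussian kernel weights for that slice."""
    radius = KERNEL_RADIUS_SIGMAS * sigma
    lo = int(np.searchsorted(pos, center - radius, side="left"))
    hi = int(np.searchsorted(pos, center + radius, side="right"))
    d = pos[lo:hi] - center
    w = np.exp(-(d.astype(float) ** 2) / (2.0 * sigma * sigma))
    return lo, hi, w


def smooth_statistic(
    loci: pd.DataFrame,
    values: np.ndarray,
    sigma: float,
    center_mask: Optional[np.ndarray] = None,
    stat_name: str = "stat",
) -> pd.DataFrame:
    """Gaussian-kernel smoothed statistic in windows centred on polymorphic loci.

    Parameters
    ----------
    loci : DataFrame with ``chrom`` and ``pos`` columns, sorted by (chrom, pos).
    values : per-locus statistic aligned with ``loci``.
    sigma : smoothing scale in bp; windows span ``center +/- 3 sigma``.
    center_mask : boolean mask of loci to use as window centres (normally the
        polymorphic loci). Default: all loci.

    Returns a DataFrame with one window per centre: ``stat, chrom, center,
    value, n_loci, locus_index`` (index of the centre locus in ``loci``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    values = np.asarray(values, dtype=float)
    if len(values) != len(loci):
        raise ValueError("values must align with loci")
    if center_mask is None:
        center_mask = np.ones(len(loci), dtype=bool)
    center_mask = np.asarray(center_mask, dtype=bool)
    if not center_mask.any():
        raise ValueError("need at least one window centre")
    out = []
    offset = 0
    for chrom, sub in loci.groupby("chrom", sort=False):
        n = len(sub)
        pos = sub["pos"].to_numpy()
        vals = values[offset : offset + n]
        cmask = center_mask[offset : offset + n]
        for ci in np.flatnonzero(cmask):
            center = int(pos[ci])
            lo, hi, w = _window_members(pos, center, sigma)
            finite = np.isfinite(vals[lo:hi])
            wsum = w[finite].sum()
            if wsum == 0:  # pragma: no cover - centre always contributes
                raise RuntimeError("window with no contributing loci")
            value = float(np.dot(w[finite], vals[lo:hi][finite]) / wsum)
            out.append(
                {
                    "stat": stat_name,
                    "chrom": chrom,
                    "center": center,
                    "value": value,
                    "n_loci": int(finite.sum()),
                    "locus_index": int(offset + ci),
                }
            )
        offset += n
    return pd.DataFrame(out)


def bootstrap_window_pvalues(
    windows: pd.DataFrame,
    loci: pd.DataFrame,
    values: np.ndarray,
    sigma: float,
    n_reps: int = 10_000,
    seed: Optional[int] = None,
    pool: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Upper-tail bootstrap p-values for smoothed windows.

    For a window with m contributing loci and kernel weights w, each
    pseudoreplicate draws m values with replacement from the genome-wide
    per-locus pool and recomputes the weighted mean;
    ``boot_p = (1 + #{pseudoreplicate >= observed}) / (n_reps + 1)``.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    values = np.asarray(values, dtype=float)
    if pool is None:
        pool = values[np.isfinite(values)]
    pool = np.asarray(pool, dtype=float)
    if pool.size < 2:
        raise ValueError("pool must contain at least 2 values")
    rng = np.random.default_rng(seed)
    out = windows.copy()
    boot_p = np.empty(len(windows))
    # group by chromosome once; member slices recomputed with the same rule
    # used by smooth_statistic so weights match exactly
    pos_by_chrom: dict[str, np.ndarray] = {}
    val_by_chrom: dict[str, np.ndarray] = {}
    offset = 0
    for chrom, sub in loci.groupby("chrom", sort=False):
        pos_by_chrom[chrom] = sub["pos"].to_numpy()
        val_by_chrom[chrom] = values[offset : offset + len(sub)]
        offset += len(sub)
    for wi, row in enumerate(windows.itertuples(index=False)):
        pos = pos_by_chrom[row.chrom]
        vals = val_by_chrom[row.chrom]
        lo, hi, w = _window_members(pos, int(row.center), sigma)
        finite = np.isfinite(vals[lo:hi])
        w = w[finite]
        m = len(w)
        wsum = w.sum()
        obs = float(row.value)
        idx = rng.integers(0, pool.size, size=(n_reps, m))
        sims = pool[idx] @ w / wsum
        tol = 1e-9 * max(1.0, abs(obs))
        n_ge = int(np.count_nonzero(sims >= obs - tol))
        boot_p[wi] = (1 + n_ge) / (n_reps + 1)
    out["boot_p"] = boot_p
    return out


def single_locus_outliers(
    values: np.ndarray, q: float = 0.99
) -> tuple[np.ndarray, float]:
    """Mask of loci in the upper (1-q) tail, ties at the threshold included.

    The threshold is the k-th largest value with ``k = ceil((1-q) n)``, so
    1000 distinct values at q=0.99 yield exactly 10 outliers.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("no finite values")
    k = max(1, _tolerant_ceil((1.0 - q) * n))
    threshold = float(np.sort(values[finite])[n - k])
    mask = finite & (values >= threshold)
    return mask, threshold


def quantile_windows(
    windows: pd.DataFrame,
    tail: str,
    q: float = 0.05,
    value_col: str = "value",
) -> pd.DataFrame:
    """Windows in the lower or upper empirical q-tail (ties included)."""
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    vals = windows[value_col].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    n = int(finite.sum())
    if n == 0:
        return windows.iloc[0:0].copy()
    k = max(1, _tolerant_ceil(q * n))
    s = np.sort(vals[finite])
    if tail == "lower":
        threshold = s[k - 1]
        mask = finite & (vals <= threshold)
    else:
        threshold = s[n - k]
        mask = finite & (vals >= threshold)
    return windows[mask].copy()


def merge_windows_to_regions(
    windows: pd.DataFrame,
    sigma: float,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Merge significant windows whose centres are < sigma apart into regions.

    Region extent is [first centre - sigma, last centre + sigma], clipped to
    [0, chromosome length]. Merging is idempotent.
    """
    cols = ["chrom", "start", "end", "n_windows", "centers"]
    if len(windows) == 0:
        return pd.DataFrame(columns=cols)
    df = windows.sort_values(["chrom", "center"]).reset_index(drop=True)
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        centers = sub["center"].to_numpy()
        run = [int(centers[0])]
        runs = []
        for c in centers[1:]:
            if c - run[-1] < sigma:
                run.append(int(c))
            else:
                runs.append(run)
                run = [int(c)]
        runs.append(run)
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        for run in runs:
            start = max(0, int(run[0] - sigma))
            end = int(run[-1] + sigma)
            if limit is not None:
                end = min(end, int(limit))
            out.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_windows": len(run),
                    "centers": run,
                }
            )
    return pd.DataFrame(out, columns=cols)


# ---------------------------------------------------------------------------
# sliding-window Tajima's D
# ---------------------------------------------------------------------------


def sliding_tajima_d(
    snps: SnpTable,
    sample_indices: Optional[Sequence[int]] = None,
    width: int = 120_000,
    step: int = 12_000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Tajima's D in fixed windows (grid anchored at 0) per chromosome.

    Per window, S counts the polymorphic sites and ``pi_hat`` sums each
    site's mean pairwise difference over its non-missing sequences; the
    sample size n is the median per-site non-missing sequence count (windows
    with heterogeneous per-site n are flagged). Windows with S = 0 are kept
    in the grid but marked not estimable.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    gt = snps.genotypes
    if sample_indices is not None:
        gt = gt[:, np.asarray(sample_indices, dtype=int), :]
    n_sites = gt.shape[0]
    rows = []
    if n_sites == 0 and not chrom_lengths:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "S", "n", "pi_hat", "D", "estimable", "heterogeneous_n"]
        )
    # per-site totals across both copies
    flat = gt.reshape(n_sites, -1) if n_sites else np.empty((0, 0), dtype=np.int8)
    called = flat >= 0
    T = called.sum(axis=1)
    alt = np.where(called, flat, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = np.where(
            T >= 2, 2.0 * alt * (T - alt) / (T * np.maximum(T - 1, 1)), 0.0
        )
    polymorphic = (T >= 2) & (alt > 0) & (alt < T)

    chrom_arr = snps.chrom.astype(str)
    chroms = list(dict.fromkeys(chrom_arr.tolist()))
    if chrom_lengths:
        for c in chrom_lengths:
            if c not in chroms:
                chroms.append(c)
    for chrom in chroms:
        in_chrom = np.flatnonzero((chrom_arr == chrom) & polymorphic)
        pos = snps.pos[in_chrom]
        order = np.argsort(pos)
        in_chrom = in_chrom[order]
        pos = pos[order]
        if chrom_lengths and chrom in chrom_lengths:
            chrom_len = int(chrom_lengths[chrom])
        else:
            chrom_len = int(pos.max()) + 1 if len(pos) else width
        last_start = max(0, chrom_len - width)
        starts = np.arange(0, last_start + 1, step)
        for start in starts:
            end = start + width
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="left"))
            site_idx = in_chrom[lo:hi]
            S = len(site_idx)
            if S == 0:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(end),
                        "S": 0,
                        "n": 0,
                        "pi_hat": 0.0,
                        "D": float("nan"),
                        "estimable": False,
                        "heterogeneous_n": False,
                    }
                )
                continue
            n_med = int(round(float(np.median(T[site_idx]))))
            pi_hat = float(site_pi[site_idx].sum())
            D = tajima_d(S, pi_hat, n_med)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "S": S,
                    "n": n_med,
                    "pi_hat": pi_hat,
                    "D": D,
                    "estimable": bool(np.isfinite(D)),
                    "heterogeneous_n": bool(T[site_idx].min() != T[site_idx].max()),
                }
            )
    return pd.DataFrame(rows)


def top_d_windows(dwindows: pd.DataFrame, q: float = 0.05) -> tuple[pd.DataFrame, int]:
    """The top-q fraction of estimable D windows.

    Selection size is round-half-up(q * n_estimable); ties at the boundary
    are resolved in genomic order (earlier windows kept) so the size is
    exact. Returns (selected windows, selection size).
    """
    est = dwindows[dwindows["estimable"]].copy()
    n = len(est)
    if n == 0:
        return est, 0
    k = _round_half_up(q * n)
    if k == 0:
        return est.iloc[0:0], 0
    est = est.sort_values(["D", "chrom", "start"], ascending=[False, True, True])
    return est.iloc[:k].sort_values(["chrom", "start"]).reset_index(drop=True), k


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    pairs: list[tuple[int, int]]  # (index in A, index in B)
    n_a_overlapping: int
    fraction: float


def interval_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame) -> OverlapResult:
    """Half-open interval overlap between two sets (chrom/start/end).

    Returns all overlapping (A, B) index pairs, the number of A members
    overlapping any B member, and that number as a fraction of |A|.
    """
    trees: dict[str, IntervalTree] = {}
    for bi, row in enumerate(set_b.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, bi)
    pairs = []
    hit = np.zeros(len(set_a), dtype=bool)
    for ai, row in enumerate(set_a.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(row.start, row.end)):
            pairs.append((ai, iv.data))
            hit[ai] = True
    n_hit = int(hit.sum())
    fraction = n_hit / len(set_a) if len(set_a) else 0.0
    return OverlapResult(pairs=pairs, n_a_overlapping=n_hit, fraction=fraction)


def windows_to_intervals(
    windows: pd.DataFrame,
    sigma: float,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Represent smoothed windows as [center - sigma, center + sigma] intervals."""
    df = pd.DataFrame(
        {
            "chrom": windows["chrom"].to_numpy(),
            "start": np.maximum(0, windows["center"].to_numpy() - int(sigma)),
            "end": windows["center"].to_numpy() + int(sigma),
        }
    )
    if chrom_lengths:
        df["end"] = [
            min(e, chrom_lengths.get(c, e)) for c, e in zip(df["chrom"], df["end"])
        ]
    return df


def sigma_for_target_loci(loci: pd.DataFrame, target: float = 30.0) -> float:
    """Sigma such that a 6-sigma window holds ~``target`` loci on average."""
    if len(loci) < 2:
        raise ValueError("need at least 2 loci to estimate density")
    span = 0.0
    for _, sub in loci.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        span += float(pos.max() - pos.min())
    density = len(loci) / span
    return target / (2 * KERNEL_RADIUS_SIGMAS * density)
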