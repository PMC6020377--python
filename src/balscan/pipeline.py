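"""End-to-end orchestration of the genome scan for one or more sample groups.

For each configured group run the pipeline executes: presence filtering ->
per-locus haplotype statistics (pi, H_e, H_o, AMOVA F_ST) -> kernel smoothing
of pi and H_e -> bootstrap significance -> significant-window categories
(H_e only / pi only / both, which must sum to the total) -> merging into
regions -> smoothed-F_ST quantile tails -> sliding-window Tajima's D and its
top 5% -> overlap counting -> gene-class enrichment -> region annotation.
All stages log input/output counts to a manifest and every random stage
derives its seed from the config seed, so a rerun reproduces the summary
byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import annotate_regions, enrichment_permutation_test, gene_counts_per_window
from .io_formats import GeneAnnotation, HaplotypeMatrix, SnpTable, write_intervals_bed
from .popgen import filter_loci_by_presence, individual_heterozygosity, locus_stats_table
from .scan import (
    _round_half_up,
    bootstrap_window_pvalues,
    interval_overlap,
    merge_windows_to_regions,
    quantile_windows,
    single_locus_outliers,
    sliding_tajima_d,
    smooth_statistic,
    top_d_windows,
    windows_to_intervals,
)

__all__ = ["GroupRun", "ScanConfig", "PipelineResult", "run_pipeline", "report_summary"]


@dataclass
class GroupRun:
    """One (group, missing-data strategy) run of the scan."""

    name: str
    group: Optional[str] = None  # metadata group id; None = all samples
    max_missing_frac: float = 0.5
    sigma: float = 60_000.0
    fst_partition: Optional[Mapping[str, Sequence[str]]] = None  # label -> individuals
    run_tajima_d: bool = True


@dataclass
class ScanConfig:
    runs: list[GroupRun] = field(default_factory=list)
    alpha: float = 0.05
    n_bootstrap: int = 10_000
    d_width: int = 120_000
    d_step: int = 12_000
    outlier_quantile: float = 0.99
    tail_quantile: float = 0.05
    n_permutations: int = 1000
    candidate_class: str = "candidate"
    control_class: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for run in self.runs:
            if run.sigma <= 0:
                raise ValueError(f"run {run.name}: sigma must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        runs = [GroupRun(**r) for r in raw.pop("runs", [])]
        return cls(runs=runs, **raw)


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    runs: dict[str, dict]
    manifest: list[dict]

    def write_artifacts(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        for name, art in self.runs.items():
            rundir = outdir / name
            rundir.mkdir(exist_ok=True)
            art["locus_stats"].to_csv(rundir / "locus_stats.tsv", sep="\t", index=False)
            art["windows"].to_csv(rundir / "windows.tsv", sep="\t", index=False)
            if len(art["regions"]):
                write_intervals_bed(
                    art["regions"][["chrom", "start", "end"]], rundir / "regions.bed"
                )
            art["fst_windows"].to_csv(rundir / "fst_windows.tsv", sep="\t", index=False)
            art["d_windows"].to_csv(rundir / "d_windows.tsv", sep="\t", index=False)
            art["individual_ho"].to_csv(rundir / "individual_ho.tsv", sep="\t", index=False)


def report_summary(
    he_only: int,
    pi_only: int,
    both: int,
    total_windows: int,
    overlap_count: Optional[int] = None,
    n_estimable_d: Optional[int] = None,
    tail_quantile: float = 0.05,
) -> dict:
    """Reporting conventions for the summary table.

    The proportion of significant windows is reported to 4 decimals; the
    D-window overlap percentage uses the round-half-up top-5% selection size
    as its denominator and is reported to 1 decimal.
    """
    for v in (he_only, pi_only, both):
        if v < 0:
            raise ValueError("category counts must be non-negative")
    total_significant = he_only + pi_only + both
    if total_significant > total_windows:
        raise ValueError("significant windows exceed total windows")
    out = {
        "he_only": he_only,
        "pi_only": pi_only,
        "both": both,
        "total_significant": total_significant,
        "total_windows": total_windows,
        "proportion_significant": round(total_significant / total_windows, 4)
        if total_windows
        else float("nan"),
    }
    if overlap_count is not None and n_estimable_d is not None:
        top_size = _round_half_up(tail_quantile * n_estimable_d)
        out["top_d_size"] = top_size
        out["d_overlap_count"] = overlap_count
        out["d_overlap_percent"] = (
            round(100.0 * overlap_count / top_size, 1) if top_size else float("nan")
        )
    return out


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    matrix: HaplotypeMatrix,
    snps: Optional[SnpTable],
    genes: Sequence[GeneAnnotation],
    config: ScanConfig,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> PipelineResult:
    """Execute the scan for every configured group run."""
    manifest: list[dict] = []
    run_artifacts: dict[str, dict] = {}
    summary_rows = []
    run_seeds = np.random.SeedSequence(config.seed).spawn(max(1, len(config.runs)))

    def log(stage: str, run: str, **counts) -> None:
        manifest.append({"stage": stage, "run": run, "time": time.time(), **counts})

    for run, seed_seq in zip(config.runs, run_seeds):
        seeds = seed_seq.spawn(4)
        if run.group is None:
            individuals = list(matrix.samples["individual"])
        else:
            individuals = list(
                matrix.samples.loc[matrix.samples["group"] == run.group, "individual"]
            )
        if not individuals:
            raise ValueError(f"run {run.name}: no individuals in group {run.group!r}")

        keep, filt_report = filter_loci_by_presence(
            matrix, individuals, run.max_missing_frac
        )
        sub = matrix.subset_loci(keep)
        log("filter_loci", run.name, **filt_report)

        fst_partition = run.fst_partition
        if fst_partition is None:
            grp_samples = matrix.samples[matrix.samples["individual"].isin(individuals)]
            fst_partition = {
                pop: list(s["individual"])
                for pop, s in grp_samples.groupby("population")
            }
            if len(fst_partition) < 2:
                fst_partition = None
        stats = locus_stats_table(
            sub, individuals, group_id=run.name, fst_partition=fst_partition
        )
        log("locus_stats", run.name, n_loci=len(stats), n_polymorphic=int(stats["is_polymorphic"].sum()))

        # single-locus outliers: loci in the top 1% of pi, H_e or H_o
        outlier_mask = np.zeros(len(stats), dtype=bool)
        for stat in ("pi", "he", "ho"):
            vals = stats[stat].to_numpy(dtype=float)
            if np.isfinite(vals).any():
                mask, _ = single_locus_outliers(
                    np.where(np.isfinite(vals), vals, -np.inf), config.outlier_quantile
                )
                stats[f"outlier_{stat}"] = mask
                outlier_mask |= mask
        log("single_outliers", run.name, n_outliers=int(outlier_mask.sum()))

        loci_df = stats[["chrom", "pos"]].copy()
        poly = stats["is_polymorphic"].to_numpy()
        windows = None
        for stat, seed in (("pi", seeds[0]), ("he", seeds[1])):
            vals = stats[stat].to_numpy(dtype=float)
            w = smooth_statistic(loci_df, vals, run.sigma, center_mask=poly, stat_name=stat)
            w = bootstrap_window_pvalues(
                w, loci_df, vals, run.sigma, n_reps=config.n_bootstrap, seed=_sub_seed(seed)
            )
            w = w.rename(columns={"value": f"{stat}_value", "boot_p": f"{stat}_p"}).drop(
                columns=["stat"]
            )
            if windows is None:
                windows = w
            else:
                windows = windows.merge(
                    w, on=["chrom", "center", "n_loci", "locus_index"], how="inner"
                )
        assert windows is not None
        windows["significant_pi"] = windows["pi_p"] < config.alpha
        windows["significant_he"] = windows["he_p"] < config.alpha
        windows["significant"] = windows["significant_pi"] | windows["significant_he"]
        he_only = int((windows["significant_he"] & ~windows["significant_pi"]).sum())
        pi_only = int((windows["significant_pi"] & ~windows["significant_he"]).sum())
        both = int((windows["significant_pi"] & windows["significant_he"]).sum())
        log(
            "bootstrap",
            run.name,
            total_windows=len(windows),
            he_only=he_only,
            pi_only=pi_only,
            both=both,
        )

        sig = windows[windows["significant"]]
        regions = merge_windows_to_regions(sig, run.sigma, chrom_lengths)
        log("merge_regions", run.name, n_regions=len(regions))

        # smoothed F_ST in the same windows, bottom/top tails
        fst_vals = stats["fst"].to_numpy(dtype=float)
        if np.isfinite(fst_vals).sum() >= 2:
            fst_windows = smooth_statistic(
                loci_df, fst_vals, run.sigma, center_mask=poly, stat_name="fst"
            )
            low_fst = quantile_windows(fst_windows, "lower", config.tail_quantile)
            high_fst = quantile_windows(fst_windows, "upper", config.tail_quantile)
            sig_centers = set(zip(sig["chrom"], sig["center"]))
            low_overlap = sum(
                (c, p) in sig_centers for c, p in zip(low_fst["chrom"], low_fst["center"])
            )
            high_overlap = sum(
                (c, p) in sig_centers for c, p in zip(high_fst["chrom"], high_fst["center"])
            )
        else:
            fst_windows = pd.DataFrame(columns=["stat", "chrom", "center", "value"])
            low_overlap = high_overlap = 0
        log("fst_windows", run.name, n_windows=len(fst_windows))

        # sliding-window Tajima's D on the group's SNPs
        d_windows = pd.DataFrame(
            columns=["chrom", "start", "end", "S", "n", "pi_hat", "D", "estimable", "heterogeneous_n"]
        )
        top_d = d_windows
        n_estimable = 0
        d_overlap_count = 0
        d_overlap_pct = float("nan")
        if run.run_tajima_d and snps is not None and snps.n_sites:
            snp_sub = snps.subset_samples(individuals)
            d_windows = sliding_tajima_d(
                snp_sub, width=config.d_width, step=config.d_step, chrom_lengths=chrom_lengths
            )
            n_estimable = int(d_windows["estimable"].sum())
            top_d, top_size = top_d_windows(d_windows, config.tail_quantile)
            if top_size:
                sig_intervals = windows_to_intervals(sig, run.sigma, chrom_lengths)
                ov = interval_overlap(top_d[["chrom", "start", "end"]], sig_intervals)
                d_overlap_count = ov.n_a_overlapping
                d_overlap_pct = round(100.0 * d_overlap_count / top_size, 1)
        log("tajima_d", run.name, n_estimable=n_estimable, d_overlap=d_overlap_count)

        # enrichment of gene classes in high-diversity windows
        enrich: dict[str, object] = {}
        if len(sig) and len(sig) < len(windows):
            counts_by_class = {}
            for cls, seed in (
                (config.candidate_class, seeds[2]),
                (config.control_class, seeds[3]),
            ):
                counts = gene_counts_per_window(windows, run.sigma, genes, gene_class=cls)
                counts_by_class[cls] = counts
                enrich[cls] = enrichment_permutation_test(
                    counts,
                    windows["significant"].to_numpy(),
                    n_permutations=config.n_permutations,
                    seed=_sub_seed(seed),
                    gene_class=cls,
                )
        log("enrichment", run.name, classes=list(enrich))

        per_region, region_totals = annotate_regions(
            regions,
            genes,
            candidate_class=config.candidate_class,
            genome_length=float(sum(chrom_lengths.values())) if chrom_lengths else None,
        )

        # per-individual heterozygosity on loci present in every group member
        all_present, _ = filter_loci_by_presence(matrix, individuals, 0.0)
        full = matrix.subset_loci(all_present)
        individual_ho = pd.DataFrame(
            {
                "individual": individuals,
                "ho": [individual_heterozygosity(full, ind) for ind in individuals],
                "n_loci": len(all_present),
            }
        )

        rep = report_summary(
            he_only,
            pi_only,
            both,
            len(windows),
            overlap_count=d_overlap_count if n_estimable else None,
            n_estimable_d=n_estimable if n_estimable else None,
            tail_quantile=config.tail_quantile,
        )
        row = {
            "run": run.name,
            "group": run.group or "all",
            "max_missing_frac": run.max_missing_frac,
            "sigma": run.sigma,
            "n_loci_retained": filt_report["retained"],
            **rep,
            "n_regions": len(regions),
            "region_span_mbp": round(region_totals["total_span_mbp"], 3),
            "n_genes_in_regions": region_totals["n_genes"],
            "n_candidate_in_regions": region_totals["n_candidate"],
            "n_estimable_d_windows": n_estimable,
            "n_single_outlier_loci": int(outlier_mask.sum()),
            "low_fst_sig_overlap": low_overlap,
            "high_fst_sig_overlap": high_overlap,
        }
        for cls, res in enrich.items():
            row[f"enrichment_p_{cls}"] = res.p_value
            row[f"enrichment_diff_{cls}"] = res.observed_diff
        summary_rows.append(row)

        run_artifacts[run.name] = {
            "locus_stats": stats,
            "windows": windows,
            "regions": regions,
            "per_region": per_region,
            "region_totals": region_totals,
            "fst_windows": fst_windows,
            "d_windows": d_windows,
            "top_d": top_d,
            "enrichment": enrich,
            "individual_ho": individual_ho,
            "filter_report": filt_report,
        }

    return PipelineResult(
        summary=pd.DataFrame(summary_rows), runs=run_artifacts, manifest=manifest
    )
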