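"""Synthetic RAD-seq datasets with planted, recoverable truth.

The generator emulates the structure of a RAD-seq population-genomic study:
short (default 92 bp) multi-SNP haplotype loci spaced ~12 kbp apart along a
small multi-chromosome genome, sampled in several groups of populations
(selfing and outcrossing), with locus-level missingness and a gene annotation
carrying a candidate gene class enriched inside planted regions.

Generative model (genealogy-free, per locus)
--------------------------------------------
1. A Poisson number of polymorphic sites is placed on the locus; each site's
   ancestral derived-allele frequency is drawn from a frequency spectrum
   chosen by ``frequency_mode``: ``neutral`` (P(k) proportional to 1/k, the
   standard neutral site-frequency spectrum), ``intermediate`` (frequencies
   concentrated near 0.5, giving positive Tajima's D) or ``rare``
   (low-frequency-skewed, giving negative D). The Poisson mean is calibrated
   so the expected pairwise diversity per bp equals the configured theta.
2. Sites are realized on a pool of ancestral haplotypes; distinct haplotypes
   become the locus's alleles with ancestral frequencies ``q``.
3. Each population draws its haplotype-frequency vector from a multiallelic
   Balding–Nichols (Dirichlet) model, ``q_pop ~ Dirichlet(q (1-F)/F)`` with
   ``F = structure_Fst`` (scaled by a region's ``fst_multiplier``). Applying
   divergence to whole-haplotype frequencies (rather than per site) makes
   both haplotype-level and site-level F_ST recover ``structure_Fst``.
4. Individuals draw two haplotypes from their population's frequencies; with
   probability ``inbreeding_F`` the second copy is identical by descent
   (selfing depresses observed heterozygosity). Whole-locus calls go missing
   per (individual, locus) with probability ``missing_rate``.

Loci whose start falls inside a planted region use
``theta * diversity_multiplier``, the region's frequency mode, and
``structure_Fst * fst_multiplier``. Everything is deterministic given
``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneAnnotation,
    HaplotypeMatrix,
    SnpTable,
    write_gene_classes,
    write_gff3_genes,
    write_haplotype_table,
    write_intervals_bed,
    write_sample_metadata,
    write_vcf_snps,
)

BASES = np.array(list("ACGT"))
FREQUENCY_MODES = ("neutral", "intermediate", "rare")
_POOL_SIZE = 200  # ancestral haplotype pool per locus
_BETA_SHAPE = 20.0  # Beta(a, a) for the "intermediate" spectrum

__all__ = [
    "GroupSpec",
    "PlantedRegion",
    "SimConfig",
    "TruthSet",
    "SimulatedDataset",
    "simulate_locus",
    "simulate_dataset",
    "assign_gene_classes",
    "write_dataset",
]


@dataclass(frozen=True)
class GroupSpec:
    group_id: str
    n_populations: int
    n_individuals_per_pop: int
    inbreeding_f: float = 0.0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_individuals_per_pop < 1:
            raise ValueError("group needs >= 1 population and individual")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    diversity_multiplier: float = 5.0
    fst_multiplier: float = 1.0
    frequency_mode: str = "neutral"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("planted region start must be < end")
        if self.diversity_multiplier <= 0:
            raise ValueError("diversity_multiplier must be > 0")
        if not 0.0 < self.fst_multiplier <= 1.0:
            raise ValueError("fst_multiplier must be in (0, 1]")
        if self.frequency_mode not in FREQUENCY_MODES:
            raise ValueError(f"frequency_mode must be one of {FREQUENCY_MODES}")


def _default_groups() -> list[GroupSpec]:
    # a selfing group (low H_o, low diversity background) and a larger
    # outcrossing group, mirroring a selfing-vs-outcrossing sampling design
    return [
        GroupSpec("selfing", n_populations=5, n_individuals_per_pop=4, inbreeding_f=0.9),
        GroupSpec("outcrossing", n_populations=8, n_individuals_per_pop=4, inbreeding_f=0.0),
    ]


def _default_regions(n_chromosomes: int, chrom_length: int) -> list[PlantedRegion]:
    # one 500-kbp elevated-diversity region per chromosome (10% of a
    # 4 x 5 Mbp genome), with reduced differentiation and intermediate
    # allele frequencies: the balancing-selection signature triplet
    regions = []
    for c in range(1, n_chromosomes + 1):
        start = chrom_length // 3
        regions.append(
            PlantedRegion(
                chrom=f"chr{c}",
                start=start,
                end=start + chrom_length // 10,
                diversity_multiplier=5.0,
                fst_multiplier=0.5,
                frequency_mode="intermediate",
            )
        )
    return regions


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset; defaults are the study
    conditions the package's own validation runs under."""

    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    locus_spacing_mean: int = 12_000
    locus_length: int = 92
    groups: list[GroupSpec] = field(default_factory=_default_groups)
    background_theta: float = 0.005
    structure_fst: float = 0.1
    planted_regions: Optional[list[PlantedRegion]] = None
    missing_rate: float = 0.2
    gene_length: int = 2_000
    gene_spacing: int = 8_000
    candidate_class_prob_in: float = 0.3
    candidate_class_prob_out: float = 0.05
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.planted_regions is None:
            self.planted_regions = _default_regions(self.n_chromosomes, self.chrom_length)
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need >= 1 chromosome of positive length")
        if not 0.0 <= self.structure_fst < 1.0:
            raise ValueError("structure_fst must be in [0, 1)")
        for p in (self.missing_rate, self.candidate_class_prob_in, self.candidate_class_prob_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.background_theta < 0:
            raise ValueError("background_theta must be >= 0")
        chroms = {f"chr{c}" for c in range(1, self.n_chromosomes + 1)}
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in self.planted_regions:
            if r.chrom not in chroms:
                raise ValueError(f"planted region on unknown chromosome {r.chrom}")
            if r.start < 0 or r.end > self.chrom_length:
                raise ValueError("planted region outside chromosome bounds")
            by_chrom.setdefault(r.chrom, []).append(r)
        for regions in by_chrom.values():
            regions = sorted(regions, key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                if b.start < a.end:
                    raise ValueError("planted regions must not overlap")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{c}" for c in range(1, self.n_chromosomes + 1)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class TruthSet:
    """Planted ground truth recorded by the simulator."""

    planted_regions: pd.DataFrame  # chrom, start, end, multipliers, mode
    locus_flags: pd.DataFrame  # per locus: in_planted_region, balanced, ...
    gene_classes: dict[str, str]
    n_segregating_sites: int


@dataclass
class SimulatedDataset:
    config: SimConfig
    matrix: HaplotypeMatrix
    snps: SnpTable
    genes: list[GeneAnnotation]
    truth: TruthSet

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.config.chrom_lengths


# ---------------------------------------------------------------------------
# frequency spectra
# ---------------------------------------------------------------------------


def _log_beta(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def _spectrum_pmf(n: int, mode: str) -> np.ndarray:
    """P(derived count k), k = 1..n-1, for a pool/sample of n sequences."""
    k = np.arange(1, n)
    if mode == "neutral":
        w = 1.0 / k
    elif mode == "intermediate":
        a = _BETA_SHAPE
        logw = np.array(
            [
                math.lgamma(n + 1)
                - math.lgamma(ki + 1)
                - math.lgamma(n - ki + 1)
                + _log_beta(ki + a, n - ki + a)
                - _log_beta(a, a)
                for ki in k
            ]
        )
        w = np.exp(logw - logw.max())
    elif mode == "rare":
        w = np.where(k <= 3, 1.0, 0.0)
    else:
        raise ValueError(f"unknown frequency_mode {mode!r}")
    return w / w.sum()


def _expected_site_diversity(n: int, mode: str) -> float:
    """E[2 k (n-k) / (n (n-1))] per segregating site under the spectrum."""
    k = np.arange(1, n)
    pmf = _spectrum_pmf(n, mode)
    return float(np.sum(pmf * 2.0 * k * (n - k) / (n * (n - 1))))


def _poisson_site_mean(theta: float, length: int, n: int, mode: str) -> float:
    """Poisson mean for S so that expected pairwise diversity/bp == theta."""
    if theta <= 0:
        return 0.0
    return theta * length / _expected_site_diversity(n, mode)


# ---------------------------------------------------------------------------
# simulate_locus (standalone sequence generator)
# ---------------------------------------------------------------------------


def simulate_locus(
    theta_locus: float,
    n_sequences: int,
    locus_length: int = 92,
    frequency_mode: str = "neutral",
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Simulate haplotype sequences with a target pairwise diversity per bp.

    Mutations are placed with Poisson site counts and derived-allele counts
    drawn from the chosen frequency spectrum, calibrated so that the expected
    mean pairwise difference per bp equals ``theta_locus``.
    """
    if n_sequences < 2:
        raise ValueError("n_sequences must be >= 2")
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    if theta_locus < 0:
        raise ValueError("theta_locus must be >= 0")
    if frequency_mode not in FREQUENCY_MODES:
        raise ValueError(f"frequency_mode must be one of {FREQUENCY_MODES}")
    rng = rng or np.random.default_rng()
    ref = rng.integers(0, 4, size=locus_length)
    seqs = np.tile(ref, (n_sequences, 1))
    mu = _poisson_site_mean(theta_locus, locus_length, n_sequences, frequency_mode)
    S = min(int(rng.poisson(mu)), locus_length)
    if S > 0:
        sites = rng.choice(locus_length, size=S, replace=False)
        pmf = _spectrum_pmf(n_sequences, frequency_mode)
        for site in sites:
            k = int(rng.choice(np.arange(1, n_sequences), p=pmf))
            carriers = rng.choice(n_sequences, size=k, replace=False)
            derived = (ref[site] + rng.integers(1, 4)) % 4
            seqs[carriers, site] = derived
    return ["".join(BASES[row]) for row in seqs]


# ---------------------------------------------------------------------------
# gene annotation and class assignment
# ---------------------------------------------------------------------------


def _tile_genes(config: SimConfig) -> list[GeneAnnotation]:
    genes = []
    period = config.gene_length + config.gene_spacing
    for chrom in config.chrom_names:
        i = 0
        start = config.gene_spacing // 2
        while start + config.gene_length <= config.chrom_length:
            genes.append(
                GeneAnnotation(
                    gene_id=f"gene_{chrom}_{i:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + config.gene_length,
                )
            )
            start += period
            i += 1
    return genes


def _midpoint_in_regions(gene: GeneAnnotation, regions: Sequence[PlantedRegion]) -> bool:
    return any(
        r.chrom == gene.chrom and r.start <= gene.midpoint < r.end for r in regions
    )


def assign_gene_classes(
    genes: Sequence[GeneAnnotation],
    planted_regions: Sequence[PlantedRegion],
    p_in: float,
    p_out: float,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Label genes candidate/control/other.

    A gene is a candidate with probability ``p_in`` if its midpoint lies in a
    planted region, else ``p_out``. Non-candidate genes are independently
    labelled control at the uniform rate ``p_out`` (the unenriched
    comparison class).
    """
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = rng or np.random.default_rng()
    classes: dict[str, str] = {}
    for gene in genes:
        p = p_in if _midpoint_in_regions(gene, planted_regions) else p_out
        if rng.random() < p:
            classes[gene.gene_id] = "candidate"
        elif rng.random() < p_out:
            classes[gene.gene_id] = "control"
        else:
            classes[gene.gene_id] = "other"
    return classes


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def _build_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in config.groups:
        for p in range(1, group.n_populations + 1):
            pop = f"{group.group_id}_p{p}"
            lat = float(rng.uniform(45.0, 65.0))
            lon = float(rng.uniform(-10.0, 30.0))
            for i in range(1, group.n_individuals_per_pop + 1):
                rows.append(
                    {
                        "individual": f"{pop}_i{i}",
                        "population": pop,
                        "group": group.group_id,
                        "lat": round(lat, 4),
                        "lon": round(lon, 4),
                    }
                )
    return pd.DataFrame(rows)


def _locus_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    positions = []
    pos = 0
    limit = config.chrom_length - config.locus_length
    while True:
        gap = max(config.locus_length, int(round(rng.exponential(config.locus_spacing_mean))))
        pos += gap
        if pos > limit:
            break
        positions.append(pos)
    return np.array(positions, dtype=int)


def _region_for(pos: int, regions: Sequence[PlantedRegion]) -> Optional[PlantedRegion]:
    for r in regions:
        if r.start <= pos < r.end:
            return r
    return None


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset (haplotypes, SNPs, genes, truth)."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chromosomes + 2)
    meta_rng = np.random.default_rng(children[-2])
    gene_rng = np.random.default_rng(children[-1])

    samples = _build_samples(config, meta_rng)
    pop_of = samples["population"].to_numpy()
    group_of = samples["group"].to_numpy()
    n_ind = len(samples)
    populations = list(pd.unique(pop_of))
    pop_members = {p: np.flatnonzero(pop_of == p) for p in populations}
    inbreeding = {
        g.group_id: g.inbreeding_f for g in config.groups
    }

    loci_rows = []
    call_rows = []
    flag_rows = []
    snp_chrom, snp_pos, snp_ref, snp_alt, snp_gt = [], [], [], [], []

    regions_by_chrom: dict[str, list[PlantedRegion]] = {}
    for r in config.planted_regions:
        regions_by_chrom.setdefault(r.chrom, []).append(r)

    M = _POOL_SIZE
    pmf_cache = {mode: _spectrum_pmf(M, mode) for mode in FREQUENCY_MODES}
    esd_cache = {mode: _expected_site_diversity(M, mode) for mode in FREQUENCY_MODES}

    for ci, chrom in enumerate(config.chrom_names):
        rng = np.random.default_rng(children[ci])
        regions = regions_by_chrom.get(chrom, [])
        for pos in _locus_positions(config, rng):
            region = _region_for(int(pos), regions)
            theta = config.background_theta
            fst = config.structure_fst
            mode = "neutral"
            if region is not None:
                theta *= region.diversity_multiplier
                fst *= region.fst_multiplier
                mode = region.frequency_mode

            L = config.locus_length
            mu = theta * L / esd_cache[mode] if theta > 0 else 0.0
            S = min(int(rng.poisson(mu)), L)
            ref = rng.integers(0, 4, size=L)
            if S > 0:
                sites = np.sort(rng.choice(L, size=S, replace=False))
                derived_base = (ref[sites] + rng.integers(1, 4, size=S)) % 4
                pool = np.zeros((M, S), dtype=np.int8)
                kvals = rng.choice(np.arange(1, M), size=S, p=pmf_cache[mode])
                for s in range(S):
                    carriers = rng.choice(M, size=int(kvals[s]), replace=False)
                    pool[carriers, s] = 1
                uniq, inverse = np.unique(pool, axis=0, return_inverse=True)
                q_anc = np.bincount(inverse, minlength=len(uniq)) / M
            else:
                sites = np.empty(0, dtype=int)
                derived_base = np.empty(0, dtype=int)
                uniq = np.zeros((1, 0), dtype=np.int8)
                q_anc = np.array([1.0])

            n_hap = len(uniq)
            # per-population haplotype frequencies: multiallelic Balding-Nichols
            hap_idx = np.empty((n_ind, 2), dtype=int)
            for p in populations:
                members = pop_members[p]
                if fst > 0 and n_hap > 1:
                    alpha = q_anc * (1.0 - fst) / fst
                    q_pop = rng.dirichlet(np.maximum(alpha, 1e-9))
                else:
                    q_pop = q_anc
                draws = rng.choice(n_hap, size=(len(members), 2), p=q_pop)
                f_inb = inbreeding[group_of[members[0]]]
                if f_inb > 0:
                    auto = rng.random(len(members)) < f_inb
                    draws[auto, 1] = draws[auto, 0]
                hap_idx[members] = draws

            missing = rng.random(n_ind) < config.missing_rate

            # haplotype strings for the unique alleles
            strings = []
            for h in range(n_hap):
                arr = ref.copy()
                if S > 0:
                    hit = uniq[h].astype(bool)
                    arr = arr.copy()
                    arr[sites[hit]] = derived_base[hit]
                strings.append("".join(BASES[arr]))

            row = []
            for i in range(n_ind):
                if missing[i]:
                    row.append(None)
                else:
                    a, b = strings[hap_idx[i, 0]], strings[hap_idx[i, 1]]
                    row.append((a, b) if a <= b else (b, a))
            locus_id = f"L_{chrom}_{pos}"
            loci_rows.append((locus_id, chrom, int(pos), L))
            call_rows.append(row)
            flag_rows.append(
                {
                    "locus_id": locus_id,
                    "chrom": chrom,
                    "pos": int(pos),
                    "in_planted_region": region is not None,
                    "balanced": region is not None and region.frequency_mode == "intermediate",
                    "diversity_multiplier": region.diversity_multiplier if region else 1.0,
                    "n_missing": int(missing.sum()),
                }
            )

            # realized SNP records (only sites polymorphic among non-missing copies)
            if S > 0:
                called = ~missing
                alleles0 = uniq[hap_idx[:, 0], :]  # (n_ind, S)
                alleles1 = uniq[hap_idx[:, 1], :]
                for s in range(S):
                    a0 = alleles0[called, s]
                    a1 = alleles1[called, s]
                    alt_copies = int(a0.sum() + a1.sum())
                    total = 2 * int(called.sum())
                    if alt_copies == 0 or alt_copies == total:
                        continue
                    gt = np.full((n_ind, 2), -1, dtype=np.int8)
                    gt[called, 0] = alleles0[called, s]
                    gt[called, 1] = alleles1[called, s]
                    snp_chrom.append(chrom)
                    snp_pos.append(int(pos) + int(sites[s]))
                    snp_ref.append(str(BASES[ref[sites[s]]]))
                    snp_alt.append(str(BASES[derived_base[s]]))
                    snp_gt.append(gt)

    loci = pd.DataFrame(loci_rows, columns=["locus_id", "chrom", "pos", "length"])
    calls = np.empty((len(loci), n_ind), dtype=object)
    for i, row in enumerate(call_rows):
        calls[i, :] = row
    matrix = HaplotypeMatrix(loci=loci, samples=samples, calls=calls)

    snps = SnpTable(
        chrom=np.array(snp_chrom, dtype=object),
        pos=np.array(snp_pos, dtype=int),
        ref=np.array(snp_ref, dtype=object),
        alt=np.array(snp_alt, dtype=object),
        genotypes=(
            np.stack(snp_gt)
            if snp_gt
            else np.empty((0, n_ind, 2), dtype=np.int8)
        ),
        samples=list(samples["individual"]),
    )

    genes = _tile_genes(config)
    classes = assign_gene_classes(
        genes,
        config.planted_regions,
        config.candidate_class_prob_in,
        config.candidate_class_prob_out,
        gene_rng,
    )
    genes = [
        GeneAnnotation(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            gene_class=classes[g.gene_id],
            strand=g.strand,
        )
        for g in genes
    ]

    truth = TruthSet(
        planted_regions=pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "diversity_multiplier": r.diversity_multiplier,
                    "fst_multiplier": r.fst_multiplier,
                    "frequency_mode": r.frequency_mode,
                }
                for r in config.planted_regions
            ]
        ),
        locus_flags=pd.DataFrame(flag_rows),
        gene_classes=classes,
        n_segregating_sites=len(snp_pos),
    )
    return SimulatedDataset(config=config, matrix=matrix, snps=snps, genes=genes, truth=truth)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write every artifact of a simulated dataset to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "haplotypes": outdir / "haplotypes.tsv",
        "samples": outdir / "samples.tsv",
        "genes": outdir / "genes.gff3",
        "gene_classes": outdir / "gene_classes.tsv",
        "vcf": outdir / "snps.vcf",
        "truth_loci": outdir / "truth_loci.tsv",
        "planted_regions": outdir / "planted_regions.bed",
    }
    write_haplotype_table(dataset.matrix, paths["haplotypes"])
    write_sample_metadata(dataset.matrix.samples, paths["samples"])
    write_gff3_genes(dataset.genes, paths["genes"])
    write_gene_classes(dataset.truth.gene_classes, paths["gene_classes"])
    write_vcf_snps(dataset.snps, paths["vcf"], contig_lengths=dataset.chrom_lengths)
    with open(paths["truth_loci"], "w") as fh:
        fh.write("#")
        dataset.truth.locus_flags.to_csv(fh, sep="\t", index=False)
    write_intervals_bed(
        dataset.truth.planted_regions.assign(
            name=[
                f"planted_{i}" for i in range(len(dataset.truth.planted_regions))
            ]
        ),
        paths["planted_regions"],
    )
    return paths
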