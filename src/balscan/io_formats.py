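"""Readers and writers for the tabular formats the scan pipeline touches.

Formats and dialects
--------------------
* **Haplotype table** (TSV): one row per RAD locus. Columns: ``locus_id``,
  ``chrom``, ``pos`` (0-based bp), ``length`` (bp), then one column per
  individual containing ``h1/h2`` (two haplotype strings), a bare ``h``
  (homozygote shorthand) or ``.`` (locus missing in that individual).
* **Sample metadata** (TSV): ``individual``, ``population``, ``group``,
  ``lat``, ``lon``.
* **Gene classes** (TSV): ``gene_id``, ``gene_class``.
* **GFF3** in, 1-based inclusive per the standard; **BED** out, 0-based
  half-open; **VCF** v4.2 with GT-only genotypes.

Internally every coordinate is 0-based half-open; conversions happen only in
this module. Haplotype pairs are canonicalized lexicographically so that a
heterozygote has a unique representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = "."

__all__ = [
    "FormatError",
    "HaplotypeMatrix",
    "GeneAnnotation",
    "SnpTable",
    "canonical_pair",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_gene_classes",
    "write_gene_classes",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_vcf_snps",
    "write_vcf_snps",
    "write_intervals_bed",
    "read_intervals_bed",
]


class FormatError(ValueError):
    """A file does not conform to the dialect this package reads/writes."""


def canonical_pair(call: str) -> Optional[tuple[str, str]]:
    """Parse one haplotype-table cell into a canonical (sorted) allele pair.

    ``.`` means missing; ``h`` alone is the homozygote ``(h, h)``.
    """
    if call == MISSING or call == "":
        return None
    parts = call.split("/")
    if len(parts) == 1:
        h = parts[0]
        return (h, h)
    if len(parts) != 2:
        raise FormatError(f"cannot parse haplotype call {call!r}")
    a, b = parts
    return (a, b) if a <= b else (b, a)


@dataclass
class HaplotypeMatrix:
    """Per-locus, per-individual pairs of RAD haplotype alleles.

    Attributes
    ----------
    loci : DataFrame with columns locus_id, chrom, pos, length, sorted by
        (chrom, pos); positions strictly increasing within a chromosome.
    samples : DataFrame with columns individual, population, group, lat, lon.
    calls : object ndarray of shape (n_loci, n_samples); entries are ``None``
        (missing) or a canonical ``(h1, h2)`` tuple of equal-length strings.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise ValueError("calls shape does not match loci x samples")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if (pos < 0).any():
                raise ValueError(f"negative position on {chrom}")
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def genotyped_mask(self) -> np.ndarray:
        """Boolean (n_loci, n_samples) array: True where a call is present."""
        return np.vectorize(lambda c: c is not None, otypes=[bool])(self.calls)

    def sample_indices(self, individuals: Sequence[str]) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.samples["individual"])}
        try:
            return np.array([lookup[i] for i in individuals], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown individual {exc.args[0]!r}") from None

    def subset_samples(self, individuals: Sequence[str]) -> "HaplotypeMatrix":
        idx = self.sample_indices(individuals)
        return HaplotypeMatrix(
            loci=self.loci.reset_index(drop=True),
            samples=self.samples.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def subset_loci(self, locus_indices: Sequence[int]) -> "HaplotypeMatrix":
        idx = np.asarray(locus_indices, dtype=int)
        return HaplotypeMatrix(
            loci=self.loci.iloc[idx].reset_index(drop=True),
            samples=self.samples.reset_index(drop=True),
            calls=self.calls[idx, :],
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (0-based half-open) with a class label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    gene_class: str = "other"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class SnpTable:
    """Biallelic SNP genotypes as parallel arrays (positions 0-based).

    ``genotypes`` has shape (n_sites, n_samples, 2) with allele codes
    0 (ref), 1 (alt) and -1 (missing). Half-missing diploid genotypes are
    stored as fully missing.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    n_skipped_multiallelic: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset_samples(self, individuals: Sequence[str]) -> "SnpTable":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = [lookup[i] for i in individuals]
        return SnpTable(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            genotypes=self.genotypes[:, idx, :],
            samples=list(individuals),
            n_skipped_multiallelic=self.n_skipped_multiallelic,
        )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLS = ["individual", "population", "group", "lat", "lon"]


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    return df[_META_COLS].copy()


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_META_COLS) + "\n")
        samples[_META_COLS].to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# haplotype table
# ---------------------------------------------------------------------------


def read_haplotype_table(path, metadata_path) -> HaplotypeMatrix:
    """Read the Stacks-style haplotype TSV together with sample metadata."""
    samples = read_sample_metadata(metadata_path)
    meta_inds = list(samples["individual"])
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}: expected '#'-prefixed header line")
        cols = header.lstrip("#").split("\t")
        if cols[:4] != ["locus_id", "chrom", "pos", "length"]:
            raise FormatError(f"{path}: unexpected header columns {cols[:4]}")
        individuals = cols[4:]
        unknown = sorted(set(individuals) - set(meta_inds))
        if unknown:
            raise FormatError(f"{path}: individuals not in metadata: {unknown}")

        loci_rows = []
        call_rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4 + len(individuals):
                raise FormatError(
                    f"{path}:{lineno}: expected {4 + len(individuals)} columns, "
                    f"got {len(fields)}"
                )
            locus_id, chrom, pos_s, len_s = fields[:4]
            length = int(len_s)
            row = []
            for ind, cell in zip(individuals, fields[4:]):
                pair = canonical_pair(cell)
                if pair is not None and any(len(h) != length for h in pair):
                    raise FormatError(
                        f"{path}:{lineno}: haplotype length mismatch at locus "
                        f"{locus_id}, individual {ind} (declared {length})"
                    )
                row.append(pair)
            loci_rows.append((locus_id, chrom, int(pos_s), length))
            call_rows.append(row)

    loci = pd.DataFrame(loci_rows, columns=["locus_id", "chrom", "pos", "length"])
    calls = np.empty((len(loci), len(individuals)), dtype=object)
    for i, row in enumerate(call_rows):
        calls[i, :] = row
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    calls = calls[order, :]
    # align sample columns to metadata order
    col_order = [individuals.index(i) for i in meta_inds if i in individuals]
    samples = samples[samples["individual"].isin(individuals)].reset_index(drop=True)
    return HaplotypeMatrix(loci=loci, samples=samples, calls=calls[:, col_order])


def write_haplotype_table(matrix: HaplotypeMatrix, path) -> None:
    inds = list(matrix.samples["individual"])
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(["locus_id", "chrom", "pos", "length"] + inds) + "\n")
        for i, locus in matrix.loci.iterrows():
            cells = []
            for call in matrix.calls[i, :]:
                cells.append(MISSING if call is None else f"{call[0]}/{call[1]}")
            fh.write(
                "\t".join(
                    [
                        str(locus["locus_id"]),
                        str(locus["chrom"]),
                        str(int(locus["pos"])),
                        str(int(locus["length"])),
                    ]
                    + cells
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene classes and GFF3
# ---------------------------------------------------------------------------


def read_gene_classes(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    if not {"gene_id", "gene_class"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, gene_class")
    return dict(zip(df["gene_id"].astype(str), df["gene_class"].astype(str)))


def write_gene_classes(classes: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tgene_class\n")
        for gene_id, cls in classes.items():
            fh.write(f"{gene_id}\t{cls}\n")


def read_gff3_genes(path, class_map: Optional[Mapping[str, str]] = None) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file (1-based inclusive -> half-open).

    Only rows of feature type ``gene`` are retained. ``class_map`` (gene_id ->
    class) supplies gene-class labels; genes absent from it get ``"other"``.
    """
    path = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    class_map = class_map or {}
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                gene_class=class_map.get(gene_id, "other"),
                strand=feat.strand or ".",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3_genes(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "balscan",
                        "gene",
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_snps(path) -> SnpTable:
    """Read biallelic SNP genotypes from a VCF (GT only).

    Multiallelic records are skipped with a logged warning; the skip count is
    reported on the returned table. Half-missing genotypes become fully
    missing at that site.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, gts = [], [], [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        chroms.append(variant.CHROM)
        positions.append(variant.POS - 1)  # VCF 1-based -> internal 0-based
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        row = np.empty((len(samples), 2), dtype=np.int8)
        for j, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                row[j] = (-1, -1)
            else:
                row[j] = (a, b)
        gts.append(row)
    vcf.close()
    if n_multi:
        logger.warning("read_vcf_snps: skipped %d multiallelic records", n_multi)
    genotypes = (
        np.stack(gts) if gts else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return SnpTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=int),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=genotypes,
        samples=samples,
        n_skipped_multiallelic=n_multi,
    )


def write_vcf_snps(snps: SnpTable, path, contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write a minimal VCF v4.2 (GT-only) from a SnpTable."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=balscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(snps.samples)
            + "\n"
        )
        order = np.lexsort((snps.pos, snps.chrom.astype(str)))
        for i in order:
            cells = []
            for a, b in snps.genotypes[i]:
                cells.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            fh.write(
                "\t".join(
                    [
                        str(snps.chrom[i]),
                        str(int(snps.pos[i]) + 1),
                        f"snp{i}",
                        str(snps.ref[i]),
                        str(snps.alt[i]),
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + cells
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def write_intervals_bed(intervals: pd.DataFrame, path) -> None:
    """Write intervals (chrom/start/end[, name, score]) as sorted BED."""
    required = {"chrom", "start", "end"}
    if not required <= set(intervals.columns):
        raise ValueError(f"intervals need columns {sorted(required)}")
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("interval end must be > start")
    df = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score"):
        if extra in df.columns:
            cols.append(extra)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_intervals_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    return df
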