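"""balscan: RAD-seq genome scan for balancing and diversifying selection.

Detects genomic regions with elevated haplotype diversity (kernel-smoothed
pi / H_e windows with bootstrap significance), reduced or elevated
differentiation (AMOVA F_ST window tails), and intermediate allele
frequencies (sliding-window Tajima's D), and tests whether a candidate gene
class is enriched in the elevated-diversity windows.
"""

from .io_formats import (
    FormatError,
    GeneAnnotation,
    HaplotypeMatrix,
    SnpTable,
    read_gff3_genes,
    read_haplotype_table,
    read_vcf_snps,
)
from .popgen import (
    filter_loci_by_presence,
    ibd_regression,
    locus_amova_fst,
    locus_gene_diversity,
    locus_observed_het,
    locus_pi,
    locus_stats_table,
    pairwise_population_fst,
    tajima_constants,
    tajima_d,
)
from .scan import (
    bootstrap_window_pvalues,
    interval_overlap,
    merge_windows_to_regions,
    quantile_windows,
    single_locus_outliers,
    sliding_tajima_d,
    smooth_statistic,
    top_d_windows,
)
from .enrichment import (
    enrichment_permutation_test,
    gene_counts_per_window,
    shared_candidates,
)
from .pipeline import GroupRun, PipelineResult, ScanConfig, report_summary, run_pipeline
from .simulate import (
    GroupSpec,
    PlantedRegion,
    SimConfig,
    SimulatedDataset,
    assign_gene_classes,
    simulate_dataset,
    simulate_locus,
    write_dataset,
)

__version__ = "0.1.0"
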