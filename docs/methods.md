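# Methods

## Scope and model

`balscan` implements a haplotype-level genome scan for balancing and
diversifying selection in RAD-seq data. The working unit is the RAD locus: a
short sequence tag (default 92 bp) genotyped as an unordered pair of
haplotype alleles per diploid individual, with whole-locus missingness per
(individual, locus). Haplotypes are used as multi-allelic alleles because
highly polymorphic targets of balancing selection carry several linked SNPs
within a tag; SNP-by-SNP analysis dilutes that signal.

Three signatures are scanned, each with its own machinery:

1. **Elevated diversity**: per-locus π and H_e, Gaussian-kernel smoothed in
   windows centred on polymorphic loci, tested by bootstrap against the
   genome-wide locus pool.
2. **Differentiation extremes**: per-locus AMOVA F_ST smoothed in the same
   windows; the bottom 5% tail suggests balancing selection (allele sharing
   across populations), the top 5% geographically diversifying selection.
   Selection is by empirical quantile, not bootstrap, because the hypothesis
   concerns the tails of the distribution itself.
3. **Intermediate frequencies**: Tajima's D from individual SNPs in a fixed
   window grid (it cannot be computed from collapsed haplotype calls),
   taking the top 5% of windows.

Windows carrying more than one signature, and candidate-class gene content
of the merged regions, are the scan's product.

## Estimators and conventions

- π sums Hamming distances over all unordered pairs of the 2n sampled
  sequences and divides by C(2n, 2) and the locus length. No additional
  n/(n−1) correction is applied — this is the plain pairwise definition;
  whether an extra sample-size correction should be applied at the haplotype
  level is genuinely ambiguous in the literature, so the divisor is the pair
  count and nothing else.
- H_e uses the unbiased correction (2n/(2n−1))(1 − Σp²). The correction is a
  keyword argument (`unbiased=False` gives the plug-in form) because
  different published pipelines disagree; the default is the unbiased form.
- AMOVA F_ST treats haplotypes as unordered alleles (frequency-based
  variance components, equivalent to Weir–Cockerham θ for allelic data),
  not the sequence-distance Φ_ST. Negative estimates are reported unclipped;
  clipping is a presentation decision left to consumers. Multi-locus
  pairwise F_ST is the ratio of summed per-locus components (not the mean of
  per-locus ratios, which is biased low).
- Tajima's D with missing data: S and π̂ accumulate per site over the
  non-missing sequences; the constants use n = the rounded median per-site
  non-missing count, and windows with heterogeneous per-site n carry a flag.
  The window grid is anchored at coordinate 0 (the anchor is otherwise
  arbitrary and is stated so results are reproducible). Windows with S = 0
  are kept in the grid but flagged not estimable and excluded from quantile
  denominators.
- Presence filtering retains loci genotyped in ≥ ceil((1 − f)·n_group)
  members (f = 0 or 0.5 in the standard run matrix), matching the
  "present in at least 50% of individuals" convention, e.g. 9 of 17.
- Quantile selections use nearest-rank thresholds with ties included, except
  the top-D selection whose size is fixed at round-half-up(q · n_estimable)
  with boundary ties resolved in genomic order — this makes reported
  overlap percentages exactly reproducible from the counts.
- Coordinates are 0-based half-open everywhere internally; GFF3 (1-based
  inclusive) and VCF positions are converted at the I/O boundary only. BED
  output is 0-based half-open. Gene-in-window assignment uses any interval
  overlap with the window's ±σ interval, strand-ignored; a gene spanning
  two windows counts in both.

## Smoothing and bootstrap

A window centred on polymorphic locus c spans 3σ either side; contributing
loci are weighted w = exp(−d²/2σ²) (weight 1 at the centre, e^{−1/2} at σ,
truncated at 3σ). The smoothed value is the weighted mean, hence always a
convex combination of the contributing per-locus values. Optional weighting
of loci by allele-count information, present in some implementations of this
smoothing, is deliberately omitted (all loci weigh equally apart from the
kernel); a hook would be straightforward but unweighted matches the default
behaviour expected here. σ is always explicit in configuration; a helper
(`sigma_for_target_loci`) suggests σ so a window holds ~30 loci on average,
which is how window sizes are chosen in practice (150 kbp for sparse selfing
data, 60 kbp for denser outcrossing data).

Bootstrap significance: each pseudoreplicate redraws the window's m locus
values with replacement from the genome-wide pool and applies the same
weight vector; p = (1 + #{pseudoreplicate ≥ observed})/(reps + 1), with an
add-one correction so p is never 0, and a relative tolerance of 1e-9 when
comparing so a degenerate constant pool yields p = 1 exactly. The default is
10,000 pseudoreplicates (the reference procedure used 1,000,000; the p-value
granularity of 1e-4 is ample for an α = 0.05 screen and the setting is
configurable).

Two properties of this design worth knowing:

- Windows are centred on *polymorphic* loci but pseudoreplicates draw from
  the pool of *all* loci (including monomorphic ones, as the genome-wide
  average should). The centre carries the largest kernel weight, so observed
  windows are slightly enriched for non-zero values relative to the null
  draws; on null simulations the significant fraction at α = 0.05 comes out
  near 0.06–0.07 rather than exactly 0.05. This mild anti-conservativeness
  is inherent to centring windows on polymorphic loci and is shared by the
  reference design; it is irrelevant once planted signal exists (see
  calibration below).
- Because adjacent windows share loci, their p-values are strongly
  correlated; uniformity of null p-values is therefore asserted on windows
  spaced > 6σ apart (disjoint support), where they are independent.

Significant windows (p < α for H_e or π) are reported in three mutually
exclusive categories — H_e only, π only, both — which must sum to the total
(asserted, not just reported). Windows with centres < σ apart merge into
regions spanning [first centre − σ, last centre + σ], clipped to chromosome
bounds; merging is idempotent. The merge criterion is centre distance: the
verbal rule "windows overlapped, i.e. separated by less than σ" is
internally inconsistent for 6σ-wide windows, and the centre-distance
reading is the one that reproduces sensible region sizes.

## Enrichment test

Each smoothed window is the interval centre ± σ. The observed statistic is
the difference in mean candidate-gene count between significant and
non-significant windows; the window labels are permuted without replacement
1000 times (configurable) for the null. The p-value uses ≥ with an add-one
correction — a strict > without the correction produces p = 0 pathologies
on degenerate data. When C(n_windows, n_high) ≤ 100,000 the null is
enumerated exhaustively and the p-value is the exact proportion over all
labelings.

**Known limitation**: the permutation null assumes window exchangeability.
Overlapping windows share genes, so when the "high" label forms long
contiguous blocks the true null variance of the observed difference exceeds
the permutation variance and the test is anti-conservative (measured
rejection ~0.2 at α = 0.05 in a worst-case contiguous-block simulation).
This is a property of the window-label randomisation design itself, which
follows the published procedure. The calibration suite therefore validates
the test under its own exchangeable null (uniform-rate class assignment and
uninformative labels), where it is exact; enrichment p-values on real scans
should be read as descriptive strength-of-association measures, with block
permutation a possible future hardening.

## Synthetic data generator

The generator is genealogy-free and built for planted-truth recovery, not
demographic realism:

- Loci are placed at exponentially distributed spacings (mean 12 kbp) along
  each chromosome; each locus gets a Poisson number of polymorphic sites.
- Site frequency spectra by mode: `neutral` P(k) ∝ 1/k (the neutral SFS,
  giving E[π] = θ exactly under the calibration below), `intermediate`
  derived frequencies from a Beta(20, 20) pushed through a binomial (D > 0
  in expectation), `rare` low-frequency variants only (D < 0). The Poisson
  mean is set to θ·L / E[per-site diversity under the mode], so expected
  pairwise diversity per bp equals θ in every mode.
- Sites are realized on a pool of 200 ancestral haplotypes; the distinct
  haplotypes become the locus's alleles. Each population draws its
  haplotype-frequency vector from a multiallelic Balding–Nichols model,
  Dirichlet(q_anc (1 − F)/F) with F = `structure_fst`. Divergence is applied
  to whole-haplotype frequencies rather than independently per site: per-site
  independent divergence makes haplotype-level F_ST systematically lower
  than the parameter (a product-of-frequencies artefact), whereas the
  Dirichlet form recovers F at both the haplotype and the site level (any
  sum of Dirichlet components is itself Balding–Nichols distributed).
- Individuals draw two haplotypes from their population's frequencies; with
  probability `inbreeding_F` the second is identical by descent, so
  F = 1 gives H_o = 0 at every locus. Missingness is whole-locus Bernoulli
  per (individual, locus) — matching RAD presence/absence — with no
  within-locus partial missingness.
- Planted regions modulate loci whose start coordinate falls inside them:
  θ × diversity_multiplier, F × fst_multiplier, and the region's frequency
  mode. Genes are tiled uniformly (2 kbp every 10 kbp); candidate-class
  labels are assigned at `p_in` for genes whose midpoint lies in a planted
  region and `p_out` elsewhere, with an unenriched control class at the
  uniform rate `p_out`.
- All randomness flows from one seed through per-chromosome spawned
  substreams; identical configs give byte-identical outputs.

Defaults are the validation study conditions: 4 × 5 Mbp chromosomes, 92-bp
loci every ~12 kbp, background θ = 0.005/bp (typical RAD-scale diversity for
a selfing-outcrossing crucifer system), among-population F_ST = 0.1, a
selfing group (5 populations × 4, F = 0.9) and an outcrossing group
(8 × 4, F = 0), 20% missingness, and one 500-kbp planted region per
chromosome (10% of the genome) with 5× diversity, halved F_ST and
intermediate frequencies; candidate genes at 0.3 inside vs 0.05 outside.

What the generator does **not** emulate: linkage and recombination within
and between loci (sites are exchangeable given the haplotype pool),
coalescent genealogies and demographic history, selection acting on
sequences, reference-alignment artefacts, and allele dropout correlated with
divergence. Passing the validation suite therefore shows that the scan
recovers the *statistical* signatures it targets at realistic magnitudes
and noise levels — not that those signatures are unconfounded in real data,
where demography and hidden structure can mimic them (the reason D is
computed within geographic subgroups in practice).

## Validation suite and problem sizes

The acceptance tests (and `scripts/acceptance.py`) use these deliberately
desk-scale sizes:

- Estimator-oracle equivalence: 40 random loci per estimator with ≤ 6
  individuals, agreement to 1e-9 against brute-force pair enumeration
  (π, H_e, H_o), a distance-matrix AMOVA decomposition (F_ST), and
  exact-rational-arithmetic constants (D).
- Null calibration: 10 null genomes (1 × 12 Mbp, ~1000 loci each), bootstrap
  at 2000 reps for the significant fraction (compared at 3 between-seed
  Monte-Carlo standard errors) and 10,000 reps on >6σ-spaced windows for the
  99% Kolmogorov band; enrichment type-I over 400 exchangeable-null datasets
  at 1000 permutations.
- Planted recovery: 10 replicate default genomes (20 Mbp, 10% planted at
  5×, σ = 60 kbp ≈ 30 loci/window): ≥ 80% of regions hit, ≤ 10% of
  significant windows outside planted regions, seed-averaged.
- Enrichment power: 50 replicate single-chromosome genomes, p_in = 0.3 vs
  p_out = 0.05: p < 0.05 in ≥ 90%.
- Directionality: whole-genome `intermediate` / `rare` modes give mean
  sliding-window D > 0 / < 0; complete selfing gives H_o = 0 everywhere.

The whole suite runs in under two minutes on one CPU; the acceptance script
in about one.
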