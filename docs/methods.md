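# Methods

This note documents the models, numerical choices and simulation conventions
behind `cfnano`, and what the synthetic-data tests do and do not demonstrate
about real plasma sequencing data.

## Methylation deconvolution

An observed plasma methylome is summarised as a vector Y of per-probe beta
values (methylated reads / total reads, in [0, 1]).  Given a reference atlas
X — a probes × cell-types matrix of beta values for purified cell
populations — cell-type abundances are estimated by non-negative least
squares:

    b* = argmin_b ||X b − Y||₂   subject to   b ≥ 0

with reported fractions b*/Σb*.  The normalisation is needed because plain
NNLS coefficients are not constrained to the simplex; dividing by their sum
re-expresses them as proportions.  The fit is restricted to marker probes
and is complete-case: a probe with a missing value in the sample or in any
atlas column is dropped from that fit (an error is raised when fewer probes
than components remain).

**Marker selection** is one-vs-rest: for target cell type t, probes are
ranked by the margin `beta_t − mean(beta_others)`, descending for
hypermethylated markers and ascending for hypomethylated ones, taking the
top `n_each` (default 1000) of each with a lexicographic probe-id
tie-break.  The margin statistic is deliberately simple and is isolated
behind `select_markers` so a different ranking can be substituted without
touching the fit.

**Two-component deconvolution** collapses the system to two columns: the
mean methylome of a target tissue (X̄₁, e.g. lung epithelium, averaged over
replicate reference samples with at least 2 valid values per probe) and the
mean healthy-plasma methylome (X̄₂).  NNLS yields coefficients β₁, β₂ and
the tissue fraction is β₁/(β₁+β₂).  When both coefficients are zero the
fraction is undefined and reported as NaN with a warning — never as 0,
which would silently read as "no tumor".  Fits on fewer than 10 shared
probes are refused; fits below 330 probes (the smallest count seen in
practice for a 0.1–0.2× genome-coverage sample) warn.

**Purity correction.**  Bulk tumor reference methylomes are contaminated by
leukocytes.  With known purity β and leukocyte methylation M_l, the pure
cancer methylation is recovered by inverting the two-population mixing
equation M_m = M_c·β + M_l·(1−β):

    M_c = (M_m − M_l (1 − β)) / β,   clipped to [0, 1].

The clip is the only non-algebraic step; it matters when measurement noise
pushes the solution outside the beta range.

**Differential CpG selection** between (purity-corrected) tumors and
healthy plasma uses a per-probe Welch t-test (the groups' variances differ
systematically), Benjamini–Hochberg adjustment across all tested probes,
and keeps probes with q < 0.001, an absolute group-mean difference ≥ 0.3,
at least 2 valid values per group, and absence from an optional exclusion
set (used to keep CpG panels disjoint between analyses).

## File dialects and coverage downsampling

Per-CpG calls arrive in an 11-column stranded BED dialect in which the read
count is implicit: `n_reads = round(col5 × col10 / 1000)` and column 11 is
the percent of reads methylated.  Positions with zero confident reads are
dropped at parse time; a missing beta is always an absent record, never a
sentinel.  All coordinates are 0-based half-open.  Strand collapsing maps
the two Cs of a CpG (forward position p, reverse p+1) onto one array probe:
per-strand methylated counts are reconstructed as `round(beta × n_reads)`
(the file stores a percentage; counts must be integral to resample) and the
probe beta is the summed methylated count over the summed total.

Downsampling to a target mean genomic coverage treats every read at every
CpG as one observation and draws `k = round(coverage × n_cpgs_genome)`
observations **without replacement** (a multivariate hypergeometric draw
over the per-CpG methylated/unmethylated pools; the genome-wide CpG count
defaults to 28,217,005).  Sampling without replacement models subsampling a
fixed sequenced library; it makes the output observation count exact and
the genome-wide mean beta unbiased, both of which are asserted in tests.

## Regional methylation

**TFBS metaplots.**  CpGs within ±1 kb of site centers are pooled into
20-bp signed-distance bins; the per-bin mean beta is divided by the flank
mean — the mean over bins lying wholly in [−1000, −800] ∪ [800, 1000] bp —
to give a fold change that is 1 for flat signal.  Bins without CpGs are
missing, not zero.  Site strand is ignored (center-reference-point
convention).  20 bp resolves the ±200 bp hypomethylation dip characteristic
of occupied TFBS while keeping ≥ 10 CpGs per bin at realistic site counts.

**PMD hypomethylation.**  Partially methylated domains lose methylation
with cell division; the most labile CpGs are solo-WCGW (A/T–CG–A/T context,
no neighbouring CpG).  Each 10-Mbp bin overlapping a PMD is summarised as
the mean beta of its covered solo-WCGW CpGs minus the genome-wide mean beta
of **all** CpGs; negative deltas mean hypomethylation.  Bins with fewer
than 10 covered solo-WCGW CpGs (a stability floor for ~0.2× coverage data)
carry a missing delta.  Copy-number status per bin is the overlap-length-
weighted mean segment log2 ratio, called gain above +0.10 and loss below
−0.10; bins without segment overlap are NA.  Group comparisons use the
one-sided Wilcoxon rank-sum test (hypomethylation in cancer is the a-priori
direction).  A tumor-fraction estimate is floored to 0 when copy-number-
altered segments cover less than 15% of the genome, where segment-based
estimates are unstable.

## Fragmentomics

Fragment length is the sum of query-consuming CIGAR operations (M, I, =, X);
deletions and introns consume reference only, so a `50M2D50M` alignment is a
100-bp molecule.  Default filters: primary alignments only, MAPQ ≥ 20,
length ≤ 700 bp, no soft-clipping at either end, barcodes at both ends.
Summary statistics are the short-mononucleosome ratio (fragments 100–150 bp
over 100–220 bp, closed intervals) and the short-dinucleosome ratio
(275–325 over 275–400 bp); both rise when tumor-derived fragments shift the
length distribution shorter.

End motifs are the 4 reference bases at the fragment's 5′ end (end1 only —
end2 of a single-end Nanopore read can misrepresent the true fragment end;
reference bases avoid read-level base-calling errors).  Minus-strand
fragments read the reverse complement of [end−4, end) so the motif is the
molecule's own 5′ sequence; a flag switches to reference-forward reporting.
Motif tables always carry all 256 4-mers (zero-filled).  Differential motif
analysis compares per-sample frequencies (not pooled counts — samples, not
reads, are the replication unit) with a two-tailed Student t-test per motif
and BH adjustment across the 256 motifs.

## Nucleosome coverage profiles

Mononucleosome fragments (130–155 bp inclusive, duplicates by identical
(chrom, start, end, strand) collapsed) are piled up per base, binned at
10 bp, and normalised RPGC: every bin scaled by effective-genome-size /
total-covered-bases so the genome-wide mean is 1.  Under RPGC the mean
reference-point profile reads directly as fold change versus genome-average
coverage.  10 bp bins resolve the ~190-bp nucleosome phasing around CTCF
sites.  An optional BED mask excludes blacklisted regions.  Because a
fragment covers its whole protected span, single-nucleosome coverage is
plateau-shaped rather than peaked; metaplot extrema are therefore located
as excess-weighted centroids of contiguous above-/below-threshold runs
(`profile_extrema_centroids`), which recovers a symmetric plateau's center
to within one bin.

## Synthetic data: what it emulates and what it does not

All generators are deterministic given a seed and return ground truth
alongside their records.

* **Atlas**: each cell type owns planted hypo- (β≈0.1) and hyper- (β≈0.9)
  methylated marker probes on a 0.5 background with truncated Gaussian
  noise (sd 0.02).  The default 1000 markers per direction per type matches
  the marker scale used for real-atlas deconvolution.
* **Mixtures**: per probe, read depth is Poisson(coverage); each read comes
  from cell type k with probability w_k and is methylated with probability
  that type's probe beta.  Poisson depth (not fixed) exercises the
  low-coverage and downsampling paths.
* **PMD genome**: a bin with tumor copy number c has local tumor-DNA
  proportion p = c·tf / (c·tf + 2(1−tf)); solo-WCGW CpGs mix healthy
  (β=0.8) and tumor (β=0.4) PMD methylation at that proportion, with
  binomial read sampling.  Background CpGs (20 per solo-WCGW CpG, mirroring
  the real minority status of PMD solo-WCGW CpGs) hold the genome mean
  fixed at the healthy level, so the diploid-bin delta is tf·(β_tumor −
  β_healthy) up to the small drag the PMD bins themselves exert on the
  genome mean.  Matching segments carry log2((c·tf + 2(1−tf))/2).
* **Fragments**: lengths are a mono/di-nucleosome normal mixture per class
  — healthy modes 167/335 bp, tumor modes 147/305 bp (sd 12/25) — chosen to
  reproduce the qualitative tumor short-shift, not any printed value.  Each
  fragment's end motif is drawn from its class multinomial (CCCA 1.9%
  healthy vs 1.7% tumor, remaining mass uniform) and written into the
  synthetic reference so motif extraction re-derives it exactly on both
  strands.
* **CTCF coverage**: nucleosome-length fragments centered at site ±
  k·190 bp (k ≤ 5, Gaussian jitter sd 8 bp) over a uniform genome-wide
  background whose central ±80 bp is depleted at each site.
* **TFBS methylation**: CpGs every 20 bp across ±1 kb of each site; within
  ±200 bp the expected beta is the mixture (1−f)·β_bg + f·β_low.

Limitations: the generators model sampling noise only — no between-library
biological or technical variance, no GC or mappability bias, no base-caller
error profile, no batch effects.  Passing tests therefore demonstrate that
the estimators are correct and well-calibrated under their own model
assumptions (unbiased read sampling, known mixing mechanisms), not that
real plasma libraries meet those assumptions.  In real data, end-motif
frequencies in particular carry batch variance well above multinomial
noise, which can make single-motif rankings unstable across batches.

## Problem sizes

Test and acceptance runs use desk-scale problem sizes chosen to keep the
relevant estimator errors far from the asserted bounds: 12,000-probe ×
5-type atlases over 100 mixture replicates; 150 10-Mbp PMD bins (50 per
copy-number state) at 50 solo-WCGW CpGs/bin and Poisson-6 read depth;
20,000-fragment length mixtures; 2-million-fragment per-sample motif counts
(the library scale at which end-motif statistics stabilise); 30 CTCF-like
sites × 600 background fragments.  The genome-wide CpG constant is replaced
by a toy value only where a test needs an exact observation count.
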