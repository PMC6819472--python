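# Methods

## Scope and model of the data

`imprintseq` analyses allele-split sequencing data from reciprocal F1
hybrid mouse embryos. Its inputs are deliberately post-alignment:
peak/region files (BED), a minimal gene-model TSV, SNP tables, simplified
aligned reads carrying SNP-base observations and splice junctions
(SAM-lite TSV), allelic count matrices, per-CpG allelic methylation calls,
and repeat annotations. Read trimming, alignment to N-masked genomes and
peak calling are upstream concerns and out of scope. All coordinates are
0-based half-open throughout; chromosome names are taken verbatim from the
inputs.

## Allele assignment

A read is sorted against a SNP table (genome1 = B6, genome2 = CAST) by the
bases it shows at known discriminating positions: genome1 if **every**
informative observation matches genome1 and at least one SNP is
overlapped; symmetrically for genome2; otherwise unassigned. A base
matching neither genome is treated as a conflict (→ unassigned), not as a
missing observation — the conservative reading of a three-way sort.
Base qualities are not weighted: the synthetic reads are error-free, and
the contract here is the sorting logic, not the aligner.

The matDKO maternal genome is an admixture (~85% B6, ~15% 129). Two-pass
assignment first sorts against a B6/CAST table from which positions where
129 and CAST share the alternate base were excluded; reads left unassigned
are re-sorted against a 129/CAST table. 129 calls merge into the maternal
set; CAST calls from either pass form the paternal set (the handling of
second-pass CAST calls is an assumption — the merged-paternal choice keeps
the partition exhaustive). The scheme is idempotent on reads already
assigned in pass 1.

## Quantitation and filtering

Reads count once per region containing their **midpoint**; this keeps
counts additive across merged peaks and tiled windows and avoids double
counting at peak borders. RNA counting over genes is exon-restricted, and
counting over LTRs is strand-aware. Consensus peak sets merge overlapping
(≥ 1 bp) peaks from the two reciprocal crosses into union intervals.

A region is *informative* when maternal + paternal reads reach the assay
threshold — 20 for ChIP-type assays, 5 for RNA — in at least one
allelically mapped replicate of either reciprocal cross. Unassigned reads
never contribute.

Library-size correction uses median-of-ratios size factors with a
geometric-mean pseudo-reference, estimated on autosomal regions positive in
all samples; sex and mitochondrial regions are scaled but never used for
estimation. Display tracks are RPKM over running windows (1 kb width,
100 bp step by default), averaged across replicates; the optional
enrichment normalisation is the affine map anchoring the 40th percentile of
non-zero values at 0 and the 99th at 1, without clipping, so rank order and
relative enrichment are preserved. One deliberate exception: allelic
H3K27me3 comparisons across pre-implantation stages are summarised on raw
counts, because maternal and paternal H3K27me3 abundances genuinely differ
and library-size scaling would remove signal.

## The allelic-bias test

Null hypothesis: allelic proportion π = ½ per region.

* n = 1 replicate, or ρ = 0: two-sided exact binomial on pooled counts,
  two-sidedness by doubling the smaller tail, capped at 1.
* otherwise: beta-binomial likelihood ratio. ρ is a single
  method-of-moments estimate shared across regions — per-region replicate
  fractions have variance p(1−p)(ρ + (1−ρ)/n); the excess over the binomial
  expectation gives a moment estimate, combined across regions by a
  total-read-weighted mean and floored at 0. Replicates are grouped within
  a cross/assay family for this estimate: pooling reciprocal crosses would
  let strain effects (whose allelic fraction flips between crosses)
  masquerade as overdispersion. Under the alternative π is profiled by
  bounded scalar optimisation with ρ held fixed; 2·ΔlogL is referred to
  χ²(1).

Multiple testing: Benjamini–Hochberg within each (tissue, assay, cross)
family; significance at q < 0.05; direction from the sign of the pooled
fraction − ½. The pseudocount in log₂((pat+1)/(mat+1)) is display-only and
never enters testing. Under a simulated null (π = ½, ρ = 0.02, depth 100,
2 replicates, 10,000 regions) the raw-p rejection rate at 0.05 is ≈ 0.044.

## Classification

* **Reciprocal consensus** — significant in both crosses, same parental
  direction → imprinted (maternal/paternal); same strain direction →
  strain-specific (B6/CAST); exactly one cross → `single_cross_only`,
  excluded from consensus; neither → biallelic. Regions missing from a
  cross are `unresolved`, never silently dropped.
* **Canonical status** (imprinted regions only) — not significant in
  matDKO **and** matDKO allelic ratio in [0.35, 0.65] → canonical maternal.
  The ratio band is this package's addition to the bare non-significance
  rule: it prevents a low-power matDKO dataset from mimicking loss of
  imprinting. Still significant with the same parental direction →
  canonical paternal if the region overlaps a known paternal gDMR, else
  non-canonical. Regions uninformative in matDKO are `unresolved`.
  Maternal-direction non-canonical calls are emitted with a flag;
  downstream feature analyses use the paternal-direction set.
* **Gene assignment** — peaks overlapping a promoter window (TSS −1,000 /
  +500 bp, strand-oriented; configurable) report all overlapped promoter
  genes; otherwise the nearest gene within 10 kb (ties by distance, then
  gene id); otherwise none.
* **Expression cross-validation** — a gene validates its imprinted peak
  when at least one informative auxiliary dataset (H3K36me3 or RNA per
  cross) shows significant bias in the same parental direction; genes
  uninformative in every dataset leave the denominator.

## LTR promoter discovery

An ERVK LTR is an active promoter when, conjunctively: (a) it lies in an
H3K4me3 peak; (b) ≥ 5 same-strand reads overlap it in ≥ 2 replicates,
where each (sample, replicate) pair counts once and tissues/datasets pool;
(c) ≥ 1 junction read has its biological donor inside the LTR; and (d) no
junction read splices into the LTR from upstream on the transcript strand
(run-through transcription is not initiation; the upstream window is
unbounded). Junctions are stored genomically as (intron start, intron end);
the biological donor is the left coordinate on + transcripts and the right
on − transcripts. Unstranded LTR annotations are evaluated on both strands
and take the better-supported one, flagged. Active calls are typed chimera
when a junction links the LTR donor to an annotated exon of a same-strand
gene (lowest exon index in transcription order reported, typically exon 2),
else ncRNA. Allelic expression over active LTRs is strand-aware and
regions with < 5 SNP-spanning reads in every replicate are reported
uninformative.

## Feature statistics

Overlap predicate everywhere: ≥ 1 bp intersection. Enrichment between two
peak sets across feature catalogs uses Pearson chi-square without
continuity correction (df from the table shape; a Yates flag exists),
Bonferroni-corrected over features; rows with an expected cell < 1 carry a
warning flag. CpG density is CG-dinucleotide count / (length − 1), groups
compared by Welch t. TSS proximity categorises LTRs by the nearest TSS
(minimum boundary distance) into same-strand / opposing-strand within 3 kb
or beyond, compared to a background LTR set on the 2×3 table. The oocyte
chromatin-state association samples its background (N = 100 by default)
without replacement under a fixed seed. "Mappable" background LTRs are
approximated by the full catalog; mappability masks are out of scope.

## Methylation and DMR dynamics

Region methylation pools meth/total over CpGs within the region ± 500 bp
per allele; zero-coverage regions are missing, never 0. A DMR requires
both alleles covered (≥ 10 calls and ≥ 5 CpGs each), |Δlevel| ≥ 0.3 and a
two-sided Fisher exact p < 0.05 on the pooled (meth, unmeth) × allele
table. These thresholds are standard bisulfite-screen values, configurable;
region-level pooling (rather than per-CpG testing) matches the region-level
readout the classification needs. A *secondary imprint* is a maternal ExE
DMR at a region with both alleles < 0.25 in gametes and pre-implantation —
germline DMRs, methylated from the gamete onward, are excluded by
construction. Biallelic epiblast methylation ≥ 0.5 flags embryonic-lineage
silencing. The 0.25/0.5 trajectory cutoffs are package constants. Missing
stages suppress the affected flags (None) rather than defaulting.

## The synthetic-data generator

The generator emulates the study design end to end: three crosses
(B6/CAST, CAST/B6, matDKO/CAST), 2 ChIP and 3 RNA replicates, and peaks in
six planted classes. Defaults (chosen once as the desk-scale study
conditions): 3 autosomes × 10 Mb, 1,000 peaks (70% biallelic, 10% each
strain, 6% canonical-maternal, 1% canonical-paternal, 3% non-canonical),
SNP rate 1/150 bp, mean depth 100 per ChIP replicate (60 for RNA),
allelic π = 0.9, ρ = 0.02, 15% 129 admixture of the matDKO maternal
genome with half of in-segment B6/CAST SNPs sharing the CAST base with
129. Solo-LTR lengths are drawn around 417 ± 19 bp. Non-canonical peaks
each overlap exactly one ERVK solo LTR near a gene TSS (80% same-strand);
canonical peaks overlap simulated CGIs; half of the non-canonical LTRs are
active promoters, half of those chimeric onto exon 2 of their partner
gene. Three decoy transcription patterns are planted in biallelic peaks:
support in only one replicate of one cross, transcription without a donor
junction, and an upstream junction splicing into the LTR.

Counts are Poisson totals with a beta-binomial maternal split — the
simplest generative model with tunable overdispersion matching what the
test must absorb; the noise model of real allelic counts is unknown, so ρ
is a calibration knob, not a claim about the original data. In matDKO,
canonical-maternal peaks revert to π = ½; non-canonical and
canonical-paternal peaks retain their bias; strain effects behave as B6.
Methylation follows per-(stage, allele) level programs (non-canonical:
0.1/0.1 → 0.1/0.1 → epiblast 0.85/0.85, ExE 0.8/0.1; canonical gDMRs high
on the favored side from the gamete onward, ~0 maternal in matDKO), with
Binomial(coverage ≈ 30, m) calls per CpG.

Randomness is organised as one named stream per output kind derived from
the master seed (seed mixed with a CRC of the stream name), so adding an
output never perturbs existing ones and identical configs give
byte-identical data.

What the simulation does **not** emulate: base-level sequence error, GC
and fragment-length bias, mappability structure, per-region dispersion
heterogeneity, and correlated replicates. Passing tests therefore
demonstrate the correctness of the inference logic under the declared
generative model, not performance on real embryo data.

## Numerical choices and degenerate inputs

* Two-sided exact binomial: double the smaller tail, cap at 1 — exactly
  the enumeration oracle, to ≤ 1e−12 on totals ≤ 60.
* LRT optimisation: bounded scalar search for π in [1e−6, 1−1e−6] with
  xatol 1e−8; the alternative log-likelihood is floored at the null's so
  the statistic is never negative.
* Percentiles: linear-interpolation quantiles over non-zero values; a
  track whose anchors coincide raises rather than emitting NaNs.
* Zero-variance t tests: equal means → p = 1; unequal → p = 0 with a
  warning.
* Regions with zero allelic reads in all replicates are reported untested;
  zero-coverage methylation is missing, not 0.
* Size factors fall back to total-count ratios (with a warning) when no
  region is positive in all samples.

## Problem sizes

The default test suite and the acceptance script run the full study at
1,000 peaks with 10,000-region null calibration; the whole pipeline
completes in well under a minute on one CPU, a scale chosen to make the
end-to-end recovery properties (sensitivity/precision ≥ 0.9, exact decoy
rejection, complete DMR recovery) statistically comfortable while staying
desk-sized.

## Known limitations

* The bias test re-implements the decision boundary of the original
  count-model package (q < 0.05) as an exact-binomial / beta-binomial LRT;
  per-region empirical-Bayes dispersion shrinkage and TMM normalisation are
  deliberately out of scope.
* The BH family definition (per cross × assay × tissue) and the midpoint
  counting rule are this package's contracts where the field's practice
  varies.
* Feature fractions count regions, not base pairs.
* matDKO canonical/non-canonical resolution requires matDKO-informative
  coverage; otherwise regions stay `unresolved` rather than guessing.
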