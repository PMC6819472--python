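# imprintseq

Allele-specific imprinting analysis for reciprocal hybrid mouse embryo
sequencing data.

## The problem

Genomic imprinting — parent-of-origin-dependent mono-allelic activity — can
be read out from F1 hybrids of divergent mouse strains (e.g. C57BL/6 ×
CAST/EiJ), where strain SNPs let each sequencing read be attributed to the
maternal or paternal allele. Two confounds make the analysis non-trivial:

1. **Strain vs parent-of-origin effects.** A region biased toward the B6
   allele may reflect a *cis* strain effect, not imprinting. Reciprocal
   crosses (B6/CAST and CAST/B6, mother listed first) separate the two: a
   strain effect stays on the same strain in both orientations, an imprint
   stays on the same parental allele.
2. **Canonical vs non-canonical mechanism.** Canonical imprints depend on a
   germline differentially methylated region (gDMR) inherited from the
   oocyte; they vanish in offspring of *Dnmt3a/b*-deficient oocytes
   (matDKO/CAST). Non-canonical imprints — driven by oocyte H3K27me3 and, in
   extra-embryonic tissue, later maintained by secondary DMRs at solo ERVK
   LTR elements — survive the matDKO contrast.

`imprintseq` implements the full inference chain: SNP-based read sorting
(including a two-pass scheme for the matDKO maternal genome, an ~85% B6 /
15% 129 admixture), allelic quantitation and informativeness filtering,
beta-binomial allelic-bias testing with Benjamini–Hochberg correction,
reciprocal-cross + matDKO classification, ERVK-LTR promoter discovery from
spliced RNA evidence (with chimeric-mRNA vs ncRNA typing), genomic-feature
enrichment statistics, and allele-resolved methylation/DMR dynamics. A
synthetic-data generator plants a known truth table so every stage is
testable end to end without external data.

## The statistical core

For a region with replicate maternal/paternal counts (mᵢ, nᵢ) the null is a
balanced allelic proportion π = ½. With one replicate (or ρ = 0) the test is
a two-sided exact binomial on pooled counts (doubling the smaller tail).
With replicates, counts are modelled as beta-binomial,

  mᵢ ~ BetaBinomial(nᵢ, π, ρ),

with a single method-of-moments intraclass correlation ρ shared across
regions, and π is profiled in a likelihood-ratio test referred to χ²(1).
Regions significant (BH q < 0.05) in **both** reciprocal crosses with a
consistent parental direction are imprinted; a switched direction marks a
strain effect. Imprinted regions that lose their bias in matDKO/CAST
(non-significant *and* allelic ratio within [0.35, 0.65]) are canonical
maternal; retained bias marks canonical paternal (known paternal-gDMR
overlap) or non-canonical imprints.

## Worked example

```python
import imprintseq as iq

cfg = iq.SimConfig(seed=1, n_chrom=2, chrom_length=5_000_000, n_peaks=200)
data, truth = iq.simulate_study(cfg)
bundle = iq.run_pipeline(data, iq.PipelineConfig(seed=1))
print(bundle.summary)
```

prints (abridged):

```
n_peaks_total: 200, n_informative: 200
consensus_class_counts: {biallelic: 130, strain_B6: 20, strain_CAST: 20,
                         imprinted_maternal: 12, imprinted_paternal: 8,
                         single_cross_only: 10}
canonical_status_counts: {canonical_maternal: 12, canonical_paternal: 2,
                          non_canonical: 6}
expression_validation_fraction: 1.0
n_active_ltr_promoters: 3
rho: 0.0158
```

The simulation planted 140 biallelic, 40 strain-specific and 20 imprinted
peaks; the pipeline recovers all 20 imprints with the correct mechanism
(12 canonical maternal, 2 canonical paternal, 6 non-canonical), estimates
the replicate overdispersion near its generative value (ρ = 0.0158 vs 0.02
planted), validates every informative imprinted peak against allelic
expression of its assigned gene, and calls exactly the 3 planted
transcriptionally active LTR promoters. The 10 `single_cross_only` regions
are truly biallelic peaks significant in only one cross — they are excluded
from the consensus rather than mislabelled. Scoring against the truth
table (`iq.pipeline.score_against_truth`) gives macro sensitivity 0.982 and
macro precision 1.0.

The same workflow is available from the shell:

```bash
imprintseq simulate --seed 1 --out study/
imprintseq run-all --indir study/ --out results/ --seed 1
```

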