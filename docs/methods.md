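# Methods

## The statistical pipeline

pathfuse scores the association between biological pathways and a
case-control phenotype by combining two independent evidence sources per
gene — genotype association and differential expression — and testing
pathways against a gene-resampling null.

**Part I — gene scores from genotypes.** Each SNP passing quality control is
tested with the Cochran–Armitage trend test (additive scores 0/1/2 on
minor-allele dosage; two-sided p from the χ²₁ tail of Z²). SNPs are mapped
to every gene whose body ±50 kb contains them (1-based inclusive window;
a SNP may map to several genes). To avoid over-counting redundant SNPs in
strong LD, a greedy tagger selects tagSNPs per gene against an external
haplotype reference panel: repeatedly pick the SNP covering (r² ≥ 0.8) the
most uncovered SNPs; ties break by genomic position then id; SNPs missing
from the panel, or monomorphic in it, tag themselves. On a phased panel r²
is the haplotype-frequency measure D²/(pA·pa·pB·pb) (equivalently the
squared Pearson correlation of the 0/1 haplotype indicators); unphased
panels fall back to the squared composite dosage correlation, without EM
phasing. The gene-wise association value P_i1 is the smallest trend p over
the gene's tagSNPs; genes with no mapped SNP are absent from the analysis
rather than imputed.

**Part II — gene scores from expression.** The module consumes an
already-normalized intensity matrix (array normalization is a separate,
upstream concern). Probe-level matrices are first collapsed to genes
(per-sample median by default; mean and strongest-probe rules available).
Each gene then gets a two-sided two-sample t-test p-value P_i2 comparing
cases and controls — equal-variance Student by default, Welch optional.
Degenerate rows (zero variance in both groups) yield p = 1 when the group
means agree, the smallest positive float when they differ; both are flagged.

**Part III — integration and pathway inference.** Genes carrying both
scores are combined by Fisher's method,

    g_i = −2·(ln P_i1 + ln P_i2),   P_i = Pr(χ²₄ > g_i),

the natural log being required for the χ² tail to be exact. Inputs are
clamped to [1e-300, 1] so that degenerate zeros stay finite and ordered.
A pathway's score over any gene p-value column is S = −2·Σ ln p across its
scored members. Significance comes from a permutation null that preserves
the number of scored genes: each of n_perm replicates draws that many genes
without replacement from the non-redundant union of scored genes across all
size-filtered pathways (5–200 members on full membership) and recomputes
S_random. The permutation p-value counts replicates with S_random strictly
greater than S_true, divided by n_perm — the strict rule, which is the only
counting consistent with reporting exact zeros for extreme pathways; a
+1-corrected conservative rule is available for users who want strictly
positive p-values. Benjamini–Hochberg step-up q-values (Storey's fixed-λ =
0.5 estimator optional) are thresholded at q < 0.05. The three modes —
gwas (P_i1), expression (P_i2), integrated (P_i) — run over the same
pathway collection, and the comparison reports their significant sets, all
intersections, and the integrated-only ("novel") pathways.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 50,000 | SNP→gene mapping flank, bp |
| `r2_threshold` | 0.8 | tagSNP coverage threshold |
| `maf_min` | 0.01 | QC: minimum minor-allele frequency |
| `hwe_p_min` | 0.001 | QC: minimum Hardy–Weinberg p (controls only by default) |
| `call_rate_min` | 0.25 | QC: minimum per-SNP call rate (set 0.95 for conventional QC) |
| `min/max_pathway_genes` | 5 / 200 | pathway size filter |
| `n_perm` | 100,000 | permutation replicates per pathway |
| `q_threshold` | 0.05 | FDR significance cutoff |

The unusual 0.25 call-rate default follows the analysis convention this
pipeline reproduces; it is exposed so users can tighten it.

Reproducibility: each pathway's permutation stream is an independent RNG
substream derived from (seed, CRC-32 of the pathway id), so results are
identical regardless of pathway evaluation order or `n_workers`.

## The synthetic study generator

Real inputs of this design — restricted consortium genotypes, public
expression series, a pathway database snapshot — are not redistributable,
so a generator produces complete study bundles with known ground truth.

*Genotypes.* Each gene is an LD block: one minor-allele frequency drawn
from `maf_range` (default U(0.05, 0.5)) is shared by its 3–8 SNPs, and
haplotypes follow a founder-copying scheme — a founder allele ~ Bernoulli(p)
per haplotype, copied by each SNP with probability √ρ, otherwise replaced
by an independent Bernoulli(p) draw. Marginals stay Bernoulli(p) and every
within-gene pair has allele correlation exactly ρ (`ld_block_rho`, default
0.8), i.e. panel r² = ρ². A thresholded latent-Gaussian AR(1) was
considered and rejected: with independently drawn MAFs the attainable
correlation between two thresholded binaries is hard-capped well below the
tagging threshold, and the AR decay leaves distant pairs untaggable, so no
setting of a single AR parameter can produce bona-fide high-LD blocks.
Disease status follows a logistic model with per-allele log-odds
ln(`genotype_odds_ratio`) at one causal SNP per causal gene (10% of genes
by default); cases and controls are sampled retrospectively by status from
a generated pool, matching the case-control design. The reference panel
(500 individuals, phased) is drawn independently from the same process.
Missing genotypes are injected at 1% so the call-rate QC path is exercised.

*Expression.* Gene × sample Gaussian matrix (baseline N(8, 1) per gene,
noise sd 1.0); DE genes (10% by default) are shifted in cases by
`de_effect_size` × noise-sd. 70% of DE genes are also causal genes, so the
integrated analysis sees strictly more signal than either single source.
The default arm is 33 cases vs 20 controls, the pooled two-group design
typical of the synovial-biopsy microarray studies this emulates.

*Pathways.* 100 gene sets with sizes U(20, 80) — representative of a
curated pathway database after the 5–200 filter, scaled to the 500-gene
synthetic genome. Five are enriched: half their members (by default) come
from the planted causal ∪ DE genes, the rest uniformly from the remainder;
background pathways draw uniformly from all genes.

Default scale (500 cases / 500 controls, 500 genes, ~2,750 SNPs, 100
pathways) is the package's desk-scale analogue of a consortium-size study;
it keeps a 20-replicate power experiment at 10,000 permutations within a
few minutes on one CPU. What the generator does **not** emulate: population
structure and relatedness, genotyping batch effects, MAF-dependent LD
decay across genes, probe-level array artefacts, expression batch effects
across pooled series (the pipeline, like the design it reproduces,
performs no batch correction), and correlated expression between genes.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under a clean generative model, not robustness to those
real-data complications.

## Numerical choices and degenerate inputs

- Trend test: a genotype distribution with zero score variance (all samples
  in one dosage class) has no defined statistic; per-SNP batch testing
  returns NaN and such SNPs are excluded from tagging/min-p, while the
  scalar API raises.
- Hardy–Weinberg: 1-df χ² goodness-of-fit by default; the conditional
  exact test (heterozygote-count enumeration) behind a flag. Monomorphic
  SNPs return p = 1 with a flag (they are then removed by the MAF filter).
- Fisher combination: p = 0 inputs are clamped to 1e-300; combined p uses
  the survival function directly, never 1 − CDF.
- Permutation ties: S_random is compared with a relative tolerance of
  1e-9 so that exact replicas of the observed set (possible when the
  pathway exhausts the universe) count as ties, not exceedances.
- BH q-values use the standard step-up with enforced monotonicity; ties in
  p give equal q (stable mergesort ranking).
- The PLINK text reader re-derives the minor allele from the data (ties
  break lexicographically), so a simulated allele near MAF 0.5 may be
  re-coded on read; every downstream statistic is invariant to that flip.

## Design choices that were genuinely open

- HWE is tested in controls only (cases can deviate through true
  association); `hwe_in="all"` reverts to all samples.
- "t-test" is read as the equal-variance Student test; Welch is a flag.
- The permutation universe is the union of scored genes over the
  size-filtered pathways, not the whole gene catalogue.
- The FDR procedure is exposed (`bh` default, `storey` optional) rather
  than hard-coded, because published q-values in this analysis family do
  not always match textbook BH and the exact procedure is often unstated.
- Genes with a single evidence source stay in the gene table with flags
  but are excluded from integrated pathway scoring.

## Known limitations

- The greedy tagger approximates minimum tag cover (set cover is NP-hard);
  tests assert validity exactly and near-minimality (≤ optimum + 1) on
  small instances.
- Permutation p-values at n_perm replicates have granularity 1/n_perm;
  with the strict rule, extreme pathways report exactly 0. FDR conclusions
  at q < 0.05 over ~100–200 pathways need n_perm ≥ 10,000 to be stable.
- The χ² tail of the trend statistic is slightly conservative near p = 1
  for small samples (count discreteness); calibration checks use cohorts
  of ≥ 1,000 per arm.
- No population-structure correction (no genomic control, no PCs): the
  synthetic cohorts are homogeneous by construction.
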