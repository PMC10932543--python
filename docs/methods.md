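# Methods

## The three-stage plasticity framework

The pipeline analyses gene expression (TPM) measured at three stages of a
colonization event: the ancestral population in situ, ancestral individuals
acclimated to the novel condition (the plastic stage), and the colonized
population. Stage summaries are the arithmetic mean and the standard error
(sample SD / √n; defined as 0 and flagged when n = 1) of TPM per gene.

**Classification.** With plastic change PC = E_plastic − E_ancestral and
evolved change EC = E_colonized − E_plastic, a gene is classified when both
|PC| and |EC| exceed τ·E_ancestral (τ default 0.5): *reinforcement* when
sign(PC) = sign(EC), *reversion* when the signs oppose. Genes with
E_ancestral = 0 cannot be judged against a relative threshold; they are kept
in the output with an exclusion flag and counted. The magnitude is
M = min(|PC|, |EC|)/E_ancestral — the binding constraint, chosen so that a
gene in a magnitude category is guaranteed to exceed the category's lower
bound in **both** changes; no single canonical definition exists for
combining the two changes, and min is the conservative choice. Categories
are half-open intervals (b, b′] over boundaries (0.5, 1.0, 1.5, 2.0) with an
open top category, matching the strict ">" of the excess condition, so the
categories are disjoint and classified genes fall in exactly one. The
alternative binning scheme groups M into consecutive bins of width 0.2, 0.4
or 0.6 starting at τ.

**Excess tests.** Reversion-vs-reinforcement (and maladaptive-vs-adaptive)
imbalances are tested with the exact two-tailed binomial test in the
*minlike* convention: the p-value sums the probabilities of all outcomes
whose point probability does not exceed that of the observed count. The
null proportion defaults to 0.5 (no directional preference) and is
configurable, since "expected proportions" can be defined otherwise.

**Parametric bootstrap.** Stage means estimated from 3–7 individuals are
noisy, so each call is re-derived 1000 times from Gaussian draws
(mean = observed stage mean, sd = stage SE) and the replicate triple is
reclassified. Support counts replicates reproducing the gene's
point-estimate class (a "reproduces either class" mode is provided);
support ≥ 950/1000 marks the call as robust, an empirical p<0.05-style
guard. Gaussian draws may legitimately be negative; only an ancestral draw
≤ 0 invalidates the relative threshold, and such replicates are redrawn
wholly (bounded at 100 rounds; leftovers count against support). Each gene
owns an independent RNG substream keyed on (seed, CRC32(gene id)), so
results are reproducible and invariant to gene order.

## Regulators and adaptive/maladaptive plasticity

Phenotypes (e.g. capillaries per fiber, fiber area) are measured on the
ancestral and colonized individuals only, so gene–phenotype Pearson
correlations are computed over those samples. A gene significant at
p < 0.05 is a positive or negative regulator by the sign of r; genes
significant for several phenotypes with conflicting signs are reported per
phenotype, flagged, and summarized by the smallest-p phenotype. For a
regulator with an excess plastic change, the change is *adaptive* when its
direction matches the regulator sign expectation (up for positive, down for
negative regulators — the phenotypic shifts in the colonized population are
taken as beneficial) and *maladaptive* otherwise. No multiple-testing
correction is applied across genes by default, matching the raw-p
convention of this analysis style.

## Co-expression analysis

A deliberately simplified correlation-network stand-in for full WGCNA
(soft-threshold calibration, TOM similarity and dynamic tree cut are out of
scope): adjacency |r|^β (β default 6), dissimilarity 1 − adjacency,
average-linkage clustering cut at height 0.25, clusters below 30 genes
unassigned — all configurable, and small datasets typically need a lower β
or higher cut. Module eigengenes are the first principal component of the
per-gene z-scored submatrix, sign-fixed to correlate positively with the
module's mean profile (so they are invariant to gene order and per-gene
rescaling). Modules whose eigengene correlation has p < 0.1 are merged
iteratively (smallest p first, eigengenes recomputed); modules whose
eigengene–stage-code correlation has p < 0.01 are stage-associated. Hub
genes are members of stage-associated modules with gene significance
GS = |r(expression, stage code)| strictly above the first quartile of GS
(linear-interpolation quantile; the quartile population is the genes of the
stage-associated modules, configurable to all genes — the convention is
genuinely ambiguous) and correlation p < 0.05. Stage codes default to
0/1/2; a degree-5 polynomial regression cannot be identified on three stage
levels, so nonlinearity beyond the linear trend is left to the
reinforcement/reversion classifier, which is the purpose-built detector of
direction reversal here.

The conserved-gene batch check takes genes with CV ≤ 0.3 on log2(TPM+1)
across all samples and mean TPM ≥ 1 (the CV is per gene across samples;
genes silent everywhere are dropped to avoid division by zero) and compares
per-sample medians of those genes between stages with the two-sided
rank-sum test — a signed-rank test would require pairing, which unequal
group sizes (e.g. 4 vs 3) preclude.

## Population-genetic divergence

FST between the ancestral and colonized populations uses the Weir &
Cockerham (1984) two-population estimator: per-site variance components a
(among populations), b (among individuals within populations) and c (within
individuals), θ = a/(a+b+c), computed from per-population allele
frequencies, observed heterozygosity and per-site called sample sizes
(missing genotypes excluded per site). Sites monomorphic in the pooled
sample are undefined and excluded from averages. The headline average is
the ratio of sums Σa/Σ(a+b+c) — the "weighted" FST that vcftools prints —
with the mean of per-site ratios as an option. Validated against
hand-evaluated cases (fixed difference: a = 0.5, b = c = 0, θ = 1;
no divergence at p = 0.5, h = 0.5, n = 10: θ = −1/18) to 1e−12.

SNPs are read from VCF (biallelic SNPs; QUAL ≥ 30; INFO/MQ ≥ 20 when
present; minimum 5 bp spacing, keeping the first of any closer pair) and
assigned to gene bodies and strand-aware 2 kb upstream/downstream flanks
(BED input, 0-based half-open internally; VCF positions converted on read;
a SNP may hit several genes; the background is the deduplicated union of
all genes' genic + flank SNPs).

**Permutation test.** The empirical mean FST of a candidate set of N SNPs
is compared with 100 random draws from the background (candidates excluded
from the pool by default; an inclusive mode exists), each of size uniform
in [⌈0.95N⌉, ⌊1.05N⌋]. The reported p uses the add-one convention
(1 + #{permuted ≥ empirical})/(n_perm + 1) to avoid p = 0 at 100
permutations; the significance flag itself follows the percentile rule
(empirical > 95th percentile of the permuted values). Tests run separately
for genic, upstream and downstream SNP sets. A caveat established during
validation: when the candidate set is a sizeable fraction of the background
pool, permuted means concentrate around the pool mean with
finite-population-shrunk variance while the empirical mean keeps its full
sampling variance, and the percentile rule becomes anti-conservative
(measured ≈11% nominal-5% rate at candidate ≈ 15% of pool). The intended
regime — and the one the calibration test exercises (candidate ≈ 2% of an
8000-SNP background, where the rate is ≈5–6%) — is a background far larger
than any candidate set, as with a genome-wide genic background of ~17k
genes.

## Synthetic data

The generator plants known truth at the study's scale and design so every
stage is testable offline. Defaults: 1000 genes, 5 samples/stage (the
study used 3–5 individuals per stage and tissue), 10% reinforcement / 30%
reversion at magnitude 0.8, ancestral means log-uniform on 1–100 TPM,
multiplicative mean-one log-normal noise with CV 0.1 (TPM is positive and
right-skewed; no noise model is canonical, log-normal is the standard
choice), three phenotypes, 20% regulator genes, and a genotype block with
the study's 12 + 11 individuals, background divergence F = 0.05 and
candidate-flank divergence 0.4.

Reinforcement genes move μ → μ(1+m) → μ(1+2m); reversion genes move
μ → μ(1+m) → μ(1+m) − 1.5mμ, overshooting back past the ancestral value so
both changes clear the threshold (the 1.5 overshoot is configurable;
configurations whose colonized means would go negative are rejected).
Regulator genes additionally multiply their TPM by exp(±γ·u_s − γ²/2)
where u_s is a per-sample standard-normal latent factor and γ = 0.35: the
phenotype is then the coupling-weighted, sign-weighted sum of standardized
regulator expression over the phenotyped (ancestral + colonized) samples
plus Gaussian noise scaled to half the signal SD. The shared latent factor
is what makes individual regulator–phenotype correlations strong enough to
recover when regulators are many — with mutually independent regulators the
per-gene correlation against a sum of G terms decays as 1/√G and no sample
size in this design range would detect it.

Genotypes follow the Balding–Nichols model: per SNP, ancestral frequency
p ~ Uniform(0.05, 0.95), each population's frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, freq). Genes sit on
one pseudo-chromosome (3 kb bodies every 10 kb, random strand, 0-based
half-open BED); SNP positions are uniform; SNPs inside candidate genes'
2 kb flanks take the elevated F — gene bodies keep background F, mirroring
the study's finding that divergence concentrates in regulatory flanks. All
randomness derives from one config seed (module-specific child streams), so
whole-dataset generation is reproducible; outputs are plain text
(expression/sample-sheet/phenotype/truth TSV, VCF v4.2 GT-only, BED6,
population map).

What the generator does *not* emulate: count-level sampling noise
(negative-binomial dispersion), linkage disequilibrium between SNPs,
tissue-specific expression structure, batch effects, or read-level
artifacts — so passing tests demonstrate correctness of the statistical
machinery under the stated models, not robustness to those real-data
phenomena.

## Numerical and design choices

- Pearson p-values use the exact t-distribution with n−2 df throughout;
  zero-variance genes get GS = 0, p = 1 in gene significance and are
  excluded from regulator correlations.
- Permutation draws are index-sorted before summation so the degenerate
  candidate-set = background, fluctuation = 0 case reproduces the empirical
  value bit-exactly.
- Quantiles are linear-interpolation (numpy default, R type 7).
- Bootstrap support is counted for the point-estimate class specifically;
  certifying "some class" is weaker than certifying the reported class.
- Problem sizes in the test-suite simulations (e.g. 200 replicate datasets
  of 8000 SNPs for permutation calibration, 1000 genes for parameter
  recovery) were chosen to keep Monte-Carlo error well below the asserted
  margins while the full suite runs in well under a minute of compute for
  each simulation block.

## Limitations

- The classifier treats stage means as given; unequal per-stage variances
  enter only through the bootstrap, not the point classification.
- The co-expression stand-in is not WGCNA; module boundaries on real data
  will differ from the R package's dynamic tree cut.
- The permutation test assumes exchangeability of SNPs between candidate
  and background sets; systematic differences in allele-frequency spectra
  or local recombination would violate it.
- Two populations only for FST; the estimator generalizes to r > 2 but the
  implementation fixes r = 2.
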