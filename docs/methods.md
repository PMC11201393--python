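# Methods

## Somatic variant triage

A call is treated as somatic when it is present in tissue and absent from
the same participant's blood, where identity is the allele-aware 4-tuple
(chromosome, 1-based position, ref, alt). Position-only identity would
merge distinct alleles at a shared position; the allele-aware convention
keeps an A>C and an A>G at the same site separate, which is what a
SNV/insertion/deletion breakdown of unique loci requires.

Detection thresholds are inclusive minima: coverage ≥ 10 reads,
variant-supporting count ≥ 2, variant-allele frequency ≥ 2%, variant
quality ≥ Q60 (phred). "Minimum" language reads naturally as ≥, and the
boundary cases are covered by tests. The three filters downstream of
paired subtraction (quality, target restriction, blacklist) are pure
predicate filters, so they commute; the pipeline applies them in the
narrative order but no result depends on it. Frequency is recomputed from
count/coverage whenever both are present; a stated frequency deviating by
more than 0.5 percentage points triggers a validation warning rather than
silently trusting either number.

Target restriction converts the 1-based variant position to the BED file's
0-based half-open coordinates and queries per-chromosome interval trees.
A call on a chromosome absent from the BED is dropped with a logged
warning, not an error: panels routinely omit contigs.

Public germline databases are consumed as a local blacklist file of
(chrom, pos, ref, alt) rows. Live dbSNP/1000G/HapMap lookups would make
results a function of database version and network state; a pinned local
file keeps the run reproducible.

Cohort classification partitions observed unique loci: seen in ≥1 tumor
and no healthy sample → tumor-only; in ≥1 of each → shared; in no tumor →
healthy-only. The partition property is asserted on every run. The
mutation-status matrix marks a tumor sample as mutant for a gene only if
it carries ≥1 tumor-only *non-synonymous* SNV in that gene; synonymous
hits and variants shared with healthy skin never count, and a stop-gain
(`*` in the protein change) is always non-synonymous.

TMB is mutations per megabase of target (all somatic variant types:
SNV + INS + DEL). Reported group medians are rounded to the nearest
integer, half away from zero — the rounding that maps 148/1.7 → 87,
180.5/1.7 → 106 and 140/1.7 → 82. The substitution spectrum keeps all 12
uncollapsed ref>alt classes (C>T and G>A are reported separately rather
than strand-collapsed), computes per-sample percentages over SNVs only,
excludes zero-SNV samples, and summarizes with the cohort median and the
2.5/97.5 percentile band. Group location comparisons use the tie-corrected
Kruskal–Wallis test; if every pooled value is identical the statistic is 0
and p = 1 by convention (the rank test is undefined there).

## Expression model

Raw counts are scaled to counts per million within each sample and
transformed as log₂(CPM + 1). The +1 offset keeps zero counts at exactly 0
and is the only zero-handling device; no gene filtering is imposed.

Gene-level inference is a one-way fixed-effects (pooled-variance,
homoskedastic) linear model on the group factor `healthy` + K tumor
subgroups. Per subgroup: effect d_k = subgroup mean − healthy mean, with
variance s²(1/n_k + 1/n₀) from the pooled residual variance s²
(df = n − K − 1 per gene). Confidence intervals use the Student t
quantile on the log₂ scale and are transformed endpoint-wise through the
signed fold change FC(d) = 2^d for d ≥ 0, −2^(−d) for d < 0; endpoint-wise
transformation is what produces the asymmetric intervals characteristic of
ratio scales. The interaction test is the Wald F on the contrast "all
subgroup effects equal", which for a single response is algebraically the
nested-model ANOVA F (verified numerically in the tests to 1e-12); the
combined tumor-vs-healthy p comes from refitting with the subgroups
collapsed and equals the pooled two-sample t test exactly. A Welch
(unequal-variance) variant is deliberately not offered: the set-level
pooled machinery below has no clean Welch analogue, and one estimator
contract is easier to validate than two.

Multiplicity is handled by Benjamini–Hochberg step-up FDR (via
statsmodels) on the combined-model p-values; subgroup fold changes and
interaction p-values are then read for the selected genes. Differential
expression uses |signed FC| ≥ 3 and q ≤ 0.05, both inclusive.

## Gene-set ANOVA

For the model Y = μ + T + G + T×G + T×Mut + ε the estimator is
fixed-effects OLS saturated in gene × group cell means: every member gene
has its own means per group (absorbing G and T×G), the residual variance
is pooled over member genes with df = Σ_genes (n − #groups), and the
set-level effect per subgroup is the unweighted average over member genes
of the gene's (subgroup mean − healthy mean). Unweighted averaging — not
inverse-variance — is the contract, so a single-gene set reproduces the
gene-level fit exactly (a test asserts this to machine precision, along
with the averaging identity at 1e-10).

Because the healthy mean is shared across subgroup effects, the effect
vector's covariance is (s²/m)(diag(1/n_k) + J/n₀) for an m-gene set; the
T×Mut p-value is the Wald F of equal effects against that covariance. The
pooled residual df grows linearly in the number of member genes, so
interaction p-values at study scale reach the 10⁻¹⁷–10⁻⁸⁰ range for
modest effect differences. That is a property of the fixed-effects
estimator — member genes are treated as independent replicates and no
per-sample random effect absorbs inter-gene correlation — and such
p-values should be read as strong ordering evidence, not literal error
probabilities. A mixed model with a sample random effect would shrink
them; that estimator is out of scope here and the fixed-effects contract
is what the tests validate.

The exposure stratification splits tumor samples at UACR 192 µg/g
creatinine (≤ 192 → low, boundary inclusive) and crosses it with mutation
status to form four subgroups against the common healthy reference; any
empty subgroup is an error naming the subgroup, since a silently dropped
cell would change the meaning of the interaction test.

## Enrichment

Over-representation builds the 2×2 table (DE / not-DE × in / out of
category) over the background of all genes present in the expression
matrix — the only background the pipeline can defend — and applies the
1-df Pearson chi-square without continuity correction; the enrichment
score is −log₁₀(p) (base 10). When any expected cell is below 5 a warning
is emitted and Fisher's exact test is available behind a flag. Category
p-values are reported raw, without multiplicity adjustment, matching how
enrichment scores are conventionally displayed.

## Synthetic cohort generator

The generator emulates the targeted-panel study design: by default 26 BCC
+ 6 SCC tumor samples and 16 healthy-skin samples, each with a paired
blood sample; a 1.7 Mb panel laid out as 400 fixed-width gene intervals
with 10 kb gaps; Poisson(148) true somatic variants per sample (tumor and
healthy skin share the rate — sun-exposed healthy skin is comparably
mutated); Poisson(30) germline variants present in tissue *and* blood; a
50-locus public blacklist carried in tissue-only by each sample with
probability 0.4; 30 recurrent hotspot loci (each sample carries each with
probability 0.15) that populate the shared tumor/healthy category; and
Poisson(25) decoys per sample that each fail exactly one triage criterion
(quality < Q60, coverage < 10, frequency < 2%, or outside the target).
True variants are drawn passing every threshold, so triage recovers the
planted somatic set with zero errors — the end-to-end recovery test.

The SNV spectrum gives C>T and G>A each ct_fraction/2 of the probability
mass (default ct_fraction = 0.315, i.e. each ≈ 15.7% — an excess over the
uniform 1/12 ≈ 8.3%, matching a moderate UVR skew) and spreads the rest
uniformly over the other ten classes; 12% of variants are 1-bp
insertions/deletions. Non-synonymous status is assigned to 37.5% of
non-driver SNVs. Tumor samples are mutant for each driver gene
(PTCH1, NOTCH1, SYNE1, PKHD1, TP53) with gene-specific prevalences around
0.27–0.5 and then receive guaranteed non-synonymous driver SNVs; random
SNVs that happen to land in a driver gene are forced synonymous, so the
planted status matrix and the recoverable one coincide exactly. Reference
alleles are implied by the drawn substitution class rather than a stored
genome sequence; cross-sample collisions at the same position with
different implied references are possible in principle but operate on
allele-aware locus identity and are statistically negligible at panel
scale.

Expression counts are negative-binomial via gamma–Poisson: mean
2^(b_g + e_gs) × f_s with gene baselines b_g ~ U(4, 10) on the log₂
scale, per-sample library factors f_s ~ U(0.5, 2), dispersion 0.1
(variance μ + 0.1μ²), a standard bulk RNA-seq noise model. True effects
e_gs are zero except for genes in configured sets, whose per-subgroup
log₂ shifts default to the mutation-raises / exposure-damps pattern
(FC ≈ 4.0 / 6.9 / 1.3 / 3.0 across the mutation × exposure cells) plus an
unaffected null set. Because effects enter before CPM scaling, up-shifted
sets slightly depress the CPM of every other gene — the compositional
artifact real RNA-seq shares — so "null" genes show fold changes just
below 1 at study scale. The generator draws all randomness from a single
seed through a fixed SeedSequence spawn layout (cohort-level draws,
expression, then one child per sample), so adding samples never perturbs
earlier samples and a fixed seed reproduces byte-identical fixtures.

What the generator does not emulate: alignment and mapping artifacts,
strand bias, CC>TT dinucleotide UVR substitutions, copy-number events,
positionally clustered mutations, inter-gene expression correlation
within sets, and covariate structure (age, sex effects on expression).
Passing tests therefore demonstrate the correctness of the estimators
under the stated generative model, not robustness to those real-data
features.

## Problem sizes and numerical choices

The acceptance script and test suite use: the full default cohort
(32 + 16 samples, ≈ 180 variants/sample) for truth recovery; 100 genes /
100 random tables for the oracle-equivalence checks; 2000 null genes for
type-I error; 2000 replicates for null-uniformity (KS); 1000 replicates
of a 30-gene set at shifts 0.7 / 1.98 (σ = 1, n = 16/14/12) for CI
coverage; and 200 replicates for the stratified ordering recovery. These
sizes give binomial/KS resolution well inside the tested bands while the
whole suite runs in seconds.

Ties in ranked outputs (top mutated genes, enrichment ranking, gene-set
reports) break alphabetically for determinism. Zero residual variance
makes the interaction and combined p undefined; they are reported as
missing with a warning rather than as 0 or 1. Report tables are written
as TSV with fixed column order and a header comment carrying the package
version and a configuration hash (destination-independent), and a rerun
with identical inputs is byte-identical.
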