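# Methods

This note documents the models and procedures implemented in
`isocohort`, the parameters that matter, the design choices made where
the methodology was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Data model and conventions

Genotypes are dosages of `allele_b` (the VCF ALT allele): 0/1/2 with a
single reserved missing code (−1). Nothing imputes missing calls;
every operation states its missing-data rule. Coordinates are 1-based
inclusive internally; BED I/O converts losslessly to/from the 0-based
half-open convention. Chromosome labels are normalized by stripping a
leading `chr`. Gene symbols are upper-cased before set membership
queries.

## Population structure

*IBS distance.* For a pair of samples, IBS0/IBS1/IBS2 count markers at
which 0, 1 or 2 alleles are shared identical-by-state, over the N
markers called in both; the distance is 1 − (0.5·IBS1 + IBS2)/N, which
equals half the mean absolute dosage difference. A pair with N = 0 is an
error rather than a silent zero.

*Exact HWE test.* The two-sided mid-less exact test: conditional on the
allele counts, the probability of every attainable heterozygote count of
the right parity is computed by recurrence, and the p-value sums those
no more probable than observed (tolerance 1e−12 on the comparison).
Equivalent to full enumeration; verified against an independent
factorial-arithmetic oracle for all totals ≤ 50.

*Marker QC.* Applied in a fixed, reported order: call rate → MAF → HWE →
LD. Three shipped profiles reflect the two analysis regimes: `ancestry`
(call rate 1.00, HWE 1e−3, no MAF cut, no LD prune), `inbreeding` (0.95,
MAF 0.05, HWE 1e−6, LD r > 0.5) and `gwas` (0.90, MAF 0.05, HWE 1e−6).
LD pruning is greedy within sliding windows (default 50 SNPs, step 5) on
pairwise-complete Pearson correlation of dosages; within a window the
later marker of an offending pair is removed. Window/step values follow
common practice; the r > 0.5 cut is the analysis parameter.

*Classical MDS.* Torgerson scaling: double-centre the squared distance
matrix, eigendecompose, scale the top-k eigenvectors by the square root
of their (positive) eigenvalues. Eigenvector sign is fixed by making the
largest-magnitude loading positive, so coordinates are deterministic.
If fewer than k positive eigenvalues exist the embedding is truncated
with a warning.

*Exclusions.* For pairs with IBS similarity above 0.9 the member with
the lower call rate is flagged; at equal call rates the
lexicographically smaller id is retained (the tie-break is arbitrary but
deterministic). MDS outliers are flagged at robust z > 6 (median /
1.4826·MAD) on either of the first two components; the cut is exposed
because no principled universal value exists.

## Runs of homozygosity and inbreeding

A run is a maximal stretch of consecutive non-missing homozygous
genotypes. Parameters: minimum 50 consecutive homozygous SNPs; zero
heterozygotes tolerated; a minimum density of one SNP per 5000 kb of
span; no minimum length; a 1 Mb maximum inter-marker gap that splits
runs. Missing genotypes terminate a run — the conservative choice, so
no-call deserts can never masquerade as autozygosity; the gap rule
guards the same risk from the map side. Segment span is measured first
SNP to last SNP (map-independent and deterministic); flanking inter-SNP
intervals are excluded.

F_ROH divides the summed (merged) segment lengths by the SNP-spanned
autosome length — the sum over autosomes of (last SNP − first SNP + 1)
on the post-QC map. The spanned denominator (rather than physical
chromosome lengths) was chosen because it is computable from the data
alone and invariant to untyped telomeric stretches; the result record
carries the denominator so users can renormalize.

Pedigree-expected inbreeding uses the standard recursive kinship
algorithm; a child of second cousins gives F = 1/64 ≈ 0.016 and a child
of first cousins 1/16. Sibling values can be averaged per family before
group tests so large sibships do not dominate.

## Rare variants

Classification is total: stopgain/splice-site/frameshift → LGD; missense
with CADD ≥ 30 → MIS30; everything else (including unrecognized labels,
logged) → OTHER. The filter cascade is ordered site QC (missingness
≤ 10%, exact HWE p ≥ 1e−6) after genotype-level masking (GQ ≥ 30,
DP ≥ 10), then frequency rules: gnomAD MAF below the analysis threshold
(1% for the homozygous load, 5% for collapsing burden) and internal
control allele frequency ≤ 15%. The internal frequency uses control
allele frequency, not carrier fraction, keeping its semantics parallel
to the gnomAD MAF. Variants absent from gnomAD pass the MAF rule (that
is what the internal-control rule exists for).

The homozygous deleterious load counts qualifying homozygous-ALT
genotypes per sample; because "mutations per individual" and "genes per
individual" are both meaningful summaries, the profile carries the
per-variant count and the distinct-gene set, and downstream code chooses.
De novo calls require both parents called homozygous reference after
genotype QC; a hom-alt child of double hom-ref parents is counted by
default (rule-consistent though genotyping-error prone) and can be
disabled.

## CNVs

Array and exome calls pass through separate cascades applied in a fixed
order with per-step counts reported: array — ≥ 3 probes, > 1 kb,
detection score ≥ 15, merge score ≥ 30, ≥ 50 kb, segdup overlap ≤ 50%;
exome — QSOME ≥ 90, ≥ 5 targets, segdup overlap ≤ 50%. Segdup overlap
is the fraction of the call covered by the union of segdup intervals.
The dual-caller consensus step is reduced to a documented rule: same
sample, same type, reciprocal overlap ≥ 0.5 merge to the union interval
with the maximum score and summed probes.

Cohort frequency of a call is the fraction of reference samples carrying
≥ 1 same-type call with reciprocal overlap at or above the rule
threshold (80% for array-style comparisons, 50% for exome target-style);
a sample's own calls count toward its own carrier status, so a unique
call from a reference sample has frequency 1/n. Exome "target overlap"
falls back to base-pair reciprocal overlap when no target map is
supplied. Burden tests use rare calls only (frequency ≤ 1%), deletions
and duplications separately, one-sided Fisher on carrier counts, with
Bonferroni over the 12-test family (2 types × 6 gene categories)
reported alongside the nominal p.

## Statistics

*Fisher exact.* p by hypergeometric enumeration (two-sided: outcomes no
more probable than observed, relative tolerance ~1e−7). The odds ratio
is the conditional MLE — the value maximizing the noncentral
hypergeometric likelihood given all margins — because that is the
estimate tied to the exact test (for the 9/22/6/43 table it is 2.89
where the sample OR is 2.93). The 95% CI inverts the conditional test at
2.5% per tail; a zero margin yields p = 1 and an undefined OR. The
enumeration, conditional MLE and CI are delegated to scipy's
implementations; independent enumeration oracles in the tests keep the
check two-route.

*Adjusted Mann–Whitney.* "Adjusted" rank tests are not uniquely defined;
this package residualizes the response on the covariates by OLS
(intercept included, fitted jointly on both groups) and applies the
tie-corrected, continuity-corrected normal-approximation U test to the
residuals. This preserves the identity of the reported statistic (a U)
while honouring the covariate adjustment; its limitation is that
residualization is a linear operation, so only linear covariate effects
are removed. With no covariates it reduces exactly to the plain test.
Constant covariate columns are dropped (they are collinear with the
intercept and carry no adjustment information); a genuinely rank-
deficient covariate matrix is an error. Exact permutation is used only
as a test oracle (cost).

*GWAS.* 1-df Pearson chi-square without continuity correction on allele
(2 per called sample), dominant-carrier or recessive-carrier 2×2 tables;
monomorphic/zero-margin markers get p = 1. Because the statistic is
discrete, calibration is checked on tail rejection rates rather than a
KS test of the full p distribution.

## Polygenic score

Summary records resolve against the marker map by id; an effect allele
equal to `allele_a` flips the sign of beta, an unresolvable allele drops
the record with a logged count. Clumping is greedy in ascending p:
retain the index marker, remove markers within 250 kb with dosage
r² > 0.1. Scores sum beta × dosage over included non-missing markers;
the default per-allele average divides by twice the per-sample included
marker count, which is also why no imputation is needed. The threshold
scan covers (0, 1] in 0.01 steps; R² is the squared Pearson correlation
between score and the 0/1 phenotype (not a pseudo-R²), and ties break to
the smallest threshold. Relabeling effect alleles shifts sum-mode scores
by a per-cohort constant and leaves group comparisons invariant
(verified numerically).

## Power

The Mann–Whitney power approximation scales Cohen's d by sqrt(ARE)
(3/π ≈ 0.955 for a normal parent; the distribution-free worst case
0.864 selectable), forms the noncentrality d_eff/sqrt(1/n1+1/n2), and
evaluates the noncentral t with df = n1+n2−2 at the one- or two-sided
critical value. This formulation reproduces the classical printed power
values for these designs to two decimals and agrees with a 20,000-rep
Monte-Carlo rank-test oracle within 0.02. Required effect sizes come
from a monotone root solve (tolerance 1e−9). Reported values round half
away from zero to 2 decimals. Fisher power enumerates all binomial
outcome pairs exactly; note the exact test's conservatism means its size
never reaches nominal alpha under the null.

## Stratification

Features are z-scored per column (constant columns left unscaled, with a
warning), distances Euclidean, linkage Ward — chosen for compact
clusters on two features; no linkage is canonical for this task and the
choice is recorded in the pipeline manifest. The tree is cut to k = 3 by
default (exposed; no automatic selection). Cluster ids are relabeled by
descending mean polygenic score so labels are deterministic under input
permutation.

## Synthetic cohort generator

The generator emulates the target study design: 36 case families (one
affected child, one genotyped sibling, both parents), 185 controls,
elevated consanguinity among case parents. Consanguineous families carry
an explicit second-cousin loop (shared great-grandparental couple), so
the pedigree expectation of each child's F is exactly 1/64. Defaults:
60% of case families consanguineous vs 25% of control families,
reproducing the direction and rough magnitude of the case-control
inbreeding contrast; the control fraction also makes exchangeable null
configurations possible for calibration runs.

Genotypes are gene-dropped: founder haplotypes are Bernoulli draws from
per-marker frequencies (uniform on [0.05, 0.5]); each gamete recombines
between adjacent markers independently with probability 0.001 per
interval at the default 1000 markers/chromosome (≈ 1 Morgan per
chromosome) — Haldane crossovers without interference, the simplest
model that produces multi-megabase autozygous tracts through pedigree
loops and only through them. The default map is 6 chromosomes × 1000
markers on 100 Mb; validation runs use denser maps (4 × 2500) so that
the 50-SNP ROH threshold corresponds to ~2 Mb.

Rare variants: configured numbers of LGD / MIS30 / other records with
gnomAD MAF log-uniform on [1e−5, 0.05] (spanning both filter
boundaries), background heterozygous carriers at roughly twice the
gnomAD frequency, and per-sample planted homozygous deleterious
genotypes Poisson(λ) with λ = 0.5 for everyone and an additive case
excess Δ (default 0.5; the per-individual baseline is a free parameter
of the emulation, not an estimate from data). Planted hits land in the
gene-set union with probability 0.5. Because planting is by variant
draw with replacement, realized means sit slightly below λ + Δ when the
qualifying pool is small.

CNVs: per-set, per-group carrier probabilities (default 18% cases vs 6%
controls for the first candidate set) plus equal-rate background calls
and a tranche of deliberately QC-failing noise calls to exercise the
cascade. GWAS summary statistics contain a configured number of causal
markers with positive betas and small p, the rest null; the polygenic
signal enters by redrawing genotypes at causal markers under
Hardy–Weinberg with a case allele-frequency shift proportional to beta.
This conditional frequency shift emulates liability-threshold
ascertainment given that case status is fixed upstream by the pedigree
layout; its cost is that transmission at causal markers is decoupled
from the pedigree, which the downstream polygenic analyses do not use.

What the generator does **not** emulate: background linkage
disequilibrium beyond pedigree transmission, mutation, genotyping error
beyond uniform missingness, sequence context, realistic gene lengths, or
ascertainment of families through probands. Passing validation therefore
demonstrates correctness of the algorithms under the stated model, not
robustness to every artefact of real array/exome data.

## Validation problem sizes and numerical choices

The test suite validates stochastic behaviour at reduced problem sizes
chosen to keep runs reproducible and quick while leaving adequate Monte-
Carlo resolution: 200 gene-dropped second-cousin children on a 4 × 2500
marker map for the F_ROH/pedigree concordance (mean within 3 SE of
1/64); 100 replicates per planted effect (inbreeding contrast,
homozygous load Δ = 2, CNV enrichment 18% vs 6%, polygenic shift) with
detection required in the majority; 200 replicates per null
configuration with empirical type-I error required inside the binomial
95% CI of 0.05 for the rank-based tests. For the one-sided Fisher CNV
burden the null check is one-sided (rate not exceeding the CI upper
bound): a discrete exact test is conservative by construction and a
correct implementation can sit below the lower bound.

Degenerate inputs are defined rather than left to chance: monomorphic
markers give HWE p = 1 and GWAS p = 1; a zero-margin 2×2 table gives
p = 1 with an undefined OR; samples with no usable polygenic markers
score 0 with a warning; a constant phenotype or an empty group is an
error; all-equal values give the tied U = n1·n2/2 and p = 1.

## Known limitations

Residualize-then-rank is one of several defensible covariate adjustments
for rank tests and can differ from, e.g., stratified or
probit-transformed approaches. The ROH density parameter is honoured as
specified (1 SNP per 5000 kb) although it is permissive on dense maps —
the gap and threshold parameters do the real work there, and all three
are configurable. The collapsing carrier test ignores relatedness
(no kinship-adjusted mixed model is provided). CNV calling itself,
variant annotation and model-based ancestry are out of scope: calls and
annotations are consumed as given.
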