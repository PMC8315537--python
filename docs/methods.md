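# Methods

This note documents the statistical models, the synthetic study design,
the numerical conventions and the open design choices behind `dartpop`.

## Marker model and QC statistics

Two marker types are handled throughout:

* **Codominant SNP dosages** g ∈ {0, 1, 2}: the count of alternate
  alleles at a biallelic locus (1 = heterozygote). Files using the DArT
  scoring convention (1 = alternate homozygote, 2 = heterozygote) are
  harmonized to dosage on read (`snp_coding="dart"`).
* **Dominant presence/absence scores** s ∈ {0, 1}: the phenotype of a
  biallelic locus where presence means at least one dominant allele.

Per-marker QC:

* **Call rate** — fraction of non-missing scores.
* **Reproducibility** — among technical replicate assay pairs with both
  calls non-missing, the fraction that agree. Markers with no scorable
  pair are reported as 1.0 and flagged rather than penalized: absence
  of evidence should not eliminate a marker, and the flag keeps the
  convention auditable. When the input carries a provider-supplied
  `Reproducibility` column (marker sets are typically pre-selected by
  the genotyping provider on its own internal replication), that column
  takes precedence over the value computed from the handful of in-data
  replicate pairs. This matters: filtering at reproducibility = 1 on
  the in-data pairs would delete exactly the loci at which replicates
  disagree, collapsing all replicate distances to zero and making the
  duplicate threshold degenerate. The synthetic generator therefore
  emits a provider column of 1.0 while the replicate columns keep their
  discordance.
* **PIC** — 1 − Σf², with f the two allele frequencies (SNPs, estimated
  from dosages: p = (2n₂ + n₁)/2n) or the two state frequencies
  (dominant markers). This is the two-state expected-heterozygosity
  form, bounded by 0.5. The alternative Botstein PIC (bounded 0.375 for
  biallelic loci) is inconsistent with marker panels whose reported PIC
  ranges reach 0.5, which is why the 1 − Σf² form is the default. A
  genotype-state variant (three states for SNPs) can be obtained by
  treating dosages as categorical; it was deliberately not exposed as a
  default because allele-frequency PIC is the standard for codominant
  biallelic markers.
* **Substitution classes** — A↔G and C↔T are transitions, the four
  other distinct pairs transversions; class frequencies use the
  classified-marker count as denominator, with unparseable allele pairs
  reported as NA.

Default filter thresholds are call rate ≥ 0.95 (at most 5% missing
data) and reproducibility ≥ 1.0; both are configurable.

## Gower dissimilarity

d(i,j) = Σ_l δ_ijl s_ijl / Σ_l δ_ijl with δ_ijl = 1 iff both samples
are scored at locus l (pairwise deletion; no imputation — this is
Gower's definition). SNP dosages are interval-scaled with range 2, so
s_ijl = |g_il − g_jl|/2; dominant scores are symmetric binary,
s_ijl = 1{s_il ≠ s_jl}. A categorical SNP treatment is available
(`snp_mode="categorical"`) because distance routines differ in whether
0/1/2 codes are range-normalized; the interval treatment is the default
as it preserves the het-between-homs geometry. Matrices are written to
CSV at 6 decimals; a pair with zero comparable loci is an error, not a
silent NaN.

## Duplicate detection

The threshold τ is the **maximum** Gower distance among technical
replicate pairs — the most conservative value consistent with "flag
pairs whose distance lies within the replicate range". Per platform,
all non-replicate accession pairs with d ≤ τ are flagged; the consensus
is the **intersection** of the two platforms' pair sets (a duplicate
call should survive both marker systems); clone groups are connected
components of the consensus graph, because synonymy is transitive
through chained similarity even when the most distant group members
were not directly flagged. One representative per group is retained —
the member with the lowest missing-data rate, ties broken
alphabetically (a deterministic, auditable rule; curators may override
it with passport data). The purge count is Σ(group size − 1).

## Synthetic study design

The generator's defaults emulate a genebank curation scenario: 87
accessions (41 landraces, 21 improved, 25 exotic), ~10,000 markers per
platform, K = 2 founder pools at Fst = 0.30, symmetric Dirichlet(0.3)
admixture, two planted clone groups (20 + 2 landraces, so 22 clone
members and 20 purgeable), 3 replicated DNAs chosen uniformly at
random, and 1% missingness.

* Founder pools follow a Balding–Nichols construction: ancestral
  frequency ~ Uniform(0.05, 0.95), pool frequency ~ Beta with that mean
  and variance scaled by Fst.
* SNP dosage ~ Binomial(2, Σ_k q_ik p_kl). Dominant presence ~
  Bernoulli(1 − (1 − π)²) with π the mixed dominant-allele frequency of
  an *independent* underlying locus set — both platforms share the same
  per-accession ancestry, so they are strongly correlated but not
  copies of one another (their Mantel correlation is high but < 1).
* Score errors stay within the platform alphabet: dominant scores
  toggle 0↔1; SNP dosage errors move to an adjacent dosage (0→1, 2→1,
  1→0 or 2 equiprobably).
* One RNG stream per generation stage, all derived from the single
  config seed, so the pipeline is bit-reproducible and stage reordering
  cannot silently change unrelated draws.

**Error-rate defaults.** `err_tech = 0.004` is the per-locus
discordance between a replicate assay and its source column — it
represents the combined error of *two* independent assays of one DNA
(≈ 0.2% per assay). `err_clone = 0.0005` is each clone member's
residual per-locus divergence from the planted founder genotype. Two
clone members then differ at ≈ 2 × 0.0005 of loci, i.e. a SNP Gower
distance ≈ 0.0005, comfortably below the calibrated τ ≈ 0.002, while
distinct genotypes sit two orders of magnitude higher. This ordering —
clone-pair distances at or below the replicate noise floor — is the
regime in which replicate-calibrated duplicate detection is valid at
all: if clones diverged *more* than replicate assays do, no threshold
derived from replicates could recover them. The defaults therefore
encode the biological assumption that clones are genetically identical
and technical error dominates observed clone-pair distances.

Not emulated: linkage disequilibrium between loci, selfing/inbreeding,
pedigree structure, or batch effects in missingness. Passing recovery
tests on this generator shows the pipeline's logic is correct under its
own assumptions; it does not certify performance on marker panels with
strong LD or structured missingness.

## Admixture model and sampler

The no-linkage, independent-allele-frequencies admixture model for
unphased diploids: allele copy c of individual i at locus l originates
from cluster k with probability q_ik and is the alternate allele with
probability p_kl. Priors: p_kl ~ Beta(λ, λ) with λ = 1; q_i ~
Dirichlet(α, ..., α) with a single α shared across clusters and
individuals, uniform prior on (0, 10], updated by a Metropolis step
with a Normal(0, 0.025) random walk (starting at 1.0). One Gibbs sweep:

1. sample each copy's origin z with P(z = k) ∝ q_ik p_klj;
2. p_kl ~ Beta(λ + alt copies assigned to k, λ + ref copies);
3. q_i ~ Dirichlet(α + copies of i per cluster);
4. Metropolis update of α.

Missing genotypes contribute no copies and no likelihood terms. The
data log-likelihood ln P(D|P,Q) = Σ log Binomial(g; 2, Σ_k q_ik p_kl)
is traced each post-burn-in sweep; the model evidence estimate is the
deviance form L(K) = mean(lnL) − var(lnL)/2 (sample variance), and
posterior means of Q and P are reported. At K = 1 the model is
degenerate (Q ≡ 1) and the p posterior is the closed-form
Beta(λ + alt, λ + ref) — used as a calibration check in the tests.

**Model order** is selected by Evanno's ΔK = |L̄(K+1) − 2L̄(K) +
L̄(K−1)| / sd(L(K) across runs), undefined at the endpoints of the K
range; zero across-run sd reports ΔK = ∞ with a warning. Replicate
runs per K default to 5 (ΔK needs an across-run sd; 3 is the practical
minimum and is what the reduced configurations use). The reported Q at
the chosen K is the highest-L run; no CLUMPP-style multi-run averaging
is performed. Label switching is handled at evaluation time by greedy
Hungarian alignment of Q columns, so all recovery metrics are
label-invariant.

Only the codominant SNP platform feeds the sampler: the dosage
likelihood is well-defined, whereas dominant scores would require an
extra latent layer for the unobserved heterozygote. The
correlated-allele-frequencies ("F-model") variant is not implemented;
on strongly diverged pools the independent-frequencies model recovers
the same structure, but per-cluster heterozygosity estimates can drift
slightly relative to tools that default to correlated frequencies.

**Diversity summaries.** He_k = mean_l 2p(1−p); net nucleotide distance
between clusters = mean_l [cross-mismatch − ½(within₁ + within₂)]
(clipped at 0 against Monte-Carlo noise); a sample is "fully assigned"
to cluster k if Q_ik ≥ 0.99 (1% admixture threshold), otherwise
admixed; membership proportions are column means of Q.

A cluster dominated by one clone group has He ≈ half the pool-level
heterozygosity (each locus is either fixed in the clone, p ∈ {0, 1}, or
heterozygous, p = 0.5), so purging duplicates and re-running strictly
increases the clone cluster's He — the pipeline's purge-and-recompute
stage reproduces this directionally on synthetic data.

## Ordination, trees, Mantel

* **UPGMA** uses the Lance–Williams weighted-average update; node
  height is half the merge distance (ultrametric). Ties are broken by
  the lexicographically smallest (smallest-leaf, smallest-leaf) label
  pair, making output deterministic. Newick branch lengths are height
  differences, 6-decimal precision, trailing zeros trimmed.
* **PCoA** eigendecomposes the double-centered −½d² matrix. Negative
  eigenvalues (non-Euclidean input, e.g. Gower with pairwise deletion)
  are counted and reported but excluded from the percent-variance
  denominator; no Cailliez/Lingoes correction is applied by default
  since different ordination tools disagree here — the convention is
  flagged in the output so axis-variance figures can be compared
  knowingly.
* **Mantel** correlates the n(n−1)/2 lower-triangle entries; the null
  permutes rows+columns of the second matrix jointly; p = (1 + #{r_perm
  ≥ r_obs})/(n_perm + 1), one-sided upper tail by default (a two-sided
  option exists). The +1 correction keeps p > 0 at any permutation
  count. Type-I calibration is verified by simulation in the test
  suite (rejection rate ≈ 5% under independence).

## Problem sizes and runtime choices

The pipeline and validation runs use deliberately reduced MCMC and
locus counts, chosen as the smallest sizes at which every recovery
property is stable across seeds:

* distance/duplicate/ordination stages run at the full default design
  (87 + 3 samples × 10,000 markers per platform);
* structure runs subsample 300 loci and use burn-in 400–500 /
  1,000–2,000 kept sweeps, 3 runs per K over K = 1..5 — at these sizes
  ΔK selection, ancestry recovery (MAE ≈ 0.01) and the
  purge-and-recompute He pattern are already unambiguous;
* full-length chains (burn-in 20,000 / 30,000 sweeps, K = 1..10, 5 runs
  per K) remain the `McmcConfig` defaults for real analyses.

## Degenerate inputs and tie-breaks

* Monomorphic loci: PIC = 0 (not an error).
* All-missing marker: excluded from every pairwise comparison; adding
  one never changes a distance matrix.
* Dirichlet α → 0: the generator degenerates to a uniformly chosen
  vertex (pure ancestry) instead of producing NaNs.
* τ = 0: only exact matches (on comparable loci) are flagged.
* Distance asymmetries ≤ 1e−6 on read are symmetrized; larger ones are
  errors.

## Known limitations

* The sampler is O(n · L · K) per sweep in vectorized numpy; it is
  comfortable at curation scale (tens-to-hundreds of samples, loci
  subsampled to hundreds for structure) but is not a substitute for
  optimized C implementations on 10⁵-locus panels at full chain length.
* Independent-frequencies prior only (see above).
* Duplicate detection is a hard threshold rule; no probabilistic clone
  assignment or explicit genotype-error model is attempted.
* The dominant-marker platform is excluded from the admixture model.
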