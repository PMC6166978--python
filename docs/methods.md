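# Methods

This note documents the models implemented in `mendelbalance`, the choices
made where the procedure was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The detection problem

A recessive lethal allele segregating in a closed breeding population leaves
no affected live animals; its footprint is statistical. With dense phased
SNP genotypes, a lethal haplotype shows *missing homozygosity*: among
offspring of two carrier parents, one quarter of conceptuses are homozygous
and die in gestation, so the genotyped progeny contain far fewer (typically
zero) homozygotes than Mendelian segregation predicts. The companion
signals are smaller carrier-by-carrier (CxC) litters, an excess of mummified
piglets, depressed array intensities over the physical deletion, allelic
imbalance at linked expressed sites, and — when the allele persists at
moderate frequency — a heterozygote advantage on the selection index.

## Missing-homozygosity test (`haploscan`)

Carrier status for a window of `w` consecutive markers is an exact string
match of either phased haplotype against the target allele string. For each
genotyped offspring with genotyped parents carrying `s` and `d` copies, the
probability of a homozygous offspring is `p_i = (s/2)(d/2)`; the expected
count is `Σ p_i` and the observed count is tested with the exact lower tail
of the Poisson-binomial distribution of `Σ Bernoulli(p_i)`:

    p = P(X ≤ observed).

When all `p_i` are equal this reduces to the exact binomial lower tail. The
implementation groups equal `p_i` (trio probabilities only take values in
{1/4, 1/2, 1}) and convolves binomial blocks, which is algebraically
identical to the one-term-at-a-time dynamic-programming convolution and is
verified against exhaustive enumeration for n ≤ 12 in the test suite.

A single predefined haplotype is judged at the raw threshold `p < 5e-3`.
The genome scan (`scan_genome`) slides a fixed-size window (default 25
markers) one marker at a time, tracks every haplotype above a minimum
frequency (default 1%), and applies a Bonferroni correction across all
tested (window, haplotype) pairs — the scan tests thousands of hypotheses,
the single-window analysis tests one. Windows truncated at chromosome ends
are skipped. Because neighbouring windows share the descent segment that
carries the lethal, a true lethal flags a run of overlapping windows; the
unit of discovery is the haplotype (its carrier set), not the window.

Genotype-ratio checks use the Pearson chi-square against 1:2:1 (df = 2).
Carrier frequency is reported from live genotyped animals; with no live
homozygotes every haplotype copy sits in a heterozygote, so carrier
frequency is exactly twice the haplotype frequency, and the expected
fraction of CxC litters under random mating is the squared carrier
frequency.

## Litter contrasts and frequency over time (`pheno`)

CxC vs CxNC litter traits are compared with Welch's unequal-variance t-test
(two-sided). The mummified-piglet excess in tracked CxC litters is a
one-sample t-test against the breed baseline (default 0.35 mummies/litter),
one-sided (greater) because the claim is directional; a resampling oracle in
the tests brackets its p-value. Mummies are recorded in their own column
and excluded from TNB by default (`mummies_in_tnb` flips this; the recording
convention differs between herdbooks).

Carrier frequency over time is binned per half-year with edges aligned to
Jan 1/Jul 1. The live population in a bin is approximated as animals born
on or before the bin end and within a configurable lifespan (default 3
years) of the bin start — the inputs carry no death dates. Two tests are
reported: a one-way ANOVA across bins on animal-level carrier indicators,
and a Cochran-Armitage trend test on the binned proportions. A repeated-
measures ANOVA on a single aggregated frequency series has no within-cell
replication, so the animal-level ANOVA plus the trend test are used instead.

## Deletion genotyping from intensities (`cnvgeno`)

A heterozygous deletion halves copy number at the markers it spans and
depresses their Log R Ratio by roughly 0.6 units. The classifier is a
logistic regression on 5 features: the LRR at the four markers inside the
deletion plus their mean. The fit minimizes the mean negative
log-likelihood plus an L2 ridge on the slopes (default 1e-3, intercept
unpenalized) by Newton iterations with step halving, converging to a
gradient norm below 1e-10. The per-observation likelihood scaling makes the
fit invariant to duplicating the training data, and the ridge keeps the
near-separable carrier/non-carrier clusters from driving the MLE to
infinity. Rare fresh-born homozygotes have no training class; they are
flagged by a secondary rule (mean LRR < −2) rather than a third class.

## Allele-specific expression and transcript impact (`ase_impact`)

Read counts at heterozygous coding sites are tested against Binomial(n,
0.5) with the exact two-sided test (summing probabilities of all outcomes
no more likely than the observed one) and Benjamini-Hochberg correction
over whatever site set is supplied. The reported ratio is
`wt_count / total`.

Transcript impact of a genomic deletion: every exon overlapping the
(closed) deletion interval is removed, the remaining exons are spliced in
transcript order, and translation restarts from the original start codon,
running to the first stop. A frameshift is declared when the deleted coding
length is not a multiple of 3; the novel-residue count is the mutant
residues after the longest common prefix with the wild-type protein.
Partial exon overlap is handled by removing the exon and flagging the
result. Loss of the start codon is reported as a zero-length protein, not
an error. The synthetic fixture gene is engineered so that skipping its
exons 20–27 (4 coding + 4 3'UTR) removes 548 coding nt (≡ 2 mod 3),
reading 11 novel residues into the former 3'UTR before a premature stop:
865 residues wild type, 694 mutant.

## Drift and balancing selection (`selsim`)

**Drift.** Wright-Fisher with viability selection: each generation forms
Hardy-Weinberg genotypes, applies fitness weights (0 for the lethal
homozygote), and draws 2N gametes binomially. The recorded trajectory is
the allele frequency at conception. For a lethal, the deterministic
recursion `q' = q/(1+q)` is a concave upper envelope of the ensemble mean.

**Balancing recursion.** Each generation with live carrier frequency `c`
and per-sex carrier advantage `s`:

1. selected parents per sex: `c_sel = c(1+s) / (1+cs)`;
2. sex-averaged parental allele frequency `q = mean(c_sel)/2`;
3. Hardy-Weinberg offspring from `q`; homozygotes removed;
4. live offspring carrier frequency `c' = 2q/(1+q)`.

With equal advantages, the stable fixed point is `c* = 2s/(1+3s)`
(`equilibrium_carrier_freq`), approached monotonically from either side.
At the observed 2.7% index advantage the equilibrium is ≈ 5.0% carrier
frequency. Published trajectories for this system level off near 6%; part
of the gap is that truncation selection amplifies a mean index shift into a
larger tail-probability ratio. `truncation_advantage` exposes exactly that
knob: with carrier and non-carrier indices normal with a 2.7%-of-mean
shift, it solves the mixture truncation threshold for a given selected
fraction (5% of boars, 25% of gilts) and returns
`s = P(selected|carrier)/P(selected|non-carrier) − 1`, which exceeds the
mean shift substantially when the shift is a sizable fraction of the index
SD. The remaining gap plausibly reflects mating-structure details
(avoidance of related matings) absent from both this recursion and the
published one. Neither value is forced; the recursion, its closed form,
and the truncation mapping are each tested on their own terms.

The recursion's linear convergence rate approaches 1 as `s → 0`, so the
per-step stopping rule (|Δc| < tol, default 1e-10 over up to 500
generations) reports an equilibrium only when it is actually reached;
tests that compare against the closed form to 1e-8 pass a tighter
tolerance and a larger generation cap.

## Deregressed-EBV association (`assoc`)

Estimated breeding values are shrunken predictors containing parent-average
information; regressing on them directly double-counts relatives and
attenuates effects. Deregression follows the two-equation parent-average
(PA)/individual mixed-model system. The effective information contents are
recovered from the published reliabilities by inverting the 2×2 coefficient
matrix

    C = [[Z'Z_PA + 4λ, −2λ], [−2λ, Z'Z_i + 2λ]],  λ = (1−h²)/h²,

whose inverse diagonal must equal the prediction-error variances
`(0.5 − r²_PA)σ²_a` and `(1 − r²)σ²_a`. Writing `A = (0.5 − r²_PA)/λ`,
`B = (1 − r²)/λ`, the solution is

    u = Z'Z_PA + 4λ = (1 + sqrt(1 + 16ABλ²)) / (2A),
    v = Z'Z_i + 2λ = 4Aλ² / (Au − 1),

the deregressed value is the individual right-hand side over `Z'Z_i`, its
reliability is `Z'Z_i/(Z'Z_i + λ)`, and the association weight is
`w = (1−h²) / ((c + (1−r²_DEBV)/r²_DEBV) h²)` with scalar `c = 0.5`.
Records are kept when `w > 0` and `r²_DEBV > 0.20`; `r²_PA ≥ 0.5` is a
degenerate input (a parent average cannot carry half the additive variance)
and raises. The PA EBV is taken from an explicit `ebv_pa` column when
present, else from the parents' EBV mean via the pedigree (0, flagged, when
neither parent has a record). The tests verify the closed form by
reconstructing the input reliabilities from the solved coefficient matrix,
and verify end-to-end that deregression exactly inverts the generator's
forward evaluation.

The association model per trait is `DEBV = μ + β·carrier + a + e` with
`a ~ N(0, A σ²_a)` (Henderson's tabular numerator relationship matrix) and
`e ~ N(0, diag(1/w) σ²_e)`. REML profiles the likelihood over the single
ratio `λ = σ²_e/σ²_a`: after one eigendecomposition of `W^{1/2} A W^{1/2}`
each profile evaluation is O(n), and a bounded scalar search over `log λ`
finds the optimum (verified against a dense grid). The reported effect is
the carrier − non-carrier difference with its Wald standard error and
two-sided normal p-value. No multiple-testing correction is applied across
traits by default.

## Synthetic populations (`simdata`)

The generator emulates a purebred Large White-like line at a scale where
the whole pipeline runs in seconds (defaults: 550 founders, 3 discrete
generations, 450 dams × 1 litter and 55 AI sires per generation, ≈ 19,000
live animals, 120 markers on 2 chromosomes). Design choices:

* **Haplotypes** descend from a pool of 30 founder haplotypes per genome,
  giving realistic haplotype sharing so the scan tracks many recurrent
  background haplotypes, not just the lethal. Transmission recombines at
  0.0004 per 40 kb marker interval (≈ 1 cM/Mb). The lethal is a distinct
  25-marker allele string; a crossover inside the window separates the
  flanking SNPs from the deletion, so carrier status is defined by the
  exact window match.
* **Stationarity.** The generator does not simulate selection (that lives
  in `selsim`); instead it imposes the balanced stationary state directly,
  holding carriers at `2q₀` among breeding parents by stratified parent
  sampling, with the founder carrier count set exactly and sires cycled
  over litters. Live-animal carrier frequency then stays within Monte-Carlo
  error of the no-live-homozygote equilibrium `2q₀(1−q₀)/(1−q₀²)` (≈ 10.25%
  at the default q₀ = 0.054).
* **Litters.** Conceptions are Poisson (mean 16); del/del conceptuses die
  with fates mummified/stillborn/weak-liveborn = 0.8/0.15/0.05, on top of
  background mummies (Poisson 0.35) and stillborns (Poisson 0.4). Mummies
  are excluded from TNB, so CxC litters average ≈ 80% of background TNB.
  Weak liveborn homozygotes die within a day and never reach the genotyped
  panel, which emulates live selection candidates — the population scan
  therefore observes zero homozygotes while litter truth labels retain the
  fresh-born ones. At the default scale a bundle contains ≈ 12–16 CxC
  litters and ≈ 45 expected homozygotes from trios, comparable to the
  published population.
* **Intensities.** LRR at the four deletion markers: N(0, 0.25²)
  non-carriers, N(−0.6, 0.30²) carriers, N(−2.5, 0.8²) homozygotes; other
  markers N(0, 0.25²) for everyone. These mimic the visual separation of
  published intensity panels and are configuration, not estimates.
* **EBVs.** True breeding values are polygenic (founders N(0, σ²_a),
  offspring midparent + Mendelian sampling) plus the carrier shift (+2.7%
  of the index mean for TSI, +12.4% for growth, −16.7 g litter birth
  weight). The published evaluation is emulated by running the same
  PA/individual mixed-model equations *forward*: per-animal reliabilities
  are drawn, the implied information contents generate pseudo-records, and
  the 2×2 system is solved for the EBV and PA EBV. Deregression therefore
  inverts the construction exactly, and association on deregressed values
  recovers the injected shifts without systematic bias (coverage of the
  2-SE interval ≈ 92–96% over seed ensembles).

What the generator does **not** emulate: linkage disequilibrium beyond the
single founder pool, overlapping generations, genotyping error, imputation
uncertainty, non-random mating, selection feedback on the lethal, or
environmental trends in litter traits. Passing tests demonstrate that the
statistical machinery is correct under the stated model, not that real
data meet its assumptions.

## Numerical notes

* HWE exact test: plain conditional exact test (sum of probabilities ≤ the
  observed configuration's), no mid-p; full enumeration of heterozygote
  counts given allele counts, in log-space for stability.
* QC order: animals (missingness > 0.20) first, then markers (call rate
  < 0.85, MAF ≤ 0.01, HWE p < 1e-6) on the retained animals; the filter is
  idempotent.
* Poisson-binomial: binomial-block convolution over the distinct
  probability values; p-values floored at the smallest positive float.
* REML: eigenvalues clipped at 0; search bounded to log λ ∈ [−12, 12];
  singular fixed-effect equations raise with rank diagnostics.
* Problem sizes in the test and acceptance runs (bundle ≈ 19k animals, 120
  markers; 50-replicate association ensembles at ≈ 700 animals; 1000–2000
  drift replicates) were chosen so the full pipeline and its property
  tests complete in well under a minute each while keeping Monte-Carlo
  error small relative to every asserted tolerance.
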