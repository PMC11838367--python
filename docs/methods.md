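# Methods

This note documents the generative model behind the synthetic cohorts, the
estimators, the numerical choices, and the limits of what the simulation
studies demonstrate.

## Generative model

### Haplotype pool

Cohorts are drawn from an explicit pool of discrete haplotype classes over a
26-variant cis panel (six annotated *APOL1* variants plus 20 background
variants), rather than from a coalescent simulation. This gives exact control
of three structural facts the analyses depend on:

1. **Mutual exclusion.** G1 (the linked pair rs73885319/rs60910145, carried
   on a single haplotype class) and G2 (rs71785313) never co-occur on a
   haplotype. Under random mating this implies a negative dosage correlation
   with closed form r = −√(p₁p₂/((1−p₁)(1−p₂))) ≈ −0.214 at the default
   African-ancestry frequencies (p₁ = 0.22, p₂ = 0.14).
2. **LD proxies.** Twelve background variants tag the G1/G2 haplotype
   classes and four tag V1/V2, with partial coverage and low-frequency
   "leak" classes so that every proxy has 0 < r < 1 with its causal variant
   (an early design that placed proxies on exactly the causal haplotype
   classes made them perfectly collinear and split the fine-mapping
   posterior, which no real locus does). Four further background variants
   segregate independently.
3. **Published frequencies.** Pool marginals match the reported
   population frequencies exactly: AFR G1 0.22, G2 0.14, M1 0.03, V1 0.35,
   V2 0.16; EUR V1 0.81, V2 0.11, with G1/G2 at their reported ~5×10⁻⁵
   residual frequencies. Trans-locus frequencies (alt alleles): KLKB1
   0.74/0.51 and F12 0.55/0.75 (AFR/EUR) as published; KNG1 and HPR lead
   variants have no printed frequencies, so typical common-variant values
   (0.30–0.42) were fixed once.

Each individual draws two haplotypes i.i.d. from the class frequencies;
trans genotypes are Binomial(2, f) per locus. A config flag can place a
fraction of G1M-only haplotypes to emulate the G1M/G1G imputation
discordance the QC module is designed to flag.

### Measurement model

A shared latent abundance `T_i = μ + β_V2·d_V2 + β_HPR·d_HPR + ε_T` is read
out by three channels:

- **MS** = T + ε (no coding-variant artifacts);
- **Olink** = T + Σ_v δ_Olink,v·d_v + γ_O·A + ε;
- **SomaLogic** = T + Σ_v δ_Soma,v·d_v + ε,

where δ are per-allele epitope effects (positive on Olink, negative on
SomaLogic for G1/G2/V1; the regulatory variant V2 and the HPR trans effect
act on T and are therefore platform-concordant) and
`A = (1 − λ_F12·l_F12/2)(1 − λ_KLKB1·l_KLKB1/2)(1 + κ·f_KNG1/2)` is a
multiplicative KKS activity entering only the Olink channel (`l` =
loss-of-function dosage, which is the *reference* allele at both protease
loci; `f` = functional kininogen dosage). The multiplicative form makes
full LOF of either protease abolish the other's effect, which is what the
stratified and product-term interaction tests are meant to detect. Defaults:
λ = 0.9 per protease, κ = 0.3, γ_O = 0.5 — chosen to produce clear but not
dominant trans structure; the interaction tests are exercised at λ = 1 where
the epistasis is strict.

Platform noise defaults are 1.0 NPX (Olink, SomaLogic) and 0.5 (MS), with
shared-latent SD 0.4 on the log2 scale — a typical inter-individual spread
for an abundant plasma protein. For the cross-platform correlation study the
noise SD is instead *solved* from the model-implied correlation
σ_T²/(σ_T² + σ²) = 0.39 at σ_T = 1.

### Stratified (epistatic) effect encoding

The published stratified slopes — G2 effect 1.212 per allele when G1 is
absent, G1 effect 0.287 when G2 is absent and 0.066 in G2 heterozygotes —
are jointly consistent with a single product-term mean surface
`0.287·g1 + 1.212·g2 − 0.221·g1·g2`. The generator therefore encodes one
stratum interaction (G2 effect 1.212 / 0.991 by G1 carrier status) plus a
constant per-allele G1 effect of 0.287. Encoding the attenuation twice
(once per direction) would double-count the interaction term and bias the
G1-in-G2-carriers slope to ≈ −0.15; this was the one place the stratified
parameterization needed care.

### Peptide layer

Nineteen tryptic peptides are simulated as log2 sample/bridge ratios
`P_ij = T_i + offset_j + ε`. Allele-specific peptides scale with the number
of carrying haplotypes — `+log2(c/2)` relative to the two-copy level — and
are **exactly 0.0** ("not detected") when no haplotype carries them:
LNILNNNYK requires the reference allele at both G1M and G2 on the same
haplotype; SELEDNIRR/LEDNIRR carry the V1 reference/alternative allele.
Exact zeros are stored as 0.0, never missing, because the classifiers treat
them as genotype-determining overrides.

Offsets centre the peptide ratios near −0.75. This is deliberate: the G1/G2
carrier thresholds `y < 5/3·x` and `y < 5/3·x − 1` are through-origin lines,
and they coincide with the natural midpoint rules (observed minus predicted
≈ −0.5 and −1.5) exactly when predictions sit near −0.75 — i.e. the
published thresholds implicitly characterize the abundance regime of the
data they were built for, and the generator reproduces that regime. For the
same reason the V1 ALT peptide runs 0.25 units above the REF peptide, which
places heterozygotes at the midpoint of the asymmetric published band
x − 0.5 < y < x + 1.

## Estimators

- **Inverse-normal transform:** Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)),
  average ranks for ties, missing values passed through.
- **Association scan:** two OLS fits per variant (transformed scale for the
  t-test, raw scale for the reported per-allele β); p-values from the t
  distribution with residual df, not the normal approximation. Collinear
  designs produce flagged records rather than exceptions. A reporting flag
  flips selected variants to reference-allele orientation (used for V1,
  whose published effects are per G allele).
- **Fine-mapping:** exhaustive enumeration up to `max_k` causal variants
  (default 3; a guard at 2×10⁶ configurations rejects unenumerable
  requests). Phenotype and dosages are covariate-residualized and
  standardized; the effect prior is N(0, τ²σ²) with τ = 0.5 per
  standardized allele and π = 1/m per-variant inclusion (capped at 1/2 for
  a single candidate, where 1/m would assert certainty). Residual variance
  is fixed at the standardized phenotype variance by default; an
  "estimated" mode integrates σ² under a Jeffreys prior via the closed-form
  t-family marginal. Marginal likelihoods use Cholesky factorizations of
  the (ridge-regularized) configuration Gram matrices, so perfectly linked
  candidates (G1M/G1G) are handled gracefully and split their inclusion
  mass. A summary-statistic entry point reconstructs the sufficient
  statistics from (z, R, n) using r = z/√(z² + n − 2).
- **Stratified contrast:** the printed statistic is implemented as the
  standard Welch-type form t = (β₁−β₂)/√(σ₁²+σ₂²) with n₁+n₂−4 df (the
  stated df identifies this reading). Covariate columns constant within a
  stratum are dropped.
- **Peptide classifiers:** strict inequalities as published; exact boundary
  values fall to the homozygous side; zero overrides always dominate the
  band rules; both-peptides-zero is an explicit no-call. The G1/G2
  predictor is an L1-penalized regression (α = 0.01, unstandardized
  features, intercept unpenalized, objective (1/2n)·RSS + α‖w‖₁) trained on
  a declared reference panel; α = 0 falls back to plain least squares.
- **Power:** case-group frequency from the exact odds transform
  p₁ = OR·p₀/(1 − p₀ + OR·p₀) under a recessive high-risk genotype; the
  default closed form uses the pooled-proportion SE under the null and the
  unpooled SE under the alternative, summing both tails. At small case
  counts (tens) the normal approximation to the case-count distribution
  is a few percent optimistic — at 44 cases, 6,725 controls, p₀ = 0.13,
  OR = 2 the closed form gives 0.502 against a true rejection rate of
  0.478 — so `method="exact"` computes the rejection probability of the
  pooled z-test by direct binomial enumeration; the tests validate it
  against Monte-Carlo simulation.

## Numerical and interface choices

- Coordinates are 1-based inclusive throughout (VCF convention); the cis
  window is TSS − 200 kb to TES + 200 kb, the same physical interval on
  either strand, clipped at position 1.
- Relatedness pruning is order-randomized greedy removal ("drop one member
  of each qualifying pair"), not minimum vertex cover — deliberately the
  light-touch filter, seeded for reproducibility.
- Missing genotypes are excluded pairwise from MAC and Hardy–Weinberg
  counts; variants without an INFO score are treated as sequenced and skip
  the INFO filter.
- The pipeline derives one sub-seed per stage by hashing the stage name
  with the top-level seed, so inserting or dropping a stage does not
  perturb the others; re-running an identical configuration reproduces
  byte-identical outputs (checksummed in the manifest).
- Hardy–Weinberg default is the exact conditional test (log-space
  enumeration over heterozygote counts), with a chi-square option; the
  exact test remains correct at the extreme deviations the imputation
  artifact produces.

## Simulation-study sizes

The recovery studies run at the original cohort sizes: 828 (UKB AFR), 461
(AASK), 194 + 366 (Health ABC AFR analysis + EUR training), 38,442 (UKB
EUR) and 35,559 (deCODE), with 50–200 replicates for replicated studies.
These sizes complete in seconds per study on one CPU while holding the
Monte-Carlo error of each reported mean an order of magnitude below the
recovery tolerance.

## What the synthetic studies do and do not show

The generator reproduces the *structure* the estimators rely on — haplotype
constraints, LD proxies, platform-specific artifacts, multiplicative
epistasis, allele-specific peptide dropout — with Gaussian noise and
without: genome-wide LD and recombination, population admixture and
stratification, batch/plate structure, TMT ratio compression or bridge
normalization artifacts, genotype uncertainty beyond the modeled
het-to-hom imputation errors, and any real relationship between plasma
APOL1 and disease. Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated model, not robustness to
real-data pathologies outside it. The published UKB sample correlation
between G1 and G2 (−0.27) is stronger than the −0.214 implied by the
population frequencies under pure mutual exclusion; since the
cohort-specific frequencies are not printed, the default pools target the
published frequencies, not that correlation.
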