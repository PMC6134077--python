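# Methods

## Trait model

Sex reversal is a binary trait y ∈ {0,1} scored only in ZW genetic females
(a ZZ fish is constitutively male and never "reversed"). The scan fits the
linear mixed model on the 0/1 indicator directly:

    y = μ + b·m + g + e,   g ~ N(0, K σ²_g),   e ~ N(0, I σ²_e)

with m the additive SNP code (0/1/2 copies of the alternate allele) and K
the realized genomic relationship matrix. A logit link applied to an
individual 0/1 outcome is undefined, so the model is the liability-scale
linear approximation; its whitened form (below) is exactly the
generalized-least-squares marker test. A penalized-quasi-likelihood
logistic variant is a known limitation, not offered.

Marker significance is T = −2(logL₀ − logL₁) computed on the Gaussian
profile, T = n·ln(RSS₀/RSS₁) after whitening, referred to χ² with 1 df.

## Relationship matrix

K = ZZ′/n_m, where Z standardizes each marker column by its observed mean
and population (divide-by-n) standard deviation. The SD convention is a
documented choice; either convention rescales K globally and is absorbed
into σ²_g. Sex-chromosome markers are included: in an all-ZW cohort W
markers are near-monomorphic and almost all fall to the MAF filter anyway.
Zero-variance columns are an error — the MAF filter must run first, which
also means K is undefined for a single individual (every column is then
constant).

## REML and whitening

Variance components are estimated once under the null (intercept-only)
model and reused for every marker, EMMAX-style. K is eigendecomposed once;
the restricted likelihood is profiled over λ = σ²_g/σ²_e on a log grid
(λ ∈ {0} ∪ 10^[−6,6], 121 points) with bounded scalar refinement around the
grid optimum. When K carries no structure (K ≈ I) the likelihood is flat in
λ; the boundary solution λ = 0 is returned with a warning rather than an
arbitrary interior point.

V = K σ²_g + I σ²_e is factored V = LL′ (jitter of 1e−8·mean(diag V) is
added once on Cholesky failure). y* = L⁻¹y, M* = L⁻¹M, and the whitened
intercept L⁻¹1 give per-marker OLS fits; the per-marker statistic is
algebraically identical (verified to 1e−6 in tests) to the direct GLS
−2ΔlogL with the same fixed V.

Degenerate markers: a column collinear with the whitened intercept
(including in-sample monomorphic markers) gets T = 0, P = 1 and a
`collinear` flag. Perfect separation (RSS₁ ≤ 1e−12·RSS₀) gives T = ∞ and P
reported as the smallest positive double with an `underflow` flag — never a
literal 0. Ties for the peak break by smallest P, then leftmost genomic
position (chromosomes ordered 1–20, W, Z).

## Genome-wide threshold

The critical value solves

    α = P(χ²₁ > c) + V·exp(−c/2)/√(2π)

the quick upcrossing (Davies-bound) approximation, with V the total
variation of the signed-root statistic z_i = sign(b_i)·√T_i summed over
adjacent markers within each chromosome. V is estimated from the observed
scan (statistics capped at 1e3 so an infinite peak cannot swamp it), which
slightly inflates V in the presence of a true signal — a conservative
direction. The solution is clipped into [pointwise χ²₁(1−α), Bonferroni
χ²₁(1−α/n_m)], guaranteeing the sandwich property by construction; a
single-marker scan returns the pointwise quantile (3.841 at α = 0.05).
Calibration is validated by simulation (family-wise error ≤ 0.10 at nominal
0.05 over 200 null scans) and against a built-in permutation oracle, not by
formula identity with any published derivation.

## Peak support interval

The 1−α support interval holds the contiguous run of markers around the
peak whose statistic stays within d = χ²₁(level) (3.841 for 95%) of the
peak value, extended outward to the midpoint between the last inside and
first outside marker and clipped to chromosome ends (chromosome lengths
when known, else the marker span). An infinite peak keeps only the
infinite-statistic run inside. Requesting an interval when no marker
exceeds the genome-wide threshold is an error ("no QTL"); the pipeline
records the absence instead.

## QC and imputation

Markers with MAF < 5% or call rate < 0.80 are discarded; both are strict
inequalities, so a marker exactly at 0.05 or 0.80 is retained. MAF is
min(p, 1−p) with p = mean(coded)/2 over non-missing calls. Filtering is
idempotent.

Imputation: for a missing call at marker j in individual i, the 10 markers
nearest to j in bp on the same chromosome that are observed in i each vote
for the genotype class of j most frequent among complete-case individuals
sharing i's genotype at that neighbor, weighted by r²(j, neighbor); ties go
to the overall modal genotype of j; a chromosome with no observed neighbor
falls back to the modal genotype (logged). The estimator is this package's
documented choice — the neighbor count and the LD principle are the fixed
inputs — validated by the requirement that it strictly beats the
marker-wise modal baseline on family-LD data under the same mask. Observed
calls are never altered.

## Synthetic populations

The generator emulates the study design so every stage is testable without
external data. Defaults, chosen once:

- **9 families**, 48 offspring each, so the conditioned Z^T W cohort is
  ~171 in expectation (9·48·½·0.8); `simulate_ztw_cohort` grows family
  sizes geometrically if a draw falls short and keeps exactly the first n.
- **Marker panel**: per-chromosome counts and spans of the study's
  post-QC panel (33,410 SNPs over chromosomes 1–20 + W + Z), scalable by
  `marker_scale`; positions uniform; the two causal Z positions are always
  inserted.
- **Founder frequencies**: neutral alternate-allele frequencies uniform in
  [maf_low, maf_high] = [0.05, 0.5] (the study states none). Causal
  founder Z haplotypes carry T at locus 1 with probability 0.8 and A at
  locus 2 with probability 0.5.
- **Cross design**: normal ZZ sires carry one A and one G Z copy at
  locus 2 by default (`sire_het_locus2=True`), so reversal segregates
  within families at ~1:1 — matching the observed 94/77 split in a cohort
  of 171. With sire haplotypes drawn i.i.d. instead, families are often
  monomorphic-reversed and family-private markers separate the phenotype
  perfectly, a degenerate design the study's within-family variation rules
  out.
- **Transmission**: autosomes get exactly one uniform crossover per
  meiosis (order-of-magnitude realism; no genetic maps are used). The Z
  does not pair in ZW fish, so ZW dams pass an intact Z or W with
  probability ½, and pseudomale ZW sires pass only their intact T–A Z;
  ZZ sires recombine their Z pair like an autosome. WW zygotes cannot
  arise from these crosses (a lethality guard exists for custom ones).
- **Coding**: hemizygous Z calls in ZW fish are 0 or 2 on the diploid
  scale, never 1, unless the `duplication_het_rate` flag emulates the rare
  heterozygous AG calls at locus 2 attributed to a *Dmrt1* duplication.
  W markers are missing in ZZ individuals.
- **Penetrance**: the rule (T and ≥1 A ⇒ pseudomale) is deterministic;
  `penetrance_noise` flips the outcome with the given probability.
- One integer seed drives a single root generator; all sub-draws derive
  from it, so equal seeds give bit-identical populations.

What the generator does *not* emulate: environmental (temperature)
modulation of reversal — the study held temperature constant precisely to
suppress it; genotyping error; linkage maps or crossover interference;
realistic minor-allele spectra. Passing tests therefore demonstrate
correctness of the machinery under the stated genetic model, not robustness
to those real-data features.

## Problem sizes in the tests

The suite runs the scan cohort at 171 individuals on a 1/10-scale panel
(~3,300 markers) and the replicate-heavy checks (threshold calibration,
interval coverage) at 80–120 individuals on 1/50-scale panels with 100–200
replicates — sizes chosen to keep each property estimable with comfortable
margins while the whole suite stays quick.

## Offspring-ratio test

The printed comparison of 24 ZW : 22 ZZ offspring against the 2:1
expectation uses the two-sided χ² goodness-of-fit with 1 df, which yields
P = 0.037 exactly; the exact one-sided binomial alternative (P ≈ 0.029) is
available via `method="binomial"`. The χ² default is the documented choice
because it reproduces the published value.

## Known limitations

- Linear (liability-scale) treatment of a binary trait; no PQL/logistic
  variant, no covariates beyond the intercept, no dominance, no multi-locus
  forward selection.
- Threshold and support interval are approximations validated by
  simulation, not closed-form guarantees.
- Haplotype matching is exact string comparison over the 11-site panel; no
  phasing and no amino-acid translation of the exon-2 SNPs (the required
  cDNA context is external).
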