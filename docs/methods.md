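# Methods

`cfdonor` estimates the fraction *d* of plasma cell-free DNA (cfDNA)
fragments that originate from a transplanted graft, using only the
recipient's genotype, per-SNP cfDNA allele counts, and population allele
frequencies — no donor genotype. This note records the model, the numerical
and design choices, and what the synthetic benchmarks do and do not show.

## The observation model

For each bi-allelic SNP *i* with alleles A and B, the inputs are the
measured recipient genotype R\*ᵢ ∈ {AA, AB, BB}, the read counts (k_A, k_B)
of the two alleles in the cfDNA, and the allele-A frequency f of a candidate
donor population. Three error processes are modeled:

* **Genotyping error** e_g ∈ [10⁻⁹, 10⁻³]: the measured genotype deviates
  from the true genotype (r₁, r₂) through the kernel
  P(AA\* | r) = (1−e_g)² 𝟙{AA} + 2e_g(1−e_g) 𝟙{het} + e_g² 𝟙{BB},
  its allele mirror for BB\*, and the normalizing remainder for AB\*.
* **Sequencing error** e_s ∈ [10⁻⁹, 10⁻²]: each read reports the true
  fragment allele with probability 1−e_s (this also absorbs PCR error).
* **Mixture**: a fragment is donor-derived with probability *d* and carries
  allele A with probability equal to half the A-dosage of its genome of
  origin, so P(read A | r, dd) = d·dose_A(dd)/2 + (1−d)·dose_A(r)/2 passed
  through the error channel.

The donor genotype prior is Hardy-Weinberg from the candidate population
(f², 2f(1−f), (1−f)²) when donor and recipient are unrelated, and the
IBD-conditional tables when they may be related: with one haploid pair IBD
the donor keeps one allele identical to a random recipient haploid and
draws the other from the population; with two pairs IBD the donor genotype
equals the recipient's.

The per-SNP likelihood marginalizes the true recipient genotype, the donor
genotype, and each read's true allele; because every factor depends on
genotypes only through allele dosage, the sum collapses to 3×3 unordered
genotype classes with a per-class read factor p_A^{k_A} p_B^{k_B}. SNPs are
treated as independent and the genome log-likelihood is the sum. The
negative log-likelihood is minimized with bounded L-BFGS-B for each
candidate population and the best population is reported (ties broken by
listing order).

### Conditioning on the measured genotype

The likelihood is, by default, the *conditional* likelihood
P(reads | R\*; θ) = P(R\*, reads | θ) / P(R\* | θ). The joint form is also
implemented (`conditional=False`). The conditional form is the package's
default because the recipient genotype is an input measured once per
patient, not an observation the donor-fraction model should explain; and
empirically, maximizing the joint form pins e_g at its upper bound on
Hardy-Weinberg-distributed genotypes (the genotype marginal alone is
maximized at e_g ≈ 0.135 because a uniform genotype prior predicts more
heterozygotes than real genomes contain), which biases *d* through the
error-rate coupling. Conditioning removes that term; all printed kernels
are unchanged, and inference on *d* at fixed e_g is identical.

### Recipient-genotype prior

Two priors over the true recipient genotype are available: the population
Hardy-Weinberg prior (default) and a uniform ¼-per-ordered-pair
simplification (`recipient_prior="uniform"`), which is the form the
likelihood is usually written in because the measured genotype is highly
informative at realistic e_g. The HW prior is the default because it
matches how genotypes actually arise and keeps the likelihood well
specified at single-read coverage, where the posterior weight of hidden
heterozygotes — flat in f under the uniform prior, ∝ 2f(1−f) under HW —
is no longer dominated by the read data.

## Relatedness: the IBD hidden Markov model

Related donors (siblings are common in bone-marrow transplantation) share
identical-by-descent segments with the recipient, inside which donor
molecules are partly or wholly indistinguishable from recipient ones;
ignoring this underestimates *d* roughly two-fold for siblings. Each of
the two haploid pairs of the duo follows an independent two-state chain
(not-IBD / IBD) along pre-computed genetic blocks of ~2 cM (transitions
only between blocks, which also damps linkage disequilibrium). For a pair
separated by m meioses (m = 1 − log₂ P_IBD, with the marginal IBD
probability P_IBD ≤ 0.5, which excludes parent-child duos), and block
distance l cM with Haldane crossover probability θ = (1 − e^{−2l/100})/2,
the chain stays IBD with probability y₁y₂ where y₁ = (1−θ)^{m−2} and
y₂ = (1−θ)² + θ², and enters IBD with probability (1 − y₁y₂)/(2^{m−1} − 1).
This parameterization makes the stationary IBD mass exactly 2^{1−m} = P_IBD
(a unit test enforces this to 10⁻¹⁰). The joint chain over both pairs has
four states; emissions depend only on the IBD count (0, 1, 2), computed per
block as the sum of per-SNP log-likelihoods under the corresponding donor
prior. The forward algorithm (scaled, restarting at each chromosome with
the stationary distribution) integrates over paths; a forward–backward
decoder exposes per-block IBD posteriors as a diagnostic. The related fit
maximizes over (d, e_s, e_g, m₁, m₂), with the meiosis counts optimized
directly in their bounded box [2, 1 − log₂ 10⁻⁶] and the reported pair
canonicalized so p_ibd_1 ≥ p_ibd_2.

## Optimization

Parameters are optimized in transformed coordinates — logit(d), log₁₀(e_s),
log₁₀(e_g), m linear — under their bounds. Two initialization modes exist:
`multi` (bounded runs from d₀ ∈ {0.001, 0.05, 0.3}) and `grid` (a coarse
scan over d ∈ [10⁻⁴, 0.99] × m ∈ {2, 3, m_max}, then one refinement per
relatedness regime). The likelihood couples d with the IBD probabilities —
"more related and more donor" can mimic "less related and less donor" — so
the related fit always refines from the best related-regime cell *and* the
best unrelated-limit cell and keeps the better optimum; the two meiosis
starts are nudged apart (m, m+0.2) so coordinate-wise gradients can leave
the symmetric diagonal. Any of (d, e_s, e_g) may be pinned
(`FitOptions.fixed_*`); block emissions are cached on (d, e_s, e_g), so
finite-difference perturbations of the relatedness parameters reuse them.
Convergence uses L-BFGS-B's relative ftol = 10⁻¹², gtol = 10⁻⁷,
maxiter = 200.

### Pre-transplant error calibration

At very low coverage (~1 read per covered SNP), e_s, e_g and small d are
three nearly-flat explanations of rare mismatching reads; jointly free,
they trade off along a ridge that the e_s ≥ 0 bound truncates
asymmetrically, inflating d̂ (observed: ≈ +140% relative at d = 0.25%,
0.1× coverage). The benchmark pipeline therefore estimates (e_s, e_g) once
per subject from a pre-transplant cfDNA sample — a fit with d pinned at
zero (`calibrate_error_rates`), the model analog of measuring the assay
background at homozygous sites — and fixes them in the post-transplant
fit (`run_benchmark(calibrate_errors=True)`, the default there). With
fixed nuisances the estimator is unbiased at every coverage tested.
Calibration runs on the unfiltered SNP set: the genotyping-error filter
(below) selects against homozygous sites whose pre-transplant reads happen
to carry errors, and calibrating after it would underestimate e_s by
~25–30%. The plain `fit_unrelated` / `fit_related` API defaults keep all
nuisances free.

## The synthetic-data generator

The simulator generates from the model's own generative assumptions, which
makes parameter recovery a well-posed oracle:

* allele frequencies Uniform(0.05, 0.95) per SNP (optional extra
  populations with Gaussian divergence);
* a uniform 1 cM/Mb genetic map over 22 equal autosomes totalling 3500 cM,
  with ~2 cM blocks built by the same code used for inference;
* recipient genotypes Hardy-Weinberg, observed through the genotyping-error
  kernel (e_g = 10⁻⁴ by default);
* donor genotypes drawn from the IBD-conditional tables along a joint IBD
  path sampled from the same transition matrices used for inference
  (p_ibd = 0 gives an unrelated donor);
* per-SNP coverage Poisson (mean 1.75 by default, matching ~26M 100-bp
  read pairs genome-wide), fragment origin Bernoulli(d), allele from a
  random chromosome of the origin genotype, flipped with e_s = 10⁻³;
* the study's down-sampling steps: top-K SNPs per block by alternative
  allele frequency, binomial read thinning to a target coverage, and a
  pre-fit filter removing homozygous SNPs whose own (pre-transplant) reads
  contain the absent allele (≥1 absent read among ≥4 covering reads; the
  thresholds are exposed because only the outcome, ~0.2% of SNPs on real
  data, is documented).

What it does **not** emulate: real read alignment (mappability, allele-
specific mapping bias), array SNP ascertainment (frequencies here are
uniform rather than array-chip MAF spectra), linkage disequilibrium within
blocks (SNPs are conditionally independent given the IBD state — the same
assumption inference makes), population mis-specification (the donor is
drawn from a listed population), index hopping or contamination. Passing
benchmarks therefore demonstrate correctness and statistical efficiency of
the estimator under its own assumptions, not robustness to real-data
artifacts.

## Benchmark designs and problem sizes

The sweep designs (`cfdonor.designs`) probe: full-coverage accuracy across
relatedness (11 fraction levels spanning 0.01%–25% × three relatedness
levels), the lowest coverages (0.1× unrelated / 1× sibling over 0.1%–25%),
reduced inputs (~150K SNPs at 1× or 0.33× coverage over the clinical
0.2%–10%), and ultra-low fractions (<0.1%). Fraction levels are spaced
several error standard deviations apart, wider at the bottom of the range:
below ~0.1% the absolute error floor makes log-dense neighbouring fractions
statistically indistinguishable, and a rank correlation over such a grid
measures noise rather than fidelity. Because every relatedness arm sweeps
the same levels, rank correlations are computed per arm (pooled ranks would
be tie-limited by construction) and the minimum across arms is reported.
Error metrics pool all replicates.

Estimation error scales with the number of sequenced reads
(≈ SNPs × coverage), so sweeps are run at reduced SNP counts chosen for
single-CPU runtimes: the acceptance script uses 300K SNPs for the
full-coverage sweep, 500K/250K for the low-coverage arms, 150K/600K for the
reduced-input arms and 600K for the ultra-low-fraction sweep; the test
suite scales down further (150K/300K-class sweeps). Each grid point draws its seed deterministically from
the master seed via `numpy` seed sequences; identical seeds reproduce
bit-identical sweeps (timing columns aside).

## Numerical choices

* Population frequencies are clamped to [10⁻⁴, 1−10⁻⁴] so monomorphic SNPs
  cannot contribute −∞.
* Per-SNP read factors are computed as k_A log p_A + k_B log p_B with the
  per-class probabilities formed directly (p_B from 1−p mixture algebra,
  not 1−p_A, which loses precision when p_A → 1); the 9-class sum is
  shifted by its per-SNP maximum before exponentiation.
* Zero-coverage SNPs contribute a closed-form genotype-marginal term (zero
  under the conditional likelihood) and are excluded from the vectorized
  kernel; at 0.1× coverage this removes ~90% of the work.
* The hot kernel has a numba-compiled path and a pure-numpy reference path;
  a unit test keeps them within 10⁻¹² of each other, and both within 10⁻¹⁰
  of exhaustive enumeration.
* The forward pass rescales per block and accumulates log-norms; block
  emissions shifted by their per-block maximum.
* Chromosomes restart the IBD chain at the stationary distribution — the
  only initial law consistent with the marginal-P_IBD semantics.
* SNP cM positions interpolate linearly between map points, with constant
  extrapolation outside the map span; inter-block distances are
  midpoint-to-midpoint cM.

## Known limitations

* Point estimates only; no confidence intervals.
* Parent-child duos are outside the related model (P_IBD ≤ 0.5); the
  conventional workaround — doubling the unrelated-model estimate — is
  exposed as an explicit flag, never applied automatically.
* Mixed donor ancestry is not modeled; the population scan picks a single
  best panel.
* The two-genomes module is a minimal pooled-count reference estimator for
  cross-validation, not a reimplementation of the full clinical pipeline.
* At fractions below ~0.1%, relative error grows as the donor signal
  approaches the error floor; absolute error stays small (the ultra-low
  sweep quantifies this).
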