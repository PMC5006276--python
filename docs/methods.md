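# Methods

## Model

Each phenotype group's genotype vector **a** = (a₁, …, a_m) is modeled
by an exponential-family distribution

    Pr(a | y) = Z_y⁻¹ exp( Σᵢ hᵢ⁽ʸ⁾ aᵢ + Σ_{i<j} J_ij⁽ʸ⁾ aᵢ aⱼ ),

the discrete analogue of the class-conditional Gaussian in classical
discriminant analysis: the fields h play the role of the mean, the
couplings J the role of the (inverse) covariance. For binary encodings
(dominant: aᵢ = 1 for carriers; recessive: aᵢ = 1 for minor-allele
homozygotes) this is an inverse Ising model. The genotypic model keeps
the three-level code through a reference-category parameterization:
level 0 carries zero energy, each SNP has two fields hᵢ(g), g ∈ {1, 2},
and each pair a 2×2 coupling block J_ij(g, g′), which reduces exactly
to the binary form when levels collapse and yields the degree-of-freedom
counts used in the tests (1 vs 2 per site, 1 vs 4 per pair).

Bayes' theorem turns the two fitted distributions into a logistic-form
risk model with β = h⁽¹⁾ − h⁽⁰⁾, γ = J⁽¹⁾ − J⁽⁰⁾ and intercept
α = logit(p₁) + ln Z₀ − ln Z₁, where p₁ is the disease prevalence.
Because the groups are modeled separately, the method sees differential
population structure (e.g., case-specific LD) that a conditional model
of Pr(y|a) averages out.

## Fitting and the penalizer

All routes maximize the penalized log-likelihood **per individual**

    L_y / n_y = (1/n_y) Σ_k ln Pr(aᵏ | y) − (λ/2) Σ_{i<j} J_ij²,

so the total penalty is n_y·(λ/2)·ΣJ². This convention makes λ's
shrinkage strength independent of sample size: λ → ∞ reaches the
independent-SNP limit at any n, and fitting case, control, and pooled
samples of identical composition returns identical parameters at any λ.
Fields are never penalized, and an ℓ₂ (not ℓ₁) penalty keeps the
objective smooth and strictly concave.

* **Exact enumeration (EE).** The log-partition gradient equals the
  model moments, so the concave objective is maximized by damped Newton
  iterations on the flat parameter vector; convergence is declared when
  the per-individual moment mismatch falls below 10⁻⁸ (hence empirical
  moments are reproduced to well under 10⁻⁶ at λ = 0), with an
  iteration cap of 500 and a step-halving line search. The objective
  depends on data only through mean sufficient statistics, so repeated
  refits (cross-validation folds, restricted models, permutations) are
  cheap; an internal engine caches the collapsed row table and reuses
  the unrestricted optimum's Hessian factor to precondition restricted
  refits. State-table limits: m ≤ 20 (binary) / 12 (genotypic) for
  fitting and 22 / 13 for the simulator's enumeration — chosen so the
  state table and feature matrix fit comfortably in a few GiB of
  memory. Beyond the dense-feature threshold the solver falls back to
  gradient-only quasi-Newton with on-the-fly moment accumulation.
* **Pseudo-likelihood (PL).** Each site's conditional distribution
  given the rest is a penalized (multinomial) logistic problem solved
  by Newton iterations on collapsed unique-row tables; the per-site
  problems are independent, dispatched through a pluggable `map_fn`
  (results are order-independent), and couplings are symmetrized by
  averaging J_ij and J_ji. At λ = 0 separation is possible; the solver
  flags non-convergence rather than failing.
* **Mean field (MF).** Couplings come from the inverse of the connected
  covariance matrix C_ij = f_ij − f_i f_j whose off-diagonal entries are
  multiplied by ε ∈ [0, 1] (within-SNP blocks kept exact in the
  genotypic case): J = −C(ε)⁻¹ off-diagonal, and fields from local
  consistency h = logit(f) − J f. ε = 0 reproduces the analytic
  independent solution exactly; ε interpolates linearly to the full
  naive-mean-field inversion at ε = 1 (no TAP correction). A singular
  covariance receives one 10⁻⁸ diagonal jitter (logged). The
  log-partition for MF (and PL) likelihood values is approximated by
  the variational mean-field free energy at the fitted parameters.
* **Independent-SNP solution.** h = logit(f) (binary) or
  h(g) = ln(f_g/f₀) (genotypic) in closed form; frequencies at 0 or 1
  receive a logged 0.5 pseudo-count so fields stay finite. The
  single-SNP test power uses the noncentral χ²₁ distribution with
  noncentrality equal to the expected likelihood-ratio statistic at the
  true carrier frequencies.

α for PL/MF risk models (no exact partition function) is calibrated by
a one-parameter intercept MLE on training data with the fixed linear
predictor, then shifted if a different prevalence is requested; this
reproduces the EE-exact α when Z is available and never affects AUC.

## Significance tests

The overall statistic is q = 2[(L₁ + L₀) − L_pooled] (clipped at 0).
Site and pair statistics restrict the model by pinning the tested
parameter — h_i (both groups) or the J_ij block — to its pooled-fit
value at the same penalizer and re-optimizing every remaining
parameter; q is twice the full-minus-restricted objective summed over
groups. At λ = 0 and m = 1 this reduces exactly to the classical 2×2
(or 2×3) G-test. Single-SNP p-values use the asymptotic χ² distribution
with 1 (binary) or 2 (genotypic) d.f.; because the penalizer compresses
null statistics, these are upper bounds. Interaction p-values never
rely on asymptotics: empirical null distributions are built by
reshuffling phenotype labels (group sizes preserved), refitting at the
same penalizer, and recording q_ij per pair; the add-one estimator
p = (1 + #{q_null ≥ q_obs})/(1 + N) keeps p in (0, 1]. One child
random stream is spawned per permutation index, so results are
independent of execution order and extending N preserves earlier
draws. For the closed-form MF route the restricted value is plugged in
without re-optimization (there is no optimization to restrict);
validity rests on the permutation null either way. Per-pair null CDFs
are kept separate rather than pooled.

## Prediction and cross-validation

AUC uses the Mann-Whitney estimator with midrank tie handling and the
Hanley-McNeil 95 % confidence interval. Cross-validation stratifies
folds by phenotype, pools held-out scores across folds into a single
ROC (stabler than averaging fold AUCs at n ~ 10³; a documented choice —
the alternative is not exposed), and selects the penalizer maximizing
AUC with ties broken toward the stronger regularization. Default grids:
13 logarithmic points 10⁻⁴…10² for λ, 11 linear points 0…1 for ε.
When an independent-SNP p-value cutoff p_c is supplied, the p-values
are computed on each training fold alone before filtering, making the
reported score an unbiased AUC; if SNPs were instead pre-selected using
the full sample's phenotypes the caller must flag it and the score is
labelled pAUC, which over-estimates the true AUC.

## Quality control and encoding

Per-SNP filters: pooled minor-allele frequency > 0.01, exact
Hardy-Weinberg test p > 10⁻⁶ computed on controls only (standard GWAS
practice; the threshold is configurable), and per-SNP missingness
< 0.05 (the conventional reading of a "genotyping rate" filter — a 5 %
genotyping-rate floor would exclude nothing). After filtering, the
minor allele is re-identified from pooled frequencies and counts
re-oriented so pooled frequency ≤ 0.5. Missing genotypes are imputed
deterministically to the per-SNP modal genotype of the pooled sample —
stochastic imputation inside a likelihood pipeline would make results
seed-dependent in a way that is hard to audit. Positions are 1-based as
in .map/.bim; alleles are taken as given (no strand flipping). Samples
with phenotype codes outside {1, 2} are dropped with a logged count.

## Simulator

Case and control parameters are drawn around group-specific means,
h⁽ʸ⁾ ~ N(h̄_y, σ_h²) and J⁽ʸ⁾ ~ N(J̄_y, σ_J²); the full state space is
enumerated, weights normalized exactly, and each group sampled by one
multinomial draw — no Markov chain, so samples are exact draws from the
model. By default the Gaussian noise realization is shared between the
two groups with only the means differing (`shared_noise=False` gives
independent draws). The shared default makes the true risk parameters
exactly the mean differences — every pair not given a distinct case
mean is exactly null — which is the property the sensitivity/specificity
designs rely on ("interaction effects cancel except the causal pair").
Parameter sampling and genotype sampling consume disjoint child streams
of one seed, so adding SNPs or redrawing genotypes never perturbs the
other stage. Three canonical designs ship as constructors: dense
effects (h̄ = (−1, −0.3), J̄ = (0, 0.1), σ = 0.2, m = 10), sparse
effects (m = 20 with 4 causal sites, Δh = 0.7, ΔJ = 0.5), and the
single-causal-pair design (shared means except one pair with case
coupling mean 0.11 vs 0.01, σ_h = 0.1, σ_J = 0.05).

What the simulator does not emulate: realistic LD block structure from
recombination, allele-frequency spectra, genotyping error, population
stratification, or covariates. Passing tests on these panels
demonstrates correctness of the inference machinery under the model's
own assumptions, not robustness to real-data artifacts.

## SNP sets and enrichment

SNPs are assigned to a gene when they lie within a window (default
50 kb) of its coding region (BED 0-based half-open; SNP positions
1-based); a pathway's set is the union over its genes, and sets with
fewer than 20 SNPs are dropped. Sets are scored by cross-validated AUC
of collective inference (ε-optimized MF by default) next to the
independent-SNP AUC, with identical fold assignments across sets so
scores are comparable; sets above 6000 SNPs get within-fold p_c
filtering. AUC→p calibration follows the permutation route: for a
selection of low-AUC sets (the 10 nearest 0.5 plus 5 evenly spaced
upward — the selection is configurable since no canonical rule exists)
label permutations with the set's CV AUC as statistic give empirical
p-values; −log₁₀p is regressed linearly on AUC above 0.52 with a
non-negative slope enforced, and the Bonferroni threshold is the AUC
mapping to p = 0.05/(number of scored sets at runtime).

Chromatin-state enrichment: each SNP contributes the fraction of its
LD proxies (user-supplied table; an r² helper exists for synthetic
phased haplotypes) overlapping "active" states; the fractions sum to a
real-valued effective count, rounded half-up for a binomial upper-tail
test against the epigenome's genome-wide active fraction (the
unrounded value is available). SNP-pair enrichment multiplies the two
proxy groups' active fractions per pair and tests against the product
of the two backgrounds; the test is symmetric under swapping the
epigenomes together with the proxy roles.

## Problem sizes in the test suite

The simulation-based properties run at reduced scale chosen to keep the
full suite a routine local run: accuracy-versus-n uses 20 parameter
realizations of the m = 10 dense design over n ∈ {10², 10³, 10⁴} with a
5-point λ grid; the sensitivity/specificity study uses 20 replicates of
the single-causal-pair design at n = 10⁴ with 199 permutations per
replicate; method-agreement checks use m ≤ 6 panels at n = 10⁴. The
suite asserts medians and rank properties rather than per-replicate
outcomes wherever a quantity is stochastic.

## Known limitations

* Exact fitting and the simulator are bounded by state-space
  enumeration; larger panels must use PL or MF.
* The naive mean-field coupling estimate is biased at strong couplings
  (|J| ≳ 0.5); it is intended for large panels where EE/PL are too
  slow, with EE as the small-panel reference.
* Restricted-model statistics for MF are plug-in, not re-optimized.
* The pairwise baseline's genotypic interaction "estimate" is a 2×2
  block summarized by its largest-magnitude entry; the LR statistic
  (4 d.f.) is the primary output.
* Under the single-causal-pair study conditions at n = 10⁴ the causal
  pair's coupling difference (γ = 0.1) sits near the information bound
  of any estimator (noncentrality ≈ 1), so the minimum-p detection rate
  across replicates remains low at that sample size and rises steeply
  by n = 10⁵; an independent per-pair Wald oracle shows the same
  behavior, indicating a property of the design rather than of the
  fitting machinery.
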