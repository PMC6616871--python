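# Methods

## Model

Phenotypes follow the standard quantitative-genetic mixed model. Under the
null (no candidate SNP):

    y = Xβ + ξ + e,    ξ ~ N(0, K φ²),    e ~ N(0, I σ²)

so Var(y) = (Kλ + I)σ² = Hσ² with λ = φ²/σ². The kinship matrix is
K = ZZᵀ/d built from raw 0/1/2 allele counts (codes count the major
allele), with d = trace(ZZᵀ)/n so that the mean diagonal of K is 1. No
centering or per-SNP standardization is applied by default; a centered
variant exists behind a flag for comparison. Raw codes make K close to a
rank-one matrix plus relatedness structure; the rank-one component lies
along the all-ones direction and is absorbed by the intercept, so it is
harmless for inference but dominates the eigenvalue spectrum (see
*Identifiability* below).

When SNP k is tested it enters as a fixed effect and the polygenic
covariance switches to the modified kinship

    K' = (ZZᵀ − Z_s Z_sᵀ)/d

where Z_s holds every marker on k's chromosome within the exclusion window
of k, including k itself, and d is the full-panel normalizer (never
recomputed per candidate). K' equals the kinship of the remaining markers
up to that fixed scale and is therefore positive semidefinite.

### Exclusion window

The window parameter is a half-width in base pairs, default 500 000, so the
default span is 1 Mb centered on the candidate ("a 1 Mb window around the
SNP" is read as a centered span; both readings are supported since the
half-width is a free parameter). Coordinates are 1-based and the window is
inclusive at both ends. Half-width 0 excludes the candidate alone; the
scanner also has an `exclude_window=False` mode that removes nothing — the
classical inclusion-kinship scan, kept as the comparison baseline for the
proximal-contamination effect.

## Restricted maximum likelihood

With K = U D Uᵀ (one eigendecomposition per data set, cached; eigenvalues
clamped at zero when within −1e−8, eigenvector signs fixed so the
largest-magnitude element is positive), rotate y* = Uᵀy, X* = UᵀX. Then

    ln|H|      = Σ_j ln(δ_j λ + 1)
    aᵀH⁻¹b    = Σ_j a*_j b*_j / (δ_j λ + 1)

and, profiling β and σ² at fixed λ,

    β̂  = (X*ᵀH⁻¹X*)⁻¹ X*ᵀH⁻¹y*
    σ̂² = (y* − X*β̂)ᵀH⁻¹(y* − X*β̂) / (n − r)        (REML divisor n − r)
    L(λ) = −½[(n−r)(ln 2πσ̂² + 1) + ln|H| + ln|X*ᵀH⁻¹X*|]

All constant terms are included, so reported log-likelihoods are absolute;
differences match a dense evaluation of the restricted likelihood to
1e−8 (tested against a dense-inverse oracle).

### Optimization

λ is maximized on [1e−5, 1e5] by Newton iteration on u = ln λ (guaranteeing
positivity) starting from λ₀ = 1. Derivatives are central finite
differences with h = 1e−4; the step is clipped to |Δu| ≤ 2; convergence at
|Δu| < 1e−8 or 50 iterations. If the curvature is non-negative or a step
leaves the bracket, a golden-section search over the full bracket takes
over. The final point is cross-checked against a 129-point grid on ln λ and
refined from the grid optimum if that beats the Newton point — a guard
against rare multimodal profiles that costs little. Boundary optima are
flagged `boundary`; a flat profile (e.g. K = I, where λ and σ² are not
separately identifiable) is flagged `unidentifiable` with `converged =
False` and λ reported at its initializer.

### Identifiability

REML can only separate φ² from σ² when relatedness varies across pairs.
For a panel of mutually unrelated individuals in Hardy–Weinberg
equilibrium, K is approximately a constant matrix plus O(1/√m) noise:
after removing the intercept direction the remaining eigenvalues are
nearly equal, the profile in λ is almost flat, and λ̂ is dominated by
sampling noise. Variance-component recovery checks therefore run on
related panels (`simulate_related_panel`: the pedigree design reduced to
n = 500 with 20 founders and four generations of 10 males + 110 females),
which carry parent–offspring, full-sib and half-sib structure like the
populations such scans are used on. This is a property of the model, not
of the implementation.

## The scan

λ̂ and σ̂² are frozen from the null fit for every SNP (the plug-in /
"population parameters previously determined" strategy; no per-SNP
re-estimation — by design, not as an approximation knob). For SNP k the
covariance is

    V_k = K'λ̂ + I = H − (λ̂/d) Z_s Z_sᵀ,    H = Kλ̂ + I

and V_k⁻¹ is applied through the Woodbury identity with A = H (diagonal in
the eigenbasis) and B = sqrt(λ̂/d)·Z_s:

    V_k⁻¹ = A⁻¹ + A⁻¹B (I_s − BᵀA⁻¹B)⁻¹ BᵀA⁻¹

Since V_k = (λ̂/d)Z_{−s}Z_{−s}ᵀ + I is positive definite, the s×s
capacitance matrix is invertible; a Cholesky failure (numerically singular
capacitance) falls back to a dense solve with a warning. The engine works
entirely in the rotated basis, caching UᵀZ, UᵀX, Uᵀy once, so a SNP costs
O(n·s + s³) with s ≪ n.

Effects come from GLS normal equations on W = [X z_k]:

    θ̂ = (WᵀV_k⁻¹W)⁻¹ WᵀV_k⁻¹ y,    γ̂_k = θ̂ last entry
    var(γ̂_k) = σ̂² [(WᵀV_k⁻¹W)⁻¹] last diagonal

algebraically identical to the mixed-model-equation BLUE; a single code
path keeps it directly testable against a dense GLS oracle (agreement to
1e−8 on random instances). The Wald statistic W_k = γ̂_k²/var(γ̂_k) is
referred to χ²(1). By default var(γ̂_k) uses the null-model σ̂²; an option
re-profiles σ² from the per-SNP GLS residuals (off by default). p-values
use the survival function with −log10 p computed from the log-tail, so
extreme signals never underflow to exactly zero; reported p is floored at
the smallest positive normal double.

Monomorphic SNPs and SNPs lying in the column span of X produce flagged NA
records rather than exceptions; the scan always emits one record per SNP
in map order.

## Quality control

Defaults follow common chip-data practice: individuals with >10% missing
genotypes are removed first, then SNPs with call rate <90%, minor allele
frequency <5%, or a Hardy–Weinberg chi-square (1 df, goodness-of-fit on
the three genotype counts) p < 1e−6. Thresholds are strict inequalities —
a marker exactly at a boundary is kept — and each removed SNP is counted
against the first criterion it fails. The exact HWE test is not
implemented; at these sample sizes the chi-square approximation is the
standard filter. Missing genotypes are mean-imputed per SNP (producing a
real-valued matrix used downstream); QC is applied to whatever matrix it
is given, before imputation in the CLI pipeline.

## Simulation experiments

### Scenarios 1–3 (unlinked panel)

`simulate_genotypes` draws independent SNPs in Hardy–Weinberg proportions
with MAF ~ Uniform(0.05, 0.5), equally spaced over a fixed synthetic
genome of 5 chromosomes × 24 Mb (a compact plant-genome scale; a smaller
panel means sparser markers, not a smaller genome, so exclusion windows
behave consistently across panel sizes). Defaults n = 199, m = 10 000.

Six QTNs with target heritabilities (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
at allele frequency 0.30 are placed on columns whose sample MAF is nearest
0.30, mutually unlinked (different chromosomes or ≥1 Mb apart). Effects
are calibrated from the heritabilities: with residual variance σ_e² = 10
and fixed background variances Bg,

    V (1 − Σ h_i²) = σ_e² + Bg,     β_i = sqrt(h_i² V / (2p(1−p)))

Scenario 1 has Bg = 0 (V = 10/0.55 = 18.18); scenario 2 adds a polygenic
effect MVN(0, 2K) using the panel's own kinship (Bg = 2, V = 21.82, so the
implied polygenic heritability is 2/21.82 = 0.092); scenario 3 adds three
epistatic pairs, each the elementwise product of two mean-centered
non-QTN columns scaled to contribute variance 1.25 (Bg = 3.75, V = 25, so
each pair's share is 0.05). The grand mean is μ = 10, read as the
intercept of the phenotype model (the heritability calibration is binding
for effect sizes). Centering the epistatic incidence keeps it nearly
orthogonal to the marginal effects. Every generator is a pure function of
(config, seed); a truth record stores indices, effects and the seed.

### Pedigree experiment

Five generations: 20 founders (10 males, 10 females), then four
generations of 20 males + 1000 females each (4100 individuals in total).
Each generation is sired by the males of the previous one with dams
sampled with replacement; from G2 on, each of the 20 sires serves 51
matings (the printed design); G1's 1020 offspring are split 102 matings
per G0 male, since a 20-individual founder generation cannot supply 20
sires and separate dams — the package's resolution of an under-determined
corner of the design. Sexes within a generation are assigned at random
with exactly 20 males.

The genome is 5 chromosomes × 100 Mb with 2000 equally spaced SNPs each
(50 kb spacing). Founder haplotypes are Bernoulli draws at per-SNP allele
frequencies ~ Uniform(0.1, 0.9); gametes are gene-dropped with Haldane
recombination at 1 cM/Mb (no interference, no mutation), implemented as a
Markov switch process between the two parental haplotypes.

50 QTLs are drawn from the even SNP indices with pleiotropic effects on
three traits, multivariate normal with unit variances and correlation 0.5
between traits 1–2, 0 elsewhere (the source design does not print its
trait covariances; these defaults are declared, configurable, not
inferred). Per-trait residual variances are set so realized heritabilities
in the analysis set — the 3000 females of G1–G3 — equal (0.35, 0.35,
0.50).

### What the generators do and do not emulate

The unlinked panel reproduces allele-frequency spectra, Hardy–Weinberg
genotype proportions and the exact variance bookkeeping of the QTN
scenarios, but carries no linkage disequilibrium and no population
structure — so passing power/calibration tests on it says nothing about
LD-induced clumping of signals or structure confounding. The pedigree
design supplies realistic family LD and relatedness but not
population-level admixture. Real-data features such as genotyping error,
imputation artifacts and selection are out of scope.

## Evaluation

Per-QTN power is the fraction of replicates where that exact marker's
p-value clears the threshold (0.05/m by default). For the dense-QTL
experiment a significant SNP within 100 kb of a true QTL also counts:
significant SNPs are matched to QTLs greedily, nearest first, each QTL and
each SNP at most once (the matching rule is not specified by the power
definition; greedy nearest-first is declared and brute-force tested), and
power is matched QTLs / 50. The false-positive denominator is the set of
tested SNPs that are neither true QTLs nor within the window of one — a
declared choice that makes null calibration testable (rate ≈ α under the
null). ROC points evaluate (FPR, power) at significance levels 1e−7 …
1e−2. Manhattan/QQ tables are exported as data; plotting is left to the
caller.

## Numerical choices and limitations

- Eigenvalues of K clamped at 0 within −1e−8; kinship reconstruction and
  orthogonality verified to 1e−8/1e−10 in tests.
- Ties in QTN selection broken by stable sort order; QTL placement
  without replacement among even indices.
- Problem sizes in the test-suite and acceptance script are reduced
  (panels of a few hundred to a few thousand SNPs, 50–200 replicates),
  stated per test; design constants (heritabilities, variances, counts)
  are never scaled.
- Not implemented: exact per-SNP REML (EMMA-style), score/likelihood-ratio
  tests, genomic-control correction, leave-one-chromosome-out kinship,
  pedigree-based (non-marker) relationship matrices, VCF input,
  sex-chromosome handling, imputation beyond per-SNP means.
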