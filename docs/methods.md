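# Methods

## Polarization model

The ancestral-allele caller treats each site independently. The focal
panel contributes a base-count vector over {A,C,G,T} (at most two bases
nonzero — multi-allelic sites are excluded upstream); each of up to three
outgroups contributes one base or a missing call, with at least one
outgroup required per site.

The generative model: the focal-ancestor node carries base `a` with
uniform prior 1/4 (K2 is reversible with uniform stationary distribution,
so the ancestor can serve as the likelihood root). Along each of the five
branches of `((focal, yak) node2, sheep) node3, camel` — ancestor→node2,
yak→node2, node2→node3, sheep→node3, camel→node3 — bases substitute under
K2 with a shared transition/transversion ratio κ and per-branch expected
substitution counts t. The closed-form K2 transition matrix (rates
normalized so α + 2β = 1) is cross-checked in the tests against a
numerically exponentiated rate matrix, and the pruning computation against
brute-force enumeration over both internal node states.

The focal tip emits the observed count configuration given the ancestor
base: a site monomorphic for `a` has weight π₀; a site segregating `a`
with alternative base `m` at derived count k has weight
relrate(a→m)·π_bin(k), where relrate is the K2 relative mutation rate
(transitions κ-fold likelier than each transversion) and π is a weight
vector over 20 derived-frequency bins plus a fixed-derived class, shared
across sites. This one-mutation emission assigns zero probability to the
hypothesis that neither segregating base is ancestral at a polymorphic
site; the residual "neither" posterior mass is therefore zero except at
monomorphic sites, and both probabilities are emitted.

Fitting is EM-flavoured coordinate ascent: the π update is a closed-form
EM step from per-site posteriors (given `a`, the SFS class is
deterministic); branch lengths and κ are then each updated by bounded 1-D
maximization of the marginal log-likelihood. Every step is
ascent-guaranteed, and the trace is checked for monotonicity. Convergence
is |Δloglik| < 1e−6 with a 500-iteration cap (non-convergence returns
best-so-far with a flag); inputs under 100 sites are flagged
low-information.

Decision rules use the posterior for the designated major allele
(`P_ancs`). At exact 50/50 sites the lower base index is designated so
`P_ancs` is always defined, and assignment falls to the outgroup-majority
tie-break; an outgroup tie (including the relevant bases all missing)
stays ambiguous — the conservative reading where the tie-break is silent.
Thresholds (0.8/0.2) are strict inequalities.

## Orthogonal coding and H′

For counted-allele counts (0, 1, 2) at counted-allele frequency p
(q = 1 − p), the additive and dominance codes are

    x' = (2p, p − q, −2q)        z' = (−2p², 2pq, −2q²)

Under HWE class weights (q², 2pq, p²) both are exactly mean-zero,
cov(x′, z′) = 0, Var(x′) = 2pq and Var(z′) = (2pq)² — enumeration
identities asserted to 1e−12 in the tests. The per-individual mean of z′
over a site partition is H′; because z′ is orthogonal to the additive
code, a regression coefficient on H′ estimates the (site-mean) dominance
deviation free of additive contamination, which the naive 0/1/0
heterozygosity H is not (cov(x, z) = 2p(1−p)(1−2p)). Site frequencies are
estimated once from the full analysis panel and reused for every
individual. Missing genotypes are coded 0 — the exact HWE mean of the
orthogonal codes — keeping the per-individual site count constant. The
simple H and the inbreeding product I = (Σ 2pᵢqᵢ)·H are computed for
completeness; H′ is the covariate used downstream. The H′ covariates
enter unstandardized (betas are per unit H′).

## Mixed models

The GRM follows the standard standardized-genotype convention
w = (x − 2p)/√(2pq), G = WWᵗ/m, with missing genotypes contributing 0.
REML for y = Xb + g + e, g ~ N(0, σ²_g G), e ~ N(0, σ²_e I) is solved on
the eigenbasis of G: the criterion is profiled over total variance and
maximized over h² by bounded 1-D search (tolerance 1e−8, 200-iteration
cap), with an explicit boundary check at σ²_g = 0. GLS fixed effects and
SEs come from the optimum. Association betas reuse one eigendecomposition
and one null-model variance estimate per trait (the standard leading-order
approximation); a per-variant re-estimation flag exists for small n.
Wald p-values use the normal reference, matching GWAS convention; the
resulting null type-I error at α = 0.05 is calibrated to within half a
percentage point at n = 500 (the t-vs-normal discrepancy is ~0.0007
there). Breeds enter as one-hot fixed effects, first level reference. The
directional-dominance test refuses joint fits when the two H′ covariates
are collinear beyond |r| = 0.999.

## BayesR

Effects on centred, unit-variance genotypes follow a four-component
normal mixture with variances (0, 10⁻⁴, 10⁻³, 10⁻²) × σ²_g. Single-site
Gibbs updates integrate the effect out to sample the component, then draw
the effect from its conjugate normal; fixed effects get conjugate normal
updates with a flat prior; σ²_e a scaled-inverse-χ² update (df 4, scale
anchored at the start value); mixture proportions a Dirichlet(1,1,1,1) +
counts update. Chain defaults are 10,000 iterations, 2,000 burn-in, thin
10, all configurable; residuals are refreshed from scratch every 200
sweeps against numerical drift; a fixed seed reproduces the chain bitwise
(the inner loop is numba-compiled with its own seeded RNG).

σ²_g stays **fixed** at its start value (typically the REML estimate for
the trait) by default, making the component variances known multiples of
a pre-estimated additive variance as in the original mixture formulation;
a flag enables a scaled-inverse-χ² update instead. The fixed default is a
deliberate identifiability choice: with σ²_g sampled, a signal-free trait
collapses σ²_g toward zero, after which the null and 10⁻⁴σ²_g components
are indistinguishable and the posterior on the mixture proportions stays
diffuse — no sampler can then concentrate mass on the null component.
Even with σ²_g fixed, distinguishing the 10⁻⁴σ²_g component from the null
requires n·10⁻⁴·σ²_g/σ²_e of order 1; the null-calibration test sizes
itself accordingly (n = 20,000, 800 variants, prior anchored at the
phenotypic variance — the agnostic upper bound when no REML estimate
exists). Collapsing the mixture to one shared variance reproduces ridge
regression, which the tests verify against the closed form.

## Direction statistics

Class windows (5e−8, 5e−5, 0.05) are half-open with the lower edge
included, require the window in both cohorts plus sign concordance on
MA-oriented betas, and zero betas count as discordant. TDRed is adopted
as 2·(concordant fraction) − 1 clamped at zero — zero at chance, one at
perfect agreement; the originating method is external, so this adopted
form is flagged here rather than presented as printed.

The KS symmetry test compares the MA-oriented effect vector with its
negation. Fed to the standard two-sample KS null distribution (the
printed procedure), the two samples are perfectly dependent and the
p-values are anti-conservative — analytically, the variance of
F̂(x) + F̂(−x) − 1 is 2p/n where the two-sample null assumes 2p(1−p)/n;
empirically the type-I error is ≈ 0.10 at α = 0.05. The default mode
keeps the printed behaviour (exact method below 50 effects, asymptotic
above); `mode="signflip"` calibrates the same D statistic by resampling
random sign assignments, which is exact under the symmetric null and
yields uniform p-values. Use the signflip mode when calibrated inference
is the point; the default when comparability with the printed procedure
is.

LD clumping is greedy by ascending p (ties broken by position, then
allele order): the best unclaimed variant indexes a clump and claims all
unclaimed variants within 1 Mb center-to-center on the same chromosome
with genotype r² ≥ 0.3. Vp = (β/se)²/N; its agreement with 2p(1−p)β² on
a standardized trait is verified by simulation to within 2%.

## Population summaries

F_ST is the Weir & Cockerham (1984) multi-population estimator computed
per variant as a/(a + b + c) from the among-population, among-individual
and within-individual components; negative per-variant estimates are
retained in group means (truncation would bias them). Averaging
per-variant ratios carries the known mild downward Jensen bias relative
to a ratio-of-sums across variants — with 4 populations of 150 under
Balding–Nichols F = 0.1 the mean per-variant estimate is ≈ 0.093 — which
is within the Monte-Carlo tolerance used by the recovery tests and is the
convention of the per-variant reporting tools this mirrors. Group
standard errors (frequency and F_ST) use one LD-clumped representative
per clump, clumped within each variant group.

## Synthetic-data generator

The generator is the study design in executable form. Defaults: 4 breeds
of 100 individuals, 2,000 sites, derived-allele frequencies uniform on
(0.05, 0.95), Balding–Nichols divergence F = 0.1 (per-breed Beta draws
with expected across-breed variance F·p(1−p), matching the dairy-breed
differentiation scale), HWE genotypes within breed. Outgroups evolve from
the focal-ancestor base through the nested topology with branch lengths
(0.02, 0.02, 0.04, 0.06, 0.15) — ascending with the yak/sheep/camel
divergence ladder — κ = 2, and 10% per-outgroup missingness (re-drawn so
no site loses all three). REF/ALT orientation is randomized per site so
the MA-orientation machinery is genuinely exercised.

Phenotypes use the naive codings deliberately — y = breed mean + Σxa +
Σzd + polygenic + residual with x the 0/1/2 MA count and z the 0/1/0 het
flag — so the orthogonal re-parameterisation downstream is tested against
data generated under the parameterisation it is meant to disentangle.
Additive effects are sparse (5% causal, SD 0.05 trait units); dominance
deviations d ~ N(0.06, 0.03²) are planted at every conserved site (10% of
sites): the positive mean is the directional-dominance signal, sized so
the default panel (n = 400) detects it with t ≈ 5–6 by the power
calculation t ≈ d̄·√(n·m_cons·E[Var z′])/σ — comfortably above the 1.96
threshold without being trivial. The paper-scale distribution of
dominance effects at conserved sites is unknown; these defaults are
stated placeholders and the tests vary them (including sign flips and
all-zero controls). The polygenic term is u = Zs with s ~ N(0, σ²_poly/m)
on standardized genotypes, so cov(u) is exactly σ²_poly·G. Cohorts
("bulls"/"cows") split each breed alternately, giving two disjoint
equal-size GWAS populations. The selection shift is a deterministic
frequency displacement (±shift by true MA effect sign, clamped to
(0.005, 0.995)) applied before the breed draws — not a forward
simulation, so the planted contrast is exact for recovery tests.
Optional duplicated-column LD blocks (r² = 1 within block) support the
clumping tests; the generator makes no attempt at realistic decaying LD,
recombination maps, or sequencing error, so passing tests certify the
statistical machinery, not robustness to those features of real data.

## Problem sizes

Test and acceptance runs use desk-scale versions of each experiment:
10,000 sites for polarization accuracy, n = 500 × 10,000 null variants
for GWAS calibration, 20 seeds × n = 400 for the dominance power and
null checks, n = 1,000 × 5,000 variants (10 causal) for BayesR recovery
and n = 20,000 × 800 for its null calibration, 4 × 150 individuals ×
5,000 sites for F_ST recovery. The analysis scripts use a single
1,000-individual panel. These sizes were chosen so each check's
Monte-Carlo error is small against its tolerance.

## Known limitations

- The polarization emission model allows one mutation per site; sites
  needing two (neither observed base ancestral) get zero likelihood, so
  "neither" calls arise only via ambiguity, not positively.
- The per-variant F_ST mean carries the ratio-estimator bias noted above.
- The printed-procedure KS mode is anti-conservative by construction; see
  above.
- Single-GRM, single-trait REML only; no multi-chain convergence
  diagnostics for the Gibbs sampler beyond seed-reproducibility and the
  ridge cross-check.
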