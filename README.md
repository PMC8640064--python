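# mutpolar

Mutant-allele analysis for complex traits: which allele at each segregating
site is the evolutionary newcomer, and do those mutant alleles push traits
in a preferred direction?

The package implements, as a tested pipeline over a ground-truth synthetic
generator, the analysis chain used to ask that question in livestock
genetics:

1. **Ancestral-allele polarization.** For each biallelic site in a focal
   panel, the joint probability of the focal allele counts and up to three
   nested outgroup bases (yak, sheep, camel on the rooted topology
   `((focal, yak), sheep), camel`) is computed under a Kimura two-parameter
   (K2) substitution model by Felsenstein pruning; branch lengths, the
   transition/transversion ratio κ and a binned unfolded-SFS weight vector
   are estimated by EM. The posterior probability `P_ancs` that the focal
   major allele is ancestral drives the decision rules: major allele
   ancestral if `P_ancs > 0.8`, minor if `P_ancs < 0.2`, an
   outgroup-majority tie-break for 50/50 sites, otherwise ambiguous. The
   non-ancestral allele is the mutant allele (MA).
2. **Directional dominance.** Genotypes are re-coded with the orthogonal
   additive/dominance parameterisation — x′ = (2p, p−q, −2q) and
   z′ = (−2p², 2pq, −2q²) for counted-allele counts (0, 1, 2) — under
   which cov(x′, z′) = 0 at Hardy–Weinberg proportions, so the
   per-individual mean of z′ (written H′) is a heterozygosity covariate
   uncorrelated with additive effects. Fitting H′ over conserved sites and
   H′ over the remaining sites jointly (with breed fixed effects and a
   polygenic GRM term, via eigendecomposition-based REML) tests whether
   dominance deviations have a positive mean — the signature of
   inbreeding depression concentrated at conserved sites.
3. **Effect estimation.** Per-variant mixed-linear-model association
   (EMMA-style single eigendecomposition, Wald tests) in two cohorts, and
   joint estimation under the BayesR four-component normal mixture
   (variances 0, 10⁻⁴, 10⁻³, 10⁻² × σ²_g) by Gibbs sampling. All effects
   are re-signed to the MA orientation in exactly one place
   (`orient_effects`); the MA effect is −1 × the ancestral-allele effect.
4. **Direction statistics.** Effect-size classes (p < 5e−8 / 5e−5 / 0.05
   in both cohorts with concordant signs), the TDRed concordance score
   (2 × concordant fraction − 1), the MA+/MA− count ratio, a KS test of
   the symmetry of the MA effect distribution, greedy LD clumping
   (r² < 0.3 within 1 Mb), and per-variant variance explained
   Vp = (β/se)²/N.
5. **Population summaries.** Per-breed MA frequency and multi-population
   Weir & Cockerham (1984) F_ST, with standard errors over LD-clumped
   variants.

Because the real cattle data (1000 Bull Genomes, national phenotype
archives) are access-controlled, the `simdata` module generates panels
with the statistical structure the analysis assumes — Balding–Nichols
breed divergence, HWE genotypes, K2-evolved outgroups, phenotypes with
directional dominance planted only at "conserved" sites, and
selection-shifted MA frequencies — with every generating choice recorded,
so each stage can be scored against the truth.

## Worked example

The numbered scripts under `analysis/` run the chain on the default
synthetic study (1,000 individuals across 4 breeds, 2,000 sites, seed
fixed in the scripts) and write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_polarize.py
python analysis/03_directional_dominance.py
python analysis/04_gwas_direction.py
python analysis/05_bayesr.py
python analysis/06_popgen.py
```

Output of `02_polarize.py`:

```
EM: 6 iterations, loglik -13002.2, kappa 2.00 (generator used 2.0)
assigned 1922/2000 sites (96.1%); high-confidence accuracy 98.49%
```

96% of sites clear the 0.8/0.2 posterior thresholds and 98.5% of those
calls match the true ancestral base; the fitted κ recovers the generating
value. `03_directional_dominance.py` then prints

```
      covariate      beta       se        t
   H_prime_cons 10.349845 1.494339 6.926037
H_prime_noncons  5.864464 4.491721 1.305616
directional dominance at conserved sites: detected (t = 6.93 vs threshold 1.96)
```

— the conserved-site heterozygosity covariate is strongly positive (the
generator planted mean-0.06 dominance deviations there) while the
non-conserved control stays below the 1.96 threshold. `06_popgen.py`
closes the loop on selection: mutant alleles that decrease the trait
(shifted down 0.05 in frequency at generation time) sit at mean frequency
0.474 vs 0.543 for trait-increasing MAs among causal sites, against a
breed differentiation of mean F_ST 0.092 (generator F = 0.1).

The same functionality is exposed as a CLI (`mutpolar simulate|ancestral|
coding|gwas|domtest|bayesr|direction|popgen|run`) for use on user-supplied
VCF/TSV data.

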