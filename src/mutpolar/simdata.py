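"""Synthetic genotype/outgroup/phenotype generator with recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* an ancestral population with derived-allele frequencies drawn uniformly
  on an interval, optionally displaced by a deterministic "selection shift"
  whose sign follows the true trait effect of the mutant (derived) allele;
* breed structure via the Balding-Nichols model: each breed's per-site
  frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F) draw around the ancestral
  frequency, giving expected differentiation F_ST ~ F;
* Hardy-Weinberg genotypes within breed;
* outgroup bases (yak, sheep, camel) generated by K2 substitution from the
  focal-ancestor base through the nested topology ((focal, yak), sheep), camel;
* phenotypes y = breed mean + sum_i x_i a_i + sum_i z_i d_i + polygenic +
  residual, built on the *naive* codings (x counts the mutant allele,
  z flags heterozygotes) so the orthogonal re-parameterisation downstream
  is tested against data generated under the naive model.  Dominance
  deviations with a positive mean are planted only at "conserved" sites.

Everything the generator decides is recorded in the truth table; nothing
is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import BASES, k2_relative_rates, k2_transition_matrix
from .genotypes import GenotypeMatrix

#: default branch lengths (expected substitutions/site), in the order
#: focal-ancestor->node2, yak->node2, node2->node3, sheep->node3, camel->node3.
#: Magnitudes follow the divergence ladder of the outgroups: yak splits from
#: cattle within Bos (a few My), sheep ~25 My, camel ~40 My.
DEFAULT_BRANCH_LENGTHS = (0.02, 0.02, 0.04, 0.06, 0.15)


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults describe a four-breed dairy-like panel with modest
    differentiation (F = 0.1, the dairy-breed baseline scale), a 10%
    conserved-site partition carrying positive-mean dominance, a sparse
    additive architecture and a polygenic + residual background.
    """

    n_per_breed: int = 100
    n_breeds: int = 4
    n_sites: int = 2000
    freq_range: tuple = (0.05, 0.95)
    F: float = 0.1
    branch_lengths: tuple = DEFAULT_BRANCH_LENGTHS
    kappa: float = 2.0
    outgroup_missing_rate: float = 0.1
    fraction_conserved: float = 0.1
    causal_fraction: float = 0.05
    additive_sd: float = 0.05
    dominance_mean: float = 0.06
    dominance_sd: float = 0.03
    polygenic_var: float = 0.5
    residual_var: float = 0.5
    breed_means: tuple | None = None
    selection_shift: float = 0.0
    ld_block_size: int = 1
    missing_rate: float = 0.0
    pos_spacing: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.F < 1):
            raise ValueError("F must lie in [0, 1)")
        if not all(np.isfinite(self.freq_range)) or not (
            0 < self.freq_range[0] < self.freq_range[1] < 1
        ):
            raise ValueError("freq_range must be finite with 0 < lo < hi < 1")
        if any(t <= 0 for t in self.branch_lengths) or len(self.branch_lengths) != 5:
            raise ValueError("need 5 positive branch lengths")
        if not (0 <= self.fraction_conserved <= 1):
            raise ValueError("fraction_conserved must lie in [0, 1]")
        for name in ("polygenic_var", "residual_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.selection_shift) >= 0.5:
            raise ValueError("selection shift magnitude must be < 0.5")
        if self.breed_means is None:
            self.breed_means = tuple(0.5 * i for i in range(self.n_breeds))
        if len(self.breed_means) != self.n_breeds:
            raise ValueError("need one breed mean per breed")

    @property
    def n_individuals(self) -> int:
        return self.n_per_breed * self.n_breeds

    @property
    def breeds(self) -> list:
        return [f"breed{i + 1}" for i in range(self.n_breeds)]


@dataclass
class SimData:
    """One simulated dataset plus all generating truth."""

    config: SimConfig
    truth: pd.DataFrame
    genotypes: GenotypeMatrix
    outgroups: pd.DataFrame
    phenotypes: pd.DataFrame
    breed_frequencies: np.ndarray
    realized: dict = field(default_factory=dict)


# --------------------------------------------------------------------------


def _draw_truth_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-site ancestral/derived bases, effects and annotations."""
    m = config.n_sites
    anc = rng.integers(0, 4, size=m)
    R = k2_relative_rates(config.kappa)
    derived = np.array([rng.choice(4, p=R[a]) for a in anc])
    conserved = rng.random(m) < config.fraction_conserved
    causal = rng.random(m) < config.causal_fraction
    a_eff = np.where(causal, rng.normal(0.0, config.additive_sd, size=m), 0.0)
    d_eff = np.where(
        conserved, rng.normal(config.dominance_mean, config.dominance_sd, size=m), 0.0
    )
    p0 = rng.uniform(*config.freq_range, size=m)
    if config.ld_block_size > 1:
        # duplicated-site LD blocks: sites within a block share frequency
        # (and later genotypes); annotations stay per-site
        block = np.arange(m) // config.ld_block_size
        first = block * config.ld_block_size
        p0 = p0[first]
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * config.pos_spacing,
            "ancestral": [BASES[i] for i in anc],
            "derived": [BASES[i] for i in derived],
            "conserved": conserved,
            "a": a_eff,
            "d": d_eff,
            "p_derived": p0,
        }
    )


def apply_selection_shift(
    frequencies: np.ndarray, effect_sign: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Displace mutant-allele frequencies according to their effect sign.

    Sites whose mutant allele decreases the trait (negative true effect,
    the "deleterious" set when the trait proxies fitness) lose
    ``selection_shift`` of frequency; beneficial sites gain it; zero-effect
    sites are untouched.  Results are clamped to (0.005, 0.995).
    """
    if abs(config.selection_shift) >= 0.5:
        raise ValueError("selection shift magnitude must be < 0.5")
    shifted = np.asarray(frequencies, dtype=float) + config.selection_shift * np.sign(
        effect_sign
    )
    return np.clip(shifted, 0.005, 0.995)


def simulate_breed_frequencies(
    config: SimConfig, p0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols per-breed frequencies around ancestral-population p0.

    Returns an (n_breeds, n_sites) matrix; with F = 0 every breed equals p0
    exactly.  Per-site across-breed variance has expectation F * p0 * (1 - p0).
    """
    p0 = np.asarray(p0, dtype=float)
    if not np.all(np.isfinite(p0)) or np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("frequencies must be finite and strictly inside (0, 1)")
    if config.F == 0:
        return np.tile(p0, (config.n_breeds, 1))
    ratio = (1.0 - config.F) / config.F
    alpha = p0 * ratio
    beta = (1.0 - p0) * ratio
    freqs = rng.beta(alpha, beta, size=(config.n_breeds, len(p0)))
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def simulate_genotypes(
    frequencies: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """HWE derived-allele counts (0/1/2) per individual, binomial within breed.

    ``frequencies`` is (n_breeds, n_sites); rows of the output are grouped
    by breed (n_per_breed consecutive rows per breed).
    """
    freqs = np.asarray(frequencies, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    parts = []
    for b in range(config.n_breeds):
        parts.append(
            rng.binomial(2, freqs[b], size=(config.n_per_breed, freqs.shape[1]))
        )
    geno = np.vstack(parts).astype(np.int8)
    if config.ld_block_size > 1:
        block = np.arange(geno.shape[1]) // config.ld_block_size
        first = block * config.ld_block_size
        geno = geno[:, first]
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = -1
    return geno


def simulate_outgroups(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Outgroup base calls by K2 substitution through the nested topology.

    Each site's focal-ancestor base evolves focal-ancestor -> node2
    (yak branch point) -> node3 (sheep/camel branch point); yak, sheep and
    camel tips are emitted from their parent nodes.  Missing calls ('.')
    are injected per outgroup at ``outgroup_missing_rate``, re-drawn where
    all three would be missing (downstream requires >= 1 outgroup).
    """
    t = config.branch_lengths
    if any(tb <= 0 for tb in t):
        raise ValueError("branch lengths must be positive")
    anc = np.array([BASES.index(b) for b in truth["ancestral"]])
    m = len(anc)

    def evolve(parent: np.ndarray, tb: float) -> np.ndarray:
        P = k2_transition_matrix(tb, config.kappa)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(parent))
        return (u[:, None] > cum[parent]).sum(axis=1)

    node2 = evolve(anc, t[0])
    yak = evolve(node2, t[1])
    node3 = evolve(node2, t[2])
    sheep = evolve(node3, t[3])
    camel = evolve(node3, t[4])

    calls = np.stack([yak, sheep, camel], axis=1)
    letters = np.array(list(BASES))[calls].astype(object)
    if config.outgroup_missing_rate > 0:
        miss = rng.random((m, 3)) < config.outgroup_missing_rate
        # guarantee at least one observed outgroup per site
        all_missing = miss.all(axis=1)
        keep = rng.integers(0, 3, size=m)
        miss[all_missing, keep[all_missing]] = False
        letters[miss] = "."
    return pd.DataFrame(
        {
            "chrom": truth["chrom"].to_numpy(),
            "pos": truth["pos"].to_numpy(),
            "yak": letters[:, 0],
            "sheep": letters[:, 1],
            "camel": letters[:, 2],
        }
    )


def simulate_phenotypes(
    derived_counts: np.ndarray,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Phenotypes under the naive additive + dominance decomposition.

    y = breed mean + sum_i x_i a_i + sum_i z_i d_i + polygenic + residual,
    with x the 0/1/2 count of the mutant (derived) allele and z the 0/1/0
    heterozygote flag.  The polygenic term is built from standardized
    genotypes (u = Z s, s ~ N(0, polygenic_var / m)), so its covariance is
    polygenic_var times the genomic relationship matrix.  Individuals are
    split into two equal cohorts ("bulls"/"cows") stratified within breed.

    Returns the phenotype table and the realized variance components.
    """
    x = np.where(derived_counts < 0, 0, derived_counts).astype(float)
    z = (derived_counts == 1).astype(float)
    n, m = x.shape
    a = truth["a"].to_numpy()
    d = truth["d"].to_numpy()

    additive = x @ a
    dominance = z @ d
    pmean = x.mean(axis=0) / 2.0
    sd = np.sqrt(np.maximum(2 * pmean * (1 - pmean), 1e-12))
    Z = (x - 2 * pmean) / sd
    s = rng.normal(0.0, np.sqrt(config.polygenic_var / m), size=m)
    polygenic = Z @ s
    residual = rng.normal(0.0, np.sqrt(config.residual_var), size=n)

    breed = np.repeat(config.breeds, config.n_per_breed)
    mu = np.repeat(np.asarray(config.breed_means, dtype=float), config.n_per_breed)
    y = mu + additive + dominance + polygenic + residual

    cohort = np.where(
        np.tile(np.arange(config.n_per_breed) % 2, config.n_breeds) == 0,
        "bulls",
        "cows",
    )
    pheno = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(n)],
            "breed": breed,
            "cohort": cohort,
            "trait": y,
        }
    )
    realized = {
        "var_additive": float(np.var(additive)),
        "var_dominance": float(np.var(dominance)),
        "var_polygenic": float(np.var(polygenic)),
        "var_residual": float(np.var(residual)),
    }
    return pheno, realized


def simulate_dataset(config: SimConfig) -> SimData:
    """Run the full generator: truth -> frequencies -> genotypes ->
    outgroups -> phenotypes, all from one seeded RNG."""
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth_sites(config, rng)

    p_shifted = (
        apply_selection_shift(
            truth["p_derived"].to_numpy(), np.sign(truth["a"].to_numpy()), config
        )
        if config.selection_shift != 0
        else truth["p_derived"].to_numpy()
    )
    truth["p_shifted"] = p_shifted

    breed_freqs = simulate_breed_frequencies(config, p_shifted, rng)
    derived_counts = simulate_genotypes(breed_freqs, config, rng)
    outgroups = simulate_outgroups(config, truth, rng)
    pheno, realized = simulate_phenotypes(derived_counts, truth, config, rng)

    # express genotypes in REF/ALT orientation with a random reference
    # allele, so downstream mutant-allele orientation is genuinely exercised
    ref_is_ancestral = rng.random(config.n_sites) < 0.5
    ref = np.where(ref_is_ancestral, truth["ancestral"], truth["derived"])
    alt = np.where(ref_is_ancestral, truth["derived"], truth["ancestral"])
    alt_counts = np.where(
        derived_counts < 0,
        -1,
        np.where(ref_is_ancestral[None, :], derived_counts, 2 - derived_counts),
    ).astype(np.int8)
    truth["ref"] = ref
    truth["alt"] = alt

    sites = truth[["chrom", "pos", "ref", "alt"]].copy()
    geno = GenotypeMatrix(alt_counts, sites, [f"ind{i}" for i in range(len(pheno))])
    return SimData(
        config=config,
        truth=truth,
        genotypes=geno,
        outgroups=outgroups,
        phenotypes=pheno,
        breed_frequencies=breed_freqs,
        realized=realized,
    )


def focal_site_counts(data: SimData) -> pd.DataFrame:
    """Focal-panel base counts + outgroup calls, the polarization input.

    Built from the simulated genotypes (so missing genotypes reduce the
    focal total) in the count-table layout: chrom, pos, countA..countT,
    yak, sheep, camel.
    """
    geno = data.genotypes
    g = geno.genotypes
    obs = g >= 0
    alt_count = np.where(obs, g, 0).sum(axis=0)
    total = 2 * obs.sum(axis=0)
    ref_count = total - alt_count

    m = geno.n_sites
    counts = np.zeros((m, 4), dtype=np.int64)
    ref_idx = np.array([BASES.index(b) for b in geno.sites["ref"]])
    alt_idx = np.array([BASES.index(b) for b in geno.sites["alt"]])
    counts[np.arange(m), ref_idx] = ref_count
    counts[np.arange(m), alt_idx] += alt_count

    df = pd.DataFrame(counts, columns=["countA", "countC", "countG", "countT"])
    df.insert(0, "pos", geno.sites["pos"].to_numpy())
    df.insert(0, "chrom", geno.sites["chrom"].to_numpy())
    for col in ("yak", "sheep", "camel"):
        df[col] = data.outgroups[col].to_numpy()
    return df
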