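"""Additive/dominance genotype codings and heterozygosity covariates.

Two parameterisations of a biallelic genotype, indexed by the count
(0, 1, 2) of the counted allele B at frequency ``p`` (``q = 1 - p``):

* naive:      x_A = 0, 1, 2          and   z_D = 0, 1, 0
* orthogonal: x'_A = 2p, p - q, -2q  and   z'_D = -2p^2, 2pq, -2q^2

Under Hardy-Weinberg genotype proportions (q^2, 2pq, p^2 for counts
0, 1, 2) the orthogonal codes are exactly mean-zero and mutually
uncorrelated, with Var(x') = 2pq and Var(z') = (2pq)^2 -- so scaled by the
allele-substitution effect and the dominance deviation they give the
additive and dominance variances, and a dominance covariate built from z'
is independent of additive effects.  That independence is what makes the
per-individual mean of z' (H') a clean directional-dominance covariate.
The naive codes are correlated: cov(x_A, z_D) = 2p(1-p)(1-2p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def naive_codings(p) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated (x_A, z_D) for counted-allele counts (0, 1, 2).

    ``p`` is accepted for signature symmetry with
    :func:`orthogonal_codings`; the naive codes do not depend on it.
    """
    p = np.asarray(p, dtype=float)
    shape = p.shape + (3,)
    x = np.broadcast_to(np.array([0.0, 1.0, 2.0]), shape).copy()
    z = np.broadcast_to(np.array([0.0, 1.0, 0.0]), shape).copy()
    return x, z


def orthogonal_codings(p) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated (x'_A, z'_D) for counted-allele counts (0, 1, 2).

    ``p`` is the frequency of the counted allele; scalars or arrays
    accepted, broadcast to shape ``p.shape + (3,)``.  The codes are the
    classical orthogonal (Falconer regression) parameterisation, exactly
    mean-zero and uncorrelated under HWE weights (q^2, 2pq, p^2).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1); monomorphic sites excluded")
    q = 1.0 - p
    x = np.stack([2 * p, p - q, -2 * q], axis=-1)
    z = np.stack([-2 * p**2, 2 * p * q, -2 * q**2], axis=-1)
    return x, z


def code_matrix(
    genotypes: np.ndarray, p: np.ndarray, scheme: str = "orthogonal"
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a coding scheme to a genotype matrix.

    ``genotypes`` holds counted-allele counts (0/1/2, -1 missing) with one
    column per site; ``p`` is the per-site frequency of the counted
    allele.  Missing genotypes are coded to 0 -- the exact HWE mean for
    the orthogonal codes, a mean-imputation for the naive ones.
    """
    if scheme == "orthogonal":
        x_tab, z_tab = orthogonal_codings(p)
    elif scheme == "naive":
        x_tab, z_tab = naive_codings(p)
    else:
        raise ValueError(f"unknown coding scheme {scheme!r}")
    g = np.asarray(genotypes)
    missing = g == MISSING
    gi = np.where(missing, 0, g)
    cols = np.arange(g.shape[1])
    x = x_tab[cols, gi]
    z = z_tab[cols, gi]
    x[missing] = 0.0
    z[missing] = 0.0
    return x, z


def heterozygosity(
    genotypes: GenotypeMatrix,
    conserved: np.ndarray,
    frequencies: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-individual heterozygosity covariates over a site partition.

    Parameters
    ----------
    genotypes : panel genotypes (ALT counts).
    conserved : boolean mask over sites; True marks the conserved partition.
    frequencies : per-site ALT frequency used in the codings; estimated
        from the panel itself when omitted (one shared panel frequency for
        every individual).

    Returns a frame indexed like ``genotypes.samples`` with:

    * ``H``: simple heterozygosity, the mean of the 0/1/0 code over all sites;
    * ``H_prime_cons`` / ``H_prime_noncons``: the mean of the orthogonal
      dominance code z' over each partition;
    * ``H_prime_all``: same over all sites;
    * ``I``: inbreeding coefficient as the product (sum_i 2 p_i q_i) * H.

    Columns for an empty partition are NaN (undefined, not zero).
    """
    conserved = np.asarray(conserved, dtype=bool)
    if conserved.shape != (genotypes.n_sites,):
        raise ValueError("conserved mask length must equal n_sites")
    p_alt = (
        genotypes.allele_freq() if frequencies is None else np.asarray(frequencies)
    )
    if np.any((p_alt <= 0) | (p_alt >= 1)):
        raise ValueError("monomorphic sites present; filter before coding")
    _, z_prime = code_matrix(genotypes.genotypes, p_alt, "orthogonal")
    _, z_naive = code_matrix(genotypes.genotypes, p_alt, "naive")

    def part_mean(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if mask.sum() == 0:
            return np.full(mat.shape[0], np.nan)
        return mat[:, mask].mean(axis=1)

    all_mask = np.ones_like(conserved)
    H = part_mean(z_naive, all_mask)
    out = pd.DataFrame(
        {
            "id": genotypes.samples,
            "H": H,
            "H_prime_cons": part_mean(z_prime, conserved),
            "H_prime_noncons": part_mean(z_prime, ~conserved),
            "H_prime_all": part_mean(z_prime, all_mask),
            "I": float(np.sum(2 * p_alt * (1 - p_alt))) * H,
        }
    )
    return out
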