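"""GRM construction, REML variance components, mixed-model association.

The model is y = X b + g + e with g ~ N(0, sigma_g^2 G) and
e ~ N(0, sigma_e^2 I).  A single eigendecomposition of the genomic
relationship matrix G diagonalizes the covariance, after which REML is a
1-D optimization over the heritability and every per-variant association
is a generalized-least-squares regression with diagonal weights
(the EMMA-style fast path).  Variance components are estimated once under
the null model per trait and reused across variants by default; a flag
re-estimates them per variant for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class GRM:
    """Genomic relationship matrix G = W W' / m from standardized genotypes."""

    matrix: np.ndarray
    n_sites: int

    def eigendecompose(self):
        d, U = np.linalg.eigh(self.matrix)
        return np.maximum(d, 0.0), U


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def build_grm(
    genotypes: GenotypeMatrix, frequencies: np.ndarray | None = None
) -> GRM:
    """GCTA-convention GRM: per-site standardization w = (x - 2p)/sqrt(2pq).

    Missing genotypes contribute 0 (the standardized mean).  Monomorphic
    sites are rejected -- filter them upstream.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least two individuals")
    g = genotypes.genotypes.astype(float)
    p = genotypes.allele_freq() if frequencies is None else np.asarray(frequencies)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic site in GRM input; filter first")
    w = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    w[genotypes.genotypes == MISSING] = 0.0
    m = genotypes.n_sites
    return GRM(w @ w.T / m, m)


def _design(covariates) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def breed_design(breed_labels, add_intercept: bool = True) -> np.ndarray:
    """One-hot breed fixed effects, first level as reference."""
    labels = pd.Series(breed_labels).astype(str)
    levels = sorted(labels.unique())
    cols = [np.ones(len(labels))] if add_intercept else []
    for lev in levels[1:] if add_intercept else levels:
        cols.append((labels == lev).to_numpy(float))
    return np.column_stack(cols)


def _profile_reml(h2, d, yt, Xt):
    """Profiled REML criterion at heritability h2 on the eigenbasis."""
    n, p = Xt.shape
    w = h2 * d + (1.0 - h2)
    wi = 1.0 / w
    XtWX = Xt.T @ (wi[:, None] * Xt)
    XtWy = Xt.T @ (wi * yt)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    q = float(r @ (wi * r))
    s = q / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(s) + np.sum(np.log(w)) + logdet + (n - p)
    )
    return ll, beta, s, XtWX


def reml(
    y,
    covariates,
    grm: GRM,
    eig=None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """REML by 1-D optimization of the profiled criterion over h^2.

    Returns the variance components and a table of GLS fixed-effect
    estimates (beta, se, t) at the REML optimum.  A boundary estimate
    (sigma_g^2 = 0) is allowed and reported with ``converged=True``.
    """
    y = np.asarray(y, dtype=float)
    X = _design(covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    d, U = grm.eigendecompose() if eig is None else eig
    yt = U.T @ y
    Xt = U.T @ X

    def neg(h2):
        return -_profile_reml(h2, d, yt, Xt)[0]

    res = minimize_scalar(
        neg, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    h2 = float(res.x)
    # the bounded optimizer never evaluates the exact endpoints; snap to the
    # boundary when it is at least as good
    for edge in (0.0,):
        if neg(edge) <= res.fun:
            h2 = edge
    ll, beta, s, XtWX = _profile_reml(h2, d, yt, Xt)
    vc = VarianceComponents(
        sigma_g2=s * h2,
        sigma_e2=s * (1.0 - h2),
        loglik=float(ll),
        converged=bool(res.success),
    )
    se = np.sqrt(np.diag(s * np.linalg.inv(XtWX)))
    fixed = pd.DataFrame({"beta": beta, "se": se})
    fixed["t"] = fixed["beta"] / fixed["se"]
    return vc, fixed


def mlm_gwas(
    y,
    covariates,
    genotypes: GenotypeMatrix,
    grm: GRM,
    variance: VarianceComponents | None = None,
    eig=None,
    per_variant_reml: bool = False,
) -> pd.DataFrame:
    """Per-variant mixed-model association under V = sigma_g^2 G + sigma_e^2 I.

    Betas are reported for the counted (ALT) allele; use
    :func:`mutpolar.bayesr.orient_effects` to re-sign them to the mutant
    allele.  Variants collinear with the covariates get NaN results.
    """
    y = np.asarray(y, dtype=float)
    X = _design(covariates)
    d, U = grm.eigendecompose() if eig is None else eig
    yt = U.T @ y
    Xt = U.T @ X

    if variance is None:
        variance, _ = reml(y, X, grm, eig=(d, U))

    if per_variant_reml:
        betas, ses = [], []
        for j in range(genotypes.n_sites):
            x = genotypes.genotypes[:, j].astype(float)
            x[genotypes.genotypes[:, j] == MISSING] = np.nan
            x = np.where(np.isnan(x), np.nanmean(x), x)
            Xj = np.column_stack([X, x])
            try:
                _, fixed = reml(y, Xj, grm, eig=(d, U))
                betas.append(fixed["beta"].iloc[-1])
                ses.append(fixed["se"].iloc[-1])
            except ValueError:
                betas.append(np.nan)
                ses.append(np.nan)
        beta = np.array(betas)
        se = np.array(ses)
    else:
        v = variance.sigma_g2 * d + variance.sigma_e2
        vi = 1.0 / v
        A = Xt.T @ (vi[:, None] * Xt)
        Ainv = np.linalg.inv(A)
        g = genotypes.genotypes.astype(float)
        g[genotypes.genotypes == MISSING] = np.nan
        col_mean = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mean, g)
        Gt = U.T @ g
        # GLS with covariates projected out: beta = (x'Mx)^-1 x'My
        My = vi * yt - (vi[:, None] * Xt) @ (Ainv @ (Xt.T @ (vi * yt)))
        num = Gt.T @ My
        XtVG = Xt.T @ (vi[:, None] * Gt)
        den = np.einsum("ij,ij->j", Gt, vi[:, None] * Gt) - np.einsum(
            "ij,ij->j", XtVG, Ainv @ XtVG
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(den > 1e-10, num / den, np.nan)
            se = np.where(den > 1e-10, np.sqrt(1.0 / den), np.nan)

    with np.errstate(invalid="ignore"):
        zstat = beta / se
    pval = 2.0 * norm.sf(np.abs(zstat))
    out = genotypes.sites[["chrom", "pos", "ref", "alt"]].copy()
    out["counted_allele"] = out["alt"]
    out["beta"] = beta
    out["se"] = se
    out["p"] = pval
    return out


@dataclass
class DirectionalDominanceResult:
    """Joint fixed-effect estimates for the two heterozygosity covariates."""

    beta_cons: float
    se_cons: float
    beta_noncons: float
    se_noncons: float
    variance: VarianceComponents

    @property
    def t_cons(self) -> float:
        return self.beta_cons / self.se_cons

    @property
    def t_noncons(self) -> float:
        return self.beta_noncons / self.se_noncons

    def significant(self, threshold: float = 1.96) -> bool:
        return abs(self.t_cons) > threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": ["H_prime_cons", "H_prime_noncons"],
                "beta": [self.beta_cons, self.beta_noncons],
                "se": [self.se_cons, self.se_noncons],
                "t": [self.t_cons, self.t_noncons],
            }
        )


def directional_dominance_test(
    y, breed_labels, h_cons, h_noncons, grm: GRM, eig=None
) -> DirectionalDominanceResult:
    """Joint test of the conserved / non-conserved H' covariates.

    Fits both heterozygosity covariates together with breed fixed effects
    and the polygenic GRM; a positive, significant conserved-partition beta
    is the directional-dominance signature.  Near-collinear covariates
    (|r| > 0.999) are refused.
    """
    h_cons = np.asarray(h_cons, dtype=float)
    h_noncons = np.asarray(h_noncons, dtype=float)
    r = np.corrcoef(h_cons, h_noncons)[0, 1]
    if abs(r) > 0.999:
        raise ValueError(
            f"H' covariates are collinear (r = {r:.4f}); joint fit refused"
        )
    B = breed_design(breed_labels)
    X = np.column_stack([B, h_cons, h_noncons])
    vc, fixed = reml(y, X, grm, eig=eig)
    k = B.shape[1]
    return DirectionalDominanceResult(
        beta_cons=float(fixed["beta"].iloc[k]),
        se_cons=float(fixed["se"].iloc[k]),
        beta_noncons=float(fixed["beta"].iloc[k + 1]),
        se_noncons=float(fixed["se"].iloc[k + 1]),
        variance=vc,
    )
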