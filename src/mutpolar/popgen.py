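"""Mutant-allele frequency summaries and multi-population Weir F_ST.

The F_ST estimator is the Weir & Cockerham (1984) variance-components
form: per variant, the among-population (a), among-individual (b) and
within-individual (c) components are computed from population sample
sizes, allele frequencies and observed heterozygote frequencies, and the
per-variant estimate is a / (a + b + c).  Negative per-variant estimates
are retained (the estimator is unbiased; truncation would bias group
means).  Group standard errors are computed over LD-clumped
representatives to blunt the correlation between nearby variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def _pop_stats(genotypes: GenotypeMatrix, populations) -> tuple:
    """Per-population sample sizes, allele frequencies and het frequencies."""
    labels = pd.Series(list(populations)).astype(str)
    if len(labels) != genotypes.n_individuals:
        raise ValueError("population labels must cover every individual")
    pops = sorted(labels.unique())
    g = genotypes.genotypes
    obs = g != MISSING
    n = np.zeros((len(pops), genotypes.n_sites))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, pop in enumerate(pops):
        rows = (labels == pop).to_numpy()
        gk = g[rows]
        ok = obs[rows]
        nk = ok.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(ok, gk, 0).sum(axis=0) / (2.0 * nk)
            h[k] = ((gk == 1) & ok).sum(axis=0) / nk
    return pops, n, p, h


def weir_fst(genotypes: GenotypeMatrix, populations) -> pd.DataFrame:
    """Per-variant Weir & Cockerham (1984) multi-population F_ST.

    Requires >= 2 populations with >= 2 genotyped individuals each at a
    used variant; variants monomorphic across all populations get NaN.
    Returns a frame with chrom, pos and fst.
    """
    pops, n, p, h = _pop_stats(genotypes, populations)
    r = len(pops)
    if r < 2:
        raise ValueError("F_ST needs at least two populations")
    if np.any(n < 2):
        raise ValueError(
            "every population needs >= 2 genotyped individuals per variant"
        )
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(np.abs(denom) > 0, a / denom, np.nan)
    poly = (pbar > 0) & (pbar < 1)
    fst = np.where(poly, fst, np.nan)
    out = genotypes.sites[["chrom", "pos"]].copy()
    out["fst"] = fst
    return out


def ma_frequency(
    genotypes: GenotypeMatrix,
    calls: pd.DataFrame,
    populations,
) -> pd.DataFrame:
    """Per-population mutant-allele frequency for every MA-assigned variant.

    ``calls`` needs chrom/pos/ancestral/mutant; ambiguous variants are
    dropped.  Returns one row per retained variant with a frequency column
    per population (``freq_<pop>``) plus the overall frequency.
    """
    sites = genotypes.sites.merge(
        calls[["chrom", "pos", "ancestral", "mutant"]],
        on=["chrom", "pos"],
        how="left",
    )
    keep = (sites["mutant"].notna() & (sites["mutant"] != ".")).to_numpy()
    if keep.sum() == 0:
        raise ValueError("no MA-assigned variants to summarize")
    sub = genotypes.take_sites(np.where(keep)[0])
    sites = sites.loc[keep].reset_index(drop=True)
    # frequency of the ALT allele, flipped where ALT is ancestral
    alt_is_mut = (sites["alt"] == sites["mutant"]).to_numpy()
    bad = ~alt_is_mut & (sites["ref"] != sites["mutant"]).to_numpy()
    if bad.any():
        raise ValueError("mutant allele absent from the variant's allele pair")

    labels = pd.Series(list(populations)).astype(str)
    pops = sorted(labels.unique())
    out = sites[["chrom", "pos", "ancestral", "mutant"]].copy()
    for pop in pops + ["all"]:
        rows = (
            np.ones(len(labels), dtype=bool)
            if pop == "all"
            else (labels == pop).to_numpy()
        )
        p_alt = sub.take_individuals(np.where(rows)[0]).allele_freq()
        out[f"freq_{pop}"] = np.where(alt_is_mut, p_alt, 1.0 - p_alt)
    return out


def group_summary(values, clump_index) -> dict:
    """Mean over all values; SE from the clumped representatives only.

    SE = sd / sqrt(k) over the k clumped values (NaN for k < 2); NaN
    values are ignored in both mean and SE.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return {"mean": np.nan, "se": np.nan, "n": 0, "n_clumped": 0}
    clumped = v[np.asarray(clump_index, dtype=int)]
    clumped = clumped[np.isfinite(clumped)]
    se = (
        float(np.std(clumped, ddof=1) / np.sqrt(len(clumped)))
        if len(clumped) > 1
        else np.nan
    )
    return {
        "mean": float(np.nanmean(v)),
        "se": se,
        "n": int(np.isfinite(v).sum()),
        "n_clumped": int(len(clumped)),
    }
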