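"""Effect-direction statistics: classification, TDRed, MA+/MA- ratio,
KS symmetry test, LD clumping and per-variant variance explained.

All operations here expect effects already oriented to the mutant allele
(column ``beta_ma``); see :func:`mutpolar.bayesr.orient_effects`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

#: GWAS p-value cut-offs for the effect-size classes
P_LARGE = 5e-8
P_MEDIUM = 5e-5
P_SMALL = 0.05


def classify_effects(bull: pd.DataFrame, cow: pd.DataFrame) -> pd.DataFrame:
    """Two-cohort effect-size classes with sign concordance.

    A variant is ``large`` when p < 5e-8 in both cohorts with the same
    effect sign, ``medium`` for 5e-8 <= p < 5e-5 in both, ``small`` for
    5e-5 <= p < 0.05 in both; anything else (including discordant signs or
    zero betas) is ``unclassified``.  Inputs must be MA-oriented and are
    matched on chrom, pos and allele pair.
    """
    for df, name in ((bull, "bull"), (cow, "cow")):
        for col in ("chrom", "pos", "ref", "alt", "beta_ma", "p"):
            if col not in df.columns:
                raise ValueError(f"{name} results need column {col!r}")
    merged = bull.merge(
        cow,
        on=["chrom", "pos", "ref", "alt"],
        suffixes=("_bull", "_cow"),
        how="inner",
    )
    if "mutant_bull" in merged.columns and "mutant_cow" in merged.columns:
        if not (merged["mutant_bull"] == merged["mutant_cow"]).all():
            raise ValueError("cohorts are oriented to different mutant alleles")

    p1 = merged["p_bull"].to_numpy()
    p2 = merged["p_cow"].to_numpy()
    b1 = merged["beta_ma_bull"].to_numpy()
    b2 = merged["beta_ma_cow"].to_numpy()
    concordant = (np.sign(b1) == np.sign(b2)) & (b1 != 0) & (b2 != 0)

    def both(lo, hi):
        return (p1 >= lo) & (p1 < hi) & (p2 >= lo) & (p2 < hi)

    cls = np.full(len(merged), "unclassified", dtype=object)
    cls[both(0.0, P_LARGE) & concordant] = "large"
    cls[both(P_LARGE, P_MEDIUM) & concordant] = "medium"
    cls[both(P_MEDIUM, P_SMALL) & concordant] = "small"
    merged["effect_class"] = cls
    return merged


def tdred(signs1, signs2) -> float:
    """True Discovery Rate by Effect Direction between two cohorts.

    Adopted formula: 2 * (fraction of sign-concordant pairs) - 1, clamped
    at 0 -- zero at chance concordance, one when every pair agrees.
    """
    s1 = np.sign(np.asarray(signs1, dtype=float))
    s2 = np.sign(np.asarray(signs2, dtype=float))
    if len(s1) == 0 or len(s1) != len(s2):
        raise ValueError("need equal-length, non-empty sign vectors")
    if np.any(s1 == 0) or np.any(s2 == 0):
        raise ValueError("zero effects have no direction; filter them first")
    concordance = float(np.mean(s1 == s2))
    return max(0.0, 2.0 * concordance - 1.0)


def ma_direction_ratio(beta_ma) -> dict:
    """Counts of trait-increasing vs trait-decreasing mutant alleles.

    Returns n_plus, n_minus and their ratio (inf when nothing decreases).
    Zero effects are excluded.
    """
    b = np.asarray(beta_ma, dtype=float)
    b = b[b != 0]
    n_plus = int(np.sum(b > 0))
    n_minus = int(np.sum(b < 0))
    ratio = n_plus / n_minus if n_minus > 0 else float("inf")
    return {"n_plus": n_plus, "n_minus": n_minus, "ratio": ratio}


def ks_direction_test(
    beta_ma,
    mode: str = "auto",
    n_resample: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS test between ancestral- and mutant-oriented effects.

    Since the ancestral-oriented effect vector is exactly -1 times the
    MA-oriented one, this is a test of symmetry of the MA effect
    distribution about zero.  Returns (D, p).

    Modes ``"auto"`` (exact below 50 effects, asymptotic above),
    ``"exact"`` and ``"asymp"`` take the p-value from the standard
    two-sample KS distribution, i.e. exactly the printed-procedure
    comparison of the two oriented vectors.  Because those two vectors are
    the same numbers negated, the independence assumption behind that
    null distribution does not hold and the p-values are anti-conservative
    (roughly twice the nominal type-I error at alpha = 0.05).  Mode
    ``"signflip"`` calibrates the same D statistic by resampling random
    sign assignments of the effects -- valid under the symmetric null --
    and yields uniform p-values.
    """
    m = np.asarray(beta_ma, dtype=float)
    if len(m) < 2:
        raise ValueError("need at least two effects")
    a = -m
    if mode == "signflip":
        d_obs = float(ks_2samp(a, m, method="asymp").statistic)
        rng = np.random.default_rng(seed)
        absm = np.abs(m)
        exceed = 0
        for _ in range(n_resample):
            flip = rng.choice([-1.0, 1.0], size=len(m))
            mb = flip * absm
            if ks_2samp(-mb, mb, method="asymp").statistic >= d_obs:
                exceed += 1
        return d_obs, (1.0 + exceed) / (n_resample + 1.0)
    method = mode if mode != "auto" else ("exact" if len(m) < 50 else "asymp")
    res = ks_2samp(a, m, method=method)
    return float(res.statistic), float(res.pvalue)


def ld_clump(
    assoc: pd.DataFrame,
    genotypes: np.ndarray,
    r2_threshold: float = 0.3,
    window_bp: int = 1_000_000,
) -> np.ndarray:
    """Greedy LD clumping: index variants by ascending p within r2/window.

    ``assoc`` needs chrom, pos and p aligned with the columns of
    ``genotypes`` (allele counts, missing as -1).  Repeatedly takes the
    unclaimed variant with the smallest p as an index variant and removes
    every unclaimed variant on the same chromosome within ``window_bp``
    (center-to-center) whose squared genotype correlation with it is
    >= ``r2_threshold``.  Ties in p break by position, then by allele
    order.  Returns the integer indices of retained index variants.
    """
    n_var = len(assoc)
    if genotypes.shape[1] != n_var:
        raise ValueError("genotype columns must align with assoc rows")
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)

    chrom = assoc["chrom"].astype(str).to_numpy()
    pos = assoc["pos"].to_numpy()
    p = assoc["p"].to_numpy()
    alleles = (
        (assoc["ref"].astype(str) + assoc["alt"].astype(str)).to_numpy()
        if {"ref", "alt"} <= set(assoc.columns)
        else np.full(n_var, "", dtype=object)
    )
    order = np.lexsort((alleles, pos, p))

    claimed = np.zeros(n_var, dtype=bool)
    kept = []
    for i in order:
        if claimed[i]:
            continue
        kept.append(i)
        claimed[i] = True
        near = (
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) < window_bp)
            & ~claimed
        )
        idx = np.where(near)[0]
        if len(idx) == 0:
            continue
        x = g[:, i]
        xs = x - x.mean()
        denom_x = float(xs @ xs)
        Y = g[:, idx] - g[:, idx].mean(axis=0)
        num = xs @ Y
        denom_y = np.einsum("ij,ij->j", Y, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(
                (denom_x > 0) & (denom_y > 0),
                num**2 / (denom_x * denom_y),
                0.0,
            )
        claimed[idx[r2 >= r2_threshold]] = True
    return np.array(sorted(kept), dtype=int)


def variance_explained(beta, se, n) -> np.ndarray:
    """Per-variant proportion of phenotypic variance: (beta / se)^2 / N.

    Equivalent in expectation to 2 p (1 - p) b^2 on a standardized trait
    but free of the allele frequency.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or n <= 0:
        raise ValueError("need se > 0 and N > 0")
    return (beta / se) ** 2 / n


def class_summary(
    effects: pd.DataFrame,
    genotypes: np.ndarray,
    n_gwas: int,
    classes=("large", "medium", "small"),
    ks_on_clumped: bool = False,
) -> pd.DataFrame:
    """Per-class direction and variance summary.

    ``effects`` needs chrom, pos, effect_class, beta_ma, se and p, with
    rows positionally aligned to the columns of ``genotypes``.  One row is
    returned per effect-size class with counts, the MA+/MA- ratio, the KS
    symmetry p-value, and the mean Vp whose standard error is computed over
    the LD-clumped subset only (clumping within the class) -- correlated
    variants inflate a naive SE.
    """
    effects = effects.reset_index(drop=True)
    rows = []
    for cls in classes:
        mask = (effects["effect_class"] == cls).to_numpy()
        sub = effects.loc[mask].reset_index(drop=True)
        if len(sub) == 0:
            rows.append(
                {
                    "effect_class": cls, "n": 0, "n_plus": 0, "n_minus": 0,
                    "ratio": np.nan, "ks_D": np.nan, "ks_p": np.nan,
                    "mean_vp": np.nan, "se_vp": np.nan, "n_clumped": 0,
                }
            )
            continue
        counts = ma_direction_ratio(sub["beta_ma"])
        kept = ld_clump(sub, genotypes[:, mask])
        vp = np.asarray(variance_explained(sub["beta_ma"], sub["se"], n_gwas))
        vp_clumped = vp[kept]
        se_vp = (
            float(np.std(vp_clumped, ddof=1) / np.sqrt(len(vp_clumped)))
            if len(vp_clumped) > 1
            else np.nan
        )
        ks_input = sub["beta_ma"].to_numpy()[kept] if ks_on_clumped else sub[
            "beta_ma"
        ].to_numpy()
        if len(ks_input) >= 2:
            ks_d, ks_p = ks_direction_test(ks_input)
        else:
            ks_d, ks_p = np.nan, np.nan
        rows.append(
            {
                "effect_class": cls,
                "n": len(sub),
                "n_plus": counts["n_plus"],
                "n_minus": counts["n_minus"],
                "ratio": counts["ratio"],
                "ks_D": ks_d,
                "ks_p": ks_p,
                "mean_vp": float(vp.mean()),
                "se_vp": se_vp,
                "n_clumped": int(len(kept)),
            }
        )
    return pd.DataFrame(rows)
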