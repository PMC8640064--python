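"""Mutant-allele frequency and Weir F_ST across breeds.

Groups MA-assigned variants by the (cow-cohort) direction of their
estimated effect and compares mean MA frequency and mean F_ST between the
MA+ and MA- groups, with LD-clump-based standard errors. The generator
shifted trait-decreasing mutant alleles down in frequency by 0.05, so the
MA- group should sit below the MA+ group among the causal subset.
Writes results/popgen_summary.tsv and results/fst.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mutpolar.bayesr import orient_effects
from mutpolar.direction import ld_clump
from mutpolar.genotypes import GenotypeMatrix
from mutpolar.popgen import group_summary, ma_frequency, weir_fst

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    geno = GenotypeMatrix.from_tsv(ROOT / "data" / "genotypes.tsv")
    pheno = pd.read_csv(ROOT / "data" / "phenotypes.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t", dtype={"chrom": str})
    calls = pd.read_csv(ROOT / "ancestral_calls.tsv", sep="\t",
                        dtype={"chrom": str})
    cows_gwas = pd.read_csv(ROOT / "gwas_cows.tsv", sep="\t", dtype={"chrom": str})

    keep = np.where(geno.maf() > 0.005)[0]
    geno = geno.take_sites(keep)
    breeds = pheno["breed"]

    fst = weir_fst(geno, breeds)
    fst.to_csv(ROOT / "fst.tsv", sep="\t", index=False)
    print(f"mean F_ST across {fst['fst'].notna().sum()} variants: "
          f"{np.nanmean(fst['fst']):.4f} (generator F = 0.1)")

    freq = ma_frequency(geno, calls, breeds)
    oriented, _ = orient_effects(cows_gwas, calls)
    merged = freq.merge(
        oriented[["chrom", "pos", "beta_ma", "p"]], on=["chrom", "pos"]
    ).merge(truth[["chrom", "pos", "a"]], on=["chrom", "pos"])
    aligned = merged[["chrom", "pos"]].merge(
        geno.sites.reset_index()[["chrom", "pos", "index"]],
        on=["chrom", "pos"], how="left",
    )["index"].to_numpy()

    rows = []
    for label, mask in (
        ("MA+ (estimated)", (merged["beta_ma"] > 0).to_numpy()),
        ("MA- (estimated)", (merged["beta_ma"] < 0).to_numpy()),
        ("MA+ (true causal)", (merged["a"] > 0).to_numpy()),
        ("MA- (true causal)", (merged["a"] < 0).to_numpy()),
    ):
        sub = merged.loc[mask].reset_index(drop=True)
        if len(sub) < 2:
            continue
        kept = ld_clump(sub, geno.genotypes[:, aligned[mask]])
        s = group_summary(sub["freq_all"], kept)
        fsub = fst.merge(sub[["chrom", "pos"]], on=["chrom", "pos"])
        sf = group_summary(fsub["fst"], kept)
        rows.append(
            {
                "group": label, "n": s["n"], "n_clumped": s["n_clumped"],
                "freq_mean": s["mean"], "freq_se": s["se"],
                "fst_mean": sf["mean"], "fst_se": sf["se"],
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "popgen_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
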