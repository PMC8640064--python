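"""End-to-end orchestration of the mutant-allele analysis chain.

Stages (each toggleable): simulate -> ancestral polarization -> coding /
heterozygosity -> mixed-model GWAS in two cohorts + directional-dominance
test -> BayesR joint effects -> direction statistics -> population
summaries.  Every stage writes a TSV under the report directory, and a
provenance record (config hash, seed, package versions) accompanies each
run, so a fixed (config, seed) regenerates every output identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import SiteCounts, polarize
from .bayesr import ChainConfig, MixturePrior, bayesr_gibbs, orient_effects
from .coding import heterozygosity
from .direction import class_summary, classify_effects, tdred
from .genotypes import GenotypeMatrix
from .mlm import breed_design, build_grm, directional_dominance_test, mlm_gwas, reml
from .popgen import group_summary, ma_frequency, weir_fst
from .simdata import SimConfig, focal_site_counts, simulate_dataset
from .direction import ld_clump


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    Thresholds default to the analysis' printed values: assignment
    probability 0.8/0.2, effect-size classes at p of 5e-8 / 5e-5 / 0.05,
    clumping r^2 < 0.3 within 1 Mb, MAF > 0.005 per cohort, significance
    |t| > 1.96.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    stages: tuple = (
        "simulate", "ancestral", "coding", "gwas", "domtest",
        "bayesr", "direction", "popgen",
    )
    maf_threshold: float = 0.005
    imputation_r2_threshold: float = 0.4
    assign_upper: float = 0.8
    assign_lower: float = 0.2
    clump_r2: float = 0.3
    clump_window_bp: int = 1_000_000
    t_significance: float = 1.96
    em_max_iter: int = 40
    bayesr_iters: int = 2_000
    bayesr_burn_in: int = 500
    bayesr_thin: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "seed" not in sim_raw and "seed" in raw:
            sim_raw["seed"] = raw["seed"]
        if "seed" not in raw and "seed" not in sim_raw:
            raise ValueError("config must set a seed")
        for key in ("freq_range", "branch_lengths", "breed_means"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def filter_variants(
    genotypes: GenotypeMatrix,
    cohorts: pd.Series,
    maf_threshold: float = 0.005,
    imputation_r2: np.ndarray | None = None,
    r2_threshold: float = 0.4,
    log: list | None = None,
) -> np.ndarray:
    """Boolean keep-mask: MAF above threshold in *every* cohort.

    An optional per-variant imputation-quality column adds a quality > 0.4
    filter; when absent the quality filter is skipped (with a logged
    notice).  Returns the mask; does not subset.
    """
    keep = np.ones(genotypes.n_sites, dtype=bool)
    for cohort in pd.Series(cohorts).unique():
        rows = (pd.Series(cohorts) == cohort).to_numpy()
        maf = genotypes.take_individuals(np.where(rows)[0]).maf()
        keep &= maf > maf_threshold
    if imputation_r2 is not None:
        keep &= np.asarray(imputation_r2) > r2_threshold
    elif log is not None:
        log.append("imputation-quality column absent; quality filter skipped")
    if log is not None:
        log.append(f"variant filter: {int(keep.sum())}/{len(keep)} retained")
    return keep


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; write the report bundle to ``outdir``.

    Returns a dict of in-memory results keyed by stage output name.  Any
    stage failure raises with the stage name attached so the (config,
    seed) state that produced it is reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    results: dict = {}
    log: list = []
    stage = "setup"

    try:
        # ---------------------------------------------------------- simulate
        stage = "simulate"
        sim_cfg = replace(config.sim, seed=config.seed)
        data = simulate_dataset(sim_cfg)
        results["sim"] = data
        log.append(
            f"simulated {data.genotypes.n_individuals} individuals x "
            f"{data.genotypes.n_sites} sites"
        )
        if "simulate" in stages:
            data.genotypes.to_tsv(outdir / "genotypes.tsv")
            data.outgroups.to_csv(outdir / "outgroups.tsv", sep="\t", index=False)
            data.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
            data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

        pheno = data.phenotypes
        cohorts = pheno["cohort"]
        keep = filter_variants(
            data.genotypes, cohorts, config.maf_threshold, log=log
        )
        geno = data.genotypes.take_sites(np.where(keep)[0])
        truth = data.truth.loc[keep].reset_index(drop=True)
        conserved = truth["conserved"].to_numpy()

        # --------------------------------------------------------- ancestral
        calls = None
        if "ancestral" in stages:
            stage = "ancestral"
            counts_df = focal_site_counts(data)
            counts_df = counts_df.loc[keep].reset_index(drop=True)
            sites = SiteCounts.from_frame(counts_df)
            calls, model, fit_info = polarize(
                sites,
                site_meta=counts_df[["chrom", "pos"]],
                max_iter=config.em_max_iter,
            )
            n_assigned = int((calls["ancestral"] != ".").sum())
            log.append(
                f"ancestral: {n_assigned}/{len(calls)} assigned, "
                f"{len(calls) - n_assigned} ambiguous; "
                f"kappa={model.kappa:.3f}, loglik={fit_info['loglik']:.2f}"
            )
            calls.to_csv(outdir / "ancestral_calls.tsv", sep="\t", index=False)
            results["calls"] = calls
            results["k2_model"] = model

        # ------------------------------------------------------------ coding
        het = None
        if "coding" in stages or "domtest" in stages:
            stage = "coding"
            het = heterozygosity(geno, conserved)
            het.to_csv(outdir / "het_covariates.tsv", sep="\t", index=False)
            results["het"] = het

        # ------------------------------------------------------ mixed models
        need_mlm = stages & {"gwas", "domtest", "direction", "popgen", "bayesr"}
        grm = eig = None
        if need_mlm:
            stage = "grm"
            grm = build_grm(geno)
            eig = grm.eigendecompose()

        gwas = {}
        if stages & {"gwas", "direction", "popgen", "bayesr"}:
            stage = "gwas"
            for cohort in ("bulls", "cows"):
                rows = np.where((cohorts == cohort).to_numpy())[0]
                sub_g = geno.take_individuals(rows)
                sub_grm = build_grm(sub_g)
                y = pheno["trait"].to_numpy()[rows]
                X = breed_design(pheno["breed"].to_numpy()[rows])
                res = mlm_gwas(y, X, sub_g, sub_grm)
                res["cohort"] = cohort
                res["n"] = len(rows)
                gwas[cohort] = res
                res.to_csv(outdir / f"gwas_{cohort}.tsv", sep="\t", index=False)
            results["gwas"] = gwas
            log.append(
                "gwas: "
                + ", ".join(f"{k} n={v['n'].iloc[0]}" for k, v in gwas.items())
            )

        if "domtest" in stages:
            stage = "domtest"
            rows = np.where((cohorts == "cows").to_numpy())[0]
            sub_g = geno.take_individuals(rows)
            dd = directional_dominance_test(
                pheno["trait"].to_numpy()[rows],
                pheno["breed"].to_numpy()[rows],
                het["H_prime_cons"].to_numpy()[rows],
                het["H_prime_noncons"].to_numpy()[rows],
                build_grm(sub_g),
            )
            dd.to_frame().to_csv(outdir / "domtest.tsv", sep="\t", index=False)
            results["domtest"] = dd
            log.append(
                f"domtest: beta_cons={dd.beta_cons:.4f} (t={dd.t_cons:.2f}), "
                f"beta_noncons={dd.beta_noncons:.4f} (t={dd.t_noncons:.2f})"
            )

        # ----------------------------------------------------------- orient
        oriented = {}
        if calls is not None and gwas:
            stage = "orient"
            for cohort, res in gwas.items():
                orient, n_dropped = orient_effects(res, calls)
                oriented[cohort] = orient
                log.append(
                    f"orient {cohort}: {len(orient)} variants, "
                    f"{n_dropped} ambiguous dropped"
                )
            results["oriented"] = oriented

        # ----------------------------------------------------------- bayesr
        if "bayesr" in stages and oriented:
            stage = "bayesr"
            both = classify_effects(oriented["bulls"], oriented["cows"])
            concordant = both.loc[
                np.sign(both["beta_ma_bull"]) == np.sign(both["beta_ma_cow"])
            ]
            pos_mask = geno.sites["pos"].isin(concordant["pos"]).to_numpy()
            idx = np.where(pos_mask)[0]
            rows = np.where((cohorts == "bulls").to_numpy())[0]
            sub_g = geno.take_individuals(rows).take_sites(idx)
            y = pheno["trait"].to_numpy()[rows]
            X = breed_design(pheno["breed"].to_numpy()[rows])
            vc, _ = reml(y, X, build_grm(geno.take_individuals(rows)))
            post = bayesr_gibbs(
                y,
                X,
                sub_g.genotypes,
                prior=MixturePrior(
                    sigma_g2_start=max(vc.sigma_g2, 1e-3),
                    sigma_e2_start=max(vc.sigma_e2, 1e-3),
                ),
                chain=ChainConfig(
                    n_iter=config.bayesr_iters,
                    burn_in=config.bayesr_burn_in,
                    thin=config.bayesr_thin,
                    seed=config.seed + 1,
                ),
            )
            eff = sub_g.sites[["chrom", "pos", "ref", "alt"]].copy()
            eff["counted_allele"] = eff["alt"]
            eff = pd.concat(
                [eff.reset_index(drop=True), post.effects.reset_index(drop=True)],
                axis=1,
            )
            eff_ma, _ = orient_effects(eff, calls, beta_col="v_posterior_mean")
            eff_ma.to_csv(outdir / "bayesr_effects.tsv", sep="\t", index=False)
            results["bayesr"] = post
            results["bayesr_effects"] = eff_ma
            log.append(
                "bayesr: proportions="
                + np.array2string(post.proportions, precision=3)
            )

        # -------------------------------------------------------- direction
        if "direction" in stages and oriented:
            stage = "direction"
            both = classify_effects(oriented["bulls"], oriented["cows"])
            n_cows = int((cohorts == "cows").sum())
            # cow-side effects carry the summary (larger cohort)
            summ_in = both.rename(
                columns={"beta_ma_cow": "beta_ma", "se_cow": "se", "p_cow": "p"}
            )[["chrom", "pos", "effect_class", "beta_ma", "se", "p"]]
            aligned = both[["chrom", "pos"]].merge(
                geno.sites.reset_index()[["chrom", "pos", "index"]],
                on=["chrom", "pos"], how="left",
            )["index"].to_numpy()
            cls_sum = class_summary(
                summ_in, geno.genotypes[:, aligned], n_cows
            )
            tdred_rows = []
            for cls in ("large", "medium", "small"):
                sub = both.loc[both["effect_class"] == cls]
                # TDRed on sign concordance needs the *unfiltered* pairing:
                # use all variants reaching the class p-window in bulls
                p1 = both["p_bull"]
                window = {
                    "large": (0.0, 5e-8),
                    "medium": (5e-8, 5e-5),
                    "small": (5e-5, 0.05),
                }[cls]
                in_win = (p1 >= window[0]) & (p1 < window[1])
                pair = both.loc[
                    in_win & (both["beta_ma_bull"] != 0) & (both["beta_ma_cow"] != 0)
                ]
                tdred_rows.append(
                    {
                        "effect_class": cls,
                        "n_pairs": len(pair),
                        "tdred": tdred(pair["beta_ma_bull"], pair["beta_ma_cow"])
                        if len(pair)
                        else np.nan,
                    }
                )
            cls_sum = cls_sum.merge(pd.DataFrame(tdred_rows), on="effect_class")
            cls_sum.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
            results["class_summary"] = cls_sum
            results["classified"] = both
            log.append("direction: " + cls_sum.to_string(index=False).split("\n")[0])

        # ----------------------------------------------------------- popgen
        if "popgen" in stages and calls is not None:
            stage = "popgen"
            breeds = pheno["breed"]
            freq = ma_frequency(geno, calls, breeds)
            fst = weir_fst(geno, breeds)
            freq.to_csv(outdir / "ma_frequency.tsv", sep="\t", index=False)
            fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
            results["ma_frequency"] = freq
            results["fst"] = fst
            # group summaries for MA+ / MA- sets (by cow-side GWAS direction)
            if oriented:
                ori = oriented["cows"]
                merged = freq.merge(
                    ori[["chrom", "pos", "beta_ma", "p"]], on=["chrom", "pos"]
                )
                aligned = merged[["chrom", "pos"]].merge(
                    geno.sites.reset_index()[["chrom", "pos", "index"]],
                    on=["chrom", "pos"], how="left",
                )["index"].to_numpy()
                rows = []
                for direction_label, mask in (
                    ("MA+", merged["beta_ma"] > 0),
                    ("MA-", merged["beta_ma"] < 0),
                ):
                    sub = merged.loc[mask.to_numpy()].reset_index(drop=True)
                    sub_geno = geno.genotypes[:, aligned[mask.to_numpy()]]
                    kept = ld_clump(sub, sub_geno, config.clump_r2,
                                    config.clump_window_bp)
                    s = group_summary(sub["freq_all"], kept)
                    fsub = fst.merge(sub[["chrom", "pos"]], on=["chrom", "pos"])
                    sf = group_summary(fsub["fst"], kept)
                    rows.append(
                        {
                            "group": direction_label,
                            "freq_mean": s["mean"],
                            "freq_se": s["se"],
                            "fst_mean": sf["mean"],
                            "fst_se": sf["se"],
                            "n": s["n"],
                        }
                    )
                popsum = pd.DataFrame(rows)
                popsum.to_csv(outdir / "popgen_summary.tsv", sep="\t", index=False)
                results["popgen_summary"] = popsum
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed under seed {config.seed} "
            f"(config hash {config.content_hash()}): {err}"
        ) from err

    # ------------------------------------------------------------ provenance
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "mutpolar_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "log": log,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    results["log"] = log
    return results
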