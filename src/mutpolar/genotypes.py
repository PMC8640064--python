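"""Genotype container and on-disk formats.

Genotypes are stored as allele counts of the ALT allele (0/1/2, -1 for
missing) in an individuals x sites int8 matrix, alongside a per-site table
(chrom, pos, ref, alt). Positions are 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for a panel of individuals.

    Attributes
    ----------
    genotypes : (n_individuals, n_sites) int8 array of ALT-allele counts,
        ``MISSING`` (-1) for missing calls.
    sites : DataFrame with columns chrom, pos, ref, alt (1-based pos).
    samples : list of sample identifiers, row order of ``genotypes``.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        if len(self.sites) != self.genotypes.shape[1]:
            raise ValueError("site table length does not match genotype columns")
        if not self.samples:
            self.samples = [f"ind{i}" for i in range(self.genotypes.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """ALT-allele frequency per site, ignoring missing genotypes."""
        g = self.genotypes
        obs = g != MISSING
        called = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(g != MISSING, g, 0).sum(axis=0) / called

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[idx],
            self.sites.reset_index(drop=True),
            [self.samples[i] for i in idx],
        )

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.samples),
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        """Write sites + genotype columns (one column per sample) as TSV."""
        df = self.sites.copy()
        gt = pd.DataFrame(
            self.genotypes.T, columns=self.samples, index=df.index
        )
        pd.concat([df, gt], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["chrom", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta_cols]
        geno = df[samples].to_numpy(dtype=np.int8).T
        return cls(geno, df[meta_cols].copy(), samples)

    def to_vcf(self, path) -> None:
        """Write a minimal VCFv4.2 with GT-only biallelic records.

        Unphased diploid GT from allele counts; ``./.`` for missing.
        """
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            contigs = pd.unique(self.sites["chrom"].astype(str))
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for j, row in enumerate(self.sites.itertuples(index=False)):
                calls = "\t".join(
                    gt_strings[int(g)] for g in self.genotypes[:, j]
                )
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic SNP records from a VCF via cyvcf2.

        Multi-allelic records are rejected: the analysis is defined for
        biallelic variants only.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        chroms, poss, refs, alts, rows = [], [], [], [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                    "split or filter to biallelic sites first"
                )
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            g = rec.gt_types.astype(np.int8)  # 0,1,2, 3=unknown with gts012
            g[g == 3] = MISSING
            rows.append(g)
        sites = pd.DataFrame(
            {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
        )
        geno = np.vstack(rows).T if rows else np.zeros((len(samples), 0), np.int8)
        return cls(geno, sites, samples)
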