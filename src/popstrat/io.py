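"""Text exports: cohort tables, frequency/architecture tables, VCF."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Cohort

__all__ = ["cohort_table", "freqs_table", "architecture_table", "write_tsv", "export_vcf"]

FLOAT_FORMAT = "%.10g"


def cohort_table(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": np.arange(cohort.n_individuals),
            "admixture": cohort.admixture,
            "genetic_component": cohort.genetic_component,
            "environment": cohort.environment,
            "noise": cohort.noise,
            "phenotype": cohort.phenotype,
        }
    )


def freqs_table(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": np.arange(cohort.n_snps),
            "ancestral": cohort.freqs.ancestral,
            "pop1": cohort.freqs.pop1,
            "pop2": cohort.freqs.pop2,
        }
    )


def architecture_table(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": np.arange(cohort.n_snps),
            "causal": cohort.arch.causal_indicator,
            "effect_size": cohort.arch.effect_sizes,
        }
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def export_vcf(cohort: Cohort, path: str | Path, contig: str = "1") -> Path:
    """Write genotypes as an uncompressed VCF v4.2 with haploid GT calls.

    SNP ``l`` sits at position ``l+1`` on a dummy contig with fixed REF/ALT
    ``A``/``G``.
    """
    path = Path(path)
    n, L = cohort.genotypes.shape
    samples = [f"ind{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popstrat\n")
        fh.write(f"##contig=<ID={contig},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        G = cohort.genotypes.astype(str)
        for l in range(L):
            fixed = f"{contig}\t{l + 1}\tsnp{l + 1}\tA\tG\t.\t.\t.\tGT\t"
            fh.write(fixed + "\t".join(G[:, l]) + "\n")
    return path
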