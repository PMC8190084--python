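"""File-format boundary: VCF, tab-delimited tables, YAML configs.

The simulator writes a plain-text VCF 4.2 with GT:GQ:DP:AD genotypes plus
tab-delimited phenotype, annotation-sidecar, ClinVar-submission-summary and
PGS-weight tables; the triage side reads the VCF back through cyvcf2 and
applies the genotype QC filter while loading.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .triage import GenotypeCall, filter_genotype

__all__ = [
    "write_vcf",
    "read_vcf_genotypes",
    "write_table",
    "read_table",
    "load_yaml",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=penexome-simulate
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""


def write_vcf(
    path: str | Path,
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    seed: int = 0,
) -> Path:
    """Write an alt-allele-count matrix as VCF 4.2 with GT:GQ:DP:AD.

    Read depths and allele depths for called genotypes are drawn from a
    seeded stream so output is deterministic; all planted genotypes are
    high-quality (the QC filter has dedicated fixtures elsewhere).
    """
    path = Path(path)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    samples = list(genotypes.index)
    lines = [_VCF_HEADER]
    for k in sorted({str(c) for c in variants["chrom"]}):
        lines.append(f"##contig=<ID={k}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    order = variants.sort_values(["chrom", "pos"]).index
    for vid in order:
        row = variants.loc[vid]
        alt_counts = genotypes[vid].to_numpy()
        dps = rng.poisson(40, size=len(samples)) + 10
        fields = []
        for ac, dp in zip(alt_counts, dps):
            if np.isnan(ac):
                fields.append("./.:.:.:.")
                continue
            ac = int(ac)
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[ac]
            alt_reads = {0: 0, 1: int(round(dp / 2)), 2: int(dp)}[ac]
            fields.append(f"{gt}:99:{dp}:{dp - alt_reads},{alt_reads}")
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
            f"\t.\tPASS\t.\tGT:GQ:DP:AD\t" + "\t".join(fields) + "\n"
        )
    path.write_text("".join(lines))
    return path


def read_vcf_genotypes(path: str | Path, apply_qc: bool = True) -> pd.DataFrame:
    """Load a VCF into an individuals x variant alt-allele-count matrix.

    With ``apply_qc`` genotypes failing the GQ/DP/allele-balance filter are
    set to NaN (treated as missing downstream).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}-{var.POS}-{var.REF}-{var.ALT[0]}"
        gts = np.array([g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else np.nan
                        for g in var.genotypes], dtype=float)
        if apply_qc:
            gq = var.format("GQ")
            dp = var.format("DP")
            ad = var.format("AD")
            for i in range(len(samples)):
                if np.isnan(gts[i]):
                    continue
                gt_label = {0.0: "hom_ref", 1.0: "het", 2.0: "hom_alt"}[gts[i]]
                call = GenotypeCall(
                    gt=gt_label,
                    gq=float(gq[i][0]) if gq is not None else 99.0,
                    dp=float(dp[i][0]) if dp is not None else 99.0,
                    ad=(int(ad[i][0]), int(ad[i][1])) if ad is not None else (0, 0),
                )
                if not filter_genotype(call):
                    gts[i] = np.nan
        data[vid] = gts
    return pd.DataFrame(data, index=samples)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
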