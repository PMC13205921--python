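"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF (read through cyvcf2) or as a TSV dialect of the
trio table; everything else is headered TSV.  Output VCFs are minimal
(GT-only) with the hybrid genotype phased (``0|1`` / ``1|0``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_trio_vcf",
    "read_tsv",
    "write_phased_vcf",
]

_GT_MAP = {
    (0, 0): "0/0", (0, 1): "0/1", (1, 0): "1/0", (1, 1): "1/1",
    (-1, -1): "./.",
}


def _code_gt(gt_list) -> str:
    alleles = tuple(a for a in gt_list[:2])
    phased = len(gt_list) > 2 and gt_list[2]
    if any(a is None or a < 0 for a in alleles):
        return "./."
    sep = "|" if phased else "/"
    return f"{alleles[0]}{sep}{alleles[1]}"


def read_trio_vcf(vcf_path: str | Path, manifest: pd.DataFrame) -> pd.DataFrame:
    """Long trio genotype table from a multi-sample VCF.

    ``manifest`` maps ``hybrid_id, female_id, male_id`` to sample columns.
    Sites whose trio samples are absent raise; multi-allelic records are
    kept (downstream phasing labels them uninformative).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    trios = []
    for t in manifest.itertuples(index=False):
        for sid in (t.hybrid_id, t.female_id, t.male_id):
            if sid not in sample_idx:
                raise ValueError(f"sample {sid!r} missing from VCF")
        trios.append((t.hybrid_id, sample_idx[t.female_id],
                      sample_idx[t.male_id], sample_idx[t.hybrid_id]))
    recs = []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}_{var.POS}"
        gts = var.genotypes
        for hyb, fi, mi, hi in trios:
            recs.append((snp_id, var.CHROM, var.POS, hyb,
                         _code_gt(gts[fi]), _code_gt(gts[mi]),
                         _code_gt(gts[hi])))
    return pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "hybrid_id",
                                       "female_gt", "male_gt", "hybrid_gt"])


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_phased_vcf(phased: pd.DataFrame, manifest: pd.DataFrame,
                     path: str | Path) -> None:
    """Minimal GT-only VCF of the phasing result (kept sites phased)."""
    samples = []
    for t in manifest.itertuples(index=False):
        samples += [t.female_id, t.male_id, t.hybrid_id]
    sites = (phased.drop_duplicates("snp_id")[["snp_id", "chrom", "pos"]]
             .sort_values(["chrom", "pos"]))
    wide = phased.set_index(["snp_id", "hybrid_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sites.itertuples(index=False):
            fields = [str(site.chrom), str(site.pos), site.snp_id, "A", "G",
                      ".", "PASS", ".", "GT"]
            for t in manifest.itertuples(index=False):
                try:
                    row = wide.loc[(site.snp_id, t.hybrid_id)]
                except KeyError:
                    fields += ["./.", "./.", "./."]
                    continue
                hyb_gt = (row["phased_gt"] if row["phased_gt"] != "none"
                          else row["hybrid_gt"])
                fields += [row["female_gt"], row["male_gt"], hyb_gt]
            fh.write("\t".join(fields) + "\n")
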