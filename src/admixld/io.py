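"""File formats: phased VCF, RFMix-msp-style local ancestry, summary stats.

Cohorts are exported as minimal phased VCF (GT only, synthesized contig
header, 1-based positions) and read back with cyvcf2. Local-ancestry
tracks use a tab-separated msp-style table: one row per maximal block of
loci whose label column pattern is constant, with physical and genetic
start/end, the number of loci covered, and one ancestry code per
haplotype. Association output is a fixed-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import GeneticMap

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_msp",
    "read_msp",
    "write_sumstats",
    "read_sumstats",
    "write_manifest",
]

SUMSTATS_COLUMNS = [
    "marker", "bp", "cm",
    "freq_anc0", "freq_anc1",
    "att_beta", "att_se", "att_p",
    "tractor_beta_anc0", "tractor_se_anc0",
    "tractor_beta_anc1", "tractor_se_anc1",
    "tractor_gamma_anc1",
    "tractor_chi2", "tractor_df", "tractor_p",
    "fe_chi2", "fe_p",
]


def write_vcf(path, haplotypes: np.ndarray, bp: np.ndarray, contig: str = "1",
              contig_length: int | None = None, sample_prefix: str = "ind") -> None:
    """Write phased GT-only VCF. `haplotypes` is (n_individuals, 2, n_loci)."""
    hap = np.asarray(haplotypes)
    bp = np.asarray(bp)
    n, _, n_loci = hap.shape
    if np.any(np.diff(bp) <= 0):
        raise ValueError("VCF positions must be strictly increasing")
    length = int(contig_length or (int(bp[-1]) + 1))
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for k in range(n_loci):
            gts = "\t".join(f"{hap[i, 0, k]}|{hap[i, 1, k]}" for i in range(n))
            fh.write(f"{contig}\t{int(bp[k]) + 1}\tsnp{k}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a phased GT-only VCF: returns (haplotypes (n,2,L) int8, bp 0-based)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    hap_cols = []
    bp = []
    last = -1
    for var in vcf:
        if var.POS <= last:
            raise ValueError(f"VCF positions not strictly increasing at POS {var.POS}")
        last = var.POS
        gts = var.genotypes  # list of [a, b, phased]
        arr = np.array(gts, dtype=np.int64)
        if arr.shape[1] != 3:
            raise ValueError(f"ploidy != 2 at POS {var.POS}")
        if np.any(arr[:, 2] == 0):
            raise ValueError(f"unphased genotype at POS {var.POS}")
        hap_cols.append(arr[:, :2].astype(np.int8))
        bp.append(var.POS - 1)
    hap = np.stack(hap_cols, axis=2)  # (n, 2, n_loci)
    return hap, np.asarray(bp, dtype=np.int64)


def write_msp(path, labels: np.ndarray, gmap: GeneticMap, contig: str = "1") -> None:
    """RFMix-msp-style local ancestry: rows are constant label blocks.

    `labels` is (n_haplotypes, n_loci); haplotype columns are named
    ind{i}.0 / ind{i}.1.
    """
    lab = np.asarray(labels)
    n_hap, n_loci = lab.shape
    if n_hap % 2:
        raise ValueError("haplotype count must be 2 x individuals")
    # block boundaries where any haplotype's label changes
    change = np.flatnonzero(np.any(lab[:, 1:] != lab[:, :-1], axis=0)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n_loci]])
    cols = [f"ind{i // 2}.{i % 2}" for i in range(n_hap)]
    with open(path, "w") as fh:
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn_snps\t" + "\t".join(cols) + "\n")
        for s, e in zip(starts, ends):
            epos = int(gmap.bp[e]) if e < n_loci else int(gmap.bp[-1]) + 1
            egpos = gmap.cm[e] if e < n_loci else gmap.cm[-1]
            row = [contig, str(int(gmap.bp[s])), str(epos),
                   f"{gmap.cm[s]:.6f}", f"{egpos:.6f}", str(e - s)]
            row += [str(int(v)) for v in lab[:, s]]
            fh.write("\t".join(row) + "\n")


def read_msp(path, bp: np.ndarray) -> np.ndarray:
    """Expand an msp-style table back to per-locus labels at positions `bp`."""
    df = pd.read_csv(path, sep="\t")
    if not df.columns[0].startswith("#chm"):
        raise ValueError("malformed msp header: expected '#chm' first column")
    bp = np.asarray(bp)
    spos = df["spos"].to_numpy()
    lab_block = df.iloc[:, 6:].to_numpy(dtype=np.int8).T  # (n_hap, n_blocks)
    idx = np.searchsorted(spos, bp, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("locus position precedes the first msp block")
    return lab_block[:, idx]


def write_sumstats(path, df: pd.DataFrame) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats table missing columns: {missing}")
    df.loc[:, SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, config: dict, seeds: dict, counts: dict | None = None,
                   outputs: list | None = None) -> None:
    """Run manifest: config echo, stage seeds, row counts, output registry."""
    from . import __version__

    payload = {
        "package_version": __version__,
        "config": config,
        "seeds": seeds,
        "row_counts": counts or {},
        "outputs": outputs or [],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
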