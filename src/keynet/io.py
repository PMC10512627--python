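"""Readers and writers for the on-disk formats used by the pipeline.

All tabular artifacts are tab-separated text with a header row; count
matrices carry gene IDs in the first column. Genotypes are exchanged as a
minimal VCF v4.2 (biallelic sites, GT-only FORMAT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GenotypeTable",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_annotation",
    "write_annotation",
    "read_vcf",
    "write_vcf",
    "read_json",
    "write_json",
]

FLOAT_FORMAT = "%.10g"


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # genes x samples
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene IDs in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in count matrix")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GenotypeTable:
    """Biallelic variant dosages (0/1/2) with genomic positions."""

    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # 1-based
    dosages: np.ndarray  # snps x samples, values in {0,1,2}
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if (self.pos < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be 0, 1, or 2")
        n = len(self.snp_ids)
        if not (len(self.chrom) == len(self.pos) == self.dosages.shape[0] == n):
            raise ValueError("inconsistent genotype table dimensions")

    def subset(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeTable(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=[self.chrom[i] for i in idx],
            pos=self.pos[idx],
            dosages=self.dosages[idx],
            sample_ids=list(self.sample_ids),
        )


def read_counts(path: str | Path, tissue: str = "") -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df, tissue=tissue)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample table must contain a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in sample table")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    lo = df[["tss", "tes"]].min(axis=1)
    hi = df[["tss", "tes"]].max(axis=1)
    df = df.assign(tss=lo, tes=hi)
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_vcf(gt: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF v4.2: fixed columns + GT for every sample."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = list(dict.fromkeys(gt.chrom))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + list(gt.sample_ids)) + "\n")
        for i, snp in enumerate(gt.snp_ids):
            fields = [
                str(gt.chrom[i]),
                str(int(gt.pos[i])),
                snp,
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields.extend(gt_strings[int(d)] for d in gt.dosages[i])
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        g = np.array([a[0] + a[1] for a in variant.genotypes], dtype=np.int8)
        rows.append(g)
    vcf.close()
    return GenotypeTable(
        snp_ids=snp_ids,
        chrom=chrom,
        pos=np.array(pos, dtype=np.int64),
        dosages=np.vstack(rows) if rows else np.zeros((0, len(sample_ids)), dtype=np.int8),
        sample_ids=sample_ids,
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
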