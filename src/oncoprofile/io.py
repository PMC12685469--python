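"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-separated text: SEG-like segment tables (sample, chrom,
start, end, value), BED-like 4-column bin counts, gene x sample expression
matrices, plasma mutation tables (TSV or minimal VCF with AD/DP), and
JSON truth/report sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_probe_table", "write_probe_table",
    "read_bin_counts", "write_bin_counts",
    "write_seg", "read_snp_alleles", "read_snp_alleles_vcf",
    "write_snp_alleles",
    "read_expression", "write_expression",
    "read_plasma_table", "write_plasma_table",
    "write_truth", "read_truth",
]


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe", "gene", "chrom", "start", "end", "ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"probe table missing columns {required - set(df.columns)}")
    return df


def write_probe_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "count"], comment="#")
    return df


def write_bin_counts(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "count"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_seg(segments: pd.DataFrame, path, sample: str = "sample") -> None:
    """SEG-like table: sample, chrom, start, end, value (segment mean)."""
    out = segments.rename(columns={"segment_mean_ratio": "value"})
    out.insert(0, "sample", sample)
    out[["sample", "chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False
    )


def read_snp_alleles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"site", "region", "ref_count", "alt_count"}
    if not required <= set(df.columns):
        raise ValueError(f"SNP table missing columns {required - set(df.columns)}")
    return df


def write_snp_alleles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snp_alleles_vcf(path, region_map=None) -> pd.DataFrame:
    """Het-SNP allele counts from a VCF with per-sample AD (first sample).

    ``region_map``: optional callable (chrom, pos) -> region label; defaults
    to the chromosome name.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            sample = rec.samples[list(rec.samples)[0]]
            ad = sample.get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                continue
            region = (
                region_map(rec.chrom, rec.pos) if region_map is not None else rec.chrom
            )
            rows.append((f"{rec.chrom}:{rec.pos}", region, int(ad[0]), int(ad[1])))
    return pd.DataFrame(rows, columns=["site", "region", "ref_count", "alt_count"])


def read_expression(counts_path, lengths_path=None, labels_path=None):
    """Gene x sample counts TSV (first column = gene id), plus optional
    gene-length and sample-label TSVs."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0]
    labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep="\t", index_col=0)
        labels = ldf.iloc[:, 0]
    return counts, lengths, labels


def write_expression(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_plasma_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"site", "depth", "alt_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"plasma table missing columns {required - set(df.columns)}")
    if "origin" not in df.columns:
        df["origin"] = "tumor_informed"
    return df


def write_plasma_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth, path) -> None:
    """Structured JSON sidecar for a TruthRecord (extras are stringified)."""
    payload = {
        "tumor_fraction": truth.tumor_fraction,
        "cnv_events": list(truth.cnv_events),
        "sv_events": list(truth.sv_events),
        "fusions": list(truth.fusions),
        "plasma_tf_trajectory": list(truth.plasma_tf_trajectory),
        "informative_genes": dict(truth.informative_genes),
    }
    if truth.tissue_label is not None:
        try:
            payload["tissue_label"] = list(truth.tissue_label)
        except TypeError:
            payload["tissue_label"] = truth.tissue_label
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
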