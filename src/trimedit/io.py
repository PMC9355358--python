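"""Readers for the pipeline's tab-separated inputs.

All genomic positions in TSV inputs are 1-based inclusive; BED files are
0-based half-open and converted on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from trimedit.errors import InputError

_BOOL_COLS = ["flag_read_end", "flag_indel_splice", "flag_homopolymer", "in_catalog", "is_common_snp"]


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in _BOOL_COLS:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id"}
    if not required <= set(df.columns):
        raise InputError(f"sample table {path} lacks columns {sorted(required - set(df.columns))}")
    return df


def read_key_table(path) -> pd.DataFrame:
    """(chrom, pos, strand) key table: catalog, SNPs, or gene map."""
    return pd.read_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_motifs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_islands_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive island intervals."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["start"] = df["start"] + 1
    return df


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
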