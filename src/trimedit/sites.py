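"""Candidate A-to-I editing-site filtering and per-sample status calls.

The filter cascade mirrors a strand-aware variant-caller post-processing
workflow: per-record thresholds on the caller statistic, total coverage and
alternate-allele depth; removal of records flagged as read-end / indel-or-
splice-proximal / homopolymeric; removal of common genomic SNPs and of
non-A>G mismatches; then two site-level rules — recurrence across samples
and membership in a known-editing-site catalog. Each site x sample record
is additionally classified as EDITED, UNEDITED or INSUFFICIENT_COVERAGE so
that absence of editing can be distinguished from absence of data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np
import pandas as pd

from trimedit.errors import ConfigurationError, InputError

SITE_KEY = ["chrom", "pos", "strand"]
RECORD_KEY = SITE_KEY + ["sample_id"]
FLAG_COLS = ["flag_read_end", "flag_indel_splice", "flag_homopolymer"]

#: fixed attrition reporting order; only attribution depends on it, not the result
FILTER_STAGES = [
    "test_stat",
    "coverage",
    "alt_depth",
    "positional_flags",
    "snp",
    "ag",
    "recurrence",
    "catalog",
]


class SiteStatus(str, Enum):
    EDITED = "EDITED"
    UNEDITED = "UNEDITED"
    INSUFFICIENT_COVERAGE = "INSUFFICIENT_COVERAGE"


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the site-filter cascade (defaults follow the JACUSA-style workflow)."""

    min_test_stat: float = 1.56
    min_total_coverage: int = 10
    min_alt_depth: int = 3
    min_samples_edited: int = 3
    require_catalog: bool = True
    ag_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_test_stat", "min_total_coverage", "min_alt_depth", "min_samples_edited"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


class FilterResult(NamedTuple):
    #: unique retained sites (chrom, pos, strand)
    retained_sites: pd.DataFrame
    #: all input records at retained sites (every sample, any coverage)
    records: pd.DataFrame
    #: records at retained sites that passed every per-record predicate
    passing_records: pd.DataFrame
    #: per-stage attrition: stage, unit (records|sites), n_removed, n_remaining
    attrition: pd.DataFrame


def _validate_records(records: pd.DataFrame, need_flags: bool = True) -> None:
    required = RECORD_KEY + ["ref_base", "alt_base", "ref_count", "alt_count"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise InputError(f"records table missing columns: {missing}")
    bad_strand = ~records["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise InputError(f"unknown strand value(s): {sorted(records.loc[bad_strand, 'strand'].unique())}")
    if records.duplicated(RECORD_KEY).any():
        dup = records[records.duplicated(RECORD_KEY, keep=False)].iloc[0]
        raise InputError(
            f"duplicate (site, sample) row: {dup['chrom']}:{dup['pos']}:{dup['strand']} {dup['sample_id']}"
        )
    if need_flags:
        missing_flags = [c for c in FLAG_COLS if c not in records.columns]
        if missing_flags:
            raise InputError(f"records table missing flag columns: {missing_flags}")


def annotate_catalog(
    records: pd.DataFrame, catalog: pd.DataFrame | None, snps: pd.DataFrame | None
) -> pd.DataFrame:
    """Attach in_catalog / is_common_snp columns from (chrom, pos, strand) key tables."""
    out = records.copy()
    for col, table in (("in_catalog", catalog), ("is_common_snp", snps)):
        if table is None:
            if col not in out.columns:
                out[col] = False
            continue
        key = pd.MultiIndex.from_frame(table[SITE_KEY])
        out[col] = pd.MultiIndex.from_frame(out[SITE_KEY]).isin(key)
    return out


def record_predicates(records: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Boolean frame of the per-record predicates, one column per cascade stage."""
    total = records["ref_count"] + records["alt_count"]
    preds = pd.DataFrame(index=records.index)
    preds["test_stat"] = records["test_stat"] >= params.min_test_stat
    preds["coverage"] = total >= params.min_total_coverage
    preds["alt_depth"] = records["alt_count"] >= params.min_alt_depth
    preds["positional_flags"] = ~records[FLAG_COLS].any(axis=1)
    preds["snp"] = ~records.get("is_common_snp", pd.Series(False, index=records.index)).astype(bool)
    if params.ag_only:
        preds["ag"] = (records["ref_base"] == "A") & (records["alt_base"] == "G")
    else:
        preds["ag"] = True
    return preds


def apply_site_filters(records: pd.DataFrame, params: FilterParams = FilterParams()) -> FilterResult:
    """Run the full cascade; returns retained sites plus per-stage attrition.

    A site is retained when it has >= ``min_samples_edited`` samples whose
    records pass every per-record predicate, and (if ``require_catalog``)
    is listed in the editing-site catalog. The retained-record frames keep
    all samples for retained sites so downstream status calls can still
    distinguish insufficient coverage.
    """
    _validate_records(records)
    preds = record_predicates(records, params)

    attrition = []
    alive = pd.Series(True, index=records.index)
    for stage in FILTER_STAGES[:6]:
        removed = int((alive & ~preds[stage]).sum())
        alive &= preds[stage]
        attrition.append({"stage": stage, "unit": "records", "n_removed": removed, "n_remaining": int(alive.sum())})

    passing = records[alive]
    detections = passing.groupby(SITE_KEY, sort=False).size()
    recurrent = detections[detections >= params.min_samples_edited]
    sites_all = records[SITE_KEY].drop_duplicates()
    n_sites_in = len(sites_all)
    site_index = pd.MultiIndex.from_frame(sites_all)
    keep = site_index.isin(recurrent.index) if params.min_samples_edited > 0 else np.ones(n_sites_in, bool)
    attrition.append(
        {
            "stage": "recurrence",
            "unit": "sites",
            "n_removed": int(n_sites_in - keep.sum()),
            "n_remaining": int(keep.sum()),
        }
    )

    if params.require_catalog:
        if "in_catalog" not in records.columns:
            raise InputError("require_catalog=True but records lack in_catalog (run annotate_catalog)")
        cat_sites = pd.MultiIndex.from_frame(records.loc[records["in_catalog"].astype(bool), SITE_KEY])
        in_cat = site_index.isin(cat_sites)
        removed = int((keep & ~in_cat).sum())
        keep = keep & in_cat
        attrition.append(
            {"stage": "catalog", "unit": "sites", "n_removed": removed, "n_remaining": int(keep.sum())}
        )
    else:
        attrition.append({"stage": "catalog", "unit": "sites", "n_removed": 0, "n_remaining": int(keep.sum())})

    retained_sites = sites_all[keep].reset_index(drop=True)
    retained_index = pd.MultiIndex.from_frame(retained_sites)
    rec_mask = pd.MultiIndex.from_frame(records[SITE_KEY]).isin(retained_index)
    retained_records = records[rec_mask].reset_index(drop=True)
    passing_mask = pd.MultiIndex.from_frame(passing[SITE_KEY]).isin(retained_index)
    return FilterResult(
        retained_sites=retained_sites,
        records=retained_records,
        passing_records=passing[passing_mask].reset_index(drop=True),
        attrition=pd.DataFrame(attrition),
    )


def classify_status(records: pd.DataFrame, params: FilterParams = FilterParams()) -> pd.Series:
    """Vectorised EDITED / UNEDITED / INSUFFICIENT_COVERAGE call per record."""
    total = records["ref_count"] + records["alt_count"]
    out = pd.Series(SiteStatus.INSUFFICIENT_COVERAGE.value, index=records.index)
    covered = total >= params.min_total_coverage
    out[covered & (records["alt_count"] >= params.min_alt_depth)] = SiteStatus.EDITED.value
    out[covered & (records["alt_count"] < params.min_alt_depth)] = SiteStatus.UNEDITED.value
    return out


def classify_site_status(ref_count: int, alt_count: int, params: FilterParams = FilterParams()) -> SiteStatus:
    """Status of a single site x sample observation."""
    if ref_count + alt_count < params.min_total_coverage:
        return SiteStatus.INSUFFICIENT_COVERAGE
    if alt_count >= params.min_alt_depth:
        return SiteStatus.EDITED
    return SiteStatus.UNEDITED


def status_table(records: pd.DataFrame, params: FilterParams = FilterParams()) -> pd.DataFrame:
    """Site x sample matrix of status strings (missing records = insufficient coverage)."""
    df = records.copy()
    df["status"] = classify_status(df, params)
    df["site_id"] = site_ids(df)
    table = df.pivot(index="site_id", columns="sample_id", values="status")
    return table.fillna(SiteStatus.INSUFFICIENT_COVERAGE.value)


def site_ids(records: pd.DataFrame) -> pd.Series:
    return (
        records["chrom"].astype(str)
        + ":"
        + records["pos"].astype(str)
        + ":"
        + records["strand"].astype(str)
    )


def count_recurrent_sites(
    records: pd.DataFrame,
    params: FilterParams = FilterParams(),
    k: int | None = None,
    require_transcribed_in_all: bool = False,
) -> tuple[int, int]:
    """Cohort-level (edited in >= k samples, edited in all samples) site counts.

    "Edited" in a sample means status EDITED under ``params``. With
    ``require_transcribed_in_all`` the >=k count additionally demands
    coverage in every sample (no INSUFFICIENT_COVERAGE calls).
    """
    if records.empty:
        return (0, 0)
    table = status_table(records, params)
    if k is None:
        k = params.min_samples_edited
    edited = table.eq(SiteStatus.EDITED.value)
    n_samples = table.shape[1]
    ge_k = edited.sum(axis=1) >= k
    if require_transcribed_in_all:
        ge_k &= ~table.eq(SiteStatus.INSUFFICIENT_COVERAGE.value).any(axis=1)
    n_all = int((edited.sum(axis=1) == n_samples).sum())
    return (int(ge_k.sum()), n_all)
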