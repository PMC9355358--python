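"""DMP calling, gap-chained DMR clustering, CpG context, and gene assignment.

Probe-level differential methylation is tested by per-probe ordinary least
squares of beta on group (plus optional covariates) with Benjamini-Hochberg
correction across probes; a DMP must pass both the adjusted-significance
(p_adj < 0.05) and the effect-size (|delta beta| >= 0.05) thresholds. DMPs
are then chained into DMRs by single-linkage clustering along each
chromosome (inter-probe gap <= max_gap), annotated with their CpG-island
context (island / shore / shelf / open sea at the conventional 2 kb / 4 kb
distances), and assigned to genes by the nearest-TSS-within-1-Mb and
promoter-within-5-kb rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from trimedit.diffedit import benjamini_hochberg
from trimedit.errors import DesignError, InputError

SHORE_BP = 2000
SHELF_BP = 4000
NEAREST_BP = 1_000_000
PROMOTER_BP = 5000


def call_dmps(
    probes: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    case_group: str = "vaccinated",
    p_threshold: float = 0.05,
    delta_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe OLS of beta on group; returns (dmps, per-probe statistics).

    ``probes`` carries probe_id/chrom/pos plus one beta column per sample;
    ``samples`` maps sample_id to group. delta_beta is case minus control.
    """
    sample_ids = samples["sample_id"].tolist()
    missing = [s for s in sample_ids if s not in probes.columns]
    if missing:
        raise InputError(f"probe table lacks beta columns for samples: {missing[:5]}")
    groups = samples.set_index("sample_id")["group"]
    if groups.nunique() != 2:
        raise DesignError(f"need exactly two groups, got {sorted(groups.unique())}")
    if (groups.value_counts() < 2).any():
        raise DesignError("each group needs at least two samples")
    if case_group not in set(groups):
        raise DesignError(f"case group {case_group!r} not present")

    Y = probes[sample_ids].to_numpy(float).T  # samples x probes
    if ((Y < 0) | (Y > 1)).any():
        raise InputError("beta values must lie in [0, 1]")
    indicator = (groups.loc[sample_ids] == case_group).to_numpy(float)
    X = np.column_stack([np.ones(len(sample_ids)), indicator])
    if covariates is not None:
        cov = covariates.loc[sample_ids].to_numpy(float)
        X = np.column_stack([X, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("degenerate design: covariates collinear with group")

    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    delta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)

    result = probes[["probe_id", "chrom", "pos"]].copy()
    result["delta_beta"] = delta
    result["p"] = p
    result["p_adj"] = benjamini_hochberg(p)
    passed = (result["p_adj"] < p_threshold) & (result["delta_beta"].abs() >= delta_threshold)
    dmps = result[passed].copy()
    dmps["direction"] = np.where(dmps["delta_beta"] > 0, "hyper", "hypo")
    return dmps.reset_index(drop=True), result


def cluster_dmps(dmps: pd.DataFrame, max_gap: int = 1000, min_probes: int = 2) -> pd.DataFrame:
    """Chain DMPs into DMRs: same chromosome, consecutive gap <= ``max_gap``.

    Returns chrom, start, end (1-based inclusive = first/last probe
    position), n_probes, mean_delta_beta, length_bp, probe_ids.
    """
    if dmps.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_probes", "mean_delta_beta", "length_bp", "probe_ids"]
        )
    if dmps.duplicated(["chrom", "pos"]).any():
        dup = dmps[dmps.duplicated(["chrom", "pos"], keep=False)].iloc[0]
        raise InputError(f"duplicate probe position {dup['chrom']}:{dup['pos']}")
    df = dmps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_cluster = (df["chrom"] != df["chrom"].shift()) | (df["pos"] - df["pos"].shift() > max_gap)
    cluster_id = new_cluster.cumsum()
    rows = []
    for _cid, grp in df.groupby(cluster_id):
        if len(grp) < min_probes:
            continue
        rows.append(
            {
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["pos"].min()),
                "end": int(grp["pos"].max()),
                "n_probes": len(grp),
                "mean_delta_beta": float(grp["delta_beta"].mean()),
                "length_bp": int(grp["pos"].max() - grp["pos"].min() + 1),
                "probe_ids": ",".join(grp["probe_id"].astype(str)),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "mean_delta_beta", "length_bp", "probe_ids"])


def _validate_islands(islands: pd.DataFrame) -> None:
    if (islands["end"] < islands["start"]).any():
        raise InputError("malformed island interval: end < start")
    for _chrom, grp in islands.groupby("chrom"):
        starts = grp["start"].sort_values().to_numpy()
        ends = grp.sort_values("start")["end"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise InputError("islands must be non-overlapping within a chromosome")


def annotate_cpg_context(intervals: pd.DataFrame, islands: pd.DataFrame) -> pd.Series:
    """CpG context per interval: island / shore / shelf / open_sea.

    ``intervals`` needs chrom plus either pos or start/end (1-based
    inclusive; spans are reduced to their midpoint). ``islands`` are 1-based
    inclusive intervals, non-overlapping per chromosome.
    """
    _validate_islands(islands)
    if "pos" in intervals.columns:
        mid = intervals["pos"].to_numpy()
    else:
        mid = ((intervals["start"] + intervals["end"]) // 2).to_numpy()
    labels = np.full(len(intervals), "open_sea", object)
    for chrom, grp in islands.groupby("chrom"):
        mask = (intervals["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = grp["start"].sort_values().to_numpy()
        ends = grp.sort_values("start")["end"].to_numpy()
        pos = mid[mask]
        # distance to the nearest island: 0 if inside
        dist = np.full(pos.shape, np.inf)
        for s, e in zip(starts, ends):
            d = np.where(pos < s, s - pos, np.where(pos > e, pos - e, 0))
            dist = np.minimum(dist, d)
        lab = np.where(dist == 0, "island", np.where(dist <= SHORE_BP, "shore", np.where(dist <= SHELF_BP, "shelf", "open_sea")))
        labels[mask] = lab
    return pd.Series(labels, index=intervals.index, name="context")


def assign_genes(
    positions: pd.DataFrame,
    genes: pd.DataFrame,
    nearest_bp: int = NEAREST_BP,
    promoter_bp: int = PROMOTER_BP,
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Nearest-gene (<= 1 Mb) and promoter (<= 5 kb of TSS) assignment.

    ``positions`` needs chrom plus pos (or start/end, reduced to midpoint);
    ``genes`` needs gene_id, chrom, tss. Equidistant ties go to the
    lexicographically smaller gene id. Returns the per-input assignment
    frame plus the two gene sets.
    """
    if "pos" in positions.columns:
        pos = positions["pos"].to_numpy()
    else:
        pos = ((positions["start"] + positions["end"]) // 2).to_numpy()
    nearest = np.full(len(positions), None, object)
    promoter_lists: list[list[str]] = [[] for _ in range(len(positions))]
    order = genes.sort_values("gene_id", kind="mergesort")
    for chrom, grp in order.groupby("chrom"):
        mask = np.flatnonzero((positions["chrom"] == chrom).to_numpy())
        if mask.size == 0:
            continue
        tss = grp["tss"].to_numpy()
        ids = grp["gene_id"].to_numpy()
        for i in mask:
            d = np.abs(tss - pos[i])
            dmin = d.min()
            if dmin <= nearest_bp:
                # ids are sorted lexicographically, argmin takes the first tie
                nearest[i] = ids[np.argmin(d)]
            promoter_lists[i] = sorted(ids[d <= promoter_bp])
    out = positions.copy()
    out["nearest_gene"] = nearest
    out["promoter_genes"] = [",".join(g) for g in promoter_lists]
    nearest_set = {g for g in nearest if g is not None}
    promoter_set = {g for lst in promoter_lists for g in lst}
    return out, nearest_set, promoter_set
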