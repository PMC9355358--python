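"""Trained-vs-attenuated response ranking and sliding-window motif enrichment.

Genes induced by the secondary LPS exposure (in naive or BCG-exposed
macrophages) are ranked by their training score: the log2 induction in
BCG-Mf (mean of the Denmark and Bulgaria strains) minus the induction in
naive macrophages, averaged over donors. Strongly shifted genes are called
TRAINED or ATTENUATED at p < 0.05 and fold change > 2; promoter motif
enrichment is then scanned along the ranking in overlapping windows with a
one-sided hypergeometric test against the full ranked background.

Induction p-values come from a paired t-test on log2(x + pseudocount)
across donors — a deliberately simple stand-in for a count-model DE engine,
suited to the small paired design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trimedit.config import BCG_CONDITIONS, NAIVE
from trimedit.errors import ConfigurationError, InputError

TRAINED = "TRAINED"
UNAFFECTED = "UNAFFECTED"
ATTENUATED = "ATTENUATED"

PRE, POST = "D6", "D6_LPS"


@dataclass(frozen=True)
class DEThresholds:
    """Differential-expression and training-call thresholds."""

    induced_p: float = 0.05
    induced_fc: float = 2.5
    expression_floor: float = 5.0
    response_p: float = 0.05
    response_fc: float = 2.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        for name in ("induced_p", "induced_fc", "expression_floor", "response_p", "response_fc", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def _log2_ratio_matrix(expression: pd.DataFrame, meta: pd.DataFrame, pseudocount: float):
    """Per-gene, per-sample log2((post+pc)/(pre+pc)) plus the post-value matrix."""
    wide = expression.pivot_table(index="gene_id", columns=["sample_id", "timepoint"], values="value")
    samples = meta["sample_id"].tolist()
    for s in samples:
        for tp in (PRE, POST):
            if (s, tp) not in wide.columns:
                raise InputError(f"missing {tp} measurement for sample {s}")
    pre = wide.loc[:, [(s, PRE) for s in samples]].to_numpy()
    post = wide.loc[:, [(s, POST) for s in samples]].to_numpy()
    if np.isnan(pre).any() or np.isnan(post).any():
        raise InputError("missing pre/post pairing for at least one gene x sample")
    ratios = np.log2(post + pseudocount) - np.log2(pre + pseudocount)
    return pd.Index(wide.index), samples, ratios, post


def _paired_t_pvalue(diffs: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t on paired differences; constant rows give p=1."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
    return p


def identify_induced_genes(
    expression: pd.DataFrame, meta: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> list[str]:
    """Genes induced by LPS restimulation in the naive OR the BCG group.

    A gene is induced in a group when the geometric-mean post/pre fold
    change exceeds ``induced_fc``, the paired t-test across that group's
    samples gives p < ``induced_p``, and mean post-stimulation expression
    is at least ``expression_floor``.
    """
    genes, samples, ratios, post = _log2_ratio_matrix(expression, meta, thresholds.pseudocount)
    cond = meta.set_index("sample_id")["condition"]
    groups = {
        "naive": [i for i, s in enumerate(samples) if cond[s] == NAIVE],
        "bcg": [i for i, s in enumerate(samples) if cond[s] in BCG_CONDITIONS],
    }
    induced = np.zeros(len(genes), bool)
    for idx in groups.values():
        if not idx:
            continue
        sub = ratios[:, idx]
        fc = np.exp2(sub.mean(axis=1))
        p = _paired_t_pvalue(sub)
        floor_ok = post[:, idx].mean(axis=1) >= thresholds.expression_floor
        induced |= (fc > thresholds.induced_fc) & (p < thresholds.induced_p) & floor_ok
    return sorted(genes[induced])


def rank_by_training(
    induced: list[str],
    expression: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Rank induced genes by BCG-vs-naive induction (descending training score).

    The per-donor training difference is the mean log2 induction over the
    two BCG strains minus the naive log2 induction; the training score is
    its donor average and the p-value a paired t-test across donors. Ties
    are broken by gene id.
    """
    if not induced:
        raise InputError("induced gene set is empty")
    genes, samples, ratios, _post = _log2_ratio_matrix(expression, meta, thresholds.pseudocount)
    keep = genes.isin(set(induced))
    genes, ratios = genes[keep], ratios[keep]
    m = meta.set_index("sample_id")
    donors = sorted(m["donor_id"].unique())
    diffs = np.empty((len(genes), len(donors)))
    naive_ind = np.empty((len(genes), len(donors)))
    bcg_ind = np.empty((len(genes), len(donors)))
    for j, donor in enumerate(donors):
        naive_idx = [i for i, s in enumerate(samples) if m.loc[s, "donor_id"] == donor and m.loc[s, "condition"] == NAIVE]
        bcg_idx = [i for i, s in enumerate(samples) if m.loc[s, "donor_id"] == donor and m.loc[s, "condition"] in BCG_CONDITIONS]
        if not naive_idx or not bcg_idx:
            raise InputError(f"donor {donor} lacks naive or BCG samples")
        naive_ind[:, j] = ratios[:, naive_idx].mean(axis=1)
        bcg_ind[:, j] = ratios[:, bcg_idx].mean(axis=1)
        diffs[:, j] = bcg_ind[:, j] - naive_ind[:, j]
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "induction_naive": naive_ind.mean(axis=1),
            "induction_bcg": bcg_ind.mean(axis=1),
            "training_score": diffs.mean(axis=1),
            "p_value": _paired_t_pvalue(diffs),
        }
    )
    out = out.sort_values(["training_score", "gene_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def classify_genes(ranked: pd.DataFrame, thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Attach TRAINED / UNAFFECTED / ATTENUATED calls to the ranked table."""
    log2fc = np.log2(thresholds.response_fc)
    score, p = ranked["training_score"], ranked["p_value"]
    klass = np.full(len(ranked), UNAFFECTED, object)
    klass[(score > log2fc) & (p < thresholds.response_p)] = TRAINED
    klass[(score < -log2fc) & (p < thresholds.response_p)] = ATTENUATED
    out = ranked.copy()
    out["gene_class"] = klass
    return out


def sliding_window_motif_enrichment(
    ranked_genes: list[str], motifs: pd.DataFrame, window: int = 60, step: int = 10
) -> pd.DataFrame:
    """One-sided hypergeometric motif enrichment along the ranked gene list.

    Windows of ``window`` consecutive genes advance by ``step``; the number
    of windows is ``floor((N - window) / step) + 1``. For each (window,
    motif): p = P[X >= k] for X hypergeometric(N, K, window), where K is
    the motif's hit count among all ranked genes.
    """
    n = len(ranked_genes)
    if window > n:
        raise InputError(f"window {window} exceeds number of ranked genes {n}")
    if step < 1:
        raise InputError("step must be >= 1")
    missing = set(ranked_genes) - set(motifs.index)
    if missing:
        raise InputError(f"motif matrix lacks {len(missing)} ranked gene(s)")
    hits = motifs.loc[ranked_genes].to_numpy(bool)
    totals = hits.sum(axis=0)
    n_windows = (n - window) // step + 1
    rows = []
    for w in range(n_windows):
        lo = w * step
        counts = hits[lo : lo + window].sum(axis=0)
        pvals = stats.hypergeom.sf(counts - 1, n, totals, window)
        for m, motif in enumerate(motifs.columns):
            rows.append(
                {
                    "window_index": w,
                    "start_rank": lo,
                    "motif": motif,
                    "hit_count": int(counts[m]),
                    "background_count": int(totals[m]),
                    "background_rate": totals[m] / n,
                    "p": float(min(pvals[m], 1.0)),
                }
            )
    return pd.DataFrame(rows)
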