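"""Gene-level allele summation and binomial-GLM differential-editing tests.

Editing evidence is aggregated by summing reference and alternate allele
counts over each gene's retained sites in each sample, so read depth enters
the likelihood directly. Differential editing between conditions is tested
with a logit-link binomial GLM, with the naive condition as reference and
donor identity as fixed-effect covariates. Set-level fits include per-gene
baseline intercepts by default: genes differ strongly in their baseline
editing rate, and without the offsets that heterogeneity leaks into the
condition contrast through sample-to-sample coverage fluctuation and
inflates its nominal significance. ``gene_effects=False`` gives the plain
condition + donor form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from trimedit.config import NAIVE
from trimedit.errors import ConvergenceError, DesignError, InputError
from trimedit.sites import SITE_KEY

#: |coefficient| beyond which a binomial fit is treated as separated
_SEPARATION_BOUND = 15.0


class GeneSummation(NamedTuple):
    #: rows: gene_id, sample_id, sum_ref, sum_alt, n_sites_covered
    table: pd.DataFrame
    #: retained records that had no gene assignment
    n_dropped_records: int


def sum_gene_alleles(
    records: pd.DataFrame, gene_map: pd.DataFrame, multi_gene: str = "error"
) -> GeneSummation:
    """Per (gene, sample) sums of reference/alternate alleles over retained sites.

    ``multi_gene`` controls sites mapping to several genes: ``"error"``
    raises, ``"first"`` keeps the lexicographically first gene id.
    """
    dup = gene_map.duplicated(SITE_KEY, keep=False)
    if dup.any():
        if multi_gene == "error":
            bad = gene_map[dup].iloc[0]
            raise InputError(
                f"site {bad['chrom']}:{bad['pos']}:{bad['strand']} maps to multiple genes "
                "(pass multi_gene='first' to keep the first by gene id)"
            )
        if multi_gene != "first":
            raise InputError(f"unknown multi_gene policy {multi_gene!r}")
        gene_map = gene_map.sort_values("gene_id", kind="mergesort").drop_duplicates(SITE_KEY)
    merged = records.merge(gene_map[SITE_KEY + ["gene_id"]], on=SITE_KEY, how="left")
    dropped = int(merged["gene_id"].isna().sum())
    merged = merged.dropna(subset=["gene_id"])
    merged = merged.assign(total=merged["ref_count"] + merged["alt_count"])
    grouped = merged.groupby(["gene_id", "sample_id"], sort=True)
    table = grouped.agg(
        sum_ref=("ref_count", "sum"),
        sum_alt=("alt_count", "sum"),
        n_sites_covered=("total", lambda t: int((t > 0).sum())),
    ).reset_index()
    table = table[(table["sum_ref"] + table["sum_alt"]) > 0].reset_index(drop=True)
    return GeneSummation(table=table, n_dropped_records=dropped)


@dataclass
class DifferentialEditingResult:
    """Per-condition contrasts vs the reference for one gene or gene set."""

    unit: str
    #: condition -> (log-odds estimate, std error, Wald p)
    contrasts: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    #: condition -> BH q (filled by test_gene_editing)
    fdr_q: dict[str, float] = field(default_factory=dict)
    n_rows: int = 0
    reference: str = NAIVE


def _design(df: pd.DataFrame, reference: str, gene_effects: bool) -> pd.DataFrame:
    conditions = [reference] + sorted(set(df["condition"]) - {reference})
    cond = pd.Categorical(df["condition"], categories=conditions)
    parts = [pd.get_dummies(cond, prefix="cond", drop_first=True)]
    if df["donor_id"].nunique() > 1:
        parts.append(pd.get_dummies(pd.Categorical(df["donor_id"]), prefix="donor", drop_first=True))
    if gene_effects and df["gene_id"].nunique() > 1:
        parts.append(pd.get_dummies(pd.Categorical(df["gene_id"]), prefix="gene", drop_first=True))
    X = pd.concat(parts, axis=1).astype(float)
    X.insert(0, "const", 1.0)
    X.index = df.index
    return X


def _fit_binomial(
    df: pd.DataFrame,
    reference: str,
    gene_effects: bool,
    quasi: bool,
    maxiter: int = 100,
) -> dict[str, tuple[float, float, float]]:
    """IRLS binomial fit; returns condition -> (estimate, se, Wald p)."""
    if reference not in set(df["condition"]):
        raise DesignError(f"reference condition {reference!r} absent")
    X = _design(df, reference, gene_effects)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("rank-deficient binomial design")
    endog = np.column_stack([df["sum_alt"].to_numpy(), df["sum_ref"].to_numpy()])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, scale="X2" if quasi else None)
    if not res.converged:
        raise ConvergenceError(
            f"binomial GLM did not converge in {maxiter} iterations", deviance=float(res.deviance)
        )
    cond_cols = [c for c in X.columns if c.startswith("cond_")]
    if any(abs(res.params[c]) > _SEPARATION_BOUND for c in cond_cols):
        raise ConvergenceError("separation detected in binomial GLM", deviance=float(res.deviance))
    out = {reference: (0.0, 0.0, 1.0)}
    for c in cond_cols:
        out[c.removeprefix("cond_")] = (
            float(res.params[c]),
            float(res.bse[c]),
            float(res.pvalues[c]),
        )
    return out


def test_geneset_editing(
    table: pd.DataFrame,
    geneset: list[str] | set[str],
    meta: pd.DataFrame,
    label: str = "set",
    reference: str = NAIVE,
    gene_effects: bool = True,
    quasi: bool = False,
) -> DifferentialEditingResult:
    """Condition contrasts of pooled editing odds within one gene set."""
    rows = table[table["gene_id"].isin(set(geneset))]
    if rows.empty:
        raise InputError(f"gene set {label!r} has no genes with editing evidence")
    df = rows.merge(meta, on="sample_id", validate="many_to_one")
    contrasts = _fit_binomial(df, reference, gene_effects, quasi)
    return DifferentialEditingResult(unit=label, contrasts=contrasts, n_rows=len(rows), reference=reference)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_gene_editing(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    min_samples_covered: int = 6,
    fdr: float = 0.01,
    reference: str = NAIVE,
    quasi: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene condition contrasts with BH correction within each contrast.

    Genes with editing rows in fewer than ``min_samples_covered`` samples
    are skipped; per-gene fit failures are reported in the skipped table,
    not raised. Returns (results, skipped) frames; results columns:
    gene_id, condition, estimate, se, p, q, significant.
    """
    if table.empty:
        raise InputError("gene editing table is empty")
    counts = table.groupby("gene_id")["sample_id"].nunique()
    testable = counts.index[counts >= min_samples_covered]
    skipped_rows = [
        {"gene_id": g, "reason": f"covered in {counts[g]} < {min_samples_covered} samples"}
        for g in counts.index.difference(testable)
    ]
    rows = []
    merged = table[table["gene_id"].isin(testable)].merge(meta, on="sample_id", validate="many_to_one")
    for gene, df in merged.groupby("gene_id", sort=True):
        try:
            contrasts = _fit_binomial(df, reference, gene_effects=False, quasi=quasi)
        except (DesignError, ConvergenceError) as exc:
            skipped_rows.append({"gene_id": gene, "reason": str(exc)})
            continue
        for cond, (est, se, p) in contrasts.items():
            if cond == reference:
                continue
            rows.append({"gene_id": gene, "condition": cond, "estimate": est, "se": se, "p": p})
    results = pd.DataFrame(rows, columns=["gene_id", "condition", "estimate", "se", "p"])
    if not results.empty:
        results["q"] = np.nan
        for cond, idx in results.groupby("condition").groups.items():
            results.loc[idx, "q"] = benjamini_hochberg(results.loc[idx, "p"].to_numpy())
        results["significant"] = results["q"] < fdr
    else:
        results["q"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
    skipped = pd.DataFrame(skipped_rows, columns=["gene_id", "reason"])
    return results, skipped


def background_adjust(
    table: pd.DataFrame,
    geneset: list[str] | set[str],
    meta: pd.DataFrame,
    background: list[str] | set[str] | None = None,
    label: str = "set",
    reference: str = NAIVE,
    gene_effects: bool = True,
) -> DifferentialEditingResult:
    """Set effect beyond the background: set x condition interaction contrasts.

    Fits one joint binomial GLM over background union set rows with a
    set-membership indicator and its interaction with each non-reference
    condition; the interaction coefficient is the set's extra log-odds shift
    after controlling for the background's own condition response.
    """
    geneset = set(geneset)
    background = set(background) if background is not None else set(table["gene_id"])
    if geneset == background:
        raise DesignError("gene set equals the background: interaction design is degenerate")
    rows = table[table["gene_id"].isin(background | geneset)]
    in_set = rows["gene_id"].isin(geneset)
    if not in_set.any():
        raise InputError(f"gene set {label!r} has no genes with editing evidence")
    df = rows.merge(meta, on="sample_id", validate="many_to_one")
    X = _design(df, reference, gene_effects)
    set_ind = in_set.to_numpy().astype(float)
    if set_ind.min() == set_ind.max():
        raise DesignError("all rows belong to the gene set: interaction design is degenerate")
    if not gene_effects:
        # with per-gene intercepts the membership main effect is absorbed by them
        X["in_set"] = set_ind
    inter_cols = []
    for c in [c for c in X.columns if c.startswith("cond_")]:
        name = f"inter_{c.removeprefix('cond_')}"
        X[name] = X[c] * set_ind
        inter_cols.append(name)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("rank-deficient interaction design")
    endog = np.column_stack([df["sum_alt"].to_numpy(), df["sum_ref"].to_numpy()])
    res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=100)
    if not res.converged:
        raise ConvergenceError("binomial GLM did not converge", deviance=float(res.deviance))
    contrasts = {reference: (0.0, 0.0, 1.0)}
    for name in inter_cols:
        cond = name.removeprefix("inter_")
        contrasts[cond] = (float(res.params[name]), float(res.bse[name]), float(res.pvalues[name]))
    return DifferentialEditingResult(unit=label, contrasts=contrasts, n_rows=len(rows), reference=reference)
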