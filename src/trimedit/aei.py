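"""Alu editing index (AEI) and the donor-controlled condition model.

The AEI of a sample is the pooled editing rate over a fixed "universal" set
of sites — those called EDITED in every sample of the cohort — computed as
total edited (alternate) reads divided by total transcribed reads. Condition
effects on the AEI are estimated by ordinary least squares with the naive
(RPMI) condition as reference and donor identity as fixed-effect covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from trimedit.config import NAIVE
from trimedit.errors import DesignError, InputError
from trimedit.sites import FilterParams, SiteStatus, site_ids, status_table


def select_universal_sites(status: pd.DataFrame) -> list[str]:
    """Sites with status EDITED in every sample of the cohort."""
    if status.shape[1] == 0:
        raise InputError("empty cohort: status table has no samples")
    universal = status.eq(SiteStatus.EDITED.value).all(axis=1)
    return sorted(status.index[universal])


def compute_aei(records: pd.DataFrame, universal_sites: list[str], sample_id: str) -> float:
    """Sum of edited reads over sum of transcribed reads for one sample."""
    if not universal_sites:
        raise InputError("universal site set is empty")
    df = records[records["sample_id"] == sample_id]
    df = df[site_ids(df).isin(universal_sites)]
    alt = int(df["alt_count"].sum())
    total = int(df["ref_count"].sum()) + alt
    if total == 0:
        raise InputError(f"zero total coverage over universal sites in sample {sample_id}")
    return alt / total


def compute_aei_table(records: pd.DataFrame, universal_sites: list[str]) -> pd.DataFrame:
    """Per-sample AEI over the universal set: sample_id, aei, n_sites."""
    if not universal_sites:
        raise InputError("universal site set is empty")
    df = records[site_ids(records).isin(universal_sites)].copy()
    grouped = df.groupby("sample_id", sort=True)
    alt = grouped["alt_count"].sum()
    total = alt + grouped["ref_count"].sum()
    if (total == 0).any():
        bad = total.index[total == 0].tolist()
        raise InputError(f"zero total coverage over universal sites in sample(s) {bad}")
    n_sites = grouped.size()
    return pd.DataFrame({"sample_id": alt.index, "aei": (alt / total).to_numpy(), "n_sites": n_sites.to_numpy()})


@dataclass
class AEIResult:
    """Per-sample AEI plus fitted condition/donor linear-model coefficients."""

    aei: pd.DataFrame
    universal_site_count: int
    #: condition -> (estimate, std error, two-sided p); reference condition maps to (0, 0, 1)
    coefficients: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    donor_coefficients: dict[str, float] = field(default_factory=dict)
    residual_df: int = 0
    reference: str = NAIVE


def fit_aei_model(
    aei: pd.DataFrame, meta: pd.DataFrame, reference: str = NAIVE, universal_site_count: int = 0
) -> AEIResult:
    """OLS of AEI on condition indicators (vs ``reference``) plus donor indicators.

    Standard errors and two-sided p-values come from the t distribution at
    the residual degrees of freedom, matching an lm()-style fit.
    """
    df = aei.merge(meta, on="sample_id", validate="one_to_one")
    conditions = df["condition"].unique()
    if reference not in conditions:
        raise DesignError(f"reference condition {reference!r} absent from the cohort")
    if len(conditions) < 2:
        raise DesignError("need at least two conditions to estimate condition effects")
    per_donor = df.groupby("donor_id")["condition"].nunique()
    if (per_donor < 2).any():
        bad = per_donor.index[per_donor < 2].tolist()
        raise DesignError(f"donor(s) observed in a single condition (collinear design): {bad}")

    cond = pd.Categorical(df["condition"], categories=[reference] + sorted(set(conditions) - {reference}))
    donor = pd.Categorical(df["donor_id"])
    X = pd.concat(
        [
            pd.get_dummies(cond, prefix="cond", drop_first=True),
            pd.get_dummies(donor, prefix="donor", drop_first=True),
        ],
        axis=1,
    ).astype(float)
    X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    res = sm.OLS(df["aei"].to_numpy(), X).fit()

    dof = int(res.df_resid)
    coeffs: dict[str, tuple[float, float, float]] = {reference: (0.0, 0.0, 1.0)}
    for c in sorted(set(conditions) - {reference}):
        name = f"cond_{c}"
        est, se = float(res.params[name]), float(res.bse[name])
        p = 2 * stats.t.sf(abs(est / se), dof) if se > 0 else 0.0
        coeffs[c] = (est, se, float(p))
    donor_coeffs = {
        name.removeprefix("donor_"): float(res.params[name])
        for name in X.columns
        if name.startswith("donor_")
    }
    return AEIResult(
        aei=aei,
        universal_site_count=universal_site_count,
        coefficients=coeffs,
        donor_coefficients=donor_coeffs,
        residual_df=dof,
        reference=reference,
    )


def aei_pipeline(
    records: pd.DataFrame, meta: pd.DataFrame, params: FilterParams = FilterParams()
) -> AEIResult:
    """Status calls -> universal sites -> per-sample AEI -> condition model."""
    status = status_table(records, params)
    universal = select_universal_sites(status)
    table = compute_aei_table(records, universal)
    return fit_aei_model(table, meta, universal_site_count=len(universal))
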