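"""Replicated simulation experiments: null calibration and effect recovery.

These functions run the pipeline end-to-end on many independently seeded
synthetic datasets and summarise how well the planted truth is recovered.
Replicates use a reduced problem size (fewer sites/genes/probes than the
full defaults) so that hundreds of pipeline runs complete in seconds; all
noise, coverage and effect-size parameters stay at their defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from trimedit import diffedit, trained
from trimedit.aei import aei_pipeline, fit_aei_model
from trimedit.config import SimulationConfig
from trimedit.methylation import call_dmps, cluster_dmps
from trimedit.simulate import (
    generate_editing_dataset,
    generate_methylation_dataset,
    generate_motif_hits,
)
from trimedit.sites import FilterParams, annotate_catalog, apply_site_filters

#: reduced editing-arm scale used for replicated experiments
REPLICATE_SCALE = dict(n_sites=200, n_genes=80)

_NULL_EFFECTS = {c: 0.0 for c in SimulationConfig().conditions}


def _null_config(seed: int, **overrides) -> SimulationConfig:
    base = dict(REPLICATE_SCALE, condition_edit_effect=dict(_NULL_EFFECTS))
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


def _sub_seed(seed: int, rep: int, stream: int) -> int:
    # keep derived seeds well below 2**31
    return (seed * 100_003 + stream * 10_000 + rep) % (2**31 - 1)


def aei_null_type1(seed: int, n_replicates: int = 500, condition: str = "BCG_DK") -> dict:
    """Rejection rate of the AEI condition test when no condition effect is planted."""
    hits = 0
    for rep in range(n_replicates):
        cfg = _null_config(_sub_seed(seed, rep, 1))
        data = generate_editing_dataset(cfg)
        records = annotate_catalog(data.sites, data.catalog, data.snps)
        result = apply_site_filters(records, FilterParams())
        fit = aei_pipeline(result.records, data.samples)
        hits += int(fit.coefficients[condition][2] < 0.05)
    return {"rate": hits / n_replicates, "n": n_replicates}


def geneset_null_type1(seed: int, n_replicates: int = 500, condition: str = "BCG_DK") -> dict:
    """Rejection rate of the gene-set binomial GLM under the null."""
    hits = 0
    done = 0
    for rep in range(n_replicates):
        cfg = _null_config(_sub_seed(seed, rep, 2), geneset_fractions={"ex_vivo": 0.25})
        data = generate_editing_dataset(cfg)
        records = annotate_catalog(data.sites, data.catalog, data.snps)
        result = apply_site_filters(records, FilterParams())
        table = diffedit.sum_gene_alleles(result.records, data.gene_map).table
        try:
            res = diffedit.test_geneset_editing(table, data.truth.genesets["ex_vivo"], data.samples)
        except Exception:
            continue
        hits += int(res.contrasts[condition][2] < 0.05)
        done += 1
    return {"rate": hits / done, "n": done}


def gene_null_type1(
    seed: int, n_replicates: int = 100, genes_per_replicate: int = 8, condition: str = "BCG_DK"
) -> dict:
    """Pre-FDR rejection rate of per-gene GLM tests under the null.

    Each fitted gene is one replicate of the unit under test; only genes
    covered in every sample are fitted, up to ``genes_per_replicate`` per
    simulated dataset.
    """
    hits = 0
    n_tests = 0
    for rep in range(n_replicates):
        cfg = _null_config(_sub_seed(seed, rep, 3))
        data = generate_editing_dataset(cfg)
        records = annotate_catalog(data.sites, data.catalog, data.snps)
        result = apply_site_filters(records, FilterParams())
        table = diffedit.sum_gene_alleles(result.records, data.gene_map).table
        counts = table.groupby("gene_id")["sample_id"].nunique()
        full = counts.index[counts == len(data.samples)][:genes_per_replicate]
        results, _skipped = diffedit.test_gene_editing(
            table[table["gene_id"].isin(full)], data.samples, min_samples_covered=len(data.samples)
        )
        sub = results[results["condition"] == condition]
        hits += int((sub["p"] < 0.05).sum())
        n_tests += len(sub)
    return {"rate": hits / n_tests, "n": n_tests}


def recover_geneset_boost(seed: int, n_replicates: int = 100, boost: float = 0.4) -> dict:
    """Mean recovered BCG log-odds shift for a planted gene-set editing boost."""
    estimates = []
    for rep in range(n_replicates):
        cfg = _null_config(
            _sub_seed(seed, rep, 4),
            n_sites=240,
            geneset_fractions={"ex_vivo": 0.25},
            geneset_edit_boost={"ex_vivo": boost},
        )
        data = generate_editing_dataset(cfg)
        records = annotate_catalog(data.sites, data.catalog, data.snps)
        result = apply_site_filters(records, FilterParams())
        table = diffedit.sum_gene_alleles(result.records, data.gene_map).table
        res = diffedit.test_geneset_editing(table, data.truth.genesets["ex_vivo"], data.samples)
        estimates.append((res.contrasts["BCG_DK"][0] + res.contrasts["BCG_BG"][0]) / 2)
    return {"mean_estimate": float(np.mean(estimates)), "planted": boost, "n": n_replicates}


def recover_aei_shift(
    seed: int,
    n_replicates: int = 200,
    shift: float = 0.02,
    noise_sd: float = 0.005,
    tolerance: float = 0.01,
    n_donors: int = 5,
) -> dict:
    """Fraction of replicates recovering a planted AEI condition shift within tolerance."""
    rng = np.random.default_rng(seed)
    conditions = list(SimulationConfig().conditions)
    meta = pd.DataFrame(
        [
            {"sample_id": f"D{d}_{c}", "donor_id": f"D{d}", "condition": c}
            for d in range(n_donors)
            for c in conditions
        ]
    )
    ok = 0
    for _rep in range(n_replicates):
        donor_means = rng.uniform(0.08, 0.12, n_donors)
        aei_vals = [
            donor_means[int(r.donor_id[1:])]
            + (shift if r.condition == "BCG_DK" else 0.0)
            + rng.normal(0, noise_sd)
            for r in meta.itertuples()
        ]
        fit = fit_aei_model(pd.DataFrame({"sample_id": meta["sample_id"], "aei": aei_vals}), meta)
        ok += int(abs(fit.coefficients["BCG_DK"][0] - shift) <= tolerance)
    return {"rate": ok / n_replicates, "planted": shift, "n": n_replicates}


def trained_class_recovery(seed: int, config: SimulationConfig | None = None) -> dict:
    """Fraction of planted trained/attenuated genes recovered with the correct class."""
    from trimedit.simulate import generate_expression_dataset

    cfg = config or SimulationConfig(seed=seed)
    data = generate_expression_dataset(cfg)
    thresholds = trained.DEThresholds()
    induced = trained.identify_induced_genes(data.expression, data.samples, thresholds)
    ranked = trained.rank_by_training(induced, data.expression, data.samples, thresholds)
    classified = trained.classify_genes(ranked, thresholds)
    called = dict(zip(classified["gene_id"], classified["gene_class"]))
    planted = {g: c for g, c in data.truth.gene_class.items() if c != trained.UNAFFECTED}
    correct = sum(called.get(g) == c for g, c in planted.items())
    induced_truth = set(data.truth.induced_genes)
    recall = len(set(induced) & induced_truth) / max(len(induced_truth), 1)
    fpr = len(set(induced) - induced_truth) / max(cfg.n_genes - len(induced_truth), 1)
    return {
        "rate": correct / max(len(planted), 1),
        "n": len(planted),
        "n_induced": len(induced),
        "induced_recall": recall,
        "induced_fpr": fpr,
    }


def motif_window_recovery(
    seed: int, n_replicates: int = 40, n_ranked: int = 300, window: int = 60, step: int = 10
) -> dict:
    """How often the planted motif's best window sits at the trained end of the ranking."""
    ok = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=_sub_seed(seed, rep, 5))
        ranked = [f"G{i:05d}" for i in range(n_ranked)]
        hits = generate_motif_hits(cfg, ranked)
        enrich = trained.sliding_window_motif_enrichment(ranked, hits, window=window, step=step)
        planted = enrich[enrich["motif"] == cfg.planted_motif]
        best = int(planted.loc[planted["p"].idxmin(), "window_index"])
        ok += int(best < 3)
    return {"rate": ok / n_replicates, "n": n_replicates}


def dmr_exact_recovery(seed: int, n_replicates: int = 30) -> dict:
    """Fraction of replicates recovering every planted DMR with exact probe membership."""
    ok = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=_sub_seed(seed, rep, 6), n_probes=400)
        data = generate_methylation_dataset(cfg)
        dmps, _ = call_dmps(data.probes, data.samples)
        dmrs = cluster_dmps(dmps)
        recovered_sets = [set(p.split(",")) for p in dmrs["probe_ids"]]
        exact = all(set(dmr["probe_ids"]) in recovered_sets for dmr in data.truth.dmr_intervals)
        ok += int(exact)
    return {"rate": ok / n_replicates, "n": n_replicates}
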