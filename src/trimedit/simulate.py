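"""Synthetic-data generators for every input the pipeline consumes.

Each generator is deterministic given (seed, config) and plants effects on
the same scale the downstream models estimate them: editing truth is
logit-additive (donor + condition + gene-set boost), expression truth is a
log2-fold training offset, methylation truth is a per-probe group delta-beta.
The planted ids and effect sizes are returned in a :class:`GroundTruth` so
recovery can be scored exactly.

Not emulated: read-level artifacts (FASTQ/BAM), splice structure, probe
cross-reactivity. Common SNPs are emulated as heterozygote-like sites with
alternate-allele fraction 0.5 in every condition, which is what makes the
SNP filter's effect observable downstream.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from trimedit.config import BCG_CONDITIONS, GroundTruth, SimulationConfig
from trimedit.errors import ConfigurationError

TRAINED = "TRAINED"
UNAFFECTED = "UNAFFECTED"
ATTENUATED = "ATTENUATED"

_CHROMS = [f"chr{i}" for i in range(1, 23)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so arms can be produced in any order
    return np.random.default_rng([config.seed, stream])


def make_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene annotation: gene_id, chrom, tss (1-based), strand."""
    n = config.n_genes
    idx = np.arange(n)
    chrom = [_CHROMS[i % len(_CHROMS)] for i in idx]
    tss = 100_000 * (idx // len(_CHROMS) + 1) + 10_000 * (idx % len(_CHROMS))
    strand = np.where(idx % 2 == 0, "+", "-")
    return pd.DataFrame(
        {"gene_id": [f"G{i:05d}" for i in idx], "chrom": chrom, "tss": tss + 1, "strand": strand}
    )


def make_sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"D{d + 1}_{c}", "donor_id": f"D{d + 1}", "condition": c}
        for d in range(config.n_donors)
        for c in config.conditions
    ]
    return pd.DataFrame(rows)


class EditingDataset(NamedTuple):
    sites: pd.DataFrame
    samples: pd.DataFrame
    gene_map: pd.DataFrame
    catalog: pd.DataFrame
    snps: pd.DataFrame
    truth: GroundTruth


def generate_editing_dataset(config: SimulationConfig) -> EditingDataset:
    """Simulate per-site allele-count records for every site x sample.

    Coverage is negative-binomial (mean ``coverage_mean``, size
    ``coverage_dispersion``); alternate counts are binomial with probability
    ``logistic(base + donor + condition + gene-set boost)``. Planted common
    SNPs edit at 0.5 in every condition; a ``decoy_fraction`` of sites carry
    a non-A>G mismatch; exactly ``frac_in_catalog`` of non-SNP sites appear
    in the editing-site catalog.
    """
    rng = _rng(config, 1)
    genes = make_gene_annotation(config)
    samples = make_sample_table(config)
    n_sites, n_samples = config.n_sites, len(samples)

    # --- site layout -----------------------------------------------------
    gene_idx = rng.integers(0, config.n_genes, n_sites)
    offsets = rng.integers(10, 20_000, n_sites)
    # resolve (gene, offset) collisions deterministically
    order = np.lexsort((offsets, gene_idx))
    for k in range(1, n_sites):
        i, j = order[k - 1], order[k]
        if gene_idx[i] == gene_idx[j] and offsets[j] <= offsets[i]:
            offsets[j] = offsets[i] + 1
    chrom = genes["chrom"].to_numpy()[gene_idx]
    pos = genes["tss"].to_numpy()[gene_idx] + offsets
    strand = genes["strand"].to_numpy()[gene_idx]
    site_id = np.array([f"{c}:{p}:{s}" for c, p, s in zip(chrom, pos, strand)])

    # --- site roles ------------------------------------------------------
    n_snp = int(round(config.frac_common_snp * n_sites))
    n_decoy = int(round(config.decoy_fraction * n_sites))
    perm = rng.permutation(n_sites)
    snp_idx = perm[:n_snp]
    decoy_idx = perm[n_snp : n_snp + n_decoy]
    is_snp = np.zeros(n_sites, bool)
    is_snp[snp_idx] = True
    is_decoy = np.zeros(n_sites, bool)
    is_decoy[decoy_idx] = True

    non_snp = np.flatnonzero(~is_snp)
    n_cat = int(round(config.frac_in_catalog * len(non_snp)))
    cat_idx = rng.choice(non_snp, size=n_cat, replace=False)
    in_catalog = np.zeros(n_sites, bool)
    in_catalog[cat_idx] = True

    ref = np.where(is_decoy, "C", "A")
    alt = np.where(is_decoy, "T", "G")

    flags = rng.random((n_sites, 3)) < config.flag_rate

    # --- gene sets -------------------------------------------------------
    gperm = rng.permutation(config.n_genes)
    genesets: dict[str, list[str]] = {}
    start = 0
    for label, frac in config.geneset_fractions.items():
        k = int(round(frac * config.n_genes))
        members = gperm[start : start + k]
        genesets[label] = sorted(genes["gene_id"].to_numpy()[members])
        start += k
    boost = np.zeros(config.n_genes)
    for label, b in config.geneset_edit_boost.items():
        if label not in genesets:
            raise ConfigurationError(f"geneset_edit_boost names unknown set {label!r}")
        member_idx = genes.index[genes["gene_id"].isin(genesets[label])]
        boost[member_idx] = b

    # --- planted logits --------------------------------------------------
    base_logit = config.base_edit_logit_mean + config.base_edit_logit_sd * rng.standard_normal(n_sites)
    donor_eff = config.donor_effect_sd * rng.standard_normal(config.n_donors)
    cond_eff = np.array([config.condition_edit_effect.get(c, 0.0) for c in config.conditions])

    donor_of = np.repeat(np.arange(config.n_donors), len(config.conditions))
    cond_of = np.tile(np.arange(len(config.conditions)), config.n_donors)
    is_bcg = np.array([c in BCG_CONDITIONS for c in config.conditions])[cond_of]

    logit = (
        base_logit[:, None]
        + donor_eff[donor_of][None, :]
        + cond_eff[cond_of][None, :]
        + np.where(is_bcg[None, :], boost[gene_idx][:, None], 0.0)
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    p[is_snp, :] = 0.5

    k = config.coverage_dispersion
    mu = config.coverage_mean
    total = rng.negative_binomial(k, k / (k + mu), (n_sites, n_samples))
    alt_count = rng.binomial(total, p)

    fail = rng.random((n_sites, n_samples)) < config.test_stat_fail_rate
    test_stat = np.where(
        fail,
        rng.uniform(0.0, 1.56, (n_sites, n_samples)),
        1.56 + rng.exponential(3.0, (n_sites, n_samples)),
    )

    sites = pd.DataFrame(
        {
            "chrom": np.repeat(chrom, n_samples),
            "pos": np.repeat(pos, n_samples),
            "strand": np.repeat(strand, n_samples),
            "ref_base": np.repeat(ref, n_samples),
            "alt_base": np.repeat(alt, n_samples),
            "sample_id": np.tile(samples["sample_id"].to_numpy(), n_sites),
            "ref_count": (total - alt_count).ravel(),
            "alt_count": alt_count.ravel(),
            "test_stat": np.round(test_stat.ravel(), 4),
            "flag_read_end": np.repeat(flags[:, 0], n_samples),
            "flag_indel_splice": np.repeat(flags[:, 1], n_samples),
            "flag_homopolymer": np.repeat(flags[:, 2], n_samples),
        }
    )

    gene_map = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": strand, "gene_id": genes["gene_id"].to_numpy()[gene_idx]}
    )
    key_cols = ["chrom", "pos", "strand"]
    catalog = gene_map.loc[in_catalog, key_cols].reset_index(drop=True)
    snps = gene_map.loc[is_snp, key_cols].reset_index(drop=True)

    edit_like = ~(is_snp | is_decoy)
    truth = GroundTruth(
        site_base_logit={s: float(b) for s, b in zip(site_id[edit_like], base_logit[edit_like])},
        donor_effects={f"D{d + 1}": float(e) for d, e in enumerate(donor_eff)},
        condition_effects={c: float(e) for c, e in zip(config.conditions, cond_eff)},
        snp_site_ids=sorted(site_id[is_snp]),
        catalog_site_ids=sorted(site_id[in_catalog]),
        decoy_site_ids=sorted(site_id[is_decoy]),
        flagged_site_ids=sorted(site_id[flags.any(axis=1)]),
        genesets=genesets,
        site_gene=dict(zip(site_id, genes["gene_id"].to_numpy()[gene_idx])),
    )
    return EditingDataset(sites, samples, gene_map, catalog, snps, truth)


class ExpressionDataset(NamedTuple):
    expression: pd.DataFrame
    samples: pd.DataFrame
    truth: GroundTruth


def generate_expression_dataset(config: SimulationConfig) -> ExpressionDataset:
    """Simulate day-6 / day-6+LPS expression with a trained-attenuated continuum.

    LPS restimulation multiplies induced genes by ``2**induced_log2fc``;
    trained genes get an extra ``2**training_log2fc`` in BCG conditions and
    attenuated genes the reciprocal, under multiplicative log-normal noise.
    """
    rng = _rng(config, 2)
    genes = make_gene_annotation(config)
    samples = make_sample_table(config)
    gene_ids = genes["gene_id"].to_numpy()
    n = config.n_genes

    n_induced = int(round(config.induced_fraction * n))
    perm = rng.permutation(n)
    induced = perm[:n_induced]
    n_trained = int(round(config.trained_fraction * n_induced))
    n_atten = int(round(config.attenuated_fraction * n_induced))
    trained = induced[:n_trained]
    attenuated = induced[n_trained : n_trained + n_atten]

    klass = np.full(n, "", object)
    klass[induced] = UNAFFECTED
    klass[trained] = TRAINED
    klass[attenuated] = ATTENUATED

    base = config.base_expression_mean_log2 + config.base_expression_sd_log2 * rng.standard_normal(n)
    induction = np.zeros(n)
    induction[induced] = config.induced_log2fc
    training = np.zeros(n)
    training[trained] = config.training_log2fc
    training[attenuated] = -config.training_log2fc

    is_bcg = samples["condition"].isin(BCG_CONDITIONS).to_numpy()
    frames = []
    for tp in ("D6", "D6_LPS"):
        log2x = np.tile(base[:, None], (1, len(samples)))
        if tp == "D6_LPS":
            log2x = log2x + induction[:, None] + np.where(is_bcg[None, :], training[:, None], 0.0)
        log2x = log2x + config.expression_noise_sd * rng.standard_normal(log2x.shape)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.repeat(gene_ids, len(samples)),
                    "sample_id": np.tile(samples["sample_id"].to_numpy(), n),
                    "timepoint": tp,
                    "value": np.round(np.exp2(log2x).ravel(), 4),
                }
            )
        )
    expression = pd.concat(frames, ignore_index=True)

    truth = GroundTruth(
        induced_genes=sorted(gene_ids[induced]),
        gene_class={g: klass[i] for i, g in enumerate(gene_ids) if klass[i]},
        training_score={g: float(training[i]) for i, g in enumerate(gene_ids) if klass[i]},
    )
    return ExpressionDataset(expression, samples, truth)


class MethylationDataset(NamedTuple):
    probes: pd.DataFrame
    islands: pd.DataFrame
    samples: pd.DataFrame
    truth: GroundTruth


def generate_methylation_dataset(config: SimulationConfig) -> MethylationDataset:
    """Simulate per-probe beta values for a vaccinated-vs-control cohort.

    Probes inside planted DMRs differ between groups by the planted
    delta-beta plus noise; background probes differ by noise only. A CpG
    island is placed under each planted DMR, with decoy islands elsewhere,
    so context annotation is recoverable.
    """
    rng = _rng(config, 3)
    n_bg = config.n_probes
    bg_chroms = _CHROMS[:6]
    per_chrom = np.full(len(bg_chroms), n_bg // len(bg_chroms))
    per_chrom[: n_bg % len(bg_chroms)] += 1

    chroms: list[str] = []
    positions: list[int] = []
    deltas: list[float] = []
    planted_mask: list[bool] = []
    for chrom_name, cnt in zip(bg_chroms, per_chrom):
        gaps = rng.exponential(config.background_probe_spacing, cnt).astype(int) + 50
        pos = 10_000 + np.cumsum(gaps)
        chroms += [chrom_name] * cnt
        positions += pos.tolist()
        deltas += [0.0] * cnt
        planted_mask += [False] * cnt
    for chrom_name, start, n_probes, delta in config.dmr_plan:
        pos = start + np.arange(n_probes) * config.dmr_probe_spacing
        chroms += [chrom_name] * n_probes
        positions += pos.tolist()
        deltas += [delta] * n_probes
        planted_mask += [True] * n_probes

    probes = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "delta": deltas, "planted": planted_mask}
    )
    # drop background probes that landed inside a planted span
    drop = np.zeros(len(probes), bool)
    for chrom_name, start, n_probes, _ in config.dmr_plan:
        end = start + (n_probes - 1) * config.dmr_probe_spacing
        drop |= (
            (~probes["planted"])
            & (probes["chrom"] == chrom_name)
            & probes["pos"].between(start - 2 * config.dmr_probe_spacing, end + 2 * config.dmr_probe_spacing)
        ).to_numpy()
    probes = probes[~drop]
    probes = probes.drop_duplicates(subset=["chrom", "pos"])
    probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    probes.insert(0, "probe_id", [f"cg{i:06d}" for i in range(len(probes))])

    m = len(probes)
    ng = config.n_per_group
    sample_ids = [f"vac{i + 1:02d}" for i in range(ng)] + [f"ctl{i + 1:02d}" for i in range(ng)]
    groups = ["vaccinated"] * ng + ["control"] * ng
    baseline = rng.uniform(0.2, 0.8, m)
    delta = probes["delta"].to_numpy()
    beta = baseline[:, None] + config.beta_noise_sd * rng.standard_normal((m, 2 * ng))
    beta[:, :ng] += delta[:, None]
    beta = np.clip(beta, 0.001, 0.999)
    beta_df = pd.DataFrame(np.round(beta, 4), columns=sample_ids)
    probe_table = pd.concat(
        [probes[["probe_id", "chrom", "pos"]].reset_index(drop=True), beta_df], axis=1
    )

    # islands: one under each planted DMR + decoys far from planted spans
    island_rows = []
    for chrom_name, start, n_probes, _ in config.dmr_plan:
        end = start + (n_probes - 1) * config.dmr_probe_spacing
        island_rows.append({"chrom": chrom_name, "start": start - 200, "end": end + 200})
    for chrom_name in bg_chroms:
        island_rows.append({"chrom": chrom_name, "start": 9_000_000, "end": 9_000_800})
    islands = (
        pd.DataFrame(island_rows).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    )

    meth_samples = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    intervals = []
    for chrom_name, start, n_probes, d in config.dmr_plan:
        end = start + (n_probes - 1) * config.dmr_probe_spacing
        member = probes[(probes["chrom"] == chrom_name) & probes["pos"].between(start, end)]
        intervals.append(
            {
                "chrom": chrom_name,
                "start": int(start),
                "end": int(end),
                "delta_beta": float(d),
                "probe_ids": member["probe_id"].tolist(),
            }
        )
    truth = GroundTruth(dmr_intervals=intervals)
    return MethylationDataset(probe_table, islands, meth_samples, truth)


def generate_motif_hits(config: SimulationConfig, ranked_genes: list[str]) -> pd.DataFrame:
    """Boolean gene x motif matrix with the planted motif boosted in the top genes.

    The first ``planted_top_n`` genes of ``ranked_genes`` carry the planted
    motif at ``planted_motif_rate``; every other (gene, motif) cell is an
    independent Bernoulli draw at ``motif_background_rate``.
    """
    if config.planted_motif_rate < config.motif_background_rate:
        raise ConfigurationError("planted_motif_rate must be >= motif_background_rate")
    rng = _rng(config, 4)
    motifs = [config.planted_motif] + [f"M{i:02d}" for i in range(1, config.n_motifs)]
    hits = rng.random((len(ranked_genes), len(motifs))) < config.motif_background_rate
    planted = ranked_genes[: config.planted_top_n]
    if planted:
        planted_rows = np.arange(len(planted))
        hits[planted_rows, 0] = rng.random(len(planted)) < config.planted_motif_rate
    return pd.DataFrame(hits, index=pd.Index(ranked_genes, name="gene_id"), columns=motifs)


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input plus merged ground truth."""
    editing = generate_editing_dataset(config)
    expression = generate_expression_dataset(config)
    methylation = generate_methylation_dataset(config)
    # motif hits are planted along the true training-score ranking
    truth = editing.truth.merge(expression.truth).merge(methylation.truth)
    score = truth.training_score
    ranked = sorted(truth.induced_genes, key=lambda g: (-score.get(g, 0.0), g))
    motifs = generate_motif_hits(config, ranked)
    truth.planted_motif = config.planted_motif
    truth.planted_motif_genes = ranked[: config.planted_top_n]
    return {
        "sites": editing.sites,
        "samples": editing.samples,
        "gene_map": editing.gene_map,
        "catalog": editing.catalog,
        "snps": editing.snps,
        "genes": make_gene_annotation(config),
        "expression": expression.expression,
        "motifs": motifs,
        "probes": methylation.probes,
        "islands": methylation.islands,
        "meth_samples": methylation.samples,
        "truth": truth,
    }


def write_dataset(data: dict, outdir) -> None:
    """Write all simulated tables as TSV/BED/JSON under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = dict(sep="\t", index=False)
    data["sites"].to_csv(out / "sites.tsv", **tsv)
    data["samples"].to_csv(out / "samples.tsv", **tsv)
    data["gene_map"].to_csv(out / "gene_map.tsv", **tsv)
    data["catalog"].to_csv(out / "catalog.tsv", **tsv)
    data["snps"].to_csv(out / "snps.tsv", **tsv)
    data["genes"].to_csv(out / "genes.tsv", **tsv)
    data["expression"].to_csv(out / "expression.tsv", **tsv)
    data["motifs"].to_csv(out / "motifs.tsv", sep="\t")
    data["probes"].to_csv(out / "probes.tsv", **tsv)
    data["meth_samples"].to_csv(out / "meth_samples.tsv", **tsv)
    bed = data["islands"].copy()
    bed["start"] = bed["start"] - 1  # 1-based inclusive -> 0-based half-open
    bed[["chrom", "start", "end"]].to_csv(out / "islands.bed", sep="\t", index=False, header=False)
    data["truth"].to_json(out / "truth.json")
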