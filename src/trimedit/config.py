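"""Simulation configuration and ground-truth containers.

The simulator emulates the study design of the in vitro TRIM model: five
donors, four 24 h exposures (Naive/RPMI, LPS, BCG Denmark, BCG Bulgaria),
RNA profiled at day 6, with a secondary 4 h LPS restimulation for the
expression arm, and an independent vaccinated-vs-control methylation cohort.
All planted effects (donor baselines, condition shifts, gene-set boosts,
DMRs, motif enrichment) are recorded in :class:`GroundTruth` so downstream
modules can be scored against them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from trimedit.errors import ConfigurationError

NAIVE = "NAIVE"
LPS = "LPS"
BCG_DK = "BCG_DK"
BCG_BG = "BCG_BG"

DEFAULT_CONDITIONS = (NAIVE, LPS, BCG_DK, BCG_BG)

#: Conditions treated as BCG exposures: gene-set editing boosts apply here.
BCG_CONDITIONS = frozenset({BCG_DK, BCG_BG})


def _default_condition_effect() -> dict[str, float]:
    return {NAIVE: 0.0, LPS: 0.15, BCG_DK: 0.4, BCG_BG: 0.4}


def _default_geneset_fractions() -> dict[str, float]:
    return {"ex_vivo": 0.10, "in_vivo_dmp": 0.10, "in_vivo_dmr": 0.05}


def _default_dmr_plan() -> list[tuple[str, int, int, float]]:
    return [
        ("chr1", 1_000_000, 10, 0.10),
        ("chr2", 3_000_000, 6, -0.08),
        ("chr3", 5_000_000, 4, 0.07),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Editing-rate truth is planted on the logit scale (matching the binomial
    GLMs used downstream): the per-site editing probability for sample *s*
    is ``logistic(base_site + donor_s + condition_s + geneset_boost)``,
    where the gene-set boost applies only in BCG conditions for genes that
    belong to the boosted set.
    """

    seed: int = 0
    n_donors: int = 5
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    # --- editing-site arm ---
    n_sites: int = 2000
    n_genes: int = 1500
    coverage_mean: float = 30.0
    #: negative-binomial size k; Var = mu + mu^2/k.
    coverage_dispersion: float = 10.0
    base_edit_logit_mean: float = -2.2
    base_edit_logit_sd: float = 0.8
    donor_effect_sd: float = 0.15
    condition_edit_effect: dict[str, float] = field(default_factory=_default_condition_effect)
    #: extra logits added in BCG conditions for genes in the named set.
    geneset_edit_boost: dict[str, float] = field(default_factory=dict)
    geneset_fractions: dict[str, float] = field(default_factory=_default_geneset_fractions)
    frac_in_catalog: float = 0.9
    frac_common_snp: float = 0.02
    #: fraction of sites emitted as non-A>G decoy mismatches.
    decoy_fraction: float = 0.05
    #: per-site probability of each upstream positional artifact flag.
    flag_rate: float = 0.02
    #: fraction of records whose caller statistic falls below 1.56.
    test_stat_fail_rate: float = 0.05
    # --- expression arm ---
    induced_fraction: float = 0.2
    trained_fraction: float = 0.16
    attenuated_fraction: float = 0.08
    base_expression_mean_log2: float = 4.0
    base_expression_sd_log2: float = 1.5
    induced_log2fc: float = 3.0
    training_log2fc: float = 2.0
    expression_noise_sd: float = 0.1
    # --- promoter motif arm ---
    n_motifs: int = 20
    planted_motif: str = "ISRE"
    motif_background_rate: float = 0.10
    planted_motif_rate: float = 0.60
    planted_top_n: int = 60
    # --- methylation arm ---
    n_probes: int = 2000
    n_per_group: int = 60
    beta_noise_sd: float = 0.02
    background_probe_spacing: float = 5000.0
    dmr_probe_spacing: int = 200
    #: list of (chrom, start, n_probes, delta_beta) planted DMRs.
    dmr_plan: list[tuple[str, int, int, float]] = field(default_factory=_default_dmr_plan)

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if self.n_donors < 2:
            raise ConfigurationError("n_donors must be >= 2")
        if len(self.conditions) < 2 or NAIVE not in self.conditions:
            raise ConfigurationError("conditions must contain NAIVE and at least one other condition")
        for name in (
            "frac_in_catalog",
            "frac_common_snp",
            "decoy_fraction",
            "flag_rate",
            "test_stat_fail_rate",
            "induced_fraction",
            "trained_fraction",
            "attenuated_fraction",
            "motif_background_rate",
            "planted_motif_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.trained_fraction + self.attenuated_fraction > 1.0:
            raise ConfigurationError("trained_fraction + attenuated_fraction must be <= 1")
        for name in ("n_sites", "n_genes", "n_motifs", "n_probes", "n_per_group", "planted_top_n"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("coverage_mean", "coverage_dispersion", "base_edit_logit_sd", "beta_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        unknown = set(self.condition_edit_effect) - set(self.conditions)
        if unknown:
            raise ConfigurationError(f"condition_edit_effect names unknown conditions: {sorted(unknown)}")
        self._check_dmr_plan()

    def _check_dmr_plan(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, n_probes, _delta in self.dmr_plan:
            if n_probes < 1:
                raise ConfigurationError("dmr_plan entries must plant at least one probe")
            end = start + (n_probes - 1) * self.dmr_probe_spacing
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ConfigurationError(f"dmr_plan intervals overlap on {chrom}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"D{d + 1}_{c}" for d in range(self.n_donors) for c in self.conditions]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        data = dict(data)
        if "dmr_plan" in data:
            data["dmr_plan"] = [tuple(entry) for entry in data["dmr_plan"]]
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset; every id here exists in the tables."""

    #: site_id -> baseline editing logit (SNP and decoy sites excluded).
    site_base_logit: dict[str, float] = field(default_factory=dict)
    donor_effects: dict[str, float] = field(default_factory=dict)
    condition_effects: dict[str, float] = field(default_factory=dict)
    snp_site_ids: list[str] = field(default_factory=list)
    catalog_site_ids: list[str] = field(default_factory=list)
    decoy_site_ids: list[str] = field(default_factory=list)
    flagged_site_ids: list[str] = field(default_factory=list)
    #: set label -> member gene ids (editing gene sets).
    genesets: dict[str, list[str]] = field(default_factory=dict)
    site_gene: dict[str, str] = field(default_factory=dict)
    induced_genes: list[str] = field(default_factory=list)
    #: gene_id -> TRAINED / UNAFFECTED / ATTENUATED for induced genes.
    gene_class: dict[str, str] = field(default_factory=dict)
    #: gene_id -> planted training log2 offset.
    training_score: dict[str, float] = field(default_factory=dict)
    planted_motif_genes: list[str] = field(default_factory=list)
    planted_motif: str | None = None
    #: planted DMRs: chrom, start, end, delta_beta, probe_ids.
    dmr_intervals: list[dict[str, Any]] = field(default_factory=list)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        merged = GroundTruth()
        for f in dataclasses.fields(GroundTruth):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, dict):
                setattr(merged, f.name, {**a, **b})
            elif isinstance(a, list):
                setattr(merged, f.name, list(a) + [x for x in b if x not in a])
            else:
                setattr(merged, f.name, b if b is not None else a)
        return merged

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))
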