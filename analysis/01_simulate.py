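"""Generate the full synthetic study: 5 donors x 4 exposures, all assay arms.

Writes every pipeline input (allele counts, metadata, catalogs, expression,
motif hits, methylation betas, islands) plus the planted ground truth under
results/sim/.
"""

from pathlib import Path

from trimedit.config import SimulationConfig
from trimedit.simulate import simulate_all, write_dataset

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    config = SimulationConfig(seed=0, geneset_edit_boost={"ex_vivo": 0.3})
    data = simulate_all(config)
    write_dataset(data, OUTDIR)
    truth = data["truth"]
    print(f"wrote {len(data['sites'])} site records ({config.n_sites} sites x {len(data['samples'])} samples)")
    print(f"planted: {len(truth.snp_site_ids)} common SNPs, {len(truth.decoy_site_ids)} non-A>G decoys")
    print(f"gene sets: " + ", ".join(f"{k}={len(v)}" for k, v in truth.genesets.items()))
    print(f"expression: {len(truth.induced_genes)} induced genes "
          f"({sum(c == 'TRAINED' for c in truth.gene_class.values())} trained, "
          f"{sum(c == 'ATTENUATED' for c in truth.gene_class.values())} attenuated)")
    print(f"methylation: {len(truth.dmr_intervals)} planted DMRs over {len(data['probes'])} probes")


if __name__ == "__main__":
    main()
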