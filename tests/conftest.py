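import numpy as np
import pandas as pd
import pytest

from trimedit.config import SimulationConfig
from trimedit.sites import FilterParams


@pytest.fixture
def small_config():
    """Scaled-down study design used for fast per-module checks."""
    return SimulationConfig(seed=7, n_sites=300, n_genes=120, n_probes=400, n_per_group=20)


@pytest.fixture
def default_params():
    return FilterParams()


def random_record_table(rng: np.random.Generator, n_sites: int, n_samples: int) -> pd.DataFrame:
    """Random editing-site record table covering every filter predicate."""
    rows = []
    for i in range(n_sites):
        strand = "+" if rng.random() < 0.5 else "-"
        ref, alt = ("A", "G") if rng.random() < 0.8 else ("C", "T")
        in_catalog = rng.random() < 0.7
        is_snp = rng.random() < 0.1
        flags = rng.random(3) < 0.1
        for s in range(n_samples):
            total = int(rng.integers(0, 40))
            alt_n = int(rng.binomial(total, 0.25))
            rows.append(
                {
                    "chrom": f"chr{1 + i % 3}",
                    "pos": 1000 + i,
                    "strand": strand,
                    "ref_base": ref,
                    "alt_base": alt,
                    "sample_id": f"S{s}",
                    "ref_count": total - alt_n,
                    "alt_count": alt_n,
                    "test_stat": float(rng.uniform(0, 6)),
                    "flag_read_end": bool(flags[0]),
                    "flag_indel_splice": bool(flags[1]),
                    "flag_homopolymer": bool(flags[2]),
                    "in_catalog": in_catalog,
                    "is_common_snp": is_snp,
                }
            )
    return pd.DataFrame(rows)
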