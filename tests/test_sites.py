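"""Filter-cascade correctness: hand examples, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest

from trimedit.config import SimulationConfig
from trimedit.errors import InputError
from trimedit.simulate import generate_editing_dataset
from trimedit.sites import (
    FilterParams,
    SiteStatus,
    annotate_catalog,
    apply_site_filters,
    classify_site_status,
    classify_status,
    count_recurrent_sites,
    site_ids,
)
from conftest import random_record_table


def _record(chrom, pos, sample, ref_n, alt_n, *, strand="+", ref="A", alt="G", stat=5.0,
            flags=(False, False, False), catalog=True, snp=False):
    return {
        "chrom": chrom, "pos": pos, "strand": strand, "ref_base": ref, "alt_base": alt,
        "sample_id": sample, "ref_count": ref_n, "alt_count": alt_n, "test_stat": stat,
        "flag_read_end": flags[0], "flag_indel_splice": flags[1], "flag_homopolymer": flags[2],
        "in_catalog": catalog, "is_common_snp": snp,
    }


def brute_force_retained(records: pd.DataFrame, params: FilterParams) -> set:
    """Predicate-conjunction oracle, evaluated row by row."""
    detections = {}
    for r in records.itertuples():
        ok = (
            r.test_stat >= params.min_test_stat
            and r.ref_count + r.alt_count >= params.min_total_coverage
            and r.alt_count >= params.min_alt_depth
            and not (r.flag_read_end or r.flag_indel_splice or r.flag_homopolymer)
            and not r.is_common_snp
            and (not params.ag_only or (r.ref_base == "A" and r.alt_base == "G"))
        )
        key = (r.chrom, r.pos, r.strand)
        detections[key] = detections.get(key, 0) + int(ok)
    sites = {k for k, v in detections.items() if v >= params.min_samples_edited}
    if params.require_catalog:
        cat = {
            (r.chrom, r.pos, r.strand) for r in records.itertuples() if r.in_catalog
        }
        sites &= cat
    return sites


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "ref_n,alt_n,expected",
        [
            (9, 3, SiteStatus.EDITED),       # total 12 >= 10, alt 3 >= 3
            (10, 0, SiteStatus.UNEDITED),
            (5, 4, SiteStatus.INSUFFICIENT_COVERAGE),  # total 9 < 10
            (7, 3, SiteStatus.EDITED),       # both thresholds exactly met
            (8, 2, SiteStatus.UNEDITED),
        ],
    )
    def test_boundaries(self, ref_n, alt_n, expected):
        assert classify_site_status(ref_n, alt_n) is expected

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"ref_count": rng.integers(0, 20, 200), "alt_count": rng.integers(0, 8, 200)})
        vec = classify_status(df)
        for i in df.index:
            assert vec[i] == classify_site_status(df.loc[i, "ref_count"], df.loc[i, "alt_count"]).value


class TestApplySiteFilters:
    def test_hand_built_table_retains_only_catalogued_recurrent_site(self):
        """Six sites, four samples: s1 and s3 pass per-record predicates in >=3
        samples but s3 is absent from the catalog, so only s1 survives."""
        samples = ["S1", "S2", "S3", "S4"]
        rows = []
        for s in samples[:3]:
            rows.append(_record("chr1", 100, s, 10, 5))                     # s1: 3 detections
        rows.append(_record("chr1", 100, "S4", 10, 1))
        for s in samples[:2]:
            rows.append(_record("chr1", 200, s, 10, 5))                     # s2: only 2 detections
        rows += [_record("chr1", 200, s, 10, 1) for s in samples[2:]]
        for s in samples[:3]:
            rows.append(_record("chr1", 300, s, 10, 5, catalog=False))      # s3: not catalogued
        rows.append(_record("chr1", 300, "S4", 10, 1, catalog=False))
        for s in samples:
            rows.append(_record("chr1", 400, s, 10, 5, flags=(False, False, True)))  # s4: flagged
        for s in samples:
            rows.append(_record("chr1", 500, s, 10, 10, snp=True))          # s5: common SNP
        for s in samples:
            rows.append(_record("chr1", 600, s, 10, 5, ref="C", alt="T"))   # s6: not A>G
        result = apply_site_filters(pd.DataFrame(rows), FilterParams())
        assert result.retained_sites[["chrom", "pos"]].to_records(index=False).tolist() == [("chr1", 100)]

    def test_alt_depth_attrition_attribution(self):
        rows = [_record("chr1", 100, f"S{i}", 20, 2) for i in range(4)]
        result = apply_site_filters(pd.DataFrame(rows), FilterParams())
        assert len(result.retained_sites) == 0
        att = result.attrition.set_index("stage")["n_removed"]
        assert att["alt_depth"] == 4
        assert att[["test_stat", "coverage", "positional_flags", "snp", "ag"]].sum() == 0

    def test_vacuous_filter_retains_every_site(self):
        rng = np.random.default_rng(1)
        records = random_record_table(rng, 40, 4)
        params = FilterParams(
            min_test_stat=0, min_total_coverage=0, min_alt_depth=0,
            min_samples_edited=0, require_catalog=False, ag_only=False,
        )
        result = apply_site_filters(records, params)
        assert len(result.retained_sites) == records[["chrom", "pos", "strand"]].drop_duplicates().shape[0]

    def test_duplicate_record_raises(self):
        rows = [_record("chr1", 100, "S1", 10, 5)] * 2
        with pytest.raises(InputError, match="duplicate"):
            apply_site_filters(pd.DataFrame(rows))

    def test_unknown_strand_raises(self):
        rows = [_record("chr1", 100, "S1", 10, 5, strand="?")]
        with pytest.raises(InputError, match="strand"):
            apply_site_filters(pd.DataFrame(rows))

    def test_cascade_equals_brute_force_conjunction(self):
        """Oracle equivalence over random tables with random thresholds."""
        rng = np.random.default_rng(42)
        for rep in range(25):
            records = random_record_table(rng, int(rng.integers(5, 60)), int(rng.integers(2, 6)))
            params = FilterParams(
                min_test_stat=float(rng.uniform(0, 3)),
                min_total_coverage=int(rng.integers(0, 15)),
                min_alt_depth=int(rng.integers(0, 5)),
                min_samples_edited=int(rng.integers(1, 4)),
                require_catalog=bool(rng.random() < 0.5),
                ag_only=bool(rng.random() < 0.5),
            )
            got = set(map(tuple, apply_site_filters(records, params).retained_sites.to_records(index=False)))
            assert got == brute_force_retained(records, params)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        records = random_record_table(rng, 50, 4)
        first = apply_site_filters(records, FilterParams())
        second = apply_site_filters(first.records, FilterParams())
        pd.testing.assert_frame_equal(first.retained_sites, second.retained_sites)

    @pytest.mark.parametrize(
        "relaxed",
        [
            {"min_test_stat": 0.5},
            {"min_total_coverage": 5},
            {"min_alt_depth": 1},
            {"min_samples_edited": 1},
            {"require_catalog": False},
            {"ag_only": False},
        ],
    )
    def test_relaxing_a_threshold_never_shrinks_the_retained_set(self, relaxed):
        rng = np.random.default_rng(4)
        records = random_record_table(rng, 60, 4)
        strict = apply_site_filters(records, FilterParams())
        loose = apply_site_filters(records, FilterParams(**relaxed))
        strict_set = set(map(tuple, strict.retained_sites.to_records(index=False)))
        loose_set = set(map(tuple, loose.retained_sites.to_records(index=False)))
        assert strict_set <= loose_set

    def test_planted_common_snps_are_always_removed(self):
        data = generate_editing_dataset(SimulationConfig(seed=6, n_sites=300, frac_common_snp=0.1))
        records = annotate_catalog(data.sites, data.catalog, data.snps)
        result = apply_site_filters(records, FilterParams())
        retained = set(site_ids(result.retained_sites))
        assert not retained & set(data.truth.snp_site_ids)


class TestCountRecurrentSites:
    def _table(self, edited_per_site):
        rows = []
        for site, n_edited in edited_per_site.items():
            for s in range(4):
                alt = 5 if s < n_edited else 0
                rows.append(_record("chr1", site, f"S{s}", 10, alt))
        return pd.DataFrame(rows)

    def test_enumeration_example(self):
        table = self._table({100: 4, 200: 3, 300: 1})
        assert count_recurrent_sites(table, k=3) == (2, 1)

    def test_empty_table(self):
        assert count_recurrent_sites(pd.DataFrame()) == (0, 0)

    def test_all_edited_everywhere(self):
        table = self._table({100: 4, 200: 4})
        assert count_recurrent_sites(table, k=3) == (2, 2)
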