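"""Gene summation, binomial-GLM oracle agreement, BH, and background adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trimedit.diffedit import (
    background_adjust,
    benjamini_hochberg,
    sum_gene_alleles,
    test_gene_editing as run_gene_tests,
    test_geneset_editing as run_geneset_test,
)
from trimedit.errors import DesignError, InputError


def _gene_map(mapping):
    return pd.DataFrame(
        [{"chrom": "chr1", "pos": pos, "strand": "+", "gene_id": g} for pos, g in mapping.items()]
    )


def _site_records(counts_by_pos, sample="S1"):
    return pd.DataFrame(
        [
            {"chrom": "chr1", "pos": pos, "strand": "+", "sample_id": sample,
             "ref_count": r, "alt_count": a}
            for pos, (r, a) in counts_by_pos.items()
        ]
    )


class TestSumGeneAlleles:
    def test_hand_summation(self):
        records = _site_records({100: (8, 2), 101: (5, 5)})
        table, _ = sum_gene_alleles(records, _gene_map({100: "gA", 101: "gA"}))
        row = table.iloc[0]
        assert (row["sum_ref"], row["sum_alt"], row["n_sites_covered"]) == (13, 7, 2)

    def test_unmapped_sites_are_dropped_and_counted(self):
        records = _site_records({100: (8, 2), 999: (5, 5)})
        result = sum_gene_alleles(records, _gene_map({100: "gA"}))
        assert result.n_dropped_records == 1
        assert set(result.table["gene_id"]) == {"gA"}

    def test_zero_coverage_rows_are_not_emitted(self):
        records = _site_records({100: (0, 0)})
        table, _ = sum_gene_alleles(records, _gene_map({100: "gA"}))
        assert table.empty

    def test_multi_gene_site_raises_or_takes_first(self):
        records = _site_records({100: (8, 2)})
        gmap = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 100, "strand": "+", "gene_id": "gB"},
                {"chrom": "chr1", "pos": 100, "strand": "+", "gene_id": "gA"},
            ]
        )
        with pytest.raises(InputError, match="multiple genes"):
            sum_gene_alleles(records, gmap)
        table, _ = sum_gene_alleles(records, gmap, multi_gene="first")
        assert set(table["gene_id"]) == {"gA"}

    def test_conservation_of_total_alleles(self):
        rng = np.random.default_rng(0)
        positions = list(range(100, 140))
        gmap = _gene_map({p: f"g{p % 7}" for p in positions[:30]})  # 10 sites unmapped
        frames = [
            _site_records({p: (int(r), int(a)) for p, (r, a) in zip(positions, rng.integers(0, 30, (40, 2)))}, sample=s)
            for s in ("S1", "S2", "S3")
        ]
        records = pd.concat(frames, ignore_index=True)
        table, dropped = sum_gene_alleles(records, gmap)
        total_in = (records["ref_count"] + records["alt_count"]).sum()
        mapped_total = (table["sum_ref"] + table["sum_alt"]).sum()
        unmapped_total = records[records["pos"].isin(positions[30:])][["ref_count", "alt_count"]].to_numpy().sum()
        assert mapped_total + unmapped_total == total_in
        assert dropped == 3 * 10


def _meta(n_donors=2, conditions=("NAIVE", "BCG_DK")):
    return pd.DataFrame(
        [
            {"sample_id": f"D{d}_{c}", "donor_id": f"D{d}", "condition": c}
            for d in range(n_donors)
            for c in conditions
        ]
    )


def _random_gene_table(rng, genes, meta, cond_effect=0.0):
    rows = []
    for g in genes:
        base = rng.normal(-2.0, 0.5)
        for r in meta.itertuples():
            shift = cond_effect if r.condition != "NAIVE" else 0.0
            p = 1 / (1 + np.exp(-(base + shift)))
            n = int(rng.integers(50, 400))
            alt = int(rng.binomial(n, p))
            rows.append({"gene_id": g, "sample_id": r.sample_id, "sum_ref": n - alt, "sum_alt": alt,
                         "n_sites_covered": 1})
    return pd.DataFrame(rows)


def newton_binomial_mle(X, alt, ref, tol=1e-12):
    """Independent Newton-Raphson maximiser of the binomial log-likelihood."""
    beta = np.zeros(X.shape[1])
    n = alt + ref
    for _ in range(100):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        grad = X.T @ (alt - n * p)
        H = X.T @ (X * (n * p * (1 - p))[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestBinomialGlm:
    def test_matches_newton_oracle_on_small_designs(self):
        """IRLS coefficients equal an independent Newton ML solve to 1e-6."""
        rng = np.random.default_rng(21)
        for rep in range(25):
            n_genes = int(rng.integers(1, 4))
            meta = _meta(n_donors=2)
            genes = [f"g{i}" for i in range(n_genes)]
            table = _random_gene_table(rng, genes, meta, cond_effect=float(rng.normal(0, 0.3)))
            result = run_geneset_test(table, genes, meta, gene_effects=True)

            # independent design construction mirroring reference coding
            merged = table.merge(meta, on="sample_id")
            cols = [np.ones(len(merged))]
            names = ["const"]
            cols.append((merged["condition"] == "BCG_DK").to_numpy(float))
            names.append("cond_BCG_DK")
            donors = sorted(meta["donor_id"].unique())[1:]
            for d in donors:
                cols.append((merged["donor_id"] == d).to_numpy(float))
                names.append(f"donor_{d}")
            for g in sorted(set(genes))[1:]:
                cols.append((merged["gene_id"] == g).to_numpy(float))
                names.append(f"gene_{g}")
            X = np.column_stack(cols)
            beta = newton_binomial_mle(X, merged["sum_alt"].to_numpy(float), merged["sum_ref"].to_numpy(float))
            assert result.contrasts["BCG_DK"][0] == pytest.approx(beta[names.index("cond_BCG_DK")], abs=1e-6)

    def test_single_gene_set_equals_per_gene_test(self):
        rng = np.random.default_rng(22)
        meta = _meta(n_donors=3, conditions=("NAIVE", "LPS", "BCG_DK"))
        table = _random_gene_table(rng, ["gX"], meta, cond_effect=0.4)
        set_result = run_geneset_test(table, ["gX"], meta)
        gene_results, _ = run_gene_tests(table, meta, min_samples_covered=1)
        for cond in ("LPS", "BCG_DK"):
            row = gene_results[(gene_results["gene_id"] == "gX") & (gene_results["condition"] == cond)]
            assert set_result.contrasts[cond][0] == pytest.approx(float(row["estimate"].iloc[0]), abs=1e-10)
            assert set_result.contrasts[cond][2] == pytest.approx(float(row["p"].iloc[0]), abs=1e-10)

    def test_empty_set_intersection_raises(self):
        rng = np.random.default_rng(23)
        meta = _meta()
        table = _random_gene_table(rng, ["gA"], meta)
        with pytest.raises(InputError, match="no genes"):
            run_geneset_test(table, ["gZ"], meta)

    def test_undercovered_gene_is_skipped_not_tested(self):
        rng = np.random.default_rng(24)
        meta = _meta(n_donors=3, conditions=("NAIVE", "BCG_DK"))  # 6 samples
        table = _random_gene_table(rng, ["gA", "gB"], meta)
        table = table[~((table["gene_id"] == "gB") & (table["sample_id"] == "D0_NAIVE"))]
        results, skipped = run_gene_tests(table, meta, min_samples_covered=6)
        assert set(results["gene_id"]) == {"gA"}
        assert skipped["gene_id"].tolist() == ["gB"]
        assert "5 < 6" in skipped["reason"].iloc[0]


def brute_force_bh(p):
    """Textbook step-up q-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBenjaminiHochberg:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_textbook_step_up(self, pvals):
        got = benjamini_hochberg(np.array(pvals))
        expected = brute_force_bh(pvals)
        assert np.allclose(got, expected, atol=1e-12)

    def test_q_dominates_p_and_is_monotone_in_ranked_order(self):
        rng = np.random.default_rng(25)
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestBackgroundAdjust:
    def test_set_equal_to_background_is_degenerate(self):
        rng = np.random.default_rng(26)
        meta = _meta()
        table = _random_gene_table(rng, ["gA", "gB"], meta)
        with pytest.raises(DesignError, match="degenerate"):
            background_adjust(table, ["gA", "gB"], meta)

    def test_empty_intersection_raises(self):
        rng = np.random.default_rng(27)
        meta = _meta()
        table = _random_gene_table(rng, ["gA", "gB"], meta)
        with pytest.raises(InputError):
            background_adjust(table, ["gZ"], meta, background=["gA", "gB"])

    def test_null_set_interaction_is_near_zero(self):
        """Set identical to background in truth: interaction within 2 SE of 0."""
        rng = np.random.default_rng(28)
        meta = _meta(n_donors=4, conditions=("NAIVE", "BCG_DK"))
        table = _random_gene_table(rng, [f"g{i}" for i in range(12)], meta, cond_effect=0.2)
        result = background_adjust(table, [f"g{i}" for i in range(4)], meta)
        est, se, _p = result.contrasts["BCG_DK"]
        assert abs(est) < 2.5 * se
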