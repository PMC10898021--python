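"""Score engine: LD, clumping, region exclusion, scoring, adjLD, z-scores."""

import numpy as np
import pandas as pd
import pytest

from prspipe.errors import DegenerateDataError
from prspipe.io_genotype import SummaryStats
from prspipe.prs import (
    APOE_CENTER_BP,
    ClumpParams,
    ExclusionRegion,
    adjust_ld,
    clump,
    compute_prs,
    exclude_region,
    ld_r2,
    standardize,
)

from conftest import make_genotypes, make_sumstats


def clump_oracle(stats, g, params):
    """Brute-force re-derivation of the greedy clumping rule.

    Independently re-implements: visit SNPs by ascending (p, pos); an
    unclaimed SNP is an index; it claims unclaimed non-index SNPs within
    the window with r² above the cutoff.  Indices with p ≤ p_max are
    returned in (chrom, pos) order.
    """
    t = stats.table
    rows = list(t.itertuples())
    order = sorted(range(len(rows)), key=lambda i: (rows[i].pvalue, rows[i].pos))
    claimed, indices = set(), []
    gid = {s: i for i, s in enumerate(g.variants["snp_id"])}
    for i in order:
        if i in claimed:
            continue
        indices.append(i)
        for j in range(len(rows)):
            if j == i or j in claimed or j in indices:
                continue
            if rows[j].chrom != rows[i].chrom:
                continue
            if abs(rows[j].pos - rows[i].pos) > params.window_kb * 1000:
                continue
            try:
                r2 = ld_r2(g, gid[rows[i].snp_id], gid[rows[j].snp_id])
            except DegenerateDataError:
                continue
            if r2 > params.r2_max:
                claimed.add(j)
    kept = [i for i in indices if rows[i].pvalue <= params.p_max]
    kept.sort(key=lambda i: (rows[i].chrom, rows[i].pos))
    return [rows[i].snp_id for i in kept]


class TestLdR2:
    def test_identical_vectors(self):
        g = make_genotypes(np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=float))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        g = make_genotypes(np.array([[0, 2], [1, 1], [2, 0]], dtype=float))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self, rng):
        d = rng.binomial(2, 0.4, size=(10000, 2)).astype(float)
        g = make_genotypes(d)
        assert ld_r2(g, 0, 1) < 0.01

    def test_monomorphic_raises(self):
        g = make_genotypes(np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(DegenerateDataError):
            ld_r2(g, 0, 1)


class TestClump:
    def test_single_block_keeps_top_hit(self):
        base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=float)
        d = np.column_stack([base, base, base])  # pairwise r² = 1
        g = make_genotypes(d, pos=[1000, 2000, 3000])
        ss = make_sumstats(["snp0", "snp1", "snp2"], [0.1] * 3,
                           [1e-8, 1e-6, 1e-4], pos=[1000, 2000, 3000])
        assert clump(ss, g) == ["snp0"]

    def test_outside_window_both_retained(self):
        base = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        g = make_genotypes(np.column_stack([base, base]), pos=[1000, 301_000])
        ss = make_sumstats(["snp0", "snp1"], [0.1, 0.1], [1e-8, 1e-6],
                           pos=[1000, 301_000])
        assert clump(ss, g, ClumpParams(window_kb=250)) == ["snp0", "snp1"]

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        """200 random ≤60-SNP instances agree with the exhaustive
        rule-checking oracle."""
        for rep in range(200):
            m = int(rng.integers(2, 61))
            n = 60
            n_chrom = int(rng.integers(1, 4))
            chrom = sorted(rng.integers(1, n_chrom + 1, size=m).astype(str))
            pos = np.sort(rng.integers(1, 500_000, size=m))
            # correlated batches: copy a base vector with noise
            d = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
            for j in range(1, m):
                if rng.random() < 0.4:
                    flip = rng.random(n) < 0.15
                    d[:, j] = np.where(flip, rng.integers(0, 3, n), d[:, j - 1])
            g = make_genotypes(d, chrom=list(chrom), pos=pos.tolist())
            ss = make_sumstats([f"snp{j}" for j in range(m)],
                               rng.normal(0, 0.1, m).tolist(),
                               rng.uniform(1e-9, 1, m).tolist(),
                               chrom=list(chrom), pos=pos.tolist())
            params = ClumpParams(
                window_kb=int(rng.integers(10, 200)),
                r2_max=float(rng.uniform(0.05, 0.9)),
                p_max=float(rng.choice([0.5, 1.0])),
            )
            assert clump(ss, g, params) == clump_oracle(ss, g, params), f"rep {rep}"

    def test_empty_stats_empty_result(self):
        g = make_genotypes(np.ones((2, 1)))
        ss = SummaryStats(pd.DataFrame(columns=SummaryStats.REQUIRED))
        assert clump(ss, g) == []


class TestExcludeRegion:
    def test_boundary_inclusive(self):
        region = ExclusionRegion("19", APOE_CENTER_BP, 500_000)
        ss = make_sumstats(
            ["at_edge", "past_edge", "other_chrom"],
            [0.1] * 3, [0.5] * 3,
            chrom=["19", "19", "18"],
            pos=[APOE_CENTER_BP + 500_000, APOE_CENTER_BP + 500_001, APOE_CENTER_BP],
        )
        out = exclude_region(ss, region)
        assert out.table["snp_id"].tolist() == ["past_edge", "other_chrom"]

    def test_whole_chromosome_mode(self):
        ss = make_sumstats(["a", "b"], [0.1, 0.1], [0.5, 0.5],
                           chrom=["19", "3"], pos=[1, 1])
        out = exclude_region(ss, ExclusionRegion("19", 1, None))
        assert out.table["snp_id"].tolist() == ["b"]


class TestComputePrs:
    def test_all_zero_dosage_gives_zero_scores(self):
        g = make_genotypes(np.zeros((3, 2)))
        ss = make_sumstats(["snp0", "snp1"], [0.5, -0.3], [0.01, 0.02])
        np.testing.assert_array_equal(
            compute_prs(g, ss, ["snp0", "snp1"]).scores.to_numpy(), 0.0
        )

    def test_single_snp_closed_form(self):
        g = make_genotypes(np.array([[2.0]]))
        ss = make_sumstats(["snp0"], [0.5], [0.01])
        assert compute_prs(g, ss, ["snp0"]).scores.iloc[0] == pytest.approx(1.0)

    def test_matches_spreadsheet_oracle(self):
        """5 samples × 4 SNPs: scores equal hand-computed weighted sums."""
        d = np.array(
            [[0, 1, 2, 0], [1, 1, 0, 2], [2, 0, 1, 1], [0, 2, 2, 2], [1, 0, 0, 0]],
            dtype=float,
        )
        beta = [0.2, -0.5, 0.1, 0.4]
        g = make_genotypes(d)
        ss = make_sumstats([f"snp{j}" for j in range(4)], beta, [0.01] * 4)
        got = compute_prs(g, ss, [f"snp{j}" for j in range(4)]).scores.to_numpy()
        want = d @ np.array(beta) / 4.0
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_thresholding_controls_m(self):
        g = make_genotypes(np.ones((2, 3)), snp_ids=["a", "b", "c"])
        ss = make_sumstats(["a", "b", "c"], [0.1, 0.2, 0.3], [1e-6, 1e-3, 0.5],
                           pos=[1000, 2000, 3000])
        p = compute_prs(g, ss, ["a", "b", "c"], p_threshold=1e-3)
        assert p.m == 2 and p.snp_ids == ["a", "b"]

    def test_missing_imputed_as_mean_dosage(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        g = make_genotypes(d)
        ss = make_sumstats(["snp0"], [1.0], [0.01])
        scores = compute_prs(g, ss, ["snp0"]).scores
        assert scores.iloc[2] == pytest.approx(1.0)  # mean dosage of 0 and 2

    def test_empty_after_threshold_raises(self):
        g = make_genotypes(np.ones((2, 1)))
        ss = make_sumstats(["snp0"], [0.1], [0.5])
        with pytest.raises(DegenerateDataError):
            compute_prs(g, ss, ["snp0"], p_threshold=1e-8)

    def test_linearity_over_snp_subsets(self, rng):
        """M-weighted recombination of per-subset scores equals the
        merged-set score (algebraic identity)."""
        d = rng.binomial(2, 0.4, size=(8, 10)).astype(float)
        beta = rng.normal(0, 0.2, 10)
        ids = [f"snp{j}" for j in range(10)]
        g = make_genotypes(d)
        ss = make_sumstats(ids, beta.tolist(), [0.01] * 10)
        full = compute_prs(g, ss, ids).scores.to_numpy()
        a = compute_prs(g, ss, ids[:4]).scores.to_numpy()
        b = compute_prs(g, ss, ids[4:]).scores.to_numpy()
        np.testing.assert_allclose(full, (4 * a + 6 * b) / 10, atol=1e-12)

    def test_region_exclusion_equals_zeroed_betas_up_to_rescale(self, rng):
        """Scoring the noAPOE set equals scoring the full set with APOE-region
        betas zeroed, after undoing the 1/M rescaling."""
        m = 6
        chrom = ["19", "19", "1", "1", "2", "2"]
        pos = [APOE_CENTER_BP, APOE_CENTER_BP + 1000, 500, 1500, 500, 1500]
        d = rng.binomial(2, 0.4, size=(10, m)).astype(float)
        beta = rng.normal(0, 0.3, m)
        ids = [f"snp{j}" for j in range(m)]
        g = make_genotypes(d, chrom=chrom, pos=pos)
        ss = make_sumstats(ids, beta.tolist(), [0.01] * m, chrom=chrom, pos=pos)
        ss_no = exclude_region(ss, ExclusionRegion())
        kept = ss_no.table["snp_id"].tolist()
        direct = compute_prs(g, ss, kept).scores.to_numpy()
        zeroed = beta.copy()
        zeroed[:2] = 0.0
        ss_zero = make_sumstats(ids, zeroed.tolist(), [0.01] * m, chrom=chrom, pos=pos)
        via_zero = compute_prs(g, ss_zero, ids).scores.to_numpy()
        np.testing.assert_allclose(direct * len(kept), via_zero * m, atol=1e-12)


class TestAdjustLd:
    def _stats(self, ids, pvals, pos, chrom=None):
        return make_sumstats(ids, [0.1] * len(ids), pvals,
                             chrom=chrom or ["1"] * len(ids), pos=pos)

    def test_adjacent_pair_keeps_lower_p(self):
        ss = self._stats(["A", "B"], [1e-7, 1e-6], [1000, 2000])
        ld = pd.DataFrame({"snp_a": ["A"], "snp_b": ["B"], "r2": [0.6]})
        assert adjust_ld(["A", "B"], ss, ld_table=ld) == ["A"]

    def test_intervening_snp_joins_block(self):
        """A–C linked with r²=0.7, B between them: one block {A,B,C},
        its minimum-p member survives."""
        ss = self._stats(["A", "B", "C"], [1e-5, 1e-8, 1e-6], [1000, 2000, 3000])
        ld = pd.DataFrame({"snp_a": ["A"], "snp_b": ["C"], "r2": [0.7]})
        assert adjust_ld(["A", "B", "C"], ss, ld_table=ld) == ["B"]

    def test_low_ld_pairs_all_retained(self):
        ss = self._stats(["A", "B"], [1e-7, 1e-6], [1000, 2000])
        ld = pd.DataFrame({"snp_a": ["A"], "snp_b": ["B"], "r2": [0.4]})
        assert adjust_ld(["A", "B"], ss, ld_table=ld) == ["A", "B"]

    def test_structural_131_to_113(self, rng):
        """131 retained SNPs with 18 in r²>0.5 pairs collapse to 113."""
        n_pairs = 18
        ids, pos, rows = [], [], []
        p = 1
        for k in range(n_pairs):  # 18 high-LD pairs -> 18 SNPs removed
            a, b = f"pair{k}_a", f"pair{k}_b"
            ids += [a, b]
            pos += [p * 10_000, p * 10_000 + 100]
            rows.append({"snp_a": a, "snp_b": b, "r2": 0.8})
            p += 1
        for k in range(131 - 2 * n_pairs):
            ids.append(f"solo{k}")
            pos.append(p * 10_000)
            p += 1
        ss = self._stats(ids, rng.uniform(1e-8, 1e-5, len(ids)).tolist(), pos)
        ld = pd.DataFrame(rows)
        kept = adjust_ld(ids, ss, ld_table=ld)
        assert len(ids) == 131 and len(kept) == 113

    def test_order_invariance_within_blocks(self, rng):
        ids = ["A", "B", "C", "D", "E"]
        pos = [1000, 2000, 3000, 50_000, 60_000]
        pv = [1e-4, 1e-6, 1e-5, 1e-3, 1e-7]
        ss = self._stats(ids, pv, pos)
        ld = pd.DataFrame(
            {"snp_a": ["A", "B", "D"], "snp_b": ["B", "C", "E"], "r2": [0.6, 0.9, 0.55]}
        )
        base = adjust_ld(ids, ss, ld_table=ld)
        for _ in range(5):
            perm = list(rng.permutation(ids))
            assert adjust_ld(perm, ss, ld_table=ld) == base

    def test_cohort_ld_fallback(self):
        base = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        g = make_genotypes(np.column_stack([base, base]), pos=[1000, 2000])
        ss = self._stats(["snp0", "snp1"], [1e-6, 1e-7], [1000, 2000])
        assert adjust_ld(["snp0", "snp1"], ss, g=g) == ["snp1"]


class TestStandardize:
    def test_closed_form(self):
        g = make_genotypes(np.array([[0.0], [1.0], [2.0]]))
        ss = make_sumstats(["snp0"], [2.0], [0.01])
        z = standardize(compute_prs(g, ss, ["snp0"]))
        np.testing.assert_allclose(z.scores.to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)
        assert abs(z.scores.mean()) < 1e-12
        assert z.scores.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_scores_raise(self):
        g = make_genotypes(np.ones((3, 1)))
        ss = make_sumstats(["snp0"], [1.0], [0.01])
        with pytest.raises(DegenerateDataError):
            standardize(compute_prs(g, ss, ["snp0"]))
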