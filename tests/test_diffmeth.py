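"""Differential methylation core: destranding, uniting, the exact Fisher
test against independent oracles, DMV arithmetic, BH q-values, and the
calling rule's threshold semantics."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from cfmeth.core import CfMethError, make_pool
from cfmeth.diffmeth import (
    DiffMethParams,
    bh_qvalues,
    call_dml,
    compute_dmv,
    destrand_merge,
    fisher_exact_2x2,
    unite_pools,
)
from cfmeth.simulate import (
    SimPoolParams,
    draw_landscape,
    make_genome,
    place_cpgs,
    simulate_pool,
)


def fisher_oracle(ma, ua, mb, ub) -> Fraction:
    """Exact-rational two-sided Fisher p by hypergeometric enumeration."""
    n1, n2, r = ma + ua, mb + ub, ma + mb
    w_obs = comb(n1, ma) * comb(n2, r - ma)
    acc = sum(
        w
        for k in range(max(0, r - n2), min(r, n1) + 1)
        if (w := comb(n1, k) * comb(n2, r - k)) <= w_obs
    )
    return Fraction(acc, comb(n1 + n2, r))


# ----------------------------------------------------------------- destrand

class TestDestrand:
    def test_dyad_counts_are_added(self):
        pool = make_pool(
            "p", "chr1", [100, 101], [3, 2], [1, 2], strand=["+", "-"]
        )
        out = destrand_merge(pool)
        assert len(out) == 1
        row = out.df.iloc[0]
        assert (row["pos"], row["strand"], row["meth"], row["unmeth"]) == (100, "+", 5, 3)

    def test_plus_only_locus_unchanged(self):
        pool = make_pool("p", "chr1", [100], [3], [1])
        out = destrand_merge(pool)
        pd.testing.assert_frame_equal(out.df, pool.df)

    def test_orphan_minus_becomes_plus_at_dyad_position(self):
        pool = make_pool("p", "chr1", [201], [2], [2], strand="-")
        out = destrand_merge(pool)
        row = out.df.iloc[0]
        assert (row["pos"], row["strand"], row["meth"]) == (200, "+", 2)

    def test_total_counts_conserved(self, rng):
        pos = np.sort(rng.choice(np.arange(2, 10_000, 2), 300, replace=False))
        pool = make_pool(
            "p", "chr1",
            list(pos) + list(pos + 1),
            list(rng.integers(0, 20, 600)[:300]) + list(rng.integers(0, 20, 300)),
            list(rng.integers(0, 20, 300)) + list(rng.integers(0, 20, 300)),
            strand=["+"] * 300 + ["-"] * 300,
        )
        out = destrand_merge(pool)
        assert out.df["meth"].sum() == pool.df["meth"].sum()
        assert out.df["unmeth"].sum() == pool.df["unmeth"].sum()
        assert (out.df["strand"] == "+").all()


# -------------------------------------------------------------------- unite

class TestUnite:
    def test_minimum_five_reads_in_each_group(self):
        a = make_pool("a", "chr1", [10, 20], [5, 5], [0, 0])
        b = make_pool("b", "chr1", [10, 20], [2, 2], [3, 2])
        united = unite_pools(a, b, DiffMethParams())
        # locus 10: 5/5 in both -> kept; locus 20: control coverage 4 -> dropped
        assert list(united["pos"]) == [10]

    def test_locus_in_one_pool_only_dropped(self):
        a = make_pool("a", "chr1", [10, 30], [5, 5], [5, 5])
        b = make_pool("b", "chr1", [10], [5], [5])
        assert list(unite_pools(a, b)["pos"]) == [10]

    def test_zero_coverage_pools_unite_empty(self):
        a = make_pool("a", "chr1", [10], [0], [0])
        b = make_pool("b", "chr1", [10], [0], [0])
        assert unite_pools(a, b).empty


# ------------------------------------------------------------------- fisher

class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 0, 0, 5), 2 / 252),
            ((3, 3, 3, 3), 1.0),
            ((10, 0, 10, 0), 1.0),
            ((9, 1, 1, 9), 0.001093333910671372),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-12)

    def test_invalid_tables_raise(self):
        with pytest.raises(CfMethError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(CfMethError):
            fisher_exact_2x2(0, 0, 3, 4)

    @given(
        ma=st.integers(0, 25), ua=st.integers(0, 25),
        mb=st.integers(0, 25), ub=st.integers(0, 25),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_exact_enumeration_and_scipy(self, ma, ua, mb, ub):
        if ma + ua == 0 or mb + ub == 0:
            return
        p = fisher_exact_2x2(ma, ua, mb, ub)
        assert p == pytest.approx(float(fisher_oracle(ma, ua, mb, ub)), rel=1e-12)
        assert p == pytest.approx(
            scipy_fisher([[ma, ua], [mb, ub]]).pvalue, rel=1e-9
        )
        assert 0 < p <= 1

    @given(
        ma=st.integers(0, 15), ua=st.integers(0, 15),
        mb=st.integers(0, 15), ub=st.integers(0, 15),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_group_swap_preserves_p(self, ma, ua, mb, ub):
        if ma + ua == 0 or mb + ub == 0:
            return
        assert fisher_exact_2x2(ma, ua, mb, ub) == fisher_exact_2x2(mb, ub, ma, ua)


# ------------------------------------------------------------------- DMV/BH

class TestDmvAndQvalues:
    @pytest.mark.parametrize(
        "table, expected",
        [((8, 2, 3, 7), 50.0), ((5, 5, 2, 2), 0.0), ((10, 0, 0, 10), 100.0)],
    )
    def test_dmv_arithmetic(self, table, expected):
        assert compute_dmv(*table) == expected

    def test_dmv_zero_coverage_is_error(self):
        with pytest.raises(CfMethError):
            compute_dmv(0, 0, 5, 5)

    @pytest.mark.parametrize(
        "p, q",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_bh_known_values(self, p, q):
        assert bh_qvalues(p) == pytest.approx(q)

    def test_bh_matches_hand_formula(self, rng):
        """Independent check: q_i = min_{j: p_j >= p_i} (p_(j) * m / rank_j)."""
        p = rng.uniform(1e-6, 1, 50)
        m = len(p)
        order = np.argsort(p)
        staircase = p[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(staircase[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(hand, 1.0)
        assert bh_qvalues(p) == pytest.approx(expected)

    def test_bh_empty_and_bounds(self):
        assert bh_qvalues([]).size == 0
        q = bh_qvalues([0.5, 0.001, 0.9])
        assert (q >= [0.5, 0.001, 0.9]).all() and (q <= 1).all()


# ----------------------------------------------------------------- call_dml

class TestCallDml:
    def make_params(self, **kw):
        kw.setdefault("destrand", False)
        return DiffMethParams(**kw)

    def test_strong_locus_called_hyper(self):
        a = make_pool("a", "chr1", [100], [9], [1])
        b = make_pool("b", "chr1", [100], [1], [9])
        records = call_dml(a, b, self.make_params())
        assert len(records) == 1
        row = records.iloc[0]
        assert row["direction"] == "hyper"
        assert row["dmv"] == 80.0
        assert row["p_value"] == pytest.approx(0.001093333910671372, rel=1e-12)

    def test_small_dmv_never_called(self):
        # 60% vs 50%: DMV 10 < 20, excluded regardless of p
        a = make_pool("a", "chr1", [100], [60], [40])
        b = make_pool("b", "chr1", [100], [50], [50])
        assert len(call_dml(a, b, self.make_params())) == 0

    @pytest.mark.parametrize("chrom", ["chrX", "X", "Y", "chrY"])
    def test_sex_chromosomes_removed(self, chrom):
        a = make_pool("a", chrom, [100], [9], [1])
        b = make_pool("b", chrom, [100], [1], [9])
        records = call_dml(a, b, self.make_params())
        assert len(records) == 0 and records.attrs["n_tested"] == 0

    def test_dmv_threshold_is_inclusive(self):
        # 7/3 vs 5/5: DMV exactly 20
        a = make_pool("a", "chr1", [100], [7], [3])
        b = make_pool("b", "chr1", [100], [5], [5])
        lax = self.make_params(p_threshold=0.999)
        assert len(call_dml(a, b, lax)) == 1
        above = self.make_params(
            p_threshold=0.999, dmv_threshold=np.nextafter(20.0, 21.0)
        )
        assert len(call_dml(a, b, above)) == 0

    def test_group_swap_negates_dmv(self, study):
        _, _, data = study
        params = DiffMethParams()
        fwd = call_dml(data.pools["MBC"], data.pools["H"], params)
        rev = call_dml(data.pools["H"], data.pools["MBC"], params)
        key = ["chrom", "pos"]
        m = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(m) == len(fwd) == len(rev)
        assert np.allclose(m["dmv_f"], -m["dmv_r"])
        assert np.array_equal(m["p_value_f"], m["p_value_r"])

    def test_null_calibration_conservative(self):
        """Identical-parameter pools (shift 0, rho 0): the p <= 0.05 fraction
        stays below 0.05 + 3*SE (Fisher is conservative for discrete counts)."""
        genome, _ = make_genome(seed=17)
        cpgs = place_cpgs(genome, seed=17)
        land = draw_landscape(cpgs, genome, seed=17)
        a = simulate_pool(
            cpgs, genome, SimPoolParams("A", depth_mean=10, overdispersion_rho=0.0),
            seed=18, landscape=land,
        )
        b = simulate_pool(
            cpgs, genome, SimPoolParams("B", depth_mean=10, overdispersion_rho=0.0),
            seed=19, landscape=land,
        )
        from cfmeth.diffmeth import fisher_exact_many

        united = unite_pools(destrand_merge(a), destrand_merge(b), DiffMethParams())
        p = fisher_exact_many(
            united["meth_a"].to_numpy(), united["unmeth_a"].to_numpy(),
            united["meth_b"].to_numpy(), united["unmeth_b"].to_numpy(),
        )
        n = len(p)
        assert (p <= 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_q_threshold_filters(self):
        a = make_pool("a", "chr1", [100, 200], [9, 6], [1, 4])
        b = make_pool("b", "chr1", [100, 200], [1, 4], [9, 6])
        loose = call_dml(a, b, self.make_params(p_threshold=0.99))
        strict = call_dml(a, b, self.make_params(p_threshold=0.99, q_threshold=0.01))
        assert len(strict) <= len(loose)
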