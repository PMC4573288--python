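"""Generator properties: determinism, density calibration, landscape shape,
shift monotonicity, planted-signal strength, truth round-trip."""

import numpy as np
import pandas as pd
import pytest

from cfmeth.core import CfMethError, GenomicInterval
from cfmeth.diffmeth import DiffMethParams, call_dml
from cfmeth.simulate import (
    SimGenomeModel,
    SimPoolParams,
    SimulationTruth,
    draw_landscape,
    emit_truth,
    island_membership,
    load_truth,
    make_genome,
    place_cpgs,
    simulate_pool,
    simulate_study,
)


@pytest.fixture(scope="module")
def genome():
    return make_genome(seed=11)


class TestPlaceCpgs:
    def test_deterministic_given_seed(self, genome):
        g, _ = genome
        a = place_cpgs(g, seed=5)
        b = place_cpgs(g, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = place_cpgs(g, seed=6)
        assert not a.equals(c)

    def test_island_density_matches_multiplier(self, genome):
        """Empirical CpG density ratio island/background ~ the configured
        multiplier, over 200 islands."""
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        inside = island_membership(cpgs, g)
        island_bp = sum(iv.end - iv.start for iv in g.islands)
        chrom_bp = g.chromosomes[0][1]
        dens_in = inside.sum() / island_bp
        dens_out = (~inside).sum() / (chrom_bp - island_bp)
        ratio = dens_in / dens_out
        assert ratio == pytest.approx(g.island_cpg_density_multiplier, rel=0.12)

    def test_degenerate_genomes_raise(self):
        with pytest.raises(CfMethError):
            SimGenomeModel(chromosomes=[("chr1", 0)])
        short = SimGenomeModel(chromosomes=[("chr1", 50)], cpg_spacing_mean=130.0)
        with pytest.raises(CfMethError, match="shorter"):
            place_cpgs(short, seed=0)

    def test_dyads_do_not_overlap(self, genome):
        g, _ = genome
        cpgs = place_cpgs(g, seed=2)
        assert (cpgs["pos"].diff().dropna() >= 2).all()


class TestSimulatePool:
    def test_deterministic_given_seed(self, genome):
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        params = SimPoolParams("H", depth_mean=10)
        a = simulate_pool(cpgs, g, params, seed=4)
        b = simulate_pool(cpgs, g, params, seed=4)
        assert a == b

    def test_null_pools_highly_correlated(self, genome):
        """Two pools from identical parameters (no shift) agree locus-by-locus:
        Pearson of percent methylation > 0.9 at depth 10 over >= 1e4 CpGs."""
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        assert len(cpgs) >= 10_000
        land = draw_landscape(cpgs, g, seed=1)
        pa = simulate_pool(cpgs, g, SimPoolParams("A", depth_mean=10), seed=21, landscape=land)
        pb = simulate_pool(cpgs, g, SimPoolParams("B", depth_mean=10), seed=22, landscape=land)
        merged = pa.df.merge(pb.df, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
        cov_a = merged["meth_a"] + merged["unmeth_a"]
        cov_b = merged["meth_b"] + merged["unmeth_b"]
        m = merged[(cov_a >= 5) & (cov_b >= 5)]
        pct_a = m["meth_a"] / (m["meth_a"] + m["unmeth_a"])
        pct_b = m["meth_b"] / (m["meth_b"] + m["unmeth_b"])
        assert np.corrcoef(pct_a, pct_b)[0, 1] > 0.9

    def test_planted_island_separates_pools_by_50_points(self, genome):
        g, tracks = genome
        data = simulate_study(
            g,
            [SimPoolParams("H", depth_mean=10), SimPoolParams("MBC", depth_mean=10)],
            seed=9, n_planted=5, planted_hyper_level=0.9, affected="MBC",
        )
        iv = data.truth.planted_hotspot_islands[0]
        for pool in data.pools.values():
            df = pool.df
            inside = (df["pos"] - 1 >= iv.start) & (df["pos"] - 1 < iv.end)
            cov = df["meth"] + df["unmeth"]
            sub = df[inside & (cov > 0)]
            mean_pct = (100.0 * sub["meth"] / (sub["meth"] + sub["unmeth"])).mean()
            if pool.label == "MBC":
                mbc_mean = mean_pct
            else:
                h_mean = mean_pct
        assert mbc_mean - h_mean > 50

    def test_degenerate_depth_yields_zero_dml(self, genome):
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        land = draw_landscape(cpgs, g, seed=1)
        pa = simulate_pool(cpgs, g, SimPoolParams("A", depth_mean=1e-4), seed=1, landscape=land)
        pb = simulate_pool(cpgs, g, SimPoolParams("B", depth_mean=1e-4), seed=2, landscape=land)
        assert (pa.coverage == 0).mean() > 0.99
        records = call_dml(pa, pb, DiffMethParams())
        assert len(records) == 0

    def test_planted_island_must_exist_in_genome(self, genome):
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        truth = SimulationTruth(
            planted_hotspot_islands=[GenomicInterval("chr1", 13, 99, "bogus")],
            planted_hyper_level=0.9, affected_pool_label="MBC", seed=0,
        )
        with pytest.raises(CfMethError, match="not an island"):
            simulate_pool(cpgs, g, SimPoolParams("MBC"), truth, seed=1)

    def test_coverage_mean_calibrated(self):
        """Law of large numbers: empirical mean coverage within 5% of
        depth_mean over >= 1e5 cytosines."""
        g, _ = make_genome(seed=2, chrom_length=4_000_000, cpg_spacing_mean=60.0)
        cpgs = place_cpgs(g, seed=2)
        pool = simulate_pool(cpgs, g, SimPoolParams("A", depth_mean=9.6), seed=3)
        assert len(pool) >= 100_000          # both strands
        assert pool.coverage.mean() == pytest.approx(9.6, rel=0.05)


class TestLandscape:
    def test_bimodal_shape(self, genome):
        """Unshifted pool: modal histogram bin above 80%, secondary mass
        below 20% (the island fraction)."""
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        pool = simulate_pool(cpgs, g, SimPoolParams("H", depth_mean=15), seed=5)
        pct = pool.percent_methylation.dropna()
        counts, edges = np.histogram(pct, bins=10, range=(0, 100))
        assert edges[np.argmax(counts)] >= 80
        assert counts[:2].sum() > 0.1 * counts.sum()

    def test_shift_monotonically_lowers_background(self, genome):
        g, _ = genome
        cpgs = place_cpgs(g, seed=1)
        land = draw_landscape(cpgs, g, seed=1)
        outside = ~island_membership(cpgs, g)
        means = []
        for shift in (0.0, 0.1, 0.2, 0.3):
            pool = simulate_pool(
                cpgs, g, SimPoolParams("S", depth_mean=12, global_hypo_shift=shift),
                seed=7, landscape=land,
            )
            df = pool.df[np.repeat(outside, 2)]
            cov = df["meth"] + df["unmeth"]
            means.append((100.0 * df["meth"] / cov)[cov > 0].mean())
        assert all(a > b for a, b in zip(means, means[1:]))


class TestTruth:
    def test_json_roundtrip(self, tmp_path, genome):
        g, _ = genome
        truth = SimulationTruth(
            planted_hotspot_islands=g.islands[:3],
            planted_hyper_level=0.9,
            affected_pool_label="MBC",
            seed=42,
            pool_params=[SimPoolParams("MBC", depth_mean=17.0, global_hypo_shift=0.15)],
        )
        path = tmp_path / "truth.json"
        emit_truth(truth, path)
        back = load_truth(path)
        assert back == truth
        assert isinstance(back.seed, int)

    def test_empty_planted_set(self, tmp_path):
        truth = SimulationTruth(
            planted_hotspot_islands=[], planted_hyper_level=0.9,
            affected_pool_label="MBC", seed=1,
        )
        path = tmp_path / "t.json"
        emit_truth(truth, path)
        assert load_truth(path).planted_hotspot_islands == []
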