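"""D statistic, block jackknife, and the outlier-region introgression scan."""

import numpy as np
import pytest

from conftest import make_panel
from selfmix.introgression_tests import (
    allele_frequencies,
    binomial_outlier_p,
    block_jackknife,
    d_statistic,
    find_outlier_regions,
    outlier_source_test,
)
from selfmix.variant_io import MISSING


class TestDStatistic:
    def test_equal_y_z_gives_zero(self):
        rng = np.random.default_rng(0)
        y = rng.random(50)
        w, x = rng.random(50), rng.random(50)
        assert d_statistic(y, y.copy(), w, x).D == pytest.approx(0.0)

    def test_single_site_closed_form(self):
        res = d_statistic([1.0], [0.0], [1.0], [0.0])
        assert res.D == pytest.approx(1.0)

    def test_antisymmetry_under_swaps(self):
        rng = np.random.default_rng(1)
        y, z, w, x = (rng.random(100) for _ in range(4))
        d0 = d_statistic(y, z, w, x).D
        assert d_statistic(z, y, w, x).D == pytest.approx(-d0)
        assert d_statistic(y, z, x, w).D == pytest.approx(-d0)

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(2)
        y, z, w, x = (rng.random(100) for _ in range(4))
        d0 = d_statistic(y, z, w, x).D
        d1 = d_statistic(1 - y, 1 - z, 1 - w, 1 - x).D
        assert d1 == pytest.approx(d0)

    def test_nan_sites_skipped(self):
        y = np.array([1.0, np.nan])
        res = d_statistic(y, [0.0, 0.5], [1.0, 0.5], [0.0, 0.5])
        assert res.n_sites == 1 and res.D == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        res = d_statistic([0.0], [0.0], [1.0], [1.0])
        assert res.undefined


class TestBlockJackknife:
    def test_identical_chromosome_contributions_zero_se(self):
        # same per-site patterns on every chromosome
        y = np.tile([1.0, 0.0, 1.0], 4)
        z = np.tile([0.0, 0.0, 1.0], 4)
        w = np.tile([1.0, 1.0, 0.0], 4)
        x = np.tile([0.0, 1.0, 0.0], 4)
        chrom = np.repeat([f"c{i}" for i in range(4)], 3)
        res = block_jackknife(y, z, w, x, chrom)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_three_chromosome_hand_computation(self):
        # one site per chromosome, worked by hand:
        #   c1: y=1,    z=0:    num = 1(1)   = 1,    den = (1 - 0)(1)       = 1
        #   c2: y=.75,  z=.25:  num = .5(1)  = .5,   den = (1 - .375)(1)    = .625
        #   c3: y=.625, z=.375: num = .25(1) = .25,  den = (1 - .46875)(1)  = .53125
        y = np.array([1.0, 0.75, 0.625])
        z = np.array([0.0, 0.25, 0.375])
        w = np.array([1.0, 1.0, 1.0])
        x = np.array([0.0, 0.0, 0.0])
        chrom = np.array(["c1", "c2", "c3"])
        res = block_jackknife(y, z, w, x, chrom)
        num_c = np.array([1.0, 0.5, 0.25])
        den_c = np.array([1.0, 0.625, 0.53125])
        N, S = num_c.sum(), den_c.sum()
        D = N / S
        assert res.D == pytest.approx(D)
        # hand-computed delete-one values
        for j, c in enumerate(chrom):
            expect = (N - num_c[j]) / (S - den_c[j])
            assert res.leave_one_out[c] == pytest.approx(expect)
        # hand-computed weighted jackknife SE with h_j = S / den_j
        g = 3
        D_j = np.array([res.leave_one_out[c] for c in chrom])
        h = S / den_c
        theta = g * D - ((1 - 1 / h) * D_j).sum()
        tau = h * D - (h - 1) * D_j
        var = np.sum((tau - theta) ** 2 / (h - 1)) / g
        assert res.se == pytest.approx(np.sqrt(var))

    def test_fewer_than_three_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            block_jackknife([1.0], [0.0], [1.0], [0.0], ["c1"])


class TestAlleleFrequencies:
    def test_frequencies_with_missing_calls(self):
        p = make_panel(chrom=["c1"] * 2, pos=[1, 2],
                       calls=[[1, 1, 0], [MISSING, 1, 0]])
        f = allele_frequencies(p, ["s0", "s1", "s2"])
        assert f[0] == pytest.approx(2 / 3)
        assert f[1] == pytest.approx(1 / 2)


def panel_with_outlier(seed=0, n_sites_per_kb=50, divergent=("sel0", 30_000, 60_000),
                       second_divergent=None):
    """Four donor-taxon samples over 100 kb; one carries a planted divergent
    haplotype (pi ~ 4% vs the others' ~0.2%)."""
    rng = np.random.default_rng(seed)
    L = 100_000
    n = int(L * n_sites_per_kb / 1000)
    pos = np.sort(rng.choice(L, size=n, replace=False))
    samples = ["sel0", "sel1", "sel2", "sel3"]
    calls = np.zeros((n, 4), dtype=np.int8)
    for j in range(4):
        calls[:, j] = (rng.random(n) < 0.001).astype(np.int8)
    hap = (rng.random(n) < 0.04).astype(np.int8)
    name, lo, hi = divergent
    j = samples.index(name)
    m = (pos >= lo) & (pos < hi)
    calls[m, j] = np.maximum(calls[m, j], hap[m])
    if second_divergent is not None:
        name2, lo2, hi2 = second_divergent
        j2 = samples.index(name2)
        hap2 = (rng.random(n) < 0.04).astype(np.int8)
        m2 = (pos >= lo2) & (pos < hi2)
        calls[m2, j2] = np.maximum(calls[m2, j2], hap2[m2])
    return make_panel(chrom=["c1"] * n, pos=pos, calls=calls, samples=samples)


class TestOutlierScan:
    def test_identical_panel_has_no_regions(self):
        n = 2000
        p = make_panel(chrom=["c1"] * n, pos=range(n),
                       calls=np.zeros((n, 3), dtype=np.int8),
                       samples=["a", "b", "c"])
        assert find_outlier_regions(p, ["a", "b", "c"], window_bp=500,
                                    region_bp=1000, min_sites=5) == []

    def test_planted_divergent_haplotype_found(self):
        p = panel_with_outlier()
        regions = find_outlier_regions(p, ["sel0", "sel1", "sel2", "sel3"],
                                       window_bp=5000, region_bp=20_000)
        assert len(regions) == 1
        assert regions[0].outlier == "sel0"
        assert regions[0].start <= 35_000 and regions[0].end >= 55_000

    def test_two_divergent_samples_rejected(self):
        p = panel_with_outlier(second_divergent=("sel1", 30_000, 60_000))
        regions = find_outlier_regions(p, ["sel0", "sel1", "sel2", "sel3"],
                                       window_bp=5000, region_bp=20_000)
        assert regions == []

    def test_short_region_dropped(self):
        p = panel_with_outlier(divergent=("sel0", 30_000, 40_000))
        regions = find_outlier_regions(p, ["sel0", "sel1", "sel2", "sel3"],
                                       window_bp=5000, region_bp=20_000)
        assert regions == []

    def test_fewer_than_three_samples_rejected(self):
        p = panel_with_outlier()
        with pytest.raises(ValueError):
            find_outlier_regions(p, ["sel0", "sel1"])


class TestOutlierSourceTest:
    def test_pooled_region_binomial_tail(self):
        # 272 successes of 490 informative regions -> p ~ 0.008
        assert binomial_outlier_p(272, 490) == pytest.approx(0.008, abs=0.002)

    def test_half_successes_gives_p_about_half(self):
        p = binomial_outlier_p(100, 200)
        assert 0.4 <= p <= 0.6

    def test_outlier_matching_source_is_detected(self):
        # source sample carries the same divergent haplotype as the outlier
        rng = np.random.default_rng(5)
        L, dens = 100_000, 50
        n = int(L * dens / 1000)
        pos = np.sort(rng.choice(L, size=n, replace=False))
        samples = ["sel0", "sel1", "sel2", "sel3", "out_source"]
        calls = np.zeros((n, 5), dtype=np.int8)
        for j in range(5):
            calls[:, j] = (rng.random(n) < 0.001).astype(np.int8)
        hap = (rng.random(n) < 0.04).astype(np.int8)
        m = (pos >= 20_000) & (pos < 80_000)
        calls[m, 0] = np.maximum(calls[m, 0], hap[m])          # outlier
        calls[m, 4] = np.maximum(calls[m, 4], hap[m])          # source
        p = make_panel(chrom=["c1"] * n, pos=pos, calls=calls, samples=samples)
        regions = find_outlier_regions(p, samples[:4], window_bp=5000,
                                       region_bp=20_000)
        assert regions and regions[0].outlier == "sel0"
        res = outlier_source_test(regions, p, samples[:4], "out_source")
        assert res.k == res.n  # outlier closer to source in every region

    def test_no_regions_rejected(self):
        p = panel_with_outlier()
        with pytest.raises(ValueError):
            outlier_source_test([], p, ["sel0", "sel1", "sel2", "sel3"], "sel3")
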