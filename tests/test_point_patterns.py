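"""Point-process generators: distributional properties and diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fragsim import (
    Window, PointPattern, ThomasParams, StraussParams,
    simulate_csr, simulate_thomas, simulate_strauss,
    nn_distances, pair_count,
)
from fragsim.point_patterns import (
    FeasibilityError, write_pattern, read_pattern,
)


class TestCSR:
    def test_empty_pattern(self):
        assert simulate_csr(0, seed=0).n == 0

    def test_count_and_bounds(self):
        pat = simulate_csr(100, seed=1)
        assert pat.n == 100
        assert pat.points.min() >= 0.0 and pat.points.max() <= 1.0

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_csr(-1, seed=0)

    def test_half_plane_fraction(self):
        # Binomial(10000, 0.5): fraction left of x=0.5 within 3 SE
        pat = simulate_csr(10_000, seed=2)
        frac = (pat.points[:, 0] < 0.5).mean()
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_marginal_uniformity(self):
        pat = simulate_csr(10_000, seed=3)
        for axis in (0, 1):
            p = stats.kstest(pat.points[:, axis], "uniform").pvalue
            assert p > 0.01

    def test_determinism(self):
        a = simulate_csr(50, seed=7).points
        b = simulate_csr(50, seed=7).points
        np.testing.assert_array_equal(a, b)


class TestThomas:
    def test_conditioned_abundance_exact(self):
        params = ThomasParams(100, 5, 0.02)
        assert params.mu == 20.0
        for seed in range(5):
            assert simulate_thomas(params, seed=seed).n == 100

    def test_degenerate_cluster(self):
        pat = simulate_thomas(ThomasParams(10, 1, 1e-9), seed=4)
        d = pat.window.separations(pat.points, pat.points)
        assert d.max() < 1e-6

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ThomasParams(100, 5, 0.0)

    def test_aggregation_vs_csr(self):
        # clustered patterns have shorter mean nn distance than CSR at same n
        agg, ran = [], []
        for seed in range(100):
            agg.append(nn_distances(
                simulate_thomas(ThomasParams(100, 5, 0.02), seed=seed)).mean())
            ran.append(nn_distances(simulate_csr(100, seed=seed)).mean())
        t = stats.ttest_ind(agg, ran, alternative="less")
        assert t.pvalue < 1e-6

    def test_poisson_mode_mean_abundance(self):
        ns = [simulate_thomas(ThomasParams(100, 5, 0.02, mode="poisson"),
                              seed=s).n for s in range(400)]
        mean = np.mean(ns)
        # total abundance ~ Poisson cluster sum, mean rho*A*mu = 100
        se = np.std(ns, ddof=1) / math.sqrt(len(ns))
        assert abs(mean - 100) < 3 * se + 1e-9

    def test_determinism(self):
        p = ThomasParams(100, 5, 0.02)
        np.testing.assert_array_equal(simulate_thomas(p, seed=9).points,
                                      simulate_thomas(p, seed=9).points)


class TestStrauss:
    def test_default_radius(self):
        assert StraussParams(100, 0.5).radius() == pytest.approx(0.1)

    def test_gamma_one_is_csr_nn_distribution(self):
        # two-sample KS on nearest-neighbour distances, n=1000 points
        a = simulate_strauss(StraussParams(1000, 1.0), seed=11)
        b = simulate_csr(1000, seed=12)
        p = stats.ks_2samp(nn_distances(a), nn_distances(b)).pvalue
        assert p > 0.01

    def test_gamma_one_pair_counts_match_csr(self):
        rs = (0.02, 0.05, 0.1)
        a = simulate_strauss(StraussParams(500, 1.0), seed=13)
        counts_csr = [pair_count(simulate_csr(500, seed=s), 0.05)
                      for s in range(50)]
        lo, hi = np.quantile(counts_csr, [0.005, 0.995])
        assert lo <= pair_count(a, 0.05) <= hi
        for r in rs:
            assert pair_count(a, r) >= 0

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_hardcore_zero_pairs(self, n):
        params = StraussParams(n, 0.0, n_sweeps=20_000, burn_in=10_000)
        pat = simulate_strauss(params, seed=n)
        r = params.radius()
        assert pair_count(pat, r) == 0
        assert nn_distances(pat).min() >= r * (1 - 1e-9)

    def test_hardcore_infeasible(self):
        # 200 points with r=0.1 exceeds the packing bound of the unit torus
        with pytest.raises(FeasibilityError):
            simulate_strauss(StraussParams(200, 0.0, r=0.1, n_sweeps=10,
                                           burn_in=5), seed=1)

    def test_intermediate_gamma_inhibits(self):
        # fewer close pairs than CSR, more than hard core
        params = StraussParams(100, 0.1)
        s_vals = [pair_count(simulate_strauss(params, seed=s), 0.1)
                  for s in range(10)]
        s_csr = [pair_count(simulate_csr(100, seed=s), 0.1)
                 for s in range(10)]
        assert np.mean(s_vals) < np.mean(s_csr)
        assert min(s_vals) >= 0

    def test_determinism(self):
        p = StraussParams(50, 0.3, n_sweeps=5000, burn_in=1000)
        np.testing.assert_array_equal(simulate_strauss(p, seed=21).points,
                                      simulate_strauss(p, seed=21).points)

    def test_mcmc_matches_exact_density_small_state(self):
        """Empirical distribution of s(x) for n=3 matches the Strauss density
        computed by independent importance-weighted integration, within 2%
        total variation."""
        gamma, r, n = 0.5, 0.3, 3
        params = StraussParams(n, gamma, r=r, n_sweeps=200_000,
                               burn_in=100_000)
        _, trace = simulate_strauss(params, seed=123, return_s_trace=True)
        emp = np.bincount(trace[params.burn_in:], minlength=4)
        emp = emp / emp.sum()

        rng = np.random.default_rng(999)
        m = 600_000
        pts = rng.random((m, 3, 2))
        s = np.zeros(m, dtype=int)
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.abs(pts[:, i, :] - pts[:, j, :])
                d = np.minimum(d, 1 - d)
                s += (d[:, 0] ** 2 + d[:, 1] ** 2 < r * r)
        w = gamma ** s.astype(float)
        oracle = np.array([(w * (s == k)).sum() for k in range(4)]) / w.sum()
        tv = 0.5 * np.abs(emp - oracle).sum()
        assert tv < 0.02


class TestDiagnostics:
    def test_nn_two_points_planar(self, planar_window):
        pat = PointPattern([(0.0, 0.0), (0.0, 0.3)], planar_window)
        np.testing.assert_allclose(nn_distances(pat), [0.3, 0.3])

    def test_nn_wraparound(self, unit_window):
        pat = PointPattern([(0.05, 0.5), (0.95, 0.5)], unit_window)
        np.testing.assert_allclose(nn_distances(pat), [0.1, 0.1])

    def test_nn_requires_two_points(self):
        with pytest.raises(ValueError):
            nn_distances(PointPattern([(0.5, 0.5)]))

    def test_nn_csr_expectation(self):
        # E[nn distance] for CSR intensity lambda is 1/(2 sqrt(lambda))
        pat = simulate_csr(1000, seed=31)
        expected = 0.5 / math.sqrt(1000)
        assert abs(nn_distances(pat).mean() - expected) < 0.1 * expected

    def test_pair_count_empty(self):
        assert pair_count(PointPattern(np.empty((0, 2))), 0.1) == 0

    def test_pair_count_collinear(self, planar_window):
        pat = PointPattern([(0.1, 0.5), (0.15, 0.5), (0.2, 0.5)],
                           planar_window)
        assert pair_count(pat, 0.06) == 2

    @given(st.integers(0, 2 ** 31 - 1))
    def test_pair_count_translation_invariant_on_torus(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((30, 2))
        shift = rng.random(2)
        w = Window()
        a = pair_count(PointPattern(pts, w), 0.15)
        b = pair_count(PointPattern((pts + shift) % 1.0, w), 0.15)
        assert a == b


class TestIO:
    def test_roundtrip(self, tmp_path):
        pat = simulate_thomas(ThomasParams(40, 4, 0.05), seed=5)
        path = tmp_path / "pattern.csv"
        write_pattern(pat, path, params={"sigma": 0.05})
        back = read_pattern(path)
        np.testing.assert_allclose(back.points, pat.points)
        assert back.process_label == "thomas"
        assert back.seed == 5
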