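"""Lattice Monte Carlo against exact enumeration, transfer-matrix values and
ideal-chain closed forms."""

import itertools
import math

import numpy as np
import pytest

import chromofold as cf
from chromofold._mc_kernels import COS_TAB, DIRS


def enumerate_chain_stats(n_bonds, eps):
    """Exhaustive Boltzmann average over all 6^N direction sequences.

    Independent oracle for small chains: returns (mean Ree^2, mean Rg^2,
    energy levels, level probabilities).
    """
    eps = np.asarray(eps, dtype=float)
    weights, ree2s, rg2s, energies = [], [], [], []
    for seq in itertools.product(range(6), repeat=n_bonds):
        e = sum(
            eps[v] * (1.0 - COS_TAB[seq[v], seq[v + 1]])
            for v in range(n_bonds - 1)
        )
        pos = np.vstack([np.zeros(3), np.cumsum(DIRS[list(seq)], axis=0)])
        weights.append(math.exp(-e))
        energies.append(round(e, 12))
        ree2s.append(((pos[-1] - pos[0]) ** 2).sum())
        rg2s.append(((pos - pos.mean(axis=0)) ** 2).sum(axis=1).mean())
    w = np.array(weights)
    w /= w.sum()
    levels = sorted(set(energies))
    probs = [w[[e == lv for e in energies]].sum() for lv in levels]
    return (
        float(np.dot(w, ree2s)),
        float(np.dot(w, rg2s)),
        np.array(levels),
        np.array(probs),
    )


def replicate_means(n_bonds, eps, n_reps, sweeps, interval, base_seed, smax=0):
    """Per-replicate observable means from independent seeds."""
    ree, rg, tc = [], [], []
    for r in range(n_reps):
        seed = cf.split_seed(base_seed, r)
        chain = cf.build_chain(n_bonds, eps, init="random", seed=seed)
        cfg = cf.MCConfig(
            n_sweeps=sweeps,
            equilibration_sweeps=10 * n_bonds,
            sample_interval=interval,
            seed=seed,
        )
        s = cf.metropolis_sample(chain, cfg, smax=smax)
        ree.append(s.ree2.mean())
        rg.append(s.rg2.mean())
        tc.append(s.tangent_correlation)
    return np.array(ree), np.array(rg), np.mean(tc, axis=0)


class TestBuildChain:
    def test_rod_end_to_end(self):
        chain = cf.build_chain(16, np.zeros(15), init="rod")
        ree2 = ((chain.coordinates[-1] - chain.coordinates[0]) ** 2).sum()
        assert ree2 == 256

    def test_unit_bonds_any_init(self):
        chain = cf.build_chain(40, np.zeros(39), init="random", seed=5)
        steps = np.diff(chain.coordinates, axis=0)
        assert np.all(np.abs(steps).sum(axis=1) == 1)

    def test_random_init_deterministic(self):
        a = cf.build_chain(32, np.zeros(31), init="random", seed=9)
        b = cf.build_chain(32, np.zeros(31), init="random", seed=9)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_stiffness_length_mismatch(self):
        with pytest.raises(ValueError):
            cf.build_chain(16, np.zeros(10))


class TestHingeMap:
    def test_no_hinges_uniform_stiff(self):
        eps = cf.hinge_stiffness_map(16, 0)
        assert np.all(eps == 2.0)

    def test_all_hinges_uniform_flexible(self):
        eps = cf.hinge_stiffness_map(16, 15, region_width=1)
        assert np.all(eps == 0.0)

    def test_equally_spaced_placement(self):
        # 16 bonds, 15 vertices, 3 hinges: 1-based labels 4, 8, 12
        eps = cf.hinge_stiffness_map(16, 3, region_width=1)
        assert set(np.where(eps == 0.0)[0]) == {3, 7, 11}
        assert np.all(eps[eps != 0.0] == 2.0)

    def test_too_many_regions(self):
        with pytest.raises(ValueError):
            cf.hinge_stiffness_map(16, 8, region_width=2)


class TestExactEnumeration:
    def test_ideal_chain_closed_forms_by_enumeration(self):
        # all 6^4 walks: <Ree^2> = N, <Rg^2> = N(N+2)/(6(N+1))
        ree2, rg2, _, _ = enumerate_chain_stats(4, np.zeros(3))
        assert ree2 == pytest.approx(4.0, rel=1e-12)
        assert rg2 == pytest.approx(cf.ideal_chain_rg2(4), rel=1e-12)

    def test_detailed_balance_energy_histogram(self):
        # 3-bond chain, asymmetric stiffness: sampled energy-level
        # frequencies match the exact Boltzmann enumeration
        eps = np.array([1.5, 0.7])
        _, _, levels, probs = enumerate_chain_stats(3, eps)
        chain = cf.build_chain(3, eps, init="random", seed=3)
        cfg = cf.MCConfig(
            n_sweeps=40_000, equilibration_sweeps=500, sample_interval=1, seed=17
        )
        s = cf.metropolis_sample(chain, cfg, smax=0)
        n = len(s.energy)
        for lv, p in zip(levels, probs):
            freq = np.mean(np.abs(s.energy - lv) < 1e-9)
            se = math.sqrt(p * (1 - p) / n)
            # correlated samples: allow a generous multiple of the iid SE
            assert abs(freq - p) < max(8.0 * se, 0.01), (lv, freq, p)
        assert np.mean(
            [np.any(np.abs(levels - e) < 1e-9) for e in s.energy]
        ) == 1.0


class TestIdealChainRecovery:
    def test_observables_match_closed_forms(self):
        n = 64
        ree, rg, tcorr = replicate_means(
            n, np.zeros(n - 1), n_reps=8, sweeps=400, interval=4,
            base_seed=101, smax=4,
        )
        se_ree = ree.std(ddof=1) / math.sqrt(len(ree))
        se_rg = rg.std(ddof=1) / math.sqrt(len(rg))
        assert abs(ree.mean() - n) < 3.0 * se_ree
        assert abs(rg.mean() - cf.ideal_chain_rg2(n)) < 3.0 * se_rg
        # memoryless: tangent correlations vanish for all s >= 1
        assert np.all(np.abs(tcorr[1:]) < 0.05)

    def test_flexible_chain_lp_reported_near_zero(self):
        chain = cf.build_chain(128, np.zeros(127), init="random", seed=7)
        cfg = cf.MCConfig(
            n_sweeps=800, equilibration_sweeps=200, sample_interval=2, seed=23
        )
        s = cf.metropolis_sample(chain, cfg, smax=6)
        fit = cf.tangent_correlation_lp(s, fit_range=(1, 3), n_bonds=128)
        assert fit.lp < 0.2


class TestStiffChain:
    def test_mean_cos_matches_transfer_matrix(self):
        n = 256
        eps = np.full(n - 1, 2.0)
        _, _, tcorr = replicate_means(
            n, eps, n_reps=8, sweeps=1200, interval=4, base_seed=33, smax=8
        )
        cos_runs = []
        for r in range(8):
            seed = cf.split_seed(33, r)
            chain = cf.build_chain(n, eps, init="random", seed=seed)
            cfg = cf.MCConfig(
                n_sweeps=1200, equilibration_sweeps=10 * n,
                sample_interval=4, seed=seed,
            )
            cos_runs.append(
                cf.metropolis_sample(chain, cfg, smax=1).tangent_correlation[1]
            )
        cos_runs = np.array(cos_runs)
        exact = cf.transfer_matrix_mean_cos(2.0)
        se = cos_runs.std(ddof=1) / math.sqrt(len(cos_runs))
        assert abs(cos_runs.mean() - exact) < 3.0 * se

    def test_tangent_lp_matches_transfer_matrix(self):
        n = 256
        eps = np.full(n - 1, 2.0)
        _, _, tcorr = replicate_means(
            n, eps, n_reps=8, sweeps=1200, interval=4, base_seed=47, smax=8
        )
        series = cf.ObservableSeries(
            ree2=np.empty(0), rg2=np.empty(0), tangent_correlation=tcorr
        )
        fit = cf.tangent_correlation_lp(series, fit_range=(1, 6), n_bonds=n)
        exact_lp = -1.0 / math.log(cf.transfer_matrix_mean_cos(2.0))
        assert abs(fit.lp - exact_lp) / exact_lp < 0.10

    def test_very_stiff_chain_flagged_rod_like(self):
        n = 32
        eps = np.full(n - 1, 20.0)
        chain = cf.build_chain(n, eps, init="rod")
        cfg = cf.MCConfig(
            n_sweeps=400, equilibration_sweeps=100, sample_interval=2, seed=5
        )
        s = cf.metropolis_sample(chain, cfg, smax=4)
        with pytest.warns(UserWarning, match="rod-like"):
            fit = cf.tangent_correlation_lp(s, fit_range=(1, 3), n_bonds=n)
        assert fit.rod_like
        assert fit.lp > n


class TestReproducibilityAndErrors:
    def test_identical_seed_identical_series(self):
        eps = cf.hinge_stiffness_map(32, 2)
        chain = cf.build_chain(32, eps, init="random", seed=1)
        cfg = cf.MCConfig(
            n_sweeps=200, equilibration_sweeps=50, sample_interval=1, seed=77
        )
        a = cf.metropolis_sample(chain, cfg, smax=4)
        b = cf.metropolis_sample(chain, cfg, smax=4)
        assert np.array_equal(a.ree2, b.ree2)
        assert np.array_equal(a.rg2, b.rg2)
        assert np.array_equal(a.tangent_correlation, b.tangent_correlation)

    def test_zero_samples_error(self):
        chain = cf.build_chain(8, np.zeros(7))
        cfg = cf.MCConfig(n_sweeps=0, equilibration_sweeps=10, seed=1)
        with pytest.raises(ValueError, match="samples"):
            cf.metropolis_sample(chain, cfg)

    def test_experiment_rejects_tiny_chains(self):
        cfg = cf.MCConfig(n_sweeps=10, equilibration_sweeps=10, seed=1)
        with pytest.raises(ValueError):
            cf.rg_ratio_experiment([3], [0], cfg, replicates=2)


class TestHingeCollapseDirection:
    def test_hinges_shrink_stiff_chains(self):
        # three soft regions vs none: Rg^2 ratio must drop
        cfg = cf.MCConfig(
            n_sweeps=24 * 8, equilibration_sweeps=640, sample_interval=8, seed=13
        )
        df = cf.rg_ratio_experiment([64], [0, 3], cfg, replicates=8)
        r0 = df[df.k == 0].ratio.iloc[0]
        r3 = df[df.k == 3].ratio.iloc[0]
        assert r3 < r0
        assert r0 > 1.0  # stiff background expands relative to flexible
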