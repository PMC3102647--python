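"""Worm-like-chain and folding-index analytics against closed forms and a
discretized-chain sampling oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chromofold as cf


def sample_wlc_r2(lp, lc, n_segments, n_chains, seed):
    """Independent oracle: Monte Carlo of a discretized worm-like chain.

    Successive tangents are deflected by polar angles drawn from the
    Boltzmann density ~ exp(kappa * cos(theta)) with kappa = Lp/ds (inverse
    transform sampling) and uniform azimuth. Returns the sampled squared
    end-to-end distances.
    """
    rng = np.random.default_rng(seed)
    ds = lc / n_segments
    kappa = lp / ds
    t = np.zeros((n_chains, 3))
    t[:, 2] = 1.0
    ree = ds * t.copy()
    for _ in range(n_segments - 1):
        u = rng.random(n_chains)
        c = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
        s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
        phi = rng.random(n_chains) * 2.0 * math.pi
        a = np.where(
            np.abs(t[:, 0:1]) < 0.9,
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
        )
        e1 = np.cross(t, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(t, e1)
        t = (
            c[:, None] * t
            + s[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        ree += ds * t
    return (ree**2).sum(axis=1)


class TestMeanSquareEndToEnd:
    def test_zero_length_chain(self):
        assert cf.wlc_mean_square_end_to_end(50.0, 0.0) == 0.0

    def test_ideal_chain_asymptote(self):
        lp, lc = 50.0, 1.0e6
        val = cf.wlc_mean_square_end_to_end(lp, lc)
        assert abs(val - 2.0 * lp * lc) / (2.0 * lp * lc) < 1e-4

    def test_rigid_rod_limit(self):
        # Lc/Lp = 0.01: <R^2> approaches Lc^2 within 1%
        lp = 100.0
        lc = 0.01 * lp
        val = cf.wlc_mean_square_end_to_end(lp, lc)
        assert abs(val - lc**2) / lc**2 < 0.01

    def test_ideal_limit_within_one_percent(self):
        lp = 50.0
        lc = 400.0 * lp
        val = cf.wlc_mean_square_end_to_end(lp, lc)
        assert abs(val - 2.0 * lp * lc) / (2.0 * lp * lc) < 0.01

    def test_monotone_increasing_in_contour_length(self):
        lcs = np.linspace(1.0, 1000.0, 200)
        vals = [cf.wlc_mean_square_end_to_end(80.0, lc) for lc in lcs]
        assert np.all(np.diff(vals) > 0)

    def test_matches_discretized_chain_sampling(self):
        # Lc = Lp = 100 nm: semiflexible crossover, no limit applies
        lp = lc = 100.0
        expected = cf.wlc_mean_square_end_to_end(lp, lc)
        r2 = sample_wlc_r2(lp, lc, n_segments=800, n_chains=20_000, seed=11)
        se = r2.std(ddof=1) / math.sqrt(len(r2))
        assert abs(r2.mean() - expected) < 4.0 * se

    @pytest.mark.parametrize("lp,lc", [(-1.0, 10.0), (0.0, 10.0), (5.0, -1.0)])
    def test_invalid_parameters(self, lp, lc):
        with pytest.raises(ValueError):
            cf.wlc_mean_square_end_to_end(lp, lc)


class TestCompactionRatio:
    def test_ideal_limit_is_lp_ratio(self):
        assert cf.compaction_ratio(280.0, 140.0) == 0.5

    def test_identity(self):
        assert cf.compaction_ratio(123.0, 123.0) == 1.0
        with pytest.warns(UserWarning):
            assert cf.compaction_ratio(123.0, 123.0, 500.0) == 1.0

    @given(
        a=st.floats(min_value=1.0, max_value=1000.0),
        b=st.floats(min_value=1.0, max_value=1000.0),
    )
    def test_reciprocal_property(self, a, b):
        assert cf.compaction_ratio(a, b) * cf.compaction_ratio(b, a) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_full_formula_between_ideal_and_unity(self):
        with pytest.warns(UserWarning):
            r = cf.compaction_ratio(280.0, 140.0, 500.0)
        assert 0.5 < r < 1.0

    def test_full_formula_matches_sampling_oracle(self):
        # short locus (Lc = 500 nm): ratio from two independently sampled
        # discretized chains agrees with the closed-form ratio
        with pytest.warns(UserWarning):
            expected = cf.compaction_ratio(280.0, 140.0, 500.0)
        r2_f = sample_wlc_r2(140.0, 500.0, 400, 20_000, seed=21)
        r2_i = sample_wlc_r2(280.0, 500.0, 400, 20_000, seed=22)
        ratio = r2_f.mean() / r2_i.mean()
        rel_se = math.sqrt(
            (r2_f.std(ddof=1) / r2_f.mean()) ** 2
            + (r2_i.std(ddof=1) / r2_i.mean()) ** 2
        ) / math.sqrt(20_000)
        assert abs(ratio - expected) < 4.0 * rel_se * expected

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            cf.compaction_ratio(-280.0, 140.0)
        with pytest.raises(ValueError):
            cf.compaction_ratio(280.0, 140.0, -5.0)


class TestFloryAmplification:
    def test_halved_r2_gives_eightfold_contacts(self):
        res = cf.flory_amplification(0.5)
        assert res.nb_ratio == pytest.approx(8.0, rel=1e-14)
        # the ~30% figure: RMS size decreases by 1 - sqrt(1/2) = 29.29%
        assert res.percent_compaction == pytest.approx(
            100.0 * (1.0 - math.sqrt(0.5)), rel=1e-14
        )
        assert 29.0 < res.percent_compaction < 29.5

    def test_no_change(self):
        res = cf.flory_amplification(1.0)
        assert res.nb_ratio == 1.0
        assert res.percent_compaction == 0.0

    @given(r=st.floats(min_value=0.05, max_value=5.0))
    def test_strict_power_law(self, r):
        cubed = cf.flory_amplification(r**3).nb_ratio
        assert cubed == pytest.approx(cf.flory_amplification(r).nb_ratio ** 3,
                                      rel=1e-9)

    def test_invalid(self):
        with pytest.raises(ValueError):
            cf.flory_amplification(0.0)


class TestFoldingIndexFramework:
    NUCLEUS_NM = 25_000.0  # 25 um
    GENOME_NM = 2.0e9  # 2 m of dsDNA contour

    def test_human_genome_worked_example(self):
        f = cf.fjc_summary(50.0, 1.0 / 3.0, self.GENOME_NM)
        assert f.n_repeat == pytest.approx(2.0e7, rel=1e-12)
        # direct evaluation: 2 * 50 nm * (2e7)^(1/3) = 27.14 um
        assert f.fjc_size / 1000.0 == pytest.approx(27.144, abs=0.01)
        # exact folding index along this route: (2e7)^(2/3)
        assert f.folding_index == pytest.approx((2.0e7) ** (2.0 / 3.0), rel=1e-12)

    def test_folding_index_from_nuclear_size(self):
        # folded size taken as the nuclear diameter: phi = Lc / C_s
        phi = cf.folding_index_from_sizes(self.GENOME_NM, self.NUCLEUS_NM)
        assert phi == pytest.approx(8.0e4, rel=1e-12)
        assert cf.folding_index_from_sizes(123.0, 123.0) == 1.0

    def test_contour_length_from_bp(self):
        # 6 Gbp at 2.94 bp/nm is very nearly 2 m
        lc = cf.contour_length_from_bp(6.0e9)
        assert lc == pytest.approx(6.0e9 / 2.94, rel=1e-14)
        assert lc * 1e-9 == pytest.approx(2.04, abs=0.01)  # metres
        phi = cf.folding_index_from_sizes(
            0.0, self.NUCLEUS_NM, genomic_distance_bp=6.0e9
        )
        assert phi == pytest.approx(lc / self.NUCLEUS_NM, rel=1e-14)

    def test_rod_limit(self):
        f = cf.fjc_summary(50.0, 1.0, 1000.0)
        assert f.fjc_size == pytest.approx(1000.0, rel=1e-14)
        assert f.folding_index == pytest.approx(1.0, rel=1e-14)

    def test_too_short_chain(self):
        with pytest.raises(ValueError):
            cf.fjc_summary(50.0, 0.5, 80.0)

    @pytest.mark.parametrize("n_repeat", [1, 7, 1000, 10**6, 10**9])
    def test_folding_index_power_of_repeat_units(self, n_repeat):
        nu = 1.0 / 3.0
        f = cf.fjc_summary(50.0, nu, 100.0 * n_repeat)
        assert f.folding_index == pytest.approx(n_repeat ** (1.0 - nu), rel=1e-12)

    def test_persistence_from_folding_quadratic_case(self):
        # phi = (25000 / (2 * 50))^2 = 62500 inverts back to Lp = 50 nm
        assert cf.persistence_from_folding(6.25e4, self.NUCLEUS_NM) == pytest.approx(
            50.0, rel=1e-12
        )

    def test_unfolded_boundary(self):
        assert cf.persistence_from_folding(1.0, self.NUCLEUS_NM) == pytest.approx(
            self.NUCLEUS_NM / 2.0, rel=1e-14
        )

    def test_rod_nu_rejected(self):
        with pytest.raises(ValueError):
            cf.persistence_from_folding(100.0, self.NUCLEUS_NM, nu=1.0)

    @given(
        lp=st.floats(min_value=1.0, max_value=1e4),
        nu=st.floats(min_value=0.15, max_value=0.85),
    )
    def test_round_trip_any_nu(self, lp, nu):
        phi = cf.folding_index_at_fixed_size(lp, self.NUCLEUS_NM, nu)
        back = cf.persistence_from_folding(max(phi, 1.0), self.NUCLEUS_NM, nu)
        if phi >= 1.0:
            assert back == pytest.approx(lp, rel=1e-12)

    def test_consistent_triangle(self):
        # fjc_summary -> folding_index_from_sizes reproduces the index
        lp, nu, lc = 75.0, 1.0 / 3.0, 5.0e7
        f = cf.fjc_summary(lp, nu, lc)
        assert cf.folding_index_from_sizes(lc, f.fjc_size) == pytest.approx(
            f.folding_index, rel=1e-12
        )

    def test_folding_curve_table(self):
        df = cf.folding_curve(self.NUCLEUS_NM, 1.0 / 3.0, 1.0, 1e4, 50)
        assert list(df.columns) == ["lp_nm", "phi", "n_repeat", "cs_nm"]
        # curve is the inverse relation point by point
        for _, row in df.iloc[::13].iterrows():
            assert cf.persistence_from_folding(
                row.phi, self.NUCLEUS_NM
            ) == pytest.approx(row.lp_nm, rel=1e-12)
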