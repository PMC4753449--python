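"""Debye profiles, Guinier fits, p(r)/IFT, χ, mixtures and GA ensembles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ringflex as rf
from ringflex.errors import ParseError


def _sphere_curve(R: float, s: np.ndarray) -> np.ndarray:
    x = s * R
    return (3 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2


class TestReadWrite:
    def test_reads_three_columns_with_headers(self, tmp_path):
        p = tmp_path / "curve.dat"
        p.write_text(
            "Sample description header\n"
            " s       I       err\n"
            " 0.10  100.0  1.0\n 0.20  80.0  1.0\n 0.30  50.0  0.9\n"
            " 0.40  30.0  0.8\n 0.50  20.0  0.7\n"
        )
        prof = rf.read_sas_curve(p, unit="nm^-1")
        assert len(prof) == 5 and prof.sigma is not None
        assert prof.unit == "nm^-1"
        assert prof.s_inv_angstrom[0] == pytest.approx(0.01)

    def test_two_column_curve_refuses_chi(self, tmp_path):
        p = tmp_path / "nosig.dat"
        p.write_text("0.1 10\n0.2 8\n0.3 5\n")
        prof = rf.read_sas_curve(p)
        assert prof.sigma is None
        with pytest.raises(ValueError, match="errors"):
            rf.chi_discrepancy(prof, prof)

    def test_garbage_file_raises(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("only words here\n")
        with pytest.raises(ParseError):
            rf.read_sas_curve(p)

    def test_roundtrip(self, tmp_path):
        prof = rf.ScatteringProfile(
            np.linspace(0.01, 0.3, 20), np.linspace(10, 1, 20), np.full(20, 0.1)
        )
        rf.write_sas_curve(prof, tmp_path / "out.dat")
        back = rf.read_sas_curve(tmp_path / "out.dat", unit="A^-1")
        np.testing.assert_allclose(back.intensity, prof.intensity)


class TestDebye:
    def test_single_bead_flat_profile(self):
        prof = rf.debye_profile(np.zeros((1, 3)), np.linspace(0.01, 0.5, 10), form_factor=2.0)
        np.testing.assert_allclose(prof.intensity, 4.0)

    def test_two_bead_closed_form(self):
        d = 7.0
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        s = np.linspace(0.01, 0.6, 50)
        prof = rf.debye_profile(pos, s, form_factor=1.5)
        expected = 2 * 1.5**2 * (1 + np.sin(s * d) / (s * d))
        np.testing.assert_allclose(prof.intensity, expected, rtol=1e-12)

    def test_rigid_motion_invariance(self, ring_c6):
        from scipy.spatial.transform import Rotation

        s = np.linspace(0.01, 0.3, 30)
        base = rf.debye_profile(ring_c6, s)
        R = Rotation.from_euler("zyx", [11, 22, 33], degrees=True).as_matrix()
        moved = ring_c6.with_positions(ring_c6.positions @ R.T + [9.0, -4.0, 2.0])
        np.testing.assert_allclose(
            rf.debye_profile(moved, s).intensity, base.intensity, rtol=1e-9
        )

    def test_histogram_approximation_close_to_exact(self, ring_c6):
        s = np.linspace(0.01, 0.3, 30)
        exact = rf.debye_profile(ring_c6, s).intensity
        approx = rf.debye_profile(ring_c6, s, approx_bin=0.25).intensity
        np.testing.assert_allclose(approx, exact, rtol=1e-2)

    def test_matches_analytic_sphere(self, sphere_cloud):
        """Continuum sphere form factor reproduced where it is appreciable
        (relative comparison is ill-posed at the interference zero)."""
        pts, R = sphere_cloud
        s = np.linspace(0.15 / R, 6.0 / R, 60)
        prof = rf.debye_profile(pts, s, approx_bin=0.2)
        analytic = _sphere_curve(R, s)
        In = prof.intensity / prof.intensity[0] * analytic[0]
        mask = analytic > 1e-2 * analytic[0]
        assert np.abs(In[mask] / analytic[mask] - 1).max() < 0.02

    def test_nm_unit_consistency(self, ring_c6):
        s_a = np.linspace(0.01, 0.3, 20)
        in_a = rf.debye_profile(ring_c6, s_a, unit="A^-1").intensity
        in_nm = rf.debye_profile(ring_c6, s_a * 10, unit="nm^-1").intensity
        np.testing.assert_allclose(in_a, in_nm, rtol=1e-12)


class TestGuinier:
    def test_ideal_gaussian_exact(self):
        s = np.linspace(1e-4, 0.05, 300)
        prof = rf.ScatteringProfile(s, 7.0 * np.exp(-(s**2) * 30.0**2 / 3))
        rg, i0, _ = rf.guinier_fit(prof)
        assert rg == pytest.approx(30.0, abs=1e-6)
        assert i0 == pytest.approx(7.0, rel=1e-6)

    def test_analytic_sphere_within_one_percent(self):
        R = 50.0
        s = np.linspace(0.001, 0.06, 400)
        prof = rf.ScatteringProfile(s, _sphere_curve(R, s))
        rg, _, _ = rf.guinier_fit(prof)
        assert rg == pytest.approx(np.sqrt(3 / 5) * R, rel=0.01)

    def test_consistent_with_model_rg(self, ring_c6):
        rg_geom = rf.radius_of_gyration(ring_c6)
        prof = rf.debye_profile(ring_c6, np.linspace(0.002, 0.08, 150))
        rg_fit, _, _ = rf.guinier_fit(prof)
        assert rg_fit == pytest.approx(rg_geom, rel=0.01)

    def test_rising_curve_rejected(self):
        s = np.linspace(0.01, 0.1, 50)
        with pytest.raises(ValueError, match="slope"):
            rf.guinier_fit(rf.ScatteringProfile(s, np.exp(+(s**2) * 100)))


class TestPrAndIft:
    def test_two_bead_histogram(self):
        pos = np.array([[0.0, 0, 0], [9.0, 0, 0]])
        dd = rf.pr_from_model(pos, bin_width=1.0)
        assert dd.dmax == 9.0
        occupied = dd.r[dd.p > 0]
        assert len(occupied) == 1 and abs(occupied[0] - 9.0) < 1.0

    def test_integral_counts_ordered_pairs(self, ring_c6):
        n = len(ring_c6)
        dd = rf.pr_from_model(ring_c6, bin_width=0.5)
        total = np.sum(dd.p) * 0.5
        assert total == pytest.approx(n * (n - 1), rel=1e-9)

    def test_sphere_pair_distance_density(self, sphere_cloud):
        """p(r) of a uniform ball matches 3x²(1−x)²(2+x), x=r/2R."""
        pts, R = sphere_cloud
        dd = rf.pr_from_model(pts, bin_width=1.5)
        x = dd.r / (2 * R)
        analytic = np.where(x <= 1, 3 * x**2 * (2 - 3 * x + x**3) * 4, 0.0)
        # same normalisation then compare in the bulk
        pn = dd.p / np.trapezoid(dd.p, dd.r)
        an = analytic / np.trapezoid(analytic, dd.r)
        bulk = (dd.r > 5) & (dd.r < 2 * R - 5)
        assert np.abs(pn[bulk] - an[bulk]).max() < 0.02 * an.max()

    def test_ift_roundtrip_recovers_planted_pr(self):
        r = np.linspace(0, 80, 200)
        p_true = np.sin(np.pi * r / 80) ** 2 * (r / 80)
        s = np.linspace(0.008, 0.35, 150)
        I = (np.sinc(s[:, None] * r[None, :] / np.pi) * p_true[None, :] * (r[1] - r[0])).sum(axis=1)
        obs = rf.simulate_sas_curve(
            rf.ScatteringProfile(s, I), rf.NoiseModel(rel_floor=0.01, seed=11)
        )
        dd = rf.ift_estimate(obs, dmax_scan=np.arange(50, 121, 2.5), n_basis=50)
        assert abs(dd.dmax - 80) <= 5
        corr = np.corrcoef(np.interp(r, dd.r, dd.p), p_true)[0, 1]
        assert corr > 0.99

    def test_ift_sphere_dmax_is_diameter(self):
        R = 30.0
        s = np.linspace(0.005, 0.3, 140)
        obs = rf.simulate_sas_curve(
            rf.ScatteringProfile(s, _sphere_curve(R, s)),
            rf.NoiseModel(rel_floor=0.01, seed=2),
        )
        dd = rf.ift_estimate(obs, dmax_scan=np.arange(40, 91, 2.0), n_basis=50)
        assert dd.dmax == pytest.approx(2 * R, rel=0.05)

    def test_ift_requires_errors(self):
        prof = rf.ScatteringProfile(np.linspace(0.01, 0.3, 50), np.ones(50))
        with pytest.raises(ValueError, match="errors"):
            rf.ift_estimate(prof, dmax_scan=np.array([50.0]))


class TestChi:
    def _noisy_pair(self):
        s = np.linspace(0.01, 0.3, 100)
        I = np.exp(-(s**2) * 400)
        sigma = np.full_like(I, 0.01 * I.max())  # constant absolute error
        return rf.ScatteringProfile(s, I, sigma), rf.ScatteringProfile(s, I)

    def test_identical_curves(self):
        exp, calc = self._noisy_pair()
        chi, c = rf.chi_discrepancy(exp, calc)
        assert chi == pytest.approx(0.0, abs=1e-10)
        assert c == pytest.approx(1.0)

    def test_scale_invariance(self):
        exp, calc = self._noisy_pair()
        scaled = rf.ScatteringProfile(calc.s, 2.7 * calc.intensity)
        chi, c = rf.chi_discrepancy(exp, scaled)
        assert chi == pytest.approx(0.0, abs=1e-10)
        assert c == pytest.approx(1 / 2.7)

    def test_one_sigma_offset_gives_chi_near_one(self):
        exp, calc = self._noisy_pair()
        shifted = rf.ScatteringProfile(exp.s, exp.intensity + exp.sigma, exp.sigma)
        chi, _ = rf.chi_discrepancy(shifted, calc)
        # the scale refit absorbs part of the 1σ offset; χ stays order one
        assert 0.5 < chi <= 1.0 + 1e-9

    def test_disjoint_grids_rejected(self):
        a = rf.ScatteringProfile(np.linspace(0.01, 0.1, 30), np.ones(30), np.ones(30))
        b = rf.ScatteringProfile(np.linspace(0.5, 0.9, 30), np.ones(30))
        with pytest.raises(ValueError, match="overlap"):
            rf.chi_discrepancy(a, b)


class TestMixture:
    def test_single_matching_basis(self):
        s = np.linspace(0.01, 0.3, 80)
        I = np.exp(-(s**2) * 500)
        exp = rf.ScatteringProfile(s, I, 0.01 * I)
        fit = rf.fit_mixture(exp, [rf.ScatteringProfile(s, 3 * I)], ["self"])
        assert fit.weights[0] == pytest.approx(1.0)
        assert fit.chi == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_without_noise(self, ring_c6, ring_c2_like, ring_c3_like):
        s = np.linspace(0.005, 0.35, 120)
        basis = [rf.debye_profile(c, s) for c in (ring_c2_like, ring_c3_like, ring_c6)]
        w_true = np.array([0.3, 0.15, 0.55])
        I_mix = sum(w * b.intensity for w, b in zip(w_true, basis))
        exp = rf.ScatteringProfile(s, I_mix, 0.01 * I_mix)
        fit = rf.fit_mixture(exp, basis)
        np.testing.assert_allclose(fit.weights, w_true, atol=1e-8)
        assert fit.chi < 1e-9

    def test_planted_ternary_with_noise(self, ring_c6, ring_c2_like, ring_c3_like):
        s = np.linspace(0.005, 0.5, 200)
        basis = [rf.debye_profile(c, s) for c in (ring_c2_like, ring_c3_like, ring_c6)]
        w_true = np.array([0.3, 0.15, 0.55])
        I_mix = sum(w * b.intensity for w, b in zip(w_true, basis))
        obs = rf.simulate_sas_curve(
            rf.ScatteringProfile(s, I_mix), rf.NoiseModel(rel_floor=0.01, seed=3)
        )
        fit = rf.fit_mixture(obs, basis, ["C2", "C3", "C6B"])
        assert np.abs(fit.weights - w_true).max() < 0.05

    @given(st.integers(0, 500))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_weights_always_in_simplex(self, seed):
        rng = np.random.default_rng(seed)
        s = np.linspace(0.01, 0.3, 40)
        basis = [
            rf.ScatteringProfile(s, np.abs(rng.lognormal(0, 1, 40)) + 0.1)
            for _ in range(3)
        ]
        I = np.abs(rng.lognormal(0, 1, 40)) + 0.1
        exp = rf.ScatteringProfile(s, I, 0.05 * I)
        fit = rf.fit_mixture(exp, basis)
        assert np.all(fit.weights >= -1e-12)
        assert fit.weights.sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def pool_setup(ring_c6):
    modes = rf.anm_modes(ring_c6, n_modes=10)
    decoys = rf.perturb_along_modes(ring_c6, modes, [2.0] * 4, 30, seed=42)
    kw = dict(inner_beads=20, outer_beads=30)
    open_ring = rf.toy_calpha(rf.ToyRingSpec(**kw, angles_deg=(70,) * 6))
    half_open = rf.toy_calpha(
        rf.ToyRingSpec(**kw, angles_deg=(0, 110, 0, 110, 0, 110))
    )
    s = np.linspace(0.005, 0.35, 120)
    pool = [rf.debye_profile(c, s) for c in decoys + [open_ring, half_open]]
    return s, pool


class TestEnsembleGA:
    def test_planted_singleton_found(self, pool_setup):
        s, pool = pool_setup
        obs = rf.simulate_sas_curve(pool[30], rf.NoiseModel(rel_floor=0.01, seed=5))
        sel = rf.select_ensemble_ga(
            obs, pool, 1, rf.GASettings(population=40, generations=40), seed=0
        )
        assert sel.members == [30]
        assert sel.chi < 1.5

    def test_fitness_trace_non_increasing(self, pool_setup):
        s, pool = pool_setup
        obs = rf.simulate_sas_curve(pool[3], rf.NoiseModel(rel_floor=0.02, seed=6))
        sel = rf.select_ensemble_ga(
            obs, pool, 3, rf.GASettings(population=30, generations=25), seed=1
        )
        assert np.all(np.diff(sel.chi_trace) <= 1e-12)

    def test_seed_reproducibility(self, pool_setup):
        s, pool = pool_setup
        obs = rf.simulate_sas_curve(pool[8], rf.NoiseModel(rel_floor=0.02, seed=7))
        g = rf.GASettings(population=20, generations=15)
        a = rf.select_ensemble_ga(obs, pool, 2, g, seed=9)
        b = rf.select_ensemble_ga(obs, pool, 2, g, seed=9)
        assert a.members == b.members and a.chi == b.chi

    def test_singleton_ga_dominates_single_model_chi(self, pool_setup):
        """With M=1 the GA must do at least as well as the best single curve."""
        s, pool = pool_setup
        obs = rf.simulate_sas_curve(pool[12], rf.NoiseModel(rel_floor=0.02, seed=8))
        sel = rf.select_ensemble_ga(
            obs, pool, 1, rf.GASettings(population=40, generations=40), seed=2
        )
        singles = [rf.chi_discrepancy(obs, p)[0] for p in pool]
        assert sel.chi <= min(singles) + 1e-9

    def test_pool_too_small_rejected(self, pool_setup):
        s, pool = pool_setup
        obs = rf.simulate_sas_curve(pool[0], rf.NoiseModel(seed=1))
        with pytest.raises(ValueError):
            rf.select_ensemble_ga(obs, pool, len(pool) + 1, seed=0)
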