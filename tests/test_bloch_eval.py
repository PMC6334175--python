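import numpy as np
import pytest

from conftest import bloch_matrix_mz
from mbverse import (
    GradientWaveform,
    RFWaveform,
    default_z_grid,
    flip_profile,
    nrmse_regions,
    offres_analysis,
    phase_deviation,
    refocus_profile,
    simulate_profile,
    spin_domain_sim,
)
from mbverse.bloch_eval import SliceProfile
from mbverse.girf import apply_girf, make_synthetic_girf
from mbverse.waveforms import GAMMA, GAMMA_BAR


class TestSpinDomainSim:
    def test_zero_rf_gives_zero_flip(self):
        rf = RFWaveform(np.zeros(32), 0.01)
        g = GradientWaveform.constant(10.0, 32, 0.01)
        a, b = spin_domain_sim(rf, g, np.linspace(-5, 5, 11))
        assert np.max(np.abs(b)) == 0.0
        assert np.allclose(np.abs(a), 1.0)

    def test_90_degree_hard_pulse(self):
        dt = 0.001
        rf = RFWaveform(np.full(10, np.pi / 2 / (GAMMA * 10 * dt)), dt)
        g = GradientWaveform(np.zeros(10), dt)
        a, b = spin_domain_sim(rf, g, np.array([0.0]))
        theta = flip_profile(a, b)
        assert abs(np.degrees(theta[0]) - 90.0) < 1e-6

    def test_matches_rotation_matrix_integrator(self, sb4):
        rf, g = sb4
        # thin the pulse so the python-loop oracle stays fast
        rf_c = RFWaveform(rf.samples[::8] , rf.dt * 8)
        g_c = GradientWaveform(g.samples[::8], g.dt * 8)
        rng = np.random.default_rng(11)
        zs = rng.uniform(-8, 8, 50)
        a, b = spin_domain_sim(rf_c, g_c, zs)
        mz_sim = 1.0 - 2.0 * np.abs(b) ** 2
        for z, mz in zip(zs, mz_sim):
            assert abs(bloch_matrix_mz(rf_c, g_c, z) - mz) < 1e-8

    def test_unitarity(self, mb3):
        mb, g = mb3
        a, b = spin_domain_sim(mb, g, np.linspace(-60, 60, 201))
        assert np.max(np.abs(np.abs(a) ** 2 + np.abs(b) ** 2 - 1)) < 1e-9

    def test_event_compression_matches_dense(self):
        # blipped pulse: zero-RF runs and constant-RF runs must compress
        # without changing the result
        rng = np.random.default_rng(2)
        rf = np.zeros(300, dtype=complex)
        g = np.zeros(300)
        rf[10:20] = 4.0
        g[30:60] = rng.uniform(5, 20)
        rf[80:95] = 2.5 - 1j
        g[120:200] = 13.0
        rfw, gw = RFWaveform(rf, 0.002), GradientWaveform(g, 0.002)
        z = np.linspace(-20, 20, 41)
        a1, b1 = spin_domain_sim(rfw, gw, z)
        # force the dense path by adding a negligible RF everywhere
        rf2 = rf + 1e-300
        a2, b2 = spin_domain_sim(RFWaveform(rf2, 0.002), gw, z)
        assert np.max(np.abs(b1 - b2)) < 1e-12


class TestProfiles:
    def test_flip_extremes(self):
        assert flip_profile(np.array([0.0]), np.array([1.0]))[0] == pytest.approx(np.pi)
        assert flip_profile(np.array([1.0]), np.array([0.0]))[0] == 0.0

    def test_beta_sq_magnitude_identity(self):
        b = np.array([0.3 + 0.4j])
        assert abs(refocus_profile(None, b)[0]) == pytest.approx(abs(b[0]) ** 2)

    def test_linear_phase_profile_is_even(self):
        # at 90° the spectral factorization is numerically exact; the 180°
        # refocusing designs reach ~2e-6 (tangential zeros of 1-|B|^2)
        from mbverse.slr_design import SLRFilterSpec, design_beta_filter, inverse_slr

        b = design_beta_filter(SLRFilterSpec(n_samples=512, tbp=4.0))
        rf = inverse_slr(b, np.pi / 2, 0.0046)
        g = GradientWaveform.constant(20.0, rf.n, rf.dt)
        z = np.linspace(-6, 6, 97)
        a, bb = spin_domain_sim(rf, g, z)
        theta = flip_profile(a, bb)
        assert np.max(np.abs(theta - theta[::-1])) < 1e-6
        # amplitude symmetry of the pulse itself
        s = np.abs(rf.samples)
        assert np.max(np.abs(s - s[::-1])) < 1e-8 * s.max()


class TestNrmseRegions:
    def _profile(self, z, flip, fov):
        return SliceProfile(z, flip, np.sin(flip / 2) ** 2 + 0j, fov)

    def test_identical_profiles_zero(self, sb4):
        rf, g = sb4
        z = default_z_grid(20.0, 2.0)
        p = simulate_profile(rf, g, z, 20.0)
        assert nrmse_regions(p, p) == (0.0, 0.0)

    def test_ghost_fixture_against_direct_sum(self):
        # N main slices inside, one ghost of the same shape outside
        fov, n_slices = 80.0, 4
        z = np.linspace(-1.5 * fov, 1.5 * fov, 4001)
        slice_shape = lambda c: np.pi * np.exp(-((z - c) ** 2) / 2.0)
        target = sum(slice_shape(c) for c in (-30, -10, 10, 30))
        ghost = 0.25 * slice_shape(55.0)
        p_t = self._profile(z, target, fov)
        p_d = self._profile(z, target + ghost, fov)
        eps_in, eps_out = nrmse_regions(p_d, p_t)
        inside = np.abs(z) <= fov / 2
        outside = (np.abs(z) > fov / 2) & (np.abs(z) <= 1.5 * fov)
        denom = np.sqrt(np.mean(target[inside] ** 2))
        assert eps_in == pytest.approx(0.0)
        assert eps_out == pytest.approx(
            np.sqrt(np.mean(ghost[outside] ** 2)) / denom, rel=1e-12)

    def test_eps_linear_in_ghost_amplitude(self):
        fov = 80.0
        z = np.linspace(-1.5 * fov, 1.5 * fov, 2001)
        target = np.pi * np.exp(-(z**2) / 2.0)
        ghost = np.exp(-((z - 60.0) ** 2) / 2.0)
        p_t = self._profile(z, target, fov)
        e1 = nrmse_regions(self._profile(z, target + 0.1 * ghost, fov), p_t)[1]
        e2 = nrmse_regions(self._profile(z, target + 0.2 * ghost, fov), p_t)[1]
        assert e2 == pytest.approx(2 * e1, abs=1e-9)

    def test_zero_target_raises(self):
        z = np.linspace(-30, 30, 301)
        p = self._profile(z, np.zeros_like(z), 20.0)
        with pytest.raises(ZeroDivisionError):
            nrmse_regions(p, p)


class TestPhaseDeviation:
    def test_identity_girf_gives_zero(self, sb4):
        rf, g = sb4
        z = default_z_grid(20.0, 2.0)
        dev = phase_deviation(rf, g, g, z, [0.0], 20.0)
        assert dev < 1e-9

    def test_pure_delay_removed_as_linear_roll(self, sb4):
        rf, g = sb4
        girf = make_synthetic_girf(fwhm=1e4, delay=2.0, f_max=1.5e5, df=0.5)
        g_act = apply_girf(g, girf)
        z = default_z_grid(20.0, 2.0)
        dev = phase_deviation(rf, g, g_act, z, [0.0], 20.0)
        assert dev < 0.2  # degrees

    def test_synthetic_quadratic_perturbation(self, sb4):
        # a hand-built quadratic in-slice phase of 3° amplitude survives the
        # linear-roll removal; compare against a direct computation
        rf, g = sb4
        z = default_z_grid(20.0, 2.0)
        scale = 0.25
        a_i, b_i = spin_domain_sim(rf.scaled(scale), g, z)
        amp = np.radians(3.0)
        halfw = 1.0
        quad = amp * np.clip(z / halfw, -1, 1) ** 2
        b_d = b_i * np.exp(1j * quad / 1.0)
        from mbverse.bloch_eval import _in_slice_mask, flip_profile

        mask = _in_slice_mask(flip_profile(a_i, b_i), z, [0.0], 20.0)
        expect_raw = quad[mask]
        coef = np.polyfit(z[mask], expect_raw, 1)
        expected = np.degrees(np.mean(np.abs(expect_raw - np.polyval(coef, z[mask]))))
        # direct call with a fabricated distorted simulation is not possible
        # through the public API; replicate its final stage instead
        dphi = np.angle(b_d[mask] * np.conj(b_i[mask]))
        coef2 = np.polyfit(z[mask], np.unwrap(dphi), 1)
        got = np.degrees(np.mean(np.abs(np.unwrap(dphi) - np.polyval(coef2, z[mask]))))
        assert got == pytest.approx(expected, rel=1e-6)


class TestOffResonance:
    def test_zero_frequency_reference(self, sb4):
        rf, g = sb4
        z = default_z_grid(20.0, 2.0)
        res = offres_analysis(rf, g, z, 0.0, 4.0, df_grid=[0.0, 100.0])
        assert res.shift[0] == 0.0
        assert res.distortion_nrmse[0] == 0.0

    def test_constant_gradient_chemical_shift(self, sb4):
        rf, g = sb4
        z = default_z_grid(20.0, 2.0)
        res = offres_analysis(rf, g, z, 0.0, 4.0, df_grid=[0.0, 100.0, 200.0])
        g0 = g.samples[0]
        for df, shift in zip(res.df_axis[1:], res.shift[1:]):
            expected = -df * 1e-3 / (GAMMA_BAR * g0)  # mm; sign per convention
            assert abs(abs(shift) - abs(expected)) < 0.15

    def test_longer_pulse_shifts_more(self, sb4):
        from mbverse.verse import stretch_to_duration

        rf, g = sb4
        stretched = stretch_to_duration(rf, g, 2.0 * rf.duration)
        z = default_z_grid(20.0, 2.0)
        r1 = offres_analysis(rf, g, z, 0.0, 4.0, df_grid=[0.0, 150.0])
        r2 = offres_analysis(stretched.rf, stretched.g, z, 0.0, 4.0,
                             df_grid=[0.0, 150.0])
        assert abs(r2.shift[1]) >= abs(r1.shift[1])


def test_grid_convergence(sb4):
    rf, g = sb4
    girf = make_synthetic_girf(fwhm=12.0)
    g_act = apply_girf(g, girf)
    eps = []
    for pps in (16, 32):
        z = default_z_grid(20.0, 2.0, points_per_slice=pps)
        tgt = simulate_profile(rf, g, z, 20.0)
        dist = simulate_profile(rf, g_act, z, 20.0)
        eps.append(nrmse_regions(dist, tgt))
    for a, b in zip(*eps):
        assert abs(a - b) / max(a, 1e-12) < 0.02
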