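import numpy as np
import pytest

import cochlearhorn as ch
from cochlearhorn import wkb
from cochlearhorn.micromechanics import admittance

from conftest import make_profile


class TestSeriesImpedance:
    def test_pure_mass_reactance(self, cat_profile):
        z = wkb.series_impedance(cat_profile, 1234.0)
        assert np.all(z.real == 0.0)
        assert np.all(z.imag > 0.0)

    def test_magnitude_scales_inverse_area(self, cat_map):
        p1 = make_profile(cat_map, lambda x: np.full_like(x, 1e-6),
                          lambda x: np.full_like(x, 1e-3),
                          lambda x: np.full_like(x, 2e-4),
                          lambda x: np.full_like(x, 1e9), n=64)
        p2 = make_profile(cat_map, lambda x: np.full_like(x, 5e-7),
                          lambda x: np.full_like(x, 1e-3),
                          lambda x: np.full_like(x, 2e-4),
                          lambda x: np.full_like(x, 1e9), n=64)
        z1 = wkb.series_impedance(p1, 1000.0)
        z2 = wkb.series_impedance(p2, 1000.0)
        assert np.allclose(np.abs(z2), 2 * np.abs(z1))
        # rho=1000, b=2e-4, S=1e-6, f=1 kHz -> 2*pi*1e3*1000*2e-4/1e-6
        assert abs(z1[0]) == pytest.approx(1.2566e9, rel=1e-3)


class TestAlphaOf:
    def test_longwave_limit_is_one(self):
        assert wkb.alpha_of(0.0) == pytest.approx(1.0)
        assert wkb.alpha_of(1e-8 + 1e-8j) == pytest.approx(1.0, abs=1e-12)

    def test_shortwave_real_value(self):
        assert wkb.alpha_of(5.0) == pytest.approx(5.0 / np.tanh(5.0), rel=1e-12)
        assert wkb.alpha_of(5.0) == pytest.approx(5.0005, abs=1e-3)

    def test_imaginary_argument(self):
        # tanh(i pi/4) = i, so alpha = pi/4
        assert wkb.alpha_of(1j * np.pi / 4) == pytest.approx(np.pi / 4, rel=1e-12)

    def test_even_function(self):
        for z in (0.3 + 0.2j, 2.0 - 1.0j, 1e-4j):
            assert wkb.alpha_of(z) == pytest.approx(wkb.alpha_of(-z), rel=1e-12)

    def test_pole_raises(self):
        with pytest.raises(ZeroDivisionError):
            wkb.alpha_of(1j * np.pi)


class TestWavenumber:
    def test_longwave_tail_is_real(self):
        # alpha=1, Y=i w/k, Z=i w m: kappa = w sqrt(m/k)
        w = 2 * np.pi * 500.0
        kap = wkb.wavenumber(1.0, 1j * w * 1e5, 1j * w / 4e9)
        assert kap.imag == pytest.approx(0.0, abs=1e-12)
        assert kap.real == pytest.approx(w * np.sqrt(1e5 / 4e9), rel=1e-12)

    def test_passive_damping_gives_decay(self):
        w = 2 * np.pi * 500.0
        D = 1 - 0.25 + 0.1j * 0.5  # passive below resonance
        kap = wkb.wavenumber(1.0, 1j * w * 1e5, 1j * w / (4e9 * D))
        assert kap.real > 0 and kap.imag < 0

    def test_tie_break_decaying(self):
        # beyond cutoff with no damping: -alpha*Z*Y real negative -> kappa imaginary
        w = 2 * np.pi * 500.0
        D = 1 - 4.0  # real, negative
        kap = wkb.wavenumber(1.0, 1j * w * 1e5, 1j * w / (4e9 * D))
        assert kap.real == pytest.approx(0.0, abs=1e-15)
        assert kap.imag < 0

    def test_shortwave_closed_form_fixed_point(self, cat_map):
        """At the self-consistent short-wave point alpha = kappa*h, the
        dispersion relation collapses to kappa = -Zbar*Y*h."""
        h = 1.5e-3
        Zbar = 1j * 2 * np.pi * 8000.0 * 1e5
        Y = 1j * 2 * np.pi * 8000.0 / (4e7 * (1 - 0.9**2 + 0.3j))
        kap_closed = -Zbar * Y * h
        alpha = kap_closed * h / np.tanh(kap_closed * h)
        kap = wkb.wavenumber(alpha, Zbar, Y)
        # only meaningful when |kappa h| >> 1 so tanh ~ 1
        assert abs(kap_closed * h) > 3
        assert kap == pytest.approx(kap_closed, rel=0.05)


class TestSolveAlphaKappa:
    def test_longwave_converges_fast(self, cat_profile, tail_micro):
        fld = wkb.solve_alpha_kappa(cat_profile, tail_micro, 5.0)
        assert fld.converged
        assert fld.iterations <= 2
        assert np.allclose(fld.alpha, 1.0, atol=1e-3)

    def test_fixed_point_self_consistency(self, cat_profile, passive_micro):
        f = 3000.0
        fld = wkb.solve_alpha_kappa(cat_profile, passive_micro, f, tol=1e-8)
        assert fld.converged
        Y = admittance(passive_micro, cat_profile.k, cat_profile.cf, f)
        Z = wkb.series_impedance(cat_profile, f)
        lhs = fld.kappa**2
        rhs = -wkb.alpha_of(fld.kappa * cat_profile.h) * Z * Y
        assert np.max(np.abs(lhs - rhs) / np.abs(lhs)) < 1e-6

    def test_active_model_converges_everywhere(self, cat_profile):
        micro = ch.MicromechanicsParams()
        for f in (300.0, 3000.0, 9000.0):
            fld = wkb.solve_alpha_kappa(cat_profile, micro, f)
            assert fld.converged, f

    def test_deep_shortwave_matches_closed_form(self, cat_map):
        # strongly short-wave at the basal point: large kappa*h, modest damping
        prof = make_profile(
            cat_map,
            lambda x: np.full_like(x, 1e-6), lambda x: np.full_like(x, 3e-3),
            lambda x: np.full_like(x, 1e-4), lambda x: np.full_like(x, 1e9),
            n=128)
        micro = ch.MicromechanicsParams(mode="passive", delta=0.5, rho_f=0.0)
        f = 0.9 * prof.cf[0]
        fld = wkb.solve_alpha_kappa(prof, micro, f, tol=1e-10)
        Y = admittance(micro, prof.k[0], prof.cf[0], f)
        Z = wkb.series_impedance(prof, f)[0]
        closed = wkb.select_bounded_branch(-Z * Y * prof.h[0])
        assert abs(fld.kappa[0] * prof.h[0]) > 5
        assert fld.kappa[0] == pytest.approx(closed, rel=0.01)


class TestWkbPressureAndVelocity:
    def test_basal_normalization(self, cat_profile, tail_micro):
        fld = wkb.solve_alpha_kappa(cat_profile, tail_micro, 50.0)
        wkb.wkb_pressure(cat_profile, fld)
        assert fld.P0[0] == pytest.approx(fld.alpha[0], rel=1e-12)

    def test_linearity_in_drive(self, cat_profile, passive_micro):
        fld1 = wkb.wkb_pressure(cat_profile,
                                wkb.solve_alpha_kappa(cat_profile, passive_micro, 800.0))
        fld2 = wkb.wkb_pressure(cat_profile,
                                wkb.solve_alpha_kappa(cat_profile, passive_micro, 800.0),
                                drive=2.0)
        assert np.allclose(fld2.P0, 2 * fld1.P0)

    def test_tail_velocity_quadrature_and_magnitude(self, cat_profile, tail_micro):
        f = 40.0
        fld = wkb.wkb_pressure(cat_profile, wkb.solve_alpha_kappa(cat_profile, tail_micro, f))
        wkb.partition_velocity(fld, cat_profile, tail_micro)
        # stiffness-dominated: V leads P0 by 90 deg, |V| = 2 pi f |P0| / k
        dphi = np.angle(fld.Vcp / fld.P0)
        assert np.allclose(dphi, np.pi / 2, atol=1e-12)
        assert np.allclose(np.abs(fld.Vcp),
                           2 * np.pi * f * np.abs(fld.P0) / cat_profile.k)

    def test_longwave_alpha_one_p0_equals_pbar(self, cat_profile, tail_micro):
        fld = wkb.wkb_pressure(cat_profile, wkb.solve_alpha_kappa(cat_profile, tail_micro, 20.0))
        kh = np.abs(fld.kappa * cat_profile.h)
        assert np.all(kh < 0.1)
        assert np.allclose(fld.alpha, 1.0, atol=2e-3)

    def test_shortwave_alpha_exceeds_one_and_grows(self, cat_profile):
        micro = ch.MicromechanicsParams(mode="passive", delta=0.3, rho_f=0.0)
        fld = wkb.solve_alpha_kappa(cat_profile, micro, 6000.0)
        kh = np.abs(fld.kappa * cat_profile.h)
        sw = kh > 1.5
        assert sw.any()
        assert np.all(np.abs(fld.alpha[sw]) > 1.0)
        # |alpha| increases with |kappa h| in the short-wave region
        order = np.argsort(kh[sw])
        a = np.abs(fld.alpha[sw])[order]
        assert np.corrcoef(kh[sw][order], a)[0, 1] > 0.9


class TestCharacteristicImpedance:
    def test_tail_limit_real_sqrt_mk(self, cat_profile, tail_micro):
        z0 = wkb.characteristic_impedance(cat_profile, tail_micro, 40.0)
        assert np.allclose(z0.imag, 0.0, atol=1e-9 * np.abs(z0).max())
        assert np.allclose(z0.real, np.sqrt(cat_profile.m_bar * cat_profile.k))

    def test_tapering_symmetry_constant_in_base(self, cat_map, tail_micro):
        prof = ch.build_geometry(cat_map, ch.TaperParams(b1=1e-4), 2048)
        z0 = wkb.characteristic_impedance(prof, tail_micro, 40.0)
        half = prof.x <= cat_map.L / 2
        mag = np.abs(z0[half])
        assert mag.max() / mag.min() - 1 < 0.10


class TestHornFdOracle:
    def test_uniform_duct_plane_wave(self, cat_map):
        prof = make_profile(
            cat_map,
            lambda x: np.full_like(x, 1e-6), lambda x: np.full_like(x, 1e-3),
            lambda x: np.full_like(x, 1e-4), lambda x: np.full_like(x, 1e9),
            n=2048)
        kap = np.full(2048, 800.0 + 0.0j)  # ~3 mm wavelength
        p = wkb.solve_horn_fd(prof, kap)
        expect = np.exp(-1j * kap[0] * prof.x)
        assert np.max(np.abs(p - expect)) < 2e-3

    def test_uniform_duct_residual_second_order(self, cat_map):
        errs = []
        for n in (1024, 2048):
            prof = make_profile(
                cat_map,
                lambda x: np.full_like(x, 1e-6), lambda x: np.full_like(x, 1e-3),
                lambda x: np.full_like(x, 1e-4), lambda x: np.full_like(x, 1e9),
                n=n)
            kap = np.full(n, 600.0 + 0.0j)
            pbar = np.exp(-1j * kap * prof.x)
            r = wkb.horn_residual(prof, kap, pbar)
            errs.append(np.max(np.abs(r[1:-1])))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)

    def test_wkb_matches_fd_in_slowly_varying_region(self, cat_profile, passive_micro):
        f = 6000.0
        fld = wkb.wkb_pressure(cat_profile,
                               wkb.solve_alpha_kappa(cat_profile, passive_micro, f))
        pbar_wkb = fld.P0 / fld.alpha
        pfd = wkb.solve_horn_fd(cat_profile, fld.kappa, basal_drive=pbar_wkb[0])
        slow = np.abs(np.gradient(1 / fld.kappa, cat_profile.x)) < 0.3
        keep = slow & (np.abs(pbar_wkb) > 1e-3 * np.abs(pbar_wkb).max())
        rel = np.abs(np.abs(pfd[keep]) - np.abs(pbar_wkb[keep])) / np.abs(pbar_wkb[keep])
        assert rel.max() < 0.05

    def test_wkb_residual_small_in_tail(self, cat_profile, tail_micro):
        f = 2000.0
        fld = wkb.wkb_pressure(cat_profile, wkb.solve_alpha_kappa(cat_profile, tail_micro, f))
        r = wkb.horn_residual(cat_profile, fld.kappa, fld.P0 / fld.alpha)
        tailish = cat_profile.cf > 4 * f
        assert np.max(np.abs(r[1:-1][tailish[1:-1]])) < 0.05

    def test_pressure_release_creates_standing_ripple(self, cat_profile, tail_micro):
        f = 1000.0
        fld = wkb.solve_alpha_kappa(cat_profile, tail_micro, f)
        p_out = wkb.solve_horn_fd(cat_profile, fld.kappa, apical_bc="outgoing")
        p_rel = wkb.solve_horn_fd(cat_profile, fld.kappa, apical_bc="pressure-release")
        assert abs(p_rel[-1]) < 1e-12

        def ripple(p):
            mag = np.abs(p[cat_profile.x < 0.8 * cat_profile.L])
            detr = mag / np.convolve(mag, np.ones(101) / 101, mode="same")
            return np.nanstd(detr[51:-51])

        assert ripple(p_rel) > 5 * ripple(p_out)
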