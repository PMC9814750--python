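"""Kubo lineshapes, 2D-IR simulation, CLS/lifetime/cross-peak extraction."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from ionspec.constants import WN_TO_ANG
from ionspec.ir2d import (
    FFCFModel, CoupledBandPair, TwoDIRSpectrum,
    kubo_lineshape, linear_absorption, linear_ir_baseline_normalize,
    simulate_2dir, gaussian_2dir, gaussian_2dir_from_ffcf,
    extract_cls, fit_cls_decay, peak_volume, fit_ver, cross_peak_kinetics,
)


def _axes(center, half=60.0, esa_extra=25.0, step=1.0):
    pump = np.arange(center - half, center + half + step / 2, step)
    probe = np.arange(center - half - esa_extra, center + half + step / 2, step)
    return pump, probe


class TestKuboLineshape:
    def test_quadrature_oracle(self):
        """g(t) closed form matches double quadrature of the FFCF < 1e-8."""
        m = FFCFModel(center=1660, components=[(10.0, 1.0)], T1=1.0,
                      anharmonicity=20)
        t = np.linspace(0.0, 5.0, 2001)
        d = 10.0 * WN_TO_ANG
        corr = d**2 * np.exp(-t / 1.0)
        inner = cumulative_trapezoid(corr, t, initial=0.0)
        g_quad = cumulative_trapezoid(inner, t, initial=0.0)
        g = kubo_lineshape(m, t)
        assert np.max(np.abs(g[1:] - g_quad[1:]) / np.abs(g[1:]).max()) < 1e-6

    def test_static_limit_gaussian(self):
        m = FFCFModel(center=1660, components=[(10.0, 1e4)], T1=1e6,
                      anharmonicity=20)
        wn = np.arange(1600, 1721, 0.1)
        A = linear_absorption(m, wn, include_lifetime=False)
        A = A / A.max()
        mu = np.sum(wn * A) / np.sum(A)
        sd = np.sqrt(np.sum((wn - mu) ** 2 * A) / np.sum(A))
        assert mu == pytest.approx(1660.0, abs=0.05)
        assert sd == pytest.approx(10.0, rel=0.01)

    def test_motional_narrowing_lorentzian_fwhm(self):
        # Delta*tau = 0.019 (angular): Lorentzian with FWHM 2 Delta^2 tau
        m = FFCFModel(center=1660, components=[(10.0, 0.01)], T1=1e6,
                      anharmonicity=20)
        wn = np.arange(1655, 1665.01, 0.005)
        A = linear_absorption(m, wn, include_lifetime=False)
        A = A / A.max()
        above = wn[A >= 0.5]
        fwhm_ang = (above[-1] - above[0]) * WN_TO_ANG
        assert fwhm_ang == pytest.approx(2 * (10 * WN_TO_ANG) ** 2 * 0.01,
                                         rel=0.03)

    def test_unresolved_fast_component_errors(self):
        m = FFCFModel(center=1660, components=[(10.0, 0.05)], T1=1.0,
                      anharmonicity=20)
        with pytest.raises(ValueError, match="resolve"):
            kubo_lineshape(m, np.arange(0.0, 2.0, 0.05))


class TestLinearIRBaseline:
    def _two_gauss(self, wn, ratio=0.8):
        return (np.exp(-0.5 * ((wn - 1660) / 12.0) ** 2)
                + ratio * np.exp(-0.5 * ((wn - 1590) / 9.0) ** 2))

    def test_pure_scaling(self):
        wn = np.arange(1480.0, 1781.0, 1.0)
        y = 2.0 * self._two_gauss(wn)
        _, out = linear_ir_baseline_normalize(wn, y)
        assert out.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out, y / y.max(), atol=1e-10)

    def test_baseline_invariance(self):
        wn = np.arange(1480.0, 1781.0, 1.0)
        y = self._two_gauss(wn)
        _, out0 = linear_ir_baseline_normalize(wn, y)
        _, out1 = linear_ir_baseline_normalize(wn, y + 0.3 + 0.002 * wn)
        np.testing.assert_allclose(out1, out0, atol=1e-10)

    def test_carboxylate_to_co_ratio_preserved(self):
        wn = np.arange(1480.0, 1781.0, 0.5)
        _, out = linear_ir_baseline_normalize(wn, self._two_gauss(wn, 0.8))
        coo = out[(wn >= 1570) & (wn <= 1610)].max()
        assert coo == pytest.approx(0.8, abs=0.005)

    def test_empty_anchor_errors(self):
        wn = np.arange(1480.0, 1781.0, 1.0)
        with pytest.raises(ValueError):
            linear_ir_baseline_normalize(wn, self._two_gauss(wn),
                                         anchor_low=(1400, 1401),
                                         anchor_high=(1400, 1401))


class TestSimulate2DIR:
    def test_homogeneous_band_has_zero_cls(self):
        m = FFCFModel(center=1660, components=[], T1=0.7, anharmonicity=20,
                      homogeneous_T2=0.66)
        pump, probe = _axes(1660, half=90)
        s = simulate_2dir(m, 0.0, pump, probe, coverage_threshold=0.1)
        assert abs(extract_cls(s, 1660, 20)) < 0.02

    def test_near_static_band_cls_near_one(self):
        m = FFCFModel(center=1660, components=[(8.0, 200.0)], T1=50.0,
                      anharmonicity=20)
        pump, probe = _axes(1660)
        s = simulate_2dir(m, 0.0, pump, probe, coverage_threshold=1.0)
        assert extract_cls(s, 1660, 20) == pytest.approx(1.0, abs=0.05)

    def test_50_50_split_matches_bivariate_gaussian_oracle(self):
        """Full engine vs closed-form doublet: < 5% peak-normalized RMS."""
        m = FFCFModel(center=1660, components=[(6.0, 100.0)], T1=50.0,
                      anharmonicity=20, homogeneous_T2=0.752)
        pump = np.arange(1600.0, 1721.0, 0.5)
        probe = np.arange(1575.0, 1721.0, 0.5)
        s = simulate_2dir(m, 0.0, pump, probe, coverage_threshold=1.0)
        g = gaussian_2dir_from_ffcf(m, 0.0, pump, probe)
        a = s.signal / np.abs(s.signal).max()
        b = g.signal / np.abs(g.signal).max()
        assert np.sqrt(np.mean((a - b) ** 2)) < 0.05

    def test_esa_offset_equals_anharmonicity(self):
        m = FFCFModel(center=1660, components=[(10.0, 1.0)], T1=0.7,
                      anharmonicity=60, homogeneous_T2=1.0)
        pump, probe = _axes(1660, half=80, esa_extra=100)
        s = simulate_2dir(m, 0.0, pump, probe, coverage_threshold=0.2)
        j = np.unravel_index(np.argmin(s.signal), s.signal.shape)[1]
        l = np.unravel_index(np.argmax(s.signal), s.signal.shape)[1]
        assert s.probe[j] - s.probe[l] == pytest.approx(60.0, abs=1.0)

    def test_linear_spectrum_equals_pump_marginal_of_bleach(self):
        m = FFCFModel(center=1660, components=[(10.0, 1.0)], T1=0.7,
                      anharmonicity=60, homogeneous_T2=1.0)
        pump, probe = _axes(1660, half=80, esa_extra=100)
        s = simulate_2dir(m, 0.0, pump, probe, coverage_threshold=0.2)
        marg = -s.signal[:, s.probe >= 1630].sum(axis=1)
        marg = marg / marg.max()
        lin = linear_absorption(m, pump)
        lin = lin / lin.max()
        assert np.max(np.abs(marg - lin)) < 0.05

    def test_cls_tracks_normalized_inhomogeneous_ffcf(self):
        """CLS(T2) ~ sum_s D_s^2 e^(-T2/tau_s)/sum D_s^2 when fast part is
        motionally narrowed and slow parts are genuinely inhomogeneous."""
        m = FFCFModel(center=1660, components=[(12.0, 10.0), (12.0, 40.0)],
                      T1=50.0, anharmonicity=20, homogeneous_T2=20.0)
        pump = np.arange(1560.0, 1761.0, 1.0)
        probe = np.arange(1535.0, 1761.0, 1.0)
        for T2 in (0.0, 5000.0, 10000.0, 20000.0):
            s = simulate_2dir(m, T2, pump, probe, coverage_threshold=1.0)
            cls = extract_cls(s, 1660, 20)
            assert cls == pytest.approx(m.ffcf_normalized(T2 / 1000.0), abs=0.05)

    def test_cls_bounded_for_gaussian_dynamics(self):
        for rho in (0.0, 0.3, 0.7, 1.0):
            g = gaussian_2dir(1660, 9.0, 9.0, min(rho, 0.995), 20,
                              *_axes(1660))
            cls = extract_cls(g, 1660, 20)
            assert -0.02 <= cls <= 1.02

    def test_coverage_error_on_narrow_axes(self):
        m = FFCFModel(center=1660, components=[(10.0, 1.0)], T1=0.7,
                      anharmonicity=20, homogeneous_T2=1.0)
        pump = np.arange(1650.0, 1671.0, 1.0)
        probe = np.arange(1640.0, 1671.0, 1.0)
        with pytest.raises(ValueError, match="too narrow"):
            simulate_2dir(m, 0.0, pump, probe)


class TestGaussianModel:
    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_cls_equals_correlation(self, rho):
        pump, probe = _axes(1660)
        g = gaussian_2dir(1660, 8.49, 8.49, rho, 20, pump, probe)
        assert extract_cls(g, 1660, 20) == pytest.approx(rho, abs=0.02)


class TestCLSDecayFit:
    def test_noiseless_exact_recovery(self):
        t2 = np.array([0.0, 250.0, 500.0, 1000.0, 2000.0])
        cls = 0.5 * np.exp(-(t2 / 1000.0) / 1.1)
        r = fit_cls_decay(t2, cls)
        assert r.cls0 == pytest.approx(0.5, rel=1e-6)
        assert r.decay_time_ps == pytest.approx(1.1, rel=1e-6)

    def test_constant_series_returns_zero_rate(self):
        t2 = np.array([0.0, 250.0, 500.0, 1000.0])
        r = fit_cls_decay(t2, np.full(4, 0.4))
        assert r.cls0 == pytest.approx(0.4)
        assert r.k == 0.0
        assert r.flag

    def test_fast_decay_monte_carlo_recovery(self):
        """Carboxylate-like 0.3 ps decay, 5% noise, 100 seeds: median in 10%."""
        t2 = np.array([0.0, 100.0, 200.0, 400.0, 700.0, 1100.0])
        true = 0.2 * np.exp(-(t2 / 1000.0) / 0.3)
        recov = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = true * (1 + 0.05 * rng.standard_normal(len(t2)))
            recov.append(fit_cls_decay(t2, noisy).decay_time_ps)
        assert np.median(recov) == pytest.approx(0.3, rel=0.10)

    def test_requires_t2_zero(self):
        with pytest.raises(ValueError):
            fit_cls_decay(np.array([100.0, 200.0, 300.0, 400.0]),
                          np.array([0.4, 0.3, 0.25, 0.2]))


class TestPeakVolumeAndVER:
    def _spec(self, amp=1.0):
        pump, probe = _axes(1660)
        x = (pump[:, None] - 1660) / 9.0
        y = (probe[None, :] - 1660) / 9.0
        sig = -amp * np.exp(-0.5 * (x**2 + y**2))
        return TwoDIRSpectrum(pump=pump, probe=probe, T2=0.0, signal=sig,
                              meta={"bands": [1660.0]})

    def test_volume_linearity(self):
        w = ((1620.0, 1700.0), (1620.0, 1700.0))
        v1 = peak_volume(self._spec(1.0), *w)
        v2 = peak_volume(self._spec(2.0), *w)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_gaussian_volume_closed_form(self):
        v = peak_volume(self._spec(1.0), (1600.0, 1720.0), (1600.0, 1720.0))
        assert v == pytest.approx(2 * np.pi * 9.0 * 9.0, rel=0.01)

    def test_volume_decay_matches_population_lifetime(self):
        m = FFCFModel(center=1660, components=[(10.0, 1.0)], T1=0.7,
                      anharmonicity=60, homogeneous_T2=1.0)
        pump, probe = _axes(1660, half=80, esa_extra=100)
        t2s = np.array([0.0, 250.0, 500.0, 1000.0, 1500.0, 2500.0])
        vols = [peak_volume(simulate_2dir(m, T2, pump, probe,
                                          coverage_threshold=0.2),
                            (1620.0, 1700.0), (1630.0, 1700.0))
                for T2 in t2s]
        r = fit_ver(t2s, vols, band="amideI")
        assert r.tau_VER == pytest.approx(0.7, rel=0.02)

    def test_ver_noiseless_exact(self):
        t2 = np.array([0.0, 200.0, 400.0, 800.0, 1600.0])
        vols = 3.0 * np.exp(-(t2 / 1000.0) / 0.4)
        r = fit_ver(t2, vols)
        assert r.tau_VER == pytest.approx(0.4, rel=1e-6)

    def test_ver_monte_carlo_recovery(self):
        t2 = np.array([0.0, 200.0, 400.0, 800.0, 1200.0, 2000.0])
        true = np.exp(-(t2 / 1000.0) / 0.7)
        recov = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = true * (1 + 0.05 * rng.standard_normal(len(t2)))
            recov.append(fit_ver(t2, noisy).tau_VER)
        assert np.median(recov) == pytest.approx(0.7, rel=0.10)

    def test_non_decaying_series_flagged(self):
        t2 = np.array([0.0, 200.0, 400.0, 800.0])
        r = fit_ver(t2, np.array([1.0, 1.1, 1.2, 1.3]))
        assert r.flag == "non-decaying series"


class TestCrossPeaks:
    @staticmethod
    def _pair(amplitude):
        a = FFCFModel(center=1660, components=[(14.0, 1.1)], T1=0.7,
                      anharmonicity=20, homogeneous_T2=2.0)
        b = FFCFModel(center=1590, components=[(18.0, 0.3)], T1=0.4,
                      anharmonicity=18, homogeneous_T2=0.667)
        return CoupledBandPair(band_a=a, band_b=b,
                               coupling_amplitude=amplitude,
                               k_rise=10.0, k_decay=2.5)

    @staticmethod
    def _axes_pair():
        pump = np.arange(1520.0, 1741.0, 1.0)
        probe = np.arange(1495.0, 1741.0, 1.0)
        return pump, probe

    def test_kinetic_time_of_maximum(self):
        """k_rise = 10/ps, k_decay = 2.5/ps: t_max = ln(4)/7.5 ps ~ 185 fs."""
        pump, probe = self._axes_pair()
        t2s = (0.0, 100.0, 200.0, 400.0, 700.0, 1100.0, 1600.0)
        base = [simulate_2dir(self._pair(0.0), T2, pump, probe,
                              coverage_threshold=0.1) for T2 in t2s]
        coup = [simulate_2dir(self._pair(0.1), T2, pump, probe,
                              coverage_threshold=0.1) for T2 in t2s]
        win = ((1650.0, 1690.0), (1578.0, 1602.0))
        # subtract diagonal-tail leakage using the uncoupled reference
        diff = []
        for s0, s1 in zip(base, coup):
            s = TwoDIRSpectrum(pump=pump, probe=probe, T2=s1.T2,
                               signal=s1.signal - s0.signal,
                               meta={"bands": [1660.0, 1590.0]})
            diff.append(s)
        res = cross_peak_kinetics(diff, *win)
        assert res["detected"]
        expected = 1000.0 * np.log(4.0) / 7.5
        assert res["t_max_fs"] == pytest.approx(expected, rel=0.10)

    def test_uncoupled_pair_has_no_cross_peak(self):
        pump, probe = self._axes_pair()
        t2s = (0.0, 200.0, 400.0, 800.0)
        base = [simulate_2dir(self._pair(0.0), T2, pump, probe,
                              coverage_threshold=0.1) for T2 in t2s]
        coup = [simulate_2dir(self._pair(0.1), T2, pump, probe,
                              coverage_threshold=0.1) for T2 in t2s]
        win = ((1650.0, 1690.0), (1578.0, 1602.0))
        floor = 1.2 * max(peak_volume(s, *win) for s in base)
        res = cross_peak_kinetics(base, *win, noise_floor=floor)
        assert not res["detected"]
        res2 = cross_peak_kinetics(coup, *win, noise_floor=floor)
        assert res2["detected"]

    def test_cross_peak_volume_linear_in_coupling(self):
        pump, probe = self._axes_pair()
        T2 = 200.0
        s0 = simulate_2dir(self._pair(0.0), T2, pump, probe,
                           coverage_threshold=0.1)
        s1 = simulate_2dir(self._pair(0.05), T2, pump, probe,
                           coverage_threshold=0.1)
        s2 = simulate_2dir(self._pair(0.10), T2, pump, probe,
                           coverage_threshold=0.1)
        win = ((1650.0, 1690.0), (1578.0, 1602.0))
        v1 = peak_volume(TwoDIRSpectrum(pump, probe, T2, s1.signal - s0.signal,
                                        {"bands": []}), *win)
        v2 = peak_volume(TwoDIRSpectrum(pump, probe, T2, s2.signal - s0.signal,
                                        {"bands": []}), *win)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-6)
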