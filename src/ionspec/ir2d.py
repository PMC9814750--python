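"""Linear-IR and 2D-IR simulation and analysis for peptide carbonyl bands.

The amide I (~1660 cm-1) and anti-symmetric carboxylate (~1590 cm-1) stretch
bands report on the local environment of the dipeptide's C=O groups.  Band
frequency fluctuations are described by a frequency-fluctuation correlation
function (FFCF)

    C(t) = sum_i Delta_i^2 exp(-t/tau_i)   [+ a pure-dephasing term]

from which the Kubo line-broadening function g(t) follows.  Two spectrum
constructions are provided deliberately:

* a full third-order response-function engine (rephasing + non-rephasing,
  impulsive pulses, purely absorptive spectra) -- the simulation used by the
  analysis chain, and
* a fast bivariate-Gaussian bleach/ESA model -- the closed-form oracle the
  engine is validated against.

Analysis operations extract center line slopes CLS(T2) (a proxy for the
normalized inhomogeneous FFCF), their exponential decay (spectral diffusion),
bleach peak volumes and the vibrational lifetime tau_VER, and cross-peak
rise/decay kinetics (vibrational energy transfer).

Sign convention: bleach / stimulated emission negative, excited-state
absorption (red-shifted by the anharmonicity on the probe axis) positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

from .constants import WN_TO_ANG

__all__ = [
    "FFCFModel",
    "CoupledBandPair",
    "TwoDIRSpectrum",
    "CLSResult",
    "VERResult",
    "kubo_lineshape",
    "linear_absorption",
    "linear_ir_baseline_normalize",
    "simulate_2dir",
    "gaussian_2dir",
    "gaussian_2dir_from_ffcf",
    "extract_cls",
    "fit_cls_decay",
    "peak_volume",
    "fit_ver",
    "cross_peak_kinetics",
]


@dataclass
class FFCFModel:
    """FFCF + band parameters that generate/characterize one 2D-IR band.

    components: list of (Delta_i [cm-1], tau_i [ps]) fluctuation amplitudes and
    correlation times; a component with Delta*tau (angular) << 1 is motionally
    narrowed and contributes homogeneous Lorentzian broadening only.
    homogeneous_T2: optional pure-dephasing time (ps), equivalent to a fully
    motionally narrowed component with Gamma = 1/T2.
    """

    center: float                      # cm-1
    components: list                   # [(Delta_cm, tau_ps), ...]
    T1: float = 0.7                    # population lifetime, ps
    anharmonicity: float = 20.0        # ESA red-shift, cm-1
    homogeneous_T2: float | None = None  # ps
    transition_strength: float = 1.0

    def __post_init__(self):
        self.components = sorted(
            [(float(d), float(t)) for d, t in self.components], key=lambda c: c[1])
        for d, t in self.components:
            if d <= 0 or t <= 0:
                raise ValueError("Delta_i and tau_i must be positive")
        if self.T1 <= 0 or self.anharmonicity <= 0:
            raise ValueError("T1 and anharmonicity must be positive")

    @property
    def inhomogeneous_variance(self) -> float:
        """Total FFCF variance (angular units, rad^2/ps^2)."""
        return sum((d * WN_TO_ANG) ** 2 for d, _ in self.components)

    def ffcf_normalized(self, t_ps) -> np.ndarray:
        """Normalized FFCF sum_i Delta_i^2 exp(-t/tau_i) / sum_i Delta_i^2."""
        t = np.asarray(t_ps, dtype=float)
        if not self.components:
            return np.zeros_like(t)
        num = sum((d * WN_TO_ANG) ** 2 * np.exp(-t / tau) for d, tau in self.components)
        return num / self.inhomogeneous_variance


@dataclass
class CoupledBandPair:
    """Two bands with vibrational energy transfer feeding cross peaks.

    The transfer channel rises with k_rise and decays with k_decay; the
    cross-peak amplitude is coupling_amplitude * (exp(-k_decay t) -
    exp(-k_rise t)), maximal at t_max = ln(k_rise/k_decay)/(k_rise-k_decay).
    """

    band_a: FFCFModel
    band_b: FFCFModel
    coupling_amplitude: float = 0.0
    k_rise: float = 10.0      # 1/ps
    k_decay: float = 2.5      # 1/ps


@dataclass
class TwoDIRSpectrum:
    """Purely absorptive 2D-IR spectrum at one waiting time.

    signal[i, j] is the response at pump[i] x probe[j]; bleach negative,
    ESA positive.
    """

    pump: np.ndarray       # cm-1, strictly increasing
    probe: np.ndarray      # cm-1, strictly increasing
    T2: float              # waiting time, fs
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pump = np.asarray(self.pump, dtype=float)
        self.probe = np.asarray(self.probe, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.pump) <= 0) or np.any(np.diff(self.probe) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.signal.shape != (len(self.pump), len(self.probe)):
            raise ValueError("signal shape must be (len(pump), len(probe))")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class CLSResult:
    T2_values: np.ndarray   # fs
    cls: np.ndarray
    cls0: float
    k: float                # 1/ps
    fit_se: dict = field(default_factory=dict)
    flag: str = ""

    @property
    def decay_time_ps(self) -> float:
        return np.inf if self.k == 0 else 1.0 / self.k


@dataclass
class VERResult:
    band: str
    T2_values: np.ndarray   # fs
    volumes: np.ndarray
    tau_VER: float          # ps
    tau_se: float
    flag: str = ""


# ---------------------------------------------------------------------------
# Kubo lineshape and linear spectra


def kubo_lineshape(model: FFCFModel, t_ps) -> np.ndarray:
    """Line-broadening function g(t) for a multi-exponential Kubo FFCF.

    g(t) = sum_i Delta_i^2 tau_i^2 (exp(-t/tau_i) + t/tau_i - 1) + t/T2_h
    with Delta_i converted to angular frequency; g is dimensionless.

    For a uniform grid starting at 0 the step must resolve the fastest
    correlation time (step <= tau_min/5), otherwise a resolution error is
    raised.
    """
    t = np.asarray(t_ps, dtype=float)
    if t.ndim == 1 and len(t) > 1 and model.components:
        steps = np.diff(t)
        if t[0] == 0.0 and np.allclose(steps, steps[0]):
            tau_min = min(tau for _, tau in model.components)
            if steps[0] > tau_min / 5.0 + 1e-12:
                raise ValueError(
                    f"time step {steps[0]:.4g} ps does not resolve the fastest "
                    f"FFCF component (tau = {tau_min:.4g} ps; need <= tau/5)")
    g = np.zeros_like(t)
    for d_cm, tau in model.components:
        d = d_cm * WN_TO_ANG
        x = t / tau
        g = g + (d * tau) ** 2 * (np.exp(-x) + x - 1.0)
    if model.homogeneous_T2 is not None:
        g = g + t / model.homogeneous_T2
    return g


def linear_absorption(model: FFCFModel, wavenumber, include_lifetime: bool = True,
                      t_max: float | None = None) -> np.ndarray:
    """Linear absorption lineshape from the same g(t) as the 2D engine.

    A(w) = Re int_0^inf exp(i(w - w0) t) exp(-g(t) - t/(2 T1)) dt.  The
    quadrature window grows until the free-induction decay has died out; for
    slowly decaying (motionally narrowed, nearly Lorentzian) envelopes the
    remaining exponential tail beyond the window is integrated analytically
    using the converged decay rate g'(T).
    """
    wn = np.asarray(wavenumber, dtype=float)
    w = (wn - model.center) * WN_TO_ANG
    wmax = max(float(np.abs(w).max()), 0.5)
    dt = min(0.05, np.pi / (2.5 * wmax))
    taus = [tau for _, tau in model.components]
    if taus:
        dt = min(dt, max(min(taus) / 6.0, 0.005))
    rate_life = 1.0 / (2.0 * model.T1) if include_lifetime else 0.0

    def decay(t):
        return _g_values(model, t) + rate_life * t

    tmax = t_max
    if tmax is None:
        tmax = 2.0
        while tmax < 2000.0 and np.exp(-decay(np.array([tmax]))[0]) > 1e-6:
            tmax *= 2.0
    t = np.arange(0.0, tmax + dt / 2, dt)
    env = np.exp(-decay(t))
    weights = np.full(len(t), dt)
    weights[0] *= 0.5
    weights[-1] *= 0.5
    out = np.empty(len(wn))
    for sl in range(0, len(wn), 512):
        wv = w[sl:sl + 512]
        ft = (np.exp(1j * np.outer(wv, t)) * (env * weights)).sum(axis=1)
        # analytic tail: e^{-g} ~ env(T) * exp(-Gamma (t-T)) beyond the window
        gamma = (decay(np.array([t[-1]]))[0]
                 - decay(np.array([t[-1] - dt]))[0]) / dt
        tail = env[-1] * np.exp(1j * wv * t[-1]) / (max(gamma, 1e-12) - 1j * wv)
        out[sl:sl + 512] = (ft + tail).real
    return model.transition_strength * out


def linear_ir_baseline_normalize(
    wavenumber, absorbance,
    anchor_low: tuple[float, float] = (1500.0, 1520.0),
    anchor_high: tuple[float, float] = (1740.0, 1760.0),
    peak_window: tuple[float, float] = (1630.0, 1690.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Linear background correction and normalization to the CO peak.

    A straight line fitted through the two anchor regions is subtracted and
    the result divided by the maximum within the CO-peak window, so the CO
    peak maximum equals 1 after normalization.
    """
    wn = np.asarray(wavenumber, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if wn.min() > 1500.0 or wn.max() < 1750.0:
        raise ValueError("wavenumber range must cover 1500-1750 cm-1")
    mask = ((wn >= anchor_low[0]) & (wn <= anchor_low[1])) | (
        (wn >= anchor_high[0]) & (wn <= anchor_high[1]))
    if not mask.any():
        raise ValueError("empty baseline anchor region")
    coef = np.polyfit(wn[mask], ab[mask], 1)
    corrected = ab - np.polyval(coef, wn)
    co = (wn >= peak_window[0]) & (wn <= peak_window[1])
    if not co.any():
        raise ValueError("empty CO-peak window")
    peak = corrected[co].max()
    if peak <= 0:
        raise ValueError("no positive CO peak after baseline correction")
    return wn, corrected / peak


# ---------------------------------------------------------------------------
# response-function 2D-IR engine


def _time_grid_params(model: FFCFModel, extra_omega: float,
                      t_max: float | None = None) -> tuple[float, float]:
    """Time step and length resolving FFCF components and evaluation frequencies."""
    tau_min = min((tau for _, tau in model.components), default=np.inf)
    dt = min(tau_min / 6.0, 0.05)
    if extra_omega > 0:
        dt = min(dt, np.pi / (2.5 * extra_omega))
    dt = min(dt, 0.05)
    if t_max is None:
        # FID decay (dephasing + lifetime) AND the rephasing echo-ridge decay
        # exp(-(4 g(t) - g(2t))), which persists much longer for slowly
        # decorrelating FFCFs; take whichever dies out later.
        t_probe = np.arange(0.0, 30.0, 0.05)
        g = _g_values(model, t_probe)
        g2 = _g_values(model, 2.0 * t_probe)
        life = t_probe / model.T1
        fid = np.exp(-g - 0.5 * life)
        ridge = np.exp(-(4.0 * g - g2) - life)
        env = np.maximum(fid, ridge)
        below = np.nonzero(env < 1e-4)[0]
        t_max = t_probe[below[0]] if len(below) else 30.0
    return dt, float(t_max)


def simulate_2dir(model, T2_fs: float, pump, probe,
                  coverage_threshold: float = 0.01) -> TwoDIRSpectrum:
    """Purely absorptive 2D-IR spectrum from third-order response functions.

    Rephasing and non-rephasing Kubo response functions are evaluated on a
    uniform (t1, t3) grid in the rotating frame of the band center, in the
    impulsive (delta-pulse) limit, with coherence-time lifetime damping
    exp(-(t1+t3)/(2 T1)) and population decay exp(-T2/T1).  The excited-state
    absorption is red-shifted by the anharmonicity on the probe axis with
    opposite sign.  The double Fourier transform is evaluated as an explicit
    DFT onto the requested pump/probe axes.

    ``model`` may be an FFCFModel (single band) or a CoupledBandPair, in which
    case the two single-band spectra are summed and Gaussian cross-peak lobes
    with rise-decay transfer kinetics are added.

    Raises a coverage error if the band is truncated above
    ``coverage_threshold`` of the peak at the axis edges.
    """
    if isinstance(model, CoupledBandPair):
        return _simulate_pair(model, T2_fs, pump, probe, coverage_threshold)

    pump = np.asarray(pump, dtype=float)
    probe = np.asarray(probe, dtype=float)
    T2 = T2_fs / 1000.0  # ps
    w1 = (pump - model.center) * WN_TO_ANG
    w3 = (probe - model.center) * WN_TO_ANG
    anh = model.anharmonicity * WN_TO_ANG

    wmax = max(np.abs(w1).max(), np.abs(w3).max() + anh)
    dt, tmax = _time_grid_params(model, extra_omega=wmax)
    t = np.arange(0.0, tmax, dt)
    n = len(t)

    g1 = kubo_lineshape(model, t)                      # g(t1) == g(t3)
    gT = float(kubo_lineshape(model, np.array([T2]))[0])
    g1T = _g_values(model, t + T2)
    g13 = _g_values(model, t[:, None] + T2 + t[None, :])   # g(t3 + T2 + t1)

    # envelopes: rows = t3, cols = t1
    life = np.exp(-t / (2.0 * model.T1))
    env_common = np.outer(life, life) * np.exp(-T2 / model.T1)
    ex_r = np.exp(-g1[None, :] + gT - g1[:, None] - g1T[None, :] - g1T[:, None] + g13)
    ex_nr = np.exp(-g1[None, :] - gT - g1[:, None] + g1T[None, :] + g1T[:, None] - g13)

    # bleach (negative, at center) + ESA (positive, shifted -anharmonicity)
    esa_phase = np.exp(1j * anh * t)[:, None]
    amp = model.transition_strength
    R_r = amp * env_common * ex_r * (-1.0 + esa_phase)
    R_nr = amp * env_common * ex_nr * (-1.0 + esa_phase)

    wt = np.full(n, dt)
    wt[0] *= 0.5
    E3 = np.exp(1j * np.outer(w3, t)) * wt          # (nprobe, nt3)
    E1p = np.exp(1j * np.outer(t, w1)) * wt[:, None]   # (nt1, npump)
    S = (E3 @ R_r @ np.conj(E1p) + E3 @ R_nr @ E1p).real   # (nprobe, npump)
    signal = S.T

    _check_coverage(signal, coverage_threshold)
    return TwoDIRSpectrum(pump=pump, probe=probe, T2=T2_fs, signal=signal,
                          meta={"bands": [model.center], "engine": "response"})


def _g_values(model: FFCFModel, t) -> np.ndarray:
    """kubo_lineshape without the uniform-grid resolution check (closed form)."""
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    for d_cm, tau in model.components:
        d = d_cm * WN_TO_ANG
        x = t / tau
        g = g + (d * tau) ** 2 * (np.exp(-x) + x - 1.0)
    if model.homogeneous_T2 is not None:
        g = g + t / model.homogeneous_T2
    return g


def _check_coverage(signal: np.ndarray, threshold: float):
    peak = np.abs(signal).max()
    if peak <= 0:
        raise ValueError("empty spectrum")
    edge = max(np.abs(signal[0, :]).max(), np.abs(signal[-1, :]).max(),
               np.abs(signal[:, 0]).max(), np.abs(signal[:, -1]).max())
    if edge > threshold * peak:
        raise ValueError(
            f"axes too narrow: edge amplitude {edge/peak:.1%} of peak exceeds "
            f"{threshold:.0%}")


def _simulate_pair(pair: CoupledBandPair, T2_fs, pump, probe, coverage_threshold):
    sa = simulate_2dir(pair.band_a, T2_fs, pump, probe, coverage_threshold=np.inf)
    sb = simulate_2dir(pair.band_b, T2_fs, pump, probe, coverage_threshold=np.inf)
    signal = sa.signal + sb.signal
    if pair.coupling_amplitude != 0.0:
        t = T2_fs / 1000.0
        xamp = pair.coupling_amplitude * (
            np.exp(-pair.k_decay * t) - np.exp(-pair.k_rise * t))
        for donor, acceptor in ((pair.band_a, pair.band_b),
                                (pair.band_b, pair.band_a)):
            sig_d = np.sqrt(donor.inhomogeneous_variance) / WN_TO_ANG + 2.0
            sig_a = np.sqrt(acceptor.inhomogeneous_variance) / WN_TO_ANG + 2.0
            gp = np.exp(-0.5 * ((pump - donor.center) / sig_d) ** 2)
            bleach = np.exp(-0.5 * ((probe - acceptor.center) / sig_a) ** 2)
            esa = np.exp(-0.5 * ((probe - acceptor.center
                                  + acceptor.anharmonicity) / sig_a) ** 2)
            signal = signal + xamp * np.outer(gp, esa - bleach)
    spec = TwoDIRSpectrum(pump=np.asarray(pump, float), probe=np.asarray(probe, float),
                          T2=T2_fs, signal=signal,
                          meta={"bands": [pair.band_a.center, pair.band_b.center],
                                "engine": "response+transfer"})
    _check_coverage(spec.signal, coverage_threshold)
    return spec


# ---------------------------------------------------------------------------
# bivariate-Gaussian fast model (analytic oracle)


def gaussian_2dir(center: float, sigma_pump: float, sigma_probe: float,
                  corr: float, anharmonicity: float, pump, probe,
                  amplitude: float = 1.0, T2_fs: float = 0.0) -> TwoDIRSpectrum:
    """Bleach/ESA doublet built from bivariate Gaussians.

    The bleach is a negative bivariate Gaussian at (center, center) with the
    given marginal widths and correlation; the ESA is its positive mirror
    shifted by -anharmonicity on the probe axis.  For equal marginal widths
    the center line slope of the bleach equals ``corr`` exactly.
    """
    pump = np.asarray(pump, dtype=float)
    probe = np.asarray(probe, dtype=float)
    x = (pump[:, None] - center) / sigma_pump
    rho = corr
    norm = 1.0 / (1.0 - rho**2)

    def lobe(shift):
        y = (probe[None, :] - center - shift) / sigma_probe
        return np.exp(-0.5 * norm * (x**2 - 2.0 * rho * x * y + y**2))

    signal = amplitude * (lobe(-anharmonicity) - lobe(0.0))
    return TwoDIRSpectrum(pump=pump, probe=probe, T2=T2_fs, signal=signal,
                          meta={"bands": [center], "engine": "gaussian"})


def gaussian_2dir_from_ffcf(model: FFCFModel, T2_fs: float, pump, probe,
                            narrowing_cut: float = 0.3,
                            amplitude: float = 1.0) -> TwoDIRSpectrum:
    """Gaussian doublet with widths/correlation derived from an FFCF.

    Components with Delta*tau (angular) below ``narrowing_cut`` are treated as
    motionally narrowed: they contribute a pseudo-Gaussian marginal width
    sigma_h = Gamma/sqrt(2 ln 2) from their Lorentzian half width
    Gamma = Delta^2 tau (as does homogeneous_T2 with Gamma = 1/T2), but no
    pump-probe correlation.  Slow components contribute their variance to both
    the marginals and the covariance, decayed by exp(-T2/tau).
    """
    var_slow0 = var_slowT = var_h = 0.0
    T2 = T2_fs / 1000.0
    for d_cm, tau in model.components:
        d = d_cm * WN_TO_ANG
        if d * tau < narrowing_cut:
            gamma = d**2 * tau
            var_h += (gamma / np.sqrt(2.0 * np.log(2.0))) ** 2
        else:
            var_slow0 += d**2
            var_slowT += d**2 * np.exp(-T2 / tau)
    if model.homogeneous_T2 is not None:
        gamma = 1.0 / model.homogeneous_T2
        var_h += (gamma / np.sqrt(2.0 * np.log(2.0))) ** 2
    var_tot = var_slow0 + var_h
    sigma = np.sqrt(var_tot) / WN_TO_ANG      # back to cm-1
    rho = var_slowT / var_tot
    return gaussian_2dir(model.center, sigma, sigma, rho, model.anharmonicity,
                         pump, probe, amplitude=amplitude, T2_fs=T2_fs)


# ---------------------------------------------------------------------------
# extraction


def extract_cls(spec: TwoDIRSpectrum, band_center: float | None = None,
                anharmonicity: float | None = 20.0,
                pump_fraction: float = 0.6,
                pump_range: tuple[float, float] | None = None,
                return_details: bool = False):
    """Center line slope of the bleach lobe.

    For each pump slice whose diagonal bleach reaches at least
    ``pump_fraction`` of the bleach extremum (or within an explicit
    ``pump_range``), the probe-frequency minimum of the (negative) bleach is
    located by parabolic interpolation within a probe window bounded below by
    band_center - anharmonicity/2 (excluding the ESA lobe).  The CLS is the
    OLS slope of the extremum probe frequency against the pump frequency.
    """
    center = band_center if band_center is not None else float(spec.meta["bands"][0])
    lo = center - (anharmonicity / 2.0 if anharmonicity else np.inf)
    probe_mask = spec.probe >= lo if np.isfinite(lo) else np.ones(len(spec.probe), bool)
    if probe_mask.sum() < 3:
        raise ValueError("probe window too narrow")
    probe_w = spec.probe[probe_mask]
    sub = spec.signal[:, probe_mask]

    depth = sub.min(axis=1)          # most negative bleach per pump slice
    extremum = depth.min()
    if extremum >= 0:
        raise ValueError("no bleach (negative signal) found in window")
    if pump_range is not None:
        usable = (spec.pump >= pump_range[0]) & (spec.pump <= pump_range[1])
    else:
        usable = depth <= pump_fraction * extremum
    idx = np.nonzero(usable)[0]
    if len(idx) < 5:
        raise ValueError(f"only {len(idx)} usable pump slices (need >= 5)")

    centers = np.empty(len(idx))
    for k, i in enumerate(idx):
        j = int(np.argmin(sub[i]))
        if j <= 0 or j >= len(probe_w) - 1:
            j = min(max(j, 1), len(probe_w) - 2)
        y0, y1, y2 = sub[i, j - 1], sub[i, j], sub[i, j + 1]
        denom = y0 - 2.0 * y1 + y2
        off = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        centers[k] = probe_w[j] + off * (probe_w[1] - probe_w[0])

    res = stats.linregress(spec.pump[idx], centers)
    cls = float(res.slope)
    if return_details:
        monotone = bool(np.all(np.diff(centers) >= 0) or np.all(np.diff(centers) <= 0))
        return cls, {"pump": spec.pump[idx], "centerline": centers,
                     "slope_se": float(res.stderr), "monotone": monotone}
    return cls


def fit_cls_decay(T2_fs, cls, sigma=None) -> CLSResult:
    """Fit CLS(T2) = CLS0 exp(-k T2); reports CLS0 and the decay rate k.

    Weighted least squares when per-point uncertainties are given.  A series
    with no resolvable decay returns k = 0 with a flag.
    """
    T2_fs = np.asarray(T2_fs, dtype=float)
    cls = np.asarray(cls, dtype=float)
    if len(T2_fs) < 4:
        raise ValueError("need at least 4 waiting times")
    if 0.0 not in T2_fs:
        raise ValueError("waiting-time series must include T2 = 0")
    t_ps = T2_fs / 1000.0

    if np.ptp(cls) < 1e-12 or np.std(cls) < 1e-3 * abs(np.mean(cls)):
        return CLSResult(T2_values=T2_fs, cls=cls, cls0=float(np.mean(cls)),
                         k=0.0, flag="no decay resolvable (k = 0)")

    def model(t, c0, k):
        return c0 * np.exp(-k * t)

    p0 = [cls[np.argmin(t_ps)], 1.0]
    try:
        popt, pcov = curve_fit(model, t_ps, cls, p0=p0, sigma=sigma,
                               absolute_sigma=sigma is not None,
                               bounds=([0.0, 0.0], [1.5, np.inf]), maxfev=10000)
    except RuntimeError:
        return CLSResult(T2_values=T2_fs, cls=cls, cls0=float(cls[0]), k=0.0,
                         flag="fit did not converge")
    perr = np.sqrt(np.diag(pcov))
    flag = ""
    if popt[1] < 2.0 * perr[1] and popt[1] < 1e-3:
        popt[1] = 0.0
        flag = "k indistinguishable from 0"
    return CLSResult(T2_values=T2_fs, cls=cls, cls0=float(popt[0]),
                     k=float(popt[1]),
                     fit_se={"cls0": float(perr[0]), "k": float(perr[1])},
                     flag=flag)


def peak_volume(spec: TwoDIRSpectrum,
                pump_window: tuple[float, float],
                probe_window: tuple[float, float],
                neighbor_windows=None) -> float:
    """|signed sum| of the bleach signal over a window times the pixel area."""
    pm = (spec.pump >= pump_window[0]) & (spec.pump <= pump_window[1])
    qm = (spec.probe >= probe_window[0]) & (spec.probe <= probe_window[1])
    if not pm.any() or not qm.any():
        raise ValueError("window does not enclose any pixels")
    dp = np.mean(np.diff(spec.pump))
    dq = np.mean(np.diff(spec.probe))
    vol = abs(float(spec.signal[np.ix_(pm, qm)].sum())) * dp * dq
    if neighbor_windows:
        for (npw, nqw) in neighbor_windows:
            opm = pm & (spec.pump >= npw[0]) & (spec.pump <= npw[1])
            oqm = qm & (spec.probe >= nqw[0]) & (spec.probe <= nqw[1])
            if opm.any() and oqm.any():
                overlap = abs(float(spec.signal[np.ix_(opm, oqm)].sum())) * dp * dq
                if vol > 0 and overlap > 0.05 * vol:
                    warnings.warn("integration window overlaps a neighboring "
                                  "band's bleach by more than 5% of the volume")
    return vol


def fit_ver(T2_fs, volumes, band: str = "") -> VERResult:
    """Single-exponential fit V0 exp(-T2/tau_VER) of bleach peak volumes."""
    T2_fs = np.asarray(T2_fs, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if len(T2_fs) < 4:
        raise ValueError("need at least 4 waiting times")
    t_ps = T2_fs / 1000.0
    if (T2_fs.max() - T2_fs.min()) / 1000.0 <= 0:
        raise ValueError("waiting times must span a positive range")
    slope = stats.linregress(t_ps, np.log(np.maximum(v, 1e-300))).slope
    if slope >= 0:
        return VERResult(band=band, T2_values=T2_fs, volumes=v,
                         tau_VER=np.inf, tau_se=np.nan, flag="non-decaying series")

    def model(t, v0, tau):
        return v0 * np.exp(-t / tau)

    popt, pcov = curve_fit(model, t_ps, v, p0=[v[0], -1.0 / slope],
                           bounds=([0.0, 1e-4], [np.inf, np.inf]), maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    return VERResult(band=band, T2_values=T2_fs, volumes=v,
                     tau_VER=float(popt[1]), tau_se=float(perr[1]))


def cross_peak_kinetics(spectra, pump_window, probe_window,
                        noise_floor: float = 0.0) -> dict:
    """Cross-peak volume versus waiting time and the time of its maximum.

    Fits the two-rate kinetic form A (exp(-k_decay t) - exp(-k_rise t)); the
    time of maximum follows as t_max = ln(k_rise/k_decay)/(k_rise - k_decay).
    Returns {'detected': False, ...} when the cross peak never exceeds the
    noise floor.
    """
    T2 = np.array([s.T2 for s in spectra], dtype=float)
    order = np.argsort(T2)
    T2 = T2[order]
    vols = np.array([peak_volume(spectra[i], pump_window, probe_window)
                     for i in order])
    if vols.max() <= noise_floor:
        return {"detected": False, "T2_fs": T2, "volumes": vols}
    t_ps = T2 / 1000.0

    def model(t, a, kr, kd):
        return a * (np.exp(-kd * t) - np.exp(-kr * t))

    i_max = int(np.argmax(vols))
    t_pk = max(t_ps[i_max], np.median(np.diff(t_ps)) / 2.0)
    p0 = [vols.max() * 2.0, min(2.0 / t_pk, 900.0), min(0.5 / t_pk, 90.0)]
    popt, pcov = curve_fit(model, t_ps, vols, p0=p0,
                           bounds=([0.0, 1e-3, 1e-3], [1e6 * max(vols.max(), 1.0),
                                                       1e3, 1e3]),
                           maxfev=20000)
    a, kr, kd = popt
    if kr <= kd:  # enforce rise faster than decay (symmetric parameterization)
        kr, kd = kd, kr
    t_max_ps = np.log(kr / kd) / (kr - kd)
    return {"detected": True, "T2_fs": T2, "volumes": vols,
            "amplitude": float(a), "k_rise": float(kr), "k_decay": float(kd),
            "t_max_fs": float(t_max_ps * 1000.0)}
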