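"""Dielectric relaxation analysis of peptide/water/electrolyte solutions.

Complex permittivity spectra of aqueous dipeptide solutions in the GHz range
show two dispersions: a low-frequency (~1 GHz) Debye mode from the rotation of
the zwitterionic peptide and a high-frequency (~20 GHz) Cole-Cole mode from
the hydrogen-bonded water network.  The model evaluated and fitted here is

    eps(v) = S_pep / (1 + 2*pi*i*v*tau_pep)
           + S_wat / (1 + (2*pi*i*v*tau_wat)^(1-alpha))
           + eps_inf + kappa / (2*pi*i*v*eps_0)

with the convention eps = eps' - i*eps'' (loss positive).  The peptide
relaxation amplitude S_pep converts to an effective dipole moment through the
Cavell relation, and its salt-induced reduction ("kinetic depolarization")
quantifies average ion-peptide proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import lmfit
from scipy.ndimage import uniform_filter1d
from scipy.signal import argrelmax

from .constants import K_B, N_A, EPS_0, DEBYE, DEFAULT_TEMPERATURE_K

__all__ = [
    "DielectricSpectrum",
    "RelaxationFit",
    "DipoleResult",
    "SaltSeries",
    "eval_permittivity",
    "fit_spectrum",
    "loss_peak_frequency",
    "effective_dipole",
    "dipole_concentration_check",
    "amplitude_depolarization",
    "kramers_kronig_real",
]

# GHz * ps = 1e-3 (dimensionless omega*tau per unit 2*pi*v*tau)
_GHZ_PS = 1.0e-3
# kappa/(2*pi*v*eps0) with v in GHz: kappa[S/m] / (2*pi * v*1e9 * EPS_0)
_COND_SCALE = 1.0 / (2.0 * np.pi * 1.0e9 * EPS_0)


@dataclass
class DielectricSpectrum:
    """One measured (or synthetic) complex permittivity spectrum.

    freq is in GHz and must be strictly increasing; eps_real/eps_imag are the
    real permittivity and the (positive) dielectric loss on that grid.
    """

    freq: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        if not (len(self.freq) == len(self.eps_real) == len(self.eps_imag)):
            raise ValueError("freq, eps_real, eps_imag must have equal length")
        if len(self.freq) < 8:
            raise ValueError("spectrum needs at least 8 frequency points")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.freq <= 0):
            raise ValueError("frequencies must be positive")
        self.meta.setdefault("temperature_K", DEFAULT_TEMPERATURE_K)

    @property
    def temperature(self) -> float:
        return float(self.meta.get("temperature_K", DEFAULT_TEMPERATURE_K))


@dataclass
class RelaxationFit:
    """Parameters of the two-mode relaxation model plus fit diagnostics.

    The peptide mode is the slower one by construction (tau_pep > tau_wat).
    Amplitudes S are dimensionless, times in ps, kappa in S/m.
    """

    S_pep: float
    tau_pep: float
    S_wat: float
    tau_wat: float
    alpha: float
    eps_inf: float
    kappa: float = 0.0
    residual: float = np.nan
    stderr: dict = field(default_factory=dict)
    converged: bool = True

    def validate(self):
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.tau_pep <= 0 or self.tau_wat <= 0:
            raise ValueError("relaxation times must be positive")
        if self.S_pep < 0 or self.S_wat < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.kappa < 0:
            raise ValueError("conductivity must be non-negative")

    @property
    def eps_static(self) -> float:
        """Static permittivity: sum of amplitudes plus eps_inf."""
        return self.S_pep + self.S_wat + self.eps_inf

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eps_static"] = self.eps_static
        return d


@dataclass
class DipoleResult:
    """Effective dipole moment derived from a relaxation amplitude."""

    mu_eff: float          # Debye
    conc: float            # mol/L
    eps_static: float
    temperature: float     # K


@dataclass
class SaltSeries:
    """Relaxation fits along a salt concentration series (shared peptide conc)."""

    salt: str
    c_salt: np.ndarray
    fits: list

    def __post_init__(self):
        self.c_salt = np.asarray(self.c_salt, dtype=float)
        if np.any(np.diff(self.c_salt) <= 0):
            raise ValueError("c_salt must be strictly increasing")
        if len(self.c_salt) != len(self.fits):
            raise ValueError("one fit per concentration required")


def eval_permittivity(fit: RelaxationFit, freq) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the two-mode relaxation model on a frequency grid.

    Parameters
    ----------
    fit : RelaxationFit
        Model parameters (peptide Debye mode, water Cole-Cole mode, eps_inf,
        conductivity).
    freq : array-like
        Frequencies in GHz, all positive.

    Returns
    -------
    (eps_real, eps_imag) : tuple of ndarray
        Real permittivity and positive dielectric loss.  The conductivity term
        contributes to the loss only.
    """
    fit.validate()
    v = np.asarray(freq, dtype=float)
    if np.any(v <= 0):
        raise ValueError("frequencies must be positive")

    # Debye peptide mode
    wt_p = 2.0 * np.pi * v * fit.tau_pep * _GHZ_PS
    debye = fit.S_pep / (1.0 + 1j * wt_p)
    # Cole-Cole water mode: (i*w*tau)^(1-alpha)
    wt_w = 2.0 * np.pi * v * fit.tau_wat * _GHZ_PS
    cc = fit.S_wat / (1.0 + (1j * wt_w) ** (1.0 - fit.alpha))
    eps = debye + cc + fit.eps_inf
    eps_real = eps.real
    # eps = eps' - i eps''  =>  loss = -Im(eps); conductivity adds kappa/(2 pi v eps0)
    eps_imag = -eps.imag + fit.kappa * _COND_SCALE / v
    return eps_real, eps_imag


def loss_peak_frequency(tau_ps: float) -> float:
    """Loss-peak frequency (GHz) of a Debye or Cole-Cole mode: 1/(2*pi*tau).

    The Cole-Cole loss is symmetric on a log-frequency axis about the same
    maximum, so the formula holds for both mode types.
    """
    if tau_ps <= 0:
        raise ValueError("tau must be positive")
    return 1.0 / (2.0 * np.pi * tau_ps * _GHZ_PS)


# ---------------------------------------------------------------------------
# fitting

_PARAM_ORDER = ("S_pep", "tau_pep", "S_wat", "tau_wat", "alpha", "eps_inf", "kappa")


def _residual(params, freq, er, ei, weighting):
    fit = RelaxationFit(
        S_pep=params["S_pep"].value, tau_pep=params["tau_pep"].value,
        S_wat=params["S_wat"].value, tau_wat=params["tau_wat"].value,
        alpha=params["alpha"].value, eps_inf=params["eps_inf"].value,
        kappa=params["kappa"].value,
    )
    mr, mi = eval_permittivity(fit, freq)
    res = np.concatenate([mr - er, mi - ei])
    if weighting == "modulus":
        w = np.sqrt(er**2 + ei**2)
        res = res / np.concatenate([w, w])
    return res


def _initial_guess(spec: DielectricSpectrum) -> dict:
    """Heuristic initialization from the loss spectrum.

    A provisional conductivity is estimated from the lowest frequencies
    (where the 1/v term dominates if present), subtracted, and the two largest
    local loss maxima of the smoothed residual loss give the two relaxation
    times; the amplitudes come from the corresponding dispersion steps.
    """
    v, er, ei = spec.freq, spec.eps_real, spec.eps_imag
    # provisional conductivity from the lowest two points, modelling the loss
    # there as a*v (rising Debye tail) + kappa*C/v and solving the 2x2 system
    v1, v2, e1, e2 = v[0], v[1], ei[0], ei[1]
    a_lin = (e1 * v1 - e2 * v2) / (v1**2 - v2**2)
    kc = e1 * v1 - a_lin * v1**2
    kappa0 = max(0.0, kc / _COND_SCALE)
    ei_corr = ei - kappa0 * _COND_SCALE / v
    n = len(v)
    smooth = uniform_filter1d(ei_corr, size=max(3, n // 20))
    idx = argrelmax(smooth, order=2)[0]
    if len(idx) >= 2:
        # two largest maxima
        idx = idx[np.argsort(smooth[idx])[::-1][:2]]
        v1, v2 = sorted(v[idx])
    else:
        v1, v2 = 1.0, 20.0
    tau_pep = 1.0 / (2.0 * np.pi * v1 * _GHZ_PS)
    tau_wat = 1.0 / (2.0 * np.pi * v2 * _GHZ_PS)
    eps_inf = max(1.0, er[-1] * 0.9)
    # dispersion steps: split er range at the geometric-mean frequency
    vmid = np.sqrt(v1 * v2)
    imid = np.searchsorted(v, vmid)
    imid = min(max(imid, 1), n - 1)
    S_pep = max(0.1, er[0] - er[imid])
    S_wat = max(1.0, er[imid] - eps_inf)
    return dict(S_pep=S_pep, tau_pep=tau_pep, S_wat=S_wat, tau_wat=tau_wat,
                alpha=0.02, eps_inf=eps_inf, kappa=kappa0)


def fit_spectrum(
    spec: DielectricSpectrum,
    init: RelaxationFit | None = None,
    fix_kappa: float | None = None,
    weighting: str = "uniform",
    restarts: int = 5,
    seed: int = 0,
) -> RelaxationFit:
    """Least-squares fit of the two-mode model to a complex permittivity spectrum.

    Real and imaginary parts are fitted jointly (concatenated residual,
    equal weights by default; ``weighting='modulus'`` divides by |eps|).
    A bounded multi-start strategy (``restarts`` jittered re-initializations,
    seeded) guards against local minima; mode labels are assigned afterwards
    so that the peptide mode is the slower one.

    Set ``fix_kappa`` to pin the conductivity to a measured DC value.
    """
    v = spec.freq
    nfree = 7 if fix_kappa is None else 6
    if 2 * len(v) <= nfree:
        raise ValueError("fewer data points than free parameters")
    if v[0] > 1.0 or v[-1] < 20.0:
        raise ValueError(
            "spectrum must cover both dispersion regions (below 1 GHz and above 20 GHz)"
        )

    guess = _initial_guess(spec) if init is None else dict(
        S_pep=init.S_pep, tau_pep=init.tau_pep, S_wat=init.S_wat,
        tau_wat=init.tau_wat, alpha=init.alpha, eps_inf=init.eps_inf,
        kappa=init.kappa,
    )
    if fix_kappa is not None:
        guess["kappa"] = fix_kappa

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, restarts)):
        params = lmfit.Parameters()
        jit = 1.0 if trial == 0 else float(np.exp(rng.normal(0.0, 0.3)))
        params.add("S_pep", value=guess["S_pep"] * jit, min=0.0, max=500.0)
        params.add("tau_pep", value=min(max(guess["tau_pep"] * jit, 0.1), 1000.0),
                   min=0.1, max=1000.0)
        params.add("S_wat", value=guess["S_wat"], min=0.0, max=500.0)
        params.add("tau_wat", value=min(max(guess["tau_wat"] / jit, 0.1), 1000.0),
                   min=0.1, max=1000.0)
        params.add("alpha", value=guess["alpha"], min=0.0, max=0.5)
        params.add("eps_inf", value=min(max(guess["eps_inf"], 1.0), 10.0),
                   min=1.0, max=10.0)
        params.add("kappa", value=max(guess["kappa"], 0.0), min=0.0, max=100.0,
                   vary=fix_kappa is None)
        try:
            out = lmfit.minimize(
                _residual, params, args=(v, spec.eps_real, spec.eps_imag, weighting),
                method="least_squares",
            )
        except Exception:
            continue
        cost = float(np.sum(np.asarray(out.residual) ** 2))
        if best is None or cost < best[0]:
            best = (cost, out)
        if cost < 1e-16:
            break

    if best is None:
        raise RuntimeError("all fit attempts failed")
    cost, out = best

    p = {k: out.params[k].value for k in _PARAM_ORDER}
    stderr = {k: (out.params[k].stderr if out.params[k].stderr is not None else np.nan)
              for k in _PARAM_ORDER}
    # label modes: peptide = slower
    if p["tau_pep"] < p["tau_wat"]:
        p["S_pep"], p["S_wat"] = p["S_wat"], p["S_pep"]
        p["tau_pep"], p["tau_wat"] = p["tau_wat"], p["tau_pep"]
        stderr["S_pep"], stderr["S_wat"] = stderr["S_wat"], stderr["S_pep"]
        stderr["tau_pep"], stderr["tau_wat"] = stderr["tau_wat"], stderr["tau_pep"]

    return RelaxationFit(
        S_pep=p["S_pep"], tau_pep=p["tau_pep"], S_wat=p["S_wat"],
        tau_wat=p["tau_wat"], alpha=p["alpha"], eps_inf=p["eps_inf"],
        kappa=p["kappa"], residual=cost, stderr=stderr,
        converged=bool(getattr(out, "success", True)),
    )


# ---------------------------------------------------------------------------
# effective dipole moment (Cavell relation, spherical cavity)


def _cavity_factor(eps_static: float) -> float:
    """Spherical-cavity field factor (2*eps_s + 1)/eps_s.

    Isolated so an ellipsoidal shape factor can be substituted.
    """
    return (2.0 * eps_static + 1.0) / eps_static


def effective_dipole(
    S: float,
    conc: float,
    eps_static: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    cavity_factor=None,
) -> DipoleResult:
    """Convert a relaxation amplitude to an effective dipole moment (Debye).

    mu_eff = sqrt(3 kB T eps0 * f(eps_s) * S / (N_A * c)) with the spherical
    cavity-field factor f = (2 eps_s + 1)/eps_s; c is the solute concentration
    in mol/L (converted to mol/m^3 internally).  For uncorrelated dipoles
    mu_eff is independent of concentration.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    if S < 0:
        raise ValueError("amplitude must be non-negative")
    if eps_static <= 1:
        raise ValueError("static permittivity must exceed 1")
    f = (_cavity_factor if cavity_factor is None else cavity_factor)(eps_static)
    n_density = conc * 1000.0 * N_A   # 1/m^3
    mu_sq = 3.0 * K_B * temperature * EPS_0 * f * S / n_density
    mu = np.sqrt(mu_sq) / DEBYE
    return DipoleResult(mu_eff=float(mu), conc=conc, eps_static=eps_static,
                        temperature=temperature)


def dipole_concentration_check(
    series: Sequence[tuple[float, float, float]],
    temperature: float = DEFAULT_TEMPERATURE_K,
    flat_threshold: float = 0.10,
) -> dict:
    """Effective dipole vs concentration and a flatness statistic.

    Parameters
    ----------
    series : sequence of (S, conc, eps_static)
        Peptide amplitude, solute concentration (mol/L) and static
        permittivity per sample; at least three concentrations.
    flat_threshold : float
        Relative spread (max-min)/mean below which the series is reported as
        showing no dipole-dipole correlation.

    Returns
    -------
    dict with 'dipoles' (list of DipoleResult), 'spread' and 'correlated'.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 concentrations")
    dipoles = [effective_dipole(S, c, es, temperature) for S, c, es in series]
    mu = np.array([d.mu_eff for d in dipoles])
    spread = float((mu.max() - mu.min()) / mu.mean())
    return {
        "dipoles": dipoles,
        "spread": spread,
        "correlated": spread >= flat_threshold,
        "message": ("no dipole-dipole correlation detected"
                    if spread < flat_threshold else
                    "dipole moment varies with concentration"),
    }


def amplitude_depolarization(series: SaltSeries) -> dict:
    """Relative peptide-amplitude reduction R(c) = 1 - S_pep(c)/S_pep(ref), in %.

    The first (lowest) concentration is the reference.  Uncertainty is
    propagated from the per-fit amplitude standard errors where available.
    """
    if any(not f.converged for f in series.fits):
        raise ValueError("all fits must have converged")
    ref = series.fits[0]
    if ref.S_pep <= 0:
        raise ValueError("reference amplitude must be positive")
    s_ref = ref.S_pep
    e_ref = ref.stderr.get("S_pep", np.nan)
    rows = []
    for c, f in zip(series.c_salt, series.fits):
        r = (1.0 - f.S_pep / s_ref) * 100.0
        e = f.stderr.get("S_pep", np.nan)
        if np.isfinite(e) and np.isfinite(e_ref):
            sigma = 100.0 * (f.S_pep / s_ref) * np.sqrt(
                (e / f.S_pep) ** 2 + (e_ref / s_ref) ** 2)
        else:
            sigma = np.nan
        rows.append({"c_salt": float(c), "S_pep": f.S_pep,
                     "reduction_pct": float(r), "reduction_se": float(sigma)})
    return {"salt": series.salt, "table": rows,
            "reduction_at_max_c": rows[-1]["reduction_pct"]}


# ---------------------------------------------------------------------------
# Kramers-Kronig


def kramers_kronig_real(freq, eps_imag, eval_freq) -> np.ndarray:
    """Numerical Kramers-Kronig transform: eps'(v) - eps_inf from the loss.

    Uses the principal-value identity
        eps'(v) - eps_inf = (2/pi) PV int_0^inf x eps''(x)/(x^2 - v^2) dx
    with the singularity removed by subtracting v*eps''(v)/(x^2 - v^2), whose
    principal value integrates to zero over (0, inf).  Accuracy depends on the
    grid extending well beyond the loss features on both sides.
    """
    x = np.asarray(freq, dtype=float)
    ei = np.asarray(eps_imag, dtype=float)
    out = np.empty(len(np.atleast_1d(eval_freq)))
    for k, v in enumerate(np.atleast_1d(eval_freq)):
        ev = np.interp(v, x, ei)
        denom = x**2 - v**2
        num = x * ei - v * ev
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(np.abs(denom) > 1e-300, num / denom, 0.0)
        # limit at x -> v: d/dx[x eps''(x)] / (2v)
        i_near = np.argmin(np.abs(x - v))
        if abs(x[i_near] - v) < 1e-9 * v and 0 < i_near < len(x) - 1:
            deriv = (x[i_near + 1] * ei[i_near + 1] - x[i_near - 1] * ei[i_near - 1]) / (
                x[i_near + 1] - x[i_near - 1])
            integrand[i_near] = deriv / (2.0 * v)
        out[k] = (2.0 / np.pi) * np.trapezoid(integrand, x)
    return out if np.ndim(eval_freq) else float(out[0])
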