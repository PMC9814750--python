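"""Seeded synthetic-data generators for all three modalities.

Every generator emulates the statistical structure of the corresponding
measurement on aqueous alanylalanine (2Ala) solutions -- binary peptide/water
dielectric spectra and ternary salt series, proton-shift titrations, and
waiting-time series of 2D-IR spectra -- and returns a machine-readable
ground-truth manifest recording every true parameter, so recovery tests can
compare pipeline output against the manifest rather than against hard-coded
numbers.  Same seed + config always gives identical output.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K
from .dielectric import DielectricSpectrum, RelaxationFit, eval_permittivity
from .ir2d import (FFCFModel, CoupledBandPair, TwoDIRSpectrum, simulate_2dir,
                   linear_absorption)
from .nmr import ProtonAssignment, ShiftSeries, PROTON_LABELS

__all__ = [
    "SALTS",
    "BASELINE_SHIFTS_PPM",
    "default_water_mode",
    "gen_dielectric_binary",
    "gen_dielectric_salt_series",
    "gen_nmr_series",
    "gen_nmr_spectrum",
    "gen_2dir_dataset",
    "default_ffcf",
]

# ---------------------------------------------------------------------------
# dielectric defaults

#: peptide relaxation amplitude per concentration, L/mol (S_pep = slope * c)
S_PER_C = 27.6
TAU_PEP_PS = 160.0

#: pure-water-like Cole-Cole mode reproducing the ~20 GHz loss peak
WATER_MODE = {"S": 73.0, "tau": 8.3, "alpha": 0.02, "eps_inf": 3.5}

#: water-amplitude depletion per mol/L of peptide (hydration)
WATER_DEPLETION_PER_M_PEPTIDE = 6.0

#: per-salt emulation parameters: fractional S_pep reduction at 1.05 M,
#: tau_pep slowdown per M, water-amplitude dilution per M, and the
#: molar-conductivity table (Lambda0 [S cm^2/mol], Kohlrausch K)
SALTS = {
    "LiCl":  {"reduction_at_ref": 0.25, "tau_slope": 0.20, "water_dilution": 0.10,
              "lambda0": 115.0, "kohlrausch": 40.0},
    "GdmCl": {"reduction_at_ref": 0.25, "tau_slope": 0.18, "water_dilution": 0.09,
              "lambda0": 133.0, "kohlrausch": 40.0},
    "KSCN":  {"reduction_at_ref": 0.20, "tau_slope": 0.12, "water_dilution": 0.08,
              "lambda0": 137.0, "kohlrausch": 37.0},
    "KCl":   {"reduction_at_ref": 0.10, "tau_slope": 0.10, "water_dilution": 0.08,
              "lambda0": 150.0, "kohlrausch": 38.0},
    "KI":    {"reduction_at_ref": 0.10, "tau_slope": 0.10, "water_dilution": 0.08,
              "lambda0": 150.0, "kohlrausch": 37.0},
}

#: reference (lowest) and top salt concentrations between which the
#: configured fractional reduction applies linearly (mol/L)
REDUCTION_REF_CONC_LOW = 0.05
REDUCTION_REF_CONC = 1.05


def default_water_mode() -> dict:
    return dict(WATER_MODE)


def _freq_grid(n: int = 101) -> np.ndarray:
    return np.geomspace(0.25, 125.0, n)


def _true_fit(c_pep: float, salt: str | None = None, c_salt: float = 0.0) -> RelaxationFit:
    """Ground-truth model parameters for one sample."""
    S_pep = S_PER_C * c_pep
    tau_pep = TAU_PEP_PS
    S_wat = WATER_MODE["S"] - WATER_DEPLETION_PER_M_PEPTIDE * c_pep
    kappa = 0.0
    if salt is not None:
        p = SALTS[salt]
        red = p["reduction_at_ref"] * (c_salt - REDUCTION_REF_CONC_LOW) / (
            REDUCTION_REF_CONC - REDUCTION_REF_CONC_LOW)
        red = max(red, 0.0)
        if red >= 1.0:
            raise ValueError("configured amplitude reduction exceeds 100%")
        S_pep *= 1.0 - red
        tau_pep *= 1.0 + p["tau_slope"] * c_salt
        S_wat *= 1.0 - p["water_dilution"] * c_salt
        lam = max(p["lambda0"] - p["kohlrausch"] * np.sqrt(c_salt), 10.0)
        kappa = lam * c_salt / 10.0   # S cm^2/mol * mol/L -> S/m
    return RelaxationFit(S_pep=S_pep, tau_pep=tau_pep, S_wat=S_wat,
                         tau_wat=WATER_MODE["tau"], alpha=WATER_MODE["alpha"],
                         eps_inf=WATER_MODE["eps_inf"], kappa=kappa)


def _noisy_spectrum(fit: RelaxationFit, freq: np.ndarray, noise: float,
                    rng: np.random.Generator, meta: dict) -> DielectricSpectrum:
    er, ei = eval_permittivity(fit, freq)
    if noise > 0:
        er = er * (1.0 + noise * rng.standard_normal(len(freq)))
        ei = ei * (1.0 + noise * rng.standard_normal(len(freq)))
    return DielectricSpectrum(freq=freq, eps_real=er, eps_imag=ei, meta=meta)


def gen_dielectric_binary(concs=(0.05, 0.10, 0.15, 0.20, 0.25), *, seed: int,
                          noise: float = 0.005, n_freq: int = 101):
    """Binary peptide/water series: S_pep proportional to peptide concentration."""
    rng = np.random.default_rng(seed)
    freq = _freq_grid(n_freq)
    spectra, truths = [], []
    for c in concs:
        fit = _true_fit(c)
        meta = {"peptide_conc_M": c, "salt": None, "salt_conc_M": 0.0,
                "temperature_K": DEFAULT_TEMPERATURE_K}
        spectra.append(_noisy_spectrum(fit, freq, noise, rng, meta))
        truths.append({"meta": dict(meta), "params": fit.to_dict()})
    manifest = {"modality": "drs", "plan": "binary", "seed": seed, "noise": noise,
                "concs": list(concs), "S_per_c": S_PER_C, "truth": truths}
    return spectra, manifest


def gen_dielectric_salt_series(salt: str, c_salt=(0.05, 0.25, 0.45, 0.65, 0.85, 1.05),
                               *, seed: int, c_pep: float = 0.25,
                               noise: float = 0.005, n_freq: int = 101):
    """Ternary peptide/salt/water series with per-salt depolarization and kappa(c)."""
    if salt not in SALTS:
        raise ValueError(f"unknown salt {salt!r}; known: {sorted(SALTS)}")
    rng = np.random.default_rng(seed)
    freq = _freq_grid(n_freq)
    spectra, truths = [], []
    for c in c_salt:
        fit = _true_fit(c_pep, salt, c)
        meta = {"peptide_conc_M": c_pep, "salt": salt, "salt_conc_M": c,
                "temperature_K": DEFAULT_TEMPERATURE_K}
        spectra.append(_noisy_spectrum(fit, freq, noise, rng, meta))
        truths.append({"meta": dict(meta), "params": fit.to_dict()})
    manifest = {"modality": "drs", "plan": "salt-series", "salt": salt,
                "seed": seed, "noise": noise, "c_salt": list(c_salt),
                "reduction_at_max": SALTS[salt]["reduction_at_ref"]
                * (c_salt[-1] - REDUCTION_REF_CONC_LOW)
                / (REDUCTION_REF_CONC - REDUCTION_REF_CONC_LOW) * 100.0,
                "truth": truths}
    return spectra, manifest


# ---------------------------------------------------------------------------
# NMR

#: printed assignment of the dipeptide's five proton resonances, ppm
BASELINE_SHIFTS_PPM = {"H-1": 1.29, "H-2": 1.10, "H-3": 3.82, "H-4": 3.88,
                       "H-5": 8.04}

#: per-salt medium slope (common to all protons) and H-5 excess slope, ppm/M
NMR_SALT_SLOPES = {
    "KI":    {"medium": -0.045, "H-5_excess": -0.030},
    "KSCN":  {"medium": -0.040, "H-5_excess": -0.025},
    "KCl":   {"medium": -0.025, "H-5_excess": 0.0},
    "LiCl":  {"medium": -0.020, "H-5_excess": 0.0},
    "GdmCl": {"medium": -0.010, "H-5_excess": 0.020},
}


def gen_nmr_series(salt: str | None, conc=(0.05, 0.25, 0.45, 0.65, 0.85, 1.05), *,
                   seed: int, noise: float = 0.005,
                   saturating: dict | None = None):
    """Shift series delta_j(c) = delta_j(0) + m_medium*c + b_j*c (+ noise).

    ``salt=None`` generates a peptide-titration series with concentration-
    independent shifts (the aggregation-free null case).  ``saturating`` may
    map proton labels to (ddelta_max_ppm, K_per_M) for the 1:1-isotherm
    variant delta_j(0) + ddelta_max*K*c/(1 + K*c).
    """
    rng = np.random.default_rng(seed)
    if salt is not None and salt not in NMR_SALT_SLOPES:
        raise ValueError(f"unknown salt {salt!r}")
    slopes = NMR_SALT_SLOPES.get(salt, {"medium": 0.0, "H-5_excess": 0.0})
    assignments, truths = [], []
    for c in conc:
        delta = {}
        for lab in PROTON_LABELS:
            d = BASELINE_SHIFTS_PPM[lab]
            if salt is not None:
                d += slopes["medium"] * c
                if lab == "H-5":
                    d += slopes["H-5_excess"] * c
            if saturating and lab in saturating:
                dmax, K = saturating[lab]
                d += dmax * K * c / (1.0 + K * c)
            delta[lab] = d + noise * rng.standard_normal()
        assignments.append(ProtonAssignment(delta=delta))
        truths.append({"c": float(c), "delta_true": {
            lab: float(BASELINE_SHIFTS_PPM[lab]
                       + (slopes["medium"] * c if salt else 0.0)
                       + (slopes["H-5_excess"] * c if salt and lab == "H-5" else 0.0))
            for lab in PROTON_LABELS}})
    series = ShiftSeries(conc=np.asarray(conc, float), assignments=assignments,
                         ref_conc=conc[0], uncertainty=max(noise, 1e-6))
    manifest = {"modality": "nmr", "salt": salt, "seed": seed, "noise": noise,
                "conc": list(conc), "medium_slope": slopes["medium"],
                "H-5_excess_slope": slopes["H-5_excess"],
                "expected_ddelta_slope": slopes["H-5_excess"],
                "truth": truths}
    return series, manifest


def gen_nmr_spectrum(shifts: dict | None = None, *, seed: int | None = None,
                     noise: float = 0.0, width_ppm: float = 0.01,
                     ppm_min: float = 0.0, ppm_max: float = 10.0,
                     resolution_ppm: float = 0.001):
    """Synthetic 1H spectrum of Lorentzian singlets at the given shifts.

    Heights fall with shift window (methyls tallest, amide weakest) the way
    integrals of 3:1:1 protons would; additive Gaussian noise is relative to
    the largest peak.
    """
    shifts = dict(BASELINE_SHIFTS_PPM if shifts is None else shifts)
    ppm = np.arange(ppm_min, ppm_max + resolution_ppm / 2, resolution_ppm)
    heights = {"H-1": 3.0, "H-2": 3.0, "H-3": 1.0, "H-4": 1.0, "H-5": 0.8}
    y = np.zeros_like(ppm)
    for lab, d in shifts.items():
        h = heights.get(lab, 1.0)
        y += h / (1.0 + ((ppm - d) / (width_ppm / 2.0)) ** 2)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + noise * y.max() * rng.standard_normal(len(ppm))
    manifest = {"modality": "nmr-spectrum", "shifts": shifts, "noise": noise,
                "seed": seed, "width_ppm": width_ppm}
    return ppm, y, manifest


# ---------------------------------------------------------------------------
# 2D-IR

#: FFCF defaults emulating the study conditions.  Pure dephasing
#: (homogeneous_T2, the fully motionally narrowed limit) sets the homogeneous
#: linewidth; the slow component carries the spectral diffusion.  Calibrated
#: once through the simulate->extract chain so the amide I band shows
#: CLS0 ~= 0.5 decaying in ~1.1 ps, the carboxylate ~0.2 decaying in ~0.3 ps,
#: and the LiCl condition raises the carboxylate heterogeneity ~2.5-fold with
#: a ~1.3 ps decay; target_* record the calibrated ground-truth labels.
FFCF_DEFAULTS = {
    ("amideI", "none"): {"center": 1660.0, "T1": 0.7, "anharmonicity": 20.0,
                         "components": [(14.0, 1.1)], "homogeneous_T2": 2.0,
                         "target_cls0": 0.48, "target_decay_ps": 1.14},
    ("coo", "none"):    {"center": 1590.0, "T1": 0.4, "anharmonicity": 18.0,
                         "components": [(18.0, 0.3)], "homogeneous_T2": 0.667,
                         "target_cls0": 0.21, "target_decay_ps": 0.31},
    ("coo", "LiCl"):    {"center": 1590.0, "T1": 0.4, "anharmonicity": 18.0,
                         "components": [(18.0, 1.3)], "homogeneous_T2": 2.0,
                         "target_cls0": 0.52, "target_decay_ps": 1.32},
    ("amideI", "LiCl"): {"center": 1660.0, "T1": 0.7, "anharmonicity": 20.0,
                         "components": [(15.0, 1.1)], "homogeneous_T2": 2.0,
                         "target_cls0": 0.51, "target_decay_ps": 1.15},
}

DEFAULT_WAITING_TIMES_FS = (0.0, 250.0, 500.0, 1000.0, 1500.0, 2500.0)


def default_ffcf(band: str = "amideI", condition: str = "none") -> FFCFModel:
    p = FFCF_DEFAULTS[(band, condition)]
    return FFCFModel(center=p["center"], components=list(p["components"]),
                     T1=p["T1"], anharmonicity=p["anharmonicity"],
                     homogeneous_T2=p.get("homogeneous_T2"))


def _band_axes(model: FFCFModel, step: float = 1.0):
    dmax = max((d for d, _ in model.components), default=10.0)
    span = 70.0 + 3.0 * dmax
    pump = np.arange(model.center - span, model.center + span + step / 2, step)
    probe = np.arange(model.center - span - model.anharmonicity - 20.0,
                      model.center + span + step / 2, step)
    return pump, probe


def gen_2dir_dataset(bands=("amideI", "coo"), condition: str = "none", *,
                     seed: int, waiting_times_fs=DEFAULT_WAITING_TIMES_FS,
                     noise: float = 0.0, axis_step: float = 1.0,
                     coupling: dict | None = None):
    """Waiting-time series of 2D spectra plus a linear-IR spectrum.

    Returns ``(dataset, manifest)`` where dataset maps band name to a list of
    TwoDIRSpectrum (one per waiting time) plus a 'linear_ir' entry
    (wavenumber, absorbance).  ``coupling`` (amplitude, k_rise, k_decay)
    switches on a vibrational-energy-transfer cross-peak channel between the
    two bands, in which case spectra cover both bands on shared axes.
    """
    rng = np.random.default_rng(seed)
    models = {b: default_ffcf(b, condition if (b, condition) in FFCF_DEFAULTS
                              else "none") for b in bands}
    dataset: dict = {}
    truth: dict = {"bands": {}}

    if coupling:
        pair = CoupledBandPair(band_a=models[bands[0]], band_b=models[bands[1]],
                               coupling_amplitude=coupling.get("amplitude", 0.05),
                               k_rise=coupling.get("k_rise", 10.0),
                               k_decay=coupling.get("k_decay", 2.5))
        centers = sorted(m.center for m in models.values())
        pump = np.arange(centers[0] - 70.0, centers[-1] + 70.0 + axis_step / 2,
                         axis_step)
        probe = np.arange(centers[0] - 95.0, centers[-1] + 70.0 + axis_step / 2,
                          axis_step)
        specs = []
        for T2 in waiting_times_fs:
            s = simulate_2dir(pair, T2, pump, probe, coverage_threshold=0.05)
            if noise > 0:
                s.signal = s.signal + noise * np.abs(s.signal).max() * \
                    rng.standard_normal(s.signal.shape)
            specs.append(s)
        dataset["pair"] = specs
        truth["coupling"] = {"amplitude": pair.coupling_amplitude,
                             "k_rise": pair.k_rise, "k_decay": pair.k_decay,
                             "t_max_fs": 1000.0 * np.log(pair.k_rise / pair.k_decay)
                             / (pair.k_rise - pair.k_decay)}
    else:
        for b, m in models.items():
            pump, probe = _band_axes(m, step=axis_step)
            specs = []
            for T2 in waiting_times_fs:
                s = simulate_2dir(m, T2, pump, probe, coverage_threshold=0.05)
                if noise > 0:
                    s.signal = s.signal + noise * np.abs(s.signal).max() * \
                        rng.standard_normal(s.signal.shape)
                specs.append(s)
            dataset[b] = specs

    for b, m in models.items():
        p = FFCF_DEFAULTS[(b, condition if (b, condition) in FFCF_DEFAULTS
                           else "none")]
        truth["bands"][b] = {"center": m.center, "components": m.components,
                             "T1_ps": m.T1, "anharmonicity": m.anharmonicity,
                             "homogeneous_T2_ps": m.homogeneous_T2,
                             "target_cls0": p["target_cls0"],
                             "target_decay_ps": p["target_decay_ps"]}

    # linear IR: amide I + carboxylate with amplitude ratio 1 : 0.8
    wn = np.arange(1480.0, 1781.0, 1.0)
    absorb = np.zeros_like(wn)
    for b, m in models.items():
        a = 1.0 if b == "amideI" else 0.8
        band_abs = linear_absorption(m, wn)
        absorb += a * band_abs / band_abs.max()
    if noise > 0:
        absorb = absorb + noise * absorb.max() * rng.standard_normal(len(wn))
    dataset["linear_ir"] = (wn, absorb)

    manifest = {"modality": "ir2d", "condition": condition, "seed": seed,
                "noise": noise, "waiting_times_fs": list(waiting_times_fs),
                "truth": truth}
    return dataset, manifest
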