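# Methods

This note records the models implemented in `ionspec`, the defaults of the
synthetic-data generators, the numerical choices that matter, and what the
test suite does and does not demonstrate.

## Dielectric relaxation model

A spectrum is the complex permittivity ε̂(ν) = ε′(ν) − iε″(ν) on a
frequency grid in GHz (time factor e^{+iωt}; the loss ε″ is reported
positive). The fitted model is a Debye mode for the peptide, a Cole–Cole
mode for water, a high-frequency offset ε_∞ and a conductivity term:

    ε̂(ν) = S_pep/(1 + 2πiν τ_pep) + S_wat/(1 + (2πiν τ_wat)^(1−α))
          + ε_∞ + κ/(2πiν ε₀)

with amplitudes S (dimensionless), times τ (ps), Cole–Cole broadening
α ∈ [0, 1), and κ (S/m) real and frequency-independent; the conductivity
term contributes to ε″ only. Either mode's loss peaks at ν = 1/(2πτ).

**Fitting.** Real and imaginary parts are fitted jointly as a concatenated
residual with equal weights (modulus weighting is available via
`weighting="modulus"`). Optimization uses bounded least squares (lmfit /
scipy TRF) with bounds α ∈ [0, 0.5], ε_∞ ∈ [1, 10], τ ∈ [0.1, 1000] ps,
κ ∈ [0, 100] S/m. Initialization: a provisional κ is solved from the lowest
two frequencies (loss modelled there as aν + κC/ν), subtracted, and the two
largest local maxima of the smoothed residual loss seed the two relaxation
times; the amplitudes come from the dispersion steps. A seeded multi-start
(default 5 restarts with log-normal jitter on the initial point) guards
against local minima. After fitting, mode labels are assigned so the
peptide mode is the slower one. κ can instead be fixed to a measured DC
value (`fix_kappa`), since whether it should be fitted or fixed is a
judgment call that depends on whether independent conductance data exist;
both paths are provided.

**Effective dipole (Cavell relation).** Amplitudes convert to dipole
moments in the spherical-cavity form

    μ_eff = sqrt( 3 k_B T ε₀ (2ε_s + 1) S / (ε_s N_A c) ),

with ε_s = ΣS_j + ε_∞ from the same fit, c in mol/L converted internally to
a number density, CODATA 2018 constants, and T defaulting to 298.15 K. The
cavity-field factor (2ε_s+1)/ε_s is isolated in one function so an
ellipsoidal shape factor can be substituted; for the elongated zwitterion
the spherical form is an approximation, but it reproduces ~30 D from
amplitude-per-concentration values of ~27.6 L/mol, and every conclusion
drawn from μ_eff here depends on its concentration *flatness*, not its
absolute value. A relative spread (max−min)/mean below 10% (configurable)
is reported as "no dipole–dipole correlation detected".

**Kramers–Kronig check.** The property suite verifies model consistency via
the principal-value transform ε′(ν) − ε_∞ = (2/π) PV ∫ x ε″(x)/(x²−ν²) dx,
computed with the singularity removed by subtracting ν ε″(ν)/(x²−ν²)
(whose PV integral vanishes on (0, ∞)); agreement is required to 2%
mid-band on a grid extended well past both dispersions.

## NMR shift analysis

Five singlet resonances are tracked (β-CH₃ at N/C termini H-1/H-2, α-CH
H-3/H-4, amide N–H H-5). Shifts are referenced rigidly to an external
standard (DMSO at 2.5 ppm). δ_rel is taken against the 0.05 M point of each
titration (50 mM for peptide titrations). Δδ = δ_rel(H-5) − δ_rel(H-1) is
fitted by unweighted OLS against concentration — error weighting is offered
but not default, because the reproducibility floor (±0.005 ppm) is common
to all points; that floor is propagated into the slope standard error in
quadrature with the regression error (each Δδ point combines four shift
readings, two of which cancel in the reference). Classification: slope
beyond ±2 SE is "anion–amide shielding" (negative) or "de-shielding"
(positive, the guanidinium signature); otherwise "medium-effect only".

Peak detection models peaks as Lorentzian singlets (J-multiplets are out of
scope): local maxima above 5× a noise estimate (median absolute
point-to-point difference / 1.128), refined by parabolic interpolation
through the three samples around each maximum, then assigned by shift order
within windows 0.8–1.6 ppm (two methyls), 3.5–4.2 ppm (two α protons),
> 6 ppm (one amide). Wrong multiplicity in any window raises an error that
lists the peaks found. Overlapping Lorentzian tails bias interpolated
positions of the α-proton pair by ~10⁻⁶ ppm — three orders of magnitude
below the experimental floor.

## 2D-IR simulation and analysis

**Lineshape theory.** Each band carries a multi-exponential FFCF
C(t) = Σ Δ_i² e^{−t/τ_i}; the Kubo line-broadening function is

    g(t) = Σ_i Δ_i² τ_i² (e^{−t/τ_i} + t/τ_i − 1)  [+ t/T₂*]

with Δ in angular units internally (cm⁻¹ × 2πc). A pure-dephasing time T₂*
represents the fully motionally narrowed limit (Lorentzian HWHM Γ = 1/T₂*).
Linear absorption is the Fourier transform of e^{−g(t)−t/2T₁}; the
quadrature window grows adaptively until the free-induction decay has died
out and the remaining exponential tail is integrated analytically with the
converged rate g′(T), which keeps narrow motionally narrowed lines accurate
without enormous grids.

**2D engine.** Purely absorptive spectra are built from the rephasing and
non-rephasing third-order Kubo response functions in the rotating frame of
the band center, impulsive (delta-pulse) limit, with coherence-time
lifetime damping e^{−(t₁+t₃)/2T₁} and population decay e^{−T₂/T₁}. The
excited-state absorption is the bleach mirrored with opposite sign and
red-shifted by the anharmonicity (default 20 cm⁻¹, a typical amide I value)
on the probe axis; bleach/stimulated emission is negative, ESA positive.
The double Fourier transform is evaluated as an explicit DFT (matrix
product) onto the requested pump/probe axes — exact at arbitrary axis
points, no interpolation. The time step resolves both the fastest FFCF
component (τ_min/6) and the evaluation bandwidth; the window covers
whichever dies later of the free-induction decay and the rephasing echo
ridge e^{−(4g(t)−g(2t))} — truncating that ridge artificially decorrelates
near-static bands. A coverage error is raised when the band is truncated
above a threshold (default 1%) at the axis edges. Instrument details
(pulse shaping, rotating-frame acquisition, finite pulses, polarization)
are deliberately not emulated.

A second, closed-form construction — bivariate-Gaussian bleach/ESA lobes
with marginal width from the total variance and correlation
ρ(T₂) = Σ_slow Δ_s² e^{−T₂/τ_s} / (Σ_slow Δ_s² + σ_h²) — serves as the
analytic oracle for the engine (for equal marginal widths the CLS of a
bivariate Gaussian equals ρ exactly). Motionally narrowed components map
onto the oracle through their Lorentzian half width, σ_h = Γ/√(2 ln 2); the
cross-validation fixture (50/50 static/narrowed variance split) agrees with
the full engine to < 5% peak-normalized RMS in the moderately narrowed
regime.

**Center line slope.** For each pump slice whose bleach depth reaches ≥ 60%
of the extremum (configurable; the convention had to be fixed here), the
probe-frequency minimum of the bleach is located by parabolic
interpolation within a probe window bounded below by center − anharmonicity/2
(excluding the ESA lobe); the CLS is the OLS slope of these extrema against
pump frequency. CLS(T₂) is fitted with CLS₀ e^{−kT₂}; both the fit
intercept CLS₀ and the directly measured CLS(T₂=0) are reported, since
either convention is found in practice. The identity CLS(T₂) ≈ normalized
inhomogeneous FFCF holds to ≤ 0.05 only when slow components are genuinely
inhomogeneous (Δτ ≫ 1 and τ long against the echo-ridge window) and
homogeneous broadening is weak; lifetime broadening (1/2T₁) and
intermediate-regime components lower the apparent CLS — this is physics,
not extraction error, and it is why realistic amide-I parameters yield
CLS₀ ≈ 0.5 rather than 1.

**Volumes, lifetimes, cross peaks.** Peak volume is the |signed sum| of the
bleach window times pixel area; with the window enclosing the full bleach
lobe the volume decays as e^{−T₂/T₁} (verified < 2% noiseless when the ESA
is well separated; with a 20 cm⁻¹ anharmonicity the unavoidable ESA overlap
biases the fitted lifetime by a few percent). τ_VER comes from a
single-exponential fit. Cross-peak kinetics are fitted with
A(e^{−k_d t} − e^{−k_r t}); the time of maximum is
ln(k_r/k_d)/(k_r − k_d). Diagonal-band tails leak into off-diagonal
windows; tests subtract an uncoupled reference simulation to isolate the
transfer channel, which is what an experimentalist's salt-free control
provides.

## Synthetic-data generators

All generators are seeded (`numpy.random.default_rng`), return a
ground-truth manifest recording every true parameter, and are bit-identical
for identical seed + config.

**Dielectric.** Frequency grid: 101 log-spaced points, 0.25–125 GHz; noise
multiplicative Gaussian, 0.5% per channel by default. Binary series:
S_pep = 27.6 L/mol × c, τ_pep = 160 ps (loss peak ~1 GHz), water mode
S = 73 − 6c, τ = 8.3 ps (~20 GHz), α = 0.02, ε_∞ = 3.5; these reproduce a
flat μ_eff ≈ 30 D. Ternary series at 0.25 M peptide, salt 0.05–1.05 M:
linear S_pep reduction reaching, at 1.05 M relative to the 0.05 M
reference, 25% (LiCl, GdmCl), 20% (KSCN), 10% (KCl, KI); τ_pep slowdown of
10–20%/M (viscosity); water amplitude dilution 8–10%/M; κ(c) from an
editable molar-conductivity table Λ(c) = Λ₀ − K√c (Kohlrausch) with Λ₀ of
115–150 S cm²/mol — the per-salt τ slopes and conductivities are plausible
placeholders, flagged as such in the manifest.

**NMR.** Baseline shifts 1.29, 1.10, 3.82, 3.88, 8.04 ppm (H-1…H-5);
δ_j(c) = δ_j(0) + m_medium c + b_j c with a common medium slope per salt
(−0.01 to −0.045 ppm/M) and an H-5 excess slope b of −0.030 (KI), −0.025
(KSCN), 0 (KCl, LiCl), +0.020 ppm/M (GdmCl); additive noise at the 0.005
ppm reproducibility floor. A saturating 1:1-isotherm variant
(Δδ_max·Kc/(1+Kc)) exists to show where the linear-regime assumption
breaks (detectable r² drop once K·c_max ≳ 1). The non-monotone
low-concentration behaviour reported for guanidinium is not modelled; only
the slope sign is emulated.

**2D-IR.** Per band and condition, FFCF defaults calibrated once through
the full simulate→extract chain and then frozen: amide I — slow component
(14 cm⁻¹, 1.1 ps), T₂* = 2.0 ps, T₁ = 0.7 ps → CLS₀ ≈ 0.48 decaying in
~1.14 ps; carboxylate, no salt — (18 cm⁻¹, 0.3 ps), T₂* = 0.667 ps,
T₁ = 0.4 ps → CLS₀ ≈ 0.21, ~0.31 ps; carboxylate + LiCl — (18 cm⁻¹,
1.3 ps), T₂* = 2.0 ps → CLS₀ ≈ 0.52, ~1.32 ps (≈ 2.5× heterogeneity and a
slowed decay); amide I + LiCl — minor CLS₀ increase only. Waiting times
default to {0, 0.25, 0.5, 1, 1.5, 2.5} ps. The optional coupling channel
adds Gaussian cross-peak lobes with rise/decay rates defaulting to
k_r = 10 ps⁻¹, k_d = 2.5 ps⁻¹ (maximum at ~185 fs). Axes default to
±(70 + 3Δ_max) cm⁻¹ around each band at 1 cm⁻¹ pixels. Detector noise is
additive and off by default.

**What passing tests show — and don't.** The generators produce exactly the
noise structure the analyses assume (Gaussian, independent per channel,
homoscedastic; Lorentzian singlets; Kubo-Gaussian frequency fluctuations).
Real measurements add correlated baselines, calibration drift between probe
heads, J-coupling multiplets, solvent background, finite pulses and
phase errors — none of which are emulated. Recovery under these tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to instrumental systematics.

## Pipeline

`run_full_analysis` executes binary-series DRS (dipole flatness), per-salt
DRS depolarization and NMR differential-shift stages, and per-condition
2D-IR CLS/lifetime extraction, assembling a joint report with per-salt
rankings, a config hash and the seed. Configs are pydantic-validated with
unit normalization (`*_mM` → mol/L); every numeric entry carries a standard
error or an explicit "n/a". Stage failures are recorded in the report and
surfaced through exit code 1 (`ionspec run-all`); config errors exit 2.
Problem sizes in the shipped defaults (101-point spectra, 6-point salt
series, 6 waiting times at 1 cm⁻¹ pixels) were chosen so a full study runs
in well under a minute on a laptop; all are configurable upward.

## Known limitations

- Spherical Cavell cavity; no ellipsoidal shape factor by default, no
  Hubbard–Onsager kinetic-depolarization theory, no activity corrections.
- No VNA calibration or raw reflection processing; spectra are assumed
  already reduced to ε̂(ν).
- NMR: no multiplet lineshape fitting, no 2D (HSQC/HMBC) processing, no
  amide exchange modelling; assignments are rule-based on shift windows.
- 2D-IR: impulsive limit only; no polarization/anisotropy analysis; no
  guanidinium C–N band, so GdmCl conditions cannot be emulated in the IR
  modality; ESA–bleach overlap at realistic anharmonicities biases volume
  lifetimes by a few percent.
- CLS₀ of strongly intermediate-regime FFCFs is not a pure inhomogeneity
  fraction; compare conditions at fixed T₁ and extraction settings.
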