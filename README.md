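# ionspec

Quantifying where ions bind on a zwitterionic dipeptide, from three
complementary spectroscopies.

Small peptides such as L-alanyl-L-alanine (2Ala) carry all fundamental
protein interaction motifs in one rigid molecule: a carboxylate C-terminus,
an amide bond, and an ammonium N-terminus. Hofmeister salts (GdmCl, LiCl,
KCl, KI, KSCN) perturb each site differently, and no single experiment sees
all of it. `ionspec` implements, as a tested and reusable pipeline, the
three analyses that together localize the interactions:

1. **Dielectric relaxation (DRS).** Complex permittivity spectra
   ε̂(ν) = ε′ − iε″ over 0.25–125 GHz are fitted with a two-mode model

   ε̂(ν) = S_pep/(1 + 2πiν τ_pep) + S_wat/(1 + (2πiν τ_wat)^(1−α)) + ε_∞ + κ/(2πiν ε₀)

   (Debye peptide mode near 1 GHz, Cole–Cole water mode near 20 GHz, plus a
   conductivity term). The peptide amplitude S_pep converts to an effective
   dipole moment through the Cavell relation,
   μ_eff = √(3 k_B T ε₀ (2ε_s+1) S / (ε_s N_A c)); its salt-induced
   reduction R(c) = 1 − S_pep(c)/S_pep(ref) measures how closely ions
   approach the rotating zwitterion (kinetic depolarization).

2. **¹H-NMR shift titrations.** Per-proton chemical shifts δ(c) relative to
   a reference concentration, δ_rel = δ(c) − δ(0.05 M), and the differential
   statistic Δδ = δ_rel(H-5) − δ_rel(H-1) (amide N–H minus an N-terminal
   methyl), whose linear slope vs. salt concentration isolates site-specific
   amide binding from bulk medium effects.

3. **2D-IR spectral dynamics.** The amide I (~1660 cm⁻¹) and anti-symmetric
   COO⁻ (~1590 cm⁻¹) bands are simulated from Kubo frequency-fluctuation
   correlation functions (FFCF) through third-order response functions, and
   analyzed by center line slope, CLS(T₂) = CLS₀ e^(−k T₂) (spectral
   diffusion), bleach peak-volume decay (vibrational lifetime τ_VER), and
   cross-peak rise/decay kinetics (vibrational energy transfer).

Because the original raw data are not publicly deposited, the
`ionspec.synthetic` module is a first-class, seeded generator that emulates
the statistical structure of all three measurements, ships a ground-truth
manifest with every dataset, and backs the recovery tests.

## Worked example

```python
from ionspec.pipeline import run_full_analysis, format_report

report = run_full_analysis({
    "seed": 5, "salts": ["LiCl", "KI"],
    "salt_concs_M": [0.05, 0.55, 1.05],
    "drs": {"n_freq": 64, "restarts": 1},
    "ir2d": {"conditions": ["none"], "bands": ["amideI", "coo"],
             "waiting_times_fs": [0.0, 250.0, 500.0, 1000.0, 1500.0, 2500.0]},
})
print(format_report(report))
```

prints

```
ion-peptide interaction study report
  seed=5 config=3b37601678b22ff2

binary series: mu_eff = 30.5 D (spread 4.8%) -- no dipole-dipole correlation detected

salt      DRS reduction %   ddelta slope ppm/M  classification
LiCl                 24.4               -0.000  medium-effect only
KI                    8.4               -0.030  anion-amide shielding

2D-IR [none ] amideI : CLS0=0.48 decay=1.14 ps tau_VER=0.67 ps
2D-IR [none ] coo    : CLS0=0.21 decay=0.31 ps tau_VER=0.39 ps
```

Reading it: the dipeptide's effective dipole (~30 D) is flat in
concentration, so the zwitterions rotate without mutual correlation; LiCl
suppresses the peptide's rotational amplitude about three times more
strongly than KI (cation at the charged carboxylate pole vs. anion at the
amide, near the rotation axis); KI — but not LiCl — shifts the amide proton
beyond the medium effect (−0.03 ppm·L/mol, iodide–amide contact); and the
two carbonyl bands show their distinct heterogeneity (CLS₀), spectral
diffusion and population lifetimes. The same pipeline is available from the
shell as `ionspec simulate | fit-drs | fit-nmr | fit-2dir | run-all | report`.

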