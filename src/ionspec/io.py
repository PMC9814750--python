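"""File formats: CSV spectra with JSON sidecars/manifests.

Dielectric spectra are CSVs with columns freq_GHz, eps_real, eps_imag plus a
metadata sidecar; NMR peak lists are tidy CSVs (sample_id, c_titrant_M,
proton_label, delta_ppm); 2D-IR datasets are directories of per-waiting-time
signal matrices with axis vectors and a metadata JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dielectric import DielectricSpectrum
from .ir2d import TwoDIRSpectrum
from .nmr import ProtonAssignment, ShiftSeries

__all__ = [
    "save_dielectric_spectrum", "load_dielectric_spectrum",
    "save_dielectric_series", "load_dielectric_series",
    "save_shift_series", "load_shift_series",
    "save_2dir_series", "load_2dir_series",
    "save_json", "load_json",
]


def save_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))


def load_json(path):
    return json.loads(Path(path).read_text())


# -- dielectric -------------------------------------------------------------

def save_dielectric_spectrum(spec: DielectricSpectrum, csv_path):
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"freq_GHz": spec.freq, "eps_real": spec.eps_real,
                  "eps_imag": spec.eps_imag}).to_csv(csv_path, index=False)
    save_json(spec.meta, csv_path.with_suffix(".meta.json"))


def load_dielectric_spectrum(csv_path) -> DielectricSpectrum:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".meta.json")
    meta = load_json(meta_path) if meta_path.exists() else {}
    return DielectricSpectrum(freq=df["freq_GHz"].to_numpy(),
                              eps_real=df["eps_real"].to_numpy(),
                              eps_imag=df["eps_imag"].to_numpy(), meta=meta)


def save_dielectric_series(spectra, manifest, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, spec in enumerate(spectra):
        name = f"spectrum_{i:03d}.csv"
        save_dielectric_spectrum(spec, out_dir / name)
        files.append(name)
    save_json({**manifest, "files": files}, out_dir / "manifest.json")


def load_dielectric_series(in_dir):
    in_dir = Path(in_dir)
    manifest = load_json(in_dir / "manifest.json")
    spectra = [load_dielectric_spectrum(in_dir / name) for name in manifest["files"]]
    return spectra, manifest


# -- NMR --------------------------------------------------------------------

def save_shift_series(series: ShiftSeries, csv_path, sample_prefix: str = "s"):
    rows = []
    for i, (c, a) in enumerate(zip(series.conc, series.assignments)):
        for lab, d in a.delta.items():
            rows.append({"sample_id": f"{sample_prefix}{i:02d}", "c_titrant_M": c,
                         "proton_label": lab, "delta_ppm": d})
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def load_shift_series(csv_path, ref_conc: float | None = None,
                      uncertainty: float = 0.005) -> ShiftSeries:
    df = pd.read_csv(csv_path)
    concs = np.sort(df["c_titrant_M"].unique())
    assignments = []
    for c in concs:
        sub = df[df["c_titrant_M"] == c]
        delta = dict(zip(sub["proton_label"], sub["delta_ppm"].astype(float)))
        assignments.append(ProtonAssignment(delta=delta))
    return ShiftSeries(conc=concs, assignments=assignments,
                       ref_conc=float(concs[0]) if ref_conc is None else ref_conc,
                       uncertainty=uncertainty)


# -- 2D-IR ------------------------------------------------------------------

def save_2dir_series(spectra, out_dir, extra_meta: dict | None = None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    first = spectra[0]
    np.savetxt(out_dir / "pump_cm-1.csv", first.pump, delimiter=",")
    np.savetxt(out_dir / "probe_cm-1.csv", first.probe, delimiter=",")
    t2s = []
    for s in spectra:
        np.savetxt(out_dir / f"signal_T2_{int(round(s.T2)):06d}fs.csv", s.signal,
                   delimiter=",")
        t2s.append(float(s.T2))
    meta = {"T2_fs": t2s, "sign_convention": "bleach negative, ESA positive",
            **(extra_meta or {}), **({k: v for k, v in first.meta.items()
                                      if k != "engine"})}
    save_json(meta, out_dir / "metadata.json")


def load_2dir_series(in_dir):
    in_dir = Path(in_dir)
    meta = load_json(in_dir / "metadata.json")
    pump = np.loadtxt(in_dir / "pump_cm-1.csv", delimiter=",")
    probe = np.loadtxt(in_dir / "probe_cm-1.csv", delimiter=",")
    spectra = []
    for t2 in meta["T2_fs"]:
        sig = np.loadtxt(in_dir / f"signal_T2_{int(round(t2)):06d}fs.csv",
                         delimiter=",")
        spectra.append(TwoDIRSpectrum(pump=pump, probe=probe, T2=t2, signal=sig,
                                      meta={k: meta[k] for k in ("bands",)
                                            if k in meta}))
    return spectra, meta
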