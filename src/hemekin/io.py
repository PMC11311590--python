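"""CSV dialects for spectra, series manifests and kinetic traces.

One spectral dialect is used everywhere: two-column CSV with an explicit
``wavelength_nm,signal`` header.  A spectral series is a manifest CSV
(``file,time_min``) pointing at spectrum files, paths relative to the
manifest.  Kinetic traces are ``time_min,delta_A`` CSVs.  All times are
minutes, wavelengths nm.
"""
from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import KineticTrace
from .spectra import SpectralSeries, Spectrum

__all__ = [
    "load_spectrum",
    "write_spectrum",
    "load_trace",
    "write_trace",
    "load_series",
    "write_series",
]

logger = logging.getLogger("hemekin")

SPECTRUM_COLUMNS = ["wavelength_nm", "signal"]
TRACE_COLUMNS = ["time_min", "delta_A"]
MANIFEST_COLUMNS = ["file", "time_min"]


def _read_numeric_csv(path: str, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(columns)}"
        )
    for col in columns:
        if col == "file":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        df[col] = coerced
    return df.dropna(subset=[c for c in columns if c != "file"])


def load_spectrum(path: str, label: str | None = None) -> Spectrum:
    """Read a ``wavelength_nm,signal`` CSV as a validated Spectrum.

    Descending wavelength order is sorted ascending with a warning;
    duplicate wavelengths are averaged.
    """
    df = _read_numeric_csv(path, SPECTRUM_COLUMNS)
    if len(df) < 2:
        raise ValueError(f"{path}: a spectrum needs at least 2 points")
    wl = df["wavelength_nm"].to_numpy(float)
    if not np.all(np.diff(wl) > 0):
        logger.warning("%s: wavelengths not ascending; sorting", path)
        df = df.sort_values("wavelength_nm")
    if df["wavelength_nm"].duplicated().any():
        logger.warning("%s: duplicate wavelengths averaged", path)
        df = df.groupby("wavelength_nm", as_index=False)["signal"].mean()
    return Spectrum(
        df["wavelength_nm"].to_numpy(float),
        df["signal"].to_numpy(float),
        label=label if label is not None else os.path.basename(path),
    )


def write_spectrum(spectrum: Spectrum, path: str) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "signal": spectrum.values}
    ).to_csv(path, index=False)


def load_trace(path: str, **trace_kwargs) -> KineticTrace:
    """Read a ``time_min,delta_A`` CSV as a KineticTrace."""
    df = _read_numeric_csv(path, TRACE_COLUMNS)
    if len(df) < 2:
        raise ValueError(f"{path}: a trace needs at least 2 points")
    return KineticTrace(
        df["time_min"].to_numpy(float),
        df["delta_A"].to_numpy(float),
        label=os.path.basename(path),
        **trace_kwargs,
    )


def write_trace(trace: KineticTrace, path: str) -> None:
    pd.DataFrame(
        {"time_min": trace.times_min, "delta_A": trace.delta_a}
    ).to_csv(path, index=False)


def load_series(manifest_path: str) -> SpectralSeries:
    """Read a ``file,time_min`` manifest into a SpectralSeries.

    Spectrum paths are resolved relative to the manifest's directory.
    """
    df = _read_numeric_csv(manifest_path, MANIFEST_COLUMNS)
    if len(df) == 0:
        raise ValueError(f"{manifest_path}: empty manifest")
    base = os.path.dirname(os.path.abspath(manifest_path))
    df = df.sort_values("time_min")
    spectra = []
    for _, row in df.iterrows():
        p = row["file"]
        full = p if os.path.isabs(p) else os.path.join(base, p)
        if not os.path.exists(full):
            raise FileNotFoundError(f"{manifest_path}: missing spectrum {p}")
        s = load_spectrum(full)
        spectra.append(
            Spectrum(
                s.wavelengths, s.values, time_min=float(row["time_min"]),
                label=s.label,
            )
        )
    return SpectralSeries(
        tuple(spectra), df["time_min"].to_numpy(float)
    )


def write_series(
    series: SpectralSeries,
    out_dir: str,
    stem: str = "spectrum",
    manifest_name: str = "manifest.csv",
) -> str:
    """Write every spectrum plus a manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (spec, t) in enumerate(zip(series, series.times_min)):
        fname = f"{stem}_{i:03d}.csv"
        write_spectrum(spec, os.path.join(out_dir, fname))
        rows.append({"file": fname, "time_min": t})
    manifest_path = os.path.join(out_dir, manifest_name)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest_path, index=False
    )
    return manifest_path


def save_ground_truth_json(truth, path: str) -> None:
    """Ground-truth sidecar for generated datasets."""
    import json

    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
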