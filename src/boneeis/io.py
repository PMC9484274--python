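"""File formats: spectrum CSVs (rectangular and polar dialects), dataset
manifests, and JSON reports.

Rectangular dialect header: ``frequency_hz,z_real_ohm,z_imag_ohm``.
Polar dialect header: ``frequency_hz,z_mod_ohm,phase_deg`` (signed phase).
The reader auto-detects the dialect from the header; frequencies must be
strictly ascending. Floating-point output uses 12 significant digits so
round trips are value-preserving and artifacts are diffable.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .circuit import FrequencyGrid, ImpedanceSpectrum, to_rectangular
from .exceptions import FormatError
from .synthdata import LabeledDataset, Sample

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "write_report",
    "read_report",
    "RECT_HEADER",
    "POLAR_HEADER",
]

RECT_HEADER = ("frequency_hz", "z_real_ohm", "z_imag_ohm")
POLAR_HEADER = ("frequency_hz", "z_mod_ohm", "phase_deg")
MANIFEST_HEADER = ("sample_id", "label_wt_percent", "file")

_FLOAT_FMT = "%.12g"


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum CSV in either documented dialect."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse spectrum CSV {path}: {exc}") from exc
    cols = tuple(df.columns)
    if cols == RECT_HEADER:
        z_real = df["z_real_ohm"].to_numpy(float)
        z_imag = df["z_imag_ohm"].to_numpy(float)
    elif cols == POLAR_HEADER:
        z_real, z_imag = to_rectangular(
            df["z_mod_ohm"].to_numpy(float), df["phase_deg"].to_numpy(float)
        )
    else:
        raise FormatError(
            f"unknown spectrum header {cols!r}; expected "
            f"{','.join(RECT_HEADER)} or {','.join(POLAR_HEADER)}"
        )
    f = df["frequency_hz"].to_numpy(float)
    if np.any(np.diff(f) <= 0):
        raise FormatError(f"frequencies in {path} must be strictly ascending")
    try:
        grid = FrequencyGrid(f)
    except ValueError as exc:
        raise FormatError(f"bad frequency column in {path}: {exc}") from exc
    return ImpedanceSpectrum(grid=grid, z_real=z_real, z_imag=z_imag)


def write_spectrum(spectrum: ImpedanceSpectrum, path, dialect: str = "rectangular"):
    """Write a spectrum CSV in the requested dialect."""
    f = spectrum.grid.frequencies
    if dialect == "rectangular":
        df = pd.DataFrame(
            {
                "frequency_hz": f,
                "z_real_ohm": spectrum.z_real,
                "z_imag_ohm": spectrum.z_imag,
            }
        )
    elif dialect == "polar":
        df = pd.DataFrame(
            {
                "frequency_hz": f,
                "z_mod_ohm": spectrum.modulus,
                "phase_deg": spectrum.phase_deg,
            }
        )
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(dataset: LabeledDataset, out_dir, dialect: str = "rectangular"):
    """Write one spectrum CSV per sample plus ``manifest.csv`` (and
    ``truth.csv`` with true circuit parameters when available)."""
    os.makedirs(out_dir, exist_ok=True)
    rows, truth_rows = [], []
    for s in dataset.samples:
        fname = f"{s.sample_id}.csv"
        write_spectrum(s.spectrum, os.path.join(out_dir, fname), dialect)
        rows.append({"sample_id": s.sample_id, "label_wt_percent": s.label,
                     "file": fname})
        if s.true_params is not None:
            truth_rows.append(
                {
                    "sample_id": s.sample_id,
                    "r_b_ohm": s.true_params.r_b,
                    "r_ct_ohm": s.true_params.r_ct,
                    "q_s_s_alpha": s.true_params.q,
                    "alpha": s.true_params.alpha,
                }
            )
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "manifest.csv"), index=False, float_format=_FLOAT_FMT
    )
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(
            os.path.join(out_dir, "truth.csv"), index=False, float_format=_FLOAT_FMT
        )
    return os.path.join(out_dir, "manifest.csv")


def read_manifest(path) -> LabeledDataset:
    """Assemble a LabeledDataset from a manifest CSV; all referenced spectra
    must share one frequency grid."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    if tuple(df.columns) != MANIFEST_HEADER:
        raise FormatError(
            f"manifest header must be {','.join(MANIFEST_HEADER)}, "
            f"got {','.join(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_ids in manifest: {dupes}")
    base = os.path.dirname(os.path.abspath(path))
    samples, ref = [], None
    mismatched = []
    for row in df.itertuples(index=False):
        fpath = row.file if os.path.isabs(row.file) else os.path.join(base, row.file)
        if not os.path.exists(fpath):
            raise FormatError(f"manifest references missing file {fpath}")
        spec = read_spectrum(fpath)
        if ref is None:
            ref = spec.grid.frequencies
        elif len(spec.grid.frequencies) != len(ref) or not np.allclose(
            spec.grid.frequencies, ref
        ):
            mismatched.append(row.sample_id)
            continue
        samples.append(
            Sample(
                sample_id=str(row.sample_id),
                label=float(row.label_wt_percent),
                spectrum=spec,
            )
        )
    if mismatched:
        raise FormatError(
            f"spectra on mismatched frequency grids for sample_ids: {mismatched}"
        )
    return LabeledDataset(samples=tuple(samples))


def write_report(report: dict, path) -> None:
    """Serialize a report as pretty JSON with stable key order."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
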