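"""CSV waveform I/O.

One dialect for all waveforms: UTF-8 CSV with a ``time_s,pressure[,ecg]``
header, one row per sample, uniform sampling enforced to a 1e-6 s grid
jitter.  Lines starting with ``#`` hold the effective run configuration
(``# key=value``) and are ignored by the parser.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SiteRecording, Waveform, detect_r_peaks

__all__ = ["read_recording", "write_recording", "read_header_config"]

_JITTER_TOL = 1e-6


def write_recording(rec: SiteRecording, path, config: dict | None = None) -> None:
    """Write a recording in the package CSV dialect, with a config header."""
    path = Path(path)
    w = rec.pressure
    cols = {"time_s": w.times, "pressure": w.samples}
    if rec.ecg is not None:
        cols["ecg"] = rec.ecg.samples
    df = pd.DataFrame(cols)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for k, v in (config or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_header_config(path) -> dict[str, str]:
    """Parse ``# key=value`` comment lines from the top of a CSV file."""
    out: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def read_recording(path, site: str = "", detect_peaks: bool = True) -> SiteRecording:
    """Read a recording; R peaks are detected if an ``ecg`` column is present.

    Raises on missing columns, ragged rows (the error names the line) and
    non-uniform sampling beyond a 1e-6 s grid jitter (the error names the
    first offending row).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path.name}: {exc}") from exc
    required = {"time_s", "pressure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    bad = np.nonzero(np.abs(dt - dt_med) > _JITTER_TOL)[0]
    if bad.size:
        raise ValueError(
            f"{path.name}: non-uniform sampling at row {int(bad[0]) + 2} "
            f"(dt={dt[bad[0]]:.6g} s vs {dt_med:.6g} s)"
        )
    fs = 1.0 / dt_med
    pressure = Waveform(df["pressure"].to_numpy(dtype=float), fs=fs, t0=float(t[0]))
    ecg = None
    r_peaks = np.empty(0)
    if "ecg" in df.columns:
        ecg = Waveform(df["ecg"].to_numpy(dtype=float), fs=fs, t0=float(t[0]))
        if detect_peaks:
            try:
                r_peaks = detect_r_peaks(ecg)
            except ValueError as exc:
                warnings.warn(f"{path.name}: R-peak detection failed ({exc})")
    else:
        warnings.warn(f"{path.name}: no ecg column; r_peaks left empty")
    return SiteRecording(pressure=pressure, ecg=ecg, r_peaks=r_peaks, site=site)
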