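"""Readers and writers for the package's plain-text interchange formats.

* scalar series: two-column CSV ``time,value`` with ``#``-prefixed metadata
  header lines (``# key: value``);
* trajectories: standard multi-frame XYZ (atom-count line, comment line,
  ``element x y z`` records) plus a JSON sidecar mapping atom index → chain id;
* curves and fits: CSV / JSON views produced by the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .observables import MsdCurve, TimeSeries, Trajectory

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_curve_csv",
    "write_xyz",
    "read_xyz_trajectory",
    "write_chain_sidecar",
    "read_chain_sidecar",
]

_FLOAT_FMT = "%.12g"


def write_series_csv(series: TimeSeries, path, metadata: dict | None = None) -> None:
    """Write a time series as ``time,value`` CSV with a commented header."""
    path = Path(path)
    lines = []
    meta = dict(metadata or {})
    if series.label and "label" not in meta:
        meta["label"] = series.label
    for key, val in meta.items():
        if isinstance(val, dict):
            val = json.dumps(val, sort_keys=True)
        lines.append(f"# {key}: {val}")
    lines.append("time,value")
    for t, v in zip(series.times, series.values):
        lines.append(f"{_FLOAT_FMT % t},{_FLOAT_FMT % v}")
    path.write_text("\n".join(lines) + "\n")


def read_series_csv(path) -> tuple[TimeSeries, dict]:
    """Read a ``time,value`` CSV; returns the series and its metadata dict."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict = {}
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty input file")
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
        else:
            break
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"{path}: could not parse CSV ({exc})") from exc
    cols = [c.strip().lower() for c in df.columns]
    if len(df.columns) < 2:
        raise FormatError(f"{path}: expected two columns (time,value)")
    tcol, vcol = df.columns[:2]
    if "time" in cols and "value" in cols:
        tcol = df.columns[cols.index("time")]
        vcol = df.columns[cols.index("value")]
    series = TimeSeries(
        df[tcol].to_numpy(float),
        df[vcol].to_numpy(float),
        label=meta.get("label", ""),
    )
    return series, meta


def write_curve_csv(curve, path, metadata: dict | None = None) -> None:
    """Write an MSD-like curve (``lags``/``values`` or ``lags``/``msd``) as CSV."""
    path = Path(path)
    values = getattr(curve, "msd", None)
    if values is None:
        values = curve.values
    lines = [f"# {k}: {v}" for k, v in (metadata or {}).items()]
    lines.append("lag,value")
    for lag, v in zip(curve.lags, values):
        lines.append(f"{_FLOAT_FMT % lag},{_FLOAT_FMT % v}")
    path.write_text("\n".join(lines) + "\n")


def write_xyz(traj: Trajectory, path, element: str = "C", comment: str = "") -> None:
    """Write a trajectory as multi-frame XYZ with 8-decimal coordinates."""
    path = Path(path)
    out = []
    for f in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        out.append(comment or f"frame {f}")
        for x, y, z in traj.coords[f]:
            out.append(f"{element} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(out) + "\n")


def read_xyz_trajectory(path, chain_sidecar=None, frame_dt: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ file.

    Every frame must carry the same atom count; violations raise
    :class:`FormatError` naming the frame index, unparsable coordinate
    records name the line number.  Chain assignment defaults to a single
    chain when no sidecar is given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty input file")
    frames = []
    i = 0
    frame_idx = 0
    n_atoms_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if n_atoms_expected is None:
            n_atoms_expected = n_atoms
        elif n_atoms != n_atoms_expected:
            raise FormatError(
                f"{path}: frame {frame_idx} declares {n_atoms} atoms, "
                f"expected {n_atoms_expected}"
            )
        if i + 1 + n_atoms >= len(lines) + 1 and i + 2 + n_atoms > len(lines):
            raise FormatError(
                f"{path}: frame {frame_idx} is truncated "
                f"(declares {n_atoms} atoms)"
            )
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise FormatError(
                    f"{path}: frame {frame_idx} is truncated "
                    f"(declares {n_atoms} atoms)"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {ln + 1}: expected 'element x y z', "
                    f"got {lines[ln]!r}"
                )
            try:
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {ln + 1}: unparsable coordinates {lines[ln]!r}"
                ) from exc
        frames.append(coords)
        i += 2 + n_atoms
        frame_idx += 1
    chain_ids = None
    if chain_sidecar is not None:
        mapping = read_chain_sidecar(chain_sidecar)
        chain_ids = np.full(n_atoms_expected, "A", dtype=object)
        for idx_str, chain in mapping.items():
            idx = int(idx_str)
            if not 0 <= idx < n_atoms_expected:
                raise FormatError(
                    f"{chain_sidecar}: atom index {idx} out of range "
                    f"for {n_atoms_expected} atoms"
                )
            chain_ids[idx] = str(chain)
    return Trajectory(np.stack(frames), frame_dt=frame_dt, chain_ids=chain_ids)


def write_chain_sidecar(traj: Trajectory, path) -> None:
    """Write the atom-index → chain-id mapping as JSON."""
    mapping = {str(i): str(c) for i, c in enumerate(traj.chain_ids)}
    Path(path).write_text(json.dumps(mapping, indent=2, sort_keys=True) + "\n")


def read_chain_sidecar(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        mapping = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON sidecar ({exc})") from exc
    if not isinstance(mapping, dict):
        raise FormatError(f"{path}: sidecar must be a JSON object")
    return mapping
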