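"""Delimited-text readers/writers and key=value configuration files.

Time series are tab-separated with a one-line header naming the columns and
units, e.g. ``time_ms\tV_mV``; paired recordings are 3-column files with a
sidecar ``<file>.meta`` holding ``distance_um = <value>``.  Values round-trip
at 9 significant digits.  Uniform sampling is validated on read (maximum
time jitter below 1% of dt).
"""
from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np

from .model import CavParams
from .traces import CurrentTrace, PairedRecording, VoltageTrace

__all__ = [
    "read_trace", "write_trace", "read_pair", "write_pair",
    "read_config", "write_config", "params_from_config",
]

_HEADERS = {
    "voltage": "time_ms\tV_mV",
    "current": "time_ms\tI_norm",
    "pair": "time_ms\tV_soma_mV\tV_bouton_mV",
}


class TraceParseError(ValueError):
    pass


def _load_columns(path, n_cols: int):
    path = Path(path)
    lines = path.read_text().splitlines()
    start = 0
    while start < len(lines) and (not lines[start].strip()
                                  or lines[start].lstrip().startswith("#")):
        start += 1
    if start >= len(lines) or lines[start].lstrip()[0] in "0123456789-+.":
        raise TraceParseError(f"{path}: missing header line")
    header = lines[start].strip()
    data = []
    for ln, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != n_cols:
            raise TraceParseError(f"{path}:{ln}: expected {n_cols} columns, "
                                  f"got {len(parts)}")
        try:
            data.append([float(p) for p in parts])
        except ValueError:
            raise TraceParseError(f"{path}:{ln}: non-numeric value") from None
    if len(data) < 2:
        raise TraceParseError(f"{path}: fewer than 2 samples")
    return header, np.asarray(data)


def _validate_time(t: np.ndarray, path) -> tuple[float, float]:
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise TraceParseError(f"{path}: time column is not increasing")
    jitter = np.abs(np.diff(t) - dt)
    if jitter.max() > 0.01 * dt:
        bad = int(np.argmax(jitter)) + 3  # header + 1-based + next row
        raise TraceParseError(f"{path}:{bad}: non-uniform sampling")
    return float(t[0]), dt


def read_trace(path, expected_kind: str):
    """Read a 2-column (voltage/current) or 3-column (pair) delimited file."""
    if expected_kind == "pair":
        return read_pair(path)
    header, arr = _load_columns(path, 2)
    t0, dt = _validate_time(arr[:, 0], path)
    if expected_kind == "voltage":
        return VoltageTrace(t0, dt, arr[:, 1])
    if expected_kind == "current":
        return CurrentTrace(t0, dt, arr[:, 1])
    raise ValueError(f"unknown trace kind {expected_kind!r}")


def write_trace(path, trace, comment: str | None = None) -> None:
    kind = "voltage" if isinstance(trace, VoltageTrace) else "current"
    y = trace.V if kind == "voltage" else trace.I
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(_HEADERS[kind] + "\n")
        for t, v in zip(trace.t, y):
            fh.write(f"{t:.9g}\t{v:.9g}\n")


def read_pair(path) -> PairedRecording:
    header, arr = _load_columns(path, 3)
    t0, dt = _validate_time(arr[:, 0], path)
    meta = Path(str(path) + ".meta")
    if not meta.exists():
        raise TraceParseError(f"{meta}: sidecar with distance_um is required")
    cfg = read_config(meta)
    return PairedRecording(
        soma=VoltageTrace(t0, dt, arr[:, 1]),
        bouton=VoltageTrace(t0, dt, arr[:, 2]),
        distance_um=float(cfg["distance_um"]))


def write_pair(path, pair: PairedRecording, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(_HEADERS["pair"] + "\n")
        for t, vs, vb in zip(pair.soma.t, pair.soma.V, pair.bouton.V):
            fh.write(f"{t:.9g}\t{vs:.9g}\t{vb:.9g}\n")
    write_config(str(path) + ".meta", {"distance_um": pair.distance_um})


def read_config(path) -> dict:
    """Parse a ``key = value`` text config; values become float when possible."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if "=" not in s:
            raise TraceParseError(f"{path}:{ln}: expected 'key = value'")
        key, _, val = s.partition("=")
        val = val.strip()
        try:
            out[key.strip()] = float(val)
        except ValueError:
            out[key.strip()] = val
    return out


def write_config(path, mapping: dict) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k} = {v:.9g}\n" if isinstance(v, float) else f"{k} = {v}\n")


def params_from_config(cfg: dict) -> CavParams:
    """CavParams from a config dict, ignoring unrelated keys."""
    names = {f.name for f in fields(CavParams)}
    return CavParams(**{k: float(v) for k, v in cfg.items() if k in names})
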