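"""CSV and JSON readers/writers for the toolkit's file dialects.

Waveform CSV dialect::

    # unit: mmHg
    # periodic: true
    # period_s: 0.65
    # provenance: intravascular
    time_s,value
    0,80.1234
    0.001,80.2345

The unit and periodic headers are mandatory; ``period_s`` is required for
periodic signals; ``provenance`` is optional.  The time column must be
uniform to 1e-9 s.  Compression records use plain three-column CSV
(``time_s,displacement_m,force_N``) with no metadata block.

Parsing is hand-rolled line by line so that malformed rows and jittered
timestamps can be reported with their 1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParseError
from .fitting import CompressionRecord
from .reconstruction import PressureScale
from .signals import GRID_TOL, SampledSignal, PulseWaveform
from .viscoelastic import ViscoParams

_FLOAT_FMT = "%.15g"  # >= 12 significant digits for lossless round trips


def _parse_float(token: str, path: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed {what} {token!r}") from None


def _read_rows(path: str | Path, n_cols: int, header: str):
    """Yield (lineno, floats) rows after the metadata block; checks header."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[float]]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("#").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != header:
                    raise ParseError(f"{path}:{lineno}: expected header {header!r}, got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != n_cols:
                raise ParseError(f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}")
            rows.append((lineno, [_parse_float(p, str(path), lineno, "value") for p in parts]))
    if not header_seen:
        raise ParseError(f"{path}: missing header line {header!r}")
    if len(rows) < 4:
        raise ParseError(f"{path}: needs at least 4 data rows, got {len(rows)}")
    return meta, rows


def _uniform_dt(times: np.ndarray, linenos: list[int], path: str | Path) -> float:
    dt = (times[-1] - times[0]) / (times.size - 1)
    dev = np.abs(times - (times[0] + dt * np.arange(times.size)))
    bad = np.flatnonzero(dev > GRID_TOL)
    if bad.size:
        raise ParseError(
            f"{path}:{linenos[bad[0]]}: non-uniform time grid "
            f"(deviation {dev[bad[0]]:.3e} s exceeds {GRID_TOL} s)"
        )
    if dt <= 0:
        raise ParseError(f"{path}: time column must be increasing")
    return float(dt)


def read_signal_csv(path: str | Path) -> SampledSignal:
    """Read a waveform CSV as a bare SampledSignal (periodic or not)."""
    meta, rows = _read_rows(path, 2, "time_s,value")
    if "unit" not in meta:
        raise ParseError(f"{path}: missing '# unit:' metadata line")
    if "periodic" not in meta:
        raise ParseError(f"{path}: missing '# periodic:' metadata line")
    periodic = meta["periodic"].lower() in ("true", "1", "yes")
    if periodic and "period_s" not in meta:
        raise ParseError(f"{path}: periodic waveform lacks '# period_s:' line")
    linenos = [r[0] for r in rows]
    data = np.array([r[1] for r in rows])
    dt = _uniform_dt(data[:, 0], linenos, path)
    period = float(meta["period_s"]) if periodic else None
    return SampledSignal(data[:, 1], dt, unit=meta["unit"], periodic=periodic,
                         period=period)


def read_waveform_csv(path: str | Path) -> PulseWaveform:
    """Read a periodic waveform CSV as a PulseWaveform with provenance."""
    meta, _ = _read_rows(path, 2, "time_s,value")
    sig = read_signal_csv(path)
    if not sig.periodic:
        raise ParseError(f"{path}: expected a periodic waveform "
                         "(use read_signal_csv for finite records)")
    return PulseWaveform(sig, provenance=meta.get("provenance", "unspecified"))


def write_waveform_csv(w: PulseWaveform | SampledSignal, path: str | Path,
                       unit: str | None = None) -> None:
    """Write a waveform/signal in the CSV dialect, converting units if asked."""
    sig = w.pressure if isinstance(w, PulseWaveform) else w
    if unit is not None:
        sig = sig.to_unit(unit)
    lines = [f"# unit: {sig.unit}", f"# periodic: {'true' if sig.periodic else 'false'}"]
    if sig.periodic:
        lines.append(f"# period_s: {_FLOAT_FMT % sig.period}")
    if isinstance(w, PulseWaveform):
        lines.append(f"# provenance: {w.provenance}")
    lines.append("time_s,value")
    t = sig.t
    for ti, vi in zip(t, sig.values):
        lines.append(f"{_FLOAT_FMT % ti},{_FLOAT_FMT % vi}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_compression_csv(path: str | Path) -> CompressionRecord:
    """Read a three-column compression record CSV."""
    _, rows = _read_rows(path, 3, "time_s,displacement_m,force_N")
    data = np.array([r[1] for r in rows])
    return CompressionRecord(time=data[:, 0], displacement=data[:, 1], force=data[:, 2])


def write_compression_csv(rec: CompressionRecord, path: str | Path) -> None:
    lines = ["time_s,displacement_m,force_N"]
    for t, d, f in zip(rec.time, rec.displacement, rec.force):
        lines.append(",".join(_FLOAT_FMT % x for x in (t, d, f)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_params_json(path: str | Path) -> tuple[ViscoParams, PressureScale]:
    """Read model parameters (E1, E2, eta in Pa, Pa*s; optional K, p0)."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON ({e})") from None
    try:
        params = ViscoParams(E1=float(obj["E1"]), E2=float(obj["E2"]),
                             eta=float(obj["eta"]))
    except KeyError as e:
        raise ParseError(f"{path}: missing parameter {e}") from None
    scale = PressureScale(K=float(obj.get("K", 1.0)),
                          p0=float(obj.get("p0", PressureScale().p0)))
    return params, scale


def write_params_json(params: ViscoParams, scale: PressureScale,
                      path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "E1": params.E1, "E2": params.E2, "eta": params.eta,
        "K": scale.K, "p0": scale.p0,
    }, indent=2) + "\n")
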