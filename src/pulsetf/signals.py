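"""Uniformly sampled signals and pulse-waveform containers.

The whole toolkit operates on real-valued, uniformly sampled time series:
stress and strain traces from indentation experiments, and periodic pressure
waveforms from pulse measurements.  :class:`SampledSignal` is the common
carrier; :class:`PulseWaveform` wraps a periodic pressure signal together
with a provenance tag (intravascular / on-skin / reconstructed).

Conventions
-----------
* Non-periodic signals sample the closed interval [0, T] with
  ``T = (n - 1) * dt`` (both endpoints present).
* Periodic signals sample [0, T) with ``T = m * dt`` — the wrap sample at
  ``t = T`` is *not* stored; a signal may span several whole periods.
* Internal computation is in SI units (Pa, s); mmHg appears only at I/O
  boundaries (1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError, InvalidSignalError, UnitError

#: Pressure conversion constant, Pa per mmHg.
MMHG_TO_PA = 133.322

PRESSURE_UNITS = ("Pa", "mmHg")
STRAIN_UNITS = ("strain", "dimensionless", "normalized")

#: Tolerance on time-grid uniformity, seconds.
GRID_TOL = 1e-9


def convert_pressure(values: np.ndarray, from_unit: str, to_unit: str) -> np.ndarray:
    """Convert an array between the supported pressure units."""
    if from_unit not in PRESSURE_UNITS or to_unit not in PRESSURE_UNITS:
        raise UnitError(
            f"cannot convert {from_unit!r} -> {to_unit!r}; "
            f"pressure units are {PRESSURE_UNITS}"
        )
    if from_unit == to_unit:
        return np.asarray(values, dtype=float)
    if from_unit == "mmHg":  # -> Pa
        return np.asarray(values, dtype=float) * MMHG_TO_PA
    return np.asarray(values, dtype=float) / MMHG_TO_PA  # Pa -> mmHg


@dataclass(frozen=True, eq=False)
class SampledSignal:
    """A uniformly sampled real signal with unit label and optional period.

    Parameters
    ----------
    values
        Sample values; converted to a float ndarray.
    dt
        Sampling interval in seconds, strictly positive.
    unit
        Unit label: ``"Pa"``, ``"mmHg"``, ``"strain"``, ``"dimensionless"``,
        or any informational string.
    periodic
        Whether the samples cover whole periods of a periodic signal.
    period
        Period T in seconds for periodic signals; defaults to ``n * dt``
        (one full period).  Must be an integer multiple of ``dt``, and the
        signal length must be a multiple of the samples per period.
    """

    values: np.ndarray
    dt: float
    unit: str = "dimensionless"
    periodic: bool = False
    period: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise InvalidSignalError(f"sampling interval must be positive, got {self.dt}")
        if v.ndim != 1:
            raise InvalidSignalError("signal values must be one-dimensional")
        if v.size < 4:
            raise InvalidSignalError(f"signal needs at least 4 samples, got {v.size}")
        if self.periodic:
            T = self.period if self.period is not None else v.size * self.dt
            m = T / self.dt
            if abs(m - round(m)) * self.dt > GRID_TOL or round(m) < 4:
                raise InvalidSignalError(
                    f"period {T} s is not an integer multiple (>=4) of dt {self.dt} s"
                )
            m = int(round(m))
            if v.size % m:
                raise InvalidSignalError(
                    f"{v.size} samples do not cover whole periods of {m} samples"
                )
            object.__setattr__(self, "period", m * self.dt)
        elif self.period is not None:
            raise InvalidSignalError("period is only meaningful for periodic signals")

    # -- geometry -----------------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def t(self) -> np.ndarray:
        """Sample times, starting at 0."""
        return np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        """Covered duration: n*dt for periodic signals, (n-1)*dt otherwise."""
        return self.n * self.dt if self.periodic else (self.n - 1) * self.dt

    @property
    def samples_per_period(self) -> int:
        if not self.periodic:
            raise ContractError("samples_per_period requires a periodic signal")
        return int(round(self.period / self.dt))

    # -- derivation ---------------------------------------------------------
    def with_values(self, values: np.ndarray, unit: str | None = None) -> "SampledSignal":
        """Return a copy with new values (and optionally a new unit label)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)

    def to_unit(self, unit: str) -> "SampledSignal":
        """Convert between pressure units; identity if the unit matches."""
        if unit == self.unit:
            return self
        return self.with_values(convert_pressure(self.values, self.unit, unit), unit=unit)


@dataclass(frozen=True, eq=False)
class PulseWaveform:
    """A periodic pressure waveform with a provenance tag.

    ``provenance`` records which stage produced the waveform:
    ``"intravascular"`` (reference pressure inside the vessel), ``"on-skin"``
    (tonometric surface measurement), or ``"reconstructed"`` (model output).
    """

    pressure: SampledSignal
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.pressure.periodic:
            raise ContractError("a pulse waveform must be periodic")
        if not np.all(np.isfinite(self.pressure.values)):
            raise InvalidSignalError("pulse waveform contains non-finite values")

    # Delegated accessors ---------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.pressure.values

    @property
    def dt(self) -> float:
        return self.pressure.dt

    @property
    def period(self) -> float:
        return self.pressure.period

    @property
    def unit(self) -> str:
        return self.pressure.unit

    @property
    def t(self) -> np.ndarray:
        return self.pressure.t

    def to_unit(self, unit: str) -> "PulseWaveform":
        return PulseWaveform(self.pressure.to_unit(unit), self.provenance)

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    provenance: str | None = None) -> "PulseWaveform":
        return PulseWaveform(
            self.pressure.with_values(values, unit=unit),
            self.provenance if provenance is None else provenance,
        )
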