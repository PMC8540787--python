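"""Intravascular pulse-waveform reconstruction from on-skin tonometry.

An on-skin tonometric pressure signal is treated (after conversion to Pa) as
the surface stress on the skin layer.  The periodic strain solution of the
standard-linear-solid model turns it into a vessel-wall strain estimate, and
the collapsible-tube relation — pulse pressure proportional to the change of
the square root of the lumen area, hence to radial strain — maps strain to
intravascular pressure:

    p(t) = K * eps_hat(t) + p0,

where K lumps the tube geometry/stiffness coefficient (2*r0*beta*sqrt(2*pi))
and p0 is the diastolic reference offset.  K is never needed in absolute
terms for shape comparisons: all shape comparisons are on min-max
normalized, phase-aligned waveforms, which are invariant to (K, p0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateNormalizationError, ParameterError
from .signals import MMHG_TO_PA, SampledSignal, PulseWaveform
from .viscoelastic import ViscoParams, solve_strain_periodic


@dataclass(frozen=True)
class PressureScale:
    """Affine strain -> pressure map p = K*eps + p0.

    K is in Pa per unit strain (default 1: comparisons are normalized, so
    the lumped tube constant is not identifiable from shape data); p0 is the
    reference offset in Pa (default the 80 mmHg diastolic fill pressure).
    """

    K: float = 1.0
    p0: float = 80.0 * MMHG_TO_PA

    def __post_init__(self) -> None:
        if not np.isfinite(self.K) or self.K <= 0:
            raise ParameterError(f"K must be positive, got {self.K}")
        if not np.isfinite(self.p0):
            raise ParameterError("p0 must be finite")


def strain_to_pressure(strain: SampledSignal, scale: PressureScale,
                       provenance: str = "reconstructed") -> PulseWaveform:
    """Map a periodic strain signal to a pressure waveform in mmHg."""
    if not strain.periodic:
        raise ContractError("strain_to_pressure expects a periodic strain signal")
    p_pa = scale.K * strain.values + scale.p0
    sig = SampledSignal(p_pa / MMHG_TO_PA, strain.dt, unit="mmHg",
                        periodic=True, period=strain.period)
    return PulseWaveform(sig, provenance)


def reconstruct_intravascular(skin: PulseWaveform, params: ViscoParams,
                              scale: PressureScale | None = None) -> PulseWaveform:
    """Reconstruct the intravascular pulse from an on-skin waveform.

    Pipeline: convert to Pa -> treat as surface stress -> periodic strain
    solution -> affine strain-to-pressure map.  Output is periodic with the
    same period and grid, provenance ``"reconstructed"``.
    """
    scale = scale or PressureScale()
    stress = skin.pressure.to_unit("Pa")
    eps_hat = solve_strain_periodic(stress, params)
    return strain_to_pressure(eps_hat, scale, provenance="reconstructed")


def normalize_waveform(w: PulseWaveform) -> PulseWaveform:
    """Min-max normalize one waveform to [0, 1] (affine-invariant shape)."""
    v = w.values
    rng = np.ptp(v)
    if rng == 0:
        raise DegenerateNormalizationError("cannot normalize a constant waveform")
    return w.with_values((v - np.min(v)) / rng, unit="normalized")


def optimal_circular_shift(ref: PulseWaveform, other: PulseWaveform) -> int:
    """Integer circular shift of ``other`` minimizing the L2 gap to ``ref``.

    The shift s is the argument of ``np.roll(other.values, s)``; candidates
    span one period and ties resolve to the smallest |s| (then the smaller
    signed s).  Cross-correlation is evaluated by FFT; the L2 cost follows
    from it exactly because the energy terms are shift-invariant.
    """
    _check_common_grid(ref, other)
    x = ref.values
    y = other.values
    n = x.size
    # cost(s) = sum((x - roll(y, s))^2) = |x|^2 + |y|^2 - 2*cc(s)
    cc = np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(y)), n)
    best = np.max(cc)
    # tolerate FFT roundoff when ranking exact ties
    tol = 1e-9 * max(1.0, abs(best))
    candidates = np.flatnonzero(cc >= best - tol)
    signed = np.where(candidates > n // 2, candidates - n, candidates)
    order = np.lexsort((signed, np.abs(signed)))
    return int(signed[order[0]])


def align_waveforms(ref: PulseWaveform, other: PulseWaveform) -> PulseWaveform:
    """Circularly shift ``other`` onto the phase of ``ref``."""
    s = optimal_circular_shift(ref, other)
    return other.with_values(np.roll(other.values, s))


def _check_common_grid(ref: PulseWaveform, other: PulseWaveform) -> None:
    if ref.values.size != other.values.size or \
            abs(ref.dt - other.dt) > 1e-12 or \
            abs(ref.period - other.period) > 1e-9:
        raise ContractError("waveforms must share period, dt and length")
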