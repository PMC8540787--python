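"""Quantitative waveform comparison: relative L2 error, ensemble
consistency, and the augmentation index.

All integrals over one period use the uniform-weight (periodic trapezoid /
Riemann) rule: on a periodic grid covering [0, T) every sample carries the
same weight dt.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import find_peaks

from .errors import ContractError, NoPeakError
from .signals import PulseWaveform
from .reconstruction import _check_common_grid


@dataclass(frozen=True)
class MetricReport:
    """Comparison summary between a test and a reference waveform."""

    test_label: str
    ref_label: str
    l2_error_pct: float
    ai_ref: float
    ai_test: float
    ai_error_pct: float
    period_ms: float

    def to_dict(self) -> dict:
        return asdict(self)


def relative_l2_error(test: PulseWaveform, ref: PulseWaveform) -> float:
    """Relative L2 error, percent: 100*sqrt(int (test-ref)^2 / int ref^2)."""
    _check_common_grid(ref, test)
    r = ref.values
    d = test.values - r
    denom = float(np.sum(r * r))
    if denom == 0.0:
        raise ZeroDivisionError("reference waveform is identically zero")
    return 100.0 * float(np.sqrt(np.sum(d * d) / denom))


def ensemble_consistency_error(samples: list[PulseWaveform],
                               mean: PulseWaveform) -> float:
    """Mean relative L2 deviation of an ensemble from its mean, percent.

    (1/n) * sum_i sqrt(int (u_i - u)^2 / int u^2) * 100, used to check that
    repeatedly generated pulses of one morphology stay consistent (the
    reference protocol averages 40 cycles).
    """
    if len(samples) < 2:
        raise ContractError("ensemble consistency needs at least 2 samples")
    return float(np.mean([relative_l2_error(s, mean) for s in samples]))


@dataclass(frozen=True)
class AIResult:
    """Augmentation index with peak bookkeeping.

    ``fallback`` marks pulses without a distinct second systolic peak, where
    the late-systolic shoulder (derivative closest to zero after the first
    peak) stands in for it.
    """

    ai: float
    fallback: bool
    i_first: int
    i_second: int


def _foot_index(v: np.ndarray) -> int:
    """Pulse-onset sample: local minimum preceding the steepest upstroke."""
    n = v.size
    d = (np.roll(v, -1) - np.roll(v, 1))
    i = int(np.argmax(d))
    for _ in range(n):
        if v[(i - 1) % n] >= v[i]:
            break
        i = (i - 1) % n
    return i


def augmentation_index(w: PulseWaveform, prominence_frac: float = 0.02,
                       systolic_frac: float = 0.6,
                       detail: bool = False) -> float | AIResult:
    """Augmentation index: second systolic peak height over the first.

    Heights are read from the foot-anchored, min-max normalized waveform
    (so AI is invariant to positive affine rescaling of the pressure axis);
    the cycle is rotated to start at the pulse foot — the local minimum
    immediately preceding the steepest upstroke, which is robust against a
    dicrotic notch dipping below end-diastole — and peaks are searched in
    the systolic window, the first ``systolic_frac`` of the period, with
    prominence at least ``prominence_frac`` of the pulse range.  If only
    one peak exists, the late-systolic shoulder (the point after the first
    peak where the derivative is closest to zero) is used and flagged.
    """
    v = w.values
    rng = np.ptp(v)
    if rng == 0:
        raise NoPeakError("constant waveform has no systolic peak")
    v = (v - np.min(v)) / rng
    v = np.roll(v, -_foot_index(v))  # start the cycle at the foot
    n = v.size
    win = v[: max(int(round(systolic_frac * n)), 3)]
    peaks, _ = find_peaks(win, prominence=prominence_frac)
    if peaks.size == 0:
        raise NoPeakError("no systolic peak found in the systolic window")
    i1 = int(peaks[0])
    if peaks.size >= 2:
        i2 = int(peaks[1])
        fallback = False
    else:
        d = np.gradient(win, w.dt)
        tail = np.arange(i1 + 1, win.size)
        if tail.size == 0:
            raise NoPeakError("no room after the first peak for a shoulder")
        i2 = int(tail[np.argmin(np.abs(d[tail]))])
        fallback = True
    ai = float(v[i2] / v[i1])
    if detail:
        return AIResult(ai=ai, fallback=fallback, i_first=i1, i_second=i2)
    return ai


def relative_ai_error(ai_test: float, ai_ref: float) -> float:
    """Relative augmentation-index error, percent: 100*|dAI|/AI_ref."""
    if not np.isfinite(ai_ref) or ai_ref <= 0:
        raise ContractError(f"reference AI must be positive, got {ai_ref}")
    return 100.0 * abs(ai_test - ai_ref) / ai_ref


def compare_waveforms(test: PulseWaveform, ref: PulseWaveform,
                      period_ms: float | None = None) -> MetricReport:
    """Normalized comparison: relative L2 error plus AI agreement.

    Both waveforms are expected already normalized and aligned upstream for
    the L2 figure; the AI computation normalizes internally either way.
    """
    return MetricReport(
        test_label=test.provenance,
        ref_label=ref.provenance,
        l2_error_pct=relative_l2_error(test, ref),
        ai_ref=float(augmentation_index(ref)),
        ai_test=float(augmentation_index(test)),
        ai_error_pct=relative_ai_error(augmentation_index(test),
                                       augmentation_index(ref)),
        period_ms=1000.0 * ref.period if period_ms is None else period_ms,
    )
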