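"""Synthetic-data generators for the whole pipeline.

Nothing in the toolkit requires instrument data: this module fabricates

* age-graded intravascular radial pulses — sums of periodically wrapped
  Gaussian bumps (percussion, tidal and dicrotic waves) scaled to the
  80/120 mmHg diastolic/systolic reference range, with the tidal-to-
  percussion amplitude ratio controlling the augmentation index;
* on-skin tonometric signals, by pushing an intravascular pulse through the
  forward skin filter (strain -> stress of the standard linear solid);
* DMA-style triangular indentation records (1 mm at 1 mm/s reference
  protocol) for both the vessel-only spring and the full skin+vessel model.

Sensor characteristics are emulated with 1000 Hz sampling and additive
Gaussian noise band-limited to the 0.1–27 Hz pass band of the pulse sensor
electronics.  Every generator is a pure function of its parameters and the
seed in :class:`NoiseSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError, ParameterError
from .fitting import CompressionRecord, IndenterGeometry
from .reconstruction import PressureScale
from .signals import MMHG_TO_PA, SampledSignal, PulseWaveform
from .viscoelastic import ViscoParams, forward_stress


@dataclass(frozen=True)
class GaussianBump:
    """One pulse component: amplitude (fraction of pulse pressure), center
    and width (fractions of the period)."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class NoiseSpec:
    """Additive band-limited Gaussian sensor noise.

    ``sd`` is the standard deviation of the generated noise in the unit of
    the host signal; the white draw is masked to the ``band`` (Hz) in the
    frequency domain and rescaled to ``sd``, mirroring the sensor's
    band-pass without committing to a filter order.
    """

    sd: float = 0.5
    band: tuple[float, float] = (0.1, 27.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("noise sd must be non-negative")


@dataclass(frozen=True)
class PulseTemplate:
    """Parametric description of a synthetic intravascular radial pulse."""

    period: float = 0.650
    p_dia: float = 80.0
    p_sys: float = 120.0
    percussion: GaussianBump = GaussianBump(1.00, 0.14, 0.050)
    tidal: GaussianBump = GaussianBump(0.45, 0.36, 0.075)
    dicrotic: GaussianBump = GaussianBump(0.18, 0.64, 0.050)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ContractError("period must be positive")
        if self.p_sys <= self.p_dia:
            raise ContractError("systolic pressure must exceed diastolic")
        if self.percussion.amplitude <= 0:
            raise ContractError("percussion amplitude must be positive")
        centers = [self.percussion.center, self.tidal.center, self.dicrotic.center]
        if not all(0.0 < c < 1.0 for c in centers) or sorted(centers) != centers:
            raise ContractError("bump centers must be ordered within (0, 1)")
        for b in (self.percussion, self.tidal, self.dicrotic):
            if b.amplitude < 0 or b.width <= 0:
                raise ContractError("bump amplitudes must be >= 0 and widths > 0")

    def with_period(self, period: float) -> "PulseTemplate":
        return replace(self, period=period)


#: Age-graded presets qualitatively following in vivo radial-pulse trends:
#: with age the tidal (reflected) wave grows and moves toward the percussion
#: wave, raising the augmentation index, while the dicrotic wave fades.
AGE_TEMPLATES: dict[int, PulseTemplate] = {
    15: PulseTemplate(percussion=GaussianBump(1.00, 0.13, 0.050),
                      tidal=GaussianBump(0.42, 0.36, 0.070),
                      dicrotic=GaussianBump(0.18, 0.64, 0.050)),
    35: PulseTemplate(percussion=GaussianBump(1.00, 0.13, 0.050),
                      tidal=GaussianBump(0.58, 0.34, 0.070),
                      dicrotic=GaussianBump(0.16, 0.64, 0.050)),
    65: PulseTemplate(percussion=GaussianBump(1.00, 0.14, 0.052),
                      tidal=GaussianBump(0.78, 0.32, 0.072),
                      dicrotic=GaussianBump(0.13, 0.63, 0.055)),
    85: PulseTemplate(percussion=GaussianBump(1.00, 0.15, 0.055),
                      tidal=GaussianBump(0.95, 0.305, 0.075),
                      dicrotic=GaussianBump(0.10, 0.62, 0.055)),
}


def band_limited_noise(n: int, dt: float, noise: NoiseSpec) -> np.ndarray:
    """Seeded Gaussian noise restricted to the sensor pass band."""
    if noise.sd == 0:
        return np.zeros(n)
    rng = np.random.default_rng(noise.seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, dt)
    spec[(f < noise.band[0]) | (f > noise.band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    s = float(np.std(x))
    return x * (noise.sd / s) if s > 0 else np.zeros(n)


def _wrapped_bumps(tpl: PulseTemplate, phase: np.ndarray) -> np.ndarray:
    """Sum of the template bumps as periodic functions of phase in [0, 1)."""
    out = np.zeros_like(phase)
    for b in (tpl.percussion, tpl.tidal, tpl.dicrotic):
        d = (phase - b.center + 0.5) % 1.0 - 0.5  # circular distance
        out += b.amplitude * np.exp(-0.5 * (d / b.width) ** 2)
    return out


def generate_intravascular_pulse(tpl: PulseTemplate, dt: float = 1e-3,
                                 n_periods: int = 1,
                                 noise: NoiseSpec | None = None) -> PulseWaveform:
    """Synthesize a periodic intravascular pulse from a template.

    The noiseless waveform spans exactly [p_dia, p_sys] mmHg; noise (if any)
    is added afterwards per period-spanning record.  Deterministic given the
    template and the noise seed.
    """
    if dt <= 0 or dt > 2e-3:
        raise ContractError("pulse synthesis expects 0 < dt <= 2 ms")
    if n_periods < 1:
        raise ContractError("n_periods must be >= 1")
    m = tpl.period / dt
    if abs(m - round(m)) > 1e-9:
        raise ContractError("period must be an integer number of samples")
    m = int(round(m))
    phase = np.arange(m) / m
    raw = _wrapped_bumps(tpl, phase)
    lo, hi = float(np.min(raw)), float(np.max(raw))
    p = tpl.p_dia + (tpl.p_sys - tpl.p_dia) * (raw - lo) / (hi - lo)
    p = np.tile(p, n_periods)
    if noise is not None:
        p = p + band_limited_noise(p.size, dt, noise)
    sig = SampledSignal(p, dt, unit="mmHg", periodic=True, period=tpl.period)
    return PulseWaveform(sig, provenance="intravascular")


def simulate_tonometry(intra: PulseWaveform, params: ViscoParams,
                       scale: PressureScale | None = None,
                       noise: NoiseSpec | None = None) -> PulseWaveform:
    """Forward model: intravascular pulse -> on-skin tonometric signal.

    Inverts the affine pressure map to vessel strain, drives the skin layer
    with it (strain -> stress of the SLS), converts to mmHg and adds sensor
    noise.  This is the exact forward counterpart of
    :func:`pulsetf.reconstruction.reconstruct_intravascular`.
    """
    scale = scale or PressureScale()
    p_pa = intra.pressure.to_unit("Pa")
    eps = SampledSignal((p_pa.values - scale.p0) / scale.K, p_pa.dt, unit="strain",
                        periodic=True, period=p_pa.period)
    sigma = forward_stress(eps, params)
    skin = sigma.values / MMHG_TO_PA
    if noise is not None:
        skin = skin + band_limited_noise(skin.size, intra.dt, noise)
    sig = SampledSignal(skin, intra.dt, unit="mmHg", periodic=True,
                        period=intra.period)
    return PulseWaveform(sig, provenance="on-skin")


@dataclass(frozen=True, eq=False)
class SyntheticDMA:
    """A pair of synthetic indentation records sharing one protocol."""

    skin_vessel: CompressionRecord
    vessel_only: CompressionRecord


def generate_dma_experiment(params: ViscoParams, depth: float = 1e-3,
                            speed: float = 1e-3,
                            geom: IndenterGeometry | None = None,
                            noise: NoiseSpec | None = None,
                            fs: float = 1000.0) -> SyntheticDMA:
    """Triangular indentation records for the skin+vessel and vessel-only tests.

    Displacement ramps 0 -> depth -> 0 at constant speed (reference: 1 mm at
    1 mm/s, 1000 Hz).  The skin+vessel force follows the viscoelastic
    forward model from zero initial stress; the vessel-only record is the
    pure spring ``sigma = E1 * eps``.  Optional noise is added to the
    forces only, leaving the commanded displacement exact.
    """
    if depth <= 0 or speed <= 0 or fs <= 0:
        raise ParameterError("depth, speed and fs must be positive")
    geom = geom or IndenterGeometry()
    dt = 1.0 / fs
    n = int(round(2.0 * depth / speed * fs)) + 1
    t = np.arange(n) * dt
    disp = depth - np.abs(depth - speed * t)
    disp[disp < 0] = 0.0
    strain = SampledSignal(disp / geom.gauge_length, dt, unit="strain", periodic=False)
    sigma_sv = forward_stress(strain, params).values
    sigma_v = params.E1 * strain.values
    force_sv = sigma_sv * geom.contact_area
    force_v = sigma_v * geom.contact_area
    if noise is not None:
        force_sv = force_sv + band_limited_noise(n, dt, noise)
        force_v = force_v + band_limited_noise(n, dt, replace(noise, seed=noise.seed + 1))
    return SyntheticDMA(
        skin_vessel=CompressionRecord(time=t, displacement=disp, force=force_sv),
        vessel_only=CompressionRecord(time=t, displacement=disp, force=force_v),
    )
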