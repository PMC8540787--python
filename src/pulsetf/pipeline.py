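"""End-to-end synthetic evaluation pipeline and its configuration.

``run_pipeline`` chains the stages of the study for every requested
age/period combination: synthesize an intravascular reference pulse, push
it through the forward skin filter to get the on-skin tonometric signal,
optionally fit (E2, eta) from a synthetic indentation experiment,
reconstruct the intravascular waveform from the on-skin signal, and compare
reconstructed and on-skin waveforms against the reference with the L2 and
augmentation-index metrics.  Reports embed full provenance (config hash,
seeds, package version) and the run is deterministic for a given config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .fitting import GridSpec, IndenterGeometry, estimate_E1, grid_search, to_stress_strain
from .metrics import MetricReport, compare_waveforms
from .reconstruction import (
    PressureScale,
    align_waveforms,
    normalize_waveform,
    reconstruct_intravascular,
)
from .synthetic import (
    AGE_TEMPLATES,
    NoiseSpec,
    generate_dma_experiment,
    generate_intravascular_pulse,
    simulate_tonometry,
)
from .viscoelastic import REFERENCE_PARAMS, ViscoParams

logger = logging.getLogger("pulsetf")

_CONFIG_KEYS = {
    "ages", "periods_ms", "dt_ms", "params", "scale", "noise_sd", "seed",
    "mismatch", "fit_dma", "grid", "gauge_length", "outdir",
}
_PARAM_KEYS = {"E1", "E2", "eta"}
_SCALE_KEYS = {"K", "p0"}
_MISMATCH_KEYS = {"E2_factor", "eta_factor"}
_GRID_KEYS = {"E2_max", "eta_max", "points"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    ages: tuple[int, ...] = (15, 35, 65, 85)
    periods_ms: tuple[float, ...] = (650.0, 750.0)
    dt_ms: float = 1.0
    params: ViscoParams = REFERENCE_PARAMS
    scale: PressureScale = field(default_factory=PressureScale)
    noise_sd: float = 0.0
    seed: int = 0
    mismatch: tuple[float, float] = (1.0, 1.0)  # (E2_factor, eta_factor)
    fit_dma: bool = False
    grid: GridSpec = field(default_factory=GridSpec)
    gauge_length: float = 5e-3
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = [a for a in self.ages if a not in AGE_TEMPLATES]
        if unknown:
            raise ConfigError(f"unknown age groups {unknown}; available: "
                              f"{sorted(AGE_TEMPLATES)}")
        if self.dt_ms <= 0 or self.dt_ms > 2.0:
            raise ConfigError("dt_ms must be in (0, 2]")
        for T in self.periods_ms:
            m = T / self.dt_ms
            if abs(m - round(m)) > 1e-9:
                raise ConfigError(f"period {T} ms is not a multiple of dt {self.dt_ms} ms")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if any(f <= 0 for f in self.mismatch):
            raise ConfigError("mismatch factors must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def check(keys: set[str], sub: dict, where: str) -> None:
            extra = set(sub) - keys
            if extra:
                raise ConfigError(f"unknown {where} keys: {sorted(extra)}")

        check(_CONFIG_KEYS, d, "config")
        kw: dict = {}
        for key in ("ages", "periods_ms"):
            if key in d:
                kw[key] = tuple(d[key])
        for key in ("dt_ms", "noise_sd", "seed", "fit_dma", "gauge_length", "outdir"):
            if key in d:
                kw[key] = d[key]
        if "params" in d:
            check(_PARAM_KEYS, d["params"], "params")
            kw["params"] = ViscoParams(**{k: float(v) for k, v in d["params"].items()})
        if "scale" in d:
            check(_SCALE_KEYS, d["scale"], "scale")
            kw["scale"] = PressureScale(**{k: float(v) for k, v in d["scale"].items()})
        if "mismatch" in d:
            check(_MISMATCH_KEYS, d["mismatch"], "mismatch")
            kw["mismatch"] = (float(d["mismatch"].get("E2_factor", 1.0)),
                              float(d["mismatch"].get("eta_factor", 1.0)))
        if "grid" in d:
            check(_GRID_KEYS, d["grid"], "grid")
            kw["grid"] = GridSpec(**{k: (int(v) if k == "points" else float(v))
                                     for k, v in d["grid"].items()})
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        obj = yaml.safe_load(path.read_text())  # YAML is a superset of JSON
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(obj)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance."""
        blob = json.dumps({
            "ages": self.ages, "periods_ms": self.periods_ms, "dt_ms": self.dt_ms,
            "params": asdict(self.params), "scale": asdict(self.scale),
            "noise_sd": self.noise_sd, "seed": self.seed,
            "mismatch": self.mismatch, "fit_dma": self.fit_dma,
            "grid": asdict(self.grid), "gauge_length": self.gauge_length,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CaseResult:
    """Per-case comparison: reconstruction and raw on-skin vs reference."""

    age: int
    period_ms: float
    recon: MetricReport
    skin: MetricReport


@dataclass(frozen=True, eq=False)
class PipelineResult:
    cases: list[CaseResult]
    summary: pd.DataFrame
    provenance: dict
    fit: dict | None = None


def _evaluate_case(test, ref, period_ms: float) -> MetricReport:
    """Normalize both waveforms, align the test onto the reference, compare."""
    n_ref = normalize_waveform(ref)
    n_test = align_waveforms(n_ref, normalize_waveform(test))
    return compare_waveforms(n_test, n_ref, period_ms=period_ms)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full synthetic study described by ``config``."""
    from . import __version__

    dt = config.dt_ms * 1e-3
    truth = config.params
    recon_params = ViscoParams(truth.E1, truth.E2 * config.mismatch[0],
                               truth.eta * config.mismatch[1])
    logger.info("pipeline: params E1=%.4g E2=%.4g eta=%.4g, mismatch %s, seed %d",
                truth.E1, truth.E2, truth.eta, config.mismatch, config.seed)

    fit_report = None
    if config.fit_dma:
        geom = IndenterGeometry(gauge_length=config.gauge_length)
        noise = (NoiseSpec(sd=config.noise_sd, seed=config.seed + 1000)
                 if config.noise_sd > 0 else None)
        dma = generate_dma_experiment(truth, geom=geom, noise=noise)
        vs, vn = to_stress_strain(dma.vessel_only, geom)
        E1_hat = estimate_E1(vs, vn)
        ss, sn = to_stress_strain(dma.skin_vessel, geom)
        fit = grid_search(ss, sn, E1_hat, config.grid)
        logger.info("DMA fit: E1=%.4g Pa, optimum E2=%.4g Pa eta=%.4g Pa*s "
                    "(objective %.3e)", E1_hat, fit.E2_hat, fit.eta_hat,
                    fit.objective_value)
        fit_report = {"E1": E1_hat, "E2": fit.E2_hat, "eta": fit.eta_hat,
                      "objective": fit.objective_value,
                      "grid": asdict(config.grid)}

    cases: list[CaseResult] = []
    rows = []
    for k, (age, T_ms) in enumerate(
            [(a, T) for a in config.ages for T in config.periods_ms]):
        tpl = AGE_TEMPLATES[age].with_period(T_ms * 1e-3)
        noise = (NoiseSpec(sd=config.noise_sd, seed=config.seed + 10 * k)
                 if config.noise_sd > 0 else None)
        intra = generate_intravascular_pulse(tpl, dt=dt, noise=noise)
        skin_noise = (NoiseSpec(sd=config.noise_sd, seed=config.seed + 10 * k + 5)
                      if config.noise_sd > 0 else None)
        skin = simulate_tonometry(intra, truth, config.scale, noise=skin_noise)
        recon = reconstruct_intravascular(skin, recon_params, config.scale)
        rep_recon = _evaluate_case(recon, intra, T_ms)
        rep_skin = _evaluate_case(skin, intra, T_ms)
        cases.append(CaseResult(age=age, period_ms=T_ms, recon=rep_recon,
                                skin=rep_skin))
        rows.append({"age": age, "period_ms": T_ms,
                     "recon_l2_pct": rep_recon.l2_error_pct,
                     "skin_l2_pct": rep_skin.l2_error_pct,
                     "recon_ai_err_pct": rep_recon.ai_error_pct,
                     "skin_ai_err_pct": rep_skin.ai_error_pct,
                     "ai_ref": rep_recon.ai_ref})
        logger.info("case age=%d T=%gms: recon L2=%.3f%% skin L2=%.3f%%",
                    age, T_ms, rep_recon.l2_error_pct, rep_skin.l2_error_pct)

    summary = pd.DataFrame(rows)
    provenance = {"config_hash": config.digest(), "seed": config.seed,
                  "version": __version__}
    result = PipelineResult(cases=cases, summary=summary, provenance=provenance,
                            fit=fit_report)
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for case in cases:
            blob = {"age": case.age, "period_ms": case.period_ms,
                    "recon": case.recon.to_dict(), "skin": case.skin.to_dict(),
                    **provenance}
            (out / f"report_age{case.age}_T{int(case.period_ms)}.json").write_text(
                json.dumps(blob, indent=2) + "\n")
        summary.to_csv(out / "summary.csv", index=False)
        if fit_report is not None:
            (out / "dma_fit.json").write_text(json.dumps(fit_report, indent=2) + "\n")
    return result
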