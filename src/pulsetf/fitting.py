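"""Indentation-experiment processing and viscoelastic parameter estimation.

The vessel modulus E1 comes from the vessel-only compression test: force and
displacement are converted to nominal stress and strain and E1 is the
least-squares slope of the loading branch.  The skin parameters (E2, eta)
come from the skin+vessel test: for each candidate pair the strain history
is reconstructed from the measured stress via the release-boundary solver
and compared with the measured strain through the L2 objective

    Obj(E2, eta) = int_0^T (eps_hat_{E2,eta}(s) - eps(s))^2 ds,

minimized by exhaustive evaluation on a uniform grid over an open parameter
rectangle (reference: (0, 80 MPa) x (0, 80 MPa*s), 222 nodes per axis with
mesh 80/221 per axis unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InvalidRecordError,
    ParameterError,
    SingularFitError,
)
from .signals import GRID_TOL, SampledSignal
from .viscoelastic import (
    _EXP_MAX,
    _cum_exp_integral,
    ViscoParams,
    sampled_derivative,
    solve_strain_release,
)


@dataclass(frozen=True, eq=False)
class CompressionRecord:
    """A loading/unloading indentation record: time, displacement, force.

    The reference protocol indents by 1 mm at 1 mm/s and releases at the
    same speed (triangular displacement).  Time must be strictly
    increasing; displacement is non-negative and starts/ends at zero.
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (t.shape == d.shape == f.shape) or t.ndim != 1 or t.size < 4:
            raise InvalidRecordError("time/displacement/force must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidRecordError("time must be strictly increasing")
        if np.any(d < -1e-12):
            raise InvalidRecordError("displacement must be non-negative")
        tol = 1e-9 + 1e-9 * float(np.max(d))
        if abs(d[0]) > tol or abs(d[-1]) > tol:
            raise InvalidRecordError("displacement must start and end at zero")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)

    @property
    def loading_mask(self) -> np.ndarray:
        """Boolean mask of the loading phase (up to peak displacement)."""
        return np.arange(self.time.size) <= int(np.argmax(self.displacement))

    @property
    def phase(self) -> np.ndarray:
        """Per-sample phase labels, 'loading' or 'unloading'."""
        return np.where(self.loading_mask, "loading", "unloading")


@dataclass(frozen=True)
class IndenterGeometry:
    """Flat indenter tip diameter and the gauge length used to form strain.

    The reference tip diameter is 4 mm (similar to the vessel's outer
    diameter).  The gauge length — the thickness over which displacement is
    expressed as strain — is a modelling choice (default 5 mm); fitted
    (E2, eta) are conditional on it, and for self-consistent synthetic
    round trips its value cancels.
    """

    tip_diameter: float = 4e-3
    gauge_length: float = 5e-3

    def __post_init__(self) -> None:
        if self.tip_diameter <= 0 or self.gauge_length <= 0:
            raise ParameterError("tip_diameter and gauge_length must be positive")

    @property
    def contact_area(self) -> float:
        """Nominal flat-punch contact area pi*(d/2)^2, m^2."""
        return np.pi * (self.tip_diameter / 2.0) ** 2


def to_stress_strain(rec: CompressionRecord, geom: IndenterGeometry,
                     dt: float | None = None) -> tuple[SampledSignal, SampledSignal]:
    """Convert a compression record to nominal stress and strain signals.

    Stress is force over the constant flat-punch area; strain is
    displacement over the gauge length.  Records with a non-uniform time
    grid are resampled by linear interpolation (target ``dt`` defaults to
    the median sampling step).
    """
    t = rec.time - rec.time[0]
    steps = np.diff(t)
    if dt is None:
        dt = float(np.median(steps))
    uniform = np.max(np.abs(steps - dt)) <= GRID_TOL
    if uniform:
        force, disp = rec.force, rec.displacement
    else:
        n = int(np.floor(t[-1] / dt)) + 1
        tu = np.arange(n) * dt
        force = np.interp(tu, t, rec.force)
        disp = np.interp(tu, t, rec.displacement)
    stress = SampledSignal(force / geom.contact_area, dt, unit="Pa", periodic=False)
    strain = SampledSignal(disp / geom.gauge_length, dt, unit="strain", periodic=False)
    return stress, strain


def estimate_E1(stress: SampledSignal, strain: SampledSignal) -> float:
    """Vessel modulus: OLS slope of stress vs strain over the loading phase.

    Intended for the (approximately linear) vessel-only experiment.
    Returns the slope in Pa.
    """
    if stress.n != strain.n or abs(stress.dt - strain.dt) > GRID_TOL:
        raise InvalidRecordError("stress and strain must share one sample grid")
    mask = np.arange(strain.n) <= int(np.argmax(strain.values))
    x = strain.values[mask]
    y = stress.values[mask]
    if x.size < 2 or np.ptp(x) == 0:
        raise SingularFitError("strain is constant; slope is undefined")
    return float(stats.linregress(x, y).slope)


@dataclass(frozen=True)
class GridSpec:
    """Uniform search grid over the open rectangle (0, E2_max] x (0, eta_max].

    Nodes along each axis sit at k*h for k = 1..points with mesh
    h = max/(points - 1), excluding the degenerate 0 node; the reference
    protocol uses 222 points per axis over 80 MPa and 80 MPa*s, i.e.
    h = 80/221 per axis unit.
    """

    E2_max: float = 80e6
    eta_max: float = 80e6
    points: int = 222

    def __post_init__(self) -> None:
        if self.E2_max <= 0 or self.eta_max <= 0:
            raise ParameterError("grid ranges must be positive")
        if self.points < 2:
            raise ParameterError("grid needs at least 2 points per axis")

    @property
    def h_E2(self) -> float:
        return self.E2_max / (self.points - 1)

    @property
    def h_eta(self) -> float:
        return self.eta_max / (self.points - 1)

    @property
    def E2_nodes(self) -> np.ndarray:
        return self.h_E2 * np.arange(1, self.points + 1)

    @property
    def eta_nodes(self) -> np.ndarray:
        return self.h_eta * np.arange(1, self.points + 1)


@dataclass(frozen=True, eq=False)
class FitResult:
    """Outcome of the (E2, eta) grid search.

    ``surface[i, j]`` is the objective at ``(E2_nodes[i], eta_nodes[j])``.
    """

    E2_hat: float
    eta_hat: float
    objective_value: float
    surface: np.ndarray
    E2_nodes: np.ndarray
    eta_nodes: np.ndarray
    refined: bool = False


def objective(E2: float, eta: float, stress: SampledSignal,
              strain: SampledSignal, E1: float) -> float:
    """L2 misfit between release-reconstructed and measured strain."""
    params = ViscoParams(E1=E1, E2=E2, eta=eta)
    eps_hat = solve_strain_release(stress, params)
    d = eps_hat.values - strain.values
    with np.errstate(over="ignore", invalid="ignore"):
        return float(np.trapezoid(d * d, dx=stress.dt))


def _objective_surface(stress: SampledSignal, strain: SampledSignal, E1: float,
                       spec: GridSpec) -> np.ndarray:
    """Objective on every grid node, via the same numerics as `objective`.

    The forcing splits as F = c1*sigma + sigma_dot/E1 with only
    c1 = (E1+E2)/(E1*eta) depending on the candidate pair, so sigma and its
    derivative are shared across all nodes.
    """
    dt = stress.dt
    sigma = stress.values
    sigma_dot = sampled_derivative(sigma, dt, periodic=False)
    t = stress.t
    T = t[-1]
    eps = strain.values
    E2s, etas = spec.E2_nodes, spec.eta_nodes
    surface = np.empty((E2s.size, etas.size))
    with np.errstate(over="ignore", invalid="ignore"):
        for j, eta in enumerate(etas):
            for i, E2 in enumerate(E2s):
                a = E2 / eta
                F = (E1 + E2) / (E1 * eta) * sigma + sigma_dot / E1
                I = _cum_exp_integral(F, a, dt)
                eps_hat = I - I[-1] * np.exp(np.minimum(a * (T - t), _EXP_MAX))
                d = eps_hat - eps
                surface[i, j] = np.trapezoid(d * d, dx=dt)
    return surface


def grid_search(stress: SampledSignal, strain: SampledSignal, E1: float,
                spec: GridSpec | None = None, refine: bool = False) -> FitResult:
    """Estimate (E2, eta) by exhaustive objective evaluation on the grid.

    Ties are broken toward the lexicographically smallest (E2, eta).  With
    ``refine=True`` a Nelder–Mead polish (off-grid) runs from the best node,
    bounded to one cell around it; the reference protocol — the bare grid
    argmin — is the default.
    """
    spec = spec or GridSpec()
    if stress.n != strain.n or abs(stress.dt - strain.dt) > GRID_TOL:
        raise InvalidRecordError("stress and strain must share one sample grid")
    surface = _objective_surface(stress, strain, E1, spec)
    finite = np.where(np.isnan(surface), np.inf, surface)
    if not np.any(np.isfinite(finite)):
        raise FitFailureError("objective surface contains no finite values")
    best = np.min(finite)
    ii, jj = np.where(finite == best)
    order = np.lexsort((spec.eta_nodes[jj], spec.E2_nodes[ii]))
    i, j = int(ii[order[0]]), int(jj[order[0]])
    E2_hat, eta_hat = float(spec.E2_nodes[i]), float(spec.eta_nodes[j])
    obj = float(surface[i, j])
    refined = False
    if refine:
        res = optimize.minimize(
            lambda p: objective(p[0], p[1], stress, strain, E1),
            x0=[E2_hat, eta_hat], method="Nelder-Mead",
            bounds=[(max(E2_hat - spec.h_E2, spec.h_E2 * 1e-3), E2_hat + spec.h_E2),
                    (max(eta_hat - spec.h_eta, spec.h_eta * 1e-3), eta_hat + spec.h_eta)],
        )
        if res.fun < obj:
            E2_hat, eta_hat, obj = float(res.x[0]), float(res.x[1]), float(res.fun)
            refined = True
    return FitResult(E2_hat=E2_hat, eta_hat=eta_hat, objective_value=obj,
                     surface=surface, E2_nodes=spec.E2_nodes,
                     eta_nodes=spec.eta_nodes, refined=refined)


def hysteresis_area(rec: CompressionRecord) -> float:
    """Signed area enclosed by the force–displacement loop, J.

    Positive for a dissipative loop traversed loading-above-unloading; zero
    for a purely elastic (reversible) response.
    """
    return float(np.trapezoid(rec.force, rec.displacement))
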