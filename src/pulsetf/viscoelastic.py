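"""Standard-linear-solid constitutive model and its time-domain solvers.

The wrist is modelled as two layers: the arterial vessel acts as a linear
spring (elastic modulus ``E1``) in series with a Kelvin–Voigt skin layer — a
spring (``E2``) in parallel with a dashpot (viscosity ``eta``).  Together
they form the standard linear solid (SLS) with constitutive law

.. math::

    \\sigma + \\frac{\\eta}{E_1+E_2}\\dot\\sigma
        = \\frac{E_1 E_2}{E_1+E_2}\\,\\epsilon
        + \\frac{E_1\\eta}{E_1+E_2}\\,\\dot\\epsilon .

Dividing by :math:`E_1\\eta/(E_1+E_2)` and treating strain as the unknown
turns this into a first-order linear ODE

.. math::

    \\dot\\epsilon + a\\,\\epsilon = F(t), \\qquad
    a = \\frac{E_2}{\\eta}, \\qquad
    F = \\frac{E_1+E_2}{E_1\\eta}
        \\Bigl(\\sigma + \\frac{\\eta}{E_1+E_2}\\dot\\sigma\\Bigr),

solved by the integrating factor: :math:`\\hat\\epsilon(t) =
e^{-at}(\\int_0^t e^{a\\tau}F\\,d\\tau + C)`.  Two boundary conditions occur
in practice and give the two solvers below:

* a finite loading/unloading (indentation) experiment whose strain returns
  to zero at the end — terminal condition :math:`\\hat\\epsilon(T)=0`
  (:func:`solve_strain_release`);
* a periodic pulse waveform driven by a rotating cam —
  :math:`\\hat\\epsilon(0)=\\hat\\epsilon(T)` (:func:`solve_strain_periodic`).

Numerics
--------
Exponentials are never evaluated with a raw ``exp(a*tau)`` growing over the
whole record; every weight is of the shifted form ``exp(-a*(t - tau))`` with
non-positive exponent, so the solvers cannot overflow for any rate ``a``
unless the solution itself does.  The cumulative integral uses an
exponential integrator that is *exact* for piecewise-linear forcing: on each
step it applies the analytic weights of ``exp(-a(t_k - tau))`` against a
linear interpolant of F.  For ``a*dt << 1`` this coincides with the
trapezoid rule to O(dt^2); unlike the plain trapezoid rule it remains
accurate in the stiff limit ``a*dt >> 1`` (needed for the eta -> 0 elastic
limit of :func:`forward_stress`).

Derivatives of sampled signals use second-order central differences with
periodic wrap for periodic signals and one-sided second-order stencils at
the ends otherwise — the same O(dt^2) accuracy as the quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import ContractError, ParameterError, UnitError
from .signals import PRESSURE_UNITS, STRAIN_UNITS, SampledSignal

#: Largest exponent passed to exp(); exp(709) ~ 8.2e307 is still finite.
_EXP_MAX = 709.0


@dataclass(frozen=True)
class ViscoParams:
    """Constitutive constants of the two-layer skin–vessel model.

    Attributes
    ----------
    E1 : float
        Elastic modulus of the vessel layer, Pa.  This is the instantaneous
        modulus of the assembly.
    E2 : float
        Elastic modulus of the skin spring, Pa.
    eta : float
        Skin viscosity, Pa*s.
    """

    E1: float
    E2: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite, got {v}")

    @property
    def a(self) -> float:
        """Strain relaxation rate a = E2/eta, 1/s."""
        return self.E2 / self.eta

    @property
    def tau_sigma(self) -> float:
        """Stress relaxation time eta/(E1+E2), s."""
        return self.eta / (self.E1 + self.E2)

    @property
    def E_inf(self) -> float:
        """Long-time (relaxed) modulus E1*E2/(E1+E2), Pa."""
        return self.E1 * self.E2 / (self.E1 + self.E2)

    @property
    def E_inst(self) -> float:
        """Instantaneous modulus, equal to E1, Pa."""
        return self.E1


#: Reference parameter set: vessel modulus from the vessel-only indentation
#: slope, skin spring and viscosity from the grid-search fit (SI units).
REFERENCE_PARAMS = ViscoParams(E1=39.58e6, E2=71.32e6, eta=39.94e6)


@dataclass(frozen=True, eq=False)
class ForcingAssembly:
    """Right-hand side F of the strain ODE together with its rate a."""

    F: SampledSignal
    a: float


def sampled_derivative(values: np.ndarray, dt: float, periodic: bool) -> np.ndarray:
    """Second-order finite-difference derivative of uniform samples.

    Periodic signals use central differences with wrap-around; finite
    records use ``np.gradient`` with second-order one-sided end stencils.
    """
    v = np.asarray(values, dtype=float)
    if periodic:
        return (np.roll(v, -1) - np.roll(v, 1)) / (2.0 * dt)
    return np.gradient(v, dt, edge_order=2)


def forcing_term(stress: SampledSignal, params: ViscoParams) -> ForcingAssembly:
    """Assemble F = ((E1+E2)/(E1*eta)) * (sigma + (eta/(E1+E2)) * dsigma/dt).

    The stress signal must carry a pressure unit; mmHg input is converted to
    Pa so that F always has SI units of 1/s (it forces a dimensionless
    strain).
    """
    if stress.unit not in PRESSURE_UNITS:
        raise UnitError(
            f"forcing_term needs a stress/pressure signal, got unit {stress.unit!r}"
        )
    sigma = stress.to_unit("Pa").values
    sigma_dot = sampled_derivative(sigma, stress.dt, stress.periodic)
    # (E1+E2)/(E1*eta) * (eta/(E1+E2)) collapses to 1/E1 on the derivative.
    F = (params.E1 + params.E2) / (params.E1 * params.eta) * sigma + sigma_dot / params.E1
    return ForcingAssembly(
        F=SampledSignal(F, stress.dt, unit="1/s", periodic=stress.periodic,
                        period=stress.period if stress.periodic else None),
        a=params.a,
    )


def _exp_weights(a: float, dt: float) -> tuple[float, float, float]:
    """Step weights of the piecewise-linear exponential integrator.

    Returns ``(r, w0, w1)`` such that with ``I_k = int_0^{t_k}
    exp(-a(t_k - tau)) G(tau) dtau`` and G linear on each step,

        I_k = r * I_{k-1} + w0 * G_{k-1} + w1 * G_k,   r = exp(-a*dt).

    Small ``x = a*dt`` uses a series expansion to avoid cancellation; both
    branches reduce to the trapezoid weights dt/2 as x -> 0.
    """
    x = a * dt
    if x < 1e-3:
        w0 = dt * (0.5 - x / 3.0 + x * x / 8.0 - x**3 / 30.0)
        w1 = dt * (0.5 - x / 6.0 + x * x / 24.0 - x**3 / 120.0)
        r = float(np.exp(-x))
    else:
        r = float(np.exp(-min(x, _EXP_MAX)))
        w0 = (1.0 - r * (1.0 + x)) / (a * a * dt)
        w1 = (1.0 - r) / a - w0
    return r, w0, w1


def _cum_exp_integral(G: np.ndarray, a: float, dt: float) -> np.ndarray:
    """Cumulative shifted-exponential integral I_k, with I_0 = 0.

    Evaluates ``I(t) = int_0^t exp(-a(t - tau)) G(tau) dtau`` on the sample
    grid via the linear recurrence of :func:`_exp_weights`, run through
    ``scipy.signal.lfilter``.  All exponents are non-positive.
    """
    G = np.asarray(G, dtype=float)
    r, w0, w1 = _exp_weights(a, dt)
    z = lfilter([w1, w0], [1.0, -r], G)
    # lfilter starts from y_0 = w1*G_0; shift the homogeneous mode so I_0 = 0.
    k = np.arange(G.size)
    decay = np.exp(-np.minimum(a * dt * k, 745.0))
    return z - w1 * G[0] * decay


def solve_strain_release(stress: SampledSignal, params: ViscoParams) -> SampledSignal:
    """Strain history of a finite load–release experiment.

    Solves ``d(eps)/dt + a*eps = F`` with the terminal condition
    ``eps(T) = 0``: the strain vanishes at the end of the releasing phase of
    an indentation experiment, which fixes the integration constant as
    ``C = -int_0^T exp(a*tau) F(tau) dtau``.  The returned signal satisfies
    the boundary condition exactly (to machine precision) by construction.

    For rates with ``a*(T - t)`` beyond the overflow threshold the true
    solution itself is astronomically large; the growth factor saturates at
    ``exp(709)`` so the result degrades to +/-inf rather than NaN.
    """
    if stress.periodic:
        raise ContractError(
            "solve_strain_release expects a finite (non-periodic) experiment; "
            "use solve_strain_periodic for periodic waveforms"
        )
    assembly = forcing_term(stress, params)
    F = assembly.F.values
    a = assembly.a
    t = stress.t
    T = t[-1]
    I = _cum_exp_integral(F, a, stress.dt)
    with np.errstate(over="ignore"):
        grow = np.exp(np.minimum(a * (T - t), _EXP_MAX))
        eps_hat = I - I[-1] * grow
    return SampledSignal(eps_hat, stress.dt, unit="strain", periodic=False)


def solve_strain_periodic(stress: SampledSignal, params: ViscoParams,
                          include_wrap: bool = False) -> SampledSignal:
    """Periodic steady-state strain response to a periodic stress.

    Solves ``d(eps)/dt + a*eps = F`` under the periodicity condition
    ``eps(0) = eps(T)``, which gives the integration constant

        C = exp(-aT) * int_0^T exp(a*tau) F dtau / (1 - exp(-aT)).

    Evaluated entirely with shifted exponentials:
    ``eps(t) = I(t) + exp(-a t) * I(T) / (1 - exp(-aT))`` where
    ``I(t) = int_0^t exp(-a(t-tau)) F dtau``.  With ``include_wrap=True``
    the wrap sample at ``t = T`` is appended (useful for inspecting the
    boundary condition and for plotting closed loops).
    """
    if not stress.periodic:
        raise ContractError(
            "solve_strain_periodic expects a periodic waveform; "
            "use solve_strain_release for finite experiments"
        )
    if stress.n != stress.samples_per_period:
        raise ContractError("solve_strain_periodic expects exactly one period of samples")
    assembly = forcing_term(stress, params)
    a = assembly.a
    F_ext = np.append(assembly.F.values, assembly.F.values[0])
    t_ext = np.arange(stress.n + 1) * stress.dt
    T = stress.period
    I = _cum_exp_integral(F_ext, a, stress.dt)
    C = I[-1] / (-np.expm1(-min(a * T, _EXP_MAX)))
    eps_ext = I + np.exp(-np.minimum(a * t_ext, 745.0)) * C
    if include_wrap:
        return SampledSignal(eps_ext, stress.dt, unit="strain", periodic=False)
    return SampledSignal(eps_ext[:-1], stress.dt, unit="strain",
                         periodic=True, period=T)


def forward_stress(strain: SampledSignal, params: ViscoParams) -> SampledSignal:
    """Stress produced by an imposed strain history (forward direction).

    Rearranging the constitutive law for stress gives

        d(sigma)/dt + b*sigma = G,   b = (E1+E2)/eta,
        G = b*E_inf*eps + E1*d(eps)/dt,

    solved by the same exponential integrating-factor scheme.  Periodic
    strain uses the periodic boundary condition; a finite record uses the
    causal instantaneous-elastic initial condition ``sigma(0) = E1*eps(0)``
    (the spring chain responds instantly, the dashpot has no history), so a
    quiescent experiment starting at zero strain starts at zero stress.
    """
    if strain.unit not in STRAIN_UNITS:
        raise UnitError(f"forward_stress needs a strain signal, got unit {strain.unit!r}")
    b = (params.E1 + params.E2) / params.eta
    eps = strain.values
    eps_dot = sampled_derivative(eps, strain.dt, strain.periodic)
    G = b * params.E_inf * eps + params.E1 * eps_dot
    if strain.periodic:
        if strain.n != strain.samples_per_period:
            raise ContractError("forward_stress expects exactly one period of samples")
        G_ext = np.append(G, G[0])
        t_ext = np.arange(strain.n + 1) * strain.dt
        I = _cum_exp_integral(G_ext, b, strain.dt)
        C = I[-1] / (-np.expm1(-min(b * strain.period, _EXP_MAX)))
        sigma = (I + np.exp(-np.minimum(b * t_ext, 745.0)) * C)[:-1]
        return SampledSignal(sigma, strain.dt, unit="Pa", periodic=True,
                             period=strain.period)
    I = _cum_exp_integral(G, b, strain.dt)
    t = strain.t
    sigma = I + np.exp(-np.minimum(b * t, 745.0)) * (params.E1 * eps[0])
    return SampledSignal(sigma, strain.dt, unit="Pa", periodic=False)


def harmonic_transfer(params: ViscoParams, omega: float | np.ndarray) -> complex | np.ndarray:
    """Frequency response H(i*omega) = strain per unit stress.

    H(iw) = ((E1+E2)/(E1*eta)) * (1 + i*w*eta/(E1+E2)) / (a + i*w).

    Limits: H(0) = 1/E_inf (static compliance of the springs in series) and
    H(inf) = 1/E1 (instantaneous modulus).  The pole sits at the strain
    relaxation rate a = E2/eta.  Serves as the independent frequency-domain
    route to the periodic time-domain solution.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ContractError("harmonic_transfer expects omega >= 0")
    num = (params.E1 + params.E2) / (params.E1 * params.eta) * (
        1.0 + 1j * w * params.eta / (params.E1 + params.E2)
    )
    H = num / (params.a + 1j * w)
    return complex(H) if np.isscalar(omega) else H
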