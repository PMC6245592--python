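"""Three-state photosynthetic-factory (PSF) kinetics.

The photosynthetic unit is modelled as occupying one of three states --
resting ``R``, activated ``A`` and photoinhibited ``B`` -- with
irradiance-driven transitions::

    R --(alpha*I)--> A --(beta*I)--> B
    A --(gamma)--> R   (photosynthetic production step)
    B --(delta)--> R   (recovery from photoinhibition)

The molar fractions y = (yR, yA, yB) evolve as a linear, input-affine ODE
``dy/dt = [A + u(t) B] y`` where ``u = I / I_opt`` is the irradiance
normalized by the optimal level ``q1``.  The generator has zero column sums
(total fraction conserved) and, for every u >= 0, one zero eigenvalue and a
fast/slow pair of stable eigenvalues whose ratio is of order 10^3 for the
Wu-Merchuk parameter set: light/dark reactions equilibrate in seconds while
photoinhibition builds up over tens of minutes.

Two parameter entry points exist: the raw rate constants (`PSFRates`) and
the reduced parametrization q1..q5 (`PSFReparam`).  The case-study preset
uses the rounded q2 = 0.3, q4 = 0.5 so that the printed steady states
(yA_ss = 0.625, yB_ss = 0.1875 at u = 1) come out exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "PSFRates", "PSFReparam", "PSFState", "WU_MERCHUK", "CASE_STUDY_REPARAM",
    "reparametrize", "reaction_generator", "reaction_generator_rates",
    "steady_state", "stiffness_ratio", "propagator", "simulate_full",
    "simulate_reduced", "KineticsTrajectory", "constant_light",
    "square_wave_light",
]


@dataclass(frozen=True)
class PSFRates:
    """Raw kinetic constants of the three-state model.

    alpha, beta are per-irradiance rates (uE^-1 m^2; multiplied by an
    irradiance in uE m^-2 s^-1 they give s^-1), gamma and delta are rates in
    s^-1, kappa is the dimensionless growth conversion factor and Me the
    maintenance rate in h^-1.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    kappa: float = 0.0
    Me: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"rate constant {name!r} must be strictly positive, "
                                 f"got {getattr(self, name)!r}")
        if self.kappa < 0.0:
            raise ValueError(f"kappa must be non-negative, got {self.kappa!r}")
        if self.Me < 0.0:
            raise ValueError(f"Me must be non-negative, got {self.Me!r}")

    @property
    def kappa_gamma(self) -> float:
        """Growth conversion kappa*gamma in s^-1."""
        return self.kappa * self.gamma


@dataclass(frozen=True)
class PSFReparam:
    """Reduced parametrization of the PSF model.

    q1 is the optimal irradiance (uE m^-2 s^-1), q2 a dimensionless shape
    parameter of the steady-state light curve, q3 the growth conversion
    (s^-1), q4 the fast relaxation rate scale (s^-1) and q5 = beta/alpha the
    (small) photoinhibition-to-activation ratio.
    """

    q1: float
    q2: float
    q3: float
    q4: float
    q5: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if not getattr(self, f.name) > 0.0:
                raise ValueError(f"{f.name} must be strictly positive, "
                                 f"got {getattr(self, f.name)!r}")


@dataclass(frozen=True)
class PSFState:
    """Molar fractions of the resting, activated and inhibited states."""

    yR: float
    yA: float
    yB: float

    def __post_init__(self) -> None:
        for name in ("yR", "yA", "yB"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"fraction {name}={v!r} outside [0, 1]")
        s = self.yR + self.yA + self.yB
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {s!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.yR, self.yA, self.yB], dtype=float)

    @staticmethod
    def from_array(y: Sequence[float]) -> "PSFState":
        return PSFState(float(y[0]), float(y[1]), float(y[2]))


#: Rate constants identified by Wu & Merchuk for Porphyridium sp.
WU_MERCHUK = PSFRates(alpha=1.935e-3, beta=5.785e-7, gamma=1.460e-1,
                      delta=4.796e-4, kappa=3.647e-3, Me=0.059)

DARK_STATE = PSFState(1.0, 0.0, 0.0)


def reparametrize(rates: PSFRates) -> PSFReparam:
    """Map raw rate constants to the reduced parameters q1..q5.

    q1 = sqrt(gamma*delta/(alpha*beta))       optimal irradiance
    q2 = sqrt(alpha*beta*gamma/(delta*(alpha+beta)^2))
    q3 = kappa*gamma*sqrt(alpha*delta/(beta*gamma))
    q4 = alpha*q1
    q5 = beta/alpha
    """
    a, b, g, d = rates.alpha, rates.beta, rates.gamma, rates.delta
    q1 = np.sqrt(g * d / (a * b))
    q2 = np.sqrt(a * b * g / (d * (a + b) ** 2))
    # q3 needs kappa > 0; fall back to a positive placeholder-free error
    # q3 carries the growth conversion and needs a positive kappa
    if rates.kappa <= 0.0:
        raise ValueError("kappa must be strictly positive to compute q3; "
                         "set PSFRates.kappa")
    q3 = rates.kappa * g * np.sqrt(a * d / (b * g))
    q4 = a * q1
    q5 = b / a
    return PSFReparam(q1=float(q1), q2=float(q2), q3=float(q3),
                      q4=float(q4), q5=float(q5))


#: Exact reparametrization of the Wu-Merchuk constants
#: (q1 = 250.1, q2 = 0.3016, q4 = 0.4840, ...).
WU_MERCHUK_REPARAM = reparametrize(WU_MERCHUK)

#: Rounded case-study parameters (q2 = 0.3, q4 = 0.5, q1 = 250) under which
#: the printed steady states 0.625 / 0.1875 and Da = 260/Re hold exactly.
CASE_STUDY_REPARAM = PSFReparam(q1=250.0, q2=0.3,
                                q3=WU_MERCHUK_REPARAM.q3, q4=0.5,
                                q5=WU_MERCHUK_REPARAM.q5)


def _check_u(u: float) -> float:
    u = float(u)
    if u < 0.0:
        raise ValueError(f"normalized irradiance must be non-negative, got {u!r}")
    return u


def reaction_generator(u: float, reparam: PSFReparam) -> np.ndarray:
    """Generator matrix M(u) = A + u*B of the reparametrized PSF model.

    State order (yR, yA, yB).  Every column of M sums to zero, so the total
    fraction is conserved by the dynamics.
    """
    u = _check_u(u)
    q2, q4, q5 = reparam.q2, reparam.q4, reparam.q5
    gam = q2 * (1.0 + q5)          # = gamma / q4
    dlt = q5 / (q2 * (1.0 + q5))   # = delta / q4
    A = q4 * np.array([[0.0, gam, dlt],
                       [0.0, -gam, 0.0],
                       [0.0, 0.0, -dlt]])
    B = q4 * np.array([[-1.0, 0.0, 0.0],
                       [1.0, -q5, 0.0],
                       [0.0, q5, 0.0]])
    return A + u * B


def reaction_generator_rates(irradiance: float, rates: PSFRates) -> np.ndarray:
    """Generator of the original parametrization, driven by physical irradiance.

    ``irradiance`` is in uE m^-2 s^-1.  Equivalent to
    ``reaction_generator(irradiance / q1, reparametrize(rates))``.
    """
    I = float(irradiance)
    if I < 0.0:
        raise ValueError(f"irradiance must be non-negative, got {I!r}")
    a, b, g, d = rates.alpha, rates.beta, rates.gamma, rates.delta
    A = np.array([[0.0, g, d],
                  [0.0, -g, 0.0],
                  [0.0, 0.0, -d]])
    B = np.array([[-a, 0.0, 0.0],
                  [a, -b, 0.0],
                  [0.0, b, 0.0]])
    return A + I * B


def yA_ss(u, q2):
    """Steady activated fraction yA_ss(u) = (u/q2) / (u^2 + u/q2 + 1).

    Vectorized in ``u``; maximal at u = 1 where it equals 1/(1 + 2*q2),
    i.e. 0.625 for q2 = 0.3.
    """
    u = np.asarray(u, dtype=float)
    return (u / q2) / (u * u + u / q2 + 1.0)


def yB_ss(u, q2):
    """Steady inhibited fraction yB_ss(u) = u^2 / (u^2 + u/q2 + 1)."""
    u = np.asarray(u, dtype=float)
    return u * u / (u * u + u / q2 + 1.0)


def steady_state(u: float, reparam: PSFReparam | None = None,
                 q2: float | None = None) -> PSFState:
    """Unique steady state of the PSF model at constant normalized irradiance.

    Accepts either a full `PSFReparam` or just ``q2`` (the steady states
    depend on q2 only).  Coincides with the normalized nullspace vector of
    ``reaction_generator(u)``.
    """
    u = _check_u(u)
    if q2 is None:
        if reparam is None:
            raise ValueError("provide either reparam or q2")
        q2 = reparam.q2
    if not q2 > 0.0:
        raise ValueError(f"q2 must be strictly positive, got {q2!r}")
    a = float(yA_ss(u, q2))
    b = float(yB_ss(u, q2))
    return PSFState(yR=1.0 - a - b, yA=a, yB=b)


def _nonzero_eigvals(M: np.ndarray) -> np.ndarray:
    """The two non-null eigenvalues of a 3x3 PSF generator, sorted by |.| desc."""
    ev = np.linalg.eigvals(M)
    # the conserved total gives one (near-)zero eigenvalue; drop the smallest
    ev = ev[np.argsort(np.abs(ev))][1:]
    return ev[np.argsort(-np.abs(ev))]


def stiffness_ratio(u: float, reparam: PSFReparam) -> float:
    """|lambda_fast / lambda_slow| of the two nonzero eigenvalues of M(u).

    Of order 10^3 for the Wu-Merchuk parameters at u = 1: the light/dark
    reactions are that much faster than photoinhibition.
    """
    ev = _nonzero_eigvals(reaction_generator(u, reparam))
    lam_fast, lam_slow = ev
    if abs(lam_slow) < 1e-300:
        raise ValueError("degenerate spectrum: fewer than two nonzero eigenvalues")
    return float(abs(lam_fast) / abs(lam_slow))


def propagator(u: float, dt: float, reparam: PSFReparam) -> np.ndarray:
    """Exact constant-light propagator expm(M(u) * dt).

    Columns sum to one (a stochastic matrix on the simplex), making the
    stiff reaction sub-step of the transport solver unconditionally stable.
    """
    return expm(reaction_generator(u, reparam) * float(dt))


@dataclass
class KineticsTrajectory:
    """Time series of PSF states: times ``t`` (s) and array ``y`` (n, 3)."""

    t: np.ndarray
    y: np.ndarray

    @property
    def yR(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def yA(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def yB(self) -> np.ndarray:
        return self.y[:, 2]

    def final_state(self) -> PSFState:
        return PSFState.from_array(self.y[-1])


def constant_light(u: float) -> Callable[[float], float]:
    """Light signal u(t) = const."""
    u = _check_u(u)
    return lambda t: u


def square_wave_light(u_on: float, period: float,
                      light_fraction: float = 0.5) -> Callable[[float], float]:
    """Square-wave light/dark cycles: u_on during the light phase, 0 in the dark.

    ``light_fraction`` is the duty cycle (L:D = light_fraction : 1-light_fraction);
    the time-mean irradiance is u_on * light_fraction.
    """
    u_on = _check_u(u_on)
    if not 0.0 < light_fraction <= 1.0:
        raise ValueError("light_fraction must be in (0, 1]")
    if period <= 0.0:
        raise ValueError("period must be positive")

    def u(t: float) -> float:
        return u_on if (t % period) < light_fraction * period else 0.0

    return u


def simulate_full(signal: Callable[[float], float], y0: PSFState,
                  t_span: tuple[float, float], dt_out: float | None = None,
                  reparam: PSFReparam = CASE_STUDY_REPARAM,
                  rtol: float = 1e-8, atol: float = 1e-10) -> KineticsTrajectory:
    """Integrate the full 3-state ODE dy/dt = M(u(t)) y.

    Uses a stiff (BDF) integrator with the analytic Jacobian M(u(t)).  For a
    constant signal the trajectory converges to ``steady_state(u)``; the
    total fraction is conserved exactly by the generator's zero column sums
    and is monitored to solver tolerance.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not np.isfinite(t0) or not np.isfinite(t1) or t1 <= t0:
        raise ValueError(f"t_span must be finite with t1 > t0, got {t_span!r}")

    def rhs(t, y):
        return reaction_generator(signal(t), reparam) @ y

    def jac(t, y):
        return reaction_generator(signal(t), reparam)

    t_eval = None
    if dt_out is not None:
        t_eval = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
        t_eval = t_eval[t_eval <= t1]
        if t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
    sol = solve_ivp(rhs, (t0, t1), y0.as_array(), method="BDF", jac=jac,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"stiff integrator failed at t = {sol.t[-1]:.6g} s: "
                           f"{sol.message}")
    return KineticsTrajectory(t=sol.t, y=sol.y.T)


def reduced_rate(u_local: float, reparam: PSFReparam) -> float:
    """Relaxation rate q4*(u_local + q2) of the fast-reduced scalar ODE (s^-1)."""
    u_local = _check_u(u_local)
    return reparam.q4 * (u_local + reparam.q2)


def reduced_fixed_point(u_local: float, u_av: float,
                        reparam: PSFReparam) -> float:
    """Fixed point of the fast-reduced yA dynamics at local irradiance u_local.

    With yB frozen at its slow quasi-steady value for the culture-average
    irradiance u_av, the activated fraction relaxes to
    ``(u_av + q2)/(u_local + q2) * (u_local/u_av) * yA_ss(u_av)``; for
    u_local = u_av this is exactly yA_ss(u_av).
    """
    u_local = _check_u(u_local)
    if not u_av > 0.0:
        raise ValueError(f"u_av must be strictly positive, got {u_av!r}")
    q2 = reparam.q2
    return float((u_av + q2) / (u_local + q2) * (u_local / u_av)
                 * yA_ss(u_av, q2))


def simulate_reduced(u_local: float, u_av: float, yA0: float,
                     t: np.ndarray | tuple[float, float],
                     reparam: PSFReparam = CASE_STUDY_REPARAM,
                     n_out: int = 201) -> KineticsTrajectory:
    """Fast-reduced model: scalar linear relaxation of yA with yB frozen.

    dyA/dt = -q4 (u_av+q2) [ (u_local+q2)/(u_av+q2) yA - (u_local/u_av) yA_ss(u_av) ]

    Solved in closed form: yA(t) = yA* + (yA0 - yA*) exp(-k t) with
    k = q4 (u_local + q2).  The frozen yB is yB_ss(u_av) and yR makes up the
    remainder, so the returned trajectory still lives on the simplex.
    """
    if isinstance(t, tuple):
        t = np.linspace(float(t[0]), float(t[1]), n_out)
    else:
        t = np.asarray(t, dtype=float)
    k = reduced_rate(u_local, reparam)
    fp = reduced_fixed_point(u_local, u_av, reparam)
    yA = fp + (yA0 - fp) * np.exp(-k * (t - t[0]))
    yB = float(yB_ss(u_av, reparam.q2)) * np.ones_like(yA)
    yR = 1.0 - yA - yB
    return KineticsTrajectory(t=t, y=np.column_stack([yR, yA, yB]))
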