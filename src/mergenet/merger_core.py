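"""Core circuit model: mass-action ODEs, steady states, and reduced laws.

Two model levels are provided.

* The *minimal* model tracks the protease ``P_X``, the output ``P_Y`` and
  their complex ``C`` with lumped resource-proportional production::

      dP_X/dt = k_X*X*R - a*P_X*P_Y + (b + k)*C - gamma*P_X
      dP_Y/dt = k_Y*Y*R - a*P_X*P_Y + b*C     - gamma*P_Y
      dC/dt   = a*P_X*P_Y - (b + k + gamma)*C

* The *full* model adds the transcriptional sensors, the two circuit
  mRNAs, ribosome binding with a conserved pool shared across all mRNAs
  (optionally including an inducible competitor cassette), translation,
  and dilution of every species.  Free ribosomes are eliminated
  algebraically through the conservation law
  ``R_free = R_tot - c_X - c_Y - c_W``, so total ribosomes are conserved
  by construction at every right-hand-side evaluation.

Under first-order protease kinetics (``P_Y << K``) and degradation much
faster than dilution the steady-state output collapses to the ratiometric
law ``P_Y = c * Y/X`` with sensitivity
``c = gamma*k_Y*K / ((k + gamma)*k_X)``; when the output lacks the
degradation tag the steady state instead follows the saturating,
resource-proportional law implemented by :func:`broken_merging_output`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import (
    ConvergenceError,
    DomainError,
    InvalidParameterError,
    InvalidStateError,
)
from .sensors_resources import SensorParams, sensor_activity

__all__ = [
    "MergerParams",
    "CompetitorParams",
    "FullCircuitParams",
    "InducerPair",
    "SteadyStateResult",
    "AssumptionReport",
    "MERGER_SPECIES",
    "FULL_SPECIES",
    "michaelis_constant",
    "sensitivity_constant",
    "reduced_merger_output",
    "broken_merging_output",
    "merger_rhs",
    "full_rhs",
    "free_ribosomes",
    "solve_steady_state",
    "solve_merger_steady_state",
    "solve_full_steady_state",
    "full_model_output",
    "effective_merger_params",
    "check_assumptions",
]

MERGER_SPECIES = ("P_X", "P_Y", "C")
FULL_SPECIES = ("m_X", "m_Y", "m_W", "c_X", "c_Y", "c_W", "P_X", "P_Y", "C")


def michaelis_constant(a: float, b: float, k: float, gamma: float) -> float:
    """Michaelis-Menten constant ``K = (b + k + gamma) / a`` of a catalytic
    binding module with association ``a``, dissociation ``b``, catalysis
    ``k`` and dilution ``gamma``."""
    if not np.isfinite(a) or a <= 0:
        raise InvalidParameterError(f"association rate a must be > 0, got {a!r}")
    if b < 0 or k < 0 or gamma < 0:
        raise InvalidParameterError("b, k, gamma must be >= 0")
    if b + k + gamma <= 0:
        raise InvalidParameterError("b + k + gamma must be > 0")
    return (b + k + gamma) / a


@dataclass(frozen=True)
class MergerParams:
    """Kinetic constants of the minimal degradation-coupled circuit.

    Attributes
    ----------
    k_X, k_Y:
        Production rate constants of P_X and P_Y per unit inducer per unit
        resource, 1/(uM*hr).
    a, b, k:
        Protease-target association (1/(uM*hr)), complex dissociation
        (1/hr) and catalytic degradation (1/hr) rates.
    gamma:
        Dilution rate constant, 1/hr.
    P_XT:
        Total protease concentration (P_X + C) at the operating point, uM;
        consumed by the fast-degradation assumption check.
    """

    k_X: float
    k_Y: float
    a: float
    b: float
    k: float
    gamma: float
    P_XT: float

    def __post_init__(self) -> None:
        for name in ("a", "gamma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"MergerParams.{name} must be finite and > 0, got {value!r}")
        # production rates may be zero (dark circuit variants); binding and
        # dilution may not.
        for name in ("k_X", "k_Y", "b", "k", "P_XT"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidParameterError(
                    f"MergerParams.{name} must be finite and >= 0, got {value!r}")

    @property
    def K(self) -> float:
        """Protease Michaelis-Menten constant (b + k + gamma) / a."""
        return michaelis_constant(self.a, self.b, self.k, self.gamma)


@dataclass(frozen=True)
class CompetitorParams:
    """Inducible resource-competitor cassette (aTc-driven reporter)."""

    max_rate: float          # maximal transcription rate per copy, uM/hr
    dna_copies: float        # promoter copy number
    theta_aTc_nM: float      # aTc half-activation constant, nM
    delta: float             # competitor mRNA decay rate, 1/hr
    a_W: float               # ribosome association, 1/(uM*hr)
    b_W: float               # ribosome dissociation, 1/hr
    k_W: float               # translation (ribosome release) rate, 1/hr

    def __post_init__(self) -> None:
        for name in ("max_rate", "dna_copies", "theta_aTc_nM", "delta",
                     "a_W", "b_W", "k_W"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"CompetitorParams.{name} must be finite and > 0, got {value!r}")

    def transcription_rate(self, aTc: float) -> float:
        if aTc < 0:
            raise DomainError("aTc must be >= 0")
        return self.max_rate * self.dna_copies * aTc / (self.theta_aTc_nM + aTc)


@dataclass(frozen=True)
class FullCircuitParams:
    """Parameters of the full sensor + mRNA + resource + protein model.

    The translation blocks follow the a/b/k naming of the ribosome binding
    modules: ``a4, b4, k4`` for the protease mRNA and ``a6, b6, k6`` for
    the output mRNA, with lumped constants ``K4`` and ``K6`` defined by the
    same ``(b + k + gamma)/a`` pattern as the protease constant ``K``.  The
    output RBS strength (translation-initiation score) is proportional to
    ``1/K6``, so rescaling ``a6`` rescales the predicted sensitivity by the
    same factor.
    """

    sensor_X: SensorParams   # repressor arm driving the protease mRNA
    sensor_Y: SensorParams   # activator arm driving the output mRNA
    delta_X: float           # m_X decay (degradation + dilution), 1/hr
    delta_Y: float           # m_Y decay, 1/hr
    a4: float                # ribosome kinetics on the protease mRNA
    b4: float
    k4: float
    a6: float                # ribosome kinetics on the output mRNA
    b6: float
    k6: float
    R_tot: float             # total ribosome pool, uM
    a: float                 # protease-target association
    b: float                 # complex dissociation
    k: float                 # catalytic degradation
    gamma: float             # shared dilution rate, 1/hr
    competitor: CompetitorParams | None = None
    degradation_tag: bool = True   # False = "broken merging" control
    calibration: float = 1.0       # GFP/OD units per uM of output protein

    def __post_init__(self) -> None:
        for name in ("delta_X", "delta_Y", "a4", "b4", "k4", "a6", "b6",
                     "k6", "R_tot", "a", "b", "k", "gamma", "calibration"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"FullCircuitParams.{name} must be finite and > 0, got {value!r}")

    @property
    def K4(self) -> float:
        return michaelis_constant(self.a4, self.b4, self.k4, self.gamma)

    @property
    def K6(self) -> float:
        return michaelis_constant(self.a6, self.b6, self.k6, self.gamma)

    @property
    def K(self) -> float:
        return michaelis_constant(self.a, self.b, self.k, self.gamma)

    @property
    def K_W(self) -> float:
        if self.competitor is None:
            raise InvalidParameterError("no competitor configured")
        w = self.competitor
        return michaelis_constant(w.a_W, w.b_W, w.k_W, self.gamma)

    def with_tir_scale(self, factor: float) -> "FullCircuitParams":
        """Rescale the output RBS strength 1/K6 by ``factor`` (scales a6)."""
        if factor <= 0:
            raise InvalidParameterError("TIR scale factor must be > 0")
        return replace(self, a6=self.a6 * factor)


@dataclass(frozen=True)
class InducerPair:
    """One input condition: X (e.g. IPTG, uM) and Y (e.g. Sal, uM)."""

    X: float
    Y: float

    def __post_init__(self) -> None:
        if self.X < 0 or self.Y < 0:
            raise InvalidParameterError("inducer concentrations must be >= 0")

    @property
    def ratio(self) -> float:
        if self.X <= 0:
            raise DomainError("ratio undefined: X must be > 0")
        return self.Y / self.X


def sensitivity_constant(p: MergerParams) -> float:
    """Ratiometric sensitivity ``c = gamma*k_Y*K / ((k + gamma)*k_X)``."""
    if p.k_X <= 0:
        raise InvalidParameterError("sensitivity undefined for k_X = 0")
    return p.gamma * p.k_Y * p.K / ((p.k + p.gamma) * p.k_X)


def reduced_merger_output(c: float, u: InducerPair) -> float:
    """Closed-form steady-state output ``c * Y/X`` of the merger circuit.

    Exactly invariant under common scaling of (X, Y) and independent of the
    resource level.
    """
    if c <= 0:
        raise InvalidParameterError("sensitivity c must be > 0")
    if u.X <= 0:
        raise DomainError("ratio undefined: X must be > 0")
    return c * u.Y / u.X


def broken_merging_output(k6: float, R_tot: float, gamma: float,
                          c1: float, c2: float,
                          X_T: float, Y_T: float) -> float:
    """Steady-state output of the untagged ("broken merging") variant::

        P_Y = (k6 * R_tot / gamma) * c2*Y_T / (1 + c1*X_T + c2*Y_T)

    Increasing and saturating in ``Y_T`` (toward ``k6*R_tot/gamma``),
    decreasing in ``X_T`` through ribosome sequestration, and directly
    proportional to ``R_tot``.
    """
    for name, value in (("k6", k6), ("R_tot", R_tot), ("gamma", gamma)):
        if value <= 0:
            raise InvalidParameterError(f"{name} must be > 0")
    if min(c1, c2, X_T, Y_T) < 0:
        raise DomainError("c1, c2, X_T, Y_T must be >= 0")
    return (k6 * R_tot / gamma) * c2 * Y_T / (1.0 + c1 * X_T + c2 * Y_T)


def _check_state(state, n: int) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (n,):
        raise InvalidStateError(f"state must have shape ({n},), got {y.shape}")
    if np.any(y < 0):
        raise InvalidStateError("species concentrations must be >= 0")
    return y


def merger_rhs(state, p: MergerParams, u: InducerPair, R: float) -> np.ndarray:
    """Mass-action time derivatives of (P_X, P_Y, C) in the minimal model."""
    if R < 0:
        raise InvalidStateError("resource level R must be >= 0")
    P_X, P_Y, C = _check_state(state, 3)
    bind = p.a * P_X * P_Y
    dP_X = p.k_X * u.X * R - bind + (p.b + p.k) * C - p.gamma * P_X
    dP_Y = p.k_Y * u.Y * R - bind + p.b * C - p.gamma * P_Y
    dC = bind - (p.b + p.k + p.gamma) * C
    return np.array([dP_X, dP_Y, dC])


def free_ribosomes(state, p: FullCircuitParams) -> float:
    """Free resource implied by conservation: R_tot minus bound ribosomes."""
    y = np.asarray(state, dtype=float)
    return p.R_tot - y[3] - y[4] - y[5]


def full_rhs(state, p: FullCircuitParams, u: InducerPair,
             aTc: float = 0.0) -> np.ndarray:
    """Time derivatives of the full model state.

    Species order is :data:`FULL_SPECIES`:
    ``(m_X, m_Y, m_W, c_X, c_Y, c_W, P_X, P_Y, C)`` where ``m_*`` are free
    mRNAs, ``c_*`` ribosome-mRNA complexes (``*_W`` the competitor's), and
    ``C`` the protease-output complex.  With ``degradation_tag=False`` the
    protease no longer binds the output (broken merging).
    """
    y = _check_state(state, 9)
    m_X, m_Y, m_W, c_X, c_Y, c_W, P_X, P_Y, C = y
    g = p.gamma
    R = p.R_tot - c_X - c_Y - c_W

    T_X = sensor_activity(p.sensor_X, u.X)
    T_Y = sensor_activity(p.sensor_Y, u.Y)

    bind_X = p.a4 * m_X * R
    bind_Y = p.a6 * m_Y * R
    dm_X = T_X - p.delta_X * m_X - bind_X + (p.b4 + p.k4) * c_X
    dm_Y = T_Y - p.delta_Y * m_Y - bind_Y + (p.b6 + p.k6) * c_Y
    dc_X = bind_X - (p.b4 + p.k4 + g) * c_X
    dc_Y = bind_Y - (p.b6 + p.k6 + g) * c_Y

    if p.competitor is not None:
        w = p.competitor
        bind_W = w.a_W * m_W * R
        dm_W = (w.transcription_rate(aTc) - w.delta * m_W
                - bind_W + (w.b_W + w.k_W) * c_W)
        dc_W = bind_W - (w.b_W + w.k_W + g) * c_W
    else:
        dm_W = -g * m_W
        dc_W = -g * c_W

    dP_X = p.k4 * c_X - g * P_X
    dP_Y = p.k6 * c_Y - g * P_Y
    if p.degradation_tag:
        bind = p.a * P_X * P_Y
        dP_X += -bind + (p.b + p.k) * C
        dP_Y += -bind + p.b * C
        dC = bind - (p.b + p.k + g) * C
    else:
        dC = -g * C
    return np.array([dm_X, dm_Y, dm_W, dc_X, dc_Y, dc_W, dP_X, dP_Y, dC])


@dataclass(frozen=True)
class SteadyStateResult:
    """Converged species concentrations with diagnostics.

    ``residual_norm`` is ``max |d/dt|`` at the reported state and
    ``uniqueness_gap`` the relative distance between the states reached
    from two distinct non-negative initializations (NaN if not checked).
    """

    values: np.ndarray
    names: tuple[str, ...]
    converged: bool
    residual_norm: float
    method: str
    tolerance: float
    uniqueness_gap: float = float("nan")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def _relax(f: Callable[[np.ndarray], np.ndarray], init: np.ndarray,
           t_max: float) -> np.ndarray:
    clipped = lambda t, y: f(np.clip(y, 0.0, None))
    sol = solve_ivp(clipped, (0.0, t_max), init, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:  # retry with the implicit stiff solver
        sol = solve_ivp(clipped, (0.0, t_max), init, method="BDF",
                        rtol=1e-10, atol=1e-12)
    y = np.clip(sol.y[:, -1], 0.0, None)
    fc = lambda y: f(np.clip(y, 0.0, None))
    polished = root(fc, y, method="hybr")
    if polished.success and np.all(polished.x > -1e-9 * (1.0 + np.max(np.abs(y)))):
        return np.clip(polished.x, 0.0, None)
    return y


def solve_steady_state(rhs: Callable[[np.ndarray], np.ndarray],
                       init: Sequence[float], *,
                       tol: float = 1e-9,
                       t_max: float = 200.0,
                       rate_scale: float | None = None,
                       names: tuple[str, ...] | None = None,
                       check_uniqueness: bool = True,
                       second_init: Sequence[float] | None = None) -> SteadyStateResult:
    """Steady state of ``dy/dt = rhs(y)`` by relaxation plus root polishing.

    The system is integrated (stiff-capable) to ``t_max`` and the endpoint
    polished with a root finder.  ``converged`` is True only when
    ``max |rhs| <= tol * rate_scale`` where ``rate_scale`` defaults to
    ``max(1, max |rhs(0)|)`` (the production scale).  When
    ``check_uniqueness`` is set the solve is repeated from a second,
    distinct non-negative initialization and the relative gap reported.
    Non-convergence yields ``converged=False``, never a silent result.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    y0 = np.asarray(init, dtype=float)
    if np.any(y0 < 0):
        raise InvalidStateError("initialization must be non-negative")
    f = lambda y: np.asarray(rhs(y), dtype=float)
    if rate_scale is None:
        rate_scale = max(1.0, float(np.max(np.abs(f(np.zeros_like(y0))))))

    y = _relax(f, y0, t_max)
    residual = float(np.max(np.abs(f(y))))
    method = "root" if residual <= tol * rate_scale else "integration"

    gap = float("nan")
    if check_uniqueness:
        if second_init is None:
            alt = 2.0 * y + 1.0
        else:
            alt = np.asarray(second_init, dtype=float)
        y2 = _relax(f, alt, t_max)
        gap = float(np.max(np.abs(y - y2)) / max(1.0, np.max(np.abs(y))))

    converged = residual <= tol * rate_scale
    if names is None:
        names = tuple(f"y{i}" for i in range(y.size))
    return SteadyStateResult(values=y, names=names, converged=converged,
                             residual_norm=residual, method=method,
                             tolerance=tol * rate_scale, uniqueness_gap=gap)


def solve_merger_steady_state(p: MergerParams, u: InducerPair, R: float,
                              **kwargs) -> SteadyStateResult:
    """Steady state of the minimal model at inputs ``u`` and resource ``R``."""
    rhs = lambda y: merger_rhs(np.clip(y, 0.0, None), p, u, R)
    init = kwargs.pop("init", np.zeros(3))
    return solve_steady_state(rhs, init, names=MERGER_SPECIES, **kwargs)


def solve_full_steady_state(p: FullCircuitParams, u: InducerPair, *,
                            aTc: float = 0.0,
                            resource_scale: float = 1.0,
                            **kwargs) -> SteadyStateResult:
    """Steady state of the full model; ``resource_scale`` rescales R_tot.

    The free-ribosome level is appended to the result under the name "R".
    """
    if resource_scale <= 0:
        raise InvalidParameterError("resource_scale must be > 0")
    ps = p if resource_scale == 1.0 else replace(p, R_tot=p.R_tot * resource_scale)
    rhs = lambda y: full_rhs(np.clip(y, 0.0, None), ps, u, aTc)
    init = kwargs.pop("init", np.zeros(9))
    res = solve_steady_state(rhs, init, names=FULL_SPECIES, **kwargs)
    values = np.append(res.values, free_ribosomes(res.values, ps))
    return replace(res, values=values, names=FULL_SPECIES + ("R",))


def full_model_output(p: FullCircuitParams, u: InducerPair, *,
                      aTc: float = 0.0, resource_scale: float = 1.0,
                      calibrated: bool = True, **kwargs) -> float:
    """Steady-state output level; raises :class:`ConvergenceError` on failure."""
    kwargs.setdefault("check_uniqueness", False)
    res = solve_full_steady_state(p, u, aTc=aTc, resource_scale=resource_scale,
                                  **kwargs)
    if not res.converged:
        raise ConvergenceError(
            f"full model did not converge at X={u.X}, Y={u.Y} "
            f"(residual {res.residual_norm:.3e})")
    out = res["P_Y"]
    return out * p.calibration if calibrated else out


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DomainError("cannot fit a through-origin slope to all-zero inputs")
    return float(np.dot(x, y) / denom)


def effective_merger_params(p: FullCircuitParams,
                            x_grid: Sequence[float],
                            y_grid: Sequence[float],
                            operating_point: InducerPair,
                            aTc: float = 0.0) -> MergerParams:
    """Lumped minimal-model parameters implied by the full circuit.

    The composite per-resource production rates of P_X and P_Y,
    ``k4/(K4*delta_X) * T_X(X)`` and ``k6/(K6*delta_Y) * T_Y(Y)``, are
    linearized by a through-origin least-squares slope over the declared
    operating grids; the total protease at the operating point is taken
    from a full-model steady-state solve.
    """
    x = np.asarray(x_grid, float)
    yg = np.asarray([v for v in np.asarray(y_grid, float) if v > 0])
    if yg.size == 0:
        raise DomainError("y_grid must contain positive concentrations")
    prod_x = p.k4 / (p.K4 * p.delta_X) * np.asarray(sensor_activity(p.sensor_X, x))
    prod_y = p.k6 / (p.K6 * p.delta_Y) * np.asarray(sensor_activity(p.sensor_Y, yg))
    k_X_eff = _through_origin_slope(x, prod_x)
    k_Y_eff = _through_origin_slope(yg, prod_y)
    ss = solve_full_steady_state(p, operating_point, aTc=aTc,
                                 check_uniqueness=False)
    P_XT = ss["P_X"] + ss["C"]
    return MergerParams(k_X=k_X_eff, k_Y=k_Y_eff, a=p.a, b=p.b, k=p.k,
                        gamma=p.gamma, P_XT=P_XT)


@dataclass(frozen=True)
class AssumptionReport:
    """Margins of the reduced-law validity conditions.

    The first-order-protease condition requires ``P_Y/K`` small; the
    fast-degradation condition requires ``gamma*K / (P_XT*(k + gamma))``
    small.  Each margin passes when <= strictness.  Linearity of the
    production rates in the inducers and in the resource is reported
    separately by the sensor linear-range scan.
    """

    a1_margin: float
    a1_pass: bool
    a2_margin: float
    a2_pass: bool
    strictness: float
    note: str = ("production-linearity (A0) is assessed by the sensor "
                 "linear-range scan, not here")

    @property
    def all_pass(self) -> bool:
        return self.a1_pass and self.a2_pass

    def to_dict(self) -> dict:
        return {
            "a1_margin": self.a1_margin, "a1_pass": self.a1_pass,
            "a2_margin": self.a2_margin, "a2_pass": self.a2_pass,
            "strictness": self.strictness, "note": self.note,
        }


def check_assumptions(p: MergerParams, ss: SteadyStateResult,
                      strictness: float = 0.1) -> AssumptionReport:
    """Evaluate the reduced-law validity margins at a converged steady state."""
    if not 0 < strictness < 1:
        raise InvalidParameterError("strictness must lie in (0, 1)")
    if not ss.converged:
        raise ConvergenceError("assumption check requires a converged steady state")
    if p.P_XT <= 0:
        raise InvalidParameterError("A2 margin undefined for P_XT = 0")
    P_Y = ss["P_Y"]
    a1 = P_Y / p.K
    a2 = p.gamma * p.K / (p.P_XT * (p.k + p.gamma))
    return AssumptionReport(a1_margin=a1, a1_pass=a1 <= strictness,
                            a2_margin=a2, a2_pass=a2 <= strictness,
                            strictness=strictness)
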