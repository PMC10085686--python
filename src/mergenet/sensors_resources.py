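"""Transcriptional sensors and the shared translational-resource pool.

Two sensor archetypes are supported: a repressor that a *negative* inducer
inactivates (de-repression, e.g. IPTG/LacI) and an activator that a
*positive* inducer switches on (e.g. Sal/NahR).  Regulator-inducer and
regulator-DNA binding are treated at thermodynamic equilibrium with
single-site stoichiometry; the Hill coefficient defaults to 1 and is
configurable.

The resource pool is a conserved total ``R_tot`` partitioned among circuit
mRNAs and an optional inducible competitor cassette; the free pool follows
from the conservation relation ``R_free * (1 + sum(demands)) = R_tot``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, InvalidParameterError

__all__ = [
    "SensorMode",
    "SensorParams",
    "ResourceContext",
    "LinearRange",
    "sensor_activity",
    "linear_range",
    "free_resource",
    "perturb_resource",
    "saturating_demand",
]


class SensorMode(str, enum.Enum):
    REPRESSOR = "repressor-with-negative-inducer"
    ACTIVATOR = "activator-with-positive-inducer"


@dataclass(frozen=True)
class SensorParams:
    """Equilibrium parameters of one transcriptional sensor.

    Attributes
    ----------
    regulator_total:
        Total regulator (repressor or activator) concentration, uM.
    inducer_Kd:
        Inducer-regulator dissociation constant, uM.
    dna_Kd:
        Regulator-DNA dissociation constant, uM.
    dna_copies:
        Target promoter copy number (dimensionless count).
    max_rate:
        Maximal transcription rate per promoter copy, uM/hr.
    mode:
        Repressor-with-negative-inducer or activator-with-positive-inducer.
    hill:
        Hill coefficient of inducer-regulator binding (default 1).
    """

    regulator_total: float
    inducer_Kd: float
    dna_Kd: float
    dna_copies: float
    max_rate: float
    mode: SensorMode
    hill: float = 1.0

    def __post_init__(self) -> None:
        for name in ("regulator_total", "inducer_Kd", "dna_Kd", "max_rate",
                     "hill"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"SensorParams.{name} must be finite and > 0, got {value!r}")
        if not np.isfinite(self.dna_copies) or self.dna_copies < 0:
            raise InvalidParameterError(
                f"SensorParams.dna_copies must be finite and >= 0, "
                f"got {self.dna_copies!r}")
        if not isinstance(self.mode, SensorMode):
            object.__setattr__(self, "mode", SensorMode(self.mode))


def sensor_activity(s: SensorParams, inducer):
    """Transcription rate (uM/hr) of the sensor's target promoter.

    Both modes are monotone non-decreasing in the inducer: a negative
    inducer strips the repressor off the DNA, a positive inducer loads the
    activator onto it.  The result lies in ``[0, max_rate * dna_copies]``.
    Accepts scalars or arrays.
    """
    x = np.asarray(inducer, dtype=float)
    if np.any(x < 0):
        raise DomainError("inducer concentration must be >= 0")
    occ_ind = (x / s.inducer_Kd) ** s.hill
    if s.mode is SensorMode.REPRESSOR:
        free_regulator = s.regulator_total / (1.0 + occ_ind)
        promoter_free = 1.0 / (1.0 + free_regulator / s.dna_Kd)
        activity = s.max_rate * s.dna_copies * promoter_free
    else:
        active_regulator = s.regulator_total * occ_ind / (1.0 + occ_ind)
        bound = (active_regulator / s.dna_Kd) / (1.0 + active_regulator / s.dna_Kd)
        activity = s.max_rate * s.dna_copies * bound
    if np.isscalar(inducer) or np.ndim(inducer) == 0:
        return float(activity)
    return activity


@dataclass(frozen=True)
class LinearRange:
    """Widest contiguous sub-interval of a grid on which a sensor is affine."""

    low: float
    high: float
    n_points: int
    max_deviation: float
    tolerance: float

    @property
    def empty(self) -> bool:
        return self.n_points == 0

    def to_dict(self) -> dict:
        return {"low": self.low, "high": self.high, "tolerance": self.tolerance}


def _affine_deviation(x: np.ndarray, y: np.ndarray) -> float:
    """Max |residual| of the least-squares affine fit, relative to the fit range."""
    coeffs = np.polyfit(x, y, 1)
    fit = np.polyval(coeffs, x)
    span = float(fit.max() - fit.min())
    resid = float(np.max(np.abs(y - fit)))
    if span == 0.0:
        return 0.0 if resid == 0.0 else np.inf
    return resid / span


def linear_range(s, grid: Sequence[float], tolerance: float) -> LinearRange:
    """Widest contiguous window of ``grid`` on which the activity is affine.

    ``s`` is a :class:`SensorParams` or any callable mapping a
    concentration array to activities.  Every contiguous window of >= 2
    grid points is scanned; a window qualifies when the maximum deviation
    of the activity from its own least-squares affine fit, relative to the
    fit's range, is <= tolerance.  The widest qualifying window (leftmost
    on ties) is returned.  If no window qualifies an empty interval is
    returned, never an exception.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 5:
        raise DomainError("grid must be a sorted 1-D array with >= 5 points")
    if np.any(np.diff(grid) <= 0):
        raise DomainError("grid must be strictly increasing")
    if tolerance < 0:
        raise DomainError("tolerance must be >= 0")
    if callable(s):
        activity = np.asarray(s(grid), dtype=float)
    else:
        activity = np.asarray(sensor_activity(s, grid), dtype=float)

    best: tuple[float, int, int] | None = None  # (width, i, j)
    best_dev = np.inf
    n = grid.size
    for i in range(n - 1):
        for j in range(i + 1, n):
            dev = _affine_deviation(grid[i:j + 1], activity[i:j + 1])
            if dev <= tolerance:
                width = grid[j] - grid[i]
                if best is None or width > best[0] + 1e-15:
                    best = (width, i, j)
                    best_dev = dev
    if best is None:
        return LinearRange(np.nan, np.nan, 0, np.inf, tolerance)
    _, i, j = best
    return LinearRange(float(grid[i]), float(grid[j]), j - i + 1, best_dev, tolerance)


def saturating_demand(demand_max: float, theta_nM: float) -> Callable[[float], float]:
    """Competitor resource demand as a saturating function of its inducer (nM)."""
    if demand_max < 0 or theta_nM <= 0:
        raise InvalidParameterError("demand_max >= 0 and theta_nM > 0 required")

    def demand(aTc: float) -> float:
        if aTc < 0:
            raise DomainError("aTc must be >= 0")
        return demand_max * aTc / (theta_nM + aTc)

    return demand


@dataclass(frozen=True)
class ResourceContext:
    """Shared resource pool with an optional inducible competitor.

    ``competitor_demand`` maps the competitor's inducer level (aTc, nM) to
    its dimensionless resource demand; ``aTc`` is the operating induction
    level of this context.  ``perturbation_fraction`` multiplies the free
    pool in robustness studies (1.0 = unperturbed).
    """

    R_tot: float
    competitor_demand: Callable[[float], float] | None = None
    perturbation_fraction: float = 1.0
    aTc: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.R_tot) or self.R_tot <= 0:
            raise InvalidParameterError("R_tot must be finite and > 0")
        if not 0 < self.perturbation_fraction <= 1:
            raise InvalidParameterError(
                "perturbation_fraction must lie in (0, 1]")
        if self.aTc < 0:
            raise InvalidParameterError("aTc must be >= 0")


def free_resource(ctx: ResourceContext, circuit_demands: Sequence[float],
                  aTc: float | None = None) -> float:
    """Free resource after conservation-based partitioning.

    Each demand ``d_i`` sequesters ``R_free * d_i`` resource, so the free
    pool solves ``R_free * (1 + sum d_i) = R_tot``.  Strictly decreasing in
    aTc for a positive competitor demand; equals the no-competitor value at
    aTc = 0.
    """
    demands = np.asarray(circuit_demands, dtype=float)
    if demands.size and (np.any(demands < 0) or not np.all(np.isfinite(demands))):
        raise DomainError("circuit demands must be finite and >= 0")
    level = ctx.aTc if aTc is None else aTc
    comp = 0.0
    if ctx.competitor_demand is not None:
        comp = float(ctx.competitor_demand(level))
        if not np.isfinite(comp) or comp < 0:
            raise DomainError("competitor demand must be finite and >= 0")
    total = float(demands.sum()) + comp
    return ctx.R_tot / (1.0 + total)


def perturb_resource(R: float, fraction: float) -> float:
    """Scale a resource level by ``fraction`` (0 < fraction <= 1)."""
    if not 0 < fraction <= 1:
        raise DomainError("fraction must lie in (0, 1]")
    return R * fraction
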