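"""Nonlinear least-squares estimation of the reduced steady-state laws.

Both reduced laws are fitted by bounded trust-region least squares with a
seeded log-uniform multistart.  Confidence intervals are linearized
(Jacobian-based); the default covariance is the heteroscedasticity-robust
sandwich form, since measured outputs carry multiplicative noise, with the
classical ``s^2 (J'J)^-1`` form available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .analysis_pipeline import DoseResponseTable
from .errors import DegenerateDesignError, DomainError

__all__ = ["FitResult", "fit_reduced_merger", "fit_broken_merging", "goodness_of_fit"]


@dataclass(frozen=True)
class FitResult:
    """Parameter estimates with diagnostics.

    ``ci95`` maps parameter names to linearized 95% intervals; it is None
    when the fit did not converge.  ``flags`` collects identifiability
    warnings (e.g. a saturation constant unconstrained by the design).
    """

    estimates: dict[str, float]
    residual_sum: float
    r_squared: float
    ci95: dict[str, tuple[float, float]] | None
    converged: bool
    n_starts: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "residual_sum": self.residual_sum,
            "r_squared": self.r_squared,
            "ci95": self.ci95,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "flags": list(self.flags),
        }


def _design(t: DoseResponseTable, on_means: bool):
    df = t.replicate_means() if on_means else t.data[t.ok_mask()]
    if (df["X_uM"] <= 0).any():
        raise DomainError("fitting requires X > 0 for every row")
    x = df["X_uM"].to_numpy(dtype=float)
    y = df["Y_uM"].to_numpy(dtype=float)
    out = df["output"].to_numpy(dtype=float)
    if np.unique(np.stack([x, y], axis=1), axis=0).shape[0] < 3:
        raise DegenerateDesignError("need >= 3 distinct (X, Y) conditions")
    return x, y, out


def _covariance(res, n: int, p: int, method: str) -> np.ndarray:
    J = res.jac
    JTJ = J.T @ J
    try:
        inv = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(JTJ)
    if method == "classical":
        dof = max(n - p, 1)
        s2 = float(res.fun @ res.fun) / dof
        return s2 * inv
    # HC3 sandwich: robust to residual variance growing with the signal,
    # with leverage-corrected squared residuals.
    leverage = np.clip(np.einsum("ij,jk,ik->i", J, inv, J), 0.0, 0.999)
    meat = J.T @ np.diag(res.fun ** 2 / (1.0 - leverage) ** 2) @ J
    return inv @ meat @ inv


def _ci95(res, names: Sequence[str], n: int, method: str) -> dict[str, tuple[float, float]]:
    p = len(names)
    cov = _covariance(res, n, p, method)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if method == "classical":
        dofs = np.full(p, max(n - p, 1.0))
    else:
        # Effective per-parameter dof from the squared influence weights
        # (Satterthwaite / Bell-McCaffrey style): leveraged designs get a
        # wider t-quantile than n - p would suggest.
        J = res.jac
        try:
            W = np.linalg.solve(J.T @ J, J.T)
        except np.linalg.LinAlgError:
            W = np.linalg.pinv(J)
        a = W ** 2
        dofs = np.maximum(a.sum(axis=1) ** 2 / (a ** 2).sum(axis=1), 1.0)
    out = {}
    for name, est, s, dof in zip(names, res.x, se, dofs):
        tval = stats.t.ppf(0.975, dof)
        out[name] = (float(est - tval * s), float(est + tval * s))
    return out


def _multistart(residual, bounds_lo, bounds_hi, seed: int, n_starts: int):
    rng = np.random.default_rng(seed)
    lo = np.asarray(bounds_lo, float)
    hi = np.asarray(bounds_hi, float)
    best = None
    for i in range(n_starts):
        if i == 0:
            x0 = np.sqrt(lo * hi)  # geometric midpoint
        else:
            x0 = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        try:
            res = optimize.least_squares(residual, x0, bounds=(lo, hi),
                                         method="trf", xtol=1e-12, ftol=1e-12,
                                         gtol=1e-12, max_nfev=5000)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, bool]:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    ss_res = float(np.sum((observed - predicted) ** 2))
    if ss_tot == 0.0:
        return (1.0 if ss_res == 0.0 else 0.0), True
    return 1.0 - ss_res / ss_tot, False


def fit_reduced_merger(t: DoseResponseTable, *, seed: int = 0,
                       n_starts: int = 10, on_means: bool = True,
                       bounds: tuple[float, float] | None = None,
                       ci_method: str = "sandwich") -> FitResult:
    """Estimate the ratiometric sensitivity c from ``output = c * Y/X``."""
    x, y, out = _design(t, on_means)
    ratio = y / x
    if not np.any(ratio > 0):
        raise DegenerateDesignError(
            "all Y are zero: the sensitivity c is unidentifiable")
    if bounds is None:
        scale = max(out.max() / ratio.max(), 1e-12)
        bounds = (scale * 1e-6, scale * 1e6)

    residual = lambda p: p[0] * ratio - out
    best = _multistart(residual, [bounds[0]], [bounds[1]], seed, n_starts)
    if best is None:
        return FitResult({}, float("nan"), float("nan"), None, False, n_starts)
    c_hat = float(best.x[0])
    r2, degenerate = _r_squared(out, c_hat * ratio)
    flags = ("zero-variance-data",) if degenerate else ()
    return FitResult(
        estimates={"c": c_hat},
        residual_sum=float(2 * best.cost),
        r_squared=r2,
        ci95=_ci95(best, ["c"], out.size, ci_method),
        converged=True,
        n_starts=n_starts,
        flags=flags,
    )


def fit_broken_merging(t: DoseResponseTable, *, seed: int = 0,
                       n_starts: int = 10, on_means: bool = True,
                       fixed: dict[str, float] | None = None,
                       bounds: dict[str, tuple[float, float]] | None = None,
                       ci_method: str = "sandwich") -> FitResult:
    """Estimate {amplitude, c1, c2} of the saturating resource-limited law::

        output = amplitude * c2*Y / (1 + c1*X + c2*Y)

    ``fixed`` pins parameters at known values (useful for reduced designs,
    e.g. X-only variation at fixed Y identifies c1 alone).  The saturation
    constant c2 is identifiable only if the design reaches c2*Y = O(1);
    otherwise an identifiability flag is raised.
    """
    x, y, out = _design(t, on_means)
    if not np.any(y > 0):
        raise DegenerateDesignError("all Y are zero: nothing to fit")
    fixed = dict(fixed or {})
    names_all = ["amplitude", "c1", "c2"]
    for name in fixed:
        if name not in names_all:
            raise DomainError(f"unknown fixed parameter {name!r}")
    free = [n for n in names_all if n not in fixed]
    if not free:
        raise DomainError("at least one parameter must be free")

    out_max = max(out.max(), 1e-12)
    default_bounds = {
        "amplitude": (out_max * 1e-2, out_max * 1e6),
        "c1": (1e-12, 1e6),
        "c2": (1e-12, 1e6),
    }
    default_bounds.update(bounds or {})
    lo = [default_bounds[n][0] for n in free]
    hi = [default_bounds[n][1] for n in free]

    def unpack(p):
        full = dict(fixed)
        full.update(dict(zip(free, p)))
        return full

    def predict(full):
        return (full["amplitude"] * full["c2"] * y
                / (1.0 + full["c1"] * x + full["c2"] * y))

    residual = lambda p: predict(unpack(p)) - out
    best = _multistart(residual, lo, hi, seed, n_starts)
    if best is None:
        return FitResult({}, float("nan"), float("nan"), None, False, n_starts)
    estimates = unpack([float(v) for v in best.x])
    pred = predict(estimates)
    r2, degenerate = _r_squared(out, pred)
    ci = _ci95(best, free, out.size, ci_method)

    flags: list[str] = []
    if degenerate:
        flags.append("zero-variance-data")
    if "c2" in free:
        if float(estimates["c2"] * y.max()) < 0.2:
            flags.append("c2-weakly-identified: design does not reach saturation")
        lo_c2, hi_c2 = ci["c2"]
        if estimates["c2"] > 0 and (hi_c2 - lo_c2) > 10 * estimates["c2"]:
            flags.append("c2-wide-ci")
    return FitResult(
        estimates=estimates,
        residual_sum=float(2 * best.cost),
        r_squared=r2,
        ci95=ci,
        converged=True,
        n_starts=n_starts,
        flags=tuple(flags),
    )


def goodness_of_fit(t: DoseResponseTable, predictions: Sequence[float], *,
                    on_means: bool = True) -> float:
    """Coefficient of determination ``1 - SS_res/SS_tot`` on replicate means.

    With zero total variance the value is degenerate: 1.0 for a perfect
    match, 0.0 otherwise (a warning is emitted).
    """
    df = t.replicate_means() if on_means else t.data[t.ok_mask()]
    pred = np.asarray(predictions, dtype=float)
    obs = df["output"].to_numpy(dtype=float)
    if pred.shape != obs.shape:
        raise DomainError(
            f"predictions length {pred.size} != observations length {obs.size}")
    r2, degenerate = _r_squared(obs, pred)
    if degenerate:
        import warnings

        warnings.warn("zero total variance: R-squared is degenerate",
                      stacklevel=2)
    return r2
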