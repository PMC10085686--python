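"""Dose-response sweeps, ratio-linearity fits, robustness and fold-change maps.

The lingua franca between simulation, synthetic data and fitting is the
:class:`DoseResponseTable`: replicate-resolved ``(X, Y, replicate, output)``
records with free-form metadata.  All fits operate on replicate means by
default; replicate-resolved fitting is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateDesignError, DomainError, InvalidParameterError
from .merger_core import InducerPair

__all__ = [
    "DoseResponseTable",
    "LinearRatioFit",
    "ConstantRatioReport",
    "FoldChangeMap",
    "dose_response_sweep",
    "ratio_response_fit",
    "tir_scaled_slope",
    "relative_percent_error",
    "constant_ratio_test",
    "fold_change_map",
]

TABLE_COLUMNS = ("X_uM", "Y_uM", "replicate", "output")


@dataclass
class DoseResponseTable:
    """Replicate-resolved dose-response records.

    ``data`` holds one row per ``(X_uM, Y_uM, replicate)`` with the measured
    or simulated ``output`` (GFP/OD).  An optional boolean ``ok`` column
    flags rows whose model evaluation failed (output NaN).  ``metadata``
    carries provenance: model tag, RBS score, competitor induction, noise
    spec, seed.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise DomainError(f"table is missing columns: {missing}")
        keys = self.data[["X_uM", "Y_uM", "replicate"]]
        if keys.duplicated().any():
            dupes = self.data.index[keys.duplicated(keep=False)].tolist()
            raise DomainError(f"duplicate (X, Y, replicate) keys at rows {dupes}")
        ok = self.ok_mask()
        out = self.data.loc[ok, "output"]
        if (out < 0).any():
            bad = self.data.index[(self.data["output"] < 0).fillna(False)].tolist()
            raise DomainError(f"negative outputs at rows {bad}")

    def ok_mask(self) -> pd.Series:
        if "ok" in self.data.columns:
            return self.data["ok"].astype(bool)
        return pd.Series(True, index=self.data.index)

    @property
    def n_failed(self) -> int:
        return int((~self.ok_mask()).sum())

    def replicate_means(self) -> pd.DataFrame:
        """Mean output per (X, Y) condition over successful replicates."""
        good = self.data[self.ok_mask()]
        return (good.groupby(["X_uM", "Y_uM"], as_index=False)["output"]
                .mean())

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class LinearRatioFit:
    """Ordinary least-squares line of output versus the input ratio Y/X."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class ConstantRatioReport:
    """Outputs at input pairs sharing one ratio, and their spread."""

    ratio: float
    outputs: tuple[float, ...]
    mean: float
    max_relative_deviation: float


@dataclass(frozen=True)
class FoldChangeMap:
    """Unsigned fold change between two resource contexts over an input grid.

    ``matrix[i, j]`` is ``max(on, off)/min(on, off)`` at
    ``(X_grid[i], Y_grid[j])``; entries where either output is zero are NaN
    and flagged in ``undefined``.
    """

    X_grid: tuple[float, ...]
    Y_grid: tuple[float, ...]
    matrix: np.ndarray
    undefined: np.ndarray

    @property
    def max_fold(self) -> float:
        finite = self.matrix[~self.undefined]
        if finite.size == 0:
            return float("nan")
        return float(np.max(finite))


def dose_response_sweep(model: Callable[[InducerPair], float],
                        X_grid: Sequence[float],
                        Y_grid: Sequence[float],
                        metadata: dict | None = None) -> DoseResponseTable:
    """Evaluate ``model`` on the product grid, one replicate per point.

    Model failures (:class:`ConvergenceError`) are flagged per-row and the
    sweep continues; the failure count lands in the metadata.
    """
    X_grid = [float(x) for x in X_grid]
    Y_grid = [float(y) for y in Y_grid]
    if not X_grid or not Y_grid:
        raise DomainError("grids must be non-empty")
    rows = []
    n_failed = 0
    for X in X_grid:
        for Y in Y_grid:
            try:
                out = float(model(InducerPair(X, Y)))
                ok = True
            except ConvergenceError:
                out, ok = math.nan, False
                n_failed += 1
            rows.append({"X_uM": X, "Y_uM": Y, "replicate": 0,
                         "output": out, "ok": ok})
    meta = dict(metadata or {})
    meta["n_failed"] = n_failed
    return DoseResponseTable(pd.DataFrame(rows), meta)


def ratio_response_fit(t: DoseResponseTable, *,
                       on_means: bool = True,
                       through_origin: bool = False) -> LinearRatioFit:
    """Least-squares line of output versus Y/X.

    Operates on replicate means by default.  With zero output variance the
    fit is degenerate: slope 0, R-squared reported as 0, flag raised.
    """
    df = t.replicate_means() if on_means else t.data[t.ok_mask()]
    if (df["X_uM"] <= 0).any():
        raise DomainError("ratio fit requires X > 0 for every row")
    ratio = (df["Y_uM"] / df["X_uM"]).to_numpy()
    y = df["output"].to_numpy(dtype=float)
    if np.unique(ratio).size < 3:
        raise DegenerateDesignError("need >= 3 distinct ratios to fit a line")
    if np.ptp(y) == 0.0:
        return LinearRatioFit(0.0, float(y[0]), 0.0, y.size, degenerate=True)
    if through_origin:
        slope = float(np.dot(ratio, y) / np.dot(ratio, ratio))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(ratio, y, 1))
    pred = slope * ratio + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return LinearRatioFit(slope, intercept, 1.0 - ss_res / ss_tot, y.size)


def tir_scaled_slope(slope_ref: float, TIR_ref: float, TIR_new: float) -> float:
    """Predicted sensitivity after an RBS swap: ``slope_ref * TIR_new/TIR_ref``.

    The RBS translation-initiation score is proportional to 1/K6 and the
    ratio-response slope is proportional to 1/K6, so slopes scale with the
    score ratio.
    """
    if slope_ref <= 0 or TIR_ref <= 0 or TIR_new <= 0:
        raise InvalidParameterError("slope and RBS scores must be > 0")
    return slope_ref * TIR_new / TIR_ref


def relative_percent_error(nominal: float, perturbed: float) -> float:
    """Robustness metric ``|nominal - perturbed| / nominal * 100`` (%)."""
    if nominal <= 0:
        raise DomainError("nominal output must be > 0")
    return abs(nominal - perturbed) / nominal * 100.0


def constant_ratio_test(model: Callable[[InducerPair], float],
                        pairs: Sequence[InducerPair],
                        rtol: float = 1e-9) -> ConstantRatioReport:
    """Spread of model outputs across input pairs sharing one ratio.

    A ratiometric model yields zero spread; a broken-merging model responds
    to the absolute input levels and yields a strictly positive spread.
    """
    if not pairs:
        raise DomainError("need at least one input pair")
    ratios = [u.ratio for u in pairs]
    ref = ratios[0]
    for r in ratios[1:]:
        if abs(r - ref) > rtol * max(1.0, abs(ref)):
            raise DomainError(f"pairs do not share one ratio: {ratios}")
    outputs = tuple(float(model(u)) for u in pairs)
    mean = float(np.mean(outputs))
    if mean == 0.0:
        spread = 0.0 if max(abs(o) for o in outputs) == 0.0 else float("inf")
    else:
        spread = float(max(abs(o - mean) for o in outputs) / abs(mean))
    return ConstantRatioReport(ratio=ref, outputs=outputs, mean=mean,
                               max_relative_deviation=spread)


def fold_change_map(model: Callable[[InducerPair, object], float],
                    X_grid: Sequence[float],
                    Y_grid: Sequence[float],
                    ctx_on, ctx_off,
                    zero_rtol: float = 1e-9) -> FoldChangeMap:
    """Unsigned fold change of ``model(u, ctx)`` between two contexts.

    Entries are ``max(on, off)/min(on, off) >= 1``; a zero output at a grid
    point marks the entry undefined (NaN) rather than raising.  Outputs
    below ``zero_rtol`` times the largest output on the grid count as zero,
    so numerical residue from a steady-state solve cannot masquerade as a
    huge fold change.
    """
    X_grid = tuple(float(x) for x in X_grid)
    Y_grid = tuple(float(y) for y in Y_grid)
    if not X_grid or not Y_grid:
        raise DomainError("grids must be non-empty")
    on = np.empty((len(X_grid), len(Y_grid)))
    off = np.empty_like(on)
    for i, X in enumerate(X_grid):
        for j, Y in enumerate(Y_grid):
            u = InducerPair(X, Y)
            on[i, j] = float(model(u, ctx_on))
            off[i, j] = float(model(u, ctx_off))
    floor = zero_rtol * max(np.max(np.abs(on)), np.max(np.abs(off)), 0.0)
    undefined = (np.minimum(on, off) <= floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        matrix = np.where(undefined, math.nan,
                          np.maximum(on, off) / np.minimum(on, off))
    return FoldChangeMap(X_grid, Y_grid, matrix, undefined)
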