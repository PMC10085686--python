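"""Synthetic measurement generators with plate-reader / flow-cytometry structure.

Noise is multiplicative lognormal: normalized readouts and per-cell
fluorescence are strictly positive with coefficients of variation around
0.5, which an additive Gaussian model cannot represent.  The lognormal is
parameterized by its arithmetic mean ``m`` and CV ``v`` through exact
moment matching::

    sigma^2 = ln(1 + v^2),    mu = ln(m) - sigma^2 / 2

so that ``E[output] = m`` and ``SD[output]/E[output] = v`` hold exactly.
All randomness flows through a mandatory integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .analysis_pipeline import DoseResponseTable
from .errors import ConvergenceError, DomainError, InvalidParameterError
from .merger_core import InducerPair

__all__ = [
    "NoiseSpec",
    "lognormal_from_mean_cv",
    "generate_plate_dataset",
    "generate_flow_distribution",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise structure of a synthetic experiment.

    ``replicate_cv`` is the plate-level multiplicative CV across biological
    replicates; ``cell_cv`` the per-cell lognormal width for flow-style
    distributions.  The seed is mandatory: there is no implicit randomness.
    """

    replicate_cv: float = 0.0
    cell_cv: float = 0.0
    n_replicates: int = 3
    n_cells: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_cv < 0 or self.cell_cv < 0:
            raise InvalidParameterError("CVs must be >= 0")
        if self.n_replicates < 1 or self.n_cells < 1:
            raise InvalidParameterError("counts must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise InvalidParameterError("seed must be an integer")

    def to_dict(self) -> dict:
        return {
            "replicate_cv": self.replicate_cv,
            "cell_cv": self.cell_cv,
            "n_replicates": self.n_replicates,
            "n_cells": self.n_cells,
            "seed": int(self.seed),
        }


def lognormal_from_mean_cv(mean: float, cv: float, size: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with arithmetic mean ``mean`` and CV ``cv``."""
    if mean <= 0:
        raise DomainError("mean must be > 0")
    if cv < 0:
        raise DomainError("cv must be >= 0")
    if cv == 0.0:
        return np.full(size, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def generate_plate_dataset(model: Callable[[InducerPair], float],
                           X_grid: Sequence[float],
                           Y_grid: Sequence[float],
                           ns: NoiseSpec,
                           metadata: dict | None = None) -> DoseResponseTable:
    """Replicate-resolved steady-state plate readout over a condition grid.

    Each grid point contributes ``n_replicates`` rows whose output is the
    noiseless model steady state times lognormal multiplicative noise of CV
    ``replicate_cv``.  Model failures at a grid point are flagged per-row
    and counted; with ``replicate_cv = 0`` outputs equal the model exactly.
    Runs are reproducible under the seed.
    """
    X_grid = [float(x) for x in X_grid]
    Y_grid = [float(y) for y in Y_grid]
    if not X_grid or not Y_grid:
        raise DomainError("grids must be non-empty")
    rng = np.random.default_rng(ns.seed)
    rows = []
    n_failed = 0
    for X in X_grid:
        for Y in Y_grid:
            try:
                base = float(model(InducerPair(X, Y)))
                ok = True
            except ConvergenceError:
                base, ok = math.nan, False
                n_failed += 1
            if ok and base > 0:
                noise = lognormal_from_mean_cv(base, ns.replicate_cv,
                                               ns.n_replicates, rng)
            else:
                noise = np.full(ns.n_replicates, base)
            for rep in range(ns.n_replicates):
                rows.append({"X_uM": X, "Y_uM": Y, "replicate": rep,
                             "output": float(noise[rep]), "ok": ok})
    meta = dict(metadata or {})
    meta.update({"noise": ns.to_dict(), "n_failed": n_failed,
                 "source": "synthetic-plate"})
    return DoseResponseTable(pd.DataFrame(rows), meta)


def generate_flow_distribution(mean: float, ns: NoiseSpec) -> np.ndarray:
    """Per-cell output values: ``n_cells`` lognormal draws at the given
    arithmetic mean and ``cell_cv``; reproducible under the seed."""
    if mean <= 0:
        raise DomainError("mean must be > 0")
    rng = np.random.default_rng(ns.seed)
    return lognormal_from_mean_cv(mean, ns.cell_cv, ns.n_cells, rng)
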