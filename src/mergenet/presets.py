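"""Reference parameter sets and operating grids.

The reference circuit operates in the regime the reduced ratiometric law
assumes: both sensor arms are affine in their inducers over the declared
operating ranges, production is linear in the free resource (circuit mRNA
ribosome demand is small), the protease works in its first-order regime,
and enzymatic degradation dominates dilution with a margin of about 5%,
which sets the residual sensitivity of the output to resource perturbations.

Concentrations are in uM, time in hours.  Output levels are converted to
GFP/OD units through a single multiplicative calibration factor chosen so
that the reference circuit's ratio-response slope is ~2.2e5 GFP/OD per unit
ratio at the reference RBS strength (score 8875).
"""

from __future__ import annotations

from .merger_core import (
    CompetitorParams,
    FullCircuitParams,
    InducerPair,
    MergerParams,
    effective_merger_params,
    sensitivity_constant,
)
from .sensors_resources import ResourceContext, SensorMode, SensorParams, saturating_demand

__all__ = [
    "X_GRID",
    "Y_GRID",
    "OPERATING_POINT",
    "TIR_REFERENCE",
    "TIR_VARIANTS",
    "CALIBRATION_GFP_PER_UM",
    "reference_full_params",
    "reference_merger_params",
    "reference_resource_context",
    "reference_ratio_slope",
]

# Operating grids (uM), inside the sensors' declared linear ranges.
X_GRID = (50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 400.0)
Y_GRID = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
OPERATING_POINT = InducerPair(X=50.0, Y=20.0)

# RBS-strength scores of the output protein variants (reference first).
TIR_REFERENCE = 8875.0
TIR_VARIANTS = (8875.0, 4575.0, 1770.0)

# GFP/OD units per uM of output protein (see module docstring).
CALIBRATION_GFP_PER_UM = 5.241e6


def _sensor_x() -> SensorParams:
    # Residual repression dominates over the 50-400 uM range, which makes
    # the de-repressed transcription rate proportional to the inducer.
    return SensorParams(
        regulator_total=1.0,      # uM
        inducer_Kd=0.1,           # uM
        dna_Kd=2.5e-6,            # uM
        dna_copies=10.0,
        max_rate=1.098,           # uM/hr per copy
        mode=SensorMode.REPRESSOR,
    )


def _sensor_y() -> SensorParams:
    # Far-from-saturation activator: activity affine in the inducer over
    # 0-50 uM to well under 10%.
    return SensorParams(
        regulator_total=1.0,      # uM
        inducer_Kd=5000.0,        # uM
        dna_Kd=10.0,              # uM
        dna_copies=10.0,
        max_rate=5.26,            # uM/hr per copy
        mode=SensorMode.ACTIVATOR,
    )


def _competitor() -> CompetitorParams:
    # Strong-RBS inducible reporter that halves the free ribosome pool at
    # full induction (aTc = 40 nM).
    return CompetitorParams(
        max_rate=0.86,
        dna_copies=10.0,
        theta_aTc_nM=10.0,
        delta=6.0,
        a_W=1000.0,
        b_W=10.0,
        k_W=300.0,
    )


def reference_full_params(tir: float = TIR_REFERENCE, *,
                          with_competitor: bool = False,
                          degradation_tag: bool = True) -> FullCircuitParams:
    """Full-model parameter set of the reference circuit.

    ``tir`` rescales the output RBS strength (1/K6) relative to the
    reference score; the predicted ratio-response slope scales by the same
    factor.
    """
    if tir <= 0:
        raise ValueError("tir must be > 0")
    return FullCircuitParams(
        sensor_X=_sensor_x(),
        sensor_Y=_sensor_y(),
        delta_X=6.0,
        delta_Y=6.0,
        a4=10.0, b4=10.0, k4=300.0,
        a6=10.0 * tir / TIR_REFERENCE, b6=10.0, k6=300.0,
        R_tot=10.0,
        a=100.0, b=10.0, k=100.0,
        gamma=1.0,
        competitor=_competitor() if with_competitor else None,
        degradation_tag=degradation_tag,
        calibration=CALIBRATION_GFP_PER_UM,
    )


def reference_merger_params() -> MergerParams:
    """Lumped minimal-model constants matching the reference full circuit."""
    return MergerParams(
        k_X=4.38e-4,   # 1/(uM*hr), per unit resource
        k_Y=1.676e-3,  # 1/(uM*hr), per unit resource
        a=100.0,
        b=10.0,
        k=100.0,
        gamma=1.0,
        P_XT=0.21,     # uM at the operating point
    )


def reference_ratio_slope(tir: float = TIR_REFERENCE) -> float:
    """Predicted ratio-response slope (GFP/OD per unit Y/X) of the
    reference circuit at the given output RBS score."""
    p = reference_full_params(tir)
    lumped = effective_merger_params(p, X_GRID, Y_GRID, OPERATING_POINT)
    return sensitivity_constant(lumped) * p.calibration


def reference_resource_context(aTc: float = 0.0, *,
                               perturbation_fraction: float = 1.0) -> ResourceContext:
    """Resource context matching the reference competitor cassette."""
    return ResourceContext(
        R_tot=10.0,
        competitor_demand=saturating_demand(demand_max=1.25, theta_nM=10.0),
        perturbation_fraction=perturbation_fraction,
        aTc=aTc,
    )
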