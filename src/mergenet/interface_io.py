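"""File formats, configuration and the command-line interface.

One CSV dialect is used everywhere: comma-separated, period decimal, UTF-8,
header required, columns ``X_uM, Y_uM, replicate, output`` (plus an
optional ``ok`` flag).  Tables round-trip losslessly; malformed files are
rejected with per-row diagnostics, never silently re-parsed.  Parameter
sets live in flat ``key = value`` config files with dotted prefixes for the
sensor and competitor blocks.  Every CLI command writes a manifest
recording the exact options and seed needed to regenerate its artifacts;
manifests carry no timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable

import click
import numpy as np
import pandas as pd

from . import presets
from .analysis_pipeline import (
    DoseResponseTable,
    dose_response_sweep,
    fold_change_map,
    ratio_response_fit,
    relative_percent_error,
)
from .errors import DialectError, MergenetError
from .merger_core import (
    CompetitorParams,
    FullCircuitParams,
    InducerPair,
    MergerParams,
    broken_merging_output,
    check_assumptions,
    effective_merger_params,
    full_model_output,
    reduced_merger_output,
    solve_full_steady_state,
)
from .model_fitting import fit_broken_merging, fit_reduced_merger
from .sensors_resources import SensorMode, SensorParams
from .synthetic_data import NoiseSpec, generate_plate_dataset

__all__ = [
    "read_dose_response_csv",
    "write_dose_response_csv",
    "load_config",
    "save_config",
    "full_params_from_config",
    "full_params_to_config",
    "merger_params_from_config",
    "cli",
]

logger = logging.getLogger("mergenet")

_REQUIRED = ["X_uM", "Y_uM", "replicate", "output"]
_OPTIONAL = ["ok"]


# ---------------------------------------------------------------------------
# dose-response CSV

def write_dose_response_csv(t: DoseResponseTable, path) -> None:
    """Write a table (full float precision) plus a JSON metadata sidecar."""
    path = Path(path)
    cols = _REQUIRED + [c for c in _OPTIONAL if c in t.data.columns]
    t.data[cols].to_csv(path, index=False)
    if t.metadata:
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(t.metadata, indent=2, default=str) + "\n")


def _parse_float(token: str, row: int, col: str) -> float:
    token = token.strip()
    if "," in token:
        raise DialectError(
            f"row {row}, column {col}: decimal commas are not part of the "
            f"dialect (got {token!r})")
    try:
        return float(token)
    except ValueError:
        raise DialectError(
            f"row {row}, column {col}: cannot parse {token!r} as a number")


def read_dose_response_csv(path) -> DoseResponseTable:
    """Read a dose-response table, validating the dialect row by row."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, sep=",", keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise DialectError(f"{path}: missing columns {missing}")
    unknown = [c for c in raw.columns if c not in _REQUIRED + _OPTIONAL]
    if unknown:
        raise DialectError(f"{path}: unknown columns {unknown}")
    dupes = raw.columns[raw.columns.duplicated()].tolist()
    if dupes:
        raise DialectError(f"{path}: duplicate columns {dupes}")

    data = {}
    for col in ("X_uM", "Y_uM", "output"):
        data[col] = [_parse_float(v, i, col) if v.strip().lower() != "nan"
                     else float("nan")
                     for i, v in enumerate(raw[col])]
    try:
        data["replicate"] = [int(v) for v in raw["replicate"]]
    except ValueError as exc:
        raise DialectError(f"{path}: non-integer replicate index ({exc})")
    if "ok" in raw.columns:
        data["ok"] = [v.strip().lower() in ("true", "1") for v in raw["ok"]]

    metadata = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    try:
        return DoseResponseTable(pd.DataFrame(data), metadata)
    except MergenetError as exc:
        raise DialectError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# flat key-value config

def _parse_value(token: str):
    token = token.strip()
    low = token.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(token)
        except ValueError:
            pass
    return token


def load_config(path) -> dict:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    cfg: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DialectError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in cfg:
            raise DialectError(f"{path}:{lineno}: duplicate key {key!r}")
        cfg[key] = _parse_value(value)
    return cfg


def save_config(cfg: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


_SENSOR_FIELDS = ("regulator_total", "inducer_Kd", "dna_Kd", "dna_copies",
                  "max_rate", "mode", "hill")
_COMP_FIELDS = ("max_rate", "dna_copies", "theta_aTc_nM", "delta",
                "a_W", "b_W", "k_W")
_SCALAR_FIELDS = ("delta_X", "delta_Y", "a4", "b4", "k4", "a6", "b6", "k6",
                  "R_tot", "a", "b", "k", "gamma", "degradation_tag",
                  "calibration")


def _sensor_from(cfg: dict, prefix: str) -> SensorParams:
    kwargs = {}
    for name in _SENSOR_FIELDS:
        key = f"{prefix}.{name}"
        if key in cfg:
            kwargs[name] = cfg[key]
    kwargs["mode"] = SensorMode(kwargs["mode"])
    return SensorParams(**kwargs)


def full_params_from_config(cfg: dict) -> FullCircuitParams:
    kwargs = {name: cfg[name] for name in _SCALAR_FIELDS if name in cfg}
    kwargs["sensor_X"] = _sensor_from(cfg, "sensor_X")
    kwargs["sensor_Y"] = _sensor_from(cfg, "sensor_Y")
    if any(k.startswith("competitor.") for k in cfg):
        kwargs["competitor"] = CompetitorParams(
            **{name: cfg[f"competitor.{name}"] for name in _COMP_FIELDS})
    return FullCircuitParams(**kwargs)


def full_params_to_config(p: FullCircuitParams) -> dict:
    cfg: dict = {"variant": "full"}
    for prefix, sensor in (("sensor_X", p.sensor_X), ("sensor_Y", p.sensor_Y)):
        for name in _SENSOR_FIELDS:
            value = getattr(sensor, name)
            cfg[f"{prefix}.{name}"] = value.value if isinstance(value, SensorMode) else value
    for name in _SCALAR_FIELDS:
        cfg[name] = getattr(p, name)
    if p.competitor is not None:
        for name in _COMP_FIELDS:
            cfg[f"competitor.{name}"] = getattr(p.competitor, name)
    return cfg


def merger_params_from_config(cfg: dict) -> MergerParams:
    names = ("k_X", "k_Y", "a", "b", "k", "gamma", "P_XT")
    return MergerParams(**{n: cfg[n] for n in names})


# ---------------------------------------------------------------------------
# CLI plumbing

def _load_full(config: str | None) -> FullCircuitParams:
    if config is None:
        logger.info("no --config given: using the reference parameter set")
        return presets.reference_full_params(with_competitor=True)
    return full_params_from_config(load_config(config))


def _parse_grid(text: str) -> tuple[float, ...]:
    try:
        return tuple(float(v) for v in text.split(","))
    except ValueError:
        raise click.BadParameter(f"grid must be comma-separated numbers, got {text!r}")


def _build_model(variant: str, config: str | None, aTc: float,
                 resource_scale: float) -> Callable[[InducerPair], float]:
    cfg = load_config(config) if config else None
    if variant == "full":
        p = _load_full(config)
        return lambda u: full_model_output(p, u, aTc=aTc,
                                           resource_scale=resource_scale)
    if variant == "reduced-merger":
        c = cfg["c_slope"] if cfg else presets.reference_ratio_slope()
        return lambda u: reduced_merger_output(c, u)
    if variant == "reduced-broken":
        if cfg is None:
            raise click.UsageError("reduced-broken needs a --config with "
                                   "amplitude_k6, R_tot, gamma, c1, c2")
        amp = dict(k6=cfg["amplitude_k6"], R_tot=cfg["R_tot"] * resource_scale,
                   gamma=cfg["gamma"], c1=cfg["c1"], c2=cfg["c2"])
        return lambda u: broken_merging_output(X_T=u.X, Y_T=u.Y, **amp)
    raise click.BadParameter(f"unknown variant {variant!r}")


def _write_json(out_dir: Path, name: str, payload: dict) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=str) + "\n")
    return path


def _manifest(out_dir: Path, command: str, options: dict) -> None:
    from . import __version__

    _write_json(out_dir, "manifest.json", {
        "command": command,
        "package_version": __version__,
        "options": options,
    })


def _common(f):
    f = click.option("--config", type=click.Path(exists=True), default=None,
                     help="Flat key=value parameter file.")(f)
    f = click.option("--out", "out_dir", type=click.Path(), default="mergenet_out",
                     help="Output directory.")(f)
    f = click.option("--seed", type=int, default=0, show_default=True)(f)
    return f


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="DEBUG-level logging.")
def cli(verbose: bool) -> None:
    """Ratiometric circuit simulation, analysis, fitting and synthesis."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@_common
@click.option("--x", "x_val", type=float, required=True, help="X inducer, uM.")
@click.option("--y", "y_val", type=float, required=True, help="Y inducer, uM.")
@click.option("--atc", type=float, default=0.0, show_default=True)
@click.option("--resource-scale", type=float, default=1.0, show_default=True)
def simulate(config, out_dir, seed, x_val, y_val, atc, resource_scale):
    """Solve the full model to steady state at one input condition."""
    p = _load_full(config)
    out_dir = Path(out_dir)
    res = solve_full_steady_state(p, InducerPair(x_val, y_val), aTc=atc,
                                  resource_scale=resource_scale)
    if not res.converged:
        raise click.ClickException(
            f"steady state did not converge (residual {res.residual_norm:.3e})")
    state = res.as_dict()
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([state]).to_csv(out_dir / "steady_state.csv", index=False)
    _write_json(out_dir, "steady_state.json", {
        "state": state, "converged": res.converged,
        "residual_norm": res.residual_norm, "method": res.method,
        "output_gfp_od": state["P_Y"] * p.calibration,
    })
    _manifest(out_dir, "simulate", {"config": config, "x": x_val, "y": y_val,
                                    "atc": atc, "resource_scale": resource_scale,
                                    "seed": seed})
    logger.info("steady state written to %s", out_dir)


@cli.command()
@_common
@click.option("--variant", type=click.Choice(["full", "reduced-merger",
                                              "reduced-broken"]),
              default="full", show_default=True)
@click.option("--grid-x", default=None, help="Comma-separated X grid (uM).")
@click.option("--grid-y", default=None, help="Comma-separated Y grid (uM).")
@click.option("--atc", type=float, default=0.0, show_default=True)
@click.option("--strict", is_flag=True,
              help="Fail (nonzero exit) on any unconverged grid point.")
def sweep(config, out_dir, seed, variant, grid_x, grid_y, atc, strict):
    """Dose-response sweep over an X-by-Y input grid."""
    x_grid = _parse_grid(grid_x) if grid_x else presets.X_GRID
    y_grid = _parse_grid(grid_y) if grid_y else presets.Y_GRID
    model = _build_model(variant, config, atc, 1.0)
    table = dose_response_sweep(model, x_grid, y_grid,
                                metadata={"variant": variant, "aTc": atc,
                                          "seed": seed})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_dose_response_csv(table, out_dir / "dose_response.csv")
    _manifest(out_dir, "sweep", {"config": config, "variant": variant,
                                 "grid_x": list(x_grid), "grid_y": list(y_grid),
                                 "atc": atc, "seed": seed})
    if table.n_failed:
        logger.warning("%d grid points did not converge", table.n_failed)
        if strict:
            raise click.ClickException(
                f"{table.n_failed} grid points failed (--strict)")
    logger.info("sweep written to %s", out_dir)


@cli.command("ratio-fit")
@_common
@click.option("--input", "input_csv", type=click.Path(exists=True), required=True)
@click.option("--through-origin", is_flag=True)
def ratio_fit(config, out_dir, seed, input_csv, through_origin):
    """Fit output versus Y/X with ordinary least squares."""
    table = read_dose_response_csv(input_csv)
    fit = ratio_response_fit(table, through_origin=through_origin)
    _write_json(Path(out_dir), "ratio_fit.json", {
        "slope": fit.slope, "intercept": fit.intercept,
        "r_squared": fit.r_squared, "n_points": fit.n_points,
        "degenerate": fit.degenerate,
    })
    _manifest(Path(out_dir), "ratio-fit", {"input": str(input_csv),
                                           "through_origin": through_origin,
                                           "seed": seed})
    logger.info("ratio fit: slope=%.6g r2=%.5f", fit.slope, fit.r_squared)


@cli.command()
@_common
@click.option("--x", "x_val", type=float, default=None)
@click.option("--y", "y_val", type=float, default=None)
@click.option("--perturbation", type=float, default=0.5, show_default=True,
              help="Fraction of nominal resource in the perturbed condition.")
def robustness(config, out_dir, seed, x_val, y_val, perturbation):
    """Relative % error of the output under a resource perturbation."""
    p = _load_full(config)
    u = (InducerPair(x_val, y_val) if x_val is not None
         else presets.OPERATING_POINT)
    nominal = full_model_output(p, u)
    perturbed = full_model_output(p, u, resource_scale=perturbation)
    err = relative_percent_error(nominal, perturbed)
    _write_json(Path(out_dir), "robustness.json", {
        "x": u.X, "y": u.Y, "perturbation": perturbation,
        "nominal": nominal, "perturbed": perturbed,
        "relative_percent_error": err,
    })
    _manifest(Path(out_dir), "robustness", {"config": config, "x": u.X,
                                            "y": u.Y,
                                            "perturbation": perturbation,
                                            "seed": seed})
    logger.info("relative %% error: %.4f", err)


@cli.command()
@_common
@click.option("--grid-x", default=None)
@click.option("--grid-y", default=None)
@click.option("--atc", type=float, default=40.0, show_default=True,
              help="Competitor induction of the 'on' context (nM).")
@click.option("--variant", type=click.Choice(["full"]), default="full")
def foldmap(config, out_dir, seed, grid_x, grid_y, atc, variant):
    """Fold-change heat map: competitor induced versus uninduced."""
    p = _load_full(config)
    if p.competitor is None:
        raise click.ClickException("foldmap requires a competitor block")
    x_grid = _parse_grid(grid_x) if grid_x else presets.X_GRID
    y_grid = _parse_grid(grid_y) if grid_y else presets.Y_GRID
    model = lambda u, level: full_model_output(p, u, aTc=level)
    fmap = fold_change_map(model, x_grid, y_grid, atc, 0.0)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(fmap.matrix, index=list(x_grid), columns=list(y_grid))
    frame.index.name = "X_uM"
    frame.to_csv(out_dir / "fold_change.csv")
    _write_json(out_dir, "fold_change_summary.json", {
        "max_fold": fmap.max_fold, "atc_on": atc, "atc_off": 0.0,
        "n_undefined": int(fmap.undefined.sum()),
    })
    _manifest(out_dir, "foldmap", {"config": config, "grid_x": list(x_grid),
                                   "grid_y": list(y_grid), "atc": atc,
                                   "seed": seed})
    logger.info("max fold change: %.4f", fmap.max_fold)


@cli.command()
@_common
@click.option("--input", "input_csv", type=click.Path(exists=True), required=True)
@click.option("--model", "model_kind", type=click.Choice(["merger", "broken"]),
              default="merger", show_default=True)
@click.option("--n-starts", type=int, default=10, show_default=True)
def fit(config, out_dir, seed, input_csv, model_kind, n_starts):
    """Nonlinear least-squares fit of a reduced law to a dose-response table."""
    table = read_dose_response_csv(input_csv)
    if model_kind == "merger":
        result = fit_reduced_merger(table, seed=seed, n_starts=n_starts)
    else:
        result = fit_broken_merging(table, seed=seed, n_starts=n_starts)
    _write_json(Path(out_dir), "fit.json", result.to_dict())
    _manifest(Path(out_dir), "fit", {"input": str(input_csv),
                                     "model": model_kind, "seed": seed,
                                     "n_starts": n_starts})
    if not result.converged:
        raise click.ClickException("fit did not converge from any start")
    logger.info("fit estimates: %s", result.estimates)


@cli.command()
@_common
@click.option("--variant", type=click.Choice(["full", "reduced-merger",
                                              "reduced-broken"]),
              default="reduced-merger", show_default=True)
@click.option("--grid-x", default=None)
@click.option("--grid-y", default=None)
@click.option("--replicate-cv", type=float, default=0.5, show_default=True)
@click.option("--n-replicates", type=int, default=3, show_default=True)
@click.option("--atc", type=float, default=0.0, show_default=True)
def synth(config, out_dir, seed, variant, grid_x, grid_y, replicate_cv,
          n_replicates, atc):
    """Generate a synthetic replicate-resolved plate dataset."""
    x_grid = _parse_grid(grid_x) if grid_x else presets.X_GRID
    y_grid = _parse_grid(grid_y) if grid_y else presets.Y_GRID
    model = _build_model(variant, config, atc, 1.0)
    ns = NoiseSpec(replicate_cv=replicate_cv, n_replicates=n_replicates,
                   seed=seed)
    table = generate_plate_dataset(model, x_grid, y_grid, ns,
                                   metadata={"variant": variant, "aTc": atc})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_dose_response_csv(table, out_dir / "synthetic.csv")
    _manifest(out_dir, "synth", {"config": config, "variant": variant,
                                 "grid_x": list(x_grid), "grid_y": list(y_grid),
                                 "replicate_cv": replicate_cv,
                                 "n_replicates": n_replicates, "atc": atc,
                                 "seed": seed})
    logger.info("synthetic dataset written to %s", out_dir)


@cli.command("check-assumptions")
@_common
@click.option("--x", "x_val", type=float, default=None)
@click.option("--y", "y_val", type=float, default=None)
@click.option("--strictness", type=float, default=0.1, show_default=True)
def check_assumptions_cmd(config, out_dir, seed, x_val, y_val, strictness):
    """Reduced-law validity margins at an operating point."""
    p = _load_full(config)
    u = (InducerPair(x_val, y_val) if x_val is not None
         else presets.OPERATING_POINT)
    mp = effective_merger_params(p, presets.X_GRID, presets.Y_GRID, u)
    ss = solve_full_steady_state(p, u)
    report = check_assumptions(mp, ss, strictness=strictness)
    _write_json(Path(out_dir), "assumptions.json", report.to_dict())
    _manifest(Path(out_dir), "check-assumptions",
              {"config": config, "x": u.X, "y": u.Y,
               "strictness": strictness, "seed": seed})
    logger.info("A1 %s (margin %.4f), A2 %s (margin %.4f)",
                "pass" if report.a1_pass else "FAIL", report.a1_margin,
                "pass" if report.a2_pass else "FAIL", report.a2_margin)


def main() -> None:  # pragma: no cover
    cli()


if __name__ == "__main__":  # pragma: no cover
    main()
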