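# mergenet

Modelling and analysis toolkit for a ratiometric gene-expression circuit:
one input molecule (X, e.g. IPTG) drives a protease that degrades the
output protein, the other (Y, e.g. Sal) drives the output's expression,
and both arms draw on a shared translational resource pool. In the proper
parameter regime the steady-state output follows the closed-form law
`P_Y = c * Y/X` — proportional to the input ratio and insensitive to the
resource level — while an untagged ("broken merging") control is neither
ratiometric nor resource-robust.

## What is in the box

| module | contents |
| --- | --- |
| `mergenet.merger_core` | domain types, mass-action ODE right-hand sides (minimal and full), stiff steady-state solver with root polishing, reduced closed-form laws, validity-assumption checks |
| `mergenet.sensors_resources` | equilibrium transcriptional sensors (repressor / activator), linear-operating-range scan, conserved resource pool with an inducible competitor |
| `mergenet.analysis_pipeline` | dose-response sweeps, output-vs-ratio linear fits, RBS-score slope scaling, relative-%-error robustness metric, constant-ratio tests, fold-change heat maps |
| `mergenet.model_fitting` | bounded multistart nonlinear least squares for both reduced laws, robust (HC3 + effective-dof) 95% confidence intervals, goodness of fit |
| `mergenet.synthetic_data` | seeded lognormal plate-replicate and per-cell flow-distribution generators (moment-matched mean/CV) |
| `mergenet.interface_io` | strict CSV dialect, flat key=value parameter configs, JSON reports/manifests, `mergenet` CLI |
| `mergenet.presets` | reference parameter set, operating grids, RBS-score variants |

Units: concentrations in uM, time in hours; outputs are converted to
GFP/OD through a single configurable calibration factor.

## CLI

Each command writes CSV/JSON artifacts plus a `manifest.json`; reruns with
the same options are byte-identical. Without `--config` the reference
parameter set is used.

```bash
mergenet simulate --x 100 --y 40 --out out/sim           # one steady state
mergenet sweep --variant full --out out/sweep            # dose-response grid
mergenet synth --variant reduced-merger --replicate-cv 0.5 --seed 7 --out out/synth
mergenet ratio-fit --input out/synth/synthetic.csv --out out/fit
mergenet fit --input out/synth/synthetic.csv --model merger --out out/fit2
mergenet robustness --perturbation 0.5 --out out/rob     # resource halving
mergenet foldmap --atc 40 --out out/fold                 # competitor on/off
mergenet check-assumptions --out out/check
```

Parameter files are flat `key = value` text; dump the reference set with

```python
from mergenet.interface_io import full_params_to_config, save_config
from mergenet.presets import reference_full_params
save_config(full_params_to_config(reference_full_params(with_competitor=True)), "params.cfg")
```

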