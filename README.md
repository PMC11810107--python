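# sizeflux

Single-cell cytometry analysis of **size-dependent compensatory growth**:
how proliferating mammalian cells that overshoot their target size slow
their mass accumulation by ramping up proteasome-mediated protein
degradation.

The package is aimed at quantitative cell biologists working with
plate-based, fixed-cell high-content imaging (per-cell integrated
intensities of DNA, a Geminin cell-cycle reporter, a total-protein dye,
and functional markers) together with live-cell nuclear-area tracks and
bulk proliferation counts. It provides:

- **`sizeflux.simulate`** — an agent-based generative model of growing,
  dividing cells with a G1 size checkpoint, a compensation law on the
  degradation flux, reporter dynamics, staining noise and replicate-well
  structure. It emits snapshot, track and bulk tables with ground-truth
  sidecar columns, standing in for the imaging experiment.
- **`sizeflux.staging`** — automatic cell-cycle staging: density-valley
  thresholds on DNA (2N / S / 4N) and log-Geminin (early G1 vs G1/S).
- **`sizeflux.trajectory`** — a continuous cell-cycle axis ℓ ∈ [0, 1]:
  the density ridge of the (DNA, log Geminin) distribution, traced as a
  polyline, with nearest-point projection of cells and (ℓ, size)
  heatmaps.
- **`sizeflux.turnover`** — proteasome-flux statistics. The central
  quantity is **ΔK48-polyUb**: the K48-polyubiquitin signal accumulated
  during a 30-minute proteasome blockade (carfilzomib), estimated as the
  cross-pair difference of well-level K48 between +CFZ and −CFZ wells.
  Satellites: superlinear size-scaling tests (is the fold change in
  ΔK48 larger than the fold change in size?), nascent/long-lived
  decomposition via cycloheximide, CHX-chase size-loss slopes, and the
  deviation of G1/S cells from the stage-wise size trend.
- **`sizeflux.growth`** — growth inference: cell-cycle length
  τ = ln 2 / α from exponential fits to cell counts, the per-cell bulk
  mass-accumulation rate ν = (1/N) dM/dt, and the single-cell track
  pipeline (smoothed nuclear-area derivatives, birth/G1-S aligned mean
  curves, phase durations, small-vs-large growth comparisons).
- **`sizeflux.io` / `sizeflux.pipeline` / CLI** — validated CSV schemas,
  a YAML run configuration, and a `sizeflux` command with subcommands
  `simulate`, `stage`, `trajectory`, `turnover`, `growthfit`, `tracks`
  and `all`. Outputs carry provenance headers and are byte-identical
  under a fixed seed.

The model, algorithms and defaults are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a control arm and a CDK2-inhibited arm (longer G1, delayed
compensatory degradation), stage the cells, and ask whether degradation
scales superlinearly with size:

```python
import numpy as np
import pandas as pd
from sizeflux import SimConfig
from sizeflux.simulate import simulate_snapshot
from sizeflux.staging import detect_thresholds, assign_stage
from sizeflux.turnover import delta_k48, scaling_analysis

cfg = SimConfig(seed=901, n_wells=9, cells_per_well=300, burn_in_h=25.0)

def cfz_pair(condition):          # 9 wells per CFZ arm, fixed at 24 h
    return pd.concat([
        simulate_snapshot(cfg, condition, 24.0, cfz=False),
        simulate_snapshot(cfg, condition, 24.0, cfz=True),
    ], ignore_index=True)

ctl_cells, prt_cells = cfz_pair("control"), cfz_pair("CDK2i")
thresholds = detect_thresholds(ctl_cells)
ctl = delta_k48(assign_stage(ctl_cells, thresholds), per_stage=True, centre="mean")
prt = delta_k48(assign_stage(prt_cells, thresholds), per_stage=True, centre="mean")

fit = scaling_analysis(ctl, prt, n_boot=2000, rng=np.random.default_rng(0))
print(f"control dK48 = {ctl[0].delta_k48:.2f} "
      f"[{ctl[0].ci_low:.2f}, {ctl[0].ci_high:.2f}] a.u./30 min")
print(f"fold dK48 = {fit.fold_delta:.3f}  fold size = {fit.fold_size:.3f}")
print(f"excess ratio = {fit.excess_ratio:.3f}  superlinear p = {fit.superlinear_p:.4f}")
```

prints

```
control dK48 = 6.10 [6.00, 6.21] a.u./30 min
fold dK48 = 1.457  fold size = 1.109  excess ratio = 1.313  superlinear p = 0.0005
```

Read: control cells clear about 6.1 a.u. of K48-polyubiquitinated
protein per 30 minutes. Under CDK2 inhibition the clearance rate rises
~46% while median cell size rises only ~11% (stage-matched folds), an
excess ratio of 1.31 — degradation increases disproportionately with
size, and the well-bootstrap test rejects proportional scaling
(p ≈ 0.0005). Running the same analysis against the `CDK46i` arm (bigger
target size, no compensation) gives an excess ratio near 1.

The same experiment from the shell, end to end:

```sh
sizeflux all --seed 901 --condition control --condition CDK2i --out results/
```

writes staged cells, the fitted trajectory, turnover and scaling tables,
growth fits and track summaries under `results/`, each with a provenance
header.

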