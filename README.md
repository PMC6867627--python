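# ringlane

Run/rest motility fingerprinting of single cells migrating on ring-shaped
micro-lanes.

## The problem

Cell migration assays on 1D micropatterns confine single cells to narrow
adhesive lanes — here rings of 150 µm diameter (fibronectin-coated, PEG
passivated) — so that a cell's position reduces to one coordinate, the
unwrapped angle φ(t) on the ring. Time-lapse tracking of many rings, each
occupied by one cell, yields large numbers of single-cell trajectories in
which two modes of motion alternate: **run states**, where the cell moves
persistently in one direction, and **rest states** with no net motion or
random wiggling. This package segments such trajectories into runs and
rests and condenses each cell population into a five-parameter motility
fingerprint:

| parameter | definition |
|---|---|
| v_run | mean absolute tangential velocity over run-state frames, v_run = ⟨\|v_tang\|⟩ (µm/h) |
| τ_run, τ_rest | characteristic lifetimes of run/rest states from a log-linear fit of the dwell-time survival function S(t) = P(T > t): log S(t) ≈ −t/τ + c on t ∈ [2, 16] h |
| P_run | fraction of observation time spent in the run state |
| q | persistence: (max φ − min φ) / Σᵢ\|φᵢ₊₁ − φᵢ\| — 1 for ballistic motion, ≪1 for diffusive wiggling |

plus the fraction of fully immobile cells (tracks that are a single rest
state). Dwell times enter the survival fit only if the state starts at
least 16 h before its track ends, so right-censoring cannot distort S(t)
inside the fit range. v_run, P_run and q carry standard errors over cells;
the τ's carry 99% confidence intervals of the fit. Conditions are compared
per parameter with two-sided Welch t-tests (τ's: non-overlap of the 99%
CIs).

Because the segmentation and estimation chain has many places to go subtly
wrong, the package ships a ground-truth simulator: a stationary alternating
renewal process with exponential dwell times, per-cell lognormal speeds, a
tunable immobile subpopulation, ballistic runs and Gaussian rest wiggle.
Every stage of the pipeline is validated against it.

A small morphology module quantifies cell/nuclear shape from binary masks
(shape factor = minimum / maximum Feret diameter) and masked relative
fluorescence intensities.

## Worked example

Simulate a population of 60 cells for 48 h at a 10-minute frame interval
(defaults: median run speed 30 µm/h, τ_run = 4 h, τ_rest = 2 h, 10%
immobile cells) and analyze it:

```sh
$ ringlane simulate --n-cells 60 --seed 1 --out-dir demo/sim
wrote 60 trajectories to demo/sim/tracks.csv
$ ringlane analyze --tracks demo/sim/tracks.csv --out-dir demo/ctrl
n=60  v_run=28.70 um/h  tau_run=5.09 h  tau_rest=3.55 h  P_run=0.659  q=0.523  immobile=0.067
```

Reading the output: v_run recovers the cohort's mean run speed; P_run ≈
τ_run/(τ_run + τ_rest) as expected for a stationary alternating process;
q ≈ 0.5 reflects direction reversals between runs. τ_rest comes out above
the 2 h of the mobile cells because the immobile cells contribute
never-ending rest states that flatten the survival tail — a real feature
of such data, not an artifact (at 60 cells the τ fits are also still
noisy; the survival fit used n = 279 run states). `demo/ctrl/` contains
the full `fingerprint.json` with uncertainties, a per-cell parameter table
and the segment table; `ringlane compare` then tests two analyzed
conditions parameter by parameter and reports how many of the five
parameters shifted. `ringlane shapes mask1.tif mask2.tif --out shapes.csv`
computes Feret shape factors of binary masks.

The same pipeline is available as a library:

```python
import ringlane as rl

coll, truth = rl.simulate_population(rl.ctrl_like(n_cells=300, seed=1))
result = rl.fingerprint(coll)          # segmentation + all five parameters
print(result.fingerprint.tau_run.tau)  # population run-state lifetime (h)
```

Real tracking tables are read with `rl.read_trajectories(path, geometry)`
from CSV columns `cell_id, time_h, x_um, y_um` (or `phi_rad`); column
names and time units are configurable via `rl.CsvDialect`.

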