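# cfcnmm

A two-node, four-population neural mass model of cross-frequency coupling
(CFC), packaged as a simulator plus a signal-analysis toolkit.

Each node contains pyramidal, excitatory-interneuron, slow-inhibitory and
fast-inhibitory populations; the fast inhibitory population carries a dynamic
self-feedback that generates gamma-band activity, and the pyramidal/slow-
inhibitory loop generates a delta-band slow oscillation. The two nodes are
mutually coupled through relay pyramidal populations, which synchronizes
their slow oscillations. Varying only the mean input-noise levels `P1`, `P2`
moves each node between a damped, a resonance (frequency-modulable) and a
limit-cycle (amplitude-modulable) fast-oscillation regime, producing five
coupling types from one fixed architecture:

| preset | P1  | P2  | coupling produced                      |
|--------|-----|-----|----------------------------------------|
| PFC    | 4.5 | 0   | slow phase → fast frequency (node 1)   |
| PAC    | 7   | 0   | slow phase → fast amplitude (node 1)   |
| FFC    | 4.5 | 4.5 | fast frequency ↔ fast frequency        |
| AAC    | 7   | 7   | fast amplitude ↔ fast amplitude        |
| AFC    | 7   | 4.5 | fast amplitude ↔ fast frequency        |

## Layout

- `cfcnmm.model` — configuration dataclasses, sigmoid rate function,
  second-order dendritic blocks, and the 26-component vector field.
- `cfcnmm.integrate` — fixed-step classical RK4 with per-step Gaussian noise
  (zero-order-held across substeps), seeded dual noise streams, transient
  removal, divergence detection. The hot loop is numba-compiled when numba
  is available (pure-Python fallback otherwise).
- `cfcnmm.analysis` — slow/fast decomposition at a 15 Hz cut-off (zero-phase
  Butterworth, z-scored), per-phase zero-crossing rate, Welch PSD (Hanning
  16384 / 25 % overlap), spectral peaks with FWHM, Hilbert envelopes, PLV.
- `cfcnmm.experiments` — the five presets, the regime classifier
  (damped / resonance / limit_cycle), report generation, P-sweeps.
- `cfcnmm.io` / `cfcnmm.cli` — YAML/JSON configs keyed by the printed
  parameter symbols, TSV/JSON outputs, run manifests, CLI.

## CLI

```sh
# integrate the default model, write t / vm_p1 / vm_p2 as TSV
cfcnmm simulate --seed 1 --duration 30 --out runs/sim

# spectra + band peaks for a simulated series
cfcnmm analyze --input runs/sim/series.tsv

# run a named preset (averaged over seeds), emit the coupling report
cfcnmm experiment --name aac --seeds 3 --out runs/aac

# regime classification along a grid of mean noise levels
cfcnmm sweep --pmin 0 --pmax 7 --steps 3 --out runs/sweep
```

Configs are flat YAML/JSON mappings using the printed symbols
(`C_pq1`, `K_12`, `tau_f1`, `P1`, `sigma2_1`, `dt`, ...); missing keys take
the shipped defaults, unknown keys are rejected.

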