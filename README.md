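# addnet

Whole-brain neural-mass simulation with activity-dependent synaptic
degeneration (ADD), plus a functional-connectivity (FC) biomarker benchmark.

The package simulates a network of coupled excitatory/inhibitory neural-mass
pairs (one per brain region, coupled through a binary structural connectome
and driven by noisy thalamic input). An activity-dependent degeneration rule
multiplicatively weakens all synapses of a region as a function of its recent
peak excitatory firing, producing progressive oscillatory slowing, rising
theta power, and a rising excitation/inhibition balance. On top of the
simulator, four pairwise FC measures — amplitude envelope correlation
(AEC/AECc), phase lag index (PLI), phase lag time (PLT), and joint
permutation entropy (JPE) — are computed per frequency band and epoch and
benchmarked as classifiers of degeneration vs. control runs (permutation
tests, Benjamini–Hochberg FDR, per-ROI profiles, ROC analysis), with
relative theta power as the reference marker.

## Layout

| module | contents |
|---|---|
| `addnet.connectome` | load/validate/save binary structural networks, seeded surrogate generator, edge-damage tables |
| `addnet.neural_mass` | model parameters, PSP filters, sigmoid, the coupled-network integrator (numba-accelerated with a pure-Python fallback) |
| `addnet.add_process` | degeneration rule (windowed max activity, exponential loss, multiplicative strength updates), E/I balance, per-epoch timecourses |
| `addnet.spectral` | zero-phase FFT band-pass, analytic signal, relative band power, median/peak frequency |
| `addnet.fc_measures` | AEC/AECc, PLI, PLT, JPE; per-epoch FC matrices and ROI summaries |
| `addnet.benchmark_stats` | permutation tests (exact when feasible), BH-FDR, ROC, significance time courses, per-ROI comparisons |
| `addnet.config` / `addnet.io` / `addnet.cli` | YAML run configuration, delimited-text/EDF I/O, command-line pipeline |

## CLI

```sh
# simulate 20 degeneration runs of 10 epochs each (78-node seeded surrogate)
addnet simulate --out runs/add --condition add --n-runs 20 --n-epochs 10 --seed 42

# matched control runs (synapse strengths frozen at 1)
addnet simulate --out runs/con --condition con --n-runs 20 --n-epochs 10 --seed 42

# FC matrices + spectral summaries for every run and epoch
addnet measure --run-dir runs/add --measures AECc,PLI,PLT,JPE --bands theta
addnet measure --run-dir runs/con --measures AECc,PLI,PLT,JPE --bands theta

# group comparison: significance curves, per-ROI tables, ROC summaries
addnet benchmark --add-dir runs/add --con-dir runs/con --out runs/bench
```

All defaults (sampling, epoch structure, model constants, degeneration
speed) live in `addnet.config.RunConfig` and can be overridden via
`--config config.yaml`; unknown keys are rejected. A user-supplied
connectome is given as an `N x N` delimited-text adjacency matrix
(`connectome_path`); otherwise a seeded surrogate is generated.

## Caveats

The structural connectome used in the original study is not published; the
default pipeline substitutes a seeded 78-node surrogate (density 0.10,
modular), so quantitative benchmark results differ from the published ones.
The degeneration speed is applied with a calibrated per-sample rescaling
(`kappa`) because the literal per-sample rule collapses the network within a
single epoch; the literal mode is available via `AddConfig(literal=True)`.
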