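# netreconfig

Time-resolved functional brain-network reconfiguration from parcellated
resting-state BOLD time series: sliding-window connectivity, multilayer
modularity, node flexibility/promiscuity/degree, surrogate-based
significance testing, and brain–behavior correlation — plus a synthetic
cohort generator with planted ground truth so every stage is verifiable
without access to subject data.

## Who this is for

Researchers analyzing dynamic functional connectivity in resting-state
fMRI — in particular individual-difference studies relating network
reconfiguration metrics to behavioral scores — who need a tested,
reproducible reference implementation of the standard pipeline: motion QC
with filtered framewise displacement, 36/26-parameter confound regression,
Hamming-tapered sliding-window Pearson correlation, ordinal multilayer
modularity with generalized-Louvain optimization, phase-randomization
surrogate testing of edge dynamics, and partial Spearman correlation grids
with FDR control.

## The core model

A subject's windowed connectivity layers A^s (negative correlations zeroed,
Fisher z-transformed) form an ordinal multilayer network in which each node
is coupled to itself in adjacent layers with strength ω. A joint community
partition g is scored by the multilayer modularity

    Q = (1/2μ) Σ_{ijsr} [ (A_ij^s − γ k_i^s k_j^s / 2m_s) δ_sr
                          + ω δ_ij [|s−r|=1] ] δ(g_is, g_jr),

with per-layer Newman–Girvan null models, resolution γ and coupling ω
(both default 1), and 2μ = Σ_s 2m_s + 2ωN(L−1). A stochastic generalized
Louvain maximizes Q; the best of (by default) 100 runs is kept. From the
partition, node *flexibility* is the fraction of adjacent-layer transitions
with a community change and node *promiscuity* the fraction of all
communities a node ever joins. Independently of modularity, an edge is
"dynamic" when the SD of its windowed correlation exceeds a null built
from phase-randomized surrogates that share one random phase vector across
nodes (preserving all auto- and cross-spectra); a node's *degree* counts
its dynamic edges after BH-FDR.

## Worked example

Generate a small synthetic cohort in which nodes 0–4 switch community
midway through the scan, run the pipeline, and look at the recovered
flexibility:

```python
import numpy as np
from netreconfig import (SyntheticConfig, WindowSpec, generate_bold,
                         windowed_correlation, prepare_layers, best_of_runs,
                         flexibility)

cfg = SyntheticConfig(
    n_subjects=20, n_nodes=20, n_volumes=300, tr_seconds=2.025,
    n_communities=2, switch_schedule=[(i, 150, 1) for i in range(5)], seed=3,
)
spec = WindowSpec(length_samples=20, scheme="nonoverlapping")

flex = []
for s in range(20):
    series, truth = generate_bold(cfg, subject_seed=s)
    stack = windowed_correlation(series, spec)          # 15 layers
    part = best_of_runs(prepare_layers(stack), n_runs=10, seed=s)
    flex.append(flexibility(part).values)

flex = np.array(flex)
print("switching nodes:", flex[:, :5].mean().round(4))
print("static nodes:   ", flex[:, 5:].mean().round(4))
```

Output:

```
switching nodes: 0.0636
static nodes:    0.0129
```

The five nodes with a planted community switch are about five times as
flexible as the rest — the pipeline recovers the planted reconfiguration.
The same cohort pushed through the surrogate test yields an edge-wise
type-I rate of ~0.002 at FDR .05 when no dynamics are planted.

The shell interface wraps the same functions:

```bash
netreconfig simulate --out cohort --n-subjects 5 --n-nodes 20 --n-volumes 300 --seed 7
netreconfig run cohort --out results --mode replication --seed 1
netreconfig sweep cohort --parameter window_length --values 20,30,40 --out sweep.json
```

`--mode replication` expands to the lenient 26-parameter denoising,
decimation by 3 to a virtual TR, and 20-sample nonoverlapping windows;
`--mode native` to 36-parameter denoising, full resolution and 148-sample
step-1 windows.

## Layout

```
src/netreconfig/
  synthetic.py    # cohort generator with planted ground truth
  preprocess.py   # FD/QC, confound models, band-pass + regression, decimation
  tvfc.py         # windowing, tapered correlation, surrogates, degree
  multilayer.py   # multilayer modularity, generalized Louvain, metrics
  stats.py        # aggregation, partial Spearman, FDR, alpha, power
  pipeline.py     # orchestration, manifests, fixtures, sweeps
  cli.py          # `netreconfig` command
docs/methods.md   # model details, parameter choices, limitations
```
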