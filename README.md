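# spikemotifs

Tools for studying why recurrent spiking networks either sustain
asynchronous, irregular, near-critical activity or let it die — and how the
answer lives in higher-order structure: the cycling of weighted directed
triplet motifs (middleman, fan-in, fan-out) through the network's
*recruitment graphs*.

The package is aimed at computational neuroscientists who want a desk-scale,
fully reproducible version of this analysis chain:

1. **Build** clustered (or Erdős–Rényi) synaptic networks: 4000 excitatory +
   1000 inhibitory units, 50 overlapping clusters with intra/inter wiring
   2:1, log-normal conductances (mean 1.13 nS), inhibitory-origin weights
   10×.
2. **Simulate** them as conductance-based AdEx units
   (C dV/dt = −g_l(V−E_l) + g_l Δ_T e^{(V−V_T)/Δ_T} − g_e(V−E_e) −
   g_i(V−E_i) − g_p(V−E_e) − w) from uniform random initial voltages under a
   30 ms / 20 Hz Poisson kick; a run is *sustained* if spiking reaches 1 s
   and *truncated* if the network falls silent for 100 ms earlier.
3. **Score** runs: rate, windowed branching parameter σ (criticality),
   synchrony heuristic, Van Rossum distance, ISI-CV, rate stationarity.
4. **Infer graphs**: confluent mutual-information functional graphs, per-bin
   active subgraphs, and recruitment graphs (functional ∩ active synaptic).
5. **Quantify motifs**: weighted directed triplet clustering
   (C_i = t_i/T_i with A = W^{1/3}), clustering propensity against
   weight-resampled surrogates, motif-space trajectories.
6. **Model dominance cycling**: per-unit motif voting, a 3-state Markov
   chain of dominant motifs, hitting times, overlap index, chi-square
   comparisons between sustained and truncated run populations.

## Worked example

```python
import numpy as np
from spikemotifs.pipeline import run_desk_campaign, compare_outcomes

campaign = run_desk_campaign(n_runs=22, master_seed=1, p_ei=0.208,
                             n_surrogates=5)
report = compare_outcomes(campaign)
print(report["n_sustained"], report["n_truncated"])
print(np.round(report["trajectory_variance_sustained"], 3))
print(np.round(report["trajectory_variance_truncated"], 3))
print(report["state_p"])
```

prints (master seed 1):

```
12 10
[0.042 0.041 0.043]
[1.067 0.945 1.081]
0.0005793822361117382
```

That is the package's headline contrast in miniature: 22 simulations on one
network with identical stimulus, differing only in initial membrane
voltages, split 12 sustained / 10 truncated.  Sustained runs trace a
low-variance closed orbit in (middleman, fan-in, fan-out) propensity space —
per-axis variance ≈0.04 versus ≈1.0 for truncated runs — their recruitment
propensities sit well above 1 (≈1.5, i.e. weights are organised into
triplets far beyond edge-matched chance), and the distribution of dominant
motifs differs significantly between outcome classes (two-sample chi-square,
p ≈ 6·10⁻⁴).

Single stages are available as plain functions (`build_clustered_network`,
`simulate_run`, `van_rossum_score`, `weighted_clustering`,
`estimate_markov`, ...) and through a thin CLI
(`spikemotifs build|simulate|score|infer|gridsearch|pipeline|fixtures`).

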