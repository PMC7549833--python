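"""End-to-end orchestration: tuned reference condition, desk campaigns, and
the sustained-vs-truncated comparison report.

``TUNED`` holds the operating point found by the two-stage grid search under
the package's default neuron parameters: the cell of the (p_ei, p_ie) grid
that sustains asynchronous activity at the lowest rate, together with the
stimulus coupling calibrated so that 30 ms of 20 Hz Poisson input onto 500
excitatory units reliably triggers spiking.  A desk campaign repeats
simulations on one tuned network with fixed stimulus and input set, varying
only the initial membrane voltages, then carries every run through scoring,
functional/recruitment inference, motif propensities, dominance voting, and
Markov summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .netbuild import TopologyConfig, SynapticNetwork, build_clustered_network
from .adex import (NeuronParams, StimulusConfig, SimulationRun,
                   choose_input_targets, make_poisson_input, init_voltages,
                   simulate_run)
from .scores import (analysis_window, firing_rate, branching_windowed,
                     ScorePanel, score_run, UndefinedScoreError)
from .graphs import (recruitment_series, density_reciprocity, bin_run,
                     RecruitmentSeries)
from .motifs import motif_trajectory, MOTIFS
from .markov import (dominance_sequence, estimate_markov, MarkovSummary,
                     chi2_compare_counts, STATE_INDEX)

# Tuned reference condition (package defaults; see docs/methods.md).
TUNED = {
    "p_ei": 0.202,
    "p_ie": 0.31,
    "input_weight_ns": 7.0,
    "params": NeuronParams(C=200.0, g_l=10.0, E_l=-60.0, V_T=-50.0,
                           delta_T=2.5, V_t=-40.0, tau_w=144.0,
                           a=1.0, b=1.0, t_ref=5.0, tau_e=5.0, tau_i=2.5,
                           tau_p=5.0, E_i=-80.0, E_e=0.0),
}


def tuned_network(seed: int = 0, **overrides) -> SynapticNetwork:
    cfg = TopologyConfig(p_ei=TUNED["p_ei"], p_ie=TUNED["p_ie"], seed=seed,
                         **overrides)
    return build_clustered_network(cfg)


@dataclass
class AnalyzedRun:
    """One simulation with its full analysis chain."""

    run: SimulationRun
    panel: Optional[ScorePanel]
    series: Optional[RecruitmentSeries]
    trajectory: Optional[dict]
    sequence: list[str]
    markov: Optional[MarkovSummary]
    functional_density: float = float("nan")
    functional_reciprocity: float = float("nan")
    recruitment_density: float = float("nan")
    recruitment_reciprocity: float = float("nan")


@dataclass
class Campaign:
    network: SynapticNetwork
    stimulus: object
    params: NeuronParams
    runs: list[AnalyzedRun] = field(default_factory=list)

    @property
    def sustained(self) -> list[AnalyzedRun]:
        return [r for r in self.runs if r.run.sustained]

    @property
    def truncated(self) -> list[AnalyzedRun]:
        return [r for r in self.runs if not r.run.sustained]


def analyze_run(run: SimulationRun, network: SynapticNetwork,
                n_surrogates: int = 10, seed: int = 0,
                compute_van_rossum: bool = False) -> AnalyzedRun:
    """Score a run and carry it through graph inference, motif propensity
    trajectories, dominance voting, and the Markov summary."""
    panel = None
    try:
        panel = score_run(run, compute_van_rossum=compute_van_rossum,
                          seed=seed)
    except UndefinedScoreError:
        pass
    series = None
    trajectory = None
    sequence: list[str] = []
    markov = None
    fd = fr = rd = rr = float("nan")
    if len(run.times):
        series = recruitment_series(run, network.weights)
        func = series.functional
        try:
            fd, fr = density_reciprocity(func)
        except ValueError:
            pass
        if series.graphs:
            dens, recs = [], []
            for g in series.graphs:
                if g.shape[0] >= 2 and (g > 0).sum() > 0:
                    try:
                        d, r = density_reciprocity(g)
                        dens.append(d)
                        recs.append(r)
                    except ValueError:
                        continue
            rd = float(np.mean(dens)) if dens else float("nan")
            rr = float(np.mean(recs)) if recs else float("nan")
            trajectory = motif_trajectory(series, n_surrogates=n_surrogates,
                                          seed=seed,
                                          collect_unit_tables=True)
            sequence, _ = dominance_sequence(trajectory["unit_tables"])
            if len(sequence) >= 3:
                markov = estimate_markov(sequence)
    return AnalyzedRun(run=run, panel=panel, series=series,
                       trajectory=trajectory, sequence=sequence,
                       markov=markov, functional_density=fd,
                       functional_reciprocity=fr, recruitment_density=rd,
                       recruitment_reciprocity=rr)


def run_desk_campaign(
    n_runs: int = 24,
    master_seed: int = 0,
    network_seed: Optional[int] = None,
    analyze: bool = True,
    n_surrogates: int = 5,
    max_duration_ms: float = 1000.0,
    params: Optional[NeuronParams] = None,
    p_ei: Optional[float] = None,
    p_ie: Optional[float] = None,
    input_weight_ns: Optional[float] = None,
) -> Campaign:
    """Run the tuned desk-scale campaign: one network, fixed stimulus and
    input set, initial voltages varying run to run."""
    ss = np.random.SeedSequence(master_seed)
    s_net, s_targets, s_stim, s_runs = ss.spawn(4)
    net_seed = (network_seed if network_seed is not None
                else int(s_net.generate_state(1)[0] % 2**31))
    cfg = TopologyConfig(p_ei=p_ei if p_ei is not None else TUNED["p_ei"],
                         p_ie=p_ie if p_ie is not None else TUNED["p_ie"],
                         seed=net_seed)
    network = build_clustered_network(cfg)
    params = params or TUNED["params"]
    iw = (input_weight_ns if input_weight_ns is not None
          else TUNED["input_weight_ns"])
    targets = choose_input_targets(network, 500,
                                   np.random.default_rng(s_targets))
    stim = make_poisson_input(
        StimulusConfig(input_weight_ns=iw,
                       seed=int(s_stim.generate_state(1)[0] % 2**31)),
        targets)
    campaign = Campaign(network=network, stimulus=stim, params=params)
    children = s_runs.spawn(n_runs)
    for k in range(n_runs):
        v0 = init_voltages(network.n_units,
                           np.random.default_rng(children[k]))
        run = simulate_run(network, params, stim, v0,
                           max_duration_ms=max_duration_ms)
        if analyze:
            campaign.runs.append(
                analyze_run(run, network, n_surrogates=n_surrogates,
                            seed=master_seed + k))
        else:
            campaign.runs.append(AnalyzedRun(run=run, panel=None,
                                             series=None, trajectory=None,
                                             sequence=[], markov=None))
    return campaign


def state_counts(runs: list[AnalyzedRun]) -> np.ndarray:
    """Occurrences of each dominant motif pooled over runs."""
    counts = np.zeros(len(MOTIFS))
    for r in runs:
        for s in r.sequence:
            counts[STATE_INDEX[s]] += 1
    return counts


def transition_matrix_variability(runs: list[AnalyzedRun]) -> float:
    """Frobenius norm of the elementwise std of per-run transition
    matrices (NaN rows ignored)."""
    mats = [r.markov.P for r in runs if r.markov is not None]
    if len(mats) < 2:
        return float("nan")
    stack = np.stack(mats)
    std = np.sqrt(np.nanmean(
        (stack - np.nanmean(stack, axis=0)) ** 2, axis=0))
    return float(np.linalg.norm(np.nan_to_num(std)))


def trajectory_variance(runs: list[AnalyzedRun]) -> np.ndarray:
    """Mean per-axis variance of the motif-space trajectory across runs."""
    out = []
    for r in runs:
        if r.trajectory is None:
            continue
        axes = [np.asarray(r.trajectory[m], dtype=float) for m in MOTIFS]
        var = [np.nanvar(a[np.isfinite(a)]) if np.isfinite(a).sum() > 1
               else np.nan for a in axes]
        out.append(var)
    if not out:
        return np.full(len(MOTIFS), np.nan)
    return np.nanmean(np.asarray(out), axis=0)


def compare_outcomes(campaign: Campaign) -> dict:
    """Sustained-vs-truncated comparison report."""
    sus, tru = campaign.sustained, campaign.truncated
    report: dict = {
        "n_sustained": len(sus),
        "n_truncated": len(tru),
        "truncation_times_ms": [r.run.truncation_time_ms for r in tru],
    }
    c_s, c_t = state_counts(sus), state_counts(tru)
    if c_s.sum() > 0 and c_t.sum() > 0:
        stat, p = chi2_compare_counts(c_s, c_t)
        report["state_chi2"] = stat
        report["state_p"] = p
        report["state_probs_sustained"] = (c_s / c_s.sum()).tolist()
        report["state_probs_truncated"] = (c_t / c_t.sum()).tolist()
    report["transition_variability_sustained"] = \
        transition_matrix_variability(sus)
    report["transition_variability_truncated"] = \
        transition_matrix_variability(tru)
    report["trajectory_variance_sustained"] = \
        trajectory_variance(sus).tolist()
    report["trajectory_variance_truncated"] = \
        trajectory_variance(tru).tolist()
    rates = [r.panel.rate_e for r in sus if r.panel]
    brs = [r.panel.branching_windowed for r in sus
           if r.panel and np.isfinite(r.panel.branching_windowed)]
    report["mean_rate_sustained"] = float(np.mean(rates)) if rates else None
    report["mean_branching_sustained"] = (float(np.mean(brs))
                                          if brs else None)
    return report
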