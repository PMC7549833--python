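"""Dynamics scores: rate, branching (criticality), synchrony, Van Rossum
distance, ISI irregularity, and rate stationarity.

All scores are evaluated on an analysis window that excludes the stimulus
period (first 30 ms) and, for truncated runs, the final 50 ms before
truncation, so that they describe self-sustained rather than stimulus-driven
or dying activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .adex import SimulationRun


class UndefinedScoreError(ValueError):
    """Raised when a score has no defined value on the given input."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open interval [start, end) in ms over which scores are computed."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise UndefinedScoreError(
                f"empty analysis window [{self.start_ms}, {self.end_ms})")

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


def analysis_window(run: SimulationRun, post_stimulus_ms: float = 30.0,
                    pre_truncation_ms: float = 50.0) -> AnalysisWindow:
    """The 'middle portion' of a run: 30 ms after start to 50 ms before
    truncation (or to the full duration for sustained runs)."""
    end = (run.max_duration_ms if run.sustained
           else run.truncation_time_ms - pre_truncation_ms)
    return AnalysisWindow(post_stimulus_ms, end)


@dataclass
class ScorePanel:
    rate_e: float
    rate_i: float
    branching_windowed: float
    synchrony_heuristic: Optional[float]
    van_rossum: Optional[float]
    isi_cv_mean: Optional[float]
    stationarity_l2: Optional[float]


def _window_spikes(units: np.ndarray, times: np.ndarray,
                   window: AnalysisWindow) -> tuple[np.ndarray, np.ndarray]:
    keep = (times >= window.start_ms) & (times < window.end_ms)
    return units[keep], times[keep]


def firing_rate(units: np.ndarray, times: np.ndarray, window: AnalysisWindow,
                population: np.ndarray) -> float:
    """Mean firing rate (spikes/s) of the given population over the window."""
    if len(population) == 0:
        raise UndefinedScoreError("empty population")
    u, _ = _window_spikes(units, times, window)
    counts = np.isin(u, population).sum()
    return counts / len(population) / (window.length_ms / 1000.0)


def population_counts(times: np.ndarray, window: AnalysisWindow,
                      bin_ms: float) -> np.ndarray:
    """Population spike counts in consecutive ``bin_ms`` bins of the window."""
    n_bins = int(np.floor(window.length_ms / bin_ms))
    if n_bins < 1:
        raise UndefinedScoreError("window shorter than one bin")
    t = times[(times >= window.start_ms)
              & (times < window.start_ms + n_bins * bin_ms)]
    idx = ((t - window.start_ms) / bin_ms).astype(np.int64)
    return np.bincount(idx, minlength=n_bins)


def branching_windowed(units: np.ndarray, times: np.ndarray,
                       window: AnalysisWindow, bin_ms: float = 5.0,
                       descendant_span_bins: int = 3) -> float:
    """Windowed branching parameter.

    Spikes in bin t are ancestors; spikes from t+1 through
    t+``descendant_span_bins`` bins (5 to 20 ms after, at the default 5-ms
    bin) are descendants.  Each step's descendant count is divided by the
    ancestor count and by ``descendant_span_bins`` so that steady activity
    scores exactly 1; steps with no ancestors are skipped.
    """
    counts = population_counts(times, window, bin_ms)
    n = len(counts)
    if n < descendant_span_bins + 1:
        raise UndefinedScoreError("window too short for branching")
    ratios = []
    for t in range(n - descendant_span_bins):
        n_a = counts[t]
        if n_a == 0:
            continue
        n_d = counts[t + 1: t + 1 + descendant_span_bins].sum()
        ratios.append(n_d / n_a / descendant_span_bins)
    if not ratios:
        raise UndefinedScoreError("no ancestor steps in window")
    return float(np.mean(ratios))


def branching_avalanche(units: np.ndarray, times: np.ndarray,
                        window: AnalysisWindow, bin_ms: float = 5.0,
                        n_max: Optional[int] = None) -> float:
    """Avalanche branching parameter sigma = sum_d d * p(d).

    The binned population activity is split into avalanches (maximal runs of
    non-empty bins bounded by empty bins).  Within each avalanche every
    consecutive bin pair is an ancestor->descendant event; d is the number of
    descendants per ancestor (rounded to the nearest integer), and p(d) is
    estimated over events weighted by their ancestor counts with the
    refractoriness correction (n_max - 1) / (n_max - n_a).
    """
    counts = population_counts(times, window, bin_ms)
    if n_max is None:
        n_max = max(int(counts.max()), 2)
    # avalanche boundaries: runs of counts > 0
    active = counts > 0
    if not active.any():
        raise UndefinedScoreError("no avalanches in window")
    d_weights: dict[int, float] = {}
    total = 0.0
    i = 0
    n = len(counts)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j]:
            j += 1
        for t in range(i, j - 1):
            n_a = int(counts[t])
            n_d = int(counts[t + 1])
            if n_a <= 0:
                continue
            d = int(round(n_d / n_a))
            corr = (n_max - 1) / max(n_max - n_a, 1)
            wgt = n_a * corr
            d_weights[d] = d_weights.get(d, 0.0) + wgt
            total += wgt
        if j - i == 1:
            # single-bin avalanche: ancestors with zero descendants
            n_a = int(counts[i])
            corr = (n_max - 1) / max(n_max - n_a, 1)
            d_weights[0] = d_weights.get(0, 0.0) + n_a * corr
            total += n_a * corr
        i = j
    if total == 0:
        raise UndefinedScoreError("no ancestor events in window")
    return float(sum(d * wgt for d, wgt in d_weights.items()) / total)


def synchrony_heuristic(voltage_traces: np.ndarray) -> float:
    """Variance of the population-mean voltage divided by the mean of the
    per-unit voltage variances.  Near 1/n for independent units, 1 for
    perfectly synchronized ones; a run is asynchronous below 0.5.

    ``voltage_traces`` is (n_units, n_samples).
    """
    V = np.asarray(voltage_traces, dtype=np.float64)
    if V.ndim != 2 or V.shape[0] < 2 or V.shape[1] < 2:
        raise UndefinedScoreError("need >= 2 units and >= 2 samples")
    per_unit_var = V.var(axis=1)
    denom = per_unit_var.mean()
    if denom == 0:
        raise UndefinedScoreError("zero per-unit voltage variance")
    return float(V.mean(axis=0).var() / denom)


def _vr_inner(t1: np.ndarray, t2: np.ndarray, tau: float) -> float:
    """<f, g> for causal exponential kernels: (tau/2) * sum exp(-|ti-sj|/tau)."""
    if len(t1) == 0 or len(t2) == 0:
        return 0.0
    d = np.abs(t1[:, None] - t2[None, :])
    return 0.5 * tau * float(np.exp(-d / tau).sum())


def van_rossum_distance(t1: np.ndarray, t2: np.ndarray,
                        tau: float = 10.0) -> float:
    """Van Rossum distance between two spike trains (times in ms).

    Each train is convolved with the causal kernel exp(-t/tau); the distance
    is the L2 norm of the trace difference, computed in closed form from the
    kernel inner products.
    """
    d2 = (_vr_inner(t1, t1, tau) + _vr_inner(t2, t2, tau)
          - 2.0 * _vr_inner(t1, t2, tau))
    return float(np.sqrt(max(d2, 0.0)))


def van_rossum_score(units: np.ndarray, times: np.ndarray,
                     window: AnalysisWindow, population: np.ndarray,
                     tau: float = 10.0, n_pairs: int = 20000,
                     seed: int = 0) -> float:
    """Network asynchrony score: mean pairwise Van Rossum distance over
    sampled unit pairs, normalized for run duration by sqrt(1000 / T_ms).

    Higher values indicate greater asynchrony; independent Poisson trains at
    ~8 spikes/s over 1 s score approximately 9.
    """
    u, t = _window_spikes(units, times, window)
    trains = {p: t[u == p] for p in population}
    rng = np.random.default_rng(seed)
    n = len(population)
    if n < 2:
        raise UndefinedScoreError("need >= 2 units")
    n_possible = n * (n - 1) // 2
    if n_pairs >= n_possible:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        a = rng.integers(0, n, size=int(n_pairs * 1.3))
        b = rng.integers(0, n, size=int(n_pairs * 1.3))
        keep = a != b
        pairs = list(zip(a[keep][:n_pairs], b[keep][:n_pairs]))
    dists = [van_rossum_distance(trains[population[i]],
                                 trains[population[j]], tau)
             for i, j in pairs]
    duration_factor = np.sqrt(1000.0 / window.length_ms)
    return float(np.mean(dists) * duration_factor)


def isi_cv(units: np.ndarray, times: np.ndarray,
           population: Optional[np.ndarray] = None,
           min_spikes: int = 3) -> tuple[dict[int, float], float]:
    """Coefficient of variation of inter-spike intervals per unit.

    Units with fewer than ``min_spikes`` spikes are excluded.  Returns the
    per-unit CVs and their mean; CV > 1 marks the irregular regime.
    """
    if population is None:
        population = np.unique(units)
    pop_set = set(int(p) for p in population)
    cvs: dict[int, float] = {}
    order = np.lexsort((times, units))
    u_sorted, t_sorted = units[order], times[order]
    bounds = np.flatnonzero(np.diff(u_sorted)) + 1
    for chunk_u, chunk_t in zip(np.split(u_sorted, bounds),
                                np.split(t_sorted, bounds)):
        p = int(chunk_u[0])
        if p not in pop_set or len(chunk_t) < min_spikes:
            continue
        isi = np.diff(chunk_t)
        m = isi.mean()
        if m == 0:
            continue
        cvs[p] = float(isi.std() / m)
    mean = float(np.mean(list(cvs.values()))) if cvs else float("nan")
    return cvs, mean


def stationarity_l2(units: np.ndarray, times: np.ndarray,
                    window: AnalysisWindow, bin_ms: float = 10.0,
                    max_lag_bins: int = 20) -> float:
    """L2 error between the variance-normalized autocovariance and the
    autocorrelation of the binned population rate.

    The autocovariance is normalized by the whole-window mean and variance;
    the autocorrelation is the per-lag Pearson correlation of the lagged
    segments (each with its own mean and variance).  For a stationary rate
    the two estimators agree and the error is near 0; a drifting rate
    inflates the global-mean autocovariance relative to the local-mean
    correlation and the error grows.
    """
    counts = population_counts(times, window, bin_ms).astype(np.float64)
    n = len(counts)
    if n <= max_lag_bins:
        raise UndefinedScoreError("window too short for requested lags")
    var = counts.var()
    if var == 0:
        raise UndefinedScoreError("zero-variance rate signal")
    mean = counts.mean()
    lags = np.arange(max_lag_bins + 1)
    acov = np.empty(len(lags))
    acorr = np.empty(len(lags))
    for k in lags:
        x, y = counts[: n - k], counts[k:] if k else counts
        acov[k] = ((x - mean) * (y - mean)).mean() / var
        sx, sy = x.std(), y.std()
        if sx > 0 and sy > 0:
            acorr[k] = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
        else:
            acorr[k] = 1.0
    return float(np.linalg.norm(acov - acorr))


def score_run(run: SimulationRun, tau: float = 10.0,
              van_rossum_pairs: int = 2000, seed: int = 0,
              compute_van_rossum: bool = True) -> ScorePanel:
    """Full score panel for a simulation run over its analysis window."""
    win = analysis_window(run)
    ne = run.n_excitatory
    exc = np.arange(ne)
    inh = np.arange(ne, run.n_units)
    rate_e = firing_rate(run.units, run.times, win, exc)
    rate_i = firing_rate(run.units, run.times, win, inh) if len(inh) else 0.0
    try:
        sigma = branching_windowed(run.units, run.times, win)
    except UndefinedScoreError:
        sigma = float("nan")
    sync = None
    if "voltage_traces" in run.seeds:
        vt = run.seeds["voltage_traces"]
        ts = run.seeds["voltage_times_ms"]
        keep = (ts >= win.start_ms) & (ts < win.end_ms)
        try:
            sync = synchrony_heuristic(vt[:, keep])
        except UndefinedScoreError:
            sync = None
    vr = None
    if compute_van_rossum:
        vr = van_rossum_score(run.units, run.times, win, exc, tau=tau,
                              n_pairs=van_rossum_pairs, seed=seed)
    _, cv_mean = isi_cv(run.units, run.times, exc)
    try:
        stat = stationarity_l2(run.units, run.times, win)
    except UndefinedScoreError:
        stat = None
    return ScorePanel(rate_e=rate_e, rate_i=rate_i, branching_windowed=sigma,
                      synchrony_heuristic=sync, van_rossum=vr,
                      isi_cv_mean=cv_mean, stationarity_l2=stat)
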