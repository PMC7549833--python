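"""Functional and recruitment graph inference from spike rasters.

A *functional graph* summarises one trial: edge i -> j carries the confluent
mutual information between unit i spiking in a 10-ms bin and unit j spiking
in the same or the following bin (a 0–20 ms interaction window), refined by
correlation gating, skewness-minimising re-expression, background-rate
residualisation, and z-normalisation; only positive normed residuals are
kept.

An *active subgraph* is the synaptic graph restricted to the units that
spiked in one 10-ms bin.  The *recruitment graph* of a bin is the
intersection of the functional graph with that bin's active subgraph:
synaptic edges that are both anatomically present and functionally engaged,
weighted by their functional weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .adex import SimulationRun

BIN_MS = 10.0


@dataclass
class BinnedRaster:
    """Binary unit x bin spike matrix at 10-ms resolution.

    Bins are half-open [t, t + bin_ms).  The final bin of a complete run has
    no successor bin, so confluent (t, t+1) analyses run over ``n_bins - 1``
    analysis bins — 99 for a complete 1-second run.
    """

    matrix: np.ndarray          # bool, (n_units, n_bins)
    bin_ms: float
    t_start_ms: float

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_analysis_bins(self) -> int:
        return self.n_bins - 1

    def active_units(self, bin_index: int) -> np.ndarray:
        return np.flatnonzero(self.matrix[:, bin_index])


def bin_spikes(units: np.ndarray, times: np.ndarray, n_units: int,
               t_start_ms: float = 0.0, t_end_ms: Optional[float] = None,
               bin_ms: float = BIN_MS) -> BinnedRaster:
    """Binarise a raster into half-open 10-ms bins."""
    if t_end_ms is None:
        t_end_ms = float(times.max()) + bin_ms if len(times) else bin_ms
    n_bins = int(np.floor((t_end_ms - t_start_ms) / bin_ms))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    m = np.zeros((n_units, n_bins), dtype=bool)
    keep = (times >= t_start_ms) & (times < t_start_ms + n_bins * bin_ms)
    b = ((times[keep] - t_start_ms) / bin_ms).astype(np.int64)
    m[units[keep], b] = True
    return BinnedRaster(matrix=m, bin_ms=bin_ms, t_start_ms=t_start_ms)


def bin_run(run: SimulationRun, bin_ms: float = BIN_MS) -> BinnedRaster:
    """Bin a complete trial from t = 0 to its maximum duration (all spikes of
    the trial are used for functional inference, regardless of outcome)."""
    return bin_spikes(run.units, run.times, run.n_units, 0.0,
                      run.max_duration_ms, bin_ms)


def _binary_mi_from_counts(n11, n10, n01, n00, n):
    """Plug-in MI (bits) of a 2x2 joint table, vectorized over arrays."""
    with np.errstate(divide="ignore", invalid="ignore"):
        total_bits = np.zeros_like(n11, dtype=np.float64)
        p1x = (n11 + n10) / n
        px1 = (n11 + n01) / n
        for nab, pa, pb in ((n11, p1x, px1),
                            (n10, p1x, 1 - px1),
                            (n01, 1 - p1x, px1),
                            (n00, 1 - p1x, 1 - px1)):
            pab = nab / n
            term = pab * np.log2(pab / (pa * pb))
            total_bits += np.where(nab > 0, np.nan_to_num(term), 0.0)
    return np.maximum(total_bits, 0.0)


def confluent_mi(binned: BinnedRaster, chunk: int = 1024) -> np.ndarray:
    """Confluent mutual information matrix.

    ``MI[i, j]`` is the plug-in mutual information (bits) between the
    indicator t_i (unit i spikes in bin t) and s_j (unit j spikes in bin t or
    t + 1), over the ``n_bins - 1`` valid values of t.  Directionality enters
    through the t / t+1 asymmetry of s_j.  Constant indicators give 0.
    """
    X = binned.matrix
    if X.shape[1] < 2:
        raise ValueError("need at least 2 bins")
    T = X.shape[1] - 1
    Xi = X[:, :T].astype(np.float32)                    # t_i
    Sj = (X[:, :T] | X[:, 1:T + 1]).astype(np.float32)  # s_j
    n_units = X.shape[0]
    xi_sum = Xi.sum(axis=1)
    sj_sum = Sj.sum(axis=1)
    mi = np.empty((n_units, n_units), dtype=np.float64)
    for lo in range(0, n_units, chunk):
        hi = min(lo + chunk, n_units)
        n11 = (Xi[lo:hi] @ Sj.T).astype(np.float64)
        n10 = xi_sum[lo:hi, None] - n11
        n01 = sj_sum[None, :] - n11
        n00 = T - n11 - n10 - n01
        mi[lo:hi] = _binary_mi_from_counts(n11, n10, n01, n00, T)
    np.fill_diagonal(mi, 0.0)
    return mi


def _pearson_sign(binned: BinnedRaster, chunk: int = 1024) -> np.ndarray:
    """Boolean matrix: True where the pairwise Pearson correlation between
    the source indicator t_i and the confluent target indicator s_j is
    non-negative (zero-variance indicators count as negative).

    Using the same indicators as the MI keeps the gate consistent with the
    0-20 ms interaction window: a unit that reliably follows another one bin
    later is positively correlated here even though its same-bin correlation
    is near zero.
    """
    X = binned.matrix
    T = X.shape[1] - 1
    Xi = X[:, :T].astype(np.float32)
    Sj = (X[:, :T] | X[:, 1:T + 1]).astype(np.float32)
    Zx = Xi - Xi.mean(axis=1, keepdims=True)
    Zs = Sj - Sj.mean(axis=1, keepdims=True)
    ok_x = Zx.std(axis=1) > 0
    ok_s = Zs.std(axis=1) > 0
    n_units = X.shape[0]
    nonneg = np.zeros((n_units, n_units), dtype=bool)
    for lo in range(0, n_units, chunk):
        hi = min(lo + chunk, n_units)
        cov = Zx[lo:hi] @ Zs.T
        nonneg[lo:hi] = cov >= 0
    nonneg[~ok_x, :] = False
    nonneg[:, ~ok_s] = False
    return nonneg


_BOXCOX_LAMBDAS = np.linspace(-1.0, 1.0, 21)
_EPS = 1e-12


def _transform_by_name(x: np.ndarray, name: str) -> np.ndarray:
    if name == "identity":
        return x
    if name == "sqrt":
        return np.sqrt(x)
    if name == "log":
        return np.log(x + _EPS)
    if name.startswith("boxcox("):
        lam = float(name[7:-1])
        return ((x + _EPS) ** lam - 1.0) / lam
    raise ValueError(name)


def _min_skew_transform(x: np.ndarray,
                        selection_sample: int = 20000,
                        seed: int = 0) -> tuple[np.ndarray, str]:
    """Re-express positive values to minimise |sample skewness|.

    Candidates: identity, sqrt, log(x + eps), and Box–Cox over a lambda
    grid.  The winning transform is selected on a subsample (skewness is a
    global property) and then applied to the full vector.
    """
    if len(x) > selection_sample:
        sel = np.random.default_rng(seed).choice(x, size=selection_sample,
                                                 replace=False)
    else:
        sel = x
    names = ["identity", "sqrt", "log"] + [
        f"boxcox({lam:.2f})" for lam in _BOXCOX_LAMBDAS
        if abs(lam) >= 1e-9]
    best_name, best_skew = None, np.inf
    for name in names:
        s = abs(float(stats.skew(_transform_by_name(sel, name))))
        if s < best_skew:
            best_name, best_skew = name, s
    return _transform_by_name(x, best_name), best_name


def refine_functional(mi: np.ndarray, binned: BinnedRaster) -> np.ndarray:
    """Refine a raw confluent-MI matrix into the functional graph.

    Steps: (1) zero pairs whose binned spike trains are negatively
    correlated; (2) re-express remaining positive weights with the transform
    minimising |skewness|; (3) regress the transformed weights on background
    strength (geometric mean of the two units' per-bin firing probabilities)
    and keep residuals; (4) z-normalise the residuals; (5) keep only strictly
    positive values.  Returns a dense weighted matrix with zero diagonal.
    """
    n = mi.shape[0]
    keep = _pearson_sign(binned)
    np.fill_diagonal(keep, False)
    w = np.where(keep, mi, 0.0)
    pos = w > 0
    idx = np.flatnonzero(pos.ravel())
    if len(idx) == 0:
        return np.zeros_like(mi)
    vals = w.ravel()[idx]
    tvals, _ = _min_skew_transform(vals)

    rate = binned.matrix.mean(axis=1).astype(np.float64)
    rows, cols = np.unravel_index(idx, (n, n))
    background = np.sqrt(rate[rows] * rate[cols])
    if background.std() > 0:
        A = np.column_stack([np.ones_like(background), background])
        coef, *_ = np.linalg.lstsq(A, tvals, rcond=None)
        resid = tvals - A @ coef
    else:
        resid = tvals - tvals.mean()
    sd = resid.std()
    z = resid / sd if sd > 0 else resid
    out = np.zeros(n * n)
    out[idx] = np.where(z > 0, z, 0.0)
    return out.reshape(n, n)


def functional_graph(run: SimulationRun,
                     bin_ms: float = BIN_MS) -> np.ndarray:
    """Single refined functional graph for a trial (all spikes used)."""
    binned = bin_run(run, bin_ms)
    return refine_functional(confluent_mi(binned), binned)


def active_subgraph(binned: BinnedRaster, synaptic: sp.spmatrix,
                    bin_index: int) -> tuple[np.ndarray, sp.csr_matrix]:
    """Synaptic subgraph over the units active in one bin.

    Returns (active unit ids, synaptic weight submatrix over those units).
    """
    active = binned.active_units(bin_index)
    sub = sp.csr_matrix(synaptic)[active][:, active]
    return active, sub.tocsr()


def recruitment_graph(functional: np.ndarray, synaptic_sub: sp.spmatrix,
                      active: np.ndarray) -> np.ndarray:
    """Recruitment graph of one bin, as a dense matrix over the active units.

    Edge i -> j is present iff the synaptic edge exists and the functional
    weight is positive; its weight is the functional weight.
    """
    syn = np.asarray(sp.csr_matrix(synaptic_sub).todense())
    func = functional[np.ix_(active, active)]
    return np.where((syn > 0) & (func > 0), func, 0.0)


@dataclass
class RecruitmentSeries:
    """Time-ordered per-bin recruitment graphs of one trial."""

    bins: list[int]
    active_sets: list[np.ndarray]
    graphs: list[np.ndarray]            # dense, over the bin's active set
    functional: np.ndarray
    n_units: int
    bin_ms: float = BIN_MS


def recruitment_series(run: SimulationRun, synaptic: sp.spmatrix,
                       functional: Optional[np.ndarray] = None,
                       bin_ms: float = BIN_MS) -> RecruitmentSeries:
    """Recruitment graphs for every analysis bin of a trial."""
    binned = bin_run(run, bin_ms)
    if functional is None:
        functional = refine_functional(confluent_mi(binned), binned)
    syn = sp.csr_matrix(synaptic)
    bins, actives, graphs = [], [], []
    for b in range(binned.n_analysis_bins):
        active = binned.active_units(b)
        if len(active) == 0:
            continue
        sub = syn[active][:, active]
        graphs.append(recruitment_graph(functional, sub, active))
        actives.append(active)
        bins.append(b)
    return RecruitmentSeries(bins=bins, active_sets=actives, graphs=graphs,
                             functional=functional, n_units=run.n_units,
                             bin_ms=bin_ms)


def density_reciprocity(adj) -> tuple[float, float]:
    """Density and reciprocity of a directed graph.

    Density is edges / n(n-1); reciprocity is the fraction of edges whose
    opposite edge also exists.  Reciprocity is undefined (ValueError) for an
    edgeless graph.
    """
    A = np.asarray(sp.csr_matrix(adj).todense()) > 0
    n = A.shape[0]
    if n < 2:
        raise ValueError("graph too small")
    np.fill_diagonal(A, False)
    e = int(A.sum())
    density = e / (n * (n - 1))
    if e == 0:
        raise ValueError("reciprocity undefined for edgeless graph")
    recip = int((A & A.T).sum()) / e
    return density, recip


def min_distance_to_sustained(point: tuple[float, float],
                              cloud: Sequence[tuple[float, float]]) -> float:
    """Euclidean distance from a (density, reciprocity) point to the nearest
    point of the sustained-run cloud."""
    if len(cloud) == 0:
        raise ValueError("empty sustained cloud")
    arr = np.asarray(cloud, dtype=np.float64)
    return float(np.sqrt(((arr - np.asarray(point))**2).sum(axis=1)).min())
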