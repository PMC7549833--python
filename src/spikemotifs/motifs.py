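"""Weighted directed triplet-motif clustering and clustering propensity.

For a weighted digraph W (no self-edges, non-negative weights) the per-node
clustering coefficient of each triangle motif follows the weighted directed
clustering family: weights are normalised by the graph maximum, the matrix
A = W^(1/3) (entrywise cube root) makes every closed triplet contribute the
geometric mean of its three weights, and

    middleman:  t_i = (A A' A)_ii        T_i = d_in d_out - d_bidir
    fan-in:     t_i = (A' A A)_ii        T_i = d_in (d_in - 1)
    fan-out:    t_i = (A A A')_ii        T_i = d_out (d_out - 1)
    cycle:      t_i = (A A A)_ii         T_i = d_in d_out - d_bidir

with C_i = t_i / T_i in [0, 1], undefined (NaN) when T_i = 0.

*Clustering propensity* compares a node's coefficient with its average over
surrogate graphs that keep the edge set but resample the weights from a
reference pool; propensity 1 means the particular weights are irrelevant,
values above 1 mean weight-driven clustering beyond chance.  Middleman,
fan-in, and fan-out are the three isomorphic (rotated) triangles used for
dominance analysis; the cycle is computed for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

MOTIFS = ("middleman", "fan_in", "fan_out")
ALL_MOTIFS = MOTIFS + ("cycle",)


@dataclass
class MotifClusteringTable:
    """Per-unit triplet measures for every motif on one graph."""

    t: dict[str, np.ndarray]       # weighted actual triplet measure
    T: dict[str, np.ndarray]       # possible triplet counts
    C: dict[str, np.ndarray]       # t / T, NaN where T == 0
    d_in: np.ndarray
    d_out: np.ndarray
    d_bidir: np.ndarray


def _as_dense(graph) -> np.ndarray:
    if sp.issparse(graph):
        return np.asarray(graph.todense(), dtype=np.float64)
    return np.asarray(graph, dtype=np.float64)


def weighted_clustering(graph, normalize: bool = True) -> MotifClusteringTable:
    """Weighted directed clustering coefficients of all four triplet motifs.

    ``normalize`` rescales weights by the graph maximum so C_i <= 1; the
    maximum is attained only when every possible triplet exists at maximal
    weight.
    """
    W = _as_dense(graph).copy()
    if (W < 0).any():
        raise ValueError("negative weights are not allowed")
    np.fill_diagonal(W, 0.0)
    wmax = W.max()
    if normalize and wmax > 0:
        W = W / wmax
    A = np.cbrt(W)
    B = (W > 0)
    d_in = B.sum(axis=0).astype(np.float64)
    d_out = B.sum(axis=1).astype(np.float64)
    d_bidir = (B & B.T).sum(axis=1).astype(np.float64)

    AAt = A @ A.T
    AtA = A.T @ A
    AA = A @ A
    t = {
        "middleman": np.einsum("ij,ji->i", AAt, A),
        "fan_in": np.einsum("ij,ji->i", AtA, A),
        "fan_out": (AA * A).sum(axis=1),
        "cycle": np.einsum("ij,ji->i", AA, A),
    }
    T = {
        "middleman": d_in * d_out - d_bidir,
        "fan_in": d_in * (d_in - 1),
        "fan_out": d_out * (d_out - 1),
        "cycle": d_in * d_out - d_bidir,
    }
    C = {}
    for m in ALL_MOTIFS:
        with np.errstate(divide="ignore", invalid="ignore"):
            C[m] = np.where(T[m] > 0, t[m] / np.maximum(T[m], 1e-300),
                            np.nan)
    return MotifClusteringTable(t=t, T=T, C=C, d_in=d_in, d_out=d_out,
                                d_bidir=d_bidir)


def _surrogate_mean_C(
    W: np.ndarray,
    weight_pool: np.ndarray,
    n_surrogates: int,
    rng: np.random.Generator,
    motifs: Sequence[str],
) -> dict[str, np.ndarray]:
    """Mean per-unit C over surrogates with the same edges but weights
    resampled with replacement from ``weight_pool``."""
    mask = W > 0
    rows, cols = np.nonzero(mask)
    acc = {m: np.zeros(W.shape[0]) for m in motifs}
    for _ in range(n_surrogates):
        S = np.zeros_like(W)
        S[rows, cols] = rng.choice(weight_pool, size=len(rows), replace=True)
        # raw weights: the propensity ratio is invariant to a common scale,
        # and per-graph max-normalization would bias surrogates whose
        # resampled pool misses the original maximum
        table = weighted_clustering(S, normalize=False)
        for m in motifs:
            acc[m] += np.nan_to_num(table.C[m])
    return {m: acc[m] / n_surrogates for m in motifs}


def unit_propensities(
    graph,
    weight_pool: np.ndarray,
    n_surrogates: int = 10,
    seed: int | np.random.Generator = 0,
    motifs: Sequence[str] = MOTIFS,
) -> dict[str, np.ndarray]:
    """Per-unit weighted clustering propensity for each motif.

    propensity_i = C_i(graph) / mean over surrogates of C_i; NaN where the
    original C is undefined or every surrogate coefficient is zero.
    """
    rng = np.random.default_rng(seed)
    W = _as_dense(graph)
    weight_pool = np.asarray(weight_pool, dtype=np.float64)
    if len(weight_pool) == 0 or (W > 0).sum() == 0:
        return {m: np.full(W.shape[0], np.nan) for m in motifs}
    orig = weighted_clustering(W, normalize=False)
    surr = _surrogate_mean_C(W, weight_pool, n_surrogates, rng, motifs)
    out = {}
    for m in motifs:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = orig.C[m] / surr[m]
        p[~np.isfinite(p)] = np.nan
        out[m] = p
    return out


def weighted_propensity(
    graph,
    weight_pool: np.ndarray,
    n_surrogates: int = 10,
    seed: int | np.random.Generator = 0,
    motifs: Sequence[str] = MOTIFS,
) -> dict[str, float]:
    """Network-level propensity: mean over units with nonzero, finite
    propensity, per motif.  NaN when no unit qualifies."""
    per_unit = unit_propensities(graph, weight_pool, n_surrogates, seed,
                                 motifs)
    out = {}
    for m in motifs:
        p = per_unit[m]
        ok = np.isfinite(p) & (p > 0)
        out[m] = float(p[ok].mean()) if ok.any() else float("nan")
    return out


def unweighted_propensity(
    graph,
    n_rewires: int = 0,
    seed: int = 0,
    motifs: Sequence[str] = MOTIFS,
) -> dict[str, dict[str, float]]:
    """Binary clustering compared to chance for a density-matched ER digraph.

    For each motif returns the mean binary coefficient, the analytic ER
    expectation (the closing edge of any candidate triplet exists with
    probability = density), and their ratio.  With ``n_rewires`` > 0 a
    degree-preserving rewired surrogate ensemble is also used.
    """
    A = (_as_dense(graph) > 0).astype(np.float64)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    e = A.sum()
    if e == 0:
        raise ValueError("zero-density graph")
    density = e / (n * (n - 1))
    table = weighted_clustering(A, normalize=False)
    out: dict[str, dict[str, float]] = {}
    rewired_means = None
    if n_rewires > 0:
        rng = np.random.default_rng(seed)
        rewired_means = {m: [] for m in motifs}
        for _ in range(n_rewires):
            R = _degree_preserving_rewire(A, rng)
            rt = weighted_clustering(R, normalize=False)
            for m in motifs:
                rewired_means[m].append(np.nanmean(rt.C[m]))
    for m in motifs:
        mean_c = float(np.nanmean(table.C[m]))
        entry = {"mean_C": mean_c, "er_expected": density,
                 "ratio_er": mean_c / density}
        if rewired_means is not None:
            rm = float(np.mean(rewired_means[m]))
            entry["rewired_expected"] = rm
            entry["ratio_rewired"] = mean_c / rm if rm > 0 else float("nan")
        out[m] = entry
    return out


def _degree_preserving_rewire(A: np.ndarray, rng: np.random.Generator,
                              n_swaps: Optional[int] = None) -> np.ndarray:
    """Double-edge swaps preserving in- and out-degrees."""
    R = A.copy()
    rows, cols = np.nonzero(R)
    edges = list(zip(rows.tolist(), cols.tolist()))
    if n_swaps is None:
        n_swaps = 3 * len(edges)
    for _ in range(n_swaps):
        k1, k2 = rng.integers(0, len(edges), size=2)
        (a, b), (c, d) = edges[k1], edges[k2]
        if len({a, b, c, d}) < 4:
            continue
        if R[a, d] or R[c, b]:
            continue
        R[a, b] = R[c, d] = 0
        R[a, d] = R[c, b] = 1
        edges[k1], edges[k2] = (a, d), (c, b)
    return R


def motif_trajectory(
    series,
    weight_pool: Optional[np.ndarray] = None,
    n_surrogates: int = 10,
    seed: int = 0,
    motifs: Sequence[str] = MOTIFS,
    collect_unit_tables: bool = False,
):
    """Per-bin network propensities of the three isomorphic motifs.

    ``series`` is a :class:`~spikemotifs.graphs.RecruitmentSeries`; the
    surrogate weight pool defaults to the strictly positive functional
    weights of the trial.  Returns a dict with 'bins', per-motif arrays, and
    (optionally) per-bin per-unit propensity tables over the full unit
    universe for dominance voting.  Bins whose recruitment graph has no
    qualifying unit yield NaN, not zero.
    """
    if weight_pool is None:
        weight_pool = series.functional[series.functional > 0]
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(series.graphs))
    traj = {m: np.full(len(series.graphs), np.nan) for m in motifs}
    unit_tables: list[np.ndarray] = []
    for k, (graph, active) in enumerate(zip(series.graphs,
                                            series.active_sets)):
        per_unit = unit_propensities(graph, weight_pool, n_surrogates,
                                     np.random.default_rng(child_seeds[k]),
                                     motifs)
        for m in motifs:
            p = per_unit[m]
            ok = np.isfinite(p) & (p > 0)
            if ok.any():
                traj[m][k] = p[ok].mean()
        if collect_unit_tables:
            full = np.full((series.n_units, len(motifs)), np.nan)
            for mi, m in enumerate(motifs):
                full[active, mi] = per_unit[m]
            unit_tables.append(full)
    out = {"bins": np.asarray(series.bins)}
    out.update(traj)
    if collect_unit_tables:
        out["unit_tables"] = unit_tables
    return out
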