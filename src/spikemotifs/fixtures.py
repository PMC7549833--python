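"""Synthetic fixtures: Poisson control rasters, planted-structure rasters,
Markov sequences, and small enumerable weighted digraphs.

These generators let every analysis stage be exercised and validated without
running the full network simulator: the Poisson raster is the rate-matched
independence control, the planted-cycle raster realises a *known* rotating
dominance of the three isomorphic triplet motifs on a known synaptic graph,
and the toy-graph enumeration feeds the brute-force motif oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterator, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .motifs import MOTIFS


def gen_poisson_raster(n_units: int, rate_hz: float, duration_ms: float,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Independent homogeneous Poisson spike trains.

    Returns (units, times) arrays sorted by time; times in ms.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    lam = rate_hz / 1000.0 * duration_ms
    counts = rng.poisson(lam, size=n_units)
    units = np.repeat(np.arange(n_units), counts)
    times = rng.uniform(0.0, duration_ms, size=counts.sum())
    order = np.argsort(times, kind="stable")
    return units[order], times[order]


def gen_feedforward_chain_raster(
    n_pairs: int, n_bins: int, p_spike: float = 0.1,
    p_follow: float = 0.9, bin_ms: float = 10.0, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Raster with planted feed-forward pairs: when unit 2k spikes in bin t,
    unit 2k+1 spikes in bin t+1 with probability ``p_follow``.

    Returns (units, times, planted (driver, follower) pairs).
    """
    rng = np.random.default_rng(seed)
    units, times = [], []
    pairs = []
    for k in range(n_pairs):
        drv, fol = 2 * k, 2 * k + 1
        pairs.append((drv, fol))
        drv_bins = np.flatnonzero(rng.random(n_bins) < p_spike)
        fol_bins = drv_bins[rng.random(len(drv_bins)) < p_follow] + 1
        fol_bins = fol_bins[fol_bins < n_bins]
        for u, bins in ((drv, drv_bins), (fol, fol_bins)):
            units.append(np.full(len(bins), u))
            times.append(bins * bin_ms + bin_ms / 2)
    u = np.concatenate(units)
    t = np.concatenate(times)
    order = np.argsort(t, kind="stable")
    return u[order], t[order], pairs


# ---------------------------------------------------------------------------
# Planted motif-dominance cycles
# ---------------------------------------------------------------------------

@dataclass
class PlantedCycleFixture:
    """A synaptic graph plus raster realising a known dominance sequence.

    The graph is a disjoint union of three gadgets, one per isomorphic motif.
    In the gadget for motif X, ``m`` of the ``m + 2`` units play role X in a
    closed triangle, so when the gadget's units spike in a bin the plurality
    vote of that bin is X.  The raster activates exactly one gadget per bin,
    following the planted state sequence.
    """

    synaptic: sp.csr_matrix
    units: np.ndarray
    times: np.ndarray
    n_units: int
    bin_ms: float
    true_sequence: list[str]
    gadget_units: dict[str, np.ndarray]


def _gadget_edges(kind: str, offset: int, m: int) -> list[tuple[int, int]]:
    """Edges of one motif gadget over nodes offset .. offset + m + 1.

    fan_in:    parents a, b (a->b) fan onto m children (a->h_k, b->h_k);
               the children are the m fan-in reference units.
    middleman: source i, sink h (i->h) with m relays (i->j_k, j_k->h);
               the relays are the m middleman units.
    fan_out:   m sources each hitting j and h (i_k->j, i_k->h, j->h);
               the sources are the m fan-out units.
    """
    a, b = offset, offset + 1
    others = list(range(offset + 2, offset + 2 + m))
    if kind == "fan_in":
        edges = [(a, b)]
        for h in others:
            edges += [(a, h), (b, h)]
    elif kind == "middleman":
        edges = [(a, b)]       # i -> h
        for j in others:
            edges += [(a, j), (j, b)]
    elif kind == "fan_out":
        edges = [(a, b)]       # j -> h
        for i in others:
            edges += [(i, a), (i, b)]
    else:
        raise ValueError(kind)
    return edges


def gen_planted_cycle_raster(
    sequence: Optional[Sequence[str]] = None,
    transition: Optional[np.ndarray] = None,
    n_bins: int = 30,
    m: int = 5,
    bin_ms: float = 10.0,
    weight: float = 1.0,
    seed: int = 0,
) -> PlantedCycleFixture:
    """Build a planted-dominance fixture.

    Either pass an explicit ``sequence`` of states, or a row-stochastic 3x3
    ``transition`` matrix from which a sequence of length ``n_bins`` is
    simulated (uniform initial state).
    """
    rng = np.random.default_rng(seed)
    if sequence is None:
        if transition is None:
            sequence = [MOTIFS[k % 3] for k in range(n_bins)]
        else:
            sequence = gen_markov_sequence(transition, n_bins, rng)
    sequence = list(sequence)
    if transition is not None and not np.allclose(
            np.asarray(transition).sum(axis=1), 1.0):
        raise ValueError("transition matrix must be row-stochastic")

    per_gadget = m + 2
    n_units = 3 * per_gadget
    edges: list[tuple[int, int]] = []
    gadget_units = {}
    for g, kind in enumerate(MOTIFS):
        off = g * per_gadget
        edges += _gadget_edges(kind, off, m)
        gadget_units[kind] = np.arange(off, off + per_gadget)
    rows, cols = zip(*edges)
    W = sp.csr_matrix((np.full(len(edges), weight),
                       (np.asarray(rows), np.asarray(cols))),
                      shape=(n_units, n_units))

    units, times = [], []
    for k, state in enumerate(sequence):
        active = gadget_units[state]
        units.append(active)
        times.append(np.full(len(active), k * bin_ms + bin_ms / 2))
    u = np.concatenate(units)
    t = np.concatenate(times)
    return PlantedCycleFixture(synaptic=W, units=u, times=t,
                               n_units=n_units, bin_ms=bin_ms,
                               true_sequence=sequence,
                               gadget_units=gadget_units)


def gen_markov_sequence(transition: np.ndarray, length: int,
                        seed: int | np.random.Generator = 0,
                        init: Optional[int] = None) -> list[str]:
    """Simulate a state sequence from a row-stochastic matrix over MOTIFS."""
    P = np.asarray(transition, dtype=np.float64)
    if P.shape != (3, 3) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be row-stochastic 3x3")
    rng = np.random.default_rng(seed)
    state = int(rng.integers(0, 3)) if init is None else init
    seq = []
    for _ in range(length):
        seq.append(MOTIFS[state])
        state = int(rng.choice(3, p=P[state]))
    return seq


def recover_dominance(fixture: PlantedCycleFixture,
                      n_surrogates: int = 3, seed: int = 0) -> list[str]:
    """Run a planted fixture through the real analysis chain.

    Bins the raster, builds per-bin recruitment graphs against the planted
    synaptic graph (every synaptic edge is functionally engaged), computes
    per-unit motif propensities, and returns the voted dominance sequence.
    """
    import scipy.sparse as sp

    from .graphs import (bin_spikes, recruitment_graph, RecruitmentSeries)
    from .motifs import motif_trajectory
    from .markov import dominance_sequence

    binned = bin_spikes(fixture.units, fixture.times, fixture.n_units,
                        0.0, (len(fixture.true_sequence) + 1)
                        * fixture.bin_ms, fixture.bin_ms)
    syn = sp.csr_matrix(fixture.synaptic)
    func = np.asarray(syn.todense())
    bins, actives, graphs = [], [], []
    for b in range(binned.n_analysis_bins):
        active = binned.active_units(b)
        if len(active) == 0:
            continue
        sub = syn[active][:, active]
        graphs.append(recruitment_graph(func, sub, active))
        actives.append(active)
        bins.append(b)
    series = RecruitmentSeries(bins=bins, active_sets=actives,
                               graphs=graphs, functional=func,
                               n_units=fixture.n_units,
                               bin_ms=fixture.bin_ms)
    traj = motif_trajectory(series, n_surrogates=n_surrogates, seed=seed,
                            collect_unit_tables=True)
    seq, _ = dominance_sequence(traj["unit_tables"])
    return seq


# ---------------------------------------------------------------------------
# Enumerable toy graphs for the brute-force motif oracle
# ---------------------------------------------------------------------------

def _all_edge_sets(n: int) -> Iterator[list[tuple[int, int]]]:
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for mask in range(1 << len(slots)):
        yield [slots[k] for k in range(len(slots)) if mask >> k & 1]


def gen_toy_graphs(max_nodes: int = 6, n_random_per_size: int = 60,
                   seed: int = 0) -> Iterator[np.ndarray]:
    """Weighted digraphs for oracle testing.

    All 64 labeled 3-node digraphs are enumerated exhaustively; for 4 to
    ``max_nodes`` nodes (where full enumeration is astronomically large) a
    seeded random sample of edge sets is drawn.  Hand-curated cases (single
    triangle, directed 3-cycle, in-star, out-star) are yielded first.
    Weights are uniform on (0, 1].
    """
    if max_nodes > 7:
        raise ValueError("enumeration budget capped at 7 nodes")
    rng = np.random.default_rng(seed)

    def weighted(n: int, edges: Sequence[tuple[int, int]]) -> np.ndarray:
        W = np.zeros((n, n))
        for i, j in edges:
            W[i, j] = rng.uniform(1e-6, 1.0)
        return W

    # curated cases
    yield weighted(3, [(0, 1), (0, 2), (1, 2)])                 # triangle
    yield weighted(3, [(0, 1), (1, 2), (2, 0)])                 # 3-cycle
    yield weighted(4, [(1, 0), (2, 0), (3, 0)])                 # in-star
    yield weighted(4, [(0, 1), (0, 2), (0, 3)])                 # out-star

    for edges in _all_edge_sets(3):
        yield weighted(3, edges)

    for n in range(4, max_nodes + 1):
        slots = [(i, j) for i in range(n) for j in range(n) if i != j]
        for _ in range(n_random_per_size):
            p = rng.uniform(0.15, 0.6)
            edges = [e for e in slots if rng.random() < p]
            yield weighted(n, edges)


def brute_force_motif_t(W: np.ndarray, normalize: bool = True
                        ) -> dict[str, np.ndarray]:
    """Explicit triplet enumeration oracle for the weighted motif measures.

    Walks every ordered node triple, checks the three-edge pattern of each
    motif, and accumulates the geometric mean of the (max-normalised) edge
    weights.  Independent of the matrix-product implementation.
    """
    W = np.asarray(W, dtype=np.float64).copy()
    np.fill_diagonal(W, 0.0)
    if normalize and W.max() > 0:
        W = W / W.max()
    n = W.shape[0]
    t = {m: np.zeros(n) for m in MOTIFS + ("cycle",)}

    def gm(*ws: float) -> float:
        return float(np.prod(ws) ** (1.0 / 3.0))

    for i in range(n):
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) < 3:
                    continue
                # middleman at i: j->i, i->h, j->h
                if W[j, i] and W[i, h] and W[j, h]:
                    t["middleman"][i] += gm(W[j, i], W[i, h], W[j, h])
                # fan-in at i: j->i, h->i, j->h
                if W[j, i] and W[h, i] and W[j, h]:
                    t["fan_in"][i] += gm(W[j, i], W[h, i], W[j, h])
                # fan-out at i: i->j, i->h, j->h
                if W[i, j] and W[i, h] and W[j, h]:
                    t["fan_out"][i] += gm(W[i, j], W[i, h], W[j, h])
                # cycle at i: i->j, j->h, h->i
                if W[i, j] and W[j, h] and W[h, i]:
                    t["cycle"][i] += gm(W[i, j], W[j, h], W[h, i])
    return t
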