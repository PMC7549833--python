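"""Motif-dominance voting and Markov-chain quantification of motif cycling.

Each unit casts one vote per 10-ms bin for the isomorphic motif (middleman,
fan-in, fan-out) with its highest demeaned propensity; the bin's dominant
state is the plurality vote.  The resulting state sequence is summarised by
maximum-likelihood first-order probabilities, a 3x3 transition matrix,
second-order (bigram) probabilities, conditional probabilities given the two
preceding states, and empirical hitting (recurrence) times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .motifs import MOTIFS

STATE_INDEX = {m: k for k, m in enumerate(MOTIFS)}
BIN_MS = 10.0


class UndefinedScoreError(ValueError):
    pass


def dominance_sequence(
    unit_tables: Sequence[np.ndarray],
    demean: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Dominant-motif state sequence from per-bin per-unit propensities.

    ``unit_tables[k]`` is an (n_units, 3) array of propensities for bin k,
    NaN where undefined (inactive unit or zero-degree role).  Propensities
    are demeaned per unit and motif across the trial so that motifs with
    different absolute magnitudes compete fairly.  A unit abstains when its
    maximum is tied or when it has no defined value; a bin with no votes is
    dropped.  Bin-level plurality ties carry the previous state (middleman
    for a leading tie).

    Returns the state sequence and the per-bin vote-proportion array
    (n_kept_bins, 3).
    """
    if len(unit_tables) == 0:
        return [], np.zeros((0, len(MOTIFS)))
    stack = np.stack(unit_tables)               # (n_bins, n_units, 3)
    if demean:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(stack, axis=0, keepdims=True)
        stack = stack - np.nan_to_num(means)
    seq: list[str] = []
    proportions: list[np.ndarray] = []
    prev_state_idx: Optional[int] = None
    for k in range(stack.shape[0]):
        table = stack[k]
        defined = np.isfinite(table)
        votes = np.zeros(len(MOTIFS))
        any_def = defined.any(axis=1)
        if any_def.any():
            masked = np.where(defined, table, -np.inf)
            best = masked.max(axis=1)
            is_max = masked == best[:, None]
            n_max = is_max.sum(axis=1)
            voters = any_def & (n_max == 1)
            if voters.any():
                votes = is_max[voters].sum(axis=0).astype(np.float64)
        total = votes.sum()
        if total == 0:
            continue                            # vote-less bin dropped
        top = votes.max()
        winners = np.flatnonzero(votes == top)
        if len(winners) == 1:
            idx = int(winners[0])
        elif prev_state_idx is not None and prev_state_idx in winners:
            idx = prev_state_idx
        else:
            idx = int(winners[0])               # documented priority order
        prev_state_idx = idx
        seq.append(MOTIFS[idx])
        proportions.append(votes / total)
    return seq, (np.stack(proportions) if proportions
                 else np.zeros((0, len(MOTIFS))))


@dataclass
class MarkovSummary:
    """Maximum-likelihood summary of a motif-dominance state sequence."""

    states: tuple[str, ...]
    pi: np.ndarray                      # first-order state probabilities
    P: np.ndarray                       # 3x3 transition matrix (NaN rows unseen)
    second_order: np.ndarray            # 3x3 bigram probabilities
    conditional: np.ndarray             # (3,3,3): P(next | prev2, prev1)
    hitting_time_ms: dict[str, float]   # empirical mean recurrence, ms
    hitting_time_chain_ms: dict[str, float]  # 1/pi_i * bin, from the chain
    n_observations: int

    def summary(self) -> str:
        lines = ["Markov summary of motif dominance",
                 f"  observations: {self.n_observations}"]
        lines.append("  state probabilities:")
        for s, p in zip(self.states, self.pi):
            lines.append(f"    {s:<10s} {p:.4f}")
        lines.append("  transition matrix (rows: from):")
        for s, row in zip(self.states, self.P):
            cells = " ".join(f"{x:.4f}" if np.isfinite(x) else "  --  "
                             for x in row)
            lines.append(f"    {s:<10s} {cells}")
        lines.append("  mean recurrence time (empirical, ms):")
        for s in self.states:
            h = self.hitting_time_ms.get(s, float("nan"))
            lines.append(f"    {s:<10s} {h:.2f}")
        return "\n".join(lines)


def estimate_markov(sequence: Sequence[str],
                    bin_ms: float = BIN_MS) -> MarkovSummary:
    """Fit first/second-order state statistics to a dominance sequence.

    Probabilities are maximum-likelihood count estimates; conditioning
    states never observed leave NaN rows rather than imputed values.
    """
    n = len(sequence)
    idx = np.array([STATE_INDEX[s] for s in sequence], dtype=np.int64)
    k = len(MOTIFS)
    counts = np.bincount(idx, minlength=k).astype(np.float64)
    pi = counts / counts.sum() if n else np.full(k, np.nan)

    bigram = np.zeros((k, k))
    for a, b in zip(idx[:-1], idx[1:]):
        bigram[a, b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        P = bigram / bigram.sum(axis=1, keepdims=True)
    second_order = (bigram / bigram.sum() if bigram.sum()
                    else np.full((k, k), np.nan))

    trigram = np.zeros((k, k, k))
    for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
        trigram[a, b, c] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        conditional = trigram / trigram.sum(axis=2, keepdims=True)

    hitting = {}
    hitting_chain = {}
    for s in MOTIFS:
        try:
            hitting[s] = hitting_time_expectation(sequence, s, bin_ms)
        except UndefinedScoreError:
            hitting[s] = float("nan")
        p = pi[STATE_INDEX[s]]
        hitting_chain[s] = bin_ms / p if p > 0 else float("nan")
    return MarkovSummary(states=MOTIFS, pi=pi, P=P,
                         second_order=second_order, conditional=conditional,
                         hitting_time_ms=hitting,
                         hitting_time_chain_ms=hitting_chain,
                         n_observations=n)


def hitting_time_expectation(sequence: Sequence[str], state: str,
                             bin_ms: float = BIN_MS) -> float:
    """Empirical mean recurrence time of a state, in ms.

    From every occurrence of the state, the return time is the number of
    steps until its next occurrence; the expectation of that empirical
    distribution times the bin width is E[H] = sum_n n p(H = n) * bin.
    """
    idx = np.flatnonzero(np.asarray(sequence, dtype=object) == state)
    if len(idx) < 2:
        raise UndefinedScoreError(
            f"state {state!r} occurs fewer than twice")
    returns = np.diff(idx)
    return float(returns.mean() * bin_ms)


def overlap_index(sample1, sample2, bins: int | np.ndarray = 50,
                  range_: Optional[tuple[float, float]] = None) -> float:
    """Histogram overlap of two samples: sum_i min(p_i1, p_i2) on shared
    bins.  0 for disjoint supports, 1 for identical distributions."""
    s1 = np.asarray(sample1, dtype=np.float64)
    s2 = np.asarray(sample2, dtype=np.float64)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both samples must be nonempty")
    if range_ is None:
        lo = min(s1.min(), s2.min())
        hi = max(s1.max(), s2.max())
        range_ = (lo, hi if hi > lo else lo + 1.0)
    h1, edges = np.histogram(s1, bins=bins, range=range_)
    h2, _ = np.histogram(s2, bins=edges)
    p1 = h1 / h1.sum()
    p2 = h2 / h2.sum()
    return float(np.minimum(p1, p2).sum())


def overlap_index_ci(sample1, sample2, bins: int = 50,
                     n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float, float]:
    """Overlap index with a percentile-bootstrap confidence interval."""
    rng = np.random.default_rng(seed)
    s1 = np.asarray(sample1, dtype=np.float64)
    s2 = np.asarray(sample2, dtype=np.float64)
    o = overlap_index(s1, s2, bins)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r1 = rng.choice(s1, size=len(s1), replace=True)
        r2 = rng.choice(s2, size=len(s2), replace=True)
        boots[b] = overlap_index(r1, r2, bins)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return o, float(lo), float(hi)


def _pool_small_bins(h1: np.ndarray, h2: np.ndarray,
                     min_expected: float = 5.0):
    """Merge adjacent bins until every pooled expected count is adequate."""
    h1, h2 = h1.astype(np.float64), h2.astype(np.float64)
    n1, n2 = h1.sum(), h2.sum()
    while len(h1) > 1:
        pooled = (h1 + h2) / (n1 + n2)
        exp1, exp2 = n1 * pooled, n2 * pooled
        small = np.flatnonzero(np.minimum(exp1, exp2) < min_expected)
        if len(small) == 0:
            break
        k = small[0]
        j = k - 1 if k == len(h1) - 1 else k + 1
        lo, hi = min(k, j), max(k, j)
        h1 = np.concatenate([h1[:lo], [h1[lo] + h1[hi]], h1[hi + 1:]])
        h2 = np.concatenate([h2[:lo], [h2[lo] + h2[hi]], h2[hi + 1:]])
    return h1, h2


def chi2_compare(sample1, sample2, bins: int = 20) -> tuple[float, float]:
    """Two-sample chi-square test on shared-bin histograms.

    Equal-width bins span the pooled sample range; adjacent bins are pooled
    until every expected count reaches 5.  Returns (statistic, p-value).
    """
    s1 = np.asarray(sample1, dtype=np.float64)
    s2 = np.asarray(sample2, dtype=np.float64)
    lo = min(s1.min(), s2.min())
    hi = max(s1.max(), s2.max())
    if hi <= lo:
        return 0.0, 1.0
    h1, edges = np.histogram(s1, bins=bins, range=(lo, hi))
    h2, _ = np.histogram(s2, bins=edges)
    h1, h2 = _pool_small_bins(h1, h2)
    if len(h1) < 2:
        raise UndefinedScoreError("insufficient counts after pooling")
    return chi2_compare_counts(h1, h2)


def chi2_compare_counts(counts1, counts2) -> tuple[float, float]:
    """Chi-square homogeneity test on two aligned count vectors."""
    c1 = np.asarray(counts1, dtype=np.float64)
    c2 = np.asarray(counts2, dtype=np.float64)
    keep = (c1 + c2) > 0
    c1, c2 = c1[keep], c2[keep]
    if len(c1) < 2:
        raise UndefinedScoreError("need at least two populated categories")
    table = np.vstack([c1, c2])
    if np.array_equal(c1 / c1.sum(), c2 / c2.sum()):
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
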