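"""Non-hierarchical baseline simulators: i.i.d. and first-order Markov.

Both simulators produce length-matched control sets: one control sequence
per requested length, so the control set has the identical multiset of
lengths as the source data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .sequences import ActionSequence, Ethogram, SequenceSet

__all__ = [
    "TransitionMatrix",
    "simulate_random",
    "fit_markov",
    "initial_distribution",
    "check_ergodic",
    "simulate_markov",
    "write_transition_matrix",
    "read_transition_matrix",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """First-order Markov transition probabilities over behavior codes."""

    states: tuple[int, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        n = len(self.states)
        if p.shape != (n, n):
            raise ValueError(f"transition matrix shape {p.shape} != ({n}, {n})")
        if (p < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every transition-matrix row must sum to 1")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TransitionMatrix)
            and self.states == other.states
            and np.array_equal(self.probs, other.probs)
        )


def _freq_vector(freq: Sequence[float]) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    s = f.sum()
    if s <= 0:
        raise ValueError("frequencies must have positive sum")
    if not math.isclose(s, 1.0, abs_tol=1e-9):
        raise ValueError(f"frequencies must sum to 1, got {s}")
    return f / s


def simulate_random(
    lengths: Sequence[int],
    freq: Sequence[float],
    seed: int,
    *,
    ethogram: Ethogram | None = None,
    group: str = "random",
    subject_id: str = "sim",
) -> SequenceSet:
    """One i.i.d. sequence per requested length, sampled from ``freq``.

    ``freq[i]`` is the probability of behavior code ``i + 1``.  Fully
    reproducible from ``seed``.
    """
    f = _freq_vector(freq)
    if any(n < 1 for n in lengths):
        raise ValueError("all requested lengths must be >= 1")
    if ethogram is None:
        ethogram = Ethogram(tuple(f"b{i}" for i in range(1, len(f) + 1)))
    rng = np.random.default_rng(seed)
    codes = np.arange(1, len(f) + 1)
    seqs = [
        ActionSequence(
            f"{group}_{i + 1:04d}",
            subject_id,
            group,
            tuple(int(c) for c in rng.choice(codes, size=n, p=f)),
        )
        for i, n in enumerate(lengths)
    ]
    return SequenceSet(ethogram, seqs, provenance=f"simulate_random(seed={seed})")


def fit_markov(sset: SequenceSet) -> TransitionMatrix:
    """Maximum-likelihood first-order transition matrix, pooled over sequences.

    Transitions never cross sequence boundaries.  A state observed only as
    a final action (no outgoing transitions) gets the pooled marginal
    frequency vector as its row, with a warning.
    """
    if not sset.sequences:
        raise ValueError("cannot fit a Markov model to an empty sequence set")
    n = sset.ethogram.n_behaviors
    counts = np.zeros((n, n), dtype=float)
    marginal = np.zeros(n, dtype=float)
    for seq in sset.sequences:
        a = seq.actions
        for x in a:
            marginal[x - 1] += 1
        for x, y in zip(a, a[1:]):
            counts[x - 1, y - 1] += 1
    marginal /= marginal.sum()
    probs = np.zeros_like(counts)
    row_sums = counts.sum(axis=1)
    for i in range(n):
        if row_sums[i] > 0:
            probs[i] = counts[i] / row_sums[i]
        else:
            warnings.warn(
                f"state {sset.ethogram.label_of(i + 1)!r} has no outgoing "
                "transitions; its row is set to the marginal frequencies"
            )
            probs[i] = marginal
    return TransitionMatrix(sset.ethogram.codes, probs)


def initial_distribution(sset: SequenceSet) -> np.ndarray:
    """Empirical distribution of first actions across the set."""
    if not sset.sequences:
        raise ValueError("empty sequence set")
    counts = np.zeros(sset.ethogram.n_behaviors, dtype=float)
    for seq in sset.sequences:
        counts[seq.actions[0] - 1] += 1
    return counts / counts.sum()


def check_ergodic(tm: TransitionMatrix) -> tuple[bool, bool]:
    """(irreducible, aperiodic) for the positive-transition digraph.

    Irreducible: the graph is strongly connected.  Aperiodic: every state
    lying on at least one cycle has cycle-length gcd 1 (states on no cycle
    impose no constraint).
    """
    n = len(tm.states)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if tm.probs[i, j] > 0:
                g.add_edge(i, j)
    irreducible = nx.is_strongly_connected(g)
    aperiodic = True
    for comp in nx.strongly_connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue  # trivial component without a self-loop: no cycles
        if not nx.is_aperiodic(sub):
            aperiodic = False
            break
    return irreducible, aperiodic


def simulate_markov(
    lengths: Sequence[int],
    tm: TransitionMatrix,
    initial: Sequence[float],
    seed: int,
    *,
    ethogram: Ethogram | None = None,
    group: str = "markov",
    subject_id: str = "sim",
) -> SequenceSet:
    """One Markov-chain realization per requested length.

    The first state is drawn from ``initial``; every subsequent state from
    the transition row of the current state.  Reproducible from ``seed``.
    """
    init = _freq_vector(initial)
    if len(init) != len(tm.states):
        raise ValueError("initial distribution size does not match state count")
    if any(n < 1 for n in lengths):
        raise ValueError("all requested lengths must be >= 1")
    if ethogram is None:
        ethogram = Ethogram(tuple(f"b{i}" for i in range(1, len(tm.states) + 1)))
    rng = np.random.default_rng(seed)
    nstates = len(tm.states)
    cum_rows = np.cumsum(tm.probs, axis=1)
    cum_init = np.cumsum(init)
    seqs = []
    for i, n in enumerate(lengths):
        actions = np.empty(n, dtype=int)
        u = rng.random(n)
        state = int(np.searchsorted(cum_init, u[0], side="right"))
        state = min(state, nstates - 1)
        actions[0] = state + 1
        for t in range(1, n):
            state = int(np.searchsorted(cum_rows[state], u[t], side="right"))
            state = min(state, nstates - 1)
            actions[t] = state + 1
        seqs.append(
            ActionSequence(
                f"{group}_{i + 1:04d}", subject_id, group,
                tuple(int(a) for a in actions),
            )
        )
    return SequenceSet(ethogram, seqs, provenance=f"simulate_markov(seed={seed})")


def write_transition_matrix(
    tm: TransitionMatrix, path: str | Path, ethogram: Ethogram | None = None
) -> None:
    labels = (
        [ethogram.label_of(c) for c in tm.states] if ethogram else list(tm.states)
    )
    pd.DataFrame(tm.probs, index=labels, columns=labels).to_csv(path)


def read_transition_matrix(path: str | Path) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0)
    return TransitionMatrix(
        tuple(range(1, len(df) + 1)), df.to_numpy(dtype=float)
    )
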