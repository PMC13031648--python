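"""Seeded generators of sequences with known structure.

Three kinds of synthetic data make every pipeline stage testable without
external downloads: pure i.i.d. sequences, first-order Markov sequences,
and sequences with planted nested motifs (grammar-generated structure).
A motif is a nested tuple template whose leaves are behavior codes; each
instance is planted at least twice per sequence so that bigram chunking
(k = 2) is guaranteed a repeated pattern to compress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .controls import fit_markov, initial_distribution, simulate_markov, simulate_random
from .sequences import ActionSequence, Ethogram, SequenceSet, behavior_frequencies

__all__ = [
    "Motif",
    "PlantedGrammarSpec",
    "doubling_motif",
    "expand_motif",
    "generate_planted",
    "generate_suite",
]

#: a motif template: a behavior code, or a nested tuple of motifs
Motif = "int | tuple"


def expand_motif(motif) -> tuple[int, ...]:
    """Flatten a nested motif template to its terminal string."""
    if isinstance(motif, int):
        return (motif,)
    out: tuple[int, ...] = ()
    for part in motif:
        out += expand_motif(part)
    return out


def doubling_motif(base: Sequence[int], depth: int) -> tuple:
    """A motif whose planted repetition induces ``depth`` levels of nesting.

    Depth 1 is the plain base pair; each further level duplicates the
    previous template, so two planted copies of the expansion present the
    compressor with a fully recursive doubling structure.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    motif: tuple = tuple(base)
    for _ in range(depth - 1):
        motif = (motif, motif)
    return motif


@dataclass(frozen=True)
class PlantedGrammarSpec:
    """Recipe for sequences carrying planted hierarchical structure."""

    lengths: tuple[int, ...]
    motifs: tuple = (doubling_motif((1, 2), 1),)
    insertion_rate: float = 1.0
    background: tuple[float, ...] = ()
    alphabet_size: int = 7
    copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.insertion_rate <= 1:
            raise ValueError("insertion_rate must lie in [0, 1]")
        if self.copies < 2:
            raise ValueError("motifs must be planted at least twice")
        for m in self.motifs:
            exp = expand_motif(m)
            if len(exp) < 2:
                raise ValueError(f"motif {m!r} expands to fewer than 2 actions")
            if any(not 1 <= a <= self.alphabet_size for a in exp):
                raise ValueError(f"motif {m!r} uses codes outside the alphabet")

    @property
    def background_freq(self) -> np.ndarray:
        if self.background:
            f = np.asarray(self.background, dtype=float)
        else:
            f = np.ones(self.alphabet_size)
        return f / f.sum()


def generate_planted(spec: PlantedGrammarSpec) -> SequenceSet:
    """Sequences interleaving planted motif copies with i.i.d. background.

    For each requested length a motif is (with probability
    ``insertion_rate``) chosen among those fitting ``copies`` times, and
    its copies are placed at seeded positions with background actions
    filling the gaps.  Raises if a sequence is too short for any motif.
    """
    rng = np.random.default_rng(spec.seed)
    ethogram = Ethogram(tuple(f"b{i}" for i in range(1, spec.alphabet_size + 1)))
    codes = np.arange(1, spec.alphabet_size + 1)
    freq = spec.background_freq
    seqs = []
    for i, length in enumerate(spec.lengths):
        if length < 1:
            raise ValueError("sequence lengths must be >= 1")
        plant = rng.random() < spec.insertion_rate
        actions: list[int] = []
        if plant:
            fitting = [
                m for m in spec.motifs
                if spec.copies * len(expand_motif(m)) <= length
            ]
            if not fitting:
                shortest = min(len(expand_motif(m)) for m in spec.motifs)
                raise ValueError(
                    f"sequence of length {length} cannot hold {spec.copies} "
                    f"copies of any motif (shortest expands to {shortest})"
                )
            motif = fitting[rng.integers(len(fitting))]
            exp = list(expand_motif(motif))
            n_background = length - spec.copies * len(exp)
            # split background into copies+1 gaps around the motif copies
            cuts = np.sort(rng.integers(0, n_background + 1, spec.copies))
            gaps = np.diff(np.concatenate(([0], cuts, [n_background])))
            for g in gaps[:-1]:
                actions.extend(int(c) for c in rng.choice(codes, size=g, p=freq))
                actions.extend(exp)
            actions.extend(
                int(c) for c in rng.choice(codes, size=gaps[-1], p=freq)
            )
        else:
            actions.extend(int(c) for c in rng.choice(codes, size=length, p=freq))
        assert len(actions) == length
        seqs.append(
            ActionSequence(f"planted_{i + 1:04d}", "sim", "planted",
                           tuple(actions))
        )
    return SequenceSet(ethogram, seqs, provenance=f"generate_planted(seed={spec.seed})")


def generate_suite(
    seed: int, n_sequences: int = 140, alphabet_size: int = 7
) -> tuple[SequenceSet, SequenceSet, SequenceSet]:
    """Three length-matched sets: planted, markov, iid.

    Lengths are drawn once and shared.  The Markov set is simulated from a
    first-order model fitted to the planted set, and the i.i.d. set from
    the planted set's pooled behavior frequencies — mirroring a
    length-matched three-way control design.
    """
    rng = np.random.default_rng(seed)
    lengths = tuple(int(x) for x in rng.integers(8, 101, size=n_sequences))
    motifs = (
        doubling_motif((1, 2), 1),
        doubling_motif((3, 4), 2),
        doubling_motif((5, 6), 3),
        doubling_motif((2, 7), 2),
    )
    spec = PlantedGrammarSpec(
        lengths=lengths,
        motifs=motifs,
        insertion_rate=0.9,
        alphabet_size=alphabet_size,
        seed=int(rng.integers(2**31)),
    )
    planted = generate_planted(spec)
    tm = fit_markov(planted)
    init = initial_distribution(planted)
    markov = simulate_markov(
        lengths, tm, init, int(rng.integers(2**31)), ethogram=planted.ethogram
    )
    iid = simulate_random(
        lengths, behavior_frequencies(planted), int(rng.integers(2**31)),
        ethogram=planted.ethogram,
    )
    return planted, markov, iid
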