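"""Binary tree encoding of grammar rules and hierarchical-complexity metrics.

Each rule is rendered as a 0/1 string by a recursive preorder walk of its
right-hand side: a terminal emits ``1``, an embedded rule emits ``0``
followed by the encoding of that rule's own right-hand side.  The rule's
root contributes no bit, so a rule embedding no other rule encodes as all
ones and scores zero on every structural measure.

Six measures are computed: nesting depth D, chunk count C, phrase length
PL, structural entropy H, Gini coefficient G of non-terminal positions,
and the terminal:non-terminal ratio R (count of 0s over count of 1s, as
defined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .sequitur import Grammar, RuleRef, Symbol

__all__ = [
    "RuleTreeEncoding",
    "RuleMetrics",
    "SequenceMetrics",
    "encode_rule",
    "nesting_depth",
    "chunks",
    "phrase_length",
    "structural_entropy",
    "gini",
    "tnt_ratio",
    "rule_metrics",
    "sequence_metrics",
    "rule_metrics_frame",
    "sequence_metrics_frame",
]


@dataclass(frozen=True)
class RuleTreeEncoding:
    """Binary shape string of one rule."""

    rule_id: int
    bits: str

    def __post_init__(self) -> None:
        if set(self.bits) - {"0", "1"}:
            raise ValueError(f"encoding must be over {{0,1}}, got {self.bits!r}")

    @property
    def n_terminal(self) -> int:
        return self.bits.count("1")

    @property
    def n_nonterminal(self) -> int:
        return self.bits.count("0")


@dataclass(frozen=True)
class RuleMetrics:
    rule_id: int
    bits: str
    nesting: int
    phrase_length: int
    entropy: float
    gini: float
    tnt_ratio: float


@dataclass(frozen=True)
class SequenceMetrics:
    sequence_id: str
    chunks: int
    max_nesting: int
    per_rule: tuple[RuleMetrics, ...] = ()


def encode_rule(grammar: Grammar, rule_id: int) -> RuleTreeEncoding:
    """Recursive preorder binary encoding of a rule's right-hand side."""

    def rec(rid: int, stack: tuple[int, ...]) -> str:
        if rid in stack:
            raise ValueError(f"cyclic reference through rule {rid}")
        out = []
        for sym in grammar.rhs(rid):
            if isinstance(sym, RuleRef):
                out.append("0" + rec(sym.rule_id, stack + (rid,)))
            else:
                out.append("1")
        return "".join(out)

    return RuleTreeEncoding(rule_id, rec(rule_id, ()))


def nesting_depth(grammar: Grammar, symbol: Symbol) -> int:
    """Maximum embedding depth D: 0 for a terminal, 1 + max over the rhs."""
    if not isinstance(symbol, RuleRef):
        return 0

    def rec(rid: int, stack: tuple[int, ...]) -> int:
        if rid in stack:
            raise ValueError(f"cyclic reference through rule {rid}")
        depth = 0
        for sym in grammar.rhs(rid):
            if isinstance(sym, RuleRef):
                depth = max(depth, rec(sym.rule_id, stack + (rid,)))
        return 1 + depth

    return rec(symbol.rule_id, ())


def chunks(grammar: Grammar) -> int:
    """Number of rules in the rule book (the start sequence excluded)."""
    return grammar.n_rules


def phrase_length(grammar: Grammar, rule_id: int) -> int:
    """Number of terminal actions the rule expands to (its yield)."""

    def rec(rid: int, stack: tuple[int, ...]) -> int:
        if rid in stack:
            raise ValueError(f"cyclic reference through rule {rid}")
        total = 0
        for sym in grammar.rhs(rid):
            if isinstance(sym, RuleRef):
                total += rec(sym.rule_id, stack + (rid,))
            else:
                total += 1
        return total

    return rec(rule_id, ())


def structural_entropy(bits: str) -> float:
    """Binary Shannon entropy of the bit composition (log base 2)."""
    if not bits:
        raise ValueError("encoding must be non-empty")
    n = len(bits)
    h = 0.0
    for p in (bits.count("0") / n, bits.count("1") / n):
        if p > 0:
            h -= p * math.log2(p)
    return h


def gini(bits: str) -> float:
    """Gini coefficient of the 1-based positions of 0s in the encoding.

    ``sum_i sum_j |x_i - x_j| / (2 m^2 mu)`` over all ordered pairs of
    0-positions; defined as 0 when there are fewer than two 0s.
    """
    if not bits:
        raise ValueError("encoding must be non-empty")
    xs = [i for i, b in enumerate(bits, start=1) if b == "0"]
    m = len(xs)
    if m <= 1:
        return 0.0
    mu = sum(xs) / m
    total = sum(abs(xi - xj) for xi in xs for xj in xs)
    return total / (2 * m * m * mu)


def tnt_ratio(bits: str) -> float:
    """Count of 0s divided by count of 1s (as the measure is defined)."""
    if not bits:
        raise ValueError("encoding must be non-empty")
    ones = bits.count("1")
    if ones == 0:
        raise ValueError("rule encoding must contain at least one terminal bit")
    return bits.count("0") / ones


def rule_metrics(grammar: Grammar, rule_id: int) -> RuleMetrics:
    enc = encode_rule(grammar, rule_id)
    return RuleMetrics(
        rule_id=rule_id,
        bits=enc.bits,
        nesting=nesting_depth(grammar, RuleRef(rule_id)),
        phrase_length=phrase_length(grammar, rule_id),
        entropy=structural_entropy(enc.bits),
        gini=gini(enc.bits),
        tnt_ratio=tnt_ratio(enc.bits),
    )


def sequence_metrics(grammar: Grammar) -> SequenceMetrics:
    """All six measures for one grammar (one per-rule row per rule)."""
    per_rule = tuple(rule_metrics(grammar, rid) for rid in sorted(grammar.rules))
    return SequenceMetrics(
        sequence_id=grammar.sequence_id,
        chunks=chunks(grammar),
        max_nesting=max((m.nesting for m in per_rule), default=0),
        per_rule=per_rule,
    )


def rule_metrics_frame(
    metrics: list[SequenceMetrics], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Long per-rule metrics table (one row per rule per sequence)."""
    rows = []
    for sm in metrics:
        grp = (groups or {}).get(sm.sequence_id, "")
        for rm in sm.per_rule:
            rows.append(
                (sm.sequence_id, grp, rm.rule_id, rm.bits, rm.nesting,
                 rm.phrase_length, rm.entropy, rm.gini, rm.tnt_ratio)
            )
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "group", "rule_id", "bits", "nesting",
                 "phrase_length", "entropy", "gini", "tnt_ratio"],
    )


def sequence_metrics_frame(
    metrics: list[SequenceMetrics], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-sequence summary table (chunks and maximum nesting)."""
    rows = [
        (sm.sequence_id, (groups or {}).get(sm.sequence_id, ""), sm.chunks,
         sm.max_nesting)
        for sm in metrics
    ]
    return pd.DataFrame(
        rows, columns=["sequence_id", "group", "chunks", "max_nesting"]
    )
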