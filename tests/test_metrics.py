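import itertools
import math
import random

import pytest

from seqhier.metrics import (
    RuleTreeEncoding,
    encode_rule,
    chunks,
    gini,
    nesting_depth,
    phrase_length,
    rule_metrics_frame,
    sequence_metrics,
    sequence_metrics_frame,
    structural_entropy,
    tnt_ratio,
)
from seqhier.sequitur import Grammar, RuleRef, expand_symbol, induce_grammar

from conftest import codes

# --------------------------------------------------------------------------
# independent brute-force oracles for the printed formulas


def oracle_entropy(bits: str) -> float:
    n = len(bits)
    p0, p1 = bits.count("0") / n, bits.count("1") / n
    total = 0.0
    for p in (p0, p1):
        total += p * math.log2(p) if p > 0 else 0.0
    return -total


def oracle_gini(bits: str) -> float:
    xs = [i + 1 for i, b in enumerate(bits) if b == "0"]
    m = len(xs)
    if m <= 1:
        return 0.0
    mu = sum(xs) / m
    acc = 0.0
    for i in range(m):
        for j in range(m):
            acc += abs(xs[i] - xs[j])
    return acc / (2 * m * m * mu)


def oracle_tnt(bits: str) -> float:
    return bits.count("0") / bits.count("1")


def oracle_tree(grammar: Grammar, sym):
    """Build the rule tree as nested tuples (terminals are leaves)."""
    if isinstance(sym, RuleRef):
        return tuple(oracle_tree(grammar, s) for s in grammar.rhs(sym.rule_id))
    return sym


def oracle_depth(tree) -> int:
    if not isinstance(tree, tuple):
        return 0
    return 1 + max(oracle_depth(child) for child in tree)


def oracle_yield(tree) -> int:
    if not isinstance(tree, tuple):
        return 1
    return sum(oracle_yield(child) for child in tree)


def all_bitstrings(max_len: int):
    for n in range(1, max_len + 1):
        for combo in itertools.product("01", repeat=n):
            yield "".join(combo)


def random_grammars(n: int, seed: int = 0):
    rng = random.Random(seed)
    out = []
    while len(out) < n:
        s = [rng.randint(1, rng.randint(2, 7)) for _ in range(rng.randint(8, 150))]
        g = induce_grammar(s, 2)
        if g.n_rules:
            out.append(g)
    return out


# --------------------------------------------------------------------------


class TestEncodeRule:
    def test_flat_rule_all_ones(self):
        g = Grammar("s", 2, (RuleRef(1), 3, RuleRef(1)), {1: (1, 2)})
        assert encode_rule(g, 1).bits == "11"

    def test_single_embedded_rule(self):
        g = Grammar(
            "s", 2, (RuleRef(2), RuleRef(2), RuleRef(1)),
            {1: (1, 1), 2: (RuleRef(1), 2)},
        )
        assert encode_rule(g, 2).bits == "0111"

    def test_double_embedding(self):
        g = Grammar(
            "s", 2, (RuleRef(2), RuleRef(2), RuleRef(1)),
            {1: (1, 2), 2: (RuleRef(1), RuleRef(1))},
        )
        assert encode_rule(g, 2).bits == "011011"

    def test_unknown_rule_errors(self):
        g = induce_grammar(codes("abdcab"), 2)
        with pytest.raises(KeyError):
            encode_rule(g, 99)

    def test_invalid_bits_rejected(self):
        with pytest.raises(ValueError):
            RuleTreeEncoding(1, "10x")


class TestNestingDepth:
    def test_terminal_is_zero(self):
        g = induce_grammar(codes("abdcab"), 2)
        assert nesting_depth(g, 1) == 0

    def test_flat_rule_is_one(self):
        g = induce_grammar(codes("abdcab"), 2)
        assert nesting_depth(g, RuleRef(1)) == 1

    def test_embedded_rule_is_two(self):
        g = Grammar(
            "s", 2, (RuleRef(2), RuleRef(2), RuleRef(1)),
            {1: (1, 1), 2: (RuleRef(1), 2)},
        )
        assert nesting_depth(g, RuleRef(2)) == 2


class TestChunksAndPhraseLength:
    def test_abdcab_one_chunk(self):
        g = induce_grammar(codes("abdcab"), 2)
        assert chunks(g) == 1

    def test_incompressible_zero_chunks(self):
        assert chunks(induce_grammar(codes("abcd"), 2)) == 0

    def test_abababab_two_chunks(self):
        assert chunks(induce_grammar(codes("abababab"), 2)) == 2

    def test_flat_rule_phrase_length_two(self):
        g = induce_grammar(codes("abdcab"), 2)
        assert phrase_length(g, 1) == 2

    def test_chunk_in_three_action_phrase(self):
        # a bigram chunk embedded in a 3-action phrase
        g = Grammar(
            "s", 2, (RuleRef(2), RuleRef(2), RuleRef(1)),
            {1: (1, 2), 2: (RuleRef(1), 3)},
        )
        assert phrase_length(g, 2) == 3

    def test_double_embedding_expands_to_four(self):
        g = Grammar(
            "s", 2, (RuleRef(2), RuleRef(2), RuleRef(1)),
            {1: (1, 2), 2: (RuleRef(1), RuleRef(1))},
        )
        assert phrase_length(g, 2) == 4
        assert expand_symbol(g, RuleRef(2)) == codes("abab")


class TestBitstringMeasures:
    @pytest.mark.parametrize(
        "bits,expected",
        [("11", 0.0), ("0111", 0.8112781244591328), ("01", 1.0)],
    )
    def test_entropy_examples(self, bits, expected):
        assert structural_entropy(bits) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "bits,expected", [("11", 0.0), ("0111", 0.0), ("011011", 0.3)]
    )
    def test_gini_examples(self, bits, expected):
        assert gini(bits) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "bits,expected", [("11", 0.0), ("0111", 1 / 3), ("011011", 0.5)]
    )
    def test_tnt_examples(self, bits, expected):
        assert tnt_ratio(bits) == pytest.approx(expected, abs=1e-12)

    def test_empty_string_errors(self):
        for fn in (structural_entropy, gini, tnt_ratio):
            with pytest.raises(ValueError):
                fn("")

    def test_tnt_without_terminals_errors(self):
        with pytest.raises(ValueError):
            tnt_ratio("000")

    def test_oracle_equivalence_exhaustive(self):
        # every bitstring of length <= 10 against the brute-force formulas
        for bits in all_bitstrings(10):
            assert structural_entropy(bits) == pytest.approx(
                oracle_entropy(bits), abs=1e-12
            )
            assert gini(bits) == pytest.approx(oracle_gini(bits), abs=1e-12)
            if "1" in bits:
                assert tnt_ratio(bits) == pytest.approx(
                    oracle_tnt(bits), abs=1e-12
                )


class TestCrossChecks:
    def test_structural_measures_on_random_grammars(self):
        for g in random_grammars(100, seed=1):
            for rid in g.rules:
                bits = encode_rule(g, rid).bits
                tree = oracle_tree(g, RuleRef(rid))
                assert phrase_length(g, rid) == bits.count("1")
                assert phrase_length(g, rid) == oracle_yield(tree)
                assert nesting_depth(g, RuleRef(rid)) == oracle_depth(tree)
                # each embedded rule expands to >= 2 terminals
                assert bits.count("0") < bits.count("1")
                assert structural_entropy(bits) < 1.0
                assert tnt_ratio(bits) < 1.0


class TestSequenceMetrics:
    def test_incompressible(self):
        sm = sequence_metrics(induce_grammar(codes("abcd"), 2))
        assert sm.chunks == 0
        assert sm.max_nesting == 0
        assert sm.per_rule == ()

    def test_abdcab(self):
        sm = sequence_metrics(induce_grammar(codes("abdcab"), 2))
        assert sm.chunks == 1 and sm.max_nesting == 1
        (rm,) = sm.per_rule
        assert rm.phrase_length == 2
        assert rm.entropy == rm.gini == rm.tnt_ratio == 0.0

    def test_abababab(self):
        sm = sequence_metrics(induce_grammar(codes("abababab"), 2))
        assert sm.chunks == 2 and sm.max_nesting == 2

    def test_frames(self):
        g = induce_grammar(codes("abdcab"), 2, sequence_id="s1")
        sms = [sequence_metrics(g)]
        rules = rule_metrics_frame(sms, {"s1": "chimpanzee"})
        seqs = sequence_metrics_frame(sms, {"s1": "chimpanzee"})
        assert list(rules.columns) == [
            "sequence_id", "group", "rule_id", "bits", "nesting",
            "phrase_length", "entropy", "gini", "tnt_ratio",
        ]
        assert rules.shape[0] == 1
        assert seqs.loc[0, "chunks"] == 1
        assert seqs.loc[0, "group"] == "chimpanzee"
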