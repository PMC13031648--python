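"""Grammar induction by lossless hierarchical compression (Sequitur).

The algorithm reads a symbol sequence left to right and maintains two
constraints on the growing grammar:

* **digram uniqueness** — no ordered pair of adjacent symbols occurs more
  than ``k - 1`` times (for the classical ``k = 2``: at most once) across
  the start sequence and all rule right-hand sides, overlapping
  occurrences excepted;
* **rule utility** — every rule is referenced at least ``k`` times,
  otherwise it is inlined at its remaining use sites and deleted.

When a digram reaches its ``k``-th (non-overlapping) occurrence it is
promoted to a rule and every occurrence is replaced by a reference to that
rule.  The output is a start sequence (the compressed sequence) plus a
rule book; expanding every reference reproduces the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

__all__ = [
    "RuleRef",
    "Grammar",
    "GrammarInvariantError",
    "induce_grammar",
    "expand",
    "expand_symbol",
    "compressed_length",
    "check_invariants",
    "grammar_to_dict",
    "grammar_from_dict",
]


class RuleRef(NamedTuple):
    """Reference to a rule by id within one grammar."""

    rule_id: int


#: a grammar symbol: a terminal behavior code or a rule reference
Symbol = Union[int, RuleRef]


@dataclass(frozen=True)
class Grammar:
    """Sequitur output: compressed start sequence plus rule book."""

    sequence_id: str
    k: int
    start: tuple[Symbol, ...]
    rules: dict[int, tuple[Symbol, ...]] = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def rhs(self, rule_id: int) -> tuple[Symbol, ...]:
        try:
            return self.rules[rule_id]
        except KeyError:
            raise KeyError(f"grammar has no rule {rule_id}") from None


class GrammarInvariantError(AssertionError):
    """A grammar violated digram uniqueness, rule utility or acyclicity."""


# ---------------------------------------------------------------------------
# internal linked-list machinery

_GUARD = object()


class _Node:
    __slots__ = ("value", "prev", "next", "owner")

    def __init__(self, value):
        self.value = value
        self.prev = None
        self.next = None
        self.owner = None  # only set on guard nodes (back-pointer to rule)

    @property
    def is_guard(self) -> bool:
        return self.value is _GUARD

    @property
    def dead(self) -> bool:
        return self.prev is None or self.next is None


class _Rule:
    __slots__ = ("rid", "guard", "users", "alive")

    def __init__(self, rid: int):
        self.rid = rid
        g = _Node(_GUARD)
        g.owner = self
        g.prev = g.next = g
        self.guard = g
        self.users: set[_Node] = set()
        self.alive = True

    def symbols(self) -> list:
        out, n = [], self.guard.next
        while n is not self.guard:
            out.append(n.value)
            n = n.next
        return out


def _join(left: _Node, right: _Node) -> None:
    left.next = right
    right.prev = left


class _Sequitur:
    def __init__(self, k: int):
        self.k = k
        self.top = _Rule(0)
        self.rules: list[_Rule] = []
        self.index: dict[tuple, list[_Node]] = {}
        self._next_rid = 1

    # -- digram bookkeeping -------------------------------------------------

    @staticmethod
    def _skey(value) -> tuple:
        if isinstance(value, _Rule):
            return ("r", value.rid)
        return ("t", value)

    def _dkey(self, node: _Node) -> tuple:
        return (self._skey(node.value), self._skey(node.next.value))

    def _unregister(self, node: _Node) -> None:
        """Forget the digram whose left symbol is ``node``, if registered."""
        if node.dead or node.is_guard or node.next.is_guard:
            return
        d = self._dkey(node)
        occs = self.index.get(d)
        if occs is not None:
            try:
                occs.remove(node)
            except ValueError:
                pass
            if not occs:
                del self.index[d]

    # -- main loop ----------------------------------------------------------

    def append(self, value: int) -> None:
        node = _Node(value)
        last = self.top.guard.prev
        _join(last, node)
        _join(node, self.top.guard)
        if not last.is_guard:
            self._check(last)

    def _check(self, node: _Node) -> None:
        """Enforce the digram constraint for the digram starting at ``node``."""
        if node.dead or node.is_guard or node.next.is_guard:
            return
        d = self._dkey(node)
        occs = self.index.get(d)
        if occs:
            if any(o is node for o in occs):
                return  # already registered
            if any(o.next is node or node.next is o for o in occs):
                return  # overlapping occurrence (e.g. middle of "aaa")
            for o in occs:
                if o.prev.is_guard and o.next.next.is_guard:
                    # the digram spans an entire existing rule body: reuse it
                    self._substitute(node, o.prev.owner)
                    return
        else:
            occs = self.index[d] = []
        occs.append(node)
        if len(occs) >= self.k:
            self._promote(d, list(occs))

    def _promote(self, d: tuple, occs: list[_Node]) -> None:
        """Create a rule for digram ``d`` and replace all its occurrences."""
        rule = _Rule(self._next_rid)
        self._next_rid += 1
        self.rules.append(rule)
        va, vb = occs[0].value, occs[0].next.value
        n1, n2 = _Node(va), _Node(vb)
        _join(rule.guard, n1)
        _join(n1, n2)
        _join(n2, rule.guard)
        for n in (n1, n2):
            if isinstance(n.value, _Rule):
                n.value.users.add(n)
        # the canonical occurrence of d now lives inside the new rule body
        self.index[d] = [n1]
        for occ in occs:
            if not occ.dead and not occ.next.is_guard and self._dkey(occ) == d:
                self._substitute(occ, rule)

    def _substitute(self, node: _Node, rule: _Rule) -> None:
        """Replace the digram at ``node`` by a reference to ``rule``."""
        a, b = node, node.next
        prev, nxt = a.prev, b.next
        self._unregister(prev)
        self._unregister(a)
        self._unregister(b)
        ref = _Node(rule)
        rule.users.add(ref)
        _join(prev, ref)
        _join(ref, nxt)
        a.prev = a.next = None
        b.prev = b.next = None
        for gone in (a, b):
            if isinstance(gone.value, _Rule):
                gone.value.users.discard(gone)
        for gone in (a, b):
            if isinstance(gone.value, _Rule):
                self._enforce_utility(gone.value)
        self._check(prev)
        if not ref.dead:
            self._check(ref)
        # removing the pair may have un-overlapped the digram at nxt
        if not nxt.dead:
            self._check(nxt)

    # -- rule utility -------------------------------------------------------

    def _enforce_utility(self, rule: _Rule) -> None:
        if not rule.alive or rule is self.top:
            return
        n_users = len(rule.users)
        if n_users >= self.k:
            return
        rule.alive = False
        self.rules.remove(rule)
        if n_users == 0:
            # unreachable rule: drop its body entirely
            node = rule.guard.next
            while not node.is_guard:
                self._unregister(node)
                node = node.next
            node = rule.guard.next
            while not node.is_guard:
                nxt = node.next
                node.prev = node.next = None
                if isinstance(node.value, _Rule):
                    node.value.users.discard(node)
                    self._enforce_utility(node.value)
                node = nxt
            return
        users = list(rule.users)
        values = rule.symbols()  # capture before the body is spliced away
        self._splice(rule, users[0], original=True)
        for user in users[1:]:
            self._splice(rule, user, original=False, values=values)

    def _splice(
        self, rule: _Rule, user: _Node, *, original: bool, values: list | None = None
    ) -> None:
        """Inline ``rule``'s body in place of the reference ``user``."""
        if user.dead:
            return
        prev, nxt = user.prev, user.next
        self._unregister(prev)
        self._unregister(user)
        user.prev = user.next = None
        rule.users.discard(user)
        if original:
            first, last = rule.guard.next, rule.guard.prev
            _join(prev, first)
            _join(last, nxt)
            self._check(prev)
            if not last.dead:
                self._check(last)
            if not nxt.dead:
                self._check(nxt)
        else:
            chain = [_Node(v) for v in values]
            for n in chain:
                if isinstance(n.value, _Rule):
                    n.value.users.add(n)
            cursor = prev
            for n in chain:
                _join(cursor, n)
                cursor = n
            _join(cursor, nxt)
            self._check(prev)
            for n in chain:
                if not n.dead:
                    self._check(n)
            if not nxt.dead:
                self._check(nxt)

    # -- extraction ---------------------------------------------------------

    def extract(self, sequence_id: str) -> Grammar:
        """Renumber reachable rules 1..n by first appearance and freeze."""
        numbering: dict[int, int] = {}
        ordered: list[_Rule] = []
        queue: list[_Rule] = []

        def visit(values: Iterable) -> None:
            for v in values:
                if isinstance(v, _Rule) and v.rid not in numbering:
                    numbering[v.rid] = len(numbering) + 1
                    ordered.append(v)
                    queue.append(v)

        start_vals = self.top.symbols()
        visit(start_vals)
        while queue:
            visit(queue.pop(0).symbols())

        def freeze(values: Iterable) -> tuple:
            return tuple(
                RuleRef(numbering[v.rid]) if isinstance(v, _Rule) else v
                for v in values
            )

        rules = {numbering[r.rid]: freeze(r.symbols()) for r in ordered}
        return Grammar(sequence_id, self.k, freeze(start_vals), rules)


# ---------------------------------------------------------------------------
# generalized-k engine (k > 2): online append + fixed-point enforcement
#
# Immediate cascading enforcement (as in the k = 2 linked-list engine above)
# is not safe for k > 2 because inlining a rule with several remaining users
# interleaves badly with concurrent promotions.  Instead each appended
# symbol is followed by whole-grammar constraint sweeps until a fixed point:
# still online left-to-right, and the invariants hold by construction.


def _induce_general(actions: Sequence[int], k: int, sequence_id: str) -> Grammar:
    start: list = [int(actions[0])]
    rules: dict[int, list] = {}
    next_rid = 1

    def bodies():
        yield "S", start
        for rid in sorted(rules):
            yield rid, rules[rid]

    def digram_sites() -> dict:
        """Non-overlapping digram occurrences in first-appearance order."""
        occ: dict[tuple, list] = {}
        for key, body in bodies():
            i = 0
            while i < len(body) - 1:
                d = (body[i], body[i + 1])
                occ.setdefault(d, []).append((key, i))
                if i + 2 < len(body) and (body[i + 1], body[i + 2]) == d:
                    i += 2
                else:
                    i += 1
        return occ

    def replace_sites(d: tuple, sites: list, rid: int) -> None:
        ref = RuleRef(rid)
        by_body: dict = {}
        for key, i in sites:
            by_body.setdefault(key, []).append(i)
        for key, idxs in by_body.items():
            body = start if key == "S" else rules[key]
            for i in sorted(idxs, reverse=True):
                body[i : i + 2] = [ref]

    def enforce_digrams() -> bool:
        nonlocal next_rid
        for d, sites in digram_sites().items():
            rid = next(
                (r for r in sorted(rules) if tuple(rules[r]) == d and len(d) == 2),
                None,
            )
            if rid is not None:
                outside = [
                    s for s in sites if not (s[0] == rid and len(rules[rid]) == 2)
                ]
                if outside:
                    replace_sites(d, outside, rid)
                    return True
            elif len(sites) >= k:
                rid, next_rid = next_rid, next_rid + 1
                rules[rid] = list(d)
                replace_sites(d, sites, rid)
                return True
        return False

    def enforce_utility() -> bool:
        uses: dict[int, int] = {rid: 0 for rid in rules}
        for _, body in bodies():
            for s in body:
                if isinstance(s, RuleRef):
                    uses[s.rule_id] += 1
        for rid in sorted(rules):
            if uses[rid] < k:
                rhs = rules.pop(rid)
                ref = RuleRef(rid)
                for key, body in [("S", start)] + [
                    (r, rules[r]) for r in sorted(rules)
                ]:
                    i = 0
                    while i < len(body):
                        if body[i] == ref:
                            body[i : i + 1] = list(rhs)
                            i += len(rhs)
                        else:
                            i += 1
                return True
        return False

    def settle() -> None:
        guard = 0
        limit = 1000 + 100 * len(actions)
        while enforce_digrams() or enforce_utility():
            guard += 1
            if guard > limit:
                raise RuntimeError(
                    "grammar constraint enforcement did not reach a fixed point"
                )

    for a in actions[1:]:
        start.append(int(a))
        settle()
    settle()

    # renumber reachable rules 1..n by first appearance
    numbering: dict[int, int] = {}
    queue: list[int] = []

    def visit(body) -> None:
        for s in body:
            if isinstance(s, RuleRef) and s.rule_id not in numbering:
                numbering[s.rule_id] = len(numbering) + 1
                queue.append(s.rule_id)

    visit(start)
    ordered = []
    while queue:
        rid = queue.pop(0)
        ordered.append(rid)
        visit(rules[rid])

    def freeze(body) -> tuple:
        return tuple(
            RuleRef(numbering[s.rule_id]) if isinstance(s, RuleRef) else s
            for s in body
        )

    return Grammar(
        sequence_id,
        k,
        freeze(start),
        {numbering[rid]: freeze(rules[rid]) for rid in ordered},
    )


# ---------------------------------------------------------------------------
# public operations


def induce_grammar(
    actions: Sequence[int], k: int = 2, *, sequence_id: str = ""
) -> Grammar:
    """Compress ``actions`` into a :class:`Grammar` with utility threshold ``k``.

    ``k = 2`` is classical Sequitur: a repeated bigram is promoted to a
    rule at its second occurrence.  For ``k > 2`` promotion happens at the
    ``k``-th occurrence and rules used fewer than ``k`` times are inlined.
    The function is deterministic: identical input gives an identical
    grammar.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(actions) == 0:
        raise ValueError("cannot induce a grammar from an empty sequence")
    if k > 2:
        return _induce_general(actions, k, sequence_id)
    builder = _Sequitur(k)
    for a in actions:
        builder.append(int(a))
    return builder.extract(sequence_id)


def expand_symbol(grammar: Grammar, symbol: Symbol) -> tuple[int, ...]:
    """Full terminal expansion (yield) of one grammar symbol."""
    memo: dict[int, tuple[int, ...]] = {}
    in_progress: set[int] = set()

    def rec(sym: Symbol) -> tuple[int, ...]:
        if isinstance(sym, RuleRef):
            rid = sym.rule_id
            if rid in memo:
                return memo[rid]
            if rid in in_progress:
                raise GrammarInvariantError(f"cyclic reference through rule {rid}")
            if rid not in grammar.rules:
                raise GrammarInvariantError(f"dangling reference to rule {rid}")
            in_progress.add(rid)
            out: tuple[int, ...] = ()
            for s in grammar.rules[rid]:
                out += rec(s)
            in_progress.discard(rid)
            memo[rid] = out
            return out
        return (sym,)

    return rec(symbol)


def expand(grammar: Grammar) -> tuple[int, ...]:
    """Reconstruct the original sequence by recursive left-to-right expansion."""
    out: tuple[int, ...] = ()
    for sym in grammar.start:
        out += expand_symbol(grammar, sym)
    return out


def compressed_length(grammar: Grammar) -> int:
    """Number of symbols in the compressed start sequence."""
    return len(grammar.start)


def _count_nonoverlapping_digrams(symbols: Sequence[Symbol]) -> dict:
    """Count digram occurrences, never counting two that share a symbol."""
    counts: dict[tuple, int] = {}
    i = 0
    while i < len(symbols) - 1:
        d = (symbols[i], symbols[i + 1])
        counts[d] = counts.get(d, 0) + 1
        if i + 2 < len(symbols) and (symbols[i + 1], symbols[i + 2]) == d:
            i += 2  # skip the overlapping repeat (e.g. middle of "aaa")
        else:
            i += 1
    return counts


def check_invariants(grammar: Grammar) -> None:
    """Raise :class:`GrammarInvariantError` on any violated grammar invariant.

    Checks, by direct scan: digram occurrence bound (< k occurrences of any
    adjacent pair across start and rule bodies), rule utility (every rule
    referenced >= k times), right-hand sides of length >= 2, acyclicity and
    absence of dangling references.
    """
    bodies = [("start", grammar.start)] + [
        (f"rule {rid}", rhs) for rid, rhs in grammar.rules.items()
    ]
    digrams: dict[tuple, int] = {}
    uses: dict[int, int] = {rid: 0 for rid in grammar.rules}
    for name, syms in bodies:
        if name != "start" and len(syms) < 2:
            raise GrammarInvariantError(f"{name} has rhs shorter than 2")
        for d, c in _count_nonoverlapping_digrams(syms).items():
            digrams[d] = digrams.get(d, 0) + c
        for s in syms:
            if isinstance(s, RuleRef):
                if s.rule_id not in grammar.rules:
                    raise GrammarInvariantError(
                        f"{name} references missing rule {s.rule_id}"
                    )
                uses[s.rule_id] += 1
    for d, c in digrams.items():
        if c >= grammar.k:
            raise GrammarInvariantError(
                f"digram {d} occurs {c} times (allowed < {grammar.k})"
            )
    for rid, c in uses.items():
        if c < grammar.k:
            raise GrammarInvariantError(
                f"rule {rid} used {c} times (rule utility requires >= {grammar.k})"
            )
    for rid in grammar.rules:
        expand_symbol(grammar, RuleRef(rid))  # raises on cycles/dangling refs


# ---------------------------------------------------------------------------
# serialization (rule-book JSON schema)


def _sym_to_str(sym: Symbol, label_of) -> str:
    if isinstance(sym, RuleRef):
        return f"#{sym.rule_id}"
    return label_of(sym)


def _sym_from_str(s: str, code_of) -> Symbol:
    if s.startswith("#"):
        return RuleRef(int(s[1:]))
    return code_of(s)


def grammar_to_dict(grammar: Grammar, label_of=None) -> dict:
    """Serialize to the rule-book schema.

    ``label_of`` maps a terminal code to its behavior label (for example
    ``ethogram.label_of``); by default codes are written as decimal strings.
    Rule references are written as the rule id prefixed with ``#``.
    """
    if label_of is None:
        label_of = str
    return {
        "sequence_id": grammar.sequence_id,
        "k": grammar.k,
        "start": [_sym_to_str(s, label_of) for s in grammar.start],
        "rules": {
            str(rid): [_sym_to_str(s, label_of) for s in rhs]
            for rid, rhs in grammar.rules.items()
        },
    }


def grammar_from_dict(d: Mapping, code_of=None) -> Grammar:
    """Inverse of :func:`grammar_to_dict`."""
    if code_of is None:
        code_of = int
    return Grammar(
        sequence_id=d["sequence_id"],
        k=int(d["k"]),
        start=tuple(_sym_from_str(s, code_of) for s in d["start"]),
        rules={
            int(rid): tuple(_sym_from_str(s, code_of) for s in rhs)
            for rid, rhs in d["rules"].items()
        },
    )
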