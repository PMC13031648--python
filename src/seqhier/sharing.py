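"""Deduplicate rule tree shapes within groups; classify shared vs unique.

Structure identity is the binary shape encoding alone — terminal labels
are ignored, so shapes are comparable across behaviorally unrelated
groups.  Sharing is computed on the union of all rules in a group across
its sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .metrics import RuleTreeEncoding

__all__ = [
    "StructureInventory",
    "build_inventory",
    "classify_shared",
    "label_rules",
    "inventory_frame",
    "classification_frame",
]


@dataclass
class StructureInventory:
    """Occurrence counts of distinct rule shapes within one group."""

    group: str
    structures: Counter = field(default_factory=Counter)

    @property
    def n_distinct(self) -> int:
        return len(self.structures)

    @property
    def total(self) -> int:
        return sum(self.structures.values())


def build_inventory(
    encodings: Iterable[RuleTreeEncoding | str], group: str
) -> StructureInventory:
    """Count distinct shape bitstrings over all rules of one group."""
    counts: Counter = Counter()
    for enc in encodings:
        bits = enc.bits if isinstance(enc, RuleTreeEncoding) else str(enc)
        if set(bits) - {"0", "1"} or bits.count("1") < 2:
            raise ValueError(f"invalid rule shape encoding {bits!r}")
        counts[bits] += 1
    return StructureInventory(group, counts)


def classify_shared(
    target: StructureInventory, others: Iterable[StructureInventory]
) -> tuple[set[str], set[str]]:
    """Split the target group's shapes into (shared, unique).

    A shape is shared iff it occurs in at least one other inventory; the
    two returned sets partition the target's keys.
    """
    pool: set[str] = set()
    for inv in others:
        pool.update(inv.structures)
    keys = set(target.structures)
    shared = keys & pool
    return shared, keys - shared


def label_rules(
    metrics: pd.DataFrame, shared: set[str], unique: set[str]
) -> pd.DataFrame:
    """Add a ``status`` column (shared/unique) to a per-rule metrics table."""
    unknown = set(metrics["bits"].astype(str)) - shared - unique
    if unknown:
        raise ValueError(
            f"encodings classified in neither set: {sorted(unknown)[:5]}"
        )
    out = metrics.copy()
    out["status"] = [
        "shared" if b in shared else "unique" for b in out["bits"].astype(str)
    ]
    return out


def inventory_frame(inventories: Iterable[StructureInventory]) -> pd.DataFrame:
    rows = [
        (inv.group, bits, count)
        for inv in inventories
        for bits, count in sorted(inv.structures.items())
    ]
    return pd.DataFrame(rows, columns=["group", "bits", "count"])


def classification_frame(
    group: str, shared: set[str], unique: set[str]
) -> pd.DataFrame:
    rows = [(group, b, "shared") for b in sorted(shared)] + [
        (group, b, "unique") for b in sorted(unique)
    ]
    return pd.DataFrame(rows, columns=["group", "bits", "status"])
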