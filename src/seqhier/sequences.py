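"""Ethogram-coded action sequences: core types, CSV I/O and filters.

A behavioral sequence is an ordered list of integer behavior codes drawn
from a fixed ethogram (the inventory of behavior categories).  Codes are
contiguous integers starting at 1; the human-readable labels travel with
every :class:`SequenceSet` so that serialized artifacts stay legible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Ethogram",
    "ActionSequence",
    "SequenceSet",
    "read_sequences",
    "write_sequences",
    "read_ethogram",
    "write_ethogram",
    "filter_min_length",
    "behavior_frequencies",
    "SEQUENCE_COLUMNS",
]

#: canonical column names of the sequence CSV dialect
SEQUENCE_COLUMNS = ("sequence_id", "subject_id", "group", "position", "behavior")


@dataclass(frozen=True)
class Ethogram:
    """Bijection between behavior labels and contiguous integer codes (1-based)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("ethogram must contain at least one behavior label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ethogram labels must be unique")
        if any(not lab for lab in self.labels):
            raise ValueError("ethogram labels must be non-empty strings")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.labels) + 1))

    @property
    def n_behaviors(self) -> int:
        return len(self.labels)

    def code_of(self, label: str) -> int:
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown behavior label {label!r}") from None

    def label_of(self, code: int) -> str:
        if not 1 <= code <= len(self.labels):
            raise KeyError(f"unknown behavior code {code}")
        return self.labels[code - 1]

    def __contains__(self, code: object) -> bool:
        return isinstance(code, int) and 1 <= code <= len(self.labels)


@dataclass(frozen=True)
class ActionSequence:
    """One coded behavioral sequence."""

    sequence_id: str
    subject_id: str
    group: str
    actions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.actions) < 1:
            raise ValueError(f"sequence {self.sequence_id!r} is empty")

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class SequenceSet:
    """A collection of sequences sharing one ethogram."""

    ethogram: Ethogram
    sequences: list[ActionSequence] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        for seq in self.sequences:
            bad = [a for a in seq.actions if a not in self.ethogram]
            if bad:
                raise ValueError(
                    f"sequence {seq.sequence_id!r} holds codes {sorted(set(bad))} "
                    f"outside the {self.ethogram.n_behaviors}-behavior ethogram"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.sequences]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seq in self.sequences:
            for pos, code in enumerate(seq.actions, start=1):
                rows.append(
                    (seq.sequence_id, seq.subject_id, seq.group, pos,
                     self.ethogram.label_of(code))
                )
        return pd.DataFrame(rows, columns=list(SEQUENCE_COLUMNS))


def read_ethogram(path: str | Path) -> Ethogram:
    """Read an ethogram CSV with columns ``code,label`` (codes 1..n)."""
    df = pd.read_csv(path)
    missing = {"code", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"ethogram file {path} lacks columns {sorted(missing)}")
    df = df.sort_values("code")
    codes = df["code"].tolist()
    if codes != list(range(1, len(codes) + 1)):
        raise ValueError(f"ethogram codes must be contiguous from 1, got {codes}")
    return Ethogram(tuple(str(x) for x in df["label"]))


def write_ethogram(ethogram: Ethogram, path: str | Path) -> None:
    pd.DataFrame({"code": ethogram.codes, "label": ethogram.labels}).to_csv(
        path, index=False
    )


def read_sequences(
    path: str | Path,
    *,
    ethogram: Ethogram | None = None,
    column_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> SequenceSet:
    """Read a sequence CSV into a :class:`SequenceSet`.

    The expected dialect has a header with columns
    ``sequence_id,subject_id,group,position,behavior``; ``column_map`` maps
    each canonical name to the column actually present in the file so that
    externally deposited tables with different headers can be ingested.
    Positions must be 1-based and contiguous within each sequence; gaps are
    an error rather than being silently reindexed.

    When no ``ethogram`` is given, codes are assigned to labels in order of
    first appearance in the file.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if column_map:
        unknown = set(column_map) - set(SEQUENCE_COLUMNS)
        if unknown:
            raise ValueError(f"column_map has unknown canonical names {sorted(unknown)}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = set(SEQUENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns {sorted(missing)}")

    df = df.astype(
        {"sequence_id": str, "subject_id": str, "group": str, "behavior": str}
    )
    df["position"] = pd.to_numeric(df["position"])

    if ethogram is None:
        seen: dict[str, None] = {}
        for lab in df["behavior"]:
            seen.setdefault(lab)
        labels = tuple(seen)
        ethogram = Ethogram(labels) if labels else Ethogram(("<none>",))

    sequences: list[ActionSequence] = []
    # preserve file order of sequence ids
    for seq_id in df["sequence_id"].drop_duplicates():
        block = df[df["sequence_id"] == seq_id].sort_values("position")
        positions = block["position"].tolist()
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(
                f"sequence {seq_id!r}: positions must be contiguous 1..n, "
                f"got {positions[:10]}{'...' if len(positions) > 10 else ''}"
            )
        subjects = block["subject_id"].unique()
        groups = block["group"].unique()
        if len(subjects) > 1 or len(groups) > 1:
            raise ValueError(
                f"sequence {seq_id!r} mixes subject/group labels: "
                f"{subjects.tolist()}, {groups.tolist()}"
            )
        actions = []
        for row_idx, lab in zip(block.index, block["behavior"]):
            try:
                actions.append(ethogram.code_of(lab))
            except KeyError:
                raise ValueError(
                    f"unknown behavior label {lab!r} at file row {row_idx + 2} "
                    f"(sequence {seq_id!r})"
                ) from None
        sequences.append(
            ActionSequence(seq_id, str(subjects[0]), str(groups[0]), tuple(actions))
        )
    return SequenceSet(ethogram, sequences, provenance or str(path))


def write_sequences(sset: SequenceSet, path: str | Path) -> None:
    """Write a :class:`SequenceSet` in the canonical CSV dialect."""
    sset.to_frame().to_csv(path, index=False)


def filter_min_length(
    sset: SequenceSet, min_len: int = 8
) -> tuple[SequenceSet, int]:
    """Drop sequences shorter than ``min_len`` actions.

    Returns the retained set (order preserved) and the number removed.  The
    default of 8 is the shortest length at which a nested rule dependency is
    possible under bigram chunking.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [s for s in sset.sequences if len(s) >= min_len]
    out = SequenceSet(sset.ethogram, kept, sset.provenance)
    return out, len(sset.sequences) - len(kept)


def behavior_frequencies(sset: SequenceSet) -> np.ndarray:
    """Pooled relative frequency of each behavior code across all sequences.

    Entry ``i`` is the frequency of code ``i + 1``.  Counts are pooled over
    every action in the set (not averaged per sequence).
    """
    if not sset.sequences:
        raise ValueError("cannot compute frequencies of an empty sequence set")
    counts = np.zeros(sset.ethogram.n_behaviors, dtype=float)
    for seq in sset.sequences:
        for a in seq.actions:
            counts[a - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence set has zero total actions")
    return counts / total
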