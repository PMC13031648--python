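"""Shared fixtures: letter-coded toy sequences and CSV factories."""

from __future__ import annotations

import string

import pandas as pd
import pytest

from seqhier.sequences import Ethogram, ActionSequence, SequenceSet


def codes(word: str) -> tuple[int, ...]:
    """Map letters to behavior codes: a->1, b->2, ..."""
    return tuple(string.ascii_lowercase.index(c) + 1 for c in word)


@pytest.fixture
def abc_ethogram() -> Ethogram:
    return Ethogram(("a", "b", "c", "d", "e", "f", "g"))


@pytest.fixture
def toy_set(abc_ethogram) -> SequenceSet:
    seqs = [
        ActionSequence("s1", "subj1", "chimpanzee", codes("abdcab")),
        ActionSequence("s2", "subj1", "chimpanzee", codes("abababab")),
        ActionSequence("s3", "subj2", "chimpanzee", codes("gfe")),
    ]
    return SequenceSet(abc_ethogram, seqs, "toy")


@pytest.fixture
def sequence_csv(tmp_path):
    """Write a sequence CSV from (sequence_id, subject, group, word) rows."""

    def factory(rows, name="sequences.csv"):
        records = []
        for seq_id, subj, group, word in rows:
            for pos, ch in enumerate(word, start=1):
                records.append((seq_id, subj, group, pos, ch))
        path = tmp_path / name
        pd.DataFrame(
            records,
            columns=["sequence_id", "subject_id", "group", "position",
                     "behavior"],
        ).to_csv(path, index=False)
        return path

    return factory
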