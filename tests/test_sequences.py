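import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqhier.sequences import (
    ActionSequence,
    Ethogram,
    SequenceSet,
    behavior_frequencies,
    filter_min_length,
    read_ethogram,
    read_sequences,
    write_ethogram,
    write_sequences,
)

from conftest import codes


class TestEthogram:
    def test_codes_contiguous_from_one(self):
        eth = Ethogram(("x", "y", "z"))
        assert eth.codes == (1, 2, 3)
        assert eth.code_of("y") == 2
        assert eth.label_of(3) == "z"

    def test_bijection_round_trip(self, abc_ethogram):
        for code in abc_ethogram.codes:
            assert abc_ethogram.code_of(abc_ethogram.label_of(code)) == code

    @pytest.mark.parametrize("labels", [(), ("a", "a"), ("a", "")])
    def test_invalid_labels_rejected(self, labels):
        with pytest.raises(ValueError):
            Ethogram(labels)

    def test_unknown_lookups_raise(self, abc_ethogram):
        with pytest.raises(KeyError):
            abc_ethogram.code_of("strike")
        with pytest.raises(KeyError):
            abc_ethogram.label_of(0)


class TestActionSequence:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ActionSequence("s", "x", "g", ())

    def test_code_outside_ethogram_rejected(self, abc_ethogram):
        seq = ActionSequence("s", "x", "g", (1, 99))
        with pytest.raises(ValueError, match="99"):
            SequenceSet(abc_ethogram, [seq])


class TestReadSequences:
    def test_single_sequence_parse(self, sequence_csv):
        path = sequence_csv([("s1", "subj", "chimpanzee", "abdcab")])
        sset = read_sequences(path)
        assert len(sset) == 1
        seq = sset.sequences[0]
        assert len(seq) == 6
        assert seq.actions == tuple(
            sset.ethogram.code_of(c) for c in "abdcab"
        )
        assert seq.group == "chimpanzee"

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sequence_id,subject_id,group,position,behavior\n")
        sset = read_sequences(path)
        assert len(sset) == 0

    def test_round_trip_identity(self, toy_set, tmp_path):
        path = tmp_path / "out.csv"
        write_sequences(toy_set, path)
        back = read_sequences(path, ethogram=toy_set.ethogram)
        assert back.ethogram == toy_set.ethogram
        assert back.sequences == toy_set.sequences

    def test_unknown_label_names_label_and_row(self, sequence_csv, abc_ethogram):
        path = sequence_csv([("s1", "x", "g", "abq")])
        with pytest.raises(ValueError, match=r"'q'.*row 4"):
            read_sequences(path, ethogram=abc_ethogram)

    def test_position_gap_is_error(self, tmp_path):
        path = tmp_path / "gap.csv"
        pd.DataFrame(
            {
                "sequence_id": ["s", "s"],
                "subject_id": ["x", "x"],
                "group": ["g", "g"],
                "position": [1, 3],
                "behavior": ["a", "b"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="contiguous"):
            read_sequences(path)

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "alien.csv"
        pd.DataFrame(
            {
                "Seq": ["s", "s"],
                "Ind": ["x", "x"],
                "Pop": ["g", "g"],
                "Idx": [1, 2],
                "Act": ["a", "b"],
            }
        ).to_csv(path, index=False)
        sset = read_sequences(
            path,
            column_map={
                "sequence_id": "Seq",
                "subject_id": "Ind",
                "group": "Pop",
                "position": "Idx",
                "behavior": "Act",
            },
        )
        assert sset.sequences[0].actions == (1, 2)

    def test_codes_assigned_by_first_appearance(self, sequence_csv):
        path = sequence_csv([("s1", "x", "g", "cab")])
        sset = read_sequences(path)
        assert sset.ethogram.labels == ("c", "a", "b")
        assert sset.sequences[0].actions == (1, 2, 3)

    @given(
        words=st.lists(
            st.text(alphabet="abcdefg", min_size=1, max_size=30),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, words, tmp_path_factory):
        eth = Ethogram(tuple("abcdefg"))
        seqs = [
            ActionSequence(f"s{i}", "x", "g", codes(w))
            for i, w in enumerate(words)
        ]
        sset = SequenceSet(eth, seqs)
        path = tmp_path_factory.mktemp("rt") / "seqs.csv"
        write_sequences(sset, path)
        assert read_sequences(path, ethogram=eth).sequences == seqs


class TestEthogramIO:
    def test_round_trip(self, abc_ethogram, tmp_path):
        path = tmp_path / "eth.csv"
        write_ethogram(abc_ethogram, path)
        assert read_ethogram(path) == abc_ethogram

    def test_non_contiguous_codes_rejected(self, tmp_path):
        path = tmp_path / "eth.csv"
        pd.DataFrame({"code": [1, 3], "label": ["a", "b"]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="contiguous"):
            read_ethogram(path)


class TestFilterMinLength:
    def test_default_min_eight_filters_short(self, abc_ethogram):
        seqs = [
            ActionSequence(f"s{n}", "x", "g", tuple([1] * n))
            for n in (7, 8, 9)
        ]
        kept, n_removed = filter_min_length(SequenceSet(abc_ethogram, seqs))
        assert [len(s) for s in kept] == [8, 9]
        assert n_removed == 1

    def test_empty_set(self, abc_ethogram):
        kept, n_removed = filter_min_length(SequenceSet(abc_ethogram, []))
        assert len(kept) == 0 and n_removed == 0

    def test_min_one_is_identity(self, toy_set):
        kept, n_removed = filter_min_length(toy_set, 1)
        assert kept.sequences == toy_set.sequences
        assert n_removed == 0

    def test_min_len_zero_rejected(self, toy_set):
        with pytest.raises(ValueError):
            filter_min_length(toy_set, 0)


class TestBehaviorFrequencies:
    def test_single_sequence(self):
        eth = Ethogram(("a", "b"))
        sset = SequenceSet(eth, [ActionSequence("s", "x", "g", (1, 1, 2))])
        np.testing.assert_allclose(
            behavior_frequencies(sset), [2 / 3, 1 / 3]
        )

    def test_pooled_over_sequences(self):
        eth = Ethogram(("a", "b"))
        sset = SequenceSet(
            eth,
            [
                ActionSequence("s1", "x", "g", (1,)),
                ActionSequence("s2", "x", "g", (2,)),
            ],
        )
        np.testing.assert_allclose(behavior_frequencies(sset), [0.5, 0.5])

    def test_sums_to_one(self, toy_set):
        assert abs(behavior_frequencies(toy_set).sum() - 1.0) < 1e-12

    def test_law_of_large_numbers_uniform(self, abc_ethogram):
        rng = np.random.default_rng(0)
        actions = tuple(int(a) for a in rng.integers(1, 8, size=100_000))
        sset = SequenceSet(
            abc_ethogram, [ActionSequence("s", "x", "g", actions)]
        )
        freq = behavior_frequencies(sset)
        assert np.abs(freq - 1 / 7).max() < 0.01

    def test_empty_set_errors(self, abc_ethogram):
        with pytest.raises(ValueError):
            behavior_frequencies(SequenceSet(abc_ethogram, []))
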