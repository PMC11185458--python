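import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chunktag import agdesign
from chunktag.agdesign import (
    DesignError,
    SyllableInventory,
    TimingSpec,
    chunk_rate,
    default_inventory,
    epoch_length,
    make_across_stream,
    make_test_trials,
    make_within_stream,
    validate_events,
)


class TestInventory:
    def test_target_and_filler_lists(self, inventory):
        assert inventory.target_syllables[:3] == ("BA", "BO", "FA")
        assert inventory.filler_syllables[:3] == ("BI", "BU", "DE")
        assert len(inventory.target_syllables) == 12
        assert len(inventory.filler_syllables) == 12

    def test_dependency_pairs(self, inventory):
        assert inventory.dependency_pairs[0] == ("FU", "LA")
        assert inventory.dependency_pairs[3] == ("WE", "HO")
        assert len(inventory.dependency_pairs) == 4

    def test_label_counts(self, inventory):
        tokens = (
            list(inventory.target_syllables)
            + list(inventory.filler_syllables)
            + [s for p in inventory.dependency_pairs for s in p]
        )
        assert len(tokens) == 32
        assert len(set(tokens)) == 32  # no label reused anywhere

    def test_duplicate_label_rejected(self):
        with pytest.raises(DesignError):
            SyllableInventory(
                ("BA",) * 12, tuple(f"F{i}" for i in range(12)),
                (("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")),
            )

    def test_pair_member_overlap_rejected(self):
        with pytest.raises(DesignError):
            SyllableInventory(
                tuple(f"T{i}" for i in range(12)),
                tuple(f"F{i}" for i in range(12)),
                (("T0", "B"), ("C", "D"), ("E", "F"), ("G", "H")),
            )

    def test_unknown_pair_rejected(self, inventory):
        with pytest.raises(DesignError):
            inventory.pair_index(("XX", "YY"))


class TestTiming:
    def test_chunk_period_and_rate(self, timing):
        assert timing.chunk_period_s == pytest.approx(1.58)
        assert round(chunk_rate(timing), 2) == 0.63

    def test_epoch_length_eight_chunks(self, timing):
        assert epoch_length(timing, 8) == pytest.approx(12.64)

    def test_zero_boundary_silence(self):
        t = TimingSpec(boundary_silence_s=0.0)
        assert chunk_rate(t) == pytest.approx(1 / 1.5)

    def test_invalid_timing(self):
        with pytest.raises(DesignError):
            TimingSpec(syllable_dur_s=-1)
        with pytest.raises(DesignError):
            TimingSpec(chunk_size=0)


class TestWithinStream:
    def test_small_stream_structure(self, inventory, timing):
        table = make_within_stream(("FU", "LA"), 2, inventory, timing, seed=0)
        assert len(table) == 24
        assert table["chunk_index"].nunique() == 4
        for chunk in (0, 2):
            sub = table[table["chunk_index"] == chunk].set_index("position")
            assert sub.loc[2, "syllable"] == "FU"
            assert sub.loc[5, "syllable"] == "LA"
            assert sub.loc[2, "role"] == "dep_first"
            assert sub.loc[5, "role"] == "dep_second"
        for chunk in (1, 3):
            sub = table[table["chunk_index"] == chunk]
            assert (sub["role"] == "filler").all()
            assert sub["syllable"].isin(inventory.filler_syllables).all()

    def test_learning_audio_size(self, inventory, timing):
        table = make_within_stream(("FU", "LA"), 72, inventory, timing, seed=0)
        assert table["chunk_index"].nunique() == 144
        assert len(table) == 144 * 6

    def test_determinism(self, inventory, timing):
        a = make_within_stream(("FU", "LA"), 10, inventory, timing, seed=42)
        b = make_within_stream(("FU", "LA"), 10, inventory, timing, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_only_free_positions(self, inventory, timing):
        a = make_within_stream(("FU", "LA"), 10, inventory, timing, seed=1)
        b = make_within_stream(("FU", "LA"), 10, inventory, timing, seed=2)
        dep = a["role"].isin(["dep_first", "dep_second"])
        pd.testing.assert_frame_equal(a[dep], b[dep])
        assert (a["onset_s"] == b["onset_s"]).all()
        assert not (a["syllable"] == b["syllable"]).all()

    def test_timing_deltas(self, inventory, timing):
        table = make_within_stream(("FU", "LA"), 6, inventory, timing, seed=0)
        deltas = np.diff(table["onset_s"].to_numpy())
        boundary = np.diff(table["chunk_index"].to_numpy()) > 0
        np.testing.assert_allclose(deltas[~boundary], 0.25, atol=1e-9)
        np.testing.assert_allclose(deltas[boundary], 0.33, atol=1e-9)

    def test_balanced_syllable_usage(self, inventory, timing):
        table = make_within_stream(("FU", "LA"), 36, inventory, timing, seed=3)
        free = table[table["role"] == "other_target"]["syllable"].value_counts()
        assert free.max() - free.min() <= 1
        fillers = table[table["role"] == "filler"]["syllable"].value_counts()
        assert fillers.max() - fillers.min() <= 1

    def test_transitional_probability_one(self, inventory, timing):
        table = make_within_stream(("FU", "LA"), 20, inventory, timing, seed=5)
        firsts = table[table["role"] == "dep_first"]
        seconds = table[table["role"] == "dep_second"]
        assert len(firsts) == len(seconds) == 20
        offsets = seconds["onset_s"].to_numpy() - firsts["onset_s"].to_numpy()
        np.testing.assert_allclose(offsets, 3 * 0.25, atol=1e-9)
        # dep syllables never appear outside dependency roles
        free = table[~table["role"].isin(["dep_first", "dep_second"])]
        assert not free["syllable"].isin(["FU", "LA"]).any()

    def test_invalid_count(self, inventory, timing):
        with pytest.raises(DesignError):
            make_within_stream(("FU", "LA"), 0, inventory, timing, seed=0)

    def test_validates(self, inventory, timing):
        validate_events(make_within_stream(("FU", "LA"), 12, inventory, timing, 0), timing)


class TestAcrossStream:
    def test_small_stream_structure(self, inventory, timing):
        table = make_across_stream(("TA", "PI"), 2, inventory, timing, seed=0)
        assert len(table) == 12
        # 1-based event 5 is TA in chunk 0; event 8 is PI in chunk 1
        assert table.iloc[4]["syllable"] == "TA"
        assert table.iloc[4]["chunk_index"] == 0
        assert table.iloc[7]["syllable"] == "PI"
        assert table.iloc[7]["chunk_index"] == 1
        assert table.iloc[4]["role"] == "dep_first"
        assert table.iloc[7]["role"] == "dep_second"

    def test_dependency_onset_offset(self, inventory, timing):
        table = make_across_stream(("TA", "PI"), 2, inventory, timing, seed=0)
        t_first = table[table["role"] == "dep_first"]["onset_s"].iloc[0]
        t_second = table[table["role"] == "dep_second"]["onset_s"].iloc[0]
        assert t_second - t_first == pytest.approx(3 * 0.25 + 0.08)

    def test_learning_audio_size(self, inventory, timing):
        table = make_across_stream(("TA", "PI"), 144, inventory, timing, seed=0)
        assert table["chunk_index"].nunique() == 144
        assert (table["condition"] == "across").all()
        assert table["syllable"].isin(
            list(inventory.target_syllables) + ["TA", "PI"]
        ).all()

    def test_odd_count_rejected(self, inventory, timing):
        with pytest.raises(DesignError):
            make_across_stream(("TA", "PI"), 3, inventory, timing, seed=0)
        with pytest.raises(DesignError):
            make_across_stream(("TA", "PI"), 0, inventory, timing, seed=0)

    def test_balanced_usage(self, inventory, timing):
        table = make_across_stream(("TA", "PI"), 48, inventory, timing, seed=9)
        free = table[table["role"] == "other_target"]["syllable"].value_counts()
        assert free.max() - free.min() <= 1


class TestTestTrials:
    def test_default_counts(self, inventory, timing):
        trials = make_test_trials(seed=0)
        assert len(trials) == 144
        cells = {}
        for t in trials:
            cond = t["condition"].iloc[0]
            violated = (t["role"] == "dep_second_violation").any()
            cells[(cond, violated)] = cells.get((cond, violated), 0) + 1
        assert cells == {
            ("within", False): 36, ("within", True): 36,
            ("across", False): 36, ("across", True): 36,
        }

    def test_within_trial_has_eight_chunks(self, inventory, timing):
        trials = make_test_trials(seed=0, n_per_cell=2)
        within = [t for t in trials if t["condition"].iloc[0] == "within"]
        assert all(t["chunk_index"].nunique() == 8 for t in within)
        across = [t for t in trials if t["condition"].iloc[0] == "across"]
        assert all(t["chunk_index"].nunique() == 4 for t in across)

    def test_violation_roles(self):
        trials = make_test_trials(seed=1, n_per_cell=3)
        for t in trials:
            violated = (t["role"] == "dep_second_violation").any()
            if violated:
                assert not (t["role"] == "dep_second").any()
                assert (t["role"] == "dep_second_violation").sum() >= 1
            else:
                assert not (t["role"] == "dep_second_violation").any()

    def test_violation_syllable_is_other_pair(self, inventory):
        trials = make_test_trials(seed=2, n_per_cell=2)
        for t in trials:
            bad = t[t["role"] == "dep_second_violation"]
            if len(bad) == 0:
                continue
            cond = t["condition"].iloc[0]
            expected = "PI" if cond == "within" else "LA"
            assert (bad["syllable"] == expected).all()

    def test_order_randomized_but_deterministic(self):
        a = make_test_trials(seed=3, n_per_cell=4)
        b = make_test_trials(seed=3, n_per_cell=4)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = make_test_trials(seed=4, n_per_cell=4)
        conds_a = [t["condition"].iloc[0] for t in a]
        conds_c = [t["condition"].iloc[0] for t in c]
        assert conds_a != conds_c  # different shuffles

    def test_trial_index_records_order(self):
        trials = make_test_trials(seed=5, n_per_cell=2)
        assert [t["trial_index"].iloc[0] for t in trials] == list(range(len(trials)))


@settings(max_examples=25, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=8),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_stream_invariants_property(n, seed):
    timing = TimingSpec()
    for table in (
        make_within_stream(("FU", "LA"), n, seed=seed),
        make_across_stream(("KE", "MÖ"), 2 * n, seed=seed),
    ):
        validate_events(table, timing)
        onsets = table["onset_s"].to_numpy()
        assert np.all(np.diff(onsets) > 0)


def test_counting_check_epochs_per_condition():
    # 4 audios x 144 chunks / 8 chunks per epoch = 72 epochs per condition
    timing = TimingSpec()
    n_chunks = 0
    for seed in range(4):
        n_chunks += make_across_stream(("TA", "PI"), 144, seed=seed)["chunk_index"].nunique()
    assert n_chunks // 8 == 72
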