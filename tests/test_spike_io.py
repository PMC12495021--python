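import logging

import numpy as np
import pandas as pd
import pytest

import spikegraph as sg
from spikegraph.errors import FormatError, ParameterError, ScheduleError


def make_set(spikes_by_channel, duration):
    return sg.SpikeTrainSet(
        channel_ids=sorted(spikes_by_channel),
        spikes={ch: np.asarray(t, dtype=float) for ch, t in spikes_by_channel.items()},
        duration_s=duration,
    )


class TestSpikeTableIO:
    def test_round_trip_preserves_content(self, tmp_path):
        st = make_set({1: [0.5, 1.25, 3.000001], 7: [2.0]}, 5.0)
        path = tmp_path / "spikes.csv"
        sg.write_spike_table(st, path)
        back = sg.read_spike_table(path, duration_s=5.0)
        assert back.channel_ids == st.channel_ids
        for ch in st.channel_ids:
            np.testing.assert_allclose(back.spikes[ch], st.spikes[ch], atol=1e-9)

    def test_round_trip_bitwise_stable(self, tmp_path):
        st = make_set({1: [0.123456, 2.5]}, 3.0)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        sg.write_spike_table(st, p1)
        sg.write_spike_table(sg.read_spike_table(p1, duration_s=3.0), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unsorted_input_sorted_with_warning(self, tmp_path, caplog):
        path = tmp_path / "s.csv"
        path.write_text("channel,time_s\n1,2.0\n1,1.0\n")
        with caplog.at_level(logging.WARNING):
            st = sg.read_spike_table(path)
        assert list(st.spikes[1]) == [1.0, 2.0]
        assert any("out of order" in r.message for r in caplog.records)

    def test_duplicates_collapsed_with_warning(self, tmp_path, caplog):
        path = tmp_path / "s.csv"
        path.write_text("channel,time_s\n1,1.0\n1,1.0\n1,2.0\n")
        with caplog.at_level(logging.WARNING):
            st = sg.read_spike_table(path)
        assert list(st.spikes[1]) == [1.0, 2.0]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("channel,time_s\n")
        with pytest.raises(FormatError, match="no records"):
            sg.read_spike_table(path)

    def test_bad_rows_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("channel,time_s\n1,1.0\n1,oops\n")
        with pytest.raises(FormatError, match="line 3"):
            sg.read_spike_table(path)
        path.write_text("channel,time_s\n1,-1.0\n")
        with pytest.raises(FormatError, match="negative"):
            sg.read_spike_table(path)


class TestSegmentExtraction:
    def test_single_interval_is_identity(self):
        st = make_set({1: [0.5, 3.2]}, 6.0)
        sched = sg.StimulusSchedule(
            entries=pd.DataFrame(
                {"stimulus_id": [1], "trial_index": [0], "start_s": [0.0], "end_s": [6.0]}
            )
        )
        seg = sg.extract_stimulus_segments(st, sched, 1)
        np.testing.assert_allclose(seg.spikes[1], [0.5, 3.2])
        assert seg.duration_s == 6.0

    def test_concatenation_offsets(self):
        # spike at 11.5 in the second of intervals [0,6) and [10,16) -> 7.5
        st = make_set({1: [2.0, 11.5]}, 20.0)
        sched = sg.StimulusSchedule(
            entries=pd.DataFrame(
                {"stimulus_id": [1, 1], "trial_index": [0, 1],
                 "start_s": [0.0, 10.0], "end_s": [6.0, 16.0]}
            )
        )
        seg = sg.extract_stimulus_segments(st, sched, 1)
        np.testing.assert_allclose(seg.spikes[1], [2.0, 7.5])
        assert seg.duration_s == 12.0

    def test_twenty_six_second_trials_give_120s(self):
        starts = np.arange(20) * 10.0
        sched = sg.StimulusSchedule(
            entries=pd.DataFrame(
                {"stimulus_id": 1, "trial_index": range(20),
                 "start_s": starts, "end_s": starts + 6.0}
            )
        )
        st = make_set({1: [0.5]}, 200.0)
        seg = sg.extract_stimulus_segments(st, sched, 1)
        assert seg.duration_s == pytest.approx(120.0)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ScheduleError, match="overlap"):
            sg.StimulusSchedule(
                entries=pd.DataFrame(
                    {"stimulus_id": [1, 1], "trial_index": [0, 1],
                     "start_s": [0.0, 5.0], "end_s": [6.0, 11.0]}
                )
            )

    def test_missing_stimulus_rejected(self):
        st = make_set({1: [0.5]}, 6.0)
        sched = sg.StimulusSchedule(
            entries=pd.DataFrame(
                {"stimulus_id": [1], "trial_index": [0], "start_s": [0.0], "end_s": [6.0]}
            )
        )
        with pytest.raises(ScheduleError, match="no intervals"):
            sg.extract_stimulus_segments(st, sched, 99)

    def test_extraction_matches_direct_filtering_of_simulation(self):
        """Segments pulled from a simulated session equal the spikes generated
        inside those intervals (oracle: direct per-interval filtering)."""
        truth = sg.GroundTruthGraph(n_nodes=3, edges=frozenset(), weights={})
        base = sg.BaselineConfig(isi_family="poisson", target_rate_hz=10.0)
        spikes, sched = sg.simulate_stimulus_session(
            {1: truth, 2: truth}, base, sg.KernelConfig(),
            n_trials=4, trial_s=3.0, gap_s=1.0, seed=9,
        )
        seg = sg.extract_stimulus_segments(spikes, sched, 1)
        iv = sched.intervals_for(1)
        for ch in spikes.channel_ids:
            expected = []
            offset = 0.0
            for _, row in iv.iterrows():
                t = spikes.spikes[ch]
                inside = t[(t >= row.start_s) & (t < row.end_s)]
                expected.extend(inside - row.start_s + offset)
                offset += row.end_s - row.start_s
            np.testing.assert_allclose(seg.spikes[ch], expected)

    def test_interior_isis_preserved_by_concatenation(self):
        """Only boundary-spanning inter-spike intervals are altered."""
        st = make_set({1: [1.0, 2.5, 3.0, 10.5, 11.0]}, 20.0)
        sched = sg.StimulusSchedule(
            entries=pd.DataFrame(
                {"stimulus_id": [1, 1], "trial_index": [0, 1],
                 "start_s": [0.0, 10.0], "end_s": [6.0, 16.0]}
            )
        )
        seg = sg.extract_stimulus_segments(st, sched, 1)
        isis_in = np.diff([1.0, 2.5, 3.0])
        isis_out = np.diff(seg.spikes[1])
        np.testing.assert_allclose(isis_out[:2], isis_in)
        np.testing.assert_allclose(isis_out[-1], 0.5)  # interior ISI of trial 2


class TestOutlierScreen:
    def test_published_rate_table_flags_4_5_29(self, rate_table_published):
        assert sg.flag_outlier_channels(rate_table_published) == {4, 5, 29}

    def test_uniform_rates_flag_nothing(self):
        rates = pd.DataFrame(10.0, index=range(1, 6), columns=range(1, 4))
        assert sg.flag_outlier_channels(rates) == set()

    def test_single_stimulus_excursion_is_enough(self):
        rates = pd.DataFrame(10.0, index=range(1, 6), columns=range(1, 4))
        rates.loc[3, 2] = 25.0
        assert sg.flag_outlier_channels(rates) == {3}

    def test_floor_flags_silent_channels(self):
        rates = pd.DataFrame(10.0, index=range(1, 4), columns=range(1, 3))
        rates.loc[2] = 0.2
        assert sg.flag_outlier_channels(rates, floor_hz=0.5) == {2}

    def test_bad_thresholds_rejected(self):
        rates = pd.DataFrame(10.0, index=[1], columns=[1])
        with pytest.raises(ParameterError):
            sg.flag_outlier_channels(rates, ceiling_hz=1.0, floor_hz=2.0)


class TestDropChannels:
    def test_labels_preserved(self):
        st = make_set({ch: [0.5] for ch in range(1, 33)}, 1.0)
        kept = sg.drop_channels(st, {4, 5, 29})
        assert kept.n_channels == 29
        assert kept.channel_ids == [ch for ch in range(1, 33) if ch not in (4, 5, 29)]

    def test_drop_nothing_is_identity(self):
        st = make_set({1: [0.1], 2: [0.2]}, 1.0)
        assert sg.drop_channels(st, set()).channel_ids == [1, 2]

    def test_drop_all_rejected(self):
        st = make_set({1: [0.1]}, 1.0)
        with pytest.raises(ParameterError, match="no channels remain"):
            sg.drop_channels(st, {1})

    def test_unknown_id_rejected(self):
        st = make_set({1: [0.1]}, 1.0)
        with pytest.raises(ParameterError, match="unknown"):
            sg.drop_channels(st, {2})
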