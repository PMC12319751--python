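"""Domain containers, fixture/FIF I/O and signal-level operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from miclean import (
    ChannelInfo,
    ChannelKind,
    EventTable,
    FixtureFormatError,
    Recording,
    ValidationError,
    average_epochs,
    concat_task,
    downsample,
    extract_epochs,
    pick_channels,
    read_fif,
    read_fixture,
    write_fixture,
)
from conftest import make_events, make_grad_recording


class TestRecordingInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            Recording(200.0, [ChannelInfo("a", ChannelKind.emg)], np.zeros((2, 10)))

    def test_duplicate_names_rejected(self):
        chans = [ChannelInfo("a", ChannelKind.emg), ChannelInfo("a", ChannelKind.emg)]
        with pytest.raises(ValidationError):
            Recording(200.0, chans, np.zeros((2, 10)))

    def test_incomplete_grad_pair_rejected(self):
        chans = [ChannelInfo("a", ChannelKind.grad, pair_id=0)]
        with pytest.raises(ValidationError):
            Recording(200.0, chans, np.zeros((1, 10)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            Recording(200.0, [ChannelInfo("a", ChannelKind.emg)], np.full((1, 5), np.nan))


class TestFixtureRoundTrip:
    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), n_pairs=st.integers(1, 4), n_ev=st.integers(0, 5))
    def test_round_trip_lossless(self, tmp_path_factory, seed, n_pairs, n_ev):
        """Data, channel metadata and events survive a write/read cycle exactly."""
        rng = np.random.default_rng(seed)
        rec = make_grad_recording(n_pairs=n_pairs, n_samples=50, seed=seed)
        onsets = np.sort(rng.choice(50, size=n_ev, replace=False)) if n_ev else []
        events = make_events(onsets)
        path = tmp_path_factory.mktemp("fx") / "r.h5"
        write_fixture(rec, events, path)
        rec2, events2 = read_fixture(path)
        np.testing.assert_array_equal(rec.data, rec2.data)
        assert rec.channels == rec2.channels
        assert rec.sfreq == rec2.sfreq
        pd.testing.assert_frame_equal(events.events, events2.events)

    def test_missing_events_group_is_error(self, tmp_path):
        import h5py

        rec = make_grad_recording()
        path = tmp_path / "r.h5"
        write_fixture(rec, EventTable.empty(), path)
        with h5py.File(path, "a") as f:
            del f["events"]
        with pytest.raises(FixtureFormatError, match="events"):
            read_fixture(path)

    def test_version_mismatch_names_versions(self, tmp_path):
        import h5py

        rec = make_grad_recording()
        path = tmp_path / "r.h5"
        write_fixture(rec, EventTable.empty(), path)
        with h5py.File(path, "a") as f:
            f["meta"].attrs["format_version"] = 99
        with pytest.raises(FixtureFormatError, match="99"):
            read_fixture(path)


class TestFifIngestion:
    def _write_fif(self, path, n_grad=204, n_emg=4, events=()):
        import mne

        names = [f"MEG{i // 2:03d}{2 + i % 2}" for i in range(n_grad)]
        names += [f"EMG{i + 1:03d}" for i in range(n_emg)] + ["STI101"]
        info = mne.create_info(
            names, 200.0, ch_types=["grad"] * n_grad + ["emg"] * n_emg + ["stim"]
        )
        data = np.random.default_rng(0).standard_normal((len(names), 1000)) * 1e-12
        data[-1] = 0.0
        for onset, code in events:
            data[-1, onset : onset + 10] = code
        raw = mne.io.RawArray(data, info, verbose="error")
        raw.save(path, verbose="error")

    def test_fixture_fif_round_trip(self, tmp_path):
        """A 204-gradiometer + 4-EMG file reads back with pairs resolved."""
        path = tmp_path / "test_raw.fif"
        self._write_fif(path, events=[(100, 1), (500, 2)])
        rec, events = read_fif(path, event_id={1: ("picture", "vocal"), 2: ("G1", "gesture")})
        assert rec.n_channels == 208
        grads = [c for c in rec.channels if c.kind is ChannelKind.grad]
        assert len(grads) == 204
        pair_sizes = pd.Series([c.pair_id for c in grads]).value_counts()
        assert (pair_sizes == 2).all()
        assert list(events.events["label"]) == ["picture", "G1"]

    def test_no_events_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty_raw.fif"
        self._write_fif(path, n_grad=4, events=[])
        _, events = read_fif(path)
        assert len(events) == 0

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_fif(tmp_path / "nope.fif")


class TestPickChannels:
    def test_pick_grad_from_mixed(self):
        rec = make_grad_recording(n_pairs=2)
        emg = Recording(
            200.0, [ChannelInfo("E1", ChannelKind.emg)], np.zeros((1, rec.n_samples))
        )
        merged = Recording(200.0, rec.channels + emg.channels, np.vstack([rec.data, emg.data]))
        picked = pick_channels(merged, {ChannelKind.grad})
        assert picked.n_channels == 4
        np.testing.assert_array_equal(picked.data, rec.data)

    def test_pick_all_is_identity(self):
        rec = make_grad_recording()
        picked = pick_channels(rec, {ChannelKind.grad})
        assert picked.channels == rec.channels

    def test_missing_kind_is_error(self):
        with pytest.raises(ValidationError):
            pick_channels(make_grad_recording(), {ChannelKind.mag})


class TestConcat:
    def test_three_runs_concatenate_with_seams(self):
        runs = [make_grad_recording(n_samples=2000, seed=s) for s in range(3)]
        events = [make_events([100], run=r) for r in range(3)]
        out, table = concat_task(runs, events)
        assert out.n_samples == 6000
        assert out.seams == (2000, 4000)
        assert list(table.events["onset_sample"]) == [100, 2100, 4100]

    def test_single_input_is_identity(self):
        rec = make_grad_recording()
        out, _ = concat_task([rec], [make_events([5])])
        np.testing.assert_array_equal(out.data, rec.data)
        assert out.seams == ()

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValidationError):
            concat_task(
                [make_grad_recording(n_pairs=2), make_grad_recording(n_pairs=3)],
                [EventTable.empty(), EventTable.empty()],
            )


class TestDownsample:
    def _sine(self, freq, sfreq=1000.0, dur=10.0, n_pairs=1):
        t = np.arange(int(dur * sfreq)) / sfreq
        base = make_grad_recording(n_pairs=n_pairs, n_samples=len(t), sfreq=sfreq)
        base.data[:] = np.sin(2 * np.pi * freq * t)
        return base

    def test_sample_count_1000_to_200(self):
        out = downsample(self._sine(5.0), 200.0)
        assert out.sfreq == 200.0
        assert out.n_samples == 2000

    def test_passband_sine_amplitude_preserved(self):
        """A 5 Hz sinusoid survives decimation with < 1 % amplitude error."""
        out = downsample(self._sine(5.0), 200.0)
        # compare against the analytic signal on the decimated grid
        t = np.arange(out.n_samples) / 200.0
        ref = np.sin(2 * np.pi * 5.0 * t)
        amp = np.dot(out.data[0], ref) / np.dot(ref, ref)
        assert abs(amp - 1.0) < 0.01

    def test_stopband_attenuated_passband_kept(self):
        """90 Hz (< new Nyquist) survives; 150 Hz is attenuated > 20 dB."""
        out90 = downsample(self._sine(90.0), 200.0)
        out150 = downsample(self._sine(150.0), 200.0)
        rms_in = np.sqrt(0.5)  # RMS of a unit sine
        assert np.std(out90.data[0]) > 0.5 * rms_in
        assert np.std(out150.data[0]) < 0.1 * rms_in

    def test_events_rescaled_round_half_even(self):
        # 1002/4 = 250.5 -> 250 (half to even), 1006/4 = 251.5 -> 252
        _, ev = downsample(self._sine(5.0), 250.0, make_events([1002, 1006, 2000]))
        assert list(ev.events["onset_sample"]) == [250, 252, 500]

    def test_upsampling_rejected(self):
        with pytest.raises(ValidationError):
            downsample(make_grad_recording(), 400.0)


class TestEpochs:
    def test_epoch_extraction_shape_and_halfopen_window(self):
        rec = make_grad_recording(n_samples=4000)
        events = make_events([100, 1000, 2000])
        ep = extract_epochs(rec, events, 0.0, 1.5)
        assert ep.data.shape == (3, rec.n_channels, 300)
        np.testing.assert_array_equal(ep.data[0], rec.data[:, 100:400])

    def test_out_of_bounds_epoch_dropped(self, caplog):
        rec = make_grad_recording(n_samples=1000)
        events = make_events([100, 980])  # second one ends past the recording
        ep = extract_epochs(rec, events, 0.0, 0.5)
        assert ep.n_epochs == 1

    def test_seam_straddling_epoch_dropped(self):
        runs = [make_grad_recording(n_samples=1000, seed=s) for s in range(2)]
        rec, _ = concat_task(runs, [EventTable.empty()] * 2)
        ep = extract_epochs(rec, make_events([950]), 0.0, 0.5)
        assert ep.n_epochs == 0

    def test_zero_matches_is_valid_empty(self):
        rec = make_grad_recording()
        ep = extract_epochs(rec, EventTable.empty(), 0.0, 0.5)
        assert ep.n_epochs == 0

    def test_average_equals_brute_force(self):
        rec = make_grad_recording(n_samples=4000)
        ep = extract_epochs(rec, make_events(np.arange(10) * 350), 0.0, 1.0)
        ev = average_epochs(ep)
        np.testing.assert_allclose(ev.data, sum(ep.data) / 10, atol=1e-14)
        assert ev.nave == 10

    def test_opposite_epochs_average_to_zero(self):
        rec = make_grad_recording(n_samples=1000)
        rec.data[:, 100:200] = 1.0
        rec.data[:, 300:400] = -1.0
        ep = extract_epochs(rec, make_events([100, 300]), 0.0, 0.5)
        assert abs(average_epochs(ep).data.mean()) < 1e-12

    def test_constant_data_average_is_exact(self):
        rec = make_grad_recording(n_samples=1000)
        rec.data[:] = 3.25
        ep = extract_epochs(rec, make_events([10, 400, 700]), 0.0, 0.5)
        assert (average_epochs(ep).data == 3.25).all()

    def test_empty_average_rejected(self):
        rec = make_grad_recording()
        ep = extract_epochs(rec, EventTable.empty(), 0.0, 0.5)
        with pytest.raises(ValidationError):
            average_epochs(ep)


def test_concat_commutes_with_downsample():
    """concat(downsample(r)) == downsample(concat(r)) away from seams."""
    runs = [make_grad_recording(n_samples=5000, sfreq=1000.0, seed=s) for s in range(2)]
    events = [EventTable.empty()] * 2
    a, _ = concat_task([downsample(r, 200.0) for r in runs], events)
    b = downsample(concat_task(runs, events)[0], 200.0)
    # the zero-phase filter differs near the seam/edges; compare the interior
    interior = slice(50, 950)
    np.testing.assert_allclose(a.data[:, interior], b.data[:, interior], atol=1e-3)
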