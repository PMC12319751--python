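"""Domain containers for MEG/EMG recordings, events, epochs and evoked responses.

The pipeline operates on planar-gradiometer MEG co-recorded with facial
surface EMG.  A :class:`Recording` holds the multichannel time series with
per-channel metadata; an :class:`EventTable` holds paradigm events (gesture
cues, picture onsets) and the task-block intervals they belong to.  Epoching
uses 0-based sample indexing and half-open windows ``[tmin, tmax)``.

I/O goes through two routes: the standard Neuromag FIF format (via MNE) for
real acquisitions, and a portable HDF5 fixture container for synthetic data
and intermediate results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

FIXTURE_FORMAT_VERSION = 1

#: labels an EventTable accepts
EVENT_LABELS = frozenset({f"G{i}" for i in range(1, 11)} | {"picture"})
#: task vocabulary
TASKS = ("gesture", "vocal", "silent", "observation")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FixtureFormatError(IOError):
    """Raised when a fixture file is missing groups or has a wrong version."""


class ChannelKind(str, Enum):
    grad = "grad"
    mag = "mag"
    emg = "emg"
    eog = "eog"
    ecg = "ecg"
    stim = "stim"


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one channel.

    ``pair_id`` groups the two planar gradiometers of one sensor element;
    ``position`` is a 2-D layout coordinate used for adjacency/topography.
    """

    name: str
    kind: ChannelKind
    pair_id: int | None = None
    position: tuple[float, float] | None = None


def _validate_channels(channels: Sequence[ChannelInfo]) -> None:
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise ValidationError("channel names must be unique within a recording")
    pair_counts: dict[int, int] = {}
    for c in channels:
        if c.kind is ChannelKind.grad:
            if c.pair_id is None:
                raise ValidationError(f"grad channel {c.name!r} has no pair_id")
            pair_counts[c.pair_id] = pair_counts.get(c.pair_id, 0) + 1
    bad = {pid: n for pid, n in pair_counts.items() if n != 2}
    if bad:
        raise ValidationError(f"gradiometer pairs must have exactly 2 members, got {bad}")


@dataclass
class Recording:
    """Multichannel time series with channel metadata.

    data is ``[n_channels, n_samples]`` in physical units (T/m for
    gradiometers, V for EMG).  ``seams`` marks sample indices where
    independently recorded runs were concatenated; epochs never straddle them.
    """

    sfreq: float
    channels: list[ChannelInfo]
    data: np.ndarray
    first_sample_time: float = 0.0
    seams: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"but {len(self.channels)} channels are declared"
            )
        if not self.sfreq > 0:
            raise ValidationError("sfreq must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording data must be finite")
        _validate_channels(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def copy(self) -> "Recording":
        return Recording(
            sfreq=self.sfreq,
            channels=list(self.channels),
            data=self.data.copy(),
            first_sample_time=self.first_sample_time,
            seams=self.seams,
        )


_EVENT_COLUMNS = ["onset_sample", "label", "task", "run", "block"]
_BLOCK_COLUMNS = ["task", "run", "block", "start_sample", "end_sample"]


@dataclass
class EventTable:
    """Paradigm events plus the task-block intervals that contain them.

    ``events`` columns: onset_sample, label (G1..G10 | picture), task, run,
    block.  ``blocks`` columns: task, run, block, start_sample, end_sample —
    used to restrict analyses to task samples.
    """

    events: pd.DataFrame
    blocks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_BLOCK_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.events = pd.DataFrame(self.events, columns=_EVENT_COLUMNS).reset_index(
            drop=True
        )
        self.blocks = pd.DataFrame(self.blocks, columns=_BLOCK_COLUMNS).reset_index(
            drop=True
        )
        for col in ("onset_sample", "run", "block"):
            self.events[col] = self.events[col].astype(np.int64, copy=False)
        if len(self.events):
            bad_labels = set(self.events["label"]) - EVENT_LABELS
            if bad_labels:
                raise ValidationError(f"unknown event labels: {sorted(bad_labels)}")
            bad_tasks = set(self.events["task"]) - set(TASKS)
            if bad_tasks:
                raise ValidationError(f"unknown tasks: {sorted(bad_tasks)}")
            for run, grp in self.events.groupby("run"):
                onsets = grp["onset_sample"].to_numpy()
                if np.any(np.diff(onsets) <= 0):
                    raise ValidationError(
                        f"event onsets must be strictly increasing within run {run}"
                    )
        for col in ("start_sample", "end_sample", "run", "block"):
            self.blocks[col] = self.blocks[col].astype(np.int64, copy=False)

    def __len__(self) -> int:
        return len(self.events)

    def select(self, task: str | None = None, label: str | None = None) -> "EventTable":
        ev = self.events
        if task is not None:
            ev = ev[ev["task"] == task]
        if label is not None:
            ev = ev[ev["label"] == label]
        bl = self.blocks
        if task is not None and len(bl):
            bl = bl[bl["task"] == task]
        return EventTable(ev.copy(), bl.copy())

    def shifted(self, offset: int) -> "EventTable":
        ev = self.events.copy()
        bl = self.blocks.copy()
        if len(ev):
            ev["onset_sample"] += offset
        if len(bl):
            bl["start_sample"] += offset
            bl["end_sample"] += offset
        return EventTable(ev, bl)

    def task_mask(self, task: str, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask covering all blocks of ``task``."""
        mask = np.zeros(n_samples, dtype=bool)
        for _, row in self.blocks[self.blocks["task"] == task].iterrows():
            mask[max(0, row["start_sample"]) : min(n_samples, row["end_sample"])] = True
        return mask

    @staticmethod
    def empty() -> "EventTable":
        return EventTable(pd.DataFrame(columns=_EVENT_COLUMNS))


@dataclass
class EpochSet:
    """Stack of fixed-length windows aligned to events, ``[n_epochs, n_channels, n_times]``."""

    data: np.ndarray
    tmin: float
    tmax: float
    sfreq: float
    channels: list[ChannelInfo]
    event_refs: np.ndarray
    baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.event_refs = np.asarray(self.event_refs, dtype=np.int64)
        n_times = int(round((self.tmax - self.tmin) * self.sfreq))
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be 3-D [epochs, channels, times]")
        if self.data.shape[2] != n_times:
            raise ValidationError(
                f"n_times {self.data.shape[2]} != round((tmax-tmin)*sfreq) = {n_times}"
            )
        if self.data.shape[1] != len(self.channels):
            raise ValidationError("channel count mismatch in EpochSet")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq


@dataclass
class Evoked:
    """Average of stimulus-locked epochs, ``[n_channels, n_times]``."""

    data: np.ndarray
    nave: int
    tmin: float
    sfreq: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.nave < 1:
            raise ValidationError("nave must be >= 1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValidationError("evoked data must be [n_channels, n_times]")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.sfreq


# ---------------------------------------------------------------------------
# FIF ingestion
# ---------------------------------------------------------------------------

_FIF_KIND_MAP = {
    "grad": ChannelKind.grad,
    "mag": ChannelKind.mag,
    "emg": ChannelKind.emg,
    "eog": ChannelKind.eog,
    "ecg": ChannelKind.ecg,
    "stim": ChannelKind.stim,
}


def read_fif(
    path: str | Path,
    event_id: Mapping[int, tuple[str, str]] | None = None,
) -> tuple[Recording, EventTable]:
    """Read a Neuromag FIF file into a :class:`Recording` and :class:`EventTable`.

    Channel kinds are inferred from the FIF channel types; stim-channel
    transitions become events.  ``event_id`` maps trigger codes to
    ``(label, task)`` pairs; unmapped codes are dropped with a warning.
    Gradiometer pair ids are assigned from sensor-element naming (the two
    gradiometers of one element share all but the last name character).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"FIF file not found: {path}")
    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    types = raw.get_channel_types()

    channels: list[ChannelInfo] = []
    keep_idx: list[int] = []
    pair_ids: dict[str, int] = {}
    for i, (name, typ) in enumerate(zip(raw.ch_names, types)):
        kind = _FIF_KIND_MAP.get(typ)
        if kind is None or kind is ChannelKind.stim:
            # stim channels are consumed into the EventTable below
            logger.info("not retaining channel %s of type %s", name, typ)
            continue
        pair_id = None
        position = None
        if kind is ChannelKind.grad:
            key = name[:-1]
            pair_id = pair_ids.setdefault(key, len(pair_ids))
            loc = raw.info["chs"][i]["loc"][:2]
            if np.all(np.isfinite(loc)) and np.any(loc != 0):
                position = (float(loc[0]), float(loc[1]))
        channels.append(ChannelInfo(name, kind, pair_id, position))
        keep_idx.append(i)
    if not any(c.kind is ChannelKind.grad for c in channels):
        raise ValidationError(f"no gradiometer channels in {path}")

    data = raw.get_data()[keep_idx]
    recording = Recording(
        sfreq=float(raw.info["sfreq"]),
        channels=channels,
        data=data,
        first_sample_time=float(raw.first_samp) / float(raw.info["sfreq"]),
    )

    rows = []
    if any(t == "stim" for t in types):
        events = mne.find_events(raw, shortest_event=1, verbose="error")
        for onset, _, code in events:
            if event_id is not None and code in event_id:
                label, task = event_id[code]
            elif event_id is not None:
                logger.warning("dropping event with unmapped trigger code %d", code)
                continue
            else:
                label, task = "picture", "vocal"
            rows.append(
                {
                    "onset_sample": int(onset - raw.first_samp),
                    "label": label,
                    "task": task,
                    "run": 0,
                    "block": 0,
                }
            )
    table = EventTable(pd.DataFrame(rows, columns=_EVENT_COLUMNS))
    return recording, table


# ---------------------------------------------------------------------------
# Fixture container (portable HDF5)
# ---------------------------------------------------------------------------


def write_fixture(
    recording: Recording, events: EventTable, path: str | Path
) -> None:
    """Write a lossless HDF5 fixture: /data, /channels, /events, /blocks, /meta."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FIXTURE_FORMAT_VERSION
        meta.attrs["sfreq"] = recording.sfreq
        meta.attrs["first_sample_time"] = recording.first_sample_time
        meta.create_dataset("seams", data=np.asarray(recording.seams, dtype=np.int64))
        f.create_dataset("data", data=recording.data)
        ch = f.create_group("channels")
        ch.create_dataset(
            "name", data=np.array([c.name for c in recording.channels], dtype="S64")
        )
        ch.create_dataset(
            "kind",
            data=np.array([c.kind.value for c in recording.channels], dtype="S8"),
        )
        ch.create_dataset(
            "pair_id",
            data=np.array(
                [-1 if c.pair_id is None else c.pair_id for c in recording.channels],
                dtype=np.int64,
            ),
        )
        pos = np.full((recording.n_channels, 2), np.nan)
        for i, c in enumerate(recording.channels):
            if c.position is not None:
                pos[i] = c.position
        ch.create_dataset("position", data=pos)
        ev = f.create_group("events")
        ev.create_dataset("onset_sample", data=events.events["onset_sample"].to_numpy(np.int64))
        ev.create_dataset("label", data=events.events["label"].to_numpy("S16"))
        ev.create_dataset("task", data=events.events["task"].to_numpy("S16"))
        ev.create_dataset("run", data=events.events["run"].to_numpy(np.int64))
        ev.create_dataset("block", data=events.events["block"].to_numpy(np.int64))
        bl = f.create_group("blocks")
        bl.create_dataset("task", data=events.blocks["task"].to_numpy("S16"))
        bl.create_dataset("run", data=events.blocks["run"].to_numpy(np.int64))
        bl.create_dataset("block", data=events.blocks["block"].to_numpy(np.int64))
        bl.create_dataset("start_sample", data=events.blocks["start_sample"].to_numpy(np.int64))
        bl.create_dataset("end_sample", data=events.blocks["end_sample"].to_numpy(np.int64))


def read_fixture(path: str | Path) -> tuple[Recording, EventTable]:
    """Read a fixture written by :func:`write_fixture` (lossless round trip)."""
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise FixtureFormatError(f"{path}: missing /meta group")
        version = int(f["meta"].attrs["format_version"])
        if version != FIXTURE_FORMAT_VERSION:
            raise FixtureFormatError(
                f"{path}: fixture format version {version} found, "
                f"expected {FIXTURE_FORMAT_VERSION}"
            )
        if "events" not in f:
            raise FixtureFormatError(f"{path}: missing /events group")
        data = f["data"][()]
        names = [n.decode() for n in f["channels/name"][()]]
        kinds = [k.decode() for k in f["channels/kind"][()]]
        pids = f["channels/pair_id"][()]
        pos = f["channels/position"][()]
        channels = [
            ChannelInfo(
                name=names[i],
                kind=ChannelKind(kinds[i]),
                pair_id=None if pids[i] < 0 else int(pids[i]),
                position=None if np.any(np.isnan(pos[i])) else (pos[i][0], pos[i][1]),
            )
            for i in range(len(names))
        ]
        recording = Recording(
            sfreq=float(f["meta"].attrs["sfreq"]),
            channels=channels,
            data=data,
            first_sample_time=float(f["meta"].attrs["first_sample_time"]),
            seams=tuple(int(s) for s in f["meta/seams"][()]),
        )
        ev = pd.DataFrame(
            {
                "onset_sample": f["events/onset_sample"][()],
                "label": [s.decode() for s in f["events/label"][()]],
                "task": [s.decode() for s in f["events/task"][()]],
                "run": f["events/run"][()],
                "block": f["events/block"][()],
            }
        )
        bl = pd.DataFrame(
            {
                "task": [s.decode() for s in f["blocks/task"][()]],
                "run": f["blocks/run"][()],
                "block": f["blocks/block"][()],
                "start_sample": f["blocks/start_sample"][()],
                "end_sample": f["blocks/end_sample"][()],
            }
        )
    return recording, EventTable(ev, bl)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def pick_channels(
    recording: Recording, kinds: Iterable[ChannelKind | str]
) -> Recording:
    """Sub-recording with only the requested channel kinds, order preserved."""
    wanted = {ChannelKind(k) for k in kinds}
    idx = [i for i, c in enumerate(recording.channels) if c.kind in wanted]
    if not idx:
        raise ValidationError(f"no channels of kinds {sorted(k.value for k in wanted)}")
    return Recording(
        sfreq=recording.sfreq,
        channels=[recording.channels[i] for i in idx],
        data=recording.data[idx].copy(),
        first_sample_time=recording.first_sample_time,
        seams=recording.seams,
    )


def concat_task(
    recordings: Sequence[Recording], events: Sequence[EventTable]
) -> tuple[Recording, EventTable]:
    """Concatenate runs along time, re-offsetting events and marking seams."""
    if len(recordings) != len(events) or not recordings:
        raise ValidationError("need equally many, and at least one, recordings/events")
    ref = recordings[0]
    for r in recordings[1:]:
        if r.sfreq != ref.sfreq:
            raise ValidationError("sampling rates differ across runs")
        if r.channel_names() != ref.channel_names() or [
            c.kind for c in r.channels
        ] != [c.kind for c in ref.channels]:
            raise ValidationError("channel sets differ across runs")
    offsets = np.concatenate([[0], np.cumsum([r.n_samples for r in recordings])])
    seams: list[int] = []
    for r, off in zip(recordings, offsets[:-1]):
        seams.extend(int(off) + s for s in r.seams)
    seams.extend(int(o) for o in offsets[1:-1])
    shifted = [t.shifted(int(off)) for t, off in zip(events, offsets[:-1])]
    table = EventTable(
        pd.concat([t.events for t in shifted], ignore_index=True),
        pd.concat([t.blocks for t in shifted], ignore_index=True),
    )
    out = Recording(
        sfreq=ref.sfreq,
        channels=list(ref.channels),
        data=np.concatenate([r.data for r in recordings], axis=1),
        first_sample_time=ref.first_sample_time,
        seams=tuple(sorted(seams)),
    )
    return out, table


def downsample(
    recording: Recording,
    target_sfreq: float,
    events: EventTable | None = None,
) -> Recording | tuple[Recording, EventTable]:
    """Anti-alias low-pass then decimate to ``target_sfreq``.

    The FIR anti-alias filter has its passband edge at 0.9x the target
    Nyquist and is applied zero-phase.  Event onsets are rescaled with
    round-half-to-even when ``events`` is given.
    """
    if target_sfreq >= recording.sfreq:
        raise ValidationError("target_sfreq must be below the current rate")
    ratio = recording.sfreq / target_sfreq
    q = int(round(ratio))
    nyq = target_sfreq / 2.0
    if abs(ratio - q) < 1e-9:
        # integer decimation: kaiser-windowed FIR, passband edge 0.9*nyq
        width = 0.2 * nyq  # transition band 0.9..1.1 * nyq
        numtaps, beta = signal.kaiserord(60.0, width / (recording.sfreq / 2.0))
        numtaps |= 1
        taps = signal.firwin(
            numtaps, nyq, window=("kaiser", beta), fs=recording.sfreq
        )
        filtered = signal.filtfilt(taps, [1.0], recording.data, axis=1)
        new_data = filtered[:, ::q]
        scale = 1.0 / q
    else:
        from fractions import Fraction

        frac = Fraction(target_sfreq / recording.sfreq).limit_denominator(1000)
        new_data = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
        scale = float(frac)
    out = Recording(
        sfreq=target_sfreq,
        channels=list(recording.channels),
        data=new_data,
        first_sample_time=recording.first_sample_time,
        seams=tuple(int(np.round(s * scale)) for s in recording.seams),
    )
    if events is None:
        return out
    ev = events.events.copy()
    bl = events.blocks.copy()
    if len(ev):
        ev["onset_sample"] = np.round(ev["onset_sample"] * scale).astype(np.int64)
    if len(bl):
        bl["start_sample"] = np.round(bl["start_sample"] * scale).astype(np.int64)
        bl["end_sample"] = np.round(bl["end_sample"] * scale).astype(np.int64)
    return out, EventTable(ev, bl)


def extract_epochs(
    recording: Recording,
    events: EventTable,
    tmin: float,
    tmax: float,
    label_filter: str | None = None,
    task: str | None = None,
    baseline: tuple[float, float] | None = None,
) -> EpochSet:
    """Cut half-open windows ``[tmin, tmax)`` around event onsets.

    Epochs that exceed the recording bounds or straddle a run seam are
    dropped with a logged warning.  Optional baseline correction subtracts
    the per-channel mean over ``baseline`` (seconds relative to the event).
    """
    table = events.select(task=task, label=label_filter)
    n_times = int(round((tmax - tmin) * recording.sfreq))
    start_off = int(round(tmin * recording.sfreq))
    seams = np.asarray(recording.seams, dtype=np.int64)
    kept: list[np.ndarray] = []
    refs: list[int] = []
    n_dropped = 0
    for ref, onset in zip(table.events.index, table.events["onset_sample"]):
        s0 = int(onset) + start_off
        s1 = s0 + n_times
        if s0 < 0 or s1 > recording.n_samples or np.any((seams > s0) & (seams < s1)):
            n_dropped += 1
            continue
        kept.append(recording.data[:, s0:s1])
        refs.append(int(ref))
    if n_dropped:
        logger.warning(
            "dropped %d/%d epochs exceeding bounds or straddling run seams",
            n_dropped,
            len(table.events),
        )
    data = (
        np.stack(kept)
        if kept
        else np.empty((0, recording.n_channels, n_times))
    )
    if baseline is not None and len(kept):
        b0 = int(round((baseline[0] - tmin) * recording.sfreq))
        b1 = int(round((baseline[1] - tmin) * recording.sfreq))
        data = data - data[:, :, b0:b1].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        tmin=tmin,
        tmax=tmax,
        sfreq=recording.sfreq,
        channels=list(recording.channels),
        event_refs=np.asarray(refs, dtype=np.int64),
        baseline=baseline,
    )


def average_epochs(epochs: EpochSet) -> Evoked:
    """Pointwise arithmetic mean of the epochs."""
    if epochs.n_epochs < 1:
        raise ValidationError("cannot average an empty EpochSet")
    return Evoked(
        data=epochs.data.mean(axis=0),
        nave=epochs.n_epochs,
        tmin=epochs.tmin,
        sfreq=epochs.sfreq,
        channels=list(epochs.channels),
    )
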