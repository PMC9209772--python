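"""Reading, writing and slicing multi-channel sEMG + accelerometer recordings.

A recording lives in two files: a delimited signal table (CSV with a header
row ``time, ch1..chN, accx, accy, accz``) and a JSON sidecar carrying the
sampling rate, channel numbering, accelerometer flag and gesture events.
Plain text keeps recordings diff-able and inspectable; binary containers are
deliberately out of scope.

Sample indexing is 0-based and event windows are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GestureEvent",
    "Recording",
    "RecordingFormatError",
    "RecordingValidationError",
    "read_recording",
    "write_recording",
    "extract_labeled_segments",
]

#: number of float decimals used when writing signal tables; round-trips are
#: exact to this precision.
SIGNAL_DECIMALS = 6


class RecordingFormatError(ValueError):
    """The on-disk table/sidecar does not have the expected layout."""


class RecordingValidationError(ValueError):
    """A structurally well-formed recording violates an invariant."""


@dataclass(frozen=True)
class GestureEvent:
    """One labeled action window.

    ``gesture_id`` 0 is reserved for rest; 1..52 are gesture classes.
    ``[onset_sample, offset_sample)`` is half-open in 0-based samples.
    """

    gesture_id: int
    onset_sample: int
    offset_sample: int
    repetition: int = 0

    def validate(self, n_samples: int) -> None:
        if not (0 <= self.gesture_id <= 52):
            raise RecordingValidationError(
                f"gesture_id must be in 0..52, got {self.gesture_id}"
            )
        if not (0 <= self.onset_sample < self.offset_sample <= n_samples):
            raise RecordingValidationError(
                f"event window [{self.onset_sample}, {self.offset_sample}) "
                f"outside recording of {n_samples} samples"
            )


@dataclass
class Recording:
    """Multi-channel sEMG (microvolts) + 3-axis accelerometer (g) time series.

    Parameters
    ----------
    semg
        ``(samples, n_channels)`` float array.
    acc
        ``(samples, 3)`` float array. When no accelerometer was recorded the
        block is all zeros and ``has_acc`` is False, so downstream fusion
        code sees a uniform shape.
    fs
        Sampling rate in Hz (1000 for the 16-electrode cuff this package
        targets).
    channel_ids
        Ordered 1-based electrode labels, unique.
    events
        Gesture annotations, each within the signal span.
    """

    semg: np.ndarray
    acc: np.ndarray
    fs: float = 1000.0
    channel_ids: tuple[int, ...] = ()
    events: list[GestureEvent] = field(default_factory=list)
    has_acc: bool = True

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if not self.channel_ids:
            self.channel_ids = tuple(range(1, self.semg.shape[1] + 1))
        else:
            self.channel_ids = tuple(int(c) for c in self.channel_ids)
        self.validate()

    def validate(self) -> None:
        if self.semg.ndim != 2:
            raise RecordingValidationError("semg must be 2-D (samples x channels)")
        if self.acc.shape != (self.semg.shape[0], 3):
            raise RecordingValidationError(
                f"acc must be (samples, 3); got {self.acc.shape} for "
                f"{self.semg.shape[0]} samples"
            )
        if self.fs <= 0:
            raise RecordingValidationError("fs must be positive")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise RecordingValidationError("channel_ids must be unique")
        if len(self.channel_ids) != self.semg.shape[1]:
            raise RecordingValidationError(
                "channel_ids length must equal number of sEMG columns"
            )
        for ev in self.events:
            ev.validate(self.n_samples)

    @property
    def n_samples(self) -> int:
        return self.semg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.semg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select_channels(self, channel_ids: list[int] | tuple[int, ...]) -> "Recording":
        """Return a copy restricted to ``channel_ids`` (order as given).

        Remaining channels' data are untouched (pure column selection).
        """
        idx = [self.channel_ids.index(int(c)) for c in channel_ids]
        return Recording(
            semg=self.semg[:, idx].copy(),
            acc=self.acc.copy(),
            fs=self.fs,
            channel_ids=tuple(int(c) for c in channel_ids),
            events=list(self.events),
            has_acc=self.has_acc,
        )


def read_recording(signal_path: str | Path, sidecar_path: str | Path) -> Recording:
    """Load a recording from a CSV signal table plus JSON sidecar.

    The table must contain a ``time`` column, one ``ch<k>`` column per entry
    of the sidecar's ``channel_ids`` (in that order), and ``accx, accy, accz``.
    """
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("fs", "channel_ids", "events"):
        if key not in meta:
            raise RecordingFormatError(f"sidecar missing required key {key!r}")

    df = pd.read_csv(signal_path)
    cols = list(df.columns)
    if len(set(cols)) != len(cols):
        raise RecordingFormatError("duplicate columns in signal table")
    ch_cols = [f"ch{int(c)}" for c in meta["channel_ids"]]
    expected = ["time", *ch_cols, "accx", "accy", "accz"]
    missing = [c for c in expected if c not in cols]
    if missing:
        raise RecordingFormatError(f"signal table missing columns: {missing}")

    events = [
        GestureEvent(
            gesture_id=int(e["gesture_id"]),
            onset_sample=int(e["onset_sample"]),
            offset_sample=int(e["offset_sample"]),
            repetition=int(e.get("repetition", 0)),
        )
        for e in meta["events"]
    ]
    return Recording(
        semg=df[ch_cols].to_numpy(dtype=float),
        acc=df[["accx", "accy", "accz"]].to_numpy(dtype=float),
        fs=float(meta["fs"]),
        channel_ids=tuple(int(c) for c in meta["channel_ids"]),
        events=events,
        has_acc=bool(meta.get("has_acc", True)),
    )


def write_recording(
    rec: Recording, signal_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write ``rec`` as CSV + JSON sidecar, readable by :func:`read_recording`.

    Floats are written with a fixed number of decimals so repeated writes of
    the same recording are byte-identical.
    """
    t = np.arange(rec.n_samples) / rec.fs
    data = {"time": t}
    for j, cid in enumerate(rec.channel_ids):
        data[f"ch{cid}"] = rec.semg[:, j]
    for j, name in enumerate(("accx", "accy", "accz")):
        data[name] = rec.acc[:, j]
    pd.DataFrame(data).to_csv(
        signal_path, index=False, float_format=f"%.{SIGNAL_DECIMALS}f"
    )
    meta = {
        "fs": rec.fs,
        "channel_ids": list(rec.channel_ids),
        "has_acc": rec.has_acc,
        "events": [
            {
                "gesture_id": e.gesture_id,
                "onset_sample": e.onset_sample,
                "offset_sample": e.offset_sample,
                "repetition": e.repetition,
            }
            for e in rec.events
        ],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def extract_labeled_segments(
    rec: Recording,
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Slice out every annotated action window.

    Returns one ``(gesture_id, semg_segment, acc_segment)`` triple per event,
    in event order, each segment being the half-open slice
    ``[onset_sample, offset_sample)``.
    """
    out = []
    for ev in rec.events:
        out.append(
            (
                ev.gesture_id,
                rec.semg[ev.onset_sample : ev.offset_sample],
                rec.acc[ev.onset_sample : ev.offset_sample],
            )
        )
    return out
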