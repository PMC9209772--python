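"""End-to-end dataset assembly: recordings → filtered, normalized decision
windows (or feature images) ready for the multi-stream network.

This is the glue the CLI and the evaluation scripts run: denoise each
recording (50 Hz notch + 20 Hz high-pass), optionally restrict to a
retained-channel subset, slice labeled action segments into decision
windows, standardize each channel with training-set statistics only, and
stack everything into the arrays the model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import BandEdges, build_feature_image
from .io import Recording, extract_labeled_segments
from .preprocessing import (
    ButterworthSpec,
    ChannelStats,
    NotchSpec,
    apply_filters,
    normalize_channels,
    segment_windows,
)
from .redundancy import RedundancyReport, crossval_aggregate

__all__ = [
    "WindowDataset",
    "labeled_windows",
    "make_window_dataset",
    "feature_image_windows",
    "redundancy_segments",
    "rank_channels",
]


@dataclass
class WindowDataset:
    """Stacked decision windows for one split.

    ``x_semg``: (N, n_streams, L) raw mode or (N, n_streams, 4, T) feature
    mode; ``x_acc``: (N, 3, L); ``y``: (N,) 1-based gesture ids.
    """

    x_semg: np.ndarray
    x_acc: np.ndarray
    y: np.ndarray


def _filtered_segments(
    recordings: list[Recording],
    notch: NotchSpec | None,
    hp: ButterworthSpec | None,
    zero_phase: bool = False,
    include_rest: bool = False,
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    out = []
    for rec in recordings:
        filtered = apply_filters(rec, notch, hp, zero_phase=zero_phase)
        for gid, semg, acc in extract_labeled_segments(filtered):
            if gid == 0 and not include_rest:
                continue
            out.append((gid, semg, acc))
    return out


def labeled_windows(
    recordings: list[Recording],
    window_ms: int = 200,
    step_ms: int = 100,
    notch: NotchSpec | None = None,
    hp: ButterworthSpec | None = None,
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Per-window triples ``(gesture_id, semg (L, S), acc (L, 3))`` after
    filtering and segmentation of every labeled action."""
    fs = recordings[0].fs
    out = []
    for gid, semg, acc in _filtered_segments(recordings, notch, hp):
        sw = segment_windows(semg, window_ms, step_ms, fs)
        aw = segment_windows(acc, window_ms, step_ms, fs)
        for s, a in zip(sw, aw):
            out.append((gid, s, a))
    return out


def make_window_dataset(
    train_recordings: list[Recording],
    test_recordings: list[Recording] | None = None,
    channels: tuple[int, ...] | None = None,
    window_ms: int = 200,
    step_ms: int = 100,
    notch: NotchSpec | None = None,
    hp: ButterworthSpec | None = None,
    stats: ChannelStats | None = None,
) -> tuple[WindowDataset, WindowDataset | None, ChannelStats]:
    """Build train (and optionally test) window arrays in raw-window mode.

    Channel standardization statistics are fit on the training windows and
    re-applied, unchanged, to the test windows; pass ``stats`` to reuse
    statistics persisted from an earlier fit (inference path).
    """
    if channels is not None:
        train_recordings = [r.select_channels(channels) for r in train_recordings]
        if test_recordings is not None:
            test_recordings = [r.select_channels(channels) for r in test_recordings]

    def collect(recs):
        wins = labeled_windows(recs, window_ms, step_ms, notch, hp)
        y = np.array([g for g, _, _ in wins], dtype=int)
        semg = [s for _, s, _ in wins]  # each (L, S)
        acc = np.stack([a.T for _, _, a in wins])  # (N, 3, L)
        return semg, acc, y

    tr_semg, tr_acc, tr_y = collect(train_recordings)
    if stats is None:
        tr_norm, stats = normalize_channels(tr_semg)
    else:
        tr_norm = [stats.transform(s) for s in tr_semg]
    train = WindowDataset(
        x_semg=np.stack([s.T for s in tr_norm]), x_acc=tr_acc, y=tr_y
    )
    test = None
    if test_recordings is not None:
        te_semg, te_acc, te_y = collect(test_recordings)
        te_norm = [stats.transform(s) for s in te_semg]
        test = WindowDataset(
            x_semg=np.stack([s.T for s in te_norm]), x_acc=te_acc, y=te_y
        )
    return train, test, stats


def feature_image_windows(
    dataset: WindowDataset,
    fs: float,
    sub_window_ms: int = 50,
    sub_step_ms: int = 25,
    bands: BandEdges | None = None,
) -> np.ndarray:
    """Feature-image network input from raw decision windows.

    Each decision window is subdivided into short strided sub-windows and
    the four features are computed per sub-window, yielding a
    ``(N, n_streams, 4, T)`` tensor — each sEMG stream's 4×T image.
    Rectification is implicit in IEMG/VAR (absolute/squared values).
    """
    n, s, length = dataset.x_semg.shape
    out = None
    for i in range(n):
        per_ch = []
        for c in range(s):
            subs = segment_windows(dataset.x_semg[i, c], sub_window_ms, sub_step_ms, fs)
            per_ch.append(np.stack(subs))
        img = build_feature_image(np.stack(per_ch), fs, bands)  # (S, 4, T)
        if out is None:
            out = np.empty((n, s, 4, img.values.shape[2]))
        out[i] = img.values
    return out


def redundancy_segments(
    recordings: list[Recording],
    notch: NotchSpec | None = None,
    hp: ButterworthSpec | None = None,
) -> list[tuple[int, np.ndarray]]:
    """Filtered ``(gesture_id, semg segment)`` pairs including rest (id 0),
    as consumed by the channel-redundancy ranking."""
    return [
        (gid, semg)
        for gid, semg, _ in _filtered_segments(
            recordings, notch, hp, include_rest=True
        )
    ]


def rank_channels(
    recordings: list[Recording],
    k_folds: int = 8,
    n_levels: int = 8,
    n_remove: int = 10,
    seed: int = 0,
    notch: NotchSpec | None = None,
    hp: ButterworthSpec | None = None,
) -> RedundancyReport:
    """Filter, slice and fold-aggregate the redundancy weighting of a set of
    recordings; returns the full report with retained/removed channels."""
    segments = redundancy_segments(recordings, notch, hp)
    return crossval_aggregate(
        segments,
        channel_ids=recordings[0].channel_ids,
        k_folds=k_folds,
        n_levels=n_levels,
        n_remove=n_remove,
        seed=seed,
    )
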