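"""Variance-based ranking and pruning of redundant sEMG electrodes.

Electrodes whose activity barely changes across gestures (relative to the
resting arm) add data volume and compute without adding class information.
The procedure here scores each channel by the variance, across gesture
classes, of its rest-corrected RMS activation; channels with *low*
cross-action variance are the redundant ones. Scores are graded into
ordinal levels, levels are coded as positive redundancy weights, and the
grading is repeated over k held-in folds (8 by default) whose per-channel
weights are averaged into a final redundancy rate used to pick the channels
to drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RedundancyReport",
    "channel_rms",
    "compute_redundancy_scores",
    "grade_and_weight",
    "crossval_aggregate",
    "select_channels",
]

LabeledSegments = list[tuple[int, np.ndarray]]


@dataclass(frozen=True)
class RedundancyReport:
    """Per-fold scores/grades and the aggregate per-channel redundancy weight.

    ``weight`` is non-negative and larger for more redundant channels;
    ``retained``/``removed`` partition ``channel_ids``.
    """

    channel_ids: tuple[int, ...]
    per_fold_score: np.ndarray  # (k_folds, n_channels)
    per_fold_grade: np.ndarray  # (k_folds, n_channels)
    weight: np.ndarray  # (n_channels,) mean weight over folds
    retained: tuple[int, ...]
    removed: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.retained) | set(self.removed) != set(self.channel_ids):
            raise ValueError("retained/removed must partition channel_ids")
        if set(self.retained) & set(self.removed):
            raise ValueError("retained and removed overlap")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": list(self.channel_ids),
                "weight": self.weight,
                "grade": np.rint(self.per_fold_grade.mean(axis=0)).astype(int),
                "removed_flag": [c in self.removed for c in self.channel_ids],
            }
        )


def channel_rms(segment: np.ndarray) -> np.ndarray:
    """Per-channel RMS of a (samples, channels) segment.

    RMS is the standard sEMG activation level; note it is unchanged by
    full-wave rectification since it squares the samples.
    """
    seg = np.asarray(segment, dtype=float)
    return np.sqrt(np.mean(seg * seg, axis=0))


def compute_redundancy_scores(segments: LabeledSegments) -> np.ndarray:
    """Cross-action variance of rest-corrected per-channel activation.

    For channel ``c``: mean RMS per gesture class minus mean rest RMS, then
    the variance of those rest-corrected levels across classes. A channel
    identical under every gesture and rest scores 0 — maximal redundancy;
    redundancy ranking is the *inverse* ordering of this score.

    ``segments`` holds ``(gesture_id, segment)`` pairs; id 0 marks rest
    (the no-movement benchmark), which must be present along with at least
    two distinct gesture classes.
    """
    rest = [s for g, s in segments if g == 0]
    if not rest:
        raise ValueError("rest (gesture_id 0) segments are required as benchmark")
    by_class: dict[int, list[np.ndarray]] = {}
    for g, s in segments:
        if g != 0:
            by_class.setdefault(g, []).append(s)
    if len(by_class) < 2:
        raise ValueError(
            "variance across actions needs >= 2 distinct gesture classes"
        )
    rest_level = np.mean([channel_rms(s) for s in rest], axis=0)
    class_levels = np.stack(
        [
            np.mean([channel_rms(s) for s in segs], axis=0) - rest_level
            for _, segs in sorted(by_class.items())
        ]
    )
    return class_levels.var(axis=0, ddof=0)


def grade_and_weight(
    scores: np.ndarray, n_levels: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-grade channels by score and code grades as redundancy weights.

    Channels are binned into ``n_levels`` ordinal grades by ascending score
    (grade 1 = lowest cross-action variance = most redundant); the weight is
    the simple reversed rank code ``n_levels − grade + 1`` so that weight is
    positively correlated with redundancy. Equal scores always share a grade.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    edges = np.quantile(scores, [k / n_levels for k in range(1, n_levels)])
    grades = 1 + np.searchsorted(edges, scores, side="left")
    weights = (n_levels - grades + 1).astype(float)
    return grades.astype(int), weights


def _stratified_folds(
    segments: LabeledSegments, k_folds: int, rng: np.random.Generator
) -> list[list[int]]:
    by_class: dict[int, list[int]] = {}
    for i, (g, _) in enumerate(segments):
        by_class.setdefault(g, []).append(i)
    min_count = min(len(v) for v in by_class.values())
    if k_folds > min_count:
        raise ValueError(
            f"k_folds={k_folds} exceeds the smallest class repetition count "
            f"({min_count})"
        )
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    for g in sorted(by_class):
        idx = np.array(by_class[g])
        rng.shuffle(idx)
        for f, part in enumerate(np.array_split(idx, k_folds)):
            folds[f].extend(int(i) for i in part)
    return folds


def crossval_aggregate(
    segments: LabeledSegments,
    channel_ids: tuple[int, ...] | list[int],
    k_folds: int = 8,
    n_levels: int = 8,
    n_remove: int = 10,
    seed: int = 0,
) -> RedundancyReport:
    """Fold-aggregated redundancy weighting.

    The labeled data are split (stratified by gesture id, seeded shuffle)
    into ``k_folds`` parts; each part is held out in turn and the score →
    grade → weight coding runs on the held-in remainder. The final
    per-channel weight is the arithmetic mean over folds (the channel's
    redundancy rate), from which the ``n_remove`` most redundant channels
    are marked removed. Deterministic given (segments, seed, k_folds).
    """
    channel_ids = tuple(int(c) for c in channel_ids)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(segments, k_folds, rng)
    n_ch = len(channel_ids)
    scores = np.empty((k_folds, n_ch))
    grades = np.empty((k_folds, n_ch), dtype=int)
    weights = np.empty((k_folds, n_ch))
    for f, held_out in enumerate(folds):
        held_in = [seg for i, seg in enumerate(segments) if i not in set(held_out)]
        scores[f] = compute_redundancy_scores(held_in)
        grades[f], weights[f] = grade_and_weight(scores[f], n_levels)
    agg = weights.mean(axis=0)
    retained, removed = _partition(channel_ids, agg, n_remove)
    return RedundancyReport(
        channel_ids=channel_ids,
        per_fold_score=scores,
        per_fold_grade=grades,
        weight=agg,
        retained=retained,
        removed=removed,
    )


def _partition(
    channel_ids: tuple[int, ...], weights: np.ndarray, n_remove: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    n_ch = len(channel_ids)
    if not (0 <= n_remove < n_ch):
        raise ValueError(f"n_remove must be in [0, {n_ch}); got {n_remove}")
    # highest weight removed first; weight ties broken by lower channel id
    order = sorted(range(n_ch), key=lambda i: (-weights[i], channel_ids[i]))
    removed = sorted(channel_ids[i] for i in order[:n_remove])
    retained = sorted(set(channel_ids) - set(removed))
    return tuple(retained), tuple(removed)


def select_channels(report: RedundancyReport, n_remove: int) -> tuple[int, ...]:
    """Retained channel ids after dropping the ``n_remove`` most redundant.

    Ties in aggregate weight remove the lower channel id first. With 16
    electrodes and the default ``n_remove=10``, six channels remain.
    """
    retained, _ = _partition(report.channel_ids, report.weight, n_remove)
    return retained
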