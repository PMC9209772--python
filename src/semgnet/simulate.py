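"""Seeded simulator of labeled sEMG + accelerometer recordings.

The generator emulates the statistical structure a gesture-recognition
pipeline assumes of cuff-electrode recordings: each active channel emits
band-limited (10–200 Hz dominant) amplitude-modulated Gaussian noise — the
standard surrogate model for interference-pattern sEMG — gated by a
trapezoidal activation envelope during each action, riding on a broadband
noise floor, 50 Hz power-line interference and slow (<5 Hz) baseline drift.
Per-class, per-channel activation gains come from an amplitude matrix whose
zero columns define *planted redundant channels* (electrodes that never
modulate with any gesture), mirroring the cuff positions a pruning stage
should discard. The accelerometer emits class-specific smooth low-frequency
pulses plus sensor noise.

Everything is a pure function of the spec (seed included): the same
:class:`SimSpec` always yields bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import GestureEvent, Recording

__all__ = ["SimSpec", "simulate_recording", "simulate_dataset"]

#: the ten cuff positions planted as redundant by default, matching the
#: electrode subset a 16-channel forearm cuff typically finds uninformative.
DEFAULT_REDUNDANT = (2, 3, 4, 5, 6, 10, 11, 12, 13, 14)


@dataclass(frozen=True)
class SimSpec:
    """Study-condition parameters of the simulator.

    Defaults follow the acquisition protocol the pipeline targets: a
    16-electrode cuff at 1000 Hz, 52 gesture classes, 15 repetitions of each
    action lasting 10 s, with rest between actions. Scaled-down specs for
    fast experimentation are provided by :meth:`easy` and
    :meth:`planted_redundancy`.
    """

    n_channels: int = 16
    n_classes: int = 52
    fs: float = 1000.0
    action_s: float = 10.0
    rest_s: float = 3.0
    reps: int = 15
    amplitude_matrix: np.ndarray | None = None  # (n_classes, n_channels)
    redundant_channels: tuple[int, ...] = DEFAULT_REDUNDANT
    line_hz: float = 50.0
    line_amp: float = 0.5
    drift_amp: float = 0.3
    noise_floor: float = 0.05
    envelope_rise_s: float = 0.5
    acc_amp: float = 0.5
    acc_noise: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_classes <= 52):
            raise ValueError("n_classes must be in 1..52")
        if self.fs <= 2 * self.line_hz:
            raise ValueError("fs must exceed twice the line frequency")
        if self.action_s <= 0 or self.rest_s < 0 or self.reps < 1:
            raise ValueError("invalid timing/repetition parameters")
        bad = [c for c in self.redundant_channels if not 1 <= c <= self.n_channels]
        if bad:
            raise ValueError(f"redundant channel ids out of range: {bad}")
        amp = self.gains()
        if amp.shape != (self.n_classes, self.n_channels):
            raise ValueError(
                f"amplitude matrix must be ({self.n_classes}, {self.n_channels})"
            )
        if np.any(amp < 0):
            raise ValueError("amplitude matrix must be non-negative")
        red_idx = [c - 1 for c in self.redundant_channels]
        if red_idx and np.any(amp[:, red_idx] != 0):
            raise ValueError("redundant channels must have all-zero gains")

    def gains(self) -> np.ndarray:
        """Per-class × per-channel activation gains a_kc ≥ 0.

        When no matrix is supplied, gains are drawn once (from the spec seed)
        uniformly in [0.5, 2.0] for active channels, giving each class a
        distinct activation pattern, with redundant columns forced to zero.
        """
        if self.amplitude_matrix is not None:
            return np.asarray(self.amplitude_matrix, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xA3F]))
        amp = rng.uniform(0.5, 2.0, size=(self.n_classes, self.n_channels))
        for c in self.redundant_channels:
            amp[:, c - 1] = 0.0
        return amp

    @classmethod
    def easy(cls, seed: int = 0) -> "SimSpec":
        """Well-separated 5-class, 6-channel spec for fast desk-scale runs.

        Classes activate nearly disjoint channel subsets at distinct gains,
        with short actions so a full train/evaluate cycle stays light.
        """
        n_classes, n_channels = 5, 6
        amp = np.zeros((n_classes, n_channels))
        for k in range(n_classes):
            amp[k, k % n_channels] = 2.0
            amp[k, (k + 2) % n_channels] = 1.0
        return cls(
            n_channels=n_channels,
            n_classes=n_classes,
            action_s=2.0,
            rest_s=1.0,
            reps=9,
            amplitude_matrix=amp,
            redundant_channels=(),
            seed=seed,
        )

    @classmethod
    def planted_redundancy(cls, seed: int = 0, reps: int = 8,
                           n_classes: int = 6) -> "SimSpec":
        """16-channel spec with the default redundant subset planted, scaled
        to short actions so fold-aggregated ranking runs in seconds."""
        return cls(
            n_classes=n_classes,
            action_s=1.0,
            rest_s=0.5,
            reps=reps,
            seed=seed,
        )


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       low: float, high: float, order: int = 4) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [low, high] Hz."""
    white = rng.standard_normal(n)
    sos = sps.butter(order, [low, min(high, 0.49 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    x = sps.sosfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _trapezoid(n: int, n_rise: int) -> np.ndarray:
    """Trapezoidal activation envelope: linear rise/fall, flat plateau."""
    n_rise = max(1, min(n_rise, n // 2))
    env = np.ones(n)
    ramp = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    env[:n_rise] = ramp
    env[n - n_rise :] = ramp[::-1]
    return env


def _schedule(spec: SimSpec, classes: list[int], reps: int):
    """Rest/action alternation: leading rest, then (action, rest) per trial.

    Yields (gesture_id, repetition, onset, offset) for actions *and* the
    interleaved rest windows (gesture_id 0), all in samples.
    """
    n_action = int(round(spec.action_s * spec.fs))
    n_rest = int(round(spec.rest_s * spec.fs))
    events = []
    pos = 0
    if n_rest:
        events.append((0, 0, pos, pos + n_rest))
        pos += n_rest
    trial = 0
    for rep in range(reps):
        for k in classes:
            events.append((k, rep, pos, pos + n_action))
            pos += n_action
            if n_rest:
                events.append((0, trial + 1, pos, pos + n_rest))
                pos += n_rest
            trial += 1
    return events, pos


def _simulate(spec: SimSpec, classes: list[int], reps: int,
              seed_seq: np.random.SeedSequence) -> Recording:
    rng = np.random.default_rng(seed_seq)
    amp = spec.gains()
    events, n_samples = _schedule(spec, classes, reps)
    t = np.arange(n_samples) / spec.fs
    n_rise = int(round(spec.envelope_rise_s * spec.fs))

    # per-channel envelope gain over the full timeline
    gain = np.zeros((n_samples, spec.n_channels))
    for g, _rep, a, b in events:
        if g == 0:
            continue
        gain[a:b] += _trapezoid(b - a, n_rise)[:, None] * amp[g - 1][None, :]

    semg = np.empty((n_samples, spec.n_channels))
    for c in range(spec.n_channels):
        muscle = _bandlimited_noise(rng, n_samples, spec.fs, 10.0, 200.0)
        floor = rng.standard_normal(n_samples) * spec.noise_floor
        line = spec.line_amp * np.sin(
            2 * np.pi * spec.line_hz * t + rng.uniform(0, 2 * np.pi)
        )
        drift_src = rng.standard_normal(n_samples)
        sos = sps.butter(2, 5.0, btype="lowpass", fs=spec.fs, output="sos")
        drift = sps.sosfilt(sos, drift_src)
        sd = drift.std()
        drift = spec.drift_amp * (drift / sd if sd > 0 else drift)
        semg[:, c] = gain[:, c] * muscle + floor + line + drift

    # ACC: class-specific smooth pulses per axis + sensor noise
    acc_pattern = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0xACC])
    ).uniform(-1.0, 1.0, size=(spec.n_classes, 3))
    acc = rng.standard_normal((n_samples, 3)) * spec.acc_noise
    for g, _rep, a, b in events:
        if g == 0:
            continue
        pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(b - a) / (b - a)))
        acc[a:b] += spec.acc_amp * pulse[:, None] * acc_pattern[g - 1][None, :]

    gesture_events = [
        GestureEvent(gesture_id=g, onset_sample=a, offset_sample=b, repetition=rep)
        for g, rep, a, b in events
    ]
    return Recording(
        semg=semg,
        acc=acc,
        fs=spec.fs,
        channel_ids=tuple(range(1, spec.n_channels + 1)),
        events=gesture_events,
        has_acc=True,
    )


def simulate_recording(spec: SimSpec) -> Recording:
    """Generate one recording containing every class × repetition.

    Rest windows are annotated as gesture 0 events so the no-movement
    benchmark can be sliced out like any other segment.
    """
    spec.validate()
    return _simulate(
        spec,
        classes=list(range(1, spec.n_classes + 1)),
        reps=spec.reps,
        seed_seq=np.random.SeedSequence([spec.seed, 1]),
    )


def simulate_dataset(
    spec: SimSpec, train_fraction: float = 8.0 / 9.0
) -> tuple[list[Recording], list[Recording]]:
    """Class-stratified train/test split at the repetition level.

    One recording is generated per repetition (each containing every class
    once), and whole repetitions are assigned to a side, so no decision
    window can straddle the split. With 9 repetitions and the default
    fraction this gives 8 training and 1 test recording per class.
    """
    spec.validate()
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(spec.reps * train_fraction))
    n_train = min(max(n_train, 1), spec.reps - 1)
    recordings = [
        _simulate(
            spec,
            classes=list(range(1, spec.n_classes + 1)),
            reps=1,
            seed_seq=np.random.SeedSequence([spec.seed, 2, rep]),
        )
        for rep in range(spec.reps)
    ]
    return recordings[:n_train], recordings[n_train:]
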