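"""Time- and frequency-domain window features and multi-channel feature images.

Four classic, cheap-to-compute sEMG descriptors are used, per channel per
decision window:

* IEMG — integrated EMG, ``Σ|x_i|``;
* VAR — the second-moment "variance", ``(1/(N−1)) Σ x_i²`` (implemented as
  printed in the sEMG literature, without mean subtraction; filtered sEMG is
  near zero-mean so the distinction is minor);
* MDF — median frequency: the smallest spectral bin where cumulative power
  first reaches half the total, on a one-sided periodogram;
* FR — frequency ratio: low-band power over high-band power
  (``fr_low_over_high``), bands given by the (LLC, LHC, HLC, HHC) cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BandEdges",
    "FeatureImage",
    "FEATURE_ORDER",
    "iemg",
    "var_feature",
    "periodogram_power",
    "mdf",
    "fr",
    "build_feature_image",
    "feature_table",
]

FEATURE_ORDER = ("IEMG", "VAR", "MDF", "FR")


@dataclass(frozen=True)
class BandEdges:
    """Low/high band cutoffs for the frequency ratio, in Hz.

    Defaults split the sEMG energy band (dominant 10–200 Hz, bandwidth
    ≤500 Hz) into a low band below and a high band above the usual
    fatigue-sensitive midpoint; all four edges are configurable.
    """

    llc: float = 20.0
    lhc: float = 45.0
    hlc: float = 95.0
    hhc: float = 450.0

    def validate(self, fs: float) -> None:
        if not (self.llc < self.lhc <= self.hlc < self.hhc <= fs / 2):
            raise ValueError(
                f"band edges must satisfy LLC < LHC <= HLC < HHC <= fs/2; "
                f"got ({self.llc}, {self.lhc}, {self.hlc}, {self.hhc}) at fs={fs}"
            )


def iemg(x: np.ndarray) -> float:
    """Integrated EMG: sum of absolute sample values."""
    return float(np.sum(np.abs(np.asarray(x, dtype=float))))


def var_feature(x: np.ndarray) -> float:
    """Second-moment amplitude feature ``(1/(N−1)) Σ x_i²`` (no mean removal)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    return float(np.sum(x * x) / (n - 1))


def periodogram_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram (freqs in Hz, power per bin)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window too short for a periodogram")
    freqs, p = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    return freqs, p


def mdf(x: np.ndarray, fs: float) -> float:
    """Median frequency of the window's power spectrum.

    The frequency of the lowest bin at which the inclusive cumulative power
    first reaches half the total (a tie at exactly half resolves to the
    lower bin). Amplitude-scale invariant.
    """
    freqs, p = periodogram_power(x, fs)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total spectral power; MDF undefined")
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(freqs[idx])


def fr(x: np.ndarray, fs: float, bands: BandEdges | None = None) -> float:
    """Frequency ratio: low-band power divided by high-band power.

    Band sums are inclusive of bins falling inside ``[LLC, LHC]`` and
    ``[HLC, HHC]``. Zero high-band power is reported as an error rather
    than returned as infinity.
    """
    bands = bands or BandEdges()
    bands.validate(fs)
    freqs, p = periodogram_power(x, fs)
    low = p[(freqs >= bands.llc) & (freqs <= bands.lhc)].sum()
    high = p[(freqs >= bands.hlc) & (freqs <= bands.hhc)].sum()
    if high <= 0:
        raise ValueError("zero high-band power; frequency ratio undefined")
    return float(low / high)


@dataclass(frozen=True)
class FeatureImage:
    """Feature tensor ``(n_channels, 4, n_windows)`` in IEMG/VAR/MDF/FR order."""

    values: np.ndarray
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[1] != len(self.feature_order):
            raise ValueError(
                f"expected (channels, {len(self.feature_order)}, windows); got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("feature image contains non-finite entries")


def build_feature_image(
    channel_windows: np.ndarray,
    fs: float,
    bands: BandEdges | None = None,
) -> FeatureImage:
    """Assemble the per-channel, per-window feature image.

    Parameters
    ----------
    channel_windows
        ``(n_channels, n_windows, window_samples)`` array of time-domain
        windows (rectification, if wanted, is done upstream for IEMG/VAR).
    fs
        Sampling rate in Hz.
    bands
        Frequency-ratio band edges.
    """
    cw = np.asarray(channel_windows, dtype=float)
    if cw.ndim != 3:
        raise ValueError("channel_windows must be (channels, windows, samples)")
    n_ch, n_win, _ = cw.shape
    out = np.empty((n_ch, 4, n_win), dtype=float)
    for c in range(n_ch):
        for w in range(n_win):
            x = cw[c, w]
            out[c, 0, w] = iemg(x)
            out[c, 1, w] = var_feature(x)
            out[c, 2, w] = mdf(x, fs)
            out[c, 3, w] = fr(x, fs, bands)
    return FeatureImage(values=out)


def feature_table(image: FeatureImage, channel_ids: list[int] | None = None) -> pd.DataFrame:
    """Flatten a feature image to a tidy table (window_id, channel, 4 features)."""
    n_ch, _, n_win = image.values.shape
    ids = channel_ids if channel_ids is not None else list(range(1, n_ch + 1))
    rows = []
    for w in range(n_win):
        for c in range(n_ch):
            rows.append(
                {
                    "window_id": w,
                    "channel": ids[c],
                    **{
                        name: image.values[c, k, w]
                        for k, name in enumerate(image.feature_order)
                    },
                }
            )
    return pd.DataFrame(rows)
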