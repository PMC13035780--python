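"""Relative band power via Welch's method.

Welch settings follow the common quantitative-EEG recipe: 1-s windows with
50% overlap, Hann taper, constant detrend per window.  Band power is a
rectangle-rule sum of PSD bins; the relative power of a band is its power
divided by the total power over 1-30 Hz.

Band-edge convention
--------------------
Each PSD bin is treated as a rectangle of width df centred on its
frequency; a band's power is the coverage-weighted rectangle sum over
[lo, hi), so a bin lying exactly on a shared edge (4, 8 or 13 Hz on the
default 1-Hz grid) contributes half its power to each neighbouring band
and no power is counted twice.  The four bands tile the total band
[1, 30), and an ideal white-noise spectrum yields band fractions equal to
the bandwidth ratios 3/29, 4/29, 5/29, 17/29.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io import EpochSet
from .simulate import BAND_NAMES, BANDS


@dataclass
class WelchConfig:
    window_length_s: float = 1.0
    overlap_frac: float = 0.5
    taper: str = "hann"
    detrend: str = "constant"
    total_band: tuple[float, float] = (1.0, 30.0)

    def __post_init__(self):
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValidationError("overlap_frac must lie in [0, 1)")
        if self.window_length_s <= 0:
            raise ValidationError("window_length_s must be positive")


@dataclass
class BandPowerResult:
    """Relative band power for one subject x session x channel."""

    subject_id: str
    session: str
    channel: str
    rpsd: Mapping[str, float]
    total_power: float  # uV^2 over the total band

    def __post_init__(self):
        total = sum(self.rpsd.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"band fractions sum to {total}, expected 1 within 1e-6")


def welch_psd(x: np.ndarray, fs: float,
              config: WelchConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (density scaling, uV^2/Hz).

    The integral of the returned PSD over frequency approximates the
    (detrended) signal variance.
    """
    config = config or WelchConfig()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(config.window_length_s * fs))
    if x.shape[-1] < nperseg:
        raise ValidationError(
            f"signal of {x.shape[-1]} samples shorter than the "
            f"{nperseg}-sample Welch window")
    noverlap = int(round(config.overlap_frac * nperseg))
    return sps.welch(x, fs=fs, window=config.taper, nperseg=nperseg,
                     noverlap=noverlap, detrend=config.detrend,
                     scaling="density")


def band_rpsd(freqs: np.ndarray, psd: np.ndarray,
              total_band: tuple[float, float] = (1.0, 30.0)
              ) -> tuple[dict[str, float], float]:
    """Relative power per canonical band, plus the absolute total power.

    Coverage-weighted rectangle-rule integration (see module docstring);
    raises if the frequency grid does not cover the total band.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo_t, hi_t = total_band
    if freqs[0] > lo_t or freqs[-1] < hi_t:
        raise ValidationError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] does not cover the "
            f"total band [{lo_t}, {hi_t}] Hz")
    df = float(freqs[1] - freqs[0])

    def coverage(lo, hi):
        left = np.maximum(freqs - df / 2, lo)
        right = np.minimum(freqs + df / 2, hi)
        return np.clip(right - left, 0.0, None) / df

    w_total = coverage(lo_t, hi_t)
    total = float(psd @ w_total)
    if total <= 0:
        raise ValidationError("zero total power in the total band")
    out = {}
    for name in BAND_NAMES:
        lo, hi = BANDS[name]
        w = np.minimum(coverage(lo, hi), w_total)
        out[name] = float(psd @ w) / total
    return out, total * df


def epoch_average_rpsd(epoch_set: EpochSet, channel: str,
                       config: WelchConfig | None = None) -> BandPowerResult:
    """Band power for one channel, PSDs averaged across epochs.

    Welch is applied per epoch and the per-epoch PSDs are averaged before
    band integration (no windows straddle epoch joins), then normalized
    once.
    """
    config = config or WelchConfig()
    if epoch_set.n_epochs == 0:
        raise ValidationError("empty epoch set")
    segs = epoch_set.channel_epochs(channel)
    freqs, psds = welch_psd(segs, epoch_set.fs, config)
    psd = psds.mean(axis=0)
    rpsd, total = band_rpsd(freqs, psd, config.total_band)
    return BandPowerResult(epoch_set.subject_id, epoch_set.session,
                           channel, rpsd, total)
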