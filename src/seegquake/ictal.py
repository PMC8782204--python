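"""Epileptogenicity Index (EI) from an ictal SEEG recording.

Per channel i, the recording is notch-filtered (50 Hz, Q = 30) and
band-passed to high gamma (60-140 Hz, 5th-order Butterworth), both
zero-phase.  Squaring and 500 ms moving-average smoothing give a
high-frequency energy trace; dividing by its mean over a user-selected
pre-ictal baseline yields the normalized high-frequency energy (NHFE).
The onset threshold is

    thre_i = max(NHFE_BL,i) + k_sigma * sd(NHFE_BL,i)        (k_sigma = 10)

and a channel's onset is the first target sample whose NHFE exceeds it.
Channels are ranked by onset time; the time coefficient is the reciprocal
rank TC_i = 1/rank_i (1, 1/2, 1/3, ...), the energy coefficient EC_i is the
mean NHFE over the 250 ms right after the earliest onset, and

    EI_i = TC_i * EC_i.

Channels with no onset get TC = 0 and hence EI = 0.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .errors import SamplingRateError, ZeroBaselineError
from .io import Recording, SegmentSpec

logger = logging.getLogger(__name__)


@dataclass
class NhfeMatrix:
    """Normalized high-frequency energy, channels x samples (dimensionless)."""

    values: np.ndarray
    fs: float
    channel_names: list


@dataclass
class OnsetTable:
    """Per-channel onset threshold, onset sample (or None), and rank (or None)."""

    thresholds: np.ndarray          # (n_channels,)
    onset_samples: np.ndarray       # (n_channels,) float; NaN = no onset
    ranks: np.ndarray               # (n_channels,) float; NaN = no onset
    channel_names: list

    @property
    def n_onsets(self) -> int:
        return int(np.isfinite(self.onset_samples).sum())


@dataclass
class EIResult:
    """TC, EC and EI per channel, plus a report sorted by EI descending."""

    tc: np.ndarray
    ec: np.ndarray
    ei: np.ndarray
    onsets: OnsetTable
    fs: float
    channel_names: list

    def to_frame(self) -> pd.DataFrame:
        onset_s = self.onsets.onset_samples / self.fs
        df = pd.DataFrame(
            {
                "channel": self.channel_names,
                "thre": self.onsets.thresholds,
                "onset_s": onset_s,
                "rank": self.onsets.ranks,
                "TC": self.tc,
                "EC": self.ec,
                "EI": self.ei,
            }
        )
        return df.sort_values("EI", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def design_filters(fs: float, band: Tuple[float, float], notch_hz: float,
                   notch_q: float, order: int):
    if fs <= 2 * band[1]:
        raise SamplingRateError(
            f"fs={fs} Hz too low for a {band[0]}-{band[1]} Hz band-pass"
        )
    b_notch, a_notch = sps.iirnotch(notch_hz, notch_q, fs=fs)
    sos_band = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return (b_notch, a_notch), sos_band


def bandpass_highgamma(
    recording: Recording,
    band: Tuple[float, float] = (60.0, 140.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    order: int = 5,
) -> Recording:
    """Zero-phase 50 Hz notch followed by a zero-phase Butterworth band-pass."""
    (b_n, a_n), sos = design_filters(recording.fs, band, notch_hz, notch_q, order)
    x = sps.filtfilt(b_n, a_n, recording.signal, axis=1)
    x = sps.sosfiltfilt(sos, x, axis=1)
    return Recording(signal=x, fs=recording.fs, channel_names=list(recording.channel_names))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis; the window shrinks at
    the edges (each output is the mean over the in-bounds part)."""
    kernel = np.ones(window)
    num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, x)
    den = np.convolve(np.ones(x.shape[1]), kernel, mode="same")
    return num / den


def compute_nhfe(
    filtered: Recording,
    segments: SegmentSpec,
    window_ms: float = 500.0,
) -> NhfeMatrix:
    """Square, smooth (window_ms moving average, one-sample step), then
    divide each channel by its mean energy over the baseline segment."""
    segments.validate_against(filtered.n_samples)
    window = max(1, int(round(window_ms / 1000.0 * filtered.fs)))
    energy = _moving_average(filtered.signal ** 2, window)
    b0, b1 = segments.baseline
    baseline_mean = energy[:, b0:b1].mean(axis=1)
    bad = baseline_mean <= 0
    if bad.any():
        names = [filtered.channel_names[i] for i in np.flatnonzero(bad)]
        raise ZeroBaselineError(f"zero baseline energy on channel(s): {names}")
    return NhfeMatrix(
        values=energy / baseline_mean[:, None],
        fs=filtered.fs,
        channel_names=list(filtered.channel_names),
    )


def detect_onsets(
    nhfe: NhfeMatrix,
    segments: SegmentSpec,
    k_sigma: float = 10.0,
) -> OnsetTable:
    """Threshold = baseline max + k_sigma * baseline sample sd (ddof=1);
    onset = first target sample strictly above it.  Ranks are by onset time
    ascending; tied onsets share the earlier rank and consume rank slots."""
    b0, b1 = segments.baseline
    t0, t1 = segments.target
    if b1 - b0 < 2:
        raise ValueError("baseline needs >= 2 samples for a standard deviation")
    bl = nhfe.values[:, b0:b1]
    thresholds = bl.max(axis=1) + k_sigma * bl.std(axis=1, ddof=1)

    n_ch = nhfe.values.shape[0]
    onset_samples = np.full(n_ch, np.nan)
    for i in range(n_ch):
        above = nhfe.values[i, t0:t1] > thresholds[i]
        if above.any():
            onset_samples[i] = t0 + int(np.argmax(above))

    ranks = np.full(n_ch, np.nan)
    has = np.isfinite(onset_samples)
    for i in np.flatnonzero(has):
        ranks[i] = 1 + int((onset_samples[has] < onset_samples[i]).sum())
    return OnsetTable(
        thresholds=thresholds,
        onset_samples=onset_samples,
        ranks=ranks,
        channel_names=list(nhfe.channel_names),
    )


def compute_ei(
    nhfe: NhfeMatrix,
    onsets: OnsetTable,
    ec_window_ms: float = 250.0,
) -> EIResult:
    """EI_i = TC_i * EC_i with TC_i = 1/rank_i (0 without an onset) and EC_i
    the mean NHFE over [t_first, t_first + ec_window) anchored at the
    globally earliest onset (truncated at the end of the recording)."""
    n_ch, n_samp = nhfe.values.shape
    tc = np.zeros(n_ch)
    ec = np.zeros(n_ch)
    has = np.isfinite(onsets.ranks)
    if not has.any():
        warnings.warn("no channel crossed its onset threshold; all EI = 0")
    else:
        tc[has] = 1.0 / onsets.ranks[has]
        t_first = int(np.nanmin(onsets.onset_samples))
        t_end = t_first + max(1, int(round(ec_window_ms / 1000.0 * nhfe.fs)))
        if t_end > n_samp:
            warnings.warn("EC window extends past the recording; truncated")
            t_end = n_samp
        ec = nhfe.values[:, t_first:t_end].mean(axis=1)
    ei = tc * ec
    return EIResult(
        tc=tc, ec=ec, ei=ei, onsets=onsets, fs=nhfe.fs,
        channel_names=list(nhfe.channel_names),
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class EpileptogenicityIndex(BaseEstimator):
    """Per-channel EI from an ictal recording, estimator style.

    ``fit`` takes a :class:`~seegquake.io.Recording` (or a channels x
    samples array with ``fs`` given in the constructor) and a
    :class:`~seegquake.io.SegmentSpec` selecting the baseline and the
    target (onset-covering) windows.

    Attributes
    ----------
    nhfe_ : NhfeMatrix
    onsets_ : OnsetTable
    tc_, ec_, ei_ : ndarray of shape (n_channels,)
    result_ : EIResult
    """

    def __init__(
        self,
        band: Tuple[float, float] = (60.0, 140.0),
        notch_hz: float = 50.0,
        notch_q: float = 30.0,
        order: int = 5,
        window_ms: float = 500.0,
        ec_window_ms: float = 250.0,
        k_sigma: float = 10.0,
        fs: Optional[float] = None,
    ):
        self.band = band
        self.notch_hz = notch_hz
        self.notch_q = notch_q
        self.order = order
        self.window_ms = window_ms
        self.ec_window_ms = ec_window_ms
        self.k_sigma = k_sigma
        self.fs = fs

    def _as_recording(self, X) -> Recording:
        if isinstance(X, Recording):
            return X
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.fs is None:
            raise SamplingRateError("fs must be set when X is a bare array")
        return Recording(
            signal=X, fs=self.fs,
            channel_names=[f"CH{i:02d}" for i in range(X.shape[0])],
        )

    def fit(self, X, y=None, segments: Optional[SegmentSpec] = None) -> "EpileptogenicityIndex":
        if segments is None:
            raise ValueError("segments (baseline/target windows) are required")
        rec = self._as_recording(X)
        filtered = bandpass_highgamma(
            rec, band=self.band, notch_hz=self.notch_hz,
            notch_q=self.notch_q, order=self.order,
        )
        self.nhfe_ = compute_nhfe(filtered, segments, window_ms=self.window_ms)
        self.onsets_ = detect_onsets(self.nhfe_, segments, k_sigma=self.k_sigma)
        self.result_ = compute_ei(self.nhfe_, self.onsets_, ec_window_ms=self.ec_window_ms)
        self.tc_ = self.result_.tc
        self.ec_ = self.result_.ec
        self.ei_ = self.result_.ei
        logger.info("EI: %d/%d channels with onsets", self.onsets_.n_onsets, rec.n_channels)
        return self

    def fit_transform(self, X, y=None, segments: Optional[SegmentSpec] = None) -> np.ndarray:
        """Fit and return the per-channel EI vector."""
        return self.fit(X, segments=segments).ei_
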