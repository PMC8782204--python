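"""High-Frequency Events Index (HI) from interictal SEEG.

The signal is notch-filtered (50 Hz, Q = 30) and band-passed to the ripple
band (80-250 Hz, 5th-order Butterworth, zero-phase); the amplitude envelope
is the magnitude of the analytic signal (Hilbert transform).  With S_i the
median envelope of channel i and S_global the median of the pooled
envelope over all channels and samples, the per-channel event threshold is

    thre_i = 2 * max(S_i, S_global).

Supra-threshold runs are events; runs separated by less than 20 ms are
merged (merge first), then events shorter than 50 ms are discarded.  HI is
the per-channel event count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .errors import SamplingRateError
from .ictal import design_filters
from .io import Recording

logger = logging.getLogger(__name__)


@dataclass
class EnvelopeMatrix:
    """Ripple-band amplitude envelope, channels x samples (microvolts)."""

    values: np.ndarray
    fs: float
    channel_names: list
    channel_medians: np.ndarray   # S_i
    global_median: float          # S_global, pooled over channels x samples


@dataclass
class EventList:
    """Per-channel merged, duration-filtered supra-threshold intervals (s)."""

    events: List[List[Tuple[float, float]]]
    thresholds: np.ndarray
    channel_names: list


@dataclass
class HIResult:
    hi: np.ndarray                # per-channel event count
    rate_per_min: np.ndarray
    events: EventList

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.events.channel_names,
                "HI": self.hi.astype(int),
                "rate_per_min": self.rate_per_min,
            }
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def ripple_envelope(
    recording: Recording,
    band: Tuple[float, float] = (80.0, 250.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    order: int = 5,
    smooth_ms: float = 10.0,
) -> EnvelopeMatrix:
    """Notch -> zero-phase band-pass -> analytic-signal magnitude, smoothed
    by a centered ``smooth_ms`` moving average.

    The short smoothing turns the instantaneous magnitude into an
    energy-envelope estimate: it leaves the envelope of any sustained
    oscillation untouched but suppresses the millisecond-scale excursions
    of a stochastic background, whose merged chains would otherwise
    register as events at the 2x-median threshold.
    """
    (b_n, a_n), sos = design_filters(recording.fs, band, notch_hz, notch_q, order)
    x = sps.filtfilt(b_n, a_n, recording.signal, axis=1)
    x = sps.sosfiltfilt(sos, x, axis=1)
    env = np.abs(sps.hilbert(x, axis=1))
    w = max(1, int(round(smooth_ms / 1000.0 * recording.fs)))
    if w > 1:
        kernel = np.ones(w)
        num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, env)
        den = np.convolve(np.ones(env.shape[1]), kernel, mode="same")
        env = num / den
    return EnvelopeMatrix(
        values=env,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        channel_medians=np.median(env, axis=1),
        global_median=float(np.median(env)),
    )


def event_threshold(envelope: EnvelopeMatrix) -> np.ndarray:
    """thre_i = 2 * max(S_i, S_global)."""
    return 2.0 * np.maximum(envelope.channel_medians, envelope.global_median)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_events(
    envelope: EnvelopeMatrix,
    thresholds: np.ndarray,
    merge_gap_ms: float = 20.0,
    min_duration_ms: float = 50.0,
) -> EventList:
    """Extract strict supra-threshold runs, merge gaps < merge_gap_ms, then
    drop events shorter than min_duration_ms — in that fixed order.

    Channels with a non-positive threshold (flat-zero envelope) emit no
    events rather than everything.
    """
    if len(thresholds) != envelope.values.shape[0]:
        raise ValueError("one threshold per channel required")
    fs = envelope.fs
    gap = merge_gap_ms / 1000.0 * fs
    min_dur = min_duration_ms / 1000.0 * fs

    all_events: List[List[Tuple[float, float]]] = []
    for i, thr in enumerate(thresholds):
        if thr <= 0:
            all_events.append([])
            continue
        runs = _runs(envelope.values[i] > thr)
        merged: List[list] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        kept = [(s / fs, e / fs) for s, e in merged if (e - s) >= min_dur]
        all_events.append(kept)
    return EventList(
        events=all_events,
        thresholds=np.asarray(thresholds, dtype=float),
        channel_names=list(envelope.channel_names),
    )


def compute_hi(events: EventList, duration_s: float) -> HIResult:
    """HI = per-channel event count; rate = count * 60 / duration_s."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    counts = np.array([len(ev) for ev in events.events], dtype=float)
    return HIResult(hi=counts, rate_per_min=counts * 60.0 / duration_s, events=events)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class HighFrequencyEventsIndex(BaseEstimator):
    """Per-channel HI from an interictal recording, estimator style.

    Attributes
    ----------
    envelope_ : EnvelopeMatrix
    thresholds_ : ndarray
    events_ : EventList
    hi_, rate_per_min_ : ndarray of shape (n_channels,)
    result_ : HIResult
    """

    def __init__(
        self,
        band: Tuple[float, float] = (80.0, 250.0),
        notch_hz: float = 50.0,
        notch_q: float = 30.0,
        order: int = 5,
        merge_gap_ms: float = 20.0,
        min_duration_ms: float = 50.0,
        smooth_ms: float = 10.0,
        fs: Optional[float] = None,
    ):
        self.band = band
        self.notch_hz = notch_hz
        self.notch_q = notch_q
        self.order = order
        self.merge_gap_ms = merge_gap_ms
        self.min_duration_ms = min_duration_ms
        self.smooth_ms = smooth_ms
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

    def fit(self, X, y=None) -> "HighFrequencyEventsIndex":
        rec = self._as_recording(X)
        self.envelope_ = ripple_envelope(
            rec, band=self.band, notch_hz=self.notch_hz,
            notch_q=self.notch_q, order=self.order, smooth_ms=self.smooth_ms,
        )
        self.thresholds_ = event_threshold(self.envelope_)
        self.events_ = detect_events(
            self.envelope_, self.thresholds_,
            merge_gap_ms=self.merge_gap_ms,
            min_duration_ms=self.min_duration_ms,
        )
        self.result_ = compute_hi(self.events_, rec.duration_s)
        self.hi_ = self.result_.hi
        self.rate_per_min_ = self.result_.rate_per_min
        logger.info("HI: %d events total on %d channels",
                    int(self.hi_.sum()), rec.n_channels)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the per-channel HI vector."""
        return self.fit(X).hi_
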