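"""Synthetic CT-like volumes and SEEG recordings with known ground truth.

The volume generator emulates a skull-stripped post-implant CT: a dim,
smooth ellipsoidal "brain" background plus additive Gaussian noise, with
depth electrodes rendered as straight (optionally arc-bent) rows of bright
isotropic Gaussian blobs (FWHM = contact diameter, so adjacent blobs at a
3.5 mm pitch partially merge, as they do in real scans).

The recording generators emulate the two signal regimes the indices are
built for: ictal runs with band-limited high-gamma (60-140 Hz) activity
ramping up from a per-channel onset time, and interictal runs with brief
80-250 Hz ripple bursts planted at known times over a pink-noise floor.

All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .config import RunConfig
from .errors import PlacementError, SamplingRateError
from .io import Recording, Volume

# ---------------------------------------------------------------------------
# specs and truth containers
# ---------------------------------------------------------------------------


@dataclass
class ElectrodeSpec:
    """Geometry and intensity parameters of the rendered electrodes."""

    n_electrodes: int = 8
    contacts_min: int = 8
    contacts_max: int = 16
    pitch_mm: float = 3.5
    contact_diameter_mm: float = 2.0
    bend_amplitude_mm: float = 0.0
    intensity_ratio: float = 10.0   # blob peak / background plateau
    noise_sd: float = 0.1           # additive noise sd, fraction of blob peak

    def __post_init__(self) -> None:
        if self.pitch_mm <= self.contact_diameter_mm / 2:
            raise ValueError("pitch must exceed half the contact diameter")
        if self.n_electrodes < 0:
            raise ValueError("n_electrodes must be >= 0")
        if not (0 < self.contacts_min <= self.contacts_max):
            raise ValueError("invalid contacts range")


@dataclass
class GroundTruth:
    """What the generators actually planted; the validation surface."""

    contacts: List[np.ndarray] = field(default_factory=list)   # per electrode, (k,3) mm
    directions: List[np.ndarray] = field(default_factory=list)  # per electrode unit vec
    soz_channels: List[str] = field(default_factory=list)
    event_times: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)
    onset_times: Dict[str, float] = field(default_factory=dict)

    @property
    def n_contacts(self) -> int:
        return int(sum(len(c) for c in self.contacts))


# ---------------------------------------------------------------------------
# volume generation
# ---------------------------------------------------------------------------


def _shaft_points(head: np.ndarray, direction: np.ndarray, n: int, pitch: float,
                  bend_amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Contact centers head-first; optional circular-arc bend of given sagitta."""
    ks = np.arange(n)[:, None]
    pts = head[None, :] + ks * pitch * direction[None, :]
    if bend_amplitude > 0 and n >= 3:
        # perpendicular unit vector in a random azimuth around the shaft
        ref = np.array([1.0, 0.0, 0.0])
        if abs(direction @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(direction, ref)
        u /= np.linalg.norm(u)
        v = np.cross(direction, u)
        phi = rng.uniform(0, 2 * np.pi)
        perp = np.cos(phi) * u + np.sin(phi) * v
        t = ks[:, 0] / (n - 1)  # 0..1 along the shaft
        sag = bend_amplitude * (1 - (2 * t - 1) ** 2)  # parabolic arc, max at middle
        pts = pts + sag[:, None] * perp[None, :]
    return pts


def _min_pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).min())


def _densify(pts: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Sample points along the polyline of contact centers at ~step mm."""
    out = [pts[0]]
    for p, q in zip(pts[:-1], pts[1:]):
        seg = q - p
        n = max(1, int(np.ceil(np.linalg.norm(seg) / step)))
        for i in range(1, n + 1):
            out.append(p + seg * i / n)
    return np.asarray(out)


def make_volume(
    spec: ElectrodeSpec,
    shape: Tuple[int, int, int] = (160, 160, 160),
    affine: Optional[np.ndarray] = None,
    seed: int = 0,
    max_retries: int = 500,
) -> Tuple[Volume, GroundTruth]:
    """Render a skull-stripped CT-like volume with known contact positions.

    Blob peak intensity is 1000 (arbitrary CT-like units); the brain
    background plateau is peak / intensity_ratio and additive white noise has
    sd = noise_sd * peak.  Shafts are rejected and re-drawn until every pair
    of electrodes keeps >= 2 contact diameters of clearance along the whole
    shaft.
    """
    rng = np.random.default_rng(seed)
    if affine is None:
        affine = np.eye(4)
    shape = tuple(int(s) for s in shape)
    peak = 1000.0
    background = peak / spec.intensity_ratio
    sigma = spec.contact_diameter_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sd

    vol = Volume(data=np.zeros(shape), affine=np.asarray(affine, dtype=float))
    inv_vox = np.linalg.inv(vol.affine)

    # brain background: smooth ellipsoid centered in the grid
    center_vox = (np.asarray(shape) - 1) / 2.0
    center_mm = vol.voxel_to_mm(center_vox)
    semi_vox = np.asarray(shape) * 0.45
    ax = [((np.arange(s, dtype=float) - c) / sv) ** 2
          for s, c, sv in zip(shape, center_vox, semi_vox)]
    r2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
    data = background / (1.0 + np.exp((r2 - 1.0) / 0.05))  # soft ellipsoid edge
    del r2

    # electrode placement
    truth = GroundTruth()
    margin_vox = 3.0
    brain_radius_mm = float(np.min(semi_vox * vol.voxel_sizes))
    placed_dense: List[np.ndarray] = []
    min_sep = 2.0 * spec.contact_diameter_mm
    for _ in range(spec.n_electrodes):
        for attempt in range(max_retries):
            n_contacts = int(rng.integers(spec.contacts_min, spec.contacts_max + 1))
            head = center_mm + rng.normal(size=3) * 4.0 + rng.uniform(-4, 4, size=3)
            head = center_mm + (head - center_mm) / max(
                1.0, np.linalg.norm(head - center_mm) / 12.0
            )
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pts = _shaft_points(head, d, n_contacts, spec.pitch_mm,
                                spec.bend_amplitude_mm, rng)
            vox = vol.mm_to_voxel(pts)
            if (vox < margin_vox).any() or (vox > np.asarray(shape) - 1 - margin_vox).any():
                continue
            dense = _densify(pts)
            if any(_min_pair_distance(dense, other) < min_sep for other in placed_dense):
                continue
            placed_dense.append(dense)
            truth.contacts.append(pts)
            truth.directions.append(d)
            break
        else:
            raise PlacementError(
                f"could not place electrode {len(truth.contacts)} after {max_retries} tries"
            )

    # render blobs (within a 4-sigma box each, in voxel space)
    vox_size = vol.voxel_sizes
    for pts in truth.contacts:
        for p_mm in pts:
            p_vox = vol.mm_to_voxel(p_mm)
            half = np.ceil(4 * sigma / vox_size).astype(int)
            lo = np.maximum(0, np.floor(p_vox).astype(int) - half)
            hi = np.minimum(np.asarray(shape), np.ceil(p_vox).astype(int) + half + 1)
            sub = tuple(slice(l, h) for l, h in zip(lo, hi))
            gsub = np.stack(
                np.meshgrid(*[np.arange(l, h, dtype=float) for l, h in zip(lo, hi)],
                            indexing="ij"), axis=-1,
            )
            mm_sub = gsub @ vol.affine[:3, :3].T + vol.affine[:3, 3]
            dist2 = ((mm_sub - p_mm) ** 2).sum(-1)
            data[sub] += peak * np.exp(-dist2 / (2 * sigma ** 2))

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd * peak, size=shape)

    vol.data = data
    return vol, truth


# ---------------------------------------------------------------------------
# signal helpers
# ---------------------------------------------------------------------------


def pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n)
    return out / out.std()


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: Tuple[float, float]) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.normal(size=n))
    return x / x.std()


# ---------------------------------------------------------------------------
# ictal recordings
# ---------------------------------------------------------------------------


def make_ictal_recording(
    n_channels: int = 12,
    fs: float = 1000.0,
    soz_channels: Optional[Sequence[str]] = None,
    onset_lags: Optional[Dict[str, float]] = None,
    duration_s: float = 90.0,
    onset_start_s: float = 65.0,
    snr: float = 3.0,
    ramp_s: float = 0.5,
    band: Tuple[float, float] = (60.0, 140.0),
    baseline_amp_uv: float = 50.0,
    seed: int = 0,
) -> Tuple[Recording, GroundTruth]:
    """Pink-noise baseline with high-gamma onsets ramping up on SOZ channels.

    ``onset_lags`` maps SOZ channel names to lags (s) added to
    ``onset_start_s``; unnamed SOZ channels get lag 0.  The planted component
    is band-limited noise whose standard deviation ramps from 0 to
    ``snr`` x the channel's own baseline in-band sd with time constant
    ``ramp_s`` (saturating exponential), reproducing the gradual high-gamma
    build-up that the onset detector is meant to time.
    """
    if fs < 500:
        raise SamplingRateError(f"fs must be >= 500 Hz for ictal synthesis, got {fs}")
    rng = np.random.default_rng(seed)
    names = [f"CH{i:02d}" for i in range(n_channels)]
    soz = list(soz_channels) if soz_channels else []
    unknown = set(soz) - set(names)
    if unknown:
        raise ValueError(f"soz_channels not in recording: {sorted(unknown)}")
    lags = dict(onset_lags or {})

    n = int(round(duration_s * fs))
    sig = np.empty((n_channels, n))
    truth = GroundTruth(soz_channels=soz)
    t = np.arange(n) / fs

    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    for i, name in enumerate(names):
        base = baseline_amp_uv * pink_noise(rng, n, fs)
        sig[i] = base
        if name in soz:
            onset = onset_start_s + float(lags.get(name, 0.0))
            if not (0.0 <= onset < duration_s):
                raise ValueError(f"onset time {onset}s outside the recording")
            inband_sd = float(sps.sosfiltfilt(sos, base).std())
            burst = _bandlimited_noise(rng, n, fs, band)
            ramp = np.zeros(n)
            after = t >= onset
            ramp[after] = 1.0 - np.exp(-(t[after] - onset) / ramp_s)
            sig[i] = base + snr * inband_sd * ramp * burst
            truth.onset_times[name] = onset

    return Recording(signal=sig, fs=fs, channel_names=names), truth


# ---------------------------------------------------------------------------
# interictal recordings
# ---------------------------------------------------------------------------


def _tukey_burst(n: int, fs: float, f0: float, phase: float, alpha: float = 0.2) -> np.ndarray:
    """Unit-plateau Tukey-windowed sinusoidal burst."""
    t = np.arange(n) / fs
    return sps.windows.tukey(n, alpha=alpha) * np.cos(2 * np.pi * f0 * t + phase)


def _place_events(rng: np.random.Generator, n_events: int, duration_s: float,
                  dur_range_s: Tuple[float, float], min_gap_s: float,
                  edge_s: float = 0.5, max_tries: int = 2000) -> List[Tuple[float, float]]:
    events: List[Tuple[float, float]] = []
    for _ in range(max_tries):
        if len(events) == n_events:
            break
        d = rng.uniform(*dur_range_s)
        s = rng.uniform(edge_s, duration_s - edge_s - d)
        ok = all(s > e1 + min_gap_s or s + d < s0 - min_gap_s for s0, e1 in events)
        if ok:
            events.append((s, s + d))
            events.sort()
    if len(events) < n_events:
        raise PlacementError(
            f"could not place {n_events} events with gap >= {min_gap_s}s in {duration_s}s"
        )
    return events


def make_interictal_recording(
    n_channels: int = 8,
    fs: float = 1000.0,
    event_rate_per_channel: float = 6.0,
    event_snr: float = 3.0,
    duration_s: float = 60.0,
    soz_channels: Optional[Sequence[str]] = None,
    background_rate: float = 0.0,
    band: Tuple[float, float] = (80.0, 250.0),
    dur_range_ms: Tuple[float, float] = (60.0, 150.0),
    min_gap_ms: float = 100.0,
    baseline_amp_uv: float = 50.0,
    seed: int = 0,
) -> Tuple[Recording, GroundTruth]:
    """Pink-noise floor with ripple bursts planted at known times.

    If ``soz_channels`` is given, those channels receive
    ``event_rate_per_channel`` events/min and the rest ``background_rate``;
    otherwise every channel gets the full rate.  Burst amplitude is set so
    the mean analytic envelope of the planted component over the event equals
    ``event_snr`` x the channel's background ripple-band envelope median.
    """
    if fs <= 2 * band[1]:
        raise SamplingRateError(f"fs={fs} too low for the {band} Hz band")
    rng = np.random.default_rng(seed)
    names = [f"CH{i:02d}" for i in range(n_channels)]
    soz = list(soz_channels) if soz_channels is not None else names
    unknown = set(soz) - set(names)
    if unknown:
        raise ValueError(f"soz_channels not in recording: {sorted(unknown)}")

    n = int(round(duration_s * fs))
    sig = np.empty((n_channels, n))
    truth = GroundTruth(soz_channels=list(soz) if soz_channels is not None else [])
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    tukey_mean = float(sps.windows.tukey(1000, alpha=0.2).mean())

    for i, name in enumerate(names):
        base = baseline_amp_uv * pink_noise(rng, n, fs)
        env_med = float(np.median(np.abs(sps.hilbert(sps.sosfiltfilt(sos, base)))))
        rate = event_rate_per_channel if name in soz else background_rate
        n_events = int(round(rate * duration_s / 60.0))
        events = (
            _place_events(rng, n_events, duration_s,
                          (dur_range_ms[0] / 1000.0, dur_range_ms[1] / 1000.0),
                          min_gap_ms / 1000.0)
            if n_events > 0
            else []
        )
        # 15% headroom over the taper mean covers band-edge filter losses and
        # envelope/phase interplay, keeping mean in-event envelope >= snr x median
        amp = 1.15 * event_snr * env_med / tukey_mean
        for (s, e) in events:
            i0, i1 = int(round(s * fs)), int(round(e * fs))
            f0 = rng.uniform(band[0] + 20, band[1] - 50)
            base[i0:i1] += amp * _tukey_burst(i1 - i0, fs, f0, rng.uniform(0, 2 * np.pi))
        sig[i] = base
        truth.event_times[name] = events

    return Recording(signal=sig, fs=fs, channel_names=names), truth
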