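"""Domain containers and file I/O.

Conventions used everywhere in the package:

* voxel indices are 0-based; user-facing coordinates are mm scanner space
  obtained through the volume affine;
* all signal segments are half-open sample intervals ``[start, end)``;
* recordings are channels x samples in microvolts.

Volumes travel as NIfTI-1 (via nibabel).  Recordings travel either as
tab-separated text (header row of channel names, one column per channel,
sampling rate supplied separately) or as 16-bit EDF.  EDF is read through
mne; writing uses a small plain-EDF encoder in this module.
"""
from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DuplicateChannelError,
    NonVolumeError,
    SamplingRateError,
    SingularAffineError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar intensity grid with a voxel-index -> mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise NonVolumeError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise SingularAffineError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SingularAffineError("affine is singular")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        single = ijk.ndim == 1
        out = np.atleast_2d(ijk) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if single else out

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        single = xyz.ndim == 1
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if single else out


@dataclass
class Recording:
    """Multichannel SEEG signal: channels x samples (microvolts)."""

    signal: np.ndarray
    fs: float
    channel_names: List[str]

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise SamplingRateError(f"fs must be > 0, got {self.fs}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("one channel name per signal row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise DuplicateChannelError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SegmentSpec:
    """Baseline and target analysis windows, half-open sample intervals."""

    baseline: Tuple[int, int]
    target: Tuple[int, int]

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        t0, t1 = self.target
        if not (0 <= b0 < b1):
            raise ValueError(f"baseline interval empty or negative: {self.baseline}")
        if not (0 <= t0 < t1):
            raise ValueError(f"target interval empty or negative: {self.target}")
        if b1 > t0:
            raise ValueError("baseline must precede the target start")

    def validate_against(self, n_samples: int) -> None:
        if self.target[1] > n_samples or self.baseline[1] > n_samples:
            raise ValueError("segment extends past the end of the recording")

    @classmethod
    def from_seconds(cls, baseline_s, target_s, fs: float) -> "SegmentSpec":
        to_samp = lambda t: int(round(t * fs))
        return cls(
            baseline=(to_samp(baseline_s[0]), to_samp(baseline_s[1])),
            target=(to_samp(target_s[0]), to_samp(target_s[1])),
        )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Load a NIfTI-1 volume; sanitizes non-finite voxels to 0 (logged)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise NonVolumeError(f"{path} has ndim={data.ndim}; a 3D volume is required")
    bad = ~np.isfinite(data)
    if bad.any():
        logger.warning("%s: %d non-finite voxels set to 0", path, int(bad.sum()))
        data = np.where(bad, 0.0, data)
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# recordings: delimited text
# ---------------------------------------------------------------------------

def read_recording_tsv(path, fs: float) -> Recording:
    """Tab-separated recording: header row of channel names, one column each."""
    if fs <= 0:
        raise SamplingRateError(f"fs must be > 0, got {fs}")
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split("\t")
    if len(set(names)) != len(names):
        raise DuplicateChannelError(f"repeated channel name in {path}")
    df = pd.read_csv(path, sep="\t")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"non-numeric or non-finite samples in {path}")
    return Recording(signal=values.T, fs=fs, channel_names=names)


def write_recording_tsv(recording: Recording, path) -> None:
    df = pd.DataFrame(recording.signal.T, columns=recording.channel_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# recordings: EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF field overflow: {s!r} > {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_phys(x: float) -> str:
    """Format a physical min/max into <= 8 ASCII chars."""
    for fmt in ("%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot encode {x} in 8 chars")


def write_recording_edf(recording: Recording, path) -> None:
    """Write a minimal 16-bit EDF file (one data record holding all samples).

    Physical ranges are per-channel; values quantize onto 65535 digital steps,
    so round trips agree to within (pmax - pmin) / 65535 per channel.
    """
    sig = recording.signal
    n_ch, n_samp = sig.shape
    dmin, dmax = -32768, 32767

    pmins, pmaxs, digital = [], [], []
    for row in sig:
        lo, hi = float(row.min()), float(row.max())
        if hi <= lo:
            hi = lo + 1.0
        # re-parse the truncated ASCII so scaling matches what a reader sees
        lo_s, hi_s = _fmt_phys(lo), _fmt_phys(hi)
        lo_p, hi_p = float(lo_s), float(hi_s)
        if hi_p <= lo_p:
            hi_p = lo_p + 1.0
            hi_s = _fmt_phys(hi_p)
        gain = (dmax - dmin) / (hi_p - lo_p)
        dig = np.clip(np.round((row - lo_p) * gain + dmin), dmin, dmax)
        pmins.append(lo_s)
        pmaxs.append(hi_s)
        digital.append(dig.astype("<i2"))

    record_duration = n_samp / recording.fs
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(1, 8),
            _edf_field(_fmt_phys(record_duration), 8),
            _edf_field(n_ch, 4),
        ]
    )
    per = b"".join(_edf_field(name[:16], 16) for name in recording.channel_names)
    per += b"".join(_edf_field("", 80) for _ in range(n_ch))
    per += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    per += b"".join(_edf_field(s, 8) for s in pmins)
    per += b"".join(_edf_field(s, 8) for s in pmaxs)
    per += b"".join(_edf_field(dmin, 8) for _ in range(n_ch))
    per += b"".join(_edf_field(dmax, 8) for _ in range(n_ch))
    per += b"".join(_edf_field("", 80) for _ in range(n_ch))
    per += b"".join(_edf_field(n_samp, 8) for _ in range(n_ch))
    per += b"".join(_edf_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + per)
        for dig in digital:
            fh.write(dig.tobytes())


def read_recording_edf(path) -> Recording:
    """Read an EDF recording through mne; output in microvolts."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    if len(set(names)) != len(names):
        raise DuplicateChannelError(f"repeated channel name in {path}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(signal=data, fs=float(raw.info["sfreq"]), channel_names=names)


def read_recording(path, format: str | None = None, fs: float | None = None) -> Recording:
    """Dispatch on format ('edf' | 'delimited'); inferred from suffix if None."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return read_recording_edf(path)
    if format == "delimited":
        if fs is None:
            raise SamplingRateError("sampling rate required for delimited recordings")
        return read_recording_tsv(path, fs=fs)
    raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """TSV with an optional '#'-prefixed config-echo first line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
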