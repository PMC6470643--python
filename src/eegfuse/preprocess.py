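"""Recordings, epoch segmentation, and sub-band filtering.

A :class:`Recording` is a plain multichannel signal (channels x samples)
with a sampling rate and channel labels. Recordings are cut into
non-overlapping fixed-length epochs (:func:`segment`) and optionally
band-pass filtered into the six standard EEG sub-bands used throughout
the package (:data:`DEFAULT_BANDS`): delta 0.5-4, theta 4-7, alpha 8-12,
beta 13-30, gamma1 30-40 and gamma2 41-100 Hz. The printed gaps between
bands (7-8, 12-13, 40-41 Hz) are deliberate and preserved; relative band
power always normalises by the full 0.5-100 Hz range, not the band union.

On-disk formats: a delimited-text matrix (one channel per row) with a
plain-text ``key: value`` sidecar, or EDF (read through :mod:`mne`,
written by :func:`write_edf`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "DEFAULT_CHANNELS",
    "EpochSet",
    "Recording",
    "TOTAL_RANGE",
    "bandpass",
    "bandpass_array",
    "read_recording",
    "read_sidecar",
    "segment",
    "write_edf",
    "write_recording",
]

#: Frontal electrodes analysed by default.
DEFAULT_CHANNELS = ["FP1", "FP2", "F3", "F4", "F7", "F8"]

#: Full frequency range (Hz) used as the relative-power denominator.
TOTAL_RANGE = (0.5, 100.0)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, got [{self.f_low}, {self.f_high}]"
            )


#: The six sub-bands, in ascending frequency order.
DEFAULT_BANDS = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma1": BandDefinition("gamma1", 30.0, 40.0),
    "gamma2": BandDefinition("gamma2", 41.0, 100.0),
}


@dataclass
class Recording:
    """Multichannel signal (channels x samples) with metadata.

    Parameters
    ----------
    data
        Real matrix of shape (n_channels, n_samples), microvolt-scale
        arbitrary units.
    fs
        Sampling rate in Hz, > 0.
    channel_labels
        One label per channel.
    subject_id
        Identifier of the subject/session.
    label
        Optional class label in {0, 1} (1 = positive class).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        n_ch, n_samp = self.data.shape
        if n_ch < 1 or n_samp < 2:
            raise ValueError(f"need >= 1 channel and >= 2 samples, got {self.data.shape}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"channel_labels has {len(self.channel_labels)} entries "
                f"but data has {n_ch} channels"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping epochs from one recording.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch); the
    epochs are contiguous slices of the source recording starting at
    sample 0. ``band`` names the sub-band the data was filtered into, or
    None for broadband.
    """

    epochs: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    label: int | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError(f"epochs must be 3-D, got shape {self.epochs.shape}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


def segment(rec: Recording, epoch_seconds: float, n_epochs: int | None = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    Epochs start at sample 0; any leftover tail shorter than one epoch is
    discarded. If ``n_epochs`` is omitted the maximal whole number of
    epochs is taken.
    """
    if epoch_seconds <= 0:
        raise ValueError(f"epoch_seconds must be > 0, got {epoch_seconds}")
    spe = int(round(epoch_seconds * rec.fs))
    max_epochs = rec.n_samples // spe
    if max_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one epoch of {epoch_seconds} s"
        )
    if n_epochs is None:
        n_epochs = max_epochs
    elif n_epochs > max_epochs:
        raise ValueError(
            f"requested {n_epochs} epochs of {epoch_seconds} s but recording only holds {max_epochs}"
        )
    used = rec.data[:, : n_epochs * spe]
    epochs = used.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2).copy()
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
        label=rec.label,
    )


def _band_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """Butterworth SOS for one band; degrades to high-pass at the Nyquist edge."""
    nyq = fs / 2.0
    if band.f_low >= nyq:
        raise ValueError(f"band {band.name!r} low edge {band.f_low} Hz >= Nyquist {nyq} Hz")
    if band.f_high >= 0.999 * nyq:
        # All-pass above f_low: only the low edge is inside the spectrum.
        return signal.butter(order, band.f_low, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    sos = _band_sos(band, fs, order=order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass(eps: EpochSet, band: BandDefinition, order: int = 4) -> EpochSet:
    """Return a band-pass-filtered copy of an epoch set, tagged with the band name.

    The filter is a zero-phase forward-backward Butterworth (default
    order 4 per direction), applied independently per epoch and channel.
    The input is left unmodified.
    """
    out = bandpass_array(eps.epochs, band, eps.fs, order=order)
    return replace(eps, epochs=out, band=band.name)


def highpass_detrend(rec: Recording, f_cut: float = 0.5, order: int = 4) -> Recording:
    """Optional preprocessing hook: zero-phase high-pass detrend.

    Stands in for artifact removal, which is out of scope; the default
    pipeline applies no cleaning at all.
    """
    sos = signal.butter(order, f_cut, btype="highpass", fs=rec.fs, output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=-1))


# ---------------------------------------------------------------------------
# I/O: delimited text + sidecar, EDF
# ---------------------------------------------------------------------------

def read_sidecar(path: str | os.PathLike) -> dict[str, str]:
    """Parse a ``key: value`` plain-text sidecar file."""
    meta: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"sidecar line not in 'key: value' form: {line!r}")
        key, val = line.split(":", 1)
        meta[key.strip()] = val.strip()
    return meta


def write_recording(rec: Recording, path: str | os.PathLike, delimiter: str = "\t") -> None:
    """Write a recording as a delimited-text matrix plus a ``.meta`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=delimiter, fmt="%.8g")
    lines = [f"fs: {rec.fs:g}", f"labels: {','.join(rec.channel_labels)}"]
    if rec.subject_id:
        lines.append(f"subject_id: {rec.subject_id}")
    if rec.label is not None:
        lines.append(f"label: {rec.label}")
    path.with_suffix(path.suffix + ".meta").write_text("\n".join(lines) + "\n")


def _read_matrix(path: Path, meta: dict[str, str]) -> Recording:
    if "fs" not in meta:
        raise ValueError(f"matrix recording {path} requires 'fs' in its sidecar")
    data = np.loadtxt(path, ndmin=2)
    labels = [s for s in meta.get("labels", "").split(",") if s]
    if labels and len(labels) != data.shape[0]:
        raise ValueError(
            f"{path}: sidecar lists {len(labels)} channel labels but matrix has "
            f"{data.shape[0]} rows"
        )
    label = meta.get("label")
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=labels,
        subject_id=meta.get("subject_id", path.stem),
        label=None if label is None else int(label),
    )


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def read_recording(
    path: str | os.PathLike,
    format: str | None = None,
    meta: dict[str, str] | str | os.PathLike | None = None,
) -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path
        Matrix text file or EDF file.
    format
        ``"matrix"`` or ``"edf"``; inferred from the extension when None.
    meta
        Sidecar metadata for matrix files: a dict, a path to a sidecar
        file, or None to look for ``<path>.meta`` next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format != "matrix":
        raise ValueError(f"unknown recording format {format!r}")
    if meta is None:
        sidecar = path.with_suffix(path.suffix + ".meta")
        if not sidecar.exists():
            raise ValueError(f"matrix recording {path} has no sidecar {sidecar} and no meta given")
        meta = read_sidecar(sidecar)
    elif not isinstance(meta, dict):
        meta = read_sidecar(meta)
    return _read_matrix(path, meta)


def write_edf(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as a plain EDF file (16-bit samples, 1-s records).

    The sampling rate must be a positive integer and the signal length a
    whole number of seconds. Physical units are recorded as microvolts,
    so values survive a round trip through any EDF reader up to the
    16-bit quantisation step of each channel.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF export requires an integer sampling rate, got {rec.fs}")
    if rec.n_samples % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds of data")
    n_records = rec.n_samples // fs
    n_ch = rec.n_channels

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((rec.data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    def pad(value: object, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),  # version
            pad(rec.subject_id or "X", 80),  # patient id
            pad("eegfuse export", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(256 + 256 * n_ch, 8),  # header bytes
            pad("", 44),
            pad(n_records, 8),
            pad("1", 8),  # record duration, seconds
            pad(n_ch, 4),
        ]
    )
    header += b"".join(pad(lbl, 16) for lbl in rec.channel_labels)
    header += b"".join(pad("EEG", 80) for _ in range(n_ch))  # transducer
    header += b"".join(pad("uV", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{v:.6g}", 8) for v in pmin)
    header += b"".join(pad(f"{v:.6g}", 8) for v in pmax)
    header += b"".join(pad(dmin, 8) for _ in range(n_ch))
    header += b"".join(pad(dmax, 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(pad(fs, 8) for _ in range(n_ch))  # samples per record
    header += b"".join(pad("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def edf_quantisation_step(rec: Recording) -> np.ndarray:
    """Per-channel quantisation step of :func:`write_edf`, shape (n_channels,)."""
    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    rng = np.maximum(pmax - pmin, 1e-12)
    return rng / 65535.0
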