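"""Multichannel EEG recording container and plain-text / EDF input-output.

The canonical interchange format is a self-describing text matrix: a small
``# key: value`` header (format tag, sampling rate, channel names, reference
state) followed by one whitespace-separated row per sample (samples x
channels, row-major).  EDF files are read through :mod:`mne` when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_FORMAT_TAG = "microdyn-recording v1"


@dataclass
class Recording:
    """An EEG recording: ``data`` is channels x samples, in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in µV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per row of ``data``.
    reference : {"original", "average"}
        Referencing state of the data.
    history : list of str
        Ordered audit trail of processing steps applied so far.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    reference: str = "original"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            reference=self.reference,
            history=list(self.history),
        )


def write_text(rec: Recording, path: str | Path) -> None:
    """Write a recording in the plain-text matrix format."""
    path = Path(path)
    header = [
        f"# {_FORMAT_TAG}",
        f"# fs_hz: {rec.fs!r}",
        f"# n_channels: {rec.n_channels}",
        f"# n_samples: {rec.n_samples}",
        f"# reference: {rec.reference}",
        "# channels: " + ",".join(rec.channel_names),
    ]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.10g")


def read_text(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_text`."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    if _FORMAT_TAG.split()[0] not in str(meta) and n_header == 0:
        raise ValueError(f"{path} is not a microdyn recording file")
    data = np.loadtxt(path, skiprows=n_header, ndmin=2).T
    names = meta["channels"].split(",")
    return Recording(
        data=data,
        fs=float(meta["fs_hz"]),
        channel_names=names,
        reference=meta.get("reference", "original"),
    )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via mne; voltages are converted to µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        reference="original",
    )


def read_recording(path: str | Path) -> Recording:
    """Dispatch on file suffix: ``.edf`` via mne, anything else as text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return read_text(path)
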