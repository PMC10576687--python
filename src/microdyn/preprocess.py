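"""Deterministic preprocessing: channel selection, zero-phase band-pass,
resampling, average reference, amplitude-based window rejection, trimming.

The filter is a linear-phase FIR applied with exact group-delay
compensation (zero net phase), because microstate timing must not be
phase-distorted.  Filtering happens at the original rate before
resampling so the 45 Hz edge cannot alias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    band: tuple[float, float] = (1.0, 45.0)
    fs_target: float = 250.0
    exclude_channels: tuple[str, ...] = ()
    epoch_s: float = 2.0
    reject_uv: float = 100.0
    keep_s: float = 120.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.fs_target / 2:
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < fs_target/2"
            )
        if self.reject_uv <= 0:
            raise ValueError("reject_uv must be positive")


def select_channels(rec: Recording, exclude: list[str]) -> Recording:
    """Drop the named channels, preserving the order of the rest."""
    unknown = [name for name in exclude if name not in rec.channel_names]
    if unknown:
        raise ValueError(f"unknown channel names in exclusion list: {unknown}")
    keep = [i for i, n in enumerate(rec.channel_names) if n not in set(exclude)]
    return Recording(
        data=rec.data[keep],
        fs=rec.fs,
        channel_names=[rec.channel_names[i] for i in keep],
        reference=rec.reference,
        history=rec.history + [f"select_channels(excluded={len(exclude)})"],
    )


def _zero_phase_bandpass(
    data: np.ndarray, fs: float, low: float, high: float
) -> np.ndarray:
    """Symmetric-FIR band-pass with the group delay removed exactly."""
    # transition width ~ the low edge; Hamming design rule 3.3 / (dF/fs)
    trans = min(low, 1.0)
    numtaps = int(3.3 * fs / trans)
    numtaps += 1 - numtaps % 2  # odd -> integer group delay, exact zero phase
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    half = numtaps // 2
    padded = np.pad(data, [(0, 0), (half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, half:-half]


def apply_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous channel mean (idempotent)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(
        data=data,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        reference="average",
        history=rec.history + ["average_reference"],
    )


def filter_resample_reref(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Band-pass at the native rate, anti-aliased resample, average reference."""
    low, high = cfg.band
    if rec.fs < 2 * high:
        raise ValueError(
            f"band edge {high} Hz outside Nyquist range of fs={rec.fs}"
        )
    data = _zero_phase_bandpass(rec.data, rec.fs, low, high)
    history = rec.history + [f"bandpass({low}-{high} Hz)"]
    if rec.fs != cfg.fs_target:
        frac = Fraction(cfg.fs_target / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        history = history + [f"resample({rec.fs}->{cfg.fs_target} Hz)"]
    out = Recording(
        data=data,
        fs=cfg.fs_target,
        channel_names=list(rec.channel_names),
        reference=rec.reference,
        history=history,
    )
    return apply_average_reference(out)


def reject_and_trim(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Reject ±``reject_uv`` windows, concatenate survivors, keep ``keep_s``.

    The recording is cut into contiguous non-overlapping ``epoch_s``
    windows; a window dies if any channel exceeds the threshold anywhere in
    it.  Survivors are concatenated in time order and truncated to the
    first ``keep_s`` seconds; a shorter-than-requested survivor set is a
    warning, not an error.
    """
    win = int(round(cfg.epoch_s * rec.fs))
    if rec.n_samples < win:
        raise ValueError("recording shorter than one epoch")
    n_win = rec.n_samples // win
    windows = rec.data[:, : n_win * win].reshape(rec.n_channels, n_win, win)
    ok = np.abs(windows).max(axis=(0, 2)) <= cfg.reject_uv
    if not ok.any():
        raise ValueError("no artifact-free windows survive rejection")
    surviving = windows[:, ok, :].reshape(rec.n_channels, -1)
    keep_n = int(round(cfg.keep_s * rec.fs))
    if surviving.shape[1] < keep_n:
        warnings.warn(
            f"only {surviving.shape[1] / rec.fs:.1f} s survive rejection "
            f"(requested {cfg.keep_s} s); proceeding with available data",
            stacklevel=2,
        )
    out = surviving[:, :keep_n]
    return Recording(
        data=out,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        reference=rec.reference,
        history=rec.history
        + [
            f"reject(kept {int(ok.sum())}/{n_win} windows)",
            f"trim({out.shape[1] / rec.fs:.1f} s)",
        ],
    )


def apply_external_cleaning(rec: Recording, cleaner=None) -> Recording:
    """Hook for externally supplied artifact cleaning.

    Manual steps (ocular-component removal, bad-channel interpolation) are
    human-in-the-loop and not implemented here; users who pre-clean with
    another tool can pass a ``cleaner(Recording) -> Recording`` callable.
    With no cleaner this is a recorded no-op.
    """
    if cleaner is None:
        out = rec.copy()
        out.history.append("external_cleaning(skipped)")
        return out
    out = cleaner(rec)
    if not isinstance(out, Recording):
        raise ValueError("cleaner must return a Recording")
    out.history.append("external_cleaning(applied)")
    return out


def preprocess(
    rec: Recording, cfg: PreprocessConfig | None = None, cleaner=None
) -> Recording:
    """Full deterministic chain: select -> clean hook -> filter/resample/
    reref -> reject/trim."""
    cfg = cfg or PreprocessConfig()
    out = select_channels(rec, list(cfg.exclude_channels))
    out = apply_external_cleaning(out, cleaner)
    out = filter_resample_reref(out, cfg)
    return reject_and_trim(out, cfg)
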