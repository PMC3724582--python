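"""Band-pass filtering and non-overlapping segmentation.

Recordings are filtered per-trial with a zero-phase 4th-order Butterworth
band-pass (30–450 Hz by default), then the active signal of each gesture is
concatenated across trials per channel and cut into contiguous
non-overlapping windows (256 ms by default).  Ten seconds of active signal
at 1000 Hz therefore yields floor(10000/256) = 39 windows per gesture per
channel; the incomplete tail is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from facemg.synthetic import ConfigurationError, EmgRecording

__all__ = [
    "Segment",
    "bandpass_filter",
    "filter_recording",
    "segment_signal",
    "segment_dataset",
    "DEFAULT_BAND",
    "DEFAULT_WINDOW_MS",
]

logger = logging.getLogger(__name__)

DEFAULT_BAND = (30.0, 450.0)
DEFAULT_WINDOW_MS = 256.0


@dataclass
class Segment:
    """One fixed-length window of a single channel (the x_1..x_N of a feature)."""

    values: np.ndarray
    channel: int
    gesture_id: str
    segment_index: int  # 0-based position within the concatenated active signal
    subject: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("segment values must be 1-D")

    def __len__(self) -> int:
        return self.values.size


def bandpass_filter(
    signal: np.ndarray, fs: float, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``) so amplitude features see no
    group-delay shift; the effective magnitude response is the square of the
    4th-order prototype.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < low < high:
        raise ConfigurationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ConfigurationError(f"band edge {high} Hz >= Nyquist {fs / 2} Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, signal, axis=-1)


def filter_recording(
    rec: EmgRecording, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]
) -> EmgRecording:
    """Return a copy of ``rec`` with every channel band-pass filtered."""
    return EmgRecording(
        samples=bandpass_filter(rec.samples, rec.sampling_rate, low, high),
        sampling_rate=rec.sampling_rate,
        gesture_id=rec.gesture_id,
        trial=rec.trial,
        subject=rec.subject,
    )


def window_samples(window_ms: float, fs: float) -> int:
    """Window length in samples: round(window_ms * fs / 1000)."""
    n = int(round(window_ms * fs / 1000.0))
    if n < 2:
        raise ConfigurationError(f"window of {window_ms} ms at {fs} Hz has < 2 samples")
    return n


def segment_signal(
    signal: np.ndarray,
    fs: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    *,
    channel: int = 0,
    gesture_id: str = "",
    subject: str = "",
) -> list[Segment]:
    """Cut a 1-D signal into contiguous non-overlapping windows.

    Returns floor(len / window) complete windows in order; an incomplete
    tail is discarded.  A signal shorter than one window yields an empty
    list and a logged warning.
    """
    signal = np.asarray(signal, dtype=float)
    if window_ms <= 0:
        raise ConfigurationError("window_ms must be positive")
    n = window_samples(window_ms, fs)
    count = signal.size // n
    if count == 0:
        logger.warning(
            "signal of %d samples shorter than one %d-sample window; no segments",
            signal.size,
            n,
        )
        return []
    return [
        Segment(
            values=signal[i * n : (i + 1) * n],
            channel=channel,
            gesture_id=gesture_id,
            segment_index=i,
            subject=subject,
        )
        for i in range(count)
    ]


def segment_dataset(
    recordings: Sequence[EmgRecording],
    window_ms: float = DEFAULT_WINDOW_MS,
    band: tuple[float, float] | None = DEFAULT_BAND,
) -> dict[tuple[str, int], list[Segment]]:
    """Filter, concatenate and segment a dataset of recordings.

    Filtering runs per-trial (avoiding splicing discontinuities); the
    filtered active signal is then concatenated across trials per
    (gesture, channel) and segmented, matching the windowing arithmetic of
    a 10-s active signal per gesture.  Pass ``band=None`` to skip filtering.

    Returns a dict mapping ``(gesture_id, channel)`` to the ordered segments.
    """
    if band is not None:
        recordings = [filter_recording(r, *band) for r in recordings]
    groups: dict[tuple[str, int], list[EmgRecording]] = {}
    order: list[tuple[str, int]] = []
    for rec in recordings:
        for ch in range(rec.n_channels):
            key = (rec.gesture_id, ch)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(rec)
    out: dict[tuple[str, int], list[Segment]] = {}
    for gesture_id, ch in order:
        recs = sorted(groups[(gesture_id, ch)], key=lambda r: r.trial)
        fs = recs[0].sampling_rate
        concatenated = np.concatenate([r.samples[ch] for r in recs])
        out[(gesture_id, ch)] = segment_signal(
            concatenated,
            fs,
            window_ms,
            channel=ch,
            gesture_id=gesture_id,
            subject=recs[0].subject,
        )
    return out
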