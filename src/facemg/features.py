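"""Time-domain EMG features and feature-set assembly.

Implements the ten classical time-domain features computed per window of N
samples x_1..x_N:

====== =====================================================================
MAV    mean absolute value, (1/N) sum |x_i|
MAVS   mean absolute value slope, MAV_{k+1} - MAV_k between adjacent windows
RMS    root mean square, sqrt((1/N) sum x_i^2)
VAR    population variance, (1/N) sum (x_i - mean)^2
WL     waveform length, sum |x_{i+1} - x_i|
IEMG   integrated EMG, sum |x_i|
SSC    thresholded sign-slope changes (count of interior local maxima with
       x_i - x_{i+1} >= epsilon; a config flag adds the minima test)
MV     mean value
SSI    simple square integral, sum x_i^2
MPV    maximum absolute peak value, max |x_i|
====== =====================================================================

A per-subject :class:`FeatureSet` holds one row per (gesture, window) and one
column per channel for a single feature (390 x 3 at study defaults: 10
gestures x 39 windows, 3 channels), or 3k columns for a k-feature
combination laid out channel-major within feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from facemg.preprocess import (
    DEFAULT_BAND,
    DEFAULT_WINDOW_MS,
    Segment,
    segment_dataset,
)
from facemg.synthetic import EmgRecording

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureSet",
    "feature_value",
    "mavs_series",
    "build_feature_set",
    "build_all_feature_sets",
    "combine_feature_sets",
]

#: Canonical feature order used when "all" features are requested.
FEATURE_NAMES = ("MAV", "MAVS", "RMS", "VAR", "WL", "IEMG", "SSC", "MV", "SSI", "MPV")

#: Features computable from one window in isolation (MAVS needs the series).
SEGMENT_FEATURES = ("MAV", "RMS", "VAR", "WL", "IEMG", "SSC", "MV", "SSI", "MPV")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of feature extraction.

    ssc_epsilon
        Noise-rejection threshold of the SSC count (EMG units, default 0.02).
    mavs_pad
        Policy filling the last MAVS element so the series keeps the window
        count: ``"zero"`` or ``"replicate"`` (repeat the final difference).
    ssc_both_extrema
        When true, SSC also counts thresholded local minima (the
        conventional slope-sign-change definition); off by default.
    """

    ssc_epsilon: float = 0.02
    mavs_pad: str = "zero"
    ssc_both_extrema: bool = False

    def __post_init__(self) -> None:
        if self.ssc_epsilon < 0:
            raise ValueError("ssc_epsilon must be >= 0")
        if self.mavs_pad not in ("zero", "replicate"):
            raise ValueError(f"unknown mavs_pad policy {self.mavs_pad!r}")


def _values(segment: Segment | np.ndarray) -> np.ndarray:
    if isinstance(segment, Segment):
        return segment.values
    return np.asarray(segment, dtype=float)


def _ssc(x: np.ndarray, eps: float, both_extrema: bool) -> float:
    if x.size < 3:
        return 0.0
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    peaks = (cur > prev) & (cur > nxt) & (cur - nxt >= eps)
    count = int(np.count_nonzero(peaks))
    if both_extrema:
        troughs = (cur < prev) & (cur < nxt) & (nxt - cur >= eps)
        count += int(np.count_nonzero(troughs))
    return float(count)


def feature_value(
    segment: Segment | np.ndarray,
    method: str,
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Evaluate one time-domain feature on one window.

    ``method`` is case-insensitive and must be one of the nine per-window
    features (MAVS is a series-level feature; see :func:`mavs_series`).
    """
    x = _values(segment)
    name = method.upper()
    if name == "MAVS":
        raise ValueError("MAVS is defined between adjacent windows; use mavs_series")
    if name not in SEGMENT_FEATURES:
        raise ValueError(f"unknown feature {method!r}")
    if name in ("WL", "SSC") and x.size < 2:
        raise ValueError(f"{name} requires at least 2 samples")
    if name == "MAV":
        return float(np.mean(np.abs(x)))
    if name == "RMS":
        return float(np.sqrt(np.mean(x**2)))
    if name == "VAR":
        return float(np.mean((x - np.mean(x)) ** 2))
    if name == "WL":
        return float(np.sum(np.abs(np.diff(x))))
    if name == "IEMG":
        return float(np.sum(np.abs(x)))
    if name == "SSC":
        return _ssc(x, config.ssc_epsilon, config.ssc_both_extrema)
    if name == "MV":
        return float(np.mean(x))
    if name == "SSI":
        return float(np.sum(x**2))
    # MPV
    return float(np.max(np.abs(x)))


def mavs_series(
    mav_values: Sequence[float], pad: str = "zero"
) -> np.ndarray:
    """Differences of adjacent MAV values, padded to the input length.

    Element k is MAV_{k+1} - MAV_k for k = 1..K-1; the final element is 0
    (``pad="zero"``) or a copy of the last difference (``pad="replicate"``)
    so that every window keeps one value per feature.
    """
    mav = np.asarray(mav_values, dtype=float)
    if mav.size < 2:
        raise ValueError("MAVS needs at least 2 windows")
    diffs = np.diff(mav)
    if pad == "zero":
        tail = 0.0
    elif pad == "replicate":
        tail = diffs[-1]
    else:
        raise ValueError(f"unknown pad policy {pad!r}")
    return np.concatenate([diffs, [tail]])


@dataclass
class FeatureSet:
    """Labeled matrix of per-window feature vectors.

    ``matrix`` has one row per (gesture, window) and one column per
    (feature, channel) pair described by ``column_meta``; ``row_labels``
    gives the gesture of each row.
    """

    matrix: np.ndarray
    row_labels: np.ndarray
    column_meta: list[tuple[str, int]]
    subject: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.row_labels = np.asarray(self.row_labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != self.row_labels.size:
            raise ValueError("row_labels length must match matrix rows")
        if self.matrix.shape[1] != len(self.column_meta):
            raise ValueError("column_meta length must match matrix columns")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{feat.lower()}_ch{ch + 1}" for feat, ch in self.column_meta]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.column_names)
        df.insert(0, "gesture", self.row_labels)
        return df

    def select_rows(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            matrix=self.matrix[idx],
            row_labels=self.row_labels[idx],
            column_meta=list(self.column_meta),
            subject=self.subject,
        )


def _per_gesture_segments(
    segments: Mapping[tuple[str, int], list[Segment]],
) -> tuple[list[str], list[int], int]:
    """Ordered gestures, ordered channels and the common window count."""
    gestures: list[str] = []
    channels: set[int] = set()
    for g, ch in segments:
        if g not in gestures:
            gestures.append(g)
        channels.add(ch)
    chans = sorted(channels)
    counts = {len(segments[(g, ch)]) for g in gestures for ch in chans}
    if counts == {0}:
        raise ValueError("dataset contains no complete window")
    if len(counts) != 1:
        raise ValueError(f"unequal window counts across gesture/channel: {counts}")
    return gestures, chans, counts.pop()


def build_feature_set(
    dataset: Sequence[EmgRecording] | Mapping[tuple[str, int], list[Segment]],
    method: str,
    config: FeatureConfig = FeatureConfig(),
    *,
    window_ms: float = DEFAULT_WINDOW_MS,
    band: tuple[float, float] | None = DEFAULT_BAND,
) -> FeatureSet:
    """Extract one feature from every window of a dataset.

    ``dataset`` is either a list of recordings (filtered and segmented here)
    or an already-segmented mapping from :func:`segment_dataset`.  Rows are
    ordered by gesture (order of appearance) then window index; columns are
    the channels.
    """
    name = method.upper()
    if name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {method!r}")
    if not isinstance(dataset, Mapping):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        dataset = segment_dataset(dataset, window_ms=window_ms, band=band)
    gestures, chans, n_seg = _per_gesture_segments(dataset)
    subject = next(iter(dataset.values()))[0].subject

    matrix = np.empty((len(gestures) * n_seg, len(chans)))
    labels = np.repeat(gestures, n_seg)
    for gi, g in enumerate(gestures):
        for ci, ch in enumerate(chans):
            segs = dataset[(g, ch)]
            if name == "MAVS":
                mav = [feature_value(s, "MAV", config) for s in segs]
                col = mavs_series(mav, pad=config.mavs_pad)
            else:
                col = [feature_value(s, name, config) for s in segs]
            matrix[gi * n_seg : (gi + 1) * n_seg, ci] = col
    return FeatureSet(
        matrix=matrix,
        row_labels=labels,
        column_meta=[(name, ch) for ch in chans],
        subject=subject,
    )


def build_all_feature_sets(
    dataset: Sequence[EmgRecording],
    config: FeatureConfig = FeatureConfig(),
    *,
    features: Sequence[str] = FEATURE_NAMES,
    window_ms: float = DEFAULT_WINDOW_MS,
    band: tuple[float, float] | None = DEFAULT_BAND,
) -> dict[str, FeatureSet]:
    """Segment once and extract every requested single feature."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    segments = segment_dataset(dataset, window_ms=window_ms, band=band)
    return {
        f.upper(): build_feature_set(segments, f, config) for f in features
    }


def combine_feature_sets(
    single_sets: Mapping[str, FeatureSet],
    order: Sequence[str],
    k: int,
) -> FeatureSet:
    """Horizontally concatenate the first ``k`` ranked single-feature sets.

    Columns are channel-major within feature, e.g. k=2 with order
    (MPV, MAV) gives [mpv_ch1, mpv_ch2, mpv_ch3, mav_ch1, mav_ch2, mav_ch3].
    """
    if not 1 <= k <= len(order):
        raise ValueError(f"k={k} out of range for {len(order)} ranked features")
    chosen = [str(name).upper() for name in order[:k]]
    sets = []
    for name in chosen:
        if name not in single_sets:
            raise KeyError(f"feature set {name!r} not provided")
        sets.append(single_sets[name])
    ref = sets[0]
    for s in sets[1:]:
        if not np.array_equal(s.row_labels, ref.row_labels):
            raise ValueError("feature sets have mismatched row labels")
    return FeatureSet(
        matrix=np.hstack([s.matrix for s in sets]),
        row_labels=ref.row_labels.copy(),
        column_meta=[meta for s in sets for meta in s.column_meta],
        subject=ref.subject,
    )
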