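"""Seeded synthetic facial-EMG generation.

Surface EMG during a held (isometric, non-fatiguing) contraction is well
described as an amplitude-modulated band-limited Gaussian random process.
This module generates multi-channel facial-EMG datasets under that model:
each channel of each trial is white Gaussian noise band-pass filtered to the
EMG band (30–450 Hz by default), rescaled to a gesture- and channel-specific
RMS amplitude, modulated by a deterministic within-trial envelope, and
corrupted by additive sensor noise.

Gesture identity is carried entirely by the per-channel amplitude signature
(a length-3 vector, one entry per electrode pair), mirroring the fact that
amplitude statistics (MAV, RMS, MPV, IEMG, SSI) are the discriminative
time-domain features for facial gestures.  One pair of gestures can be
declared *confusable*: their signatures stay close together regardless of
how far the other classes are pushed apart, emulating gestures that share a
signaling source (e.g. mouth opening vs. bilateral smiling, which recruit
overlapping muscle groups).

Everything is deterministic given ``(seed, subject, gesture_id, trial)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ConfigurationError",
    "GestureProfile",
    "SimulationConfig",
    "EmgRecording",
    "default_profiles",
    "generate_gesture_trial",
    "generate_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]

N_CHANNELS = 3

#: Gesture labels in reporting order.  G1 = opening the mouth,
#: G2 = clenching the molars, G3 = raising the eyebrows, G4 = closing both
#: eyes, G5 = closing the left eye, G6 = closing the right eye, G7 =
#: frowning, G8 = smiling with both sides of the mouth, G9 = smiling left,
#: G10 = smiling right.
GESTURE_LABELS = tuple(f"G{i}" for i in range(1, 11))


class ConfigurationError(ValueError):
    """Invalid simulation or filter configuration."""


@dataclass(frozen=True)
class GestureProfile:
    """Amplitude signature of one facial gesture.

    Parameters
    ----------
    gesture_id
        Class label, unique within a profile set.
    amplitude
        Per-channel RMS scale of the active signal (arbitrary EMG units,
        length 3: left temporalis, frontalis, right temporalis).
    envelope_shape
        Deterministic within-trial modulation: ``"constant"`` (held
        contraction) or ``"trapezoid"`` (ramp up, hold, ramp down).
    confusable_with
        Optional gesture_id sharing a signaling source; the dataset
        generator keeps the two signatures close together.
    """

    gesture_id: str
    amplitude: tuple[float, ...]
    envelope_shape: str = "constant"
    confusable_with: str | None = None

    def __post_init__(self) -> None:
        amp = tuple(float(a) for a in self.amplitude)
        object.__setattr__(self, "amplitude", amp)
        if any(a < 0 for a in amp):
            raise ConfigurationError("amplitude entries must be >= 0")
        if self.envelope_shape not in ("constant", "trapezoid"):
            raise ConfigurationError(
                f"unknown envelope_shape {self.envelope_shape!r}"
            )
        if self.confusable_with == self.gesture_id:
            raise ConfigurationError("a gesture cannot be confusable with itself")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition geometry and noise model of a synthetic recording session.

    Defaults reproduce the study conditions: ~1000 Hz sampling, 2 s of
    active signal per trial, five trials per gesture, three channels,
    signal band 30–450 Hz.
    """

    sampling_rate: float = 1000.0
    trial_duration: float = 2000.0  # ms of active signal
    trials_per_gesture: int = 5
    band: tuple[float, float] = (30.0, 450.0)
    noise_floor: float = 0.02  # std of additive sensor noise, EMG units
    class_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ConfigurationError(f"invalid band {self.band}: need 0 < low < high")
        if high >= self.sampling_rate / 2:
            raise ConfigurationError(
                f"band edge {high} Hz >= Nyquist {self.sampling_rate / 2} Hz"
            )
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be positive")
        if self.trials_per_gesture < 1:
            raise ConfigurationError("trials_per_gesture must be >= 1")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor must be >= 0")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate / 1000.0))


@dataclass
class EmgRecording:
    """One trial of multi-channel EMG: ``samples`` has shape (channels, n)."""

    samples: np.ndarray
    sampling_rate: float
    gesture_id: str
    trial: int
    subject: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def default_profiles() -> list[GestureProfile]:
    """Ten-gesture profile set with realistic channel signatures.

    Channel order is (left temporalis, frontalis, right temporalis).
    Jaw gestures load the temporalis channels, eye/brow gestures the
    frontalis channel, and unilateral gestures are lateralized.  G8
    (bilateral smile) is declared confusable with G1 (mouth opening):
    both recruit perioral musculature seen only as cross-talk on these
    electrodes, so their signatures are nearly parallel.
    """
    sig = {
        "G1": (0.55, 0.18, 0.55),
        "G2": (1.10, 0.12, 1.05),
        "G3": (0.15, 0.95, 0.15),
        "G4": (0.38, 0.60, 0.38),
        "G5": (0.52, 0.42, 0.12),
        "G6": (0.12, 0.42, 0.52),
        "G7": (0.22, 0.78, 0.40),
        "G8": (0.60, 0.22, 0.50),
        "G9": (0.85, 0.15, 0.28),
        "G10": (0.28, 0.15, 0.85),
    }
    return [
        GestureProfile(
            gesture_id=g,
            amplitude=sig[g],
            confusable_with="G1" if g == "G8" else None,
        )
        for g in GESTURE_LABELS
    ]


def _stream(config_seed: int, subject: str, gesture_id: str, trial: int) -> np.random.Generator:
    """Independent, reproducible RNG per (seed, subject, gesture, trial)."""
    key = [
        int(config_seed),
        zlib.crc32(subject.encode()),
        zlib.crc32(gesture_id.encode()),
        int(trial),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _envelope(shape: str, n: int) -> np.ndarray:
    if shape == "constant":
        return np.ones(n)
    # trapezoid: 15% linear onset, hold, 15% linear offset
    ramp = max(int(round(0.15 * n)), 1)
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp:] = np.linspace(1.0, 0.0, ramp + 1)[1:]
    return env


def _band_sos(low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def generate_gesture_trial(
    profile: GestureProfile,
    config: SimulationConfig,
    trial: int,
    subject: str = "S1",
) -> EmgRecording:
    """Generate one 3-channel trial of active signal for one gesture.

    Each channel is band-limited Gaussian noise scaled so its long-run RMS
    equals ``profile.amplitude[channel]`` times the trial envelope, plus
    independent sensor noise of std ``config.noise_floor``.
    """
    if trial < 0 or trial >= config.trials_per_gesture:
        raise ValueError(f"trial {trial} out of range [0, {config.trials_per_gesture})")
    if len(profile.amplitude) != N_CHANNELS:
        raise ConfigurationError(f"amplitude must have length {N_CHANNELS}")

    n = config.samples_per_trial
    sos = _band_sos(*config.band, config.sampling_rate)
    env = _envelope(profile.envelope_shape, n)
    rng = _stream(config.seed, subject, profile.gesture_id, trial)

    channels = np.empty((N_CHANNELS, n))
    for ch in range(N_CHANNELS):
        white = rng.standard_normal(n)
        carrier = sps.sosfiltfilt(sos, white)
        rms = float(np.sqrt(np.mean(carrier**2)))
        carrier = carrier / rms if rms > 0 else carrier
        x = profile.amplitude[ch] * env * carrier
        if config.noise_floor > 0:
            x = x + config.noise_floor * rng.standard_normal(n)
        channels[ch] = x
    return EmgRecording(
        samples=channels,
        sampling_rate=config.sampling_rate,
        gesture_id=profile.gesture_id,
        trial=trial,
        subject=subject,
    )


def _effective_profiles(
    profiles: Sequence[GestureProfile], class_separation: float
) -> list[GestureProfile]:
    """Apply the inter-gesture contrast multiplier.

    Non-confusable signatures are pushed away from the grand-mean signature
    by ``class_separation``; a confusable gesture keeps its *base* offset
    from its partner, so the pair's relative contrast shrinks by
    ``1 / class_separation``.
    """
    by_id = {p.gesture_id: p for p in profiles}
    amps = np.array([p.amplitude for p in profiles])
    center = amps.mean(axis=0)
    out: dict[str, GestureProfile] = {}
    # first pass: non-confusable gestures
    for p in profiles:
        if p.confusable_with is None:
            eff = np.clip(center + class_separation * (np.array(p.amplitude) - center), 0, None)
            out[p.gesture_id] = GestureProfile(
                p.gesture_id, tuple(eff), p.envelope_shape, None
            )
    # second pass: confusable gestures ride along with their partner
    for p in profiles:
        if p.confusable_with is not None:
            partner = by_id.get(p.confusable_with)
            if partner is None:
                raise ConfigurationError(
                    f"{p.gesture_id} is confusable with unknown gesture {p.confusable_with!r}"
                )
            base_offset = np.array(p.amplitude) - np.array(partner.amplitude)
            anchor = np.array(out[partner.gesture_id].amplitude)
            eff = np.clip(anchor + base_offset, 0, None)
            out[p.gesture_id] = GestureProfile(
                p.gesture_id, tuple(eff), p.envelope_shape, p.confusable_with
            )
    return [out[p.gesture_id] for p in profiles]


def generate_dataset(
    profiles: Sequence[GestureProfile],
    config: SimulationConfig,
    subject: str = "S1",
) -> list[EmgRecording]:
    """Generate ``trials_per_gesture`` recordings for every gesture profile.

    At defaults this yields 10 gestures x 5 trials x 2 s x 3 channels:
    10 000 samples of active signal per gesture per channel.
    """
    ids = [p.gesture_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate gesture_id in profile set")
    effective = _effective_profiles(profiles, config.class_separation)
    recordings: list[EmgRecording] = []
    for prof in effective:
        for trial in range(config.trials_per_gesture):
            recordings.append(generate_gesture_trial(prof, config, trial, subject))
    return recordings


# ---------------------------------------------------------------------------
# delimited-text persistence


def write_dataset_csv(
    recordings: Sequence[EmgRecording],
    config: SimulationConfig,
    out_dir: str | Path,
) -> Path:
    """Write one long-format CSV per subject plus a JSON config sidecar.

    Columns: ``subject,gesture,trial,channel,sample_index,value``.
    Returns the directory written into.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[EmgRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject, []).append(rec)
    for subject, recs in by_subject.items():
        frames = []
        for rec in recs:
            n = rec.n_samples
            for ch in range(rec.n_channels):
                frames.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "gesture": rec.gesture_id,
                            "trial": rec.trial,
                            "channel": ch + 1,
                            "sample_index": np.arange(n),
                            "value": rec.samples[ch],
                        }
                    )
                )
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / f"{subject}.csv", index=False
        )
    sidecar = asdict(config)
    (out_dir / "config.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_dataset_csv(csv_path: str | Path, sampling_rate: float | None = None) -> list[EmgRecording]:
    """Read recordings back from the CSV dialect of :func:`write_dataset_csv`.

    The sampling rate is taken from ``config.json`` next to the CSV unless
    given explicitly.
    """
    csv_path = Path(csv_path)
    if sampling_rate is None:
        sidecar = csv_path.parent / "config.json"
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no sampling_rate given and no sidecar {sidecar} found"
            )
        sampling_rate = float(json.loads(sidecar.read_text())["sampling_rate"])
    df = pd.read_csv(csv_path)
    recordings = []
    for (subject, gesture, trial), grp in df.groupby(
        ["subject", "gesture", "trial"], sort=False
    ):
        channels = []
        for ch, cgrp in grp.groupby("channel", sort=True):
            channels.append(cgrp.sort_values("sample_index")["value"].to_numpy())
        recordings.append(
            EmgRecording(
                samples=np.vstack(channels),
                sampling_rate=sampling_rate,
                gesture_id=str(gesture),
                trial=int(trial),
                subject=str(subject),
            )
        )
    return recordings
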