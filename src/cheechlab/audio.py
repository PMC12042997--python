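"""Sampled-audio container shared by the stimulus and task modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WordSegment:
    """A word annotation on an audio track.

    ``is_color_word`` marks the monosyllabic color words that serve as
    behavioral targets in the attention task.
    """

    start_s: float
    end_s: float
    label: str = ""
    is_color_word: bool = False

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError(
                f"word segment ends before it starts: [{self.start_s}, {self.end_s})"
            )


@dataclass
class AudioTrack:
    """A sampled waveform with voicing and word annotations.

    Parameters
    ----------
    samples
        Waveform, shape ``(n,)`` mono or ``(n, 2)`` stereo, float.
    rate_hz
        Sample rate in Hz (stimuli are synthesized at 48 kHz).
    pulse_times_s
        Exact glottal-pulse onset times recorded by the generator.
        Real recordings fill this via pitch-mark extraction upstream.
    voiced_segments
        ``(start_s, end_s)`` pairs of ground-truth voiced regions.
    words
        Word annotations, including designated color-word slots.
    meta
        Free-form provenance (RMS checks, synthesis parameters, ...).
    """

    samples: np.ndarray
    rate_hz: float
    pulse_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    voiced_segments: list[tuple[float, float]] = field(default_factory=list)
    words: list[WordSegment] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (n, channels)")
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=np.float64)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def mono(self) -> np.ndarray:
        """Channel-averaged waveform."""
        if self.samples.ndim == 1:
            return self.samples
        return self.samples.mean(axis=1)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.mono))))

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz
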