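"""Chirped-speech ("Cheech") synthesis.

Voiced-epoch detection, chirp scheduling against glottal pulses under the
18.2 ms / 48 ms spacing rules, and band-interleaved mixing of narrowband
chirps into continuous speech.  The chirp insertion turns running speech
into a stimulus from which transient auditory evoked potentials can be
extracted while the listener follows natural narration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from cheechlab.audio import AudioTrack

#: Octave-wide bands carrying chirp energy (Hz).
CHIRP_BANDS = ((250.0, 500.0), (1_000.0, 2_000.0), (4_000.0, 11_000.0))

#: Interleaved bands retaining the original speech (Hz; None = Nyquist).
SPEECH_BANDS = ((0.0, 250.0), (500.0, 1_000.0), (2_000.0, 4_000.0), (11_000.0, None))

MIN_CHIRP_ISI_S = 0.0182  # 18.2 ms ⇒ at most 55 chirps/s
FIRST_CHIRP_GAP_S = 0.048  # longer gap after the first chirp of a voiced run


@dataclass(frozen=True)
class VoicedEpoch:
    """Half-open voiced interval [start_s, end_s), at least 50 ms long."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s - self.start_s < 0.050 - 1e-12:
            raise ValueError(
                f"voiced epoch [{self.start_s:.3f}, {self.end_s:.3f}) shorter than 50 ms"
            )

    def __contains__(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class ChirpEvent:
    """A scheduled chirp: onset, its band, and the first-of-sequence flag.

    First chirps of each voiced sequence are the epoching anchors for the
    long-latency (N1) analysis.
    """

    time_s: float
    band: tuple[float, float]
    is_first: bool = False


@dataclass
class BandPlan:
    """Interleaved speech/chirp band layout with the band-split filter contract."""

    speech_bands: tuple = SPEECH_BANDS
    chirp_bands: tuple = CHIRP_BANDS
    filter_order: int = 4  # Butterworth, applied zero-phase

    def validate(self) -> None:
        edges = []
        for lo, hi in self.chirp_bands:
            edges.append((lo, hi, "chirp"))
        for lo, hi in self.speech_bands:
            edges.append((lo, np.inf if hi is None else hi, "speech"))
        edges.sort()
        for (lo1, hi1, k1), (lo2, hi2, k2) in zip(edges, edges[1:]):
            if lo2 < hi1 - 1e-9:
                raise ValueError(
                    f"bands overlap: {k1} ({lo1}-{hi1} Hz) and {k2} ({lo2}-{hi2} Hz)"
                )


def detect_voiced_epochs(
    track: AudioTrack,
    rms_fraction: float = 0.28,
    min_dur_s: float = 0.050,
) -> list[VoicedEpoch]:
    """Detect voiced periods from the low-frequency speech envelope.

    The audio is band-limited to 20–1,000 Hz; its envelope (magnitude of
    the analytic signal) is band-passed 20–40 Hz (2nd-order, zero-phase)
    and its magnitude taken again, yielding a smooth nonnegative 20–40 Hz
    envelope-modulation strength.  Runs where this exceeds ``rms_fraction``
    of the whole-track (full-band) RMS for at least ``min_dur_s`` are
    voiced epochs.
    """
    x = track.mono
    if x.size == 0:
        raise ValueError("empty track")
    if not np.any(x):
        return []
    fs = track.rate_hz

    sos = signal.butter(4, [20.0, 1000.0], btype="bandpass", fs=fs, output="sos")
    low = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(low))
    sos_env = signal.butter(2, [20.0, 40.0], btype="bandpass", fs=fs, output="sos")
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos_env, env)))

    threshold = rms_fraction * float(np.sqrt(np.mean(np.square(x))))
    above = env > threshold

    epochs: list[VoicedEpoch] = []
    min_len = int(round(min_dur_s * fs))
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[above[edges + 1]] + 1) if edges.size else []
    if above[0]:
        starts.insert(0, 0)
    for s in starts:
        e = s
        while e < len(above) and above[e]:
            e += 1
        if e - s >= min_len:
            epochs.append(VoicedEpoch(s / fs, e / fs))
    return epochs


def schedule_chirps(
    pulse_times: np.ndarray,
    epochs: list[VoicedEpoch],
    min_isi_s: float = MIN_CHIRP_ISI_S,
    first_gap_s: float = FIRST_CHIRP_GAP_S,
    *,
    band_mode: str = "composite",
) -> list[ChirpEvent]:
    """Greedily place chirps on glottal pulses inside voiced epochs.

    Within each epoch the first pulse receives a chirp flagged ``is_first``.
    Later pulses receive chirps only if they are at least ``min_isi_s`` after
    the previous chirp *and* at least ``first_gap_s`` after the epoch's first
    chirp; pulses inside either window are skipped.  The first-gap window is
    measured from the first chirp's onset only (skipped pulses do not reset
    it).

    ``band_mode='composite'`` (default) emits one event per onset spanning
    all three chirp bands simultaneously, represented as one
    :class:`ChirpEvent` per band sharing the onset; ``'cyclic'`` rotates
    through the bands across successive onsets.
    """
    pulses = np.asarray(pulse_times, dtype=float)
    if np.any(np.diff(pulses) < 0):
        raise ValueError("pulse_times must be sorted nondecreasing")
    if band_mode not in ("composite", "cyclic"):
        raise ValueError(f"unknown band_mode {band_mode!r}")

    onsets: list[tuple[float, bool]] = []
    for ep in epochs:
        in_ep = pulses[(pulses >= ep.start_s) & (pulses < ep.end_s)]
        if in_ep.size == 0:
            continue
        first = in_ep[0]
        onsets.append((first, True))
        last = first
        for t in in_ep[1:]:
            if t - last >= min_isi_s and t - first >= first_gap_s:
                onsets.append((t, False))
                last = t

    events: list[ChirpEvent] = []
    for k, (t, is_first) in enumerate(onsets):
        if band_mode == "composite":
            events.extend(ChirpEvent(t, band, is_first) for band in CHIRP_BANDS)
        else:
            events.append(ChirpEvent(t, CHIRP_BANDS[k % len(CHIRP_BANDS)], is_first))
    return events


def chirp_onsets(schedule: list[ChirpEvent]) -> np.ndarray:
    """Distinct chirp onset times of a schedule, sorted."""
    return np.unique([ev.time_s for ev in schedule])


def first_chirp_onsets(schedule: list[ChirpEvent]) -> np.ndarray:
    """Onsets flagged as the first chirp of a voiced sequence, sorted."""
    return np.unique([ev.time_s for ev in schedule if ev.is_first])


def _chirp_waveform(band: tuple[float, float], rate_hz: float, dur_s: float = 0.005) -> np.ndarray:
    """A cosine-gated rising exponential frequency sweep spanning ``band``.

    The exact chirp acoustics of the original stimulus are proprietary; this
    5 ms unit-peak sweep is this package's documented convention.
    """
    n = int(round(dur_s * rate_hz))
    t = np.arange(n) / rate_hz
    lo, hi = band
    sweep = signal.chirp(t, f0=lo, f1=hi, t1=dur_s, method="logarithmic")
    gate = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
    w = sweep * gate
    return w / np.abs(w).max()


def _band_filter(
    x: np.ndarray, lo: float, hi: float | None, fs: float, order: int
) -> np.ndarray:
    nyq = fs / 2.0
    if hi is not None and hi >= nyq:
        hi = None
    if lo <= 0 and hi is None:
        return x.copy()
    if lo <= 0:
        sos = signal.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    elif hi is None:
        sos = signal.butter(order, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def synthesize_cheech(
    track: AudioTrack,
    schedule: list[ChirpEvent],
    plan: BandPlan | None = None,
    *,
    chirp_to_speech_ratio: float = 1.0,
) -> AudioTrack:
    """Mix scheduled chirps into the band-partitioned speech.

    The speech is filtered into the plan's retained bands and summed; a
    short narrowband chirp is rendered at each event in its band and added;
    the mono mix is duplicated to stereo and RMS-matched to the input track
    (the achieved ratio is reported in ``meta['rms_ratio']``).
    """
    plan = plan or BandPlan()
    plan.validate()
    fs = track.rate_hz
    nyq = fs / 2.0
    for ev in schedule:
        if not 0 <= ev.time_s <= track.duration_s:
            raise ValueError(f"chirp at {ev.time_s:.3f}s outside the track")
        if ev.band[1] >= nyq:
            raise ValueError(
                f"chirp band {ev.band} exceeds the Nyquist frequency {nyq:.0f} Hz"
            )

    x = track.mono
    speech = np.zeros_like(x)
    for lo, hi in plan.speech_bands:
        speech += _band_filter(x, lo, hi, fs, plan.filter_order)

    speech_rms = float(np.sqrt(np.mean(np.square(x)))) or 1.0
    chirp_peak = chirp_to_speech_ratio * speech_rms
    out = speech.copy()
    waveforms = {band: _chirp_waveform(band, fs) for band in CHIRP_BANDS}
    for ev in schedule:
        w = waveforms[ev.band] * chirp_peak
        i = int(round(ev.time_s * fs))
        seg = w[: max(0, min(len(w), len(out) - i))]
        out[i : i + len(seg)] += seg

    in_rms = track.rms()
    out_rms = float(np.sqrt(np.mean(np.square(out))))
    if in_rms > 0 and out_rms > 0:
        out *= in_rms / out_rms
    final_rms = float(np.sqrt(np.mean(np.square(out))))
    stereo = np.column_stack([out, out])

    return AudioTrack(
        samples=stereo,
        rate_hz=fs,
        pulse_times_s=track.pulse_times_s.copy(),
        voiced_segments=list(track.voiced_segments),
        words=list(track.words),
        meta={
            **track.meta,
            "rms_ratio": (final_rms / in_rms) if in_rms > 0 else float("nan"),
            "n_chirp_onsets": len(chirp_onsets(schedule)),
        },
    )


def schedule_to_frame(schedule: list[ChirpEvent]) -> pd.DataFrame:
    """Chirp schedule as a table (onset_s, band_low_hz, band_high_hz, is_first)."""
    return pd.DataFrame(
        {
            "onset_s": [ev.time_s for ev in schedule],
            "band_low_hz": [ev.band[0] for ev in schedule],
            "band_high_hz": [ev.band[1] for ev in schedule],
            "is_first": [ev.is_first for ev in schedule],
        }
    )
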