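"""Continuous EEG → condition-wise N1 measures.

Filtering contracts (zero-phase Butterworth of the stated orders),
frequency-tagged line-noise detection with a sinusoid-regression cleaner,
earlobe/mastoid re-referencing, epoching around first-chirp events,
two-step artifact rejection, and mean-amplitude N1 extraction at Fz over
110–160 ms.

Time conventions: seconds internally, 0-based samples, half-open windows
[a, b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

N1_WINDOW_S = (0.110, 0.160)
EPOCH_WINDOW_S = (-0.050, 0.500)
BASELINE_WINDOW_S = (-0.050, 0.0)
VOLTAGE_THRESHOLD_UV = 300.0
SINGLE_CHANNEL_Z = 6.0
ACROSS_CHANNEL_Z = 2.0
LINE_BASE_HZ = 60.0
LINE_HARMONICS = 4  # 120, 180, 240, 300 Hz
LINE_SD_CRITERION = 8.0
MAX_CLEANING_ITERATIONS = 5

EARLOBE_PAIR = ("A1", "A2")
MASTOID_PAIR = ("M1", "M2")


@dataclass
class EEGRecording:
    """Multichannel EEG: channels × samples in µV plus event annotations."""

    channel_names: list[str]
    rate_hz: float
    samples: np.ndarray
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["onset_s", "code"])
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} data rows"
            )
        if len(self.events) and (
            (self.events["onset_s"] < 0).any()
            or (self.events["onset_s"] > self.duration_s).any()
        ):
            raise ValueError("event annotations outside the recording span")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            list(self.channel_names),
            self.rate_hz,
            self.samples.copy(),
            self.events.copy(),
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Filtering


def apply_filters(recording: EEGRecording, stage: str) -> EEGRecording:
    """Apply one contracted filtering stage and return a new recording.

    * ``initial_hp`` — DC removal, then a noncausal (zero-phase)
      second-order 0.1 Hz high-pass Butterworth;
    * ``final_bp`` — noncausal 0.5–40 Hz eighth-order Butterworth bandpass;
    * ``downsample_512`` — polyphase resampling to 512 Hz (anti-alias
      filtering built in).
    """
    fs = recording.rate_hz
    out = recording.copy()
    if stage == "initial_hp":
        data = out.samples - out.samples.mean(axis=1, keepdims=True)
        sos = signal.butter(2, 0.1, btype="highpass", fs=fs, output="sos")
        out.samples = signal.sosfiltfilt(sos, data, axis=1)
    elif stage == "final_bp":
        if fs < 2 * 40.0:
            raise ValueError(f"sample rate {fs} Hz below twice the 40 Hz band edge")
        # butter(4, ..) yields an 8th-order bandpass (order doubles for BP)
        sos = signal.butter(4, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
        out.samples = signal.sosfiltfilt(sos, out.samples, axis=1)
    elif stage == "downsample_512":
        ratio = Fraction(512, int(round(fs))).limit_denominator(10_000)
        out.samples = signal.resample_poly(
            out.samples, ratio.numerator, ratio.denominator, axis=1
        )
        out.rate_hz = fs * ratio.numerator / ratio.denominator
    else:
        raise ValueError(
            f"unknown stage {stage!r}; expected initial_hp, final_bp, or downsample_512"
        )
    return out


def filter_response_db(stage: str, freq_hz: float, fs: float) -> float:
    """Analytic magnitude response (dB) of a filtering stage at ``freq_hz``.

    Zero-phase application squares the magnitude response, which is
    accounted for here; used as the transfer-function oracle for the
    filtering contracts.
    """
    if stage == "initial_hp":
        sos = signal.butter(2, 0.1, btype="highpass", fs=fs, output="sos")
    elif stage == "final_bp":
        sos = signal.butter(4, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
    else:
        raise ValueError(f"no analytic response for stage {stage!r}")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    mag = np.abs(h[0]) ** 2  # forward-backward pass
    return float(20 * np.log10(max(mag, 1e-300)))


# ---------------------------------------------------------------------------
# Line noise


@dataclass
class LineNoiseReport:
    """Outcome of the frequency-tagging line-noise detector."""

    flagged_channels: list[str]
    offending_freqs: dict[str, list[float]]
    corrected_power: dict[str, dict[float, float]]
    thresholds: dict[str, float]
    iterations_used: int = 0

    @property
    def clean(self) -> bool:
        return not self.flagged_channels


def _neighbor_corrected_spectrum(x: np.ndarray, fs: float):
    """1 Hz-resolution average periodogram and its neighbor-corrected power.

    c(f) = p(f) − mean{p(f±2), p(f±3)}; the immediately adjacent bins are
    left out so narrowband peaks do not mask themselves.
    """
    nper = int(round(fs))
    freqs, p = signal.welch(x, fs=fs, nperseg=nper, noverlap=0)
    c = np.full_like(p, np.nan)
    for i in range(3, len(p) - 3):
        c[i] = p[i] - (p[i - 2] + p[i - 3] + p[i + 2] + p[i + 3]) / 4.0
    return freqs, c


def detect_line_noise(recording: EEGRecording, base_hz: float = LINE_BASE_HZ) -> LineNoiseReport:
    """Flag channels whose neighbor-corrected power at the line frequency or
    any of its first four harmonics exceeds 8 SD of the corrected power at
    all other frequencies."""
    if recording.duration_s < 2.0:
        raise ValueError("need at least 2 s of data for 1 Hz spectral resolution")
    line_freqs = [base_hz * (k + 1) for k in range(1 + LINE_HARMONICS)]
    nyq = recording.rate_hz / 2.0
    line_freqs = [f for f in line_freqs if f < nyq - 3.0]

    flagged, offending, power, thresholds = [], {}, {}, {}
    for name, row in zip(recording.channel_names, recording.samples):
        freqs, c = _neighbor_corrected_spectrum(row, recording.rate_hz)
        line_idx = [int(np.argmin(np.abs(freqs - f))) for f in line_freqs]
        others = np.ones(len(freqs), dtype=bool)
        others[line_idx] = False
        others &= ~np.isnan(c)
        sd = float(np.std(c[others]))
        thresholds[name] = LINE_SD_CRITERION * sd
        power[name] = {f: float(c[i]) for f, i in zip(line_freqs, line_idx)}
        bad = [f for f, i in zip(line_freqs, line_idx) if c[i] > LINE_SD_CRITERION * sd]
        if bad:
            flagged.append(name)
            offending[name] = bad
    return LineNoiseReport(flagged, offending, power, thresholds)


def remove_line_noise(
    recording: EEGRecording,
    report: LineNoiseReport | None = None,
    *,
    window_s: float = 4.0,
) -> tuple[EEGRecording, LineNoiseReport]:
    """Clean flagged channels by sliding-window sinusoid regression.

    On each flagged channel, sine/cosine components at the offending
    frequencies are least-squares fitted in Hann-weighted windows
    (``window_s`` long, 50% overlap) and subtracted; the detector is then
    re-run, iterating up to five times or until clean.  Channels never
    flagged pass through bit-identical.
    """
    out = recording.copy()
    rep = report or detect_line_noise(out)
    iterations = 0
    while not rep.clean and iterations < MAX_CLEANING_ITERATIONS:
        for name in rep.flagged_channels:
            idx = out.channel_names.index(name)
            out.samples[idx] = _subtract_sinusoids(
                out.samples[idx], out.rate_hz, rep.offending_freqs[name], window_s
            )
        iterations += 1
        rep = detect_line_noise(out)
    rep.iterations_used = iterations
    return out, rep


def _subtract_sinusoids(
    x: np.ndarray, fs: float, freqs: list[float], window_s: float
) -> np.ndarray:
    n = len(x)
    nw = min(n, int(round(window_s * fs)))
    hop = max(1, nw // 2)
    fit = np.zeros(n)
    weight = np.zeros(n)
    win = np.hanning(nw)
    t = np.arange(n) / fs
    cols = []
    for f in freqs:
        cols.extend([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    design_full = np.column_stack(cols)
    starts = list(range(0, max(n - nw, 0) + 1, hop))
    if starts[-1] + nw < n:
        starts.append(n - nw)
    for s in starts:
        sl = slice(s, s + nw)
        design = design_full[sl]
        coef, *_ = np.linalg.lstsq(design, x[sl], rcond=None)
        w = win[: sl.stop - sl.start]
        fit[sl] += (design @ coef) * w
        weight[sl] += w
    weight[weight == 0] = 1.0
    return x - fit / weight


# ---------------------------------------------------------------------------
# Re-referencing


def rereference(
    recording: EEGRecording,
    *,
    preferred_pair: tuple[str, str] = EARLOBE_PAIR,
    fallback_pair: tuple[str, str] = MASTOID_PAIR,
) -> EEGRecording:
    """Re-reference to the mean of the left/right earlobes (mastoid fallback).

    If Cz (the online reference) is absent it is restored as a zero data
    channel before subtraction, so its referenced activity reappears.
    """
    out = recording.copy()
    if "Cz" not in out.channel_names:
        out.channel_names.append("Cz")
        out.samples = np.vstack([out.samples, np.zeros(out.n_samples)])
    for pair in (preferred_pair, fallback_pair):
        if all(ch in out.channel_names for ch in pair):
            ref = (out.channel(pair[0]) + out.channel(pair[1])) / 2.0
            out.samples = out.samples - ref[None, :]
            out.meta["reference"] = pair
            return out
    raise ValueError(
        f"neither the earlobe pair {preferred_pair} nor the mastoid pair "
        f"{fallback_pair} is present"
    )


def interpolate_bad_channels(
    recording: EEGRecording, bad: list[str], positions: dict[str, tuple[float, float]]
) -> EEGRecording:
    """Inverse-distance-weighted interpolation of bad channels from 2-D
    scalp coordinates; interpolated channels are flagged in ``meta``."""
    out = recording.copy()
    good = [ch for ch in out.channel_names if ch not in bad and ch in positions]
    if not good:
        raise ValueError("no good channels with known positions to interpolate from")
    for ch in bad:
        if ch not in out.channel_names or ch not in positions:
            continue
        p = np.asarray(positions[ch])
        dists = np.array([np.linalg.norm(p - np.asarray(positions[g])) for g in good])
        w = 1.0 / np.maximum(dists, 1e-6)
        w /= w.sum()
        out.samples[out.channel_names.index(ch)] = sum(
            wi * out.channel(g) for wi, g in zip(w, good)
        )
    out.meta["interpolated"] = list(bad)
    return out


# ---------------------------------------------------------------------------
# Epoching, rejection, N1


@dataclass
class EpochSet:
    """Baseline-corrected epochs (trials × channels × samples) per condition."""

    condition: str
    epochs: np.ndarray
    channel_names: list[str]
    rate_hz: float
    event_times_s: np.ndarray
    window_s: tuple[float, float] = EPOCH_WINDOW_S
    kept_indices: list[int] = field(default_factory=list)
    rejection_log: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_rejected(self) -> int:
        return len(self.rejection_log)

    @property
    def n_total(self) -> int:
        return self.n_kept + self.n_rejected

    def times_s(self) -> np.ndarray:
        """Per-sample latency relative to the event onset."""
        n_pre = int(round(-self.window_s[0] * self.rate_hz))
        return (np.arange(self.epochs.shape[2]) - n_pre) / self.rate_hz


def epoch_and_baseline(
    recording: EEGRecording,
    event_times_s,
    condition: str = "",
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
) -> EpochSet:
    """Cut [−50, +500) ms epochs around first-chirp events and subtract the
    per-channel mean of the [−50, 0) ms prestimulus baseline.

    Events too close to the recording edge are skipped and logged, not
    fatal.
    """
    fs = recording.rate_hz
    n_pre = int(round(-window_s[0] * fs))
    n_post = int(round(window_s[1] * fs))
    b0 = int(round((baseline_s[0] - window_s[0]) * fs))
    b1 = int(round((baseline_s[1] - window_s[0]) * fs))

    epochs, kept, log = [], [], []
    for k, t in enumerate(np.asarray(event_times_s, dtype=float)):
        i = int(round(t * fs))
        if i - n_pre < 0 or i + n_post > recording.n_samples:
            log.append((k, f"event at {t:.3f}s too close to the recording edge"))
            continue
        ep = recording.samples[:, i - n_pre : i + n_post].copy()
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(ep)
        kept.append(k)

    if not epochs:
        shape = (0, len(recording.channel_names), n_pre + n_post)
        arr = np.empty(shape)
    else:
        arr = np.stack(epochs)
    return EpochSet(
        condition=condition,
        epochs=arr,
        channel_names=list(recording.channel_names),
        rate_hz=fs,
        event_times_s=np.asarray(event_times_s, dtype=float)[kept],
        window_s=window_s,
        kept_indices=kept,
        rejection_log=log,
    )


def reject_epochs(
    epochs: EpochSet,
    voltage_threshold_uv: float = VOLTAGE_THRESHOLD_UV,
    single_channel_z: float = SINGLE_CHANNEL_Z,
    across_channel_z: float = ACROSS_CHANNEL_Z,
) -> EpochSet:
    """Two-step artifact rejection.

    Step 1 removes epochs containing any |sample| above ±300 µV.  Step 2
    computes per-epoch, per-channel peak-to-peak amplitudes, z-scores them
    per channel across the surviving epochs, and rejects epochs whose
    largest single-channel z exceeds 6 or whose mean z across channels
    exceeds 2.  Degenerate (zero-variance) channels yield z = 0.  Kept plus
    rejected counts equal the input count; every rejection logs its rule.
    """
    if epochs.n_kept < 2:
        raise ValueError("need at least 2 epochs to estimate rejection statistics")
    data = epochs.epochs
    log = list(epochs.rejection_log)

    extreme = np.max(np.abs(data), axis=(1, 2)) > voltage_threshold_uv
    for k in np.flatnonzero(extreme):
        log.append((epochs.kept_indices[k], f"|V| > {voltage_threshold_uv:g} µV"))
    survivors = np.flatnonzero(~extreme)

    p2p = data[survivors].max(axis=2) - data[survivors].min(axis=2)  # epochs × channels
    mu = p2p.mean(axis=0)
    sd = p2p.std(axis=0, ddof=0)
    z = np.zeros_like(p2p)
    nz = sd > 0
    z[:, nz] = (p2p[:, nz] - mu[nz]) / sd[nz]
    bad_single = z.max(axis=1) > single_channel_z
    bad_across = z.mean(axis=1) > across_channel_z
    keep_mask = ~(bad_single | bad_across)
    for j in np.flatnonzero(~keep_mask):
        k = survivors[j]
        rule = (
            f"single-channel peak-to-peak z > {single_channel_z:g}"
            if bad_single[j]
            else f"across-channel mean peak-to-peak z > {across_channel_z:g}"
        )
        log.append((epochs.kept_indices[k], rule))
    final = survivors[keep_mask]

    if final.size == 0:
        flags = "all epochs rejected"
    else:
        flags = None
    out = EpochSet(
        condition=epochs.condition,
        epochs=data[final],
        channel_names=epochs.channel_names,
        rate_hz=epochs.rate_hz,
        event_times_s=epochs.event_times_s[final],
        window_s=epochs.window_s,
        kept_indices=[epochs.kept_indices[k] for k in final],
        rejection_log=log,
    )
    if flags:
        out.rejection_log.append((-1, flags))
    return out


@dataclass(frozen=True)
class N1Measure:
    condition: str
    mean_amplitude_uv: float
    n_epochs: int


@dataclass
class N1Result:
    measures: dict[str, N1Measure]
    difference_uv: float | None  # target − masker


def n1_window_mean(
    erp: np.ndarray, rate_hz: float, n_pre: int, window_s=N1_WINDOW_S
) -> float:
    """Arithmetic mean of samples with latency in [110, 160) ms."""
    lat = (np.arange(erp.shape[-1]) - n_pre) / rate_hz
    mask = (lat >= window_s[0]) & (lat < window_s[1])
    return float(np.asarray(erp)[..., mask].mean())


def extract_n1(
    epoch_sets: list[EpochSet],
    electrode: str = "Fz",
    window_s: tuple[float, float] = N1_WINDOW_S,
) -> N1Result:
    """Average kept epochs per condition and take the Fz mean amplitude over
    110–160 ms post-chirp; the difference score is target − masker.

    Sign convention: a negative difference means a stronger (more negative)
    N1 to the attended target than to the ignored masker.
    """
    measures: dict[str, N1Measure] = {}
    for es in epoch_sets:
        if electrode not in es.channel_names:
            raise ValueError(f"electrode {electrode} missing from epoch set {es.condition!r}")
        if es.n_kept == 0:
            raise ValueError(f"no kept epochs in condition {es.condition!r}")
        erp = es.epochs.mean(axis=0)
        n_pre = int(round(-es.window_s[0] * es.rate_hz))
        amp = n1_window_mean(erp[es.channel_names.index(electrode)], es.rate_hz, n_pre, window_s)
        measures[es.condition] = N1Measure(es.condition, amp, es.n_kept)

    target = next((m for c, m in measures.items() if "target" in c.lower()), None)
    masker = next((m for c, m in measures.items() if "masker" in c.lower()), None)
    diff = (
        target.mean_amplitude_uv - masker.mean_amplitude_uv
        if target and masker
        else None
    )
    return N1Result(measures, diff)
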