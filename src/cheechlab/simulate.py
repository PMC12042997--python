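"""Synthetic inputs: cohorts, speech-proxy audio, chirp-locked EEG, observers.

Everything downstream of this module (stimulus synthesis, task scheduling,
ERP extraction, scoring, inference) is exercised against data generated
here, so each generator exposes its ground truth: glottal-pulse times are
recorded exactly, evoked kernels are known analytically, and cohort tables
carry the true (pre-measurement-noise) N1 difference per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from cheechlab.audio import AudioTrack, WordSegment

PREDICTOR_NAMES = ("Flanker", "Stroop", "TMT", "ReadingSpan", "TFS")

#: Pairwise Pearson correlations between the five predictors
#: (order: Flanker, Stroop, TMT, ReadingSpan, TFS).
DEFAULT_PREDICTOR_CORR = np.array(
    [
        [1.000, -0.369, 0.065, 0.245, -0.127],
        [-0.369, 1.000, 0.156, -0.393, 0.196],
        [0.065, 0.156, 1.000, -0.023, 0.520],
        [0.245, -0.393, -0.023, 1.000, -0.075],
        [-0.127, 0.196, 0.520, -0.075, 1.000],
    ]
)

#: Standardized generating coefficients for the N1-difference model.
#: The TMT coefficient is −0.094, not the commonly quoted −0.009: the
#: reported t statistic (−0.518) times its SE (0.182) gives −0.094, and only
#: that value makes βᵀRβ equal both the sum of the general dominance weights
#: (0.583) and the unadjusted R² implied by adjusted R² = 0.467 at n = 24,
#: p = 5.  The −0.009 variant remains selectable via ``CohortSpec.betas``.
DEFAULT_BETAS = np.array([0.047, 0.598, -0.094, 0.649, -0.359])

BETA_TMT_AS_PRINTED = -0.009

#: Population R² = βᵀRβ under the defaults.
DEFAULT_POPULATION_R2 = float(DEFAULT_BETAS @ DEFAULT_PREDICTOR_CORR @ DEFAULT_BETAS)

#: Cohort-level distribution of the N1 amplitude difference (µV):
#: mean −0.254, SD 0.340 across participants.
N1_DIFF_MEAN_UV = -0.254
N1_DIFF_SD_UV = 0.340

#: Affine maps from standardized scores to plausible native units.
#: The study reports only score distributions graphically, so these
#: center/scale constants are conventions, not reproductions.
NATIVE_UNIT_MAPS = {
    "Flanker": (60.0, 30.0),  # ms RT difference, incongruent − congruent
    "Stroop": (150.0, 80.0),  # ms RT difference, color words − neutral words
    "TMT": (400.0, 200.0),  # ms RT difference, TMT-B − TMT-A
    "ReadingSpan": (0.80, 0.12),  # proportion correct, 3/4-letter trials
    "TFS": (20.0, 10.0),  # degrees IPD, mean of 250 and 500 Hz thresholds
}


@dataclass
class CohortSpec:
    """Generative model of the participant cohort.

    Predictors are drawn multivariate normal with correlation
    ``predictor_corr``; the standardized N1-difference outcome is
    ``X @ betas`` plus Gaussian noise of SD ``residual_sd``, then mapped
    to µV with the cohort mean/SD of the N1 difference.
    """

    n_participants: int = 24
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    predictor_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_PREDICTOR_CORR.copy()
    )
    betas: np.ndarray = field(default_factory=lambda: DEFAULT_BETAS.copy())
    residual_sd: float = float(np.sqrt(1.0 - DEFAULT_POPULATION_R2))
    n1_diff_mean_uv: float = N1_DIFF_MEAN_UV
    n1_diff_sd_uv: float = N1_DIFF_SD_UV
    seed: int = 0

    def validate(self) -> None:
        p = len(self.predictor_names)
        corr = np.asarray(self.predictor_corr, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"predictor_corr must be {p}x{p}, got {corr.shape}")
        if not np.allclose(corr, corr.T):
            raise ValueError("predictor_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("predictor_corr must have a unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals[0] < -1e-10:
            raise ValueError(
                "predictor_corr is not positive semi-definite: "
                f"smallest eigenvalue {eigvals[0]:.6g} < 0"
            )
        if len(np.asarray(self.betas)) != p:
            raise ValueError("betas must match predictor_names in length")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")

    @property
    def population_r2(self) -> float:
        """Variance explained in the standardized outcome, βᵀRβ / (βᵀRβ + σ²)."""
        b = np.asarray(self.betas, dtype=float)
        explained = float(b @ np.asarray(self.predictor_corr, float) @ b)
        return explained / (explained + self.residual_sd**2)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort with the configured correlation structure.

    Returns a table with one row per participant: native-unit predictor
    scores, their empirically z-scored versions (``z_<name>``, cohort mean
    exactly 0 and SD exactly 1), and the true N1 amplitude difference in µV
    (``true_n1_diff_uv``).  ``observed_n1_diff_uv`` starts equal to the true
    value; the EEG simulation/extraction chain overwrites it with measured
    values when run.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = len(spec.predictor_names)
    corr = np.asarray(spec.predictor_corr, dtype=float)

    # Eigen-decomposition square root tolerates semi-definite matrices.
    eigvals, eigvecs = np.linalg.eigh(corr)
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    X = rng.standard_normal((spec.n_participants, p)) @ root.T

    y_std = X @ np.asarray(spec.betas, float) + spec.residual_sd * rng.standard_normal(
        spec.n_participants
    )
    true_n1 = spec.n1_diff_mean_uv + spec.n1_diff_sd_uv * y_std

    table = pd.DataFrame({"id": [f"P{i:04d}" for i in range(spec.n_participants)]})
    for j, name in enumerate(spec.predictor_names):
        center, scale = NATIVE_UNIT_MAPS.get(name, (0.0, 1.0))
        table[name] = center + scale * X[:, j]
    for j, name in enumerate(spec.predictor_names):
        col = X[:, j]
        table[f"z_{name}"] = (col - col.mean()) / col.std(ddof=0)
    table["true_n1_diff_uv"] = true_n1
    table["observed_n1_diff_uv"] = true_n1.copy()
    return table


# ---------------------------------------------------------------------------
# Speech-proxy audio


def generate_story_track(
    duration_s: float,
    f0_hz: float = 128.0,
    word_plan: list[WordSegment] | None = None,
    seed: int = 0,
    *,
    rate_hz: float = 48_000.0,
    pulse_jitter: float = 0.02,
    resonance_hz: float = 500.0,
    resonance_decay_s: float = 0.004,
    am_rate_hz: float = 30.0,
    am_depth: float = 0.5,
) -> AudioTrack:
    """Synthesize a speech proxy: glottal-pulse trains in voiced segments.

    Each glottal pulse is rendered as an impulse-excited decaying resonance
    (default 500 Hz, 4 ms decay); pulse onsets are spaced ~1/f0 with a small
    multiplicative jitter and are recorded exactly on the returned track.
    Voiced segments additionally carry slow amplitude modulation
    (``am_rate_hz``, ``am_depth``) emulating the 20–40 Hz envelope
    fluctuations of natural speech that voiced-epoch detection relies on.

    ``word_plan`` semantics:

    * ``None`` — the whole track is one voiced segment with no words
      (useful for dense pulse trains);
    * ``[]`` — a silent track (no pulses, no voiced segments);
    * a list of :class:`~cheechlab.audio.WordSegment` — each word is voiced,
      the gaps between words are silent.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 50.0 <= f0_hz <= 400.0:
        raise ValueError(f"f0_hz {f0_hz} outside the supported 50-400 Hz range")
    rng = np.random.default_rng(seed)

    if word_plan is None:
        voiced = [(0.0, duration_s)]
        words: list[WordSegment] = []
    else:
        for w in word_plan:
            if w.end_s > duration_s:
                raise ValueError(
                    f"word '{w.label}' ends at {w.end_s:.3f}s, beyond the "
                    f"{duration_s:.3f}s track"
                )
        words = sorted(word_plan, key=lambda w: w.start_s)
        voiced = [(w.start_s, w.end_s) for w in words]

    n = int(round(duration_s * rate_hz))
    samples = np.zeros(n)

    pulse_times: list[float] = []
    period = 1.0 / f0_hz
    for start, end in voiced:
        t = start
        while t < end:
            pulse_times.append(t)
            t += period * (1.0 + pulse_jitter * rng.uniform(-1.0, 1.0))
    pulses = np.array(pulse_times)

    # One impulse response, added at every pulse onset.
    ir_len = int(round(6 * resonance_decay_s * rate_hz))
    t_ir = np.arange(ir_len) / rate_hz
    ir = np.exp(-t_ir / resonance_decay_s) * np.sin(2 * np.pi * resonance_hz * t_ir)
    for t in pulses:
        i = int(round(t * rate_hz))
        seg = ir[: max(0, min(ir_len, n - i))]
        gain = 1.0 + am_depth * np.sin(2 * np.pi * am_rate_hz * t)
        samples[i : i + len(seg)] += gain * seg

    return AudioTrack(
        samples=samples,
        rate_hz=rate_hz,
        pulse_times_s=pulses,
        voiced_segments=voiced,
        words=words,
        meta={"f0_hz": f0_hz, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Chirp-locked EEG


@dataclass
class EvokedKernel:
    """Analytic template of the chirp-evoked cortical response.

    The default shape is a negative-going Gaussian component peaking at
    ``peak_s`` (N1-like); the kernel is causal (identically zero before the
    chirp) and supported on [0, ``support_s``).  ``amplitude_target``,
    ``amplitude_masker`` and ``amplitude_mono`` scale the template per
    attention condition, in µV at the kernel peak.
    """

    peak_s: float = 0.135
    width_s: float = 0.025
    support_s: float = 0.500
    amplitude_target: float = -1.0
    amplitude_masker: float = -1.0
    amplitude_mono: float = -1.0

    def sample(self, rate_hz: float) -> np.ndarray:
        """Unit-amplitude template on [0, support_s) at ``rate_hz``."""
        t = np.arange(int(round(self.support_s * rate_hz))) / rate_hz
        shape = -np.exp(-0.5 * ((t - self.peak_s) / self.width_s) ** 2)
        return shape

    def window_mean(self, rate_hz: float, lo_s: float = 0.110, hi_s: float = 0.160) -> float:
        """Mean of the unit template over the N1 window [lo, hi) s."""
        w = self.sample(rate_hz)
        t = np.arange(len(w)) / rate_hz
        mask = (t >= lo_s) & (t < hi_s)
        return float(w[mask].mean())

    def with_window_means(
        self,
        rate_hz: float,
        target_uv: float,
        masker_uv: float,
        mono_uv: float | None = None,
    ) -> "EvokedKernel":
        """Rescale amplitudes so the per-condition [110, 160) ms window means
        of the scaled kernel equal the requested values in µV."""
        base = self.window_mean(rate_hz)
        if mono_uv is None:
            mono_uv = target_uv
        return replace(
            self,
            amplitude_target=target_uv / base,
            amplitude_masker=masker_uv / base,
            amplitude_mono=mono_uv / base,
        )

    def amplitude_for(self, condition: str) -> float:
        key = condition.lower()
        if "target" in key:
            return self.amplitude_target
        if "masker" in key:
            return self.amplitude_masker
        if "mono" in key:
            return self.amplitude_mono
        raise KeyError(f"unknown condition label {condition!r}")


#: Default synthetic montage: a reduced 10-20 layout that keeps every channel
#: the pipeline contracts on (Fz for N1, Cz reference, earlobe pair A1/A2,
#: mastoid pair M1/M2, frontal sites for blink artifacts).
DEFAULT_CHANNELS = (
    "Fp1",
    "Fp2",
    "F3",
    "Fz",
    "F4",
    "C3",
    "Cz",
    "C4",
    "P3",
    "Pz",
    "P4",
    "Oz",
    "A1",
    "A2",
    "M1",
    "M2",
)

#: Relative gain of the evoked kernel per channel (fronto-central maximum,
#: silent at the reference-adjacent ear channels).
DEFAULT_TOPOGRAPHY = {
    "Fp1": 0.5,
    "Fp2": 0.5,
    "F3": 0.8,
    "Fz": 1.0,
    "F4": 0.8,
    "C3": 0.7,
    "Cz": 0.9,
    "C4": 0.7,
    "P3": 0.4,
    "Pz": 0.5,
    "P4": 0.4,
    "Oz": 0.2,
    "A1": 0.0,
    "A2": 0.0,
    "M1": 0.0,
    "M2": 0.0,
}


@dataclass
class NoiseConfig:
    """Additive noise model for the EEG simulation.

    ``background_rms_uv`` sets the RMS of 1/f^exponent background noise per
    channel; ``line_amplitude_uv`` adds a 60 Hz (``line_hz``) sinusoid to
    ``line_channels``; blink transients (stereotyped 300 ms biphasic
    deflections on frontal channels) are injected at ``blink_rate_hz``.
    """

    background_rms_uv: float = 0.0
    one_over_f_exponent: float = 1.0
    line_hz: float = 60.0
    line_amplitude_uv: float = 0.0
    line_channels: tuple[str, ...] = ()
    blink_rate_hz: float = 0.0
    blink_amplitude_uv: float = 150.0
    blink_channels: tuple[str, ...] = ("Fp1", "Fp2")

    def validate(self) -> None:
        if self.background_rms_uv < 0:
            raise ValueError("background_rms_uv must be nonnegative")
        if self.line_amplitude_uv < 0 or self.blink_amplitude_uv < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        if self.blink_rate_hz < 0:
            raise ValueError("blink_rate_hz must be nonnegative")


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, rate_hz: float,
    exponent: float, rms: float,
) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^exponent."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate_hz)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spectrum = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ) * scale
    noise = np.fft.irfft(spectrum, n=n_samples, axis=1)
    current = noise.std(axis=1, keepdims=True)
    current[current == 0] = 1.0
    return noise / current * rms


def simulate_eeg(
    chirp_events,
    kernel: EvokedKernel,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    *,
    duration_s: float | None = None,
    rate_hz: float = 2048.0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    topography: dict[str, float] | None = None,
):
    """Render a multichannel EEG recording containing chirp-locked responses.

    ``chirp_events`` is an iterable of ``(time_s, condition)`` pairs (or a
    DataFrame with ``onset_s`` and ``condition`` columns).  Each event adds
    the kernel, scaled by its condition's amplitude and the channel
    topography.  With a zero/absent noise config the recording is the exact
    superposition of kernels.
    """
    from cheechlab.erp import EEGRecording  # local import: erp depends on audio only

    noise_cfg = noise_cfg or NoiseConfig()
    noise_cfg.validate()
    topography = topography if topography is not None else DEFAULT_TOPOGRAPHY

    if isinstance(chirp_events, pd.DataFrame):
        events = list(zip(chirp_events["onset_s"], chirp_events["condition"]))
    else:
        events = [(float(t), str(c)) for t, c in chirp_events]

    if duration_s is None:
        last = max((t for t, _ in events), default=0.0)
        duration_s = last + kernel.support_s + 0.5
    for t, _ in events:
        if t < 0 or t > duration_s:
            raise ValueError(f"chirp event at {t:.3f}s outside recording span")

    n = int(round(duration_s * rate_hz))
    data = np.zeros((len(channels), n))
    template = kernel.sample(rate_hz)
    gains = np.array([topography.get(ch, 0.0) for ch in channels])

    for t, cond in events:
        amp = kernel.amplitude_for(cond)
        i = int(round(t * rate_hz))
        seg = template[: max(0, min(len(template), n - i))]
        data[:, i : i + len(seg)] += amp * gains[:, None] * seg[None, :]

    rng = np.random.default_rng(seed)
    if noise_cfg.background_rms_uv > 0:
        data += _one_over_f_noise(
            rng, len(channels), n, rate_hz,
            noise_cfg.one_over_f_exponent, noise_cfg.background_rms_uv,
        )
    if noise_cfg.line_amplitude_uv > 0 and noise_cfg.line_channels:
        t_axis = np.arange(n) / rate_hz
        line = noise_cfg.line_amplitude_uv * np.sin(
            2 * np.pi * noise_cfg.line_hz * t_axis + rng.uniform(0, 2 * np.pi)
        )
        for ch in noise_cfg.line_channels:
            data[channels.index(ch)] += line
    if noise_cfg.blink_rate_hz > 0:
        n_blinks = rng.poisson(noise_cfg.blink_rate_hz * duration_s)
        blink_len = int(round(0.300 * rate_hz))
        bt = np.linspace(0, 1, blink_len)
        blink = np.sin(np.pi * bt) * np.sin(2 * np.pi * bt)  # biphasic
        blink *= noise_cfg.blink_amplitude_uv / np.abs(blink).max()
        for t in rng.uniform(0, duration_s - 0.3, size=n_blinks):
            i = int(round(t * rate_hz))
            seg = blink[: max(0, min(blink_len, n - i))]
            for ch in noise_cfg.blink_channels:
                if ch in channels:
                    data[channels.index(ch), i : i + len(seg)] += seg

    event_table = pd.DataFrame(
        {"onset_s": [t for t, _ in events], "code": [c for _, c in events]}
    )
    return EEGRecording(
        channel_names=list(channels),
        rate_hz=rate_hz,
        samples=data,
        events=event_table,
    )


# ---------------------------------------------------------------------------
# Psychophysical observer


@dataclass
class ObserverModel:
    """Ideal observer for the interaural-phase (TFS-LF) 2AFC task.

    ``p(correct | φ) = 0.5 + (0.5 − lapse_rate) · Φ((ln φ − ln threshold_phi) / slope)``

    so a lapse-free observer is at chance (0.5) for φ → 0 and passes 75%
    correct at ``threshold_phi`` degrees IPD.  ``slope`` is the SD of the
    cumulative-normal psychometric function on the log-IPD axis; the
    default (0.3) keeps the staircase's final step (ln 1.25 ≈ 0.22) inside
    the operating regime where up-down tracking theory applies
    (step/slope ≈ 0.5–1) — see the methods note on staircase bias.
    """

    threshold_phi: float = 20.0
    slope: float = 0.3
    lapse_rate: float = 0.02

    def validate(self) -> None:
        if self.threshold_phi <= 0:
            raise ValueError("threshold_phi must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")

    def p_correct(self, phi_deg: float) -> float:
        self.validate()
        if not 0.0 <= phi_deg <= 180.0:
            raise ValueError(f"IPD φ = {phi_deg} outside [0, 180] degrees")
        if phi_deg == 0.0:
            return 0.5
        z = (np.log(phi_deg) - np.log(self.threshold_phi)) / self.slope
        return float(0.5 + (0.5 - self.lapse_rate) * norm.cdf(z))


def observer_respond(
    observer: ObserverModel, phi_deg: float, seed: int | np.random.Generator = 0
) -> bool:
    """One Bernoulli 2AFC response at IPD ``phi_deg``; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return bool(rng.uniform() < observer.p_correct(phi_deg))
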