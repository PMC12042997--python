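"""Behavioral and psychophysical scoring.

Color-word hit rates for the attention task, median-RT interference scores
(Flanker, Stroop, TMT), reading-span letter-recall accuracy, and the
two-down/one-up interaural-phase (TFS-LF) adaptive staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cheechlab.simulate import ObserverModel

HIT_WINDOW_S = 2.0
OVERLAP_EXCLUSION_S = 2.0

#: Step factors of the staircase by phase: before the first turn point,
#: between the first and second, and after the second.
STAIRCASE_FACTORS = (1.25**3, 1.25**2, 1.25)
STAIRCASE_START_DEG = 180.0


@dataclass
class HitSummary:
    """Outcome of scoring button presses against target color words."""

    hits: int
    possible: int
    excluded_onsets_s: list[float]
    hit_onsets_s: list[float]

    @property
    def proportion(self) -> float:
        if self.possible == 0:
            return float("nan")
        return self.hits / self.possible

    @property
    def undefined(self) -> bool:
        return self.possible == 0


def score_hits(
    press_times_s,
    target_word_onsets_s,
    masker_word_onsets_s=(),
    window_s: float = HIT_WINDOW_S,
) -> HitSummary:
    """Score spacebar presses against target color-word onsets.

    Target words with any masker word within ±``window_s`` are excluded
    from both numerator and denominator.  A hit is at least one press in
    the half-open window (onset, onset + ``window_s``]; presses are
    consumed in time order and each press credits at most one word (the
    earliest still-unhit eligible word).
    """
    presses = np.sort(np.asarray(press_times_s, dtype=float))
    targets = np.sort(np.asarray(target_word_onsets_s, dtype=float))
    maskers = np.sort(np.asarray(masker_word_onsets_s, dtype=float))

    excluded = []
    scoreable = []
    for t in targets:
        if maskers.size and np.min(np.abs(maskers - t)) <= window_s:
            excluded.append(float(t))
        else:
            scoreable.append(float(t))

    hit = [False] * len(scoreable)
    for p in presses:
        for i, onset in enumerate(scoreable):
            if not hit[i] and onset < p <= onset + window_s:
                hit[i] = True
                break

    return HitSummary(
        hits=int(sum(hit)),
        possible=len(scoreable),
        excluded_onsets_s=excluded,
        hit_onsets_s=[t for t, h in zip(scoreable, hit) if h],
    )


#: (baseline condition, interference condition) per task; the score is
#: median RT(interference) − median RT(baseline).
TASK_CONDITIONS = {
    "Flanker": ("congruent", "incongruent"),
    "Stroop": ("neutral", "color"),  # Part W vs Part C
    "TMT": ("A", "B"),
}


@dataclass(frozen=True)
class InterferenceScore:
    task: str
    score_ms: float
    n_baseline: int
    n_interference: int


def score_rt_interference(trials: pd.DataFrame, task: str) -> InterferenceScore:
    """Median-RT interference for Flanker, Stroop (Part C − Part W), or TMT (B − A).

    ``trials`` needs ``condition`` and ``rt_ms`` columns.  For the Flanker
    task, rows with a ``correct`` column are filtered to correct trials
    before taking medians (the other tasks advance only on correct
    responses, so their RTs are per-item completion times).
    """
    if task not in TASK_CONDITIONS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASK_CONDITIONS)}")
    baseline, interference = TASK_CONDITIONS[task]
    t = trials
    if task == "Flanker" and "correct" in t.columns:
        t = t[t["correct"].astype(bool)]
    rts = {c: t.loc[t["condition"] == c, "rt_ms"].to_numpy(float) for c in (baseline, interference)}
    for c, arr in rts.items():
        if arr.size == 0:
            raise ValueError(f"{task}: condition {c!r} has no trials; score undefined")
    return InterferenceScore(
        task=task,
        score_ms=float(np.median(rts[interference]) - np.median(rts[baseline])),
        n_baseline=len(rts[baseline]),
        n_interference=len(rts[interference]),
    )


@dataclass
class ReadingSpanScore:
    score: float
    per_trial: list[float]
    flags: list[str]


def score_reading_span(trials: list[tuple[str, str]]) -> ReadingSpanScore:
    """Average letter-recall accuracy over the three- and four-letter trials.

    Each trial is ``(presented, recalled)`` letter sequences; underscores or
    missing positions in the recall count as blanks.  Per-trial accuracy is
    the number of positions recalled with the correct letter divided by the
    list length (strict position matching); the score is the mean over the
    three 3-letter and three 4-letter trials — longer trials are ignored.
    """
    per_trial = []
    counts = {3: 0, 4: 0}
    for presented, recalled in trials:
        k = len(presented)
        if k not in (3, 4):
            continue
        counts[k] += 1
        correct = sum(
            1
            for i, letter in enumerate(presented)
            if i < len(recalled) and recalled[i] == letter
        )
        per_trial.append(correct / k)
    flags = [
        f"expected three {k}-letter trials, found {n}"
        for k, n in counts.items()
        if n != 3
    ]
    if not per_trial:
        raise ValueError("no three- or four-letter trials to score")
    return ReadingSpanScore(float(np.mean(per_trial)), per_trial, flags)


@dataclass
class StaircaseResult:
    """Trace and threshold of one adaptive 2-down/1-up run."""

    threshold_deg: float
    reversal_phis_deg: list[float]
    trace: pd.DataFrame  # trial, phi_deg, correct, reversal
    freq_hz: float
    flags: list[str] = field(default_factory=list)


def run_staircase(
    observer: ObserverModel,
    freq_hz: float = 250.0,
    seed: int | np.random.Generator = 0,
    max_reversals: int = 8,
    max_trials: int = 60,
) -> StaircaseResult:
    """Adaptive 2-down/1-up estimation of the 71%-correct IPD threshold.

    φ starts at 180° (maximally lateralized) and is divided by the step
    factor after two successive correct responses or multiplied by it after
    one incorrect response, capped at 180°.  The factor is 1.25³ before the
    first turn point, 1.25² between the first and second, and 1.25 after
    (the factor changes on the trial after the reversal).  The run stops at
    ``max_reversals`` turn points or ``max_trials`` trials; the threshold is
    the geometric mean of φ at the last six turn points.  The asymptotic
    convergence point of the rule satisfies p² = 0.5, i.e. ≈70.7% correct.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = STAIRCASE_START_DEG
    streak = 0
    last_step: int | None = None  # −1 down, +1 up
    reversal_phis: list[float] = []
    rows = []

    for trial in range(max_trials):
        correct = bool(rng.uniform() < observer.p_correct(phi))
        step = 0
        if correct:
            streak += 1
            if streak == 2:
                step = -1
                streak = 0
        else:
            step = +1
            streak = 0

        reversal = step != 0 and last_step is not None and step != last_step
        rows.append((trial, phi, correct, reversal))
        if reversal:
            reversal_phis.append(phi)

        if step != 0:
            # factor by the phase in force on this trial (pre-step count,
            # except the reversal just logged advances the phase afterwards)
            k = STAIRCASE_FACTORS[min(len(reversal_phis) - int(reversal), 2)]
            phi = min(STAIRCASE_START_DEG, phi * k if step > 0 else phi / k)
            last_step = step
        if len(reversal_phis) >= max_reversals:
            break

    flags = []
    if len(reversal_phis) < 6:
        flags.append(
            f"only {len(reversal_phis)} reversals before stopping; "
            "threshold uses all available turn points"
        )
    tail = reversal_phis[-6:]
    threshold = float(np.exp(np.mean(np.log(tail)))) if tail else float("nan")
    trace = pd.DataFrame(rows, columns=["trial", "phi_deg", "correct", "reversal"])
    return StaircaseResult(threshold, reversal_phis, trace, freq_hz, flags)


def measure_tfs(
    observers: dict[float, ObserverModel],
    seed: int = 0,
    **staircase_kwargs,
) -> float:
    """The TFS-LF measure: mean staircase threshold across test frequencies
    (250 and 500 Hz in the standard protocol)."""
    rng = np.random.default_rng(seed)
    thresholds = [
        run_staircase(obs, freq_hz=f, seed=rng, **staircase_kwargs).threshold_deg
        for f, obs in sorted(observers.items())
    ]
    return float(np.mean(thresholds))
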