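"""Continuous multitalker spatial-attention task generation.

A 7.5 min story block contains 75 left/right attention switches spaced
6 ± 1 s apart; 25 target color words are locked to switches at lags of
0.125–2 s (five per lag class, directions balanced 13/12); the two speech
streams swap ears with a 35 ms equal-power crossfade at each switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cheechlab.audio import AudioTrack

BLOCK_DURATION_S = 450.0
N_SWITCHES = 75
LAG_CLASSES_S = (0.125, 0.25, 0.5, 1.0, 2.0)
N_LAGGED_WORDS = 25
CROSSFADE_S = 0.035

#: Fixed event-time corrections (seconds), each toggleable: spatialization
#: processing delay, audio travel time through the insert-earphone tubes,
#: the hardware delay on one trigger channel, and the chirp-onset offset
#: between the scheduled and rendered chirp times.
DEFAULT_EVENT_OFFSETS = {
    "spatialization_delay_s": 0.001973,
    "earphone_tube_s": 0.001,
    "trigger_channel_s": 0.001,
    "chirp_onset_s": 0.000541,
}


@dataclass
class SwitchSchedule:
    """75 attention switches over a 450 s block.

    ``switch_times_s[k]`` is the cumulative sum of the first ``k+1``
    inter-switch intervals, so the final switch coincides with the block
    end; ``directions[k]`` is ``"LR"`` (target moves left → right) or
    ``"RL"``, strictly alternating.  The target starts on the side the
    first switch departs from.
    """

    switch_times_s: np.ndarray
    directions: list[str]
    block_duration_s: float = BLOCK_DURATION_S

    @property
    def intervals_s(self) -> np.ndarray:
        return np.diff(np.concatenate([[0.0], self.switch_times_s]))

    @property
    def initial_target_side(self) -> str:
        return "left" if self.directions[0] == "LR" else "right"

    def validate(self) -> None:
        t = self.switch_times_s
        if len(t) != len(self.directions):
            raise ValueError("switch_times_s and directions must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("switch times must be strictly increasing")
        if t[-1] > self.block_duration_s + 1e-9:
            raise ValueError("switches extend beyond the block")
        for d1, d2 in zip(self.directions, self.directions[1:]):
            if d1 == d2:
                raise ValueError("directions must alternate")


@dataclass(frozen=True)
class ColorWordEvent:
    """A color-word onset in one stream, with its switch-lag class if any."""

    onset_s: float
    stream: str  # "target" | "masker"
    lag_class_s: float | None = None
    direction: str | None = None  # direction of the preceding switch


def generate_switch_schedule(
    seed: int = 0,
    *,
    n_switches: int = N_SWITCHES,
    block_duration_s: float = BLOCK_DURATION_S,
    interval_bounds_s: tuple[float, float] = (5.0, 7.0),
) -> SwitchSchedule:
    """Draw inter-switch intervals uniform on [5, 7] s and normalize them to
    total exactly the block duration (iterative rescale-and-clip), keeping
    every interval inside the bounds and the interval mean exactly 6 s."""
    rng = np.random.default_rng(seed)
    lo, hi = interval_bounds_s
    if not lo * n_switches <= block_duration_s <= hi * n_switches:
        raise ValueError(
            f"{n_switches} intervals in [{lo}, {hi}] s cannot total {block_duration_s} s"
        )
    x = rng.uniform(lo, hi, size=n_switches)
    for _ in range(200):
        x = np.clip(x * (block_duration_s / x.sum()), lo, hi)
        if abs(x.sum() - block_duration_s) < 1e-12:
            break
    # exact final adjustment spread over intervals with slack
    resid = block_duration_s - x.sum()
    if abs(resid) > 0:
        room = (x < hi - 1e-9) if resid > 0 else (x > lo + 1e-9)
        x[room] += resid / max(room.sum(), 1)
    times = np.cumsum(x)
    start = rng.choice(["LR", "RL"])
    other = "RL" if start == "LR" else "LR"
    directions = [start if k % 2 == 0 else other for k in range(n_switches)]
    sched = SwitchSchedule(times, directions, block_duration_s)
    sched.validate()
    return sched


def assign_color_word_lags(
    schedule: SwitchSchedule,
    seed: int = 0,
    *,
    lag_classes_s: tuple[float, ...] = LAG_CLASSES_S,
    per_class: int = 5,
    n_extra_words: int = 0,
) -> list[ColorWordEvent]:
    """Lock target color words to switches at the five lag classes.

    Picks ``per_class × len(lag_classes_s)`` distinct switches (each switch
    carries at most one lagged word), balances them between left→right and
    right→left switches as evenly as the odd count allows (13/12 by default,
    which direction gets the extra word is seeded), and sets each word onset
    to its switch time plus its lag.  ``n_extra_words`` additional target
    words are placed at least 2.5 s away from every switch.
    """
    schedule.validate()
    rng = np.random.default_rng(seed)
    n_lagged = per_class * len(lag_classes_s)
    max_lag = max(lag_classes_s)

    eligible = [
        k
        for k, t in enumerate(schedule.switch_times_s)
        if t + max_lag <= schedule.block_duration_s
    ]
    by_dir: dict[str, list[int]] = {"LR": [], "RL": []}
    for k in eligible:
        by_dir[schedule.directions[k]].append(k)

    n_major = n_lagged // 2 + n_lagged % 2
    n_minor = n_lagged // 2
    major = rng.choice(["LR", "RL"])
    minor = "RL" if major == "LR" else "LR"
    if len(by_dir[major]) < n_major or len(by_dir[minor]) < n_minor:
        raise ValueError(
            f"too few eligible switches to place {n_lagged} lagged words "
            f"({len(by_dir['LR'])} LR / {len(by_dir['RL'])} RL available)"
        )
    chosen = np.concatenate(
        [
            rng.choice(by_dir[major], size=n_major, replace=False),
            rng.choice(by_dir[minor], size=n_minor, replace=False),
        ]
    )
    lags = np.repeat(lag_classes_s, per_class)
    rng.shuffle(lags)

    events = [
        ColorWordEvent(
            onset_s=float(schedule.switch_times_s[k] + lag),
            stream="target",
            lag_class_s=float(lag),
            direction=schedule.directions[k],
        )
        for k, lag in zip(chosen, lags)
    ]

    if n_extra_words:
        gaps = _away_from_switches(schedule, margin_s=2.5)
        if not gaps:
            raise ValueError("no room for extra words away from switches")
        for _ in range(n_extra_words):
            lo, hi = gaps[rng.integers(len(gaps))]
            events.append(
                ColorWordEvent(onset_s=float(rng.uniform(lo, hi)), stream="target")
            )
    return sorted(events, key=lambda e: e.onset_s)


def _away_from_switches(
    schedule: SwitchSchedule, margin_s: float
) -> list[tuple[float, float]]:
    """Open intervals of the block at least ``margin_s`` from every switch."""
    gaps = []
    prev = 0.0
    for t in np.concatenate([schedule.switch_times_s, [schedule.block_duration_s]]):
        lo, hi = prev + margin_s, t - margin_s
        if hi > lo:
            gaps.append((lo, hi))
        prev = t
    return gaps


def validate_masker_constraint(
    target_schedule: SwitchSchedule,
    masker_word_onsets,
    *,
    before_s: float = 0.5,
    after_s: float = 0.1,
) -> list[tuple[float, float]]:
    """Masker color words may not fall within (switch − 0.5 s, switch + 0.1 s).

    Returns ``(word_onset, offending_switch_time)`` pairs; an empty list
    means the constraint holds.
    """
    onsets = np.asarray(
        [w.onset_s if isinstance(w, ColorWordEvent) else float(w) for w in masker_word_onsets]
    )
    violations = []
    for w in onsets:
        idx = np.flatnonzero(
            (target_schedule.switch_times_s - before_s < w)
            & (w < target_schedule.switch_times_s + after_s)
        )
        for k in idx:
            violations.append((float(w), float(target_schedule.switch_times_s[k])))
    return violations


def render_spatial_audio(
    target: AudioTrack,
    masker: AudioTrack | None,
    schedule: SwitchSchedule,
    fade_s: float = CROSSFADE_S,
) -> AudioTrack:
    """Pan the streams to alternating ears with equal-power crossfades.

    The target's left/right amplitude gains follow complementary
    raised-cosine trajectories (gL² + gR² = 1 throughout), swapping sides
    over ``fade_s`` starting at each switch onset; the masker (if present)
    mirrors the target.  Visual-cue markers switch instantaneously and are
    recorded in ``meta['cue_times_s']``.
    """
    schedule.validate()
    if masker is not None and masker.rate_hz != target.rate_hz:
        raise ValueError("target and masker sample rates differ")
    if np.any(np.diff(schedule.switch_times_s) < fade_s):
        raise ValueError("switch interval shorter than the crossfade; fades overlap")

    fs = target.rate_hz
    n = target.n_samples
    t = np.arange(n) / fs

    # Target-left amplitude gain trajectory.
    g_left = np.empty(n)
    side_left = schedule.initial_target_side == "left"
    g_left[:] = 1.0 if side_left else 0.0
    for s in schedule.switch_times_s:
        i0 = int(round(s * fs))
        if i0 >= n:
            break
        i1 = min(n, int(round((s + fade_s) * fs)))
        u = (t[i0:i1] - s) / fade_s
        theta = 0.5 * np.pi * np.clip(u, 0.0, 1.0)
        if side_left:  # moving to the right ear
            g_left[i0:i1] = np.cos(theta)
            g_left[i1:] = 0.0
        else:
            g_left[i0:i1] = np.sin(theta)
            g_left[i1:] = 1.0
        side_left = not side_left
    g_right = np.sqrt(np.clip(1.0 - g_left**2, 0.0, 1.0))

    tgt = target.mono
    left = g_left * tgt
    right = g_right * tgt
    if masker is not None:
        msk = masker.mono[:n]
        msk = np.pad(msk, (0, n - len(msk)))
        left = left + g_right * msk
        right = right + g_left * msk

    return AudioTrack(
        samples=np.column_stack([left, right]),
        rate_hz=fs,
        words=list(target.words) + (list(masker.words) if masker else []),
        meta={
            "cue_times_s": schedule.switch_times_s.copy(),
            "directions": list(schedule.directions),
            "fade_s": fade_s,
            "mono_talker": masker is None,
        },
    )


@dataclass
class AlignmentReport:
    """Outcome of reconciling recorded trigger events with the expected list."""

    corrected_times_s: np.ndarray
    matched: np.ndarray  # bool per expected event
    inserted_indices: list[int] = field(default_factory=list)
    dropped_recorded: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def align_events(
    recorded_times_s,
    expected_times_s,
    fixed_offsets: dict[str, float] | None = None,
    *,
    tolerance_s: float = 0.005,
    enabled_offsets: set[str] | None = None,
) -> AlignmentReport:
    """Reconcile recorded events against the authoritative expected list.

    Greedy nearest-neighbor matching within ``tolerance_s``: each expected
    event snaps to its nearest unmatched recorded event; expected events
    with no recorded partner are inserted at their expected times; recorded
    events left unmatched are dropped.  The enabled fixed timing offsets
    (see :data:`DEFAULT_EVENT_OFFSETS`) are then added to every corrected
    time.  More than 10% unmatched events raises a warning in the report,
    not an error.
    """
    recorded = np.sort(np.asarray(recorded_times_s, dtype=float))
    expected = np.asarray(expected_times_s, dtype=float)
    offsets = DEFAULT_EVENT_OFFSETS if fixed_offsets is None else fixed_offsets
    enabled = set(offsets) if enabled_offsets is None else enabled_offsets
    shift = sum(v for k, v in offsets.items() if k in enabled)

    used = np.zeros(len(recorded), dtype=bool)
    matched = np.zeros(len(expected), dtype=bool)
    inserted: list[int] = []
    for i, e in enumerate(expected):
        lo = np.searchsorted(recorded, e - tolerance_s)
        hi = np.searchsorted(recorded, e + tolerance_s, side="right")
        candidates = [j for j in range(lo, hi) if not used[j]]
        if candidates:
            j = min(candidates, key=lambda j: abs(recorded[j] - e))
            used[j] = True
            matched[i] = True
        else:
            inserted.append(i)

    dropped = [float(r) for r, u in zip(recorded, used) if not u]
    warnings = []
    n_unmatched = len(inserted) + len(dropped)
    denom = max(len(expected) + len(dropped), 1)
    if n_unmatched / denom > 0.10:
        warnings.append(
            f"{n_unmatched} unmatched events out of {denom} "
            f"({100 * n_unmatched / denom:.1f}% > 10%)"
        )

    return AlignmentReport(
        corrected_times_s=expected + shift,
        matched=matched,
        inserted_indices=inserted,
        dropped_recorded=dropped,
        warnings=warnings,
    )


def events_to_frame(events: list[ColorWordEvent]) -> pd.DataFrame:
    """Color-word events as a table (onset_s, stream, lag_class, direction)."""
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "stream": [e.stream for e in events],
            "lag_class": [e.lag_class_s for e in events],
            "direction": [e.direction for e in events],
        }
    )
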