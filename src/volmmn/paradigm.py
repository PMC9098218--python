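"""Volatility oddball paradigm: probability schedule, tone sequence, distractors.

The paradigm presents 1800 pure tones (528 Hz vs 440 Hz, 70 ms, 500 ms ISI).
The probability of hearing tone 1 is piecewise constant: 0.85 or 0.15 during
stable phases (constant for >= 100 trials) and during volatile phases (where
it reverses every 25-60 trials), plus four 50-trial neutral phases at p = 0.5.
The second half of the stream is a copy of the first half with the tone
identities swapped, so each tone serves as the minority ("deviant") tone
equally often over the session.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STABLE = "stable"
VOLATILE = "volatile"
NEUTRAL = "neutral"


class LayoutError(ValueError):
    """Requested phase layout cannot be fitted into the sequence."""


@dataclass(frozen=True)
class ScheduleParams:
    """Parameters of the probability schedule.

    Defaults reproduce the published paradigm: 1800 trials, tone-1 probability
    0.85/0.15 outside four 50-trial neutral phases at 0.5, stable phases of at
    least 100 trials, volatile reversals every 25-60 trials, mirrored halves.
    """

    n_trials: int = 1800
    p_major: float = 0.85
    p_minor: float = 0.15
    p_neutral: float = 0.5
    n_neutral_phases: int = 4
    neutral_phase_len: int = 50
    stable_min_len: int = 100
    volatile_seg_min: int = 25
    volatile_seg_max: int = 60
    mirror: bool = True
    tone_freqs: tuple[float, float] = (528.0, 440.0)
    tone_dur: float = 70.0  # ms
    isi: float = 500.0  # ms

    def __post_init__(self) -> None:
        if not (0.0 < self.p_minor < self.p_neutral < self.p_major < 1.0):
            raise ValueError("require 0 < p_minor < p_neutral < p_major < 1")
        if self.volatile_seg_min > self.volatile_seg_max:
            raise ValueError("volatile_seg_min must be <= volatile_seg_max")
        if self.n_neutral_phases * self.neutral_phase_len >= self.n_trials:
            raise ValueError("neutral phases do not fit into n_trials")
        if self.mirror and self.n_trials % 2:
            raise ValueError("n_trials must be even when mirror is true")

    @property
    def soa(self) -> float:
        """Stimulus onset asynchrony in ms (tone duration + ISI)."""
        return self.tone_dur + self.isi


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Trial-wise probability of tone 1 with phase labels.

    ``p_tone1`` is piecewise constant between ``segment_boundaries``;
    ``phase_label`` marks each trial stable, volatile, or neutral.
    """

    p_tone1: np.ndarray
    phase_label: np.ndarray
    segment_boundaries: np.ndarray
    params: ScheduleParams

    @property
    def n_trials(self) -> int:
        return self.p_tone1.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "p_tone1": self.p_tone1,
                "phase_label": self.phase_label,
            }
        )


@dataclass(frozen=True)
class ToneSequence:
    """Realized binary tone stream (tones coded 1 and 2)."""

    tones: np.ndarray
    schedule: ProbabilitySchedule
    seed: int

    @property
    def n_trials(self) -> int:
        return self.tones.size

    def onsets_ms(self) -> np.ndarray:
        """Tone onset times in ms assuming a constant SOA from trial 0."""
        return np.arange(self.n_trials) * self.schedule.params.soa


@dataclass(frozen=True)
class RunLengthSummary:
    """Run-length distribution of maximal identical-tone blocks."""

    lengths: np.ndarray  # length of each maximal run, in order
    run_tones: np.ndarray  # tone identity of each run

    @property
    def n_runs(self) -> int:
        return self.lengths.size

    def counts(self) -> pd.Series:
        return pd.Series(self.lengths).value_counts().sort_index()

    def fraction_at_least(self, k: int) -> float:
        return float(np.mean(self.lengths >= k))

    def fraction_at_most(self, k: int) -> float:
        return float(np.mean(self.lengths <= k))


@dataclass(frozen=True)
class DistractorSchedule:
    """Visual distractor events: onset times, sides, and delays after tone offset."""

    event_times: np.ndarray  # ms, absolute
    sides: np.ndarray  # "left"/"right"
    delays: np.ndarray  # ms after tone offset
    trial_index: np.ndarray  # tone carrying each target
    n_targets: int


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams derived from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_half_layout(params: ScheduleParams, rng: np.random.Generator):
    """Draw the first-half phase layout: list of (length, kind, p) segments.

    The half alternates stable blocks (>= stable_min_len trials at p_major or
    p_minor) with volatile blocks (runs of reversal segments drawn uniformly
    on [volatile_seg_min, volatile_seg_max]), and embeds half the neutral
    phases. Volatile segment lengths are always untruncated uniform draws;
    budget that cannot fit another whole segment is absorbed by stable blocks,
    so the realized segment-length distribution stays exactly uniform. The
    layout is drawn freshly per seed; the published experiment used one fixed
    realization of this family.
    """
    half = params.n_trials // 2 if params.mirror else params.n_trials
    n_neutral_half = (
        params.n_neutral_phases // 2 if params.mirror else params.n_neutral_phases
    )
    if params.mirror and params.n_neutral_phases % 2:
        raise LayoutError("n_neutral_phases must be even when mirroring")
    remaining = half - n_neutral_half * params.neutral_phase_len
    s_min, v_min, v_max = params.stable_min_len, params.volatile_seg_min, params.volatile_seg_max
    if remaining < s_min:
        raise LayoutError(
            f"cannot fit a stable phase of {s_min} trials into "
            f"{remaining} non-neutral trials per half"
        )

    # Alternate stable blocks and volatile blocks until the budget is spent.
    blocks: list[tuple[str, object]] = []  # ("stable", length) | ("volatile", [seg lengths])
    budget = remaining
    want_stable = True
    while budget > 0:
        if want_stable:
            if budget < s_min + 2 * v_min:
                # closing block: absorb everything that is left
                if budget >= s_min:
                    blocks.append((STABLE, budget))
                else:
                    idx = max(i for i, b in enumerate(blocks) if b[0] == STABLE)
                    blocks[idx] = (STABLE, blocks[idx][1] + budget)
                budget = 0
            else:
                max_extra = min(150, budget - s_min - 2 * v_min)
                length = s_min + int(rng.integers(0, max_extra + 1))
                blocks.append((STABLE, length))
                budget -= length
            want_stable = False
        else:
            # volatile block: leave room for a closing stable phase
            v_cap = budget - s_min
            if v_cap >= v_min:
                v_budget = int(rng.integers(v_min, min(v_cap, 6 * v_max) + 1))
                seglens: list[int] = []
                while True:
                    s = int(rng.integers(v_min, v_max + 1))
                    if sum(seglens) + s > v_budget:
                        break
                    seglens.append(s)
                if seglens:
                    blocks.append((VOLATILE, seglens))
                    budget -= sum(seglens)
            want_stable = True

    # Flatten to segments with alternating probabilities.
    p_current = params.p_major if rng.random() < 0.5 else params.p_minor

    def flip(p: float) -> float:
        return params.p_major if p == params.p_minor else params.p_minor

    segs: list[tuple[int, str, float]] = []
    for kind, payload in blocks:
        if kind == STABLE:
            segs.append((int(payload), STABLE, p_current))
            p_current = flip(p_current)
        else:
            for seg_len in payload:  # type: ignore[union-attr]
                segs.append((int(seg_len), VOLATILE, p_current))
                p_current = flip(p_current)

    # Insert neutral phases between segments at random positions (never
    # first, keeping the opening stable phase intact).
    if n_neutral_half:
        positions = sorted(
            rng.choice(np.arange(1, len(segs) + 1), size=n_neutral_half, replace=False)
        )
        for off, pos in enumerate(positions):
            segs.insert(pos + off, (params.neutral_phase_len, NEUTRAL, params.p_neutral))
    total = sum(s[0] for s in segs)
    if total != half:
        raise LayoutError(f"layout totals {total} trials, expected {half}")
    return segs


def build_schedule(params: ScheduleParams | None = None, seed: int = 0) -> ProbabilitySchedule:
    """Generate a probability schedule satisfying the paradigm's constraints.

    The first half is drawn from the parameterized layout family; when
    ``params.mirror`` the second half is the probability-flipped copy
    (p -> 1 - p), so neutral phases stay at 0.5 and each tone is the minority
    tone in exactly half of the non-neutral trials.
    """
    params = params or ScheduleParams()
    rng = _rng_streams(seed, 2)[0]
    segs = _draw_half_layout(params, rng)
    if params.mirror:
        # Reject layouts whose closing probability equals the flipped opening
        # probability: a constant-p run would straddle the mirror boundary and
        # break the exact half-symmetry of phase labels.
        for _ in range(50):
            if not np.isclose(segs[-1][2], 1.0 - segs[0][2]):
                break
            segs = _draw_half_layout(params, rng)

    p = np.concatenate([np.full(n, pv) for n, _, pv in segs])
    labels = np.concatenate([np.full(n, kind, dtype=object) for n, kind, _ in segs])
    bounds = np.cumsum([0] + [n for n, _, _ in segs])
    if params.mirror:
        p = np.concatenate([p, 1.0 - p])
        labels = np.concatenate([labels, labels.copy()])
        bounds = np.concatenate([bounds, bounds[1:] + params.n_trials // 2])
    return ProbabilitySchedule(
        p_tone1=p, phase_label=labels.astype("U8"), segment_boundaries=bounds, params=params
    )


def generate_sequence(schedule: ProbabilitySchedule, seed: int = 0) -> ToneSequence:
    """Draw the tone stream: independent Bernoulli draws in the first half,
    deterministic tone-flip copy in the second half when mirrored."""
    params = schedule.params
    rng = _rng_streams(seed, 2)[1]
    n = schedule.n_trials
    if params.mirror:
        half = n // 2
        first = np.where(rng.random(half) < schedule.p_tone1[:half], 1, 2)
        tones = np.concatenate([first, 3 - first])
    else:
        tones = np.where(rng.random(n) < schedule.p_tone1, 1, 2)
    return ToneSequence(tones=tones.astype(np.int8), schedule=schedule, seed=seed)


def run_length_table(seq: ToneSequence | np.ndarray) -> RunLengthSummary:
    """Run lengths of maximal identical-tone blocks ("mini-blocks")."""
    tones = seq.tones if isinstance(seq, ToneSequence) else np.asarray(seq)
    if tones.size == 0:
        raise ValueError("empty sequence")
    change = np.flatnonzero(np.diff(tones) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [tones.size]])
    return RunLengthSummary(lengths=ends - starts, run_tones=tones[starts])


def schedule_distractors(
    seq: ToneSequence, n_targets: int = 36, seed: int = 0
) -> DistractorSchedule:
    """Place visual targets on distinct tones, 50-250 ms after tone offset.

    Exactly half of the targets (rounding down) open to the left. Delays are
    uniform on [50, 250] ms after tone offset (offset = onset + tone_dur), so
    events never coincide with a tone presentation.
    """
    if n_targets > seq.n_trials:
        raise ValueError("more targets than tones")
    rng = np.random.default_rng(seed)
    params = seq.schedule.params
    trials = np.sort(rng.choice(seq.n_trials, size=n_targets, replace=False))
    delays = rng.uniform(50.0, 250.0, size=n_targets)
    n_left = n_targets // 2
    sides = np.array(["left"] * n_left + ["right"] * (n_targets - n_left), dtype="U5")
    rng.shuffle(sides)
    onsets = trials * params.soa + params.tone_dur + delays
    return DistractorSchedule(
        event_times=onsets, sides=sides, delays=delays, trial_index=trials, n_targets=n_targets
    )


def trial_sheet(seq: ToneSequence) -> pd.DataFrame:
    """TSV-ready trial sheet: trial, tone, p_tone1, phase_label."""
    sched = seq.schedule
    return pd.DataFrame(
        {
            "trial": np.arange(seq.n_trials),
            "tone": seq.tones,
            "p_tone1": sched.p_tone1,
            "phase_label": sched.phase_label,
        }
    )
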