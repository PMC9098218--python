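"""Standard/deviant trial labels (INIT and 2REP definitions) and stability labels.

INIT: a deviant is a tone that differs from its predecessor after the
predecessor's run reached at least 5 repetitions; a standard is the 6th
consecutive identical tone. 2REP: every switch tone after at least 2
repetitions is a deviant; repetition tones with at least 2 preceding
repetitions are candidate standards, subsampled so that for each preceding
run length there are as many standards as deviants.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import ProbabilitySchedule, ToneSequence, STABLE, VOLATILE

INIT = "INIT"
TWO_REP = "2REP"


@dataclass(frozen=True)
class TrialTable:
    """Per-trial labels: role, preceding-repetition count, stability."""

    frame: pd.DataFrame  # columns: trial, tone, role, n_prev_reps, stability
    definition: str

    @property
    def deviants(self) -> np.ndarray:
        return self.frame.index[self.frame["role"] == "deviant"].to_numpy()

    @property
    def standards(self) -> np.ndarray:
        return self.frame.index[self.frame["role"] == "standard"].to_numpy()

    def counts(self) -> dict[str, int]:
        return {
            "deviant": int((self.frame["role"] == "deviant").sum()),
            "standard": int((self.frame["role"] == "standard").sum()),
        }


def _run_positions(tones: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each trial: position within its run (1-based) and the length of
    the maximal run ending at the *previous* trial (0 for trial 0)."""
    n = tones.size
    pos = np.ones(n, dtype=int)
    for t in range(1, n):
        pos[t] = pos[t - 1] + 1 if tones[t] == tones[t - 1] else 1
    prev_run = np.zeros(n, dtype=int)
    prev_run[1:] = np.where(tones[1:] == tones[:-1], 0, pos[:-1])
    # for repetitions, the "preceding run" is the run including the previous
    # tone (same run): pos[t-1]
    prev_same = np.zeros(n, dtype=int)
    prev_same[1:] = pos[:-1]
    return pos, np.where(prev_run > 0, prev_run, prev_same)


def assign_stability(schedule: ProbabilitySchedule) -> np.ndarray:
    """Stable iff the trial lies in a phase where p is unchanged for at least
    ``stable_min_len`` trials; all other trials (including neutral phases)
    are volatile."""
    p = schedule.p_tone1
    n = p.size
    min_len = schedule.params.stable_min_len
    change = np.flatnonzero(np.diff(p) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [n]])
    labels = np.full(n, VOLATILE, dtype="U8")
    for s, e in zip(starts, ends):
        if e - s >= min_len and p[s] != schedule.params.p_neutral:
            labels[s:e] = STABLE
    return labels


def _base_frame(seq: ToneSequence) -> pd.DataFrame:
    tones = np.asarray(seq.tones)
    pos, prev = _run_positions(tones)
    return pd.DataFrame(
        {
            "trial": np.arange(tones.size),
            "tone": tones,
            "run_pos": pos,
            "n_prev_reps": prev,
            "stability": assign_stability(seq.schedule),
        }
    )


def label_trials_init(seq: ToneSequence) -> TrialTable:
    """INIT definition: deviants follow >= 5 repetitions of the other tone;
    standards are the 6th consecutive identical tone."""
    df = _base_frame(seq)
    tones = df["tone"].to_numpy()
    pos = df["run_pos"].to_numpy()
    is_switch = np.zeros(len(df), dtype=bool)
    is_switch[1:] = tones[1:] != tones[:-1]
    role = np.full(len(df), "none", dtype="U8")
    role[is_switch & (df["n_prev_reps"].to_numpy() >= 5)] = "deviant"
    role[pos == 6] = "standard"
    df["role"] = role
    return TrialTable(frame=df, definition=INIT)


def label_trials_2rep(seq: ToneSequence, seed: int = 0) -> TrialTable:
    """2REP definition with repetition-matched standard subsampling.

    Candidate deviants: switch tones whose preceding run is >= 2. Candidate
    standards: repetition tones that complete at least 2 preceding identical
    tones (run position >= 3). Standards are subsampled uniformly at random
    within each preceding-run-length stratum so the per-stratum counts match
    the deviant counts exactly; shortfalls are kept in full and reported via
    a warning.
    """
    df = _base_frame(seq)
    rng = np.random.default_rng(seed)
    tones = df["tone"].to_numpy()
    pos = df["run_pos"].to_numpy()
    prev = df["n_prev_reps"].to_numpy()
    is_switch = np.zeros(len(df), dtype=bool)
    is_switch[1:] = tones[1:] != tones[:-1]

    role = np.full(len(df), "none", dtype="U8")
    dev_idx = np.flatnonzero(is_switch & (prev >= 2))
    role[dev_idx] = "deviant"
    # for a standard at run position p, the number of preceding repetitions of
    # the same tone is p - 1
    cand_std = np.flatnonzero(~is_switch & (pos >= 3) & (df["trial"].to_numpy() > 0))

    dev_r = prev[dev_idx]
    std_r = pos[cand_std] - 1
    kept: list[np.ndarray] = []
    for r in np.unique(dev_r):
        n_dev = int((dev_r == r).sum())
        pool = cand_std[std_r == r]
        if pool.size < n_dev:
            warnings.warn(
                f"2REP matching shortfall at r={r}: {pool.size} standards for {n_dev} deviants",
                stacklevel=2,
            )
            kept.append(pool)
        else:
            kept.append(rng.choice(pool, size=n_dev, replace=False))
    if kept:
        role[np.concatenate(kept)] = "standard"
    df["role"] = role
    return TrialTable(frame=df, definition=TWO_REP)
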