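"""Synthetic two-study EEG cohort simulator.

Three granularities share one template code path (:mod:`volmmn.templates`):

* continuous recordings at 500 Hz with 1/f + white sensor noise and blink
  transients (exercises the full preprocessing chain);
* per-trial epochs at the analysis rate (exercises trial-level statistics);
* per-condition average ERPs (the scaled path used for cohort-level
  statistical simulations, where the trial-averaged noise is drawn
  directly at the condition level).

Group sizes, effect sizes, and behavioral parameters default to the
published study-1 cohort (placebo N=25, amisulpride N=24, biperiden N=22;
hit rate ~94.8%, mean RT ~510 ms).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import labeling, paradigm
from .montage import Montage, make_montage
from .templates import (
    ERPComponentSpec,
    EffectSpec,
    PLACEBO_EFFECT,
    default_components,
    evoked_template,
    group_effects_study1,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise and artifact model.

    Amplitudes are in µV. ``pink_sd`` and ``white_sd`` set the RMS of the
    1/f-shaped and white components of the continuous background;
    ``spatial_scale_mm`` is the e-folding distance of the between-channel
    correlation. ``erp_sd`` is the residual (trial-averaged) noise SD of a
    condition-average ERP at a single channel/time point in the scaled
    cohort path; ``subject_amp_sd`` is the SD of the multiplicative
    between-subject ERP gain.
    """

    pink_sd: float = 9.0
    white_sd: float = 4.0
    spatial_scale_mm: float = 120.0
    blink_rate_per_min: float = 15.0
    blink_amp_uv: float = 120.0
    erp_sd: float = 1.07
    erp_time_smooth_ms: float = 25.0
    subject_amp_sd: float = 0.10

    def scaled(self, factor: float) -> "NoiseSpec":
        return replace(
            self,
            pink_sd=self.pink_sd * factor,
            white_sd=self.white_sd * factor,
            erp_sd=self.erp_sd * factor,
        )


NOISELESS = NoiseSpec(pink_sd=0, white_sd=0, blink_rate_per_min=0, erp_sd=0, subject_amp_sd=0)


@dataclass(frozen=True)
class SubjectRecord:
    """Subject metadata: group assignment, plasma draws, behavior parameters."""

    id: str
    study: int
    group: str  # PLA/AMI/BIP (study 1) or PLA/LEV/GAL (study 2)
    plasma_conc: tuple[float, float] = (0.0, 0.0)
    draw_times_min: tuple[float, float] = (75.7, 189.0)
    task_time_min: float = 120.0
    mean_rt_ms: float = 510.0
    hit_prob: float = 0.948

    def __post_init__(self) -> None:
        if min(self.plasma_conc) < 0:
            raise ValueError("plasma concentrations must be non-negative")


@dataclass(frozen=True)
class RawRecording:
    """Continuous multichannel recording in µV at 500 Hz."""

    data: np.ndarray  # (n_channels, n_samples)
    ch_names: tuple[str, ...]  # scalp channels then EOG
    sfreq: float
    onsets_ms: np.ndarray  # tone onsets
    tones: np.ndarray
    subject: SubjectRecord
    montage: Montage

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


def interpolate_plasma(subject: SubjectRecord) -> float:
    """Drug plasma concentration at task time, linearly interpolated (and, if
    the task time lies outside the draws, extrapolated) between the two blood
    draws. Placebo subjects return 0."""
    if subject.group == "PLA":
        return 0.0
    (c1, c2), (t1, t2) = subject.plasma_conc, subject.draw_times_min
    if t1 == t2:
        raise ValueError("blood draw times must be distinct")
    return float(c1 + (c2 - c1) * (subject.task_time_min - t1) / (t2 - t1))


def _spatial_chol(montage: Montage, scale_mm: float, n_extra: int = 1) -> np.ndarray:
    """Cholesky factor of a distance-decay channel covariance (EOG appended
    as a frontal position)."""
    pos = montage.pos2d
    eog = pos[montage.index("Fp1")] + np.array([0.0, 25.0])  # beyond the front rim
    pts = np.vstack([pos] + [eog[None, :]] * n_extra)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    k = np.exp(-d / scale_mm) + 1e-6 * np.eye(len(pts))
    return np.linalg.cholesky(k)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, sfreq: float) -> np.ndarray:
    """1/f-shaped noise with unit RMS per channel via spectral shaping."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, 1 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    shape[0] = 0.0  # no DC drift component
    out = np.fft.irfft(spec * shape, n=n_samp, axis=1)
    return out / out.std(axis=1, keepdims=True)


def blink_topography(montage: Montage) -> np.ndarray:
    """Frontal-dominant blink scalp weights plus the infraorbital EOG weight
    (opposite sign, larger) as the last element.

    The scalp part is a steep frontal-pole falloff, orthogonalized (in the
    average-reference subspace) against the default evoked topographies:
    blink and signal subspaces are distinct in real recordings — blinks
    arise from ocular, not cortical, generators — and the low spatial rank
    of the 2D simulation would otherwise create artificial collinearity
    between them.
    """
    from .templates import default_components

    front = 0.5 * (
        montage.pos2d[montage.index("Fp1")] + montage.pos2d[montage.index("Fp2")]
    )
    d = np.linalg.norm(montage.pos2d - front, axis=1)
    w = np.exp(-d / 25.0)
    w = w - w.mean()
    basis = []
    for comp in default_components(montage).values():
        t = comp.topography - comp.topography.mean()
        for b in basis:
            t = t - (t @ b) * b
        n = np.linalg.norm(t)
        if n > 1e-9:
            basis.append(t / n)
    for b in basis:
        w = w - (w @ b) * b
    w = w / np.abs(w).max()
    return np.concatenate([w, [-1.5]])


def _blink_waveform(sfreq: float) -> np.ndarray:
    t = np.arange(int(0.4 * sfreq)) / sfreq
    return np.exp(-0.5 * ((t - 0.2) / 0.06) ** 2)


def simulate_recording(
    seq: paradigm.ToneSequence,
    subject: SubjectRecord,
    components: dict[str, ERPComponentSpec] | None = None,
    effects: dict[str, EffectSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    montage: Montage | None = None,
    sfreq: float = 500.0,
    pad_s: float = 1.0,
) -> RawRecording:
    """Continuous recording: every tone evokes the generic auditory template;
    INIT deviants additionally evoke the (group- and stability-modulated)
    mismatch component; plus 1/f + white noise and Poisson blink transients."""
    montage = montage or make_montage()
    components = components or default_components(montage)
    effects = effects or group_effects_study1()
    noise = noise or NoiseSpec()
    effect = effects[subject.group]
    rng = np.random.default_rng(seed)

    soa = seq.schedule.params.soa
    onsets_ms = seq.onsets_ms() + pad_s * 1000.0
    n_samp = int((onsets_ms[-1] / 1000.0 + 0.6 + pad_s) * sfreq)
    n_scalp = montage.n_scalp
    data = np.zeros((n_scalp + 1, n_samp))

    # evoked activity: add the condition template at each tone onset
    table = labeling.label_trials_init(seq).frame
    tmpl_times = np.arange(0.0, 500.0, 1000.0 / sfreq)  # 0..500 ms post-onset
    cache: dict[tuple[str, str], np.ndarray] = {}
    for role_key in ("standard_like", "deviant"):
        for stab in ("stable", "volatile"):
            role = "deviant" if role_key == "deviant" else "standard"
            cache[(role_key, stab)] = evoked_template(
                components, tmpl_times, role, stab, effect, montage
            )
    n_t = tmpl_times.size
    for trial in range(seq.n_trials):
        role = table["role"].iat[trial]
        stab = table["stability"].iat[trial]
        key = ("deviant" if role == "deviant" else "standard_like", stab)
        s0 = int(round(onsets_ms[trial] / 1000.0 * sfreq))
        data[:n_scalp, s0 : s0 + n_t] += cache[key][:, : n_samp - s0]

    # background noise, spatially correlated across channels (incl. EOG)
    if noise.pink_sd > 0 or noise.white_sd > 0:
        chol = _spatial_chol(montage, noise.spatial_scale_mm)
        bg = noise.pink_sd * _pink_noise(rng, n_scalp + 1, n_samp, sfreq)
        bg += noise.white_sd * rng.standard_normal((n_scalp + 1, n_samp))
        data += chol @ bg / np.sqrt(np.diag(chol @ chol.T))[:, None]

    # blinks at Poisson times with a fixed frontal topography
    if noise.blink_rate_per_min > 0:
        wave = _blink_waveform(sfreq)
        topo = blink_topography(montage) * noise.blink_amp_uv
        rate_per_samp = noise.blink_rate_per_min / 60.0 / sfreq
        n_blinks = rng.poisson(rate_per_samp * n_samp)
        starts = np.sort(rng.integers(0, n_samp - wave.size, size=n_blinks))
        # enforce a refractory gap so blinks do not pile up
        keep = np.concatenate([[True], np.diff(starts) > wave.size]) if n_blinks else np.array([], bool)
        for s0 in starts[keep]:
            amp = 1.0 + 0.3 * rng.standard_normal()
            data[:, s0 : s0 + wave.size] += amp * np.outer(topo, wave)

    return RawRecording(
        data=data,
        ch_names=montage.all_names,
        sfreq=sfreq,
        onsets_ms=onsets_ms,
        tones=np.asarray(seq.tones),
        subject=subject,
        montage=montage,
    )


def _erp_noise(
    rng: np.random.Generator,
    montage: Montage,
    times_ms: np.ndarray,
    noise: NoiseSpec,
) -> np.ndarray:
    """Spatio-temporally smooth condition-level ERP noise with per-point SD
    ``noise.erp_sd`` µV."""
    if noise.erp_sd == 0:
        return np.zeros((montage.n_scalp, times_ms.size))
    chol = _spatial_chol(montage, noise.spatial_scale_mm, n_extra=0)
    e = rng.standard_normal((montage.n_scalp, times_ms.size))
    # temporal smoothing by Gaussian kernel
    dt = times_ms[1] - times_ms[0]
    sigma = noise.erp_time_smooth_ms / dt
    from scipy.ndimage import gaussian_filter1d

    e = gaussian_filter1d(e, sigma, axis=1, mode="reflect")
    e = chol @ e
    return noise.erp_sd * e / e.std()


def simulate_condition_erps(
    subject: SubjectRecord,
    components: dict[str, ERPComponentSpec] | None = None,
    effects: dict[str, EffectSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    montage: Montage | None = None,
    times_ms: np.ndarray | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-condition average ERPs (role x stability) for one subject.

    Returns {(role, stability): (n_scalp, n_times) µV}. Noise enters as a
    shared multiplicative subject gain plus independent condition-level
    residual noise, the scaled stand-in for averaging over that condition's
    trials.
    """
    montage = montage or make_montage()
    components = components or default_components(montage)
    effects = effects or group_effects_study1()
    noise = noise or NoiseSpec()
    times_ms = times_ms if times_ms is not None else np.arange(-100.0, 400.1, 4.0)
    effect = effects[subject.group]
    rng = np.random.default_rng(seed)
    gain = 1.0 + noise.subject_amp_sd * rng.standard_normal()
    out = {}
    for role in ("standard", "deviant"):
        for stab in ("stable", "volatile"):
            tmpl = evoked_template(components, times_ms, role, stab, effect, montage)
            out[(role, stab)] = gain * tmpl + _erp_noise(rng, montage, times_ms, noise)
    return out


@dataclass(frozen=True)
class BehaviorResult:
    responses: pd.DataFrame  # per-target: rt_ms, correct
    hit_rate: float | None  # None when there were no targets

    @property
    def mean_rt(self) -> float | None:
        ok = self.responses.loc[self.responses["correct"], "rt_ms"]
        return float(ok.mean()) if len(ok) else None


def simulate_behavior(
    subject: SubjectRecord, distractors: paradigm.DistractorSchedule, seed: int = 0
) -> BehaviorResult:
    """Bernoulli hits at the subject's hit probability; lognormal RTs around
    the subject's mean RT for correct responses."""
    rng = np.random.default_rng(seed)
    n = distractors.n_targets
    if n == 0:
        return BehaviorResult(
            responses=pd.DataFrame(columns=["rt_ms", "correct"]), hit_rate=None
        )
    correct = rng.random(n) < subject.hit_prob
    sigma = 0.14  # lognormal shape: RT CV ~ 14%
    mu = np.log(subject.mean_rt_ms) - sigma**2 / 2
    rts = np.where(correct, rng.lognormal(mu, sigma, size=n), np.nan)
    frame = pd.DataFrame({"rt_ms": rts, "correct": correct})
    return BehaviorResult(responses=frame, hit_rate=float(correct.mean()))


# plasma concentration models per active drug: (mean, sd) at first draw and
# a decay fraction by the second draw
_PLASMA_MODEL = {
    "AMI": (500.0, 150.0, 0.8),  # nmol/L
    "BIP": (10.0, 3.0, 0.75),  # nmol/L
    "LEV": (800.0, 250.0, 0.5),  # µg/L
    "GAL": (30.0, 8.0, 0.85),  # µg/L
    "PLA": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and simulation granularity."""

    study: int = 1
    groups: tuple[str, ...] = ("PLA", "AMI", "BIP")
    group_sizes: tuple[int, ...] = (25, 24, 22)
    n_targets: int = 36
    mode: str = "erp"  # "erp" | "continuous"
    schedule_params: paradigm.ScheduleParams = field(default_factory=paradigm.ScheduleParams)

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.group_sizes):
            raise ValueError("groups and group_sizes must align")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecord]
    sequence: paradigm.ToneSequence
    data: dict[str, object]  # subject id -> recording or condition-ERP dict
    behavior: dict[str, BehaviorResult]
    montage: Montage
    seed: int

    def subject_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            beh = self.behavior[s.id]
            rows.append(
                {
                    "id": s.id,
                    "study": s.study,
                    "group": s.group,
                    "plasma_task": interpolate_plasma(s),
                    "hit_rate": beh.hit_rate,
                    "mean_rt": beh.mean_rt,
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    components: dict[str, ERPComponentSpec] | None = None,
    effects: dict[str, EffectSpec] | None = None,
    noise: NoiseSpec | None = None,
) -> Cohort:
    """Simulate a full cohort; per-subject seeds derive deterministically
    from the cohort seed, so equal seeds give byte-identical cohorts."""
    config = config or CohortConfig()
    montage = make_montage()
    components = components or default_components(montage)
    effects = effects or group_effects_study1()
    noise = noise or NoiseSpec()

    root = np.random.SeedSequence(seed)
    seq_ss, subj_ss = root.spawn(2)
    seq_seed = int(seq_ss.generate_state(1)[0] % (2**31))
    schedule = paradigm.build_schedule(config.schedule_params, seed=seq_seed)
    seq = paradigm.generate_sequence(schedule, seed=seq_seed)
    distractors = paradigm.schedule_distractors(seq, config.n_targets, seed=seq_seed)

    subjects: list[SubjectRecord] = []
    data: dict[str, object] = {}
    behavior: dict[str, BehaviorResult] = {}
    streams = subj_ss.spawn(sum(config.group_sizes))
    k = 0
    for group, n in zip(config.groups, config.group_sizes):
        for i in range(n):
            ss = streams[k]
            k += 1
            rng = np.random.default_rng(ss)
            sid = f"S{config.study}_{group}_{i:02d}"
            c0, c_sd, decay = _PLASMA_MODEL[group]
            c1 = max(0.0, rng.normal(c0, c_sd))
            subject = SubjectRecord(
                id=sid,
                study=config.study,
                group=group,
                plasma_conc=(c1, c1 * decay),
                draw_times_min=(75.7 + rng.normal(0, 3.2), 189.0 + rng.normal(0, 9.9)),
                task_time_min=120.0,
                mean_rt_ms=max(250.0, rng.normal(510.0, 70.0)),
                hit_prob=float(np.clip(rng.normal(0.948, 0.05), 0.5, 1.0)),
            )
            subjects.append(subject)
            sub_seed = int(ss.generate_state(1)[0] % (2**31))
            if config.mode == "erp":
                data[sid] = simulate_condition_erps(
                    subject, components, effects, noise, seed=sub_seed, montage=montage
                )
            elif config.mode == "continuous":
                data[sid] = simulate_recording(
                    seq, subject, components, effects, noise, seed=sub_seed, montage=montage
                )
            else:
                raise ValueError(f"unknown cohort mode: {config.mode!r}")
            behavior[sid] = simulate_behavior(subject, distractors, seed=sub_seed)
    return Cohort(
        config=config,
        subjects=subjects,
        sequence=seq,
        data=data,
        behavior=behavior,
        montage=montage,
        seed=seed,
    )
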