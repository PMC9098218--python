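"""EEG preprocessing: filtering/referencing, SSP blink projection, epoching.

Two variants are supported: the main pipeline (average reference, 0.1 Hz
high-pass, 250 Hz resampling, 30 Hz low-pass, no baseline) and the control
pipeline (linked-mastoid reference, 1 Hz high-pass, 100 ms pre-stimulus
baseline correction). Filters are 4th-order zero-phase (forward-backward)
Butterworth; the processing order is reference -> high-pass -> anti-aliased
resampling -> low-pass.

Eye blinks are detected on the vertical EOG derivation (Fp1 minus the
infraorbital EOG electrode) by robust thresholding; the leading left
singular vector of the stacked blink-epoch topographies defines the noise
subspace removed by signal-space projection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import RawRecording


@dataclass(frozen=True)
class PipelineVariant:
    reference: str = "average"  # "average" | "linked_mastoid"
    hp_cutoff: float = 0.1  # Hz
    lp_cutoff: float = 30.0  # Hz
    resample: float = 250.0  # Hz
    baseline: str = "none"  # "none" | "pre100"

    def __post_init__(self) -> None:
        if self.hp_cutoff >= self.lp_cutoff:
            raise ValueError("high-pass cutoff must be below low-pass cutoff")

    @classmethod
    def main(cls) -> "PipelineVariant":
        return cls()

    @classmethod
    def control(cls) -> "PipelineVariant":
        return cls(reference="linked_mastoid", hp_cutoff=1.0, baseline="pre100")


@dataclass(frozen=True)
class SSPProjector:
    """Orthogonal projector removing the blink subspace from scalp channels."""

    basis: np.ndarray  # (n_scalp, rank), orthonormal columns
    n_epochs_used: int
    threshold_sd: float = 5.0

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return np.eye(self.basis.shape[0]) - self.basis @ self.basis.T

    def apply(self, scalp_data: np.ndarray) -> np.ndarray:
        """Project (n_scalp, ...) data onto the orthogonal complement."""
        flat = scalp_data.reshape(scalp_data.shape[0], -1)
        out = flat - self.basis @ (self.basis.T @ flat)
        return out.reshape(scalp_data.shape)


@dataclass
class Epochs:
    """Trials x channels x time, in µV, with aligned metadata."""

    data: np.ndarray
    times_ms: np.ndarray  # relative to tone onset
    ch_names: tuple[str, ...]  # scalp channels only
    metadata: pd.DataFrame  # aligned to retained trials
    sfreq: float
    rejected: np.ndarray  # boolean over the original trials
    rejection_by_channel: pd.Series  # fraction of trials rejected per channel

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def average(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_channels, n_times) mean over (a subset of) retained trials."""
        d = self.data if mask is None else self.data[np.asarray(mask)]
        if d.shape[0] == 0:
            raise ValueError("no trials in selection")
        return d.mean(axis=0)


def _sos(cutoff: float, sfreq: float, btype: str) -> np.ndarray:
    return signal.butter(4, cutoff, btype=btype, fs=sfreq, output="sos")


def filter_and_reference(raw: RawRecording, variant: PipelineVariant) -> RawRecording:
    """Re-reference scalp channels, zero-phase filter, and resample.

    The EOG channel is carried through the filters unreferenced so the vEOG
    derivation stays interpretable. After average referencing the scalp
    channel mean is zero at every sample.
    """
    n_scalp = len(raw.ch_names) - 1
    data = raw.data.astype(float).copy()
    scalp = data[:n_scalp]
    if variant.reference == "average":
        scalp -= scalp.mean(axis=0, keepdims=True)
    elif variant.reference == "linked_mastoid":
        for m in ("TP9", "TP10"):
            if m not in raw.ch_names:
                raise ValueError(f"linked-mastoid reference requires channel {m}")
        mast = (raw.channel("TP9") + raw.channel("TP10")) / 2.0
        scalp -= mast[None, :]
    else:
        raise ValueError(f"unknown reference {variant.reference!r}")
    data[:n_scalp] = scalp

    data = signal.sosfiltfilt(_sos(variant.hp_cutoff, raw.sfreq, "highpass"), data, axis=1)
    if variant.resample != raw.sfreq:
        q = raw.sfreq / variant.resample
        if not np.isclose(q, round(q)):
            raise ValueError("resampling rate must divide the sampling rate")
        data = signal.decimate(data, int(round(q)), axis=1, zero_phase=True)
    data = signal.sosfiltfilt(_sos(variant.lp_cutoff, variant.resample, "lowpass"), data, axis=1)
    return replace(raw, data=np.ascontiguousarray(data), sfreq=variant.resample)


def compute_veog(raw: RawRecording) -> np.ndarray:
    """Vertical EOG derivation: Fp1 minus the infraorbital EOG channel."""
    for name in ("Fp1", "EOG"):
        if name not in raw.ch_names:
            raise ValueError(f"channel {name} missing")
    return raw.channel("Fp1") - raw.channel("EOG")


def detect_blinks(
    veog: np.ndarray,
    sfreq: float,
    threshold_sd: float = 5.0,
    refractory_s: float = 0.5,
) -> np.ndarray:
    """Sample indices of blink peaks: |vEOG| above threshold_sd robust SDs
    (1.4826 x MAD), merged within a refractory window."""
    if veog.size == 0:
        raise ValueError("empty vEOG trace")
    x = veog - np.median(veog)
    robust_sd = 1.4826 * np.median(np.abs(x))
    if robust_sd == 0:
        return np.array([], dtype=int)
    above = np.abs(x) > threshold_sd * robust_sd
    if above.mean() > 0.10:
        warnings.warn(
            f"{above.mean():.0%} of samples exceed the blink threshold; "
            f"threshold {threshold_sd} SD looks pathologically low",
            stacklevel=2,
        )
    if not above.any():
        return np.array([], dtype=int)
    idx = np.flatnonzero(above)
    gaps = np.flatnonzero(np.diff(idx) > refractory_s * sfreq)
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps + 1, [idx.size]])
    peaks = np.array(
        [idx[s:e][np.argmax(np.abs(x[idx[s:e]]))] for s, e in zip(starts, ends)]
    )
    return peaks


def compute_ssp(
    raw: RawRecording,
    blink_events: np.ndarray,
    window_s: float = 1.0,
    rank: int = 1,
    transient_factor: float = 5.0,
) -> SSPProjector:
    """SSP projector from the leading SVD component of blink topographies.

    Blink epochs (``window_s`` around each event) whose peak-to-peak range
    exceeds ``transient_factor`` times the median range are excluded as large
    transients. Raises if no usable blink epoch remains, mirroring the
    exclusion of subjects without an identifiable blink component.
    """
    n_scalp = len(raw.ch_names) - 1
    half = int(window_s * raw.sfreq / 2)
    segs = []
    for ev in np.asarray(blink_events, dtype=int):
        if ev - half < 0 or ev + half > raw.n_samples:
            continue
        segs.append(raw.data[:n_scalp, ev - half : ev + half])
    if not segs:
        raise ValueError("no blink epochs available; cannot identify a blink component")
    ptp = np.array([s.max() - s.min() for s in segs])
    keep = ptp <= transient_factor * np.median(ptp)
    segs = [s for s, k in zip(segs, keep) if k]
    if not segs:
        raise ValueError("all blink epochs excluded as large transients")
    mat = np.concatenate(segs, axis=1)
    mat = mat - mat.mean(axis=1, keepdims=True)
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    return SSPProjector(basis=u[:, :rank], n_epochs_used=len(segs))


def epoch_and_reject(
    raw: RawRecording,
    variant: PipelineVariant,
    metadata: pd.DataFrame | None = None,
    projector: SSPProjector | None = None,
    reject_uv: float = 75.0,
    tmin_ms: float = -100.0,
    tmax_ms: float = 400.0,
) -> Epochs:
    """Epoch around tone onsets, apply SSP, baseline-correct (control variant
    only), and drop epochs where any scalp channel exceeds ``reject_uv``.

    ``metadata`` rows (one per tone) are carried through aligned to the
    retained trials. A data-quality warning is issued if any channel's
    rejected fraction exceeds 20%.
    """
    n_scalp = len(raw.ch_names) - 1
    sf = raw.sfreq
    i0 = int(round(tmin_ms / 1000.0 * sf))
    i1 = int(round(tmax_ms / 1000.0 * sf))
    times_ms = np.arange(i0, i1 + 1) * 1000.0 / sf
    onset_samples = np.round(raw.onsets_ms / 1000.0 * sf).astype(int)
    if onset_samples[0] + i0 < 0 or onset_samples[-1] + i1 >= raw.n_samples:
        raise ValueError("tone events fall outside the recording")

    idx = onset_samples[:, None] + np.arange(i0, i1 + 1)[None, :]
    data = raw.data[:n_scalp][:, idx].transpose(1, 0, 2).copy()  # trials x ch x time

    if projector is not None:
        data = np.einsum("ij,tjk->tik", projector.matrix, data)
    if variant.baseline == "pre100":
        pre = times_ms < 0
        data -= data[:, :, pre].mean(axis=2, keepdims=True)
    elif variant.baseline != "none":
        raise ValueError(f"unknown baseline mode {variant.baseline!r}")

    over = np.abs(data) > reject_uv  # trials x ch x time
    bad_trial = over.any(axis=(1, 2))
    by_channel = pd.Series(
        over.any(axis=2).mean(axis=0), index=raw.ch_names[:n_scalp], name="rejected_fraction"
    )
    if (by_channel > 0.20).any():
        worst = by_channel.idxmax()
        warnings.warn(
            f"channel {worst} exceeds the 20% rejection bound "
            f"({by_channel.max():.1%})",
            stacklevel=2,
        )

    if metadata is None:
        metadata = pd.DataFrame({"trial": np.arange(len(onset_samples))})
    meta = metadata.iloc[~bad_trial].reset_index(drop=True)
    return Epochs(
        data=data[~bad_trial],
        times_ms=times_ms,
        ch_names=raw.ch_names[:n_scalp],
        metadata=meta,
        sfreq=sf,
        rejected=bad_trial,
        rejection_by_channel=by_channel,
    )


def preprocess(
    raw: RawRecording,
    variant: PipelineVariant | None = None,
    metadata: pd.DataFrame | None = None,
    threshold_sd: float = 5.0,
) -> tuple[Epochs, SSPProjector]:
    """Full chain: filter/reference, blink SSP, epoch, reject."""
    variant = variant or PipelineVariant.main()
    filtered = filter_and_reference(raw, variant)
    veog = compute_veog(filtered)
    events = detect_blinks(veog, filtered.sfreq, threshold_sd=threshold_sd)
    projector = compute_ssp(filtered, events)
    epochs = epoch_and_reject(filtered, variant, metadata=metadata, projector=projector)
    return epochs, projector
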