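"""Readers and writers: trial sheets, marker tables, BrainVision, NIfTI, HDF5."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ImageGeometry
from .paradigm import ProbabilitySchedule, ToneSequence, trial_sheet
from .simulate import RawRecording


def write_trial_sheet(seq: ToneSequence, path: str | Path) -> None:
    trial_sheet(seq).to_csv(path, sep="\t", index=False)


def write_schedule_json(schedule: ProbabilitySchedule, path: str | Path) -> None:
    desc = {
        "n_trials": int(schedule.n_trials),
        "segment_boundaries": [int(b) for b in schedule.segment_boundaries],
        "segments": [
            {
                "start": int(s),
                "end": int(e),
                "p_tone1": float(schedule.p_tone1[s]),
                "phase": str(schedule.phase_label[s]),
            }
            for s, e in zip(schedule.segment_boundaries[:-1], schedule.segment_boundaries[1:])
        ],
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(schedule.params).items()
        },
    }
    Path(path).write_text(json.dumps(desc, indent=1))


def write_vmrk_table(seq: ToneSequence, path: str | Path, sfreq: float = 500.0) -> None:
    """BrainVision-compatible marker table for the tone events."""
    onsets = np.round(seq.onsets_ms() / 1000.0 * sfreq).astype(int) + 1  # 1-based
    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "DataFile=",
        "[Marker Infos]",
    ]
    for i, (s, tone) in enumerate(zip(onsets, seq.tones), start=1):
        lines.append(f"Mk{i}=Stimulus,S{int(tone)},{int(s)},1,0")
    Path(path).write_text("\n".join(lines) + "\n")


def write_brainvision(raw: RawRecording, basename: str | Path) -> Path:
    """Write a continuous recording as BrainVision .vhdr/.vmrk/.eeg
    (multiplexed IEEE float32, unit µV). Returns the header path."""
    base = Path(basename)
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")
    n_ch = raw.data.shape[0]
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / raw.sfreq:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(raw.ch_names, start=1):
        header.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    onsets = np.round(raw.onsets_ms / 1000.0 * raw.sfreq).astype(int) + 1
    for i, (s, tone) in enumerate(zip(onsets, raw.tones), start=2):
        markers.append(f"Mk{i}=Stimulus,S{int(tone):>2d},{int(s)},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    raw.data.T.astype("<f4").tofile(eeg)
    return vhdr


def write_stat_nifti(volume: np.ndarray, geometry: ImageGeometry, path: str | Path) -> None:
    """Statistical scalp-time volume as NIfTI; the affine encodes the
    mm/mm/ms voxel sizes and grid origin."""
    import nibabel as nib

    dx, dy, dt = geometry.voxel_size
    affine = np.diag([dx, dy, dt, 1.0])
    affine[:3, 3] = [geometry.x_mm[0], geometry.y_mm[0], geometry.t_ms[0]]
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def write_epochs_h5(epochs, path: str | Path) -> None:
    """Epochs as an HDF5 container plus an embedded TSV-style metadata table."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("rejected", data=epochs.rejected)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["ch_names"] = list(epochs.ch_names)
        f.attrs["metadata_tsv"] = epochs.metadata.to_csv(sep="\t", index=False)
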