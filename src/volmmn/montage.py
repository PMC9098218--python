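"""Electrode montage: 63-channel 10-20 scalp layout plus an infraorbital EOG.

3D positions come from MNE's standard 10-05 montage; the 2D scalp map uses an
azimuthal equidistant projection (preserving left/right and
anterior/posterior ordering), scaled to millimetres so that the equatorial
ring sits at an 85 mm head radius.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

# 64-channel EasyCap-style layout (one slot is the infraorbital EOG electrode).
EASYCAP64_SCALP = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FCz", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
]

EOG_NAME = "EOG"
REQUIRED = {"Fz", "FCz", "Cz", "Fp1", "Fp2", "C2", "C4", "TP9", "TP10"}
HEAD_RADIUS_MM = 85.0


@dataclass(frozen=True)
class Montage:
    """Channel names with 3D head positions (m) and 2D scalp positions (mm)."""

    ch_names: tuple[str, ...]  # scalp channels only
    pos3d: np.ndarray  # (n, 3), MNE head frame
    pos2d: np.ndarray  # (n, 2), mm; +x right, +y anterior
    eog_name: str = EOG_NAME

    @property
    def n_scalp(self) -> int:
        return len(self.ch_names)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names])

    @property
    def all_names(self) -> tuple[str, ...]:
        """Scalp channels followed by the EOG channel."""
        return self.ch_names + (self.eog_name,)


def _project_2d(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection of unit-sphere positions to mm."""
    centered = pos3d - pos3d.mean(axis=0) * 0  # positions already head-centered
    r = np.linalg.norm(centered, axis=1)
    unit = centered / r[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1, 1))  # 0 at vertex
    phi = np.arctan2(unit[:, 1], unit[:, 0])  # 0 = right, pi/2 = anterior
    rad = theta * (2 / np.pi) * HEAD_RADIUS_MM
    return np.column_stack([rad * np.cos(phi), rad * np.sin(phi)])


@lru_cache(maxsize=4)
def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    return {k: v.copy() for k, v in std.get_positions()["ch_pos"].items()}


def make_montage(layout: str = "easycap64", drop: tuple[str, ...] = ()) -> Montage:
    """Build the montage for a named layout.

    ``drop`` removes channels (for testing degraded layouts); layouts missing
    any channel required by the pipeline (Fz/FCz/Cz, the frontal and
    right-central sensors, and both mastoids) are rejected.
    """
    if layout != "easycap64":
        raise ValueError(f"unknown montage layout: {layout!r}")
    names = [n for n in EASYCAP64_SCALP if n not in set(drop)]
    missing = REQUIRED - set(names)
    if missing:
        raise ValueError(f"layout is missing required channels: {sorted(missing)}")
    pos = _standard_positions()
    pos3d = np.array([pos[n] for n in names])
    pos2d = _project_2d(pos3d)
    return Montage(ch_names=tuple(names), pos3d=pos3d, pos2d=pos2d)
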