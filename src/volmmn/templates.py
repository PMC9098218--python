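"""ERP component templates and group effect specifications.

Each component is a Gaussian time course times a fixed signed scalp
topography (max |weight| = 1). The default set comprises a generic auditory
response (N1/P2 on every tone), the mismatch component added on deviant
tones (fronto-central negativity ~172 ms with temporo-parietal polarity
reversal), and optional later P3a/P3b-like components.

Group effects act on the mismatch component (amplitude scale, latency shift,
topographic displacement toward right-central sensors) plus additive
per-condition offsets, spanning the phenomenology of a muscarinic-antagonist
group: delayed, topographically shifted mismatch with opposite-sign effects
on standard and deviant responses.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage


def gaussian_bump_2d(montage: Montage, center_mm: tuple[float, float], sigma_mm: float) -> np.ndarray:
    d2 = ((montage.pos2d - np.asarray(center_mm)) ** 2).sum(axis=1)
    return np.exp(-0.5 * d2 / sigma_mm**2)


def _balanced(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Dipolar topography: scale the reversal lobes so the scalp sum is zero
    (EEG fields of cortical dipoles integrate to ~0 over the sensor array),
    then normalize to max |w| = 1."""
    c = pos.sum() / neg.sum()
    w = pos - c * neg
    return w / np.abs(w).max()


def mmn_topography(montage: Montage, shift_mm: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Fronto-central lobe with temporo-parietal and prefrontal polarity
    reversals; zero-sum, max |w| = 1.

    The prefrontal reversal mirrors the empirical mismatch pattern (the
    deviant-positive counterpart of the fronto-central negativity at
    frontal-pole sites). ``shift_mm`` displaces the fronto-central lobe in
    the 2D plane (positive x = rightward, negative y = posterior), modeling
    a topographic shift of the mismatch response toward right central
    channels.
    """
    fcz = montage.pos2d[montage.index("FCz")]
    center = (fcz[0] + shift_mm[0], fcz[1] + shift_mm[1])
    pos = gaussian_bump_2d(montage, center, 45.0)
    left = montage.pos2d[montage.index("TP7")]
    right = montage.pos2d[montage.index("TP8")]
    fpz = 0.5 * (montage.pos2d[montage.index("Fp1")] + montage.pos2d[montage.index("Fp2")])
    pos = pos - 0.6 * gaussian_bump_2d(montage, tuple(fpz), 28.0)
    neg = gaussian_bump_2d(montage, tuple(left), 32.0) + gaussian_bump_2d(
        montage, tuple(right), 32.0
    )
    return _balanced(pos, neg)


def auditory_topography(montage: Montage) -> np.ndarray:
    """Vertex-dominant auditory N1/P2-like topography with mastoid reversal
    and a weak frontal-pole reversal."""
    cz = montage.pos2d[montage.index("Cz")]
    pos = gaussian_bump_2d(montage, tuple(cz), 60.0)
    fpz = 0.5 * (montage.pos2d[montage.index("Fp1")] + montage.pos2d[montage.index("Fp2")])
    pos = pos - 0.35 * gaussian_bump_2d(montage, tuple(fpz), 28.0)
    neg = gaussian_bump_2d(
        montage, tuple(montage.pos2d[montage.index("TP9")]), 30.0
    ) + gaussian_bump_2d(montage, tuple(montage.pos2d[montage.index("TP10")]), 30.0)
    return _balanced(pos, neg)


def parietal_topography(montage: Montage) -> np.ndarray:
    """Parietal-positive topography with a frontal counter-lobe (P3b-like)."""
    pz = montage.pos2d[montage.index("Pz")]
    pos = gaussian_bump_2d(montage, tuple(pz), 55.0)
    afz = 0.5 * (
        montage.pos2d[montage.index("AF3")] + montage.pos2d[montage.index("AF4")]
    )
    neg = gaussian_bump_2d(montage, tuple(afz), 45.0)
    return _balanced(pos, neg)


@dataclass(frozen=True)
class ERPComponentSpec:
    """Gaussian-in-time ERP component with a fixed signed topography."""

    name: str
    peak_ms: float
    width_ms: float  # Gaussian sigma
    amplitude_uv: float
    topography: np.ndarray  # (n_scalp,), max |w| = 1

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if not np.isclose(np.abs(self.topography).max(), 1.0):
            raise ValueError("topography must be normalized to max |w| = 1")

    def waveform(self, times_ms: np.ndarray, latency_shift: float = 0.0) -> np.ndarray:
        t0 = self.peak_ms + latency_shift
        return self.amplitude_uv * np.exp(-0.5 * ((times_ms - t0) / self.width_ms) ** 2)

    def evaluate(self, times_ms: np.ndarray, latency_shift: float = 0.0) -> np.ndarray:
        """(n_scalp, n_times) signal in µV."""
        return np.outer(self.topography, self.waveform(times_ms, latency_shift))


def default_components(montage: Montage, include_late: bool = True) -> dict[str, ERPComponentSpec]:
    """Standard component battery used by the cohort simulator."""
    aud = auditory_topography(montage)
    mmn = mmn_topography(montage)
    comps = {
        "n1": ERPComponentSpec("n1", 100.0, 22.0, -1.2, aud),
        "p2": ERPComponentSpec("p2", 210.0, 30.0, 1.0, aud),
        "mmn": ERPComponentSpec("mmn", 172.0, 28.0, -2.0, mmn),
    }
    if include_late:
        comps["p3a"] = ERPComponentSpec("p3a", 300.0, 35.0, 0.8, mmn)
        comps["p3b"] = ERPComponentSpec("p3b", 385.0, 30.0, 0.6, parietal_topography(montage))
    return comps


@dataclass(frozen=True)
class EffectSpec:
    """Per-group modulation of the mismatch response.

    mmn_amplitude_scale multiplies the mismatch amplitude; mmn_latency_shift
    delays it; topography_shift_mm displaces its fronto-central lobe;
    stability_gain multiplies the mismatch on stable-phase trials (all
    groups share the paradigm-level default of 1.3 unless overridden);
    standard_offset_uv / deviant_offset_uv add a Gaussian component at the
    (shifted) mismatch latency and topography to standard / deviant
    responses, reproducing per-condition drug effects.
    """

    mmn_amplitude_scale: float = 1.0
    mmn_latency_shift: float = 0.0  # ms
    topography_shift_mm: tuple[float, float] = (0.0, 0.0)
    stability_gain: float = 1.3
    standard_offset_uv: float = 0.0
    deviant_offset_uv: float = 0.0

    def __post_init__(self) -> None:
        if self.mmn_amplitude_scale < 0 or self.stability_gain < 0:
            raise ValueError("scales must be non-negative")


NULL_EFFECT = EffectSpec(stability_gain=1.0)
PLACEBO_EFFECT = EffectSpec()

# Biperiden-like effect: +13 ms delay and a rightward/central displacement of
# the mismatch topography, standards more positive and deviants more negative
# at the peak. Offset amplitudes are calibrated against the default noise
# level (between-subject SD ~1 µV per condition-cell image at the mismatch
# peak voxel) so that, at the empirically selected interaction peak of a
# full-size cohort, the mismatch x drug peak t is ~4.5 and the
# per-condition effect sizes average Cohen's d ~0.9 (the deviant side
# carries the latency/topography shift in addition to its offset, so its d
# runs above the standard side's).
BIPERIDEN_LIKE = EffectSpec(
    mmn_latency_shift=13.0,
    topography_shift_mm=(25.0, -20.0),
    standard_offset_uv=0.40,
    deviant_offset_uv=-0.44,
)


def group_effects_study1(biperiden: EffectSpec = BIPERIDEN_LIKE) -> dict[str, EffectSpec]:
    return {"PLA": PLACEBO_EFFECT, "AMI": PLACEBO_EFFECT, "BIP": biperiden}


def group_effects_null() -> dict[str, EffectSpec]:
    return {g: PLACEBO_EFFECT for g in ("PLA", "AMI", "BIP")}


def evoked_template(
    components: dict[str, ERPComponentSpec],
    times_ms: np.ndarray,
    role: str,
    stability: str,
    effect: EffectSpec,
    montage: Montage | None = None,
) -> np.ndarray:
    """Noiseless evoked response (n_scalp, n_times) for one condition cell.

    Every tone evokes the generic auditory components; deviants additionally
    evoke the mismatch component (and any later components), scaled by
    stability_gain in stable phases and modified by the group effect.
    Per-condition offsets are added at the group's shifted mismatch
    topography and latency.
    """
    base = np.zeros((components["n1"].topography.size, times_ms.size))
    for name in ("n1", "p2"):
        if name in components:
            base += components[name].evaluate(times_ms)

    mmn = components["mmn"]
    gain = effect.mmn_amplitude_scale * (
        effect.stability_gain if stability == "stable" else 1.0
    )
    topo = mmn.topography
    if effect.topography_shift_mm != (0.0, 0.0):
        if montage is None:
            raise ValueError("montage required for a topography shift")
        topo = mmn_topography(montage, effect.topography_shift_mm)
    wave = mmn.waveform(times_ms, effect.mmn_latency_shift)

    if role == "deviant":
        base = base + gain * np.outer(topo, wave)
        for name in ("p3a", "p3b"):
            if name in components:
                base += components[name].evaluate(times_ms, effect.mmn_latency_shift)
        if effect.deviant_offset_uv:
            base += effect.deviant_offset_uv * np.outer(
                topo, np.exp(-0.5 * ((times_ms - mmn.peak_ms - effect.mmn_latency_shift) / mmn.width_ms) ** 2)
            )
    elif effect.standard_offset_uv:
        base += effect.standard_offset_uv * np.outer(
            topo, np.exp(-0.5 * ((times_ms - mmn.peak_ms - effect.mmn_latency_shift) / mmn.width_ms) ** 2)
        )
    return base
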