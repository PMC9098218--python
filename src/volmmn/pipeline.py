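"""Study orchestration: simulate -> label -> first level -> group stats -> report.

``run_study`` drives the full analysis for one simulated study: cohort
simulation, first-level effect images per subject, the eight-contrast
group-level battery per effect with GRF (or permutation) correction,
functional-mask small-volume correction for drug contrasts, cluster tables,
ROI peak analysis, and behavioral tests. Outputs are deterministic given
the configuration and seed; every written file records the configuration
hash.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters, glm, labeling, rft, roi
from .images import ImageGeometry, ScalpMapper, smooth_images
from .simulate import Cohort, CohortConfig, NoiseSpec, simulate_cohort
from .templates import BIPERIDEN_LIKE, EffectSpec, PLACEBO_EFFECT, group_effects_study1


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of one simulated study run."""

    study: int = 1
    groups: tuple[str, ...] = ("PLA", "AMI", "BIP")
    group_sizes: tuple[int, ...] = (25, 24, 22)
    trial_definition: str = "INIT"  # INIT | 2REP (labels in the erp path are by cell)
    correction: str = "grf"  # grf | perm
    geometry: str = "reduced"  # reduced | default
    alpha: float = 0.05
    seed: int = 0
    effects: str = "study1"  # study1 | null
    n_targets: int = 36
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("groups", "group_sizes"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ReportBundle:
    config: StudyConfig
    cluster_tables: dict[str, pd.DataFrame]  # effect/contrast -> table
    roi_tables: dict[str, object]
    behavior: dict
    subject_frame: pd.DataFrame
    corrected: dict[str, rft.CorrectedMap]
    geometry: ImageGeometry
    log: list[dict]

    def significant_drug_contrasts(self, effect: str = "mismatch") -> list[str]:
        out = []
        for key, table in self.cluster_tables.items():
            if key.startswith(f"{effect}/") and "avg" not in key and len(table):
                out.append(key)
        return out


def _log(log: list[dict], stage: str, t0: float, **kw) -> None:
    log.append({"stage": stage, "wall_s": round(time.perf_counter() - t0, 3), **kw})


def first_level_images(
    cohort: Cohort, mapper: ScalpMapper, times_ms: np.ndarray | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject smoothed first-level effect images from condition ERPs."""
    times_ms = times_ms if times_ms is not None else np.arange(-100.0, 400.1, 4.0)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sid, cells in cohort.data.items():
        if not isinstance(cells, dict):
            raise TypeError("first_level_images expects an 'erp'-mode cohort")
        imgs = {
            cond: smooth_images(mapper.to_images(erp, times_ms), mapper)
            for cond, erp in cells.items()
        }
        out[sid] = glm.first_level_contrasts(imgs)
    return out


def run_study(config: StudyConfig | None = None) -> ReportBundle:
    config = config or StudyConfig()
    log: list[dict] = []
    t0 = time.perf_counter()

    effects = group_effects_study1() if config.effects == "study1" else {
        g: PLACEBO_EFFECT for g in config.groups
    }
    cohort = simulate_cohort(
        CohortConfig(
            study=config.study,
            groups=config.groups,
            group_sizes=config.group_sizes,
            n_targets=config.n_targets,
            mode="erp",
        ),
        seed=config.seed,
        effects=effects,
    )
    _log(log, "simulate", t0, n_subjects=len(cohort.subjects), seed=config.seed)

    geometry = (
        ImageGeometry.reduced(cohort.montage)
        if config.geometry == "reduced"
        else ImageGeometry.default(cohort.montage)
    )
    mapper = ScalpMapper(cohort.montage, geometry)
    firsts = first_level_images(cohort, mapper)
    _log(log, "first_level", t0)

    frame = cohort.subject_frame()
    design = glm.GroupDesign.from_frame(frame)
    battery = design.battery()

    cluster_tables: dict[str, pd.DataFrame] = {}
    corrected: dict[str, rft.CorrectedMap] = {}
    for effect in glm.EFFECTS:
        stack = np.stack([firsts[s.id][effect] for s in cohort.subjects])
        mask3 = mapper.mask3d
        # average effects define the functional mask for the drug contrasts
        avg_maps = []
        for name in ("avg_pos", "avg_neg"):
            sm = glm.group_glm(stack, design, battery[name], mask=mask3, contrast_name=name)
            smooth = rft.estimate_smoothness(sm.residuals, mask3)
            cm = rft.fwe_peak_correct(sm, smooth, alpha=config.alpha)
            corrected[f"{effect}/{name}"] = cm
            cluster_tables[f"{effect}/{name}"] = clusters.extract_clusters(cm, geometry)
            avg_maps.append(cm)
        fmask = rft.build_functional_mask(*avg_maps)
        for name, cvec in battery.items():
            if name.startswith("avg"):
                continue
            sm = glm.group_glm(stack, design, cvec, mask=mask3, contrast_name=name)
            smooth = rft.estimate_smoothness(sm.residuals, mask3)
            cm = rft.fwe_peak_correct(sm, smooth, alpha=config.alpha)
            corrected[f"{effect}/{name}"] = cm
            cluster_tables[f"{effect}/{name}"] = clusters.extract_clusters(cm, geometry)
            # small-volume correction within the functional mask, reported
            # alongside the whole-volume route when the latter is empty
            if not cm.significant.any() and fmask.any():
                cm_svc = rft.fwe_peak_correct(sm, smooth, alpha=config.alpha, mask=fmask)
                if cm_svc.significant.any():
                    corrected[f"{effect}/{name}@svc"] = cm_svc
                    cluster_tables[f"{effect}/{name}@svc"] = clusters.extract_clusters(
                        cm_svc, geometry
                    )
    _log(log, "group_glm", t0, n_contrasts=len(corrected))

    # ROI peak analysis on the condition-average difference waves
    times = np.arange(-100.0, 400.1, 4.0)
    rows = []
    for s in cohort.subjects:
        cells = cohort.data[s.id]
        diff = (
            (cells[("deviant", "stable")] + cells[("deviant", "volatile")]) / 2
            - (cells[("standard", "stable")] + cells[("standard", "volatile")]) / 2
        )
        pk = roi.peak_mmn(diff, times, cohort.montage.ch_names)
        pk["subject"] = s.id
        pk["group"] = s.group
        rows.append(pk)
    peaktable = pd.concat(rows, ignore_index=True)
    roi_tables = {
        "peaks": peaktable,
        "anova_amplitude": roi.anova_drug_by_sensor(peaktable, "amplitude_uv"),
        "anova_latency": roi.anova_drug_by_sensor(peaktable, "latency_ms"),
    }
    _log(log, "roi", t0)

    behavior = roi.behavior_stats(frame)
    _log(log, "behavior", t0)

    bundle = ReportBundle(
        config=config,
        cluster_tables=cluster_tables,
        roi_tables=roi_tables,
        behavior=behavior,
        subject_frame=frame,
        corrected=corrected,
        geometry=geometry,
        log=log,
    )
    if config.out_dir:
        _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: ReportBundle) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = bundle.config.config_hash()
    bundle.config.to_yaml(out / f"config_{h}.yaml")
    for key, table in bundle.cluster_tables.items():
        if len(table):
            name = key.replace("/", "_")
            table.to_csv(out / f"clusters_{name}_{h}.tsv", sep="\t", index=False)
    bundle.roi_tables["peaks"].to_csv(out / f"roi_peaks_{h}.tsv", sep="\t", index=False)
    bundle.subject_frame.to_csv(out / f"subjects_{h}.tsv", sep="\t", index=False)
    with open(out / f"log_{h}.jsonl", "w") as f:
        for entry in bundle.log:
            f.write(json.dumps(entry) + "\n")
    with open(out / f"behavior_{h}.json", "w") as f:
        json.dump(bundle.behavior, f, indent=1, default=float)
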