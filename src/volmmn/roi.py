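"""ROI peak analysis at Fz/FCz/Cz and behavioral group statistics.

The MMN peak is the minimum of the deviant-minus-standard difference wave
in the 150-250 ms window (the sign convention that yields the published
negative peak amplitudes); peak amplitude and latency per subject and
sensor enter separate 3 x 3 (drug group x sensor) ANOVAs with post-hoc
pairwise t-tests on significant group effects. Behavioral group tests are
a one-way ANOVA on mean reaction times and a Kruskal-Wallis test on hit
rates, with low performers (hit rate < 75%) flagged.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

ROI_CHANNELS = ("Fz", "FCz", "Cz")
PEAK_WINDOW_MS = (150.0, 250.0)


def difference_wave(
    epochs, definition_table=None, roles: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-subject condition ERPs and the deviant-minus-standard difference.

    ``epochs`` is a :class:`volmmn.preprocessing.Epochs`; roles come either
    from its metadata (column "role") or from an explicit array aligned to
    retained trials.
    """
    if roles is None:
        roles = epochs.metadata["role"].to_numpy()
    std_mask = roles == "standard"
    dev_mask = roles == "deviant"
    if not std_mask.any() or not dev_mask.any():
        raise ValueError("need at least one standard and one deviant trial")
    std = epochs.average(std_mask)
    dev = epochs.average(dev_mask)
    return {"standard": std, "deviant": dev, "difference": dev - std}


def peak_mmn(
    diff: np.ndarray,
    times_ms: np.ndarray,
    ch_names,
    channels=ROI_CHANNELS,
    window_ms: tuple[float, float] = PEAK_WINDOW_MS,
) -> pd.DataFrame:
    """Minimum of the difference wave per ROI channel within the window.

    Ties break to the earliest sample; minima on the window boundary are
    flagged (the peak-based estimator is noise-susceptible there).
    """
    names = list(ch_names)
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("peak window outside the epoch")
    twin = times_ms[sel]
    rows = []
    for ch in channels:
        if ch not in names:
            raise ValueError(f"ROI channel {ch} missing")
        wave = diff[names.index(ch)][sel]
        i = int(np.argmin(wave))
        rows.append(
            {
                "channel": ch,
                "amplitude_uv": float(wave[i]),
                "latency_ms": float(twin[i]),
                "boundary": i in (0, wave.size - 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    measure: str
    F_group: float
    df_group: tuple[float, float]
    p_group: float
    F_sensor: float
    p_sensor: float
    F_interaction: float
    p_interaction: float
    posthoc: pd.DataFrame | None  # pairwise group t-tests (if group p < .05)


def anova_drug_by_sensor(peaktable: pd.DataFrame, measure: str) -> AnovaResult:
    """3 x 3 two-way ANOVA (drug group x sensor) on one peak measure.

    ``peaktable`` has one row per subject x channel with columns "group",
    "channel", and the measure ("amplitude_uv" or "latency_ms"). Post-hoc
    pairwise group t-tests are run when the group main effect is significant.
    """
    data = peaktable.rename(columns={measure: "y"})
    model = smf.ols("y ~ C(group) + C(channel) + C(group):C(channel)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    fg = table.loc["C(group)"]
    fs = table.loc["C(channel)"]
    fi = table.loc["C(group):C(channel)"]
    res_df = table.loc["Residual", "df"]
    posthoc = None
    if fg["PR(>F)"] < 0.05:
        rows = []
        for a, b in itertools.combinations(pd.unique(data["group"]), 2):
            ya = data.loc[data["group"] == a, "y"]
            yb = data.loc[data["group"] == b, "y"]
            t, p = stats.ttest_ind(ya, yb)
            rows.append({"a": a, "b": b, "t": t, "p": p, "mean_a": ya.mean(), "mean_b": yb.mean()})
        posthoc = pd.DataFrame(rows)
    return AnovaResult(
        measure=measure,
        F_group=float(fg["F"]),
        df_group=(float(fg["df"]), float(res_df)),
        p_group=float(fg["PR(>F)"]),
        F_sensor=float(fs["F"]),
        p_sensor=float(fs["PR(>F)"]),
        F_interaction=float(fi["F"]),
        p_interaction=float(fi["PR(>F)"]),
        posthoc=posthoc,
    )


def behavior_stats(subject_frame: pd.DataFrame) -> dict:
    """Group tests on the distraction-task behavior.

    One-way ANOVA on mean RTs, Kruskal-Wallis on hit rates; pairwise
    post-hoc comparisons when an omnibus test is significant; subjects with
    hit rate < 75% flagged as low performers.
    """
    df = subject_frame.dropna(subset=["hit_rate", "mean_rt"])
    groups = pd.unique(df["group"])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rts = [df.loc[df["group"] == g, "mean_rt"] for g in groups]
    hits = [df.loc[df["group"] == g, "hit_rate"] for g in groups]
    F, p_rt = stats.f_oneway(*rts)
    H, p_hit = stats.kruskal(*hits)
    out = {
        "rt_anova": {"F": float(F), "p": float(p_rt)},
        "hit_kruskal": {"chi2": float(H), "p": float(p_hit)},
        "low_performers": df.loc[df["hit_rate"] < 0.75, "id"].tolist()
        if "id" in df
        else [],
    }
    if p_rt < 0.05:
        out["rt_posthoc"] = _pairwise(df, groups, "mean_rt", parametric=True)
    if p_hit < 0.05:
        out["hit_posthoc"] = _pairwise(df, groups, "hit_rate", parametric=False)
    return out


def _pairwise(df: pd.DataFrame, groups, col: str, parametric: bool) -> list[dict]:
    rows = []
    for a, b in itertools.combinations(groups, 2):
        xa = df.loc[df["group"] == a, col]
        xb = df.loc[df["group"] == b, col]
        if parametric:
            stat, p = stats.ttest_ind(xa, xb)
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"a": a, "b": b, "stat": float(stat), "p": float(p)})
    return rows
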