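"""First-level contrasts and the group-level GLM on scalp-time images.

First level: the trial-wise design contains only condition indicators
(mismatch x stability), so the GLM reduces to cell means; the five effects
of interest are linear combinations of the four cell means:

* mismatch          = standards - deviants (main effect)
* stability         = stable - volatile (main effect)
* interaction       = stable mismatch - volatile mismatch
* stable mismatch   = stable standards - stable deviants
* volatile mismatch = volatile standards - volatile deviants

Group level: a between-subject factor (three drug groups) plus a plasma
covariate mean-centered within groups, one column per active-drug group.
The error model assumes independence across subjects and non-identity
across groups: per-group variances are estimated voxel-wise and the
contrast is tested by feasible weighted least squares with
Welch-Satterthwaite degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EFFECTS = ("mismatch", "stability", "interaction", "stable_mismatch", "volatile_mismatch")

_CELLS = (
    ("standard", "stable"),
    ("standard", "volatile"),
    ("deviant", "stable"),
    ("deviant", "volatile"),
)
# weights over (std_st, std_vol, dev_st, dev_vol)
_CONTRASTS = {
    "mismatch": np.array([0.5, 0.5, -0.5, -0.5]),
    "stability": np.array([0.5, -0.5, 0.5, -0.5]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
    "stable_mismatch": np.array([1.0, 0.0, -1.0, 0.0]),
    "volatile_mismatch": np.array([0.0, 1.0, 0.0, -1.0]),
}


class EmptyCellError(ValueError):
    """A condition cell has no trials; the contrast is undefined."""


def cell_means_from_trials(
    stack: np.ndarray, roles: np.ndarray, stability: np.ndarray
) -> dict[tuple[str, str], np.ndarray]:
    """Mean image per (role, stability) cell from a per-trial image stack."""
    out = {}
    roles = np.asarray(roles)
    stability = np.asarray(stability)
    for role, stab in _CELLS:
        sel = (roles == role) & (stability == stab)
        if not sel.any():
            raise EmptyCellError(f"no trials in cell ({role}, {stab})")
        out[(role, stab)] = stack[sel].mean(axis=0)
    return out


def first_level_contrasts(
    cells: dict[tuple[str, str], np.ndarray]
) -> dict[str, np.ndarray]:
    """The five effect images as linear combinations of the cell means."""
    missing = [c for c in _CELLS if c not in cells]
    if missing:
        raise EmptyCellError(f"missing cells: {missing}")
    stacked = np.stack([cells[c] for c in _CELLS])
    return {name: np.tensordot(w, stacked, axes=1) for name, w in _CONTRASTS.items()}


@dataclass(frozen=True)
class GroupDesign:
    """Group-level design: group indicators plus within-group mean-centered
    plasma covariate columns for active-drug groups."""

    X: np.ndarray  # (n_subjects, n_columns)
    columns: tuple[str, ...]
    groups: np.ndarray  # group label per subject
    group_names: tuple[str, ...]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        covariate: str | None = "plasma_task",
        placebo: str = "PLA",
    ) -> "GroupDesign":
        groups = frame["group"].to_numpy()
        names = tuple(pd.unique(groups))
        cols, labels = [], []
        for g in names:
            cols.append((groups == g).astype(float))
            labels.append(f"group:{g}")
        if covariate is not None and covariate in frame:
            for g in names:
                if g == placebo:
                    continue
                col = np.zeros(len(frame))
                sel = groups == g
                vals = frame.loc[sel, covariate].to_numpy(dtype=float)
                col[sel] = vals - vals.mean()
                cols.append(col)
                labels.append(f"plasma:{g}")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return cls(X=X, columns=tuple(labels), groups=groups, group_names=names)

    def contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Contrast over group-mean columns, e.g. {"AMI": 1, "BIP": -1}."""
        c = np.zeros(self.X.shape[1])
        for g, w in weights.items():
            c[self.columns.index(f"group:{g}")] = w
        return c

    def battery(self) -> dict[str, np.ndarray]:
        """The eight t-contrasts tested per first-level effect: positive and
        negative average effect across groups, and the pairwise drug
        differences in both directions."""
        g = self.group_names
        n = len(g)
        avg = {name: 1.0 / n for name in g}
        out = {
            "avg_pos": self.contrast(avg),
            "avg_neg": -self.contrast(avg),
        }
        assert n == 3
        pairs = [(g[1], g[0]), (g[2], g[0]), (g[1], g[2])]
        for a, b in pairs:
            out[f"{a}>{b}"] = self.contrast({a: 1.0, b: -1.0})
            out[f"{b}>{a}"] = self.contrast({b: 1.0, a: -1.0})
        return out


@dataclass
class StatMap:
    """Voxel-wise t statistics with Satterthwaite df and metadata."""

    t: np.ndarray
    df: np.ndarray  # voxel-wise effective df
    contrast_name: str
    mask: np.ndarray  # boolean, same shape as t
    residuals: np.ndarray | None = None  # (n_subjects, ...) whitened residuals

    @property
    def df_scalar(self) -> float:
        return float(np.median(self.df[self.mask]))


def group_glm(
    images: np.ndarray,
    design: GroupDesign,
    contrast: np.ndarray,
    mask: np.ndarray | None = None,
    contrast_name: str = "",
    keep_residuals: bool = True,
    variance_model: str = "pooled",
) -> StatMap:
    """Voxel-wise feasible WLS with per-group variances.

    ``variance_model`` selects how the group variance structure is
    estimated:

    * ``"pooled"`` (default): per-group variance *factors* are pooled
      across voxels (moment-based analogue of SPM's global non-sphericity
      estimate), the model is whitened once, and the residual variance per
      voxel uses n - p degrees of freedom. This keeps the t field's df
      homogeneous, which the random-field correction relies on.
    * ``"welch"``: fully voxel-wise per-group variances with
      Welch-Satterthwaite degrees of freedom. With two groups, no
      covariate, and a group-difference contrast this reduces exactly to
      Welch's t test (the closed-form oracle used in the tests).
    """
    X = design.X
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    shape = images.shape[1:]
    Y = images.reshape(n, -1)
    v = Y.shape[1]
    if mask is not None:
        mvec = mask.reshape(-1)
        Y = Y[:, mvec]
    else:
        mvec = np.ones(v, bool)

    group_ids = np.array([list(design.group_names).index(g) for g in design.groups])
    n_groups = len(design.group_names)
    # per-group residual dof: subjects minus columns supported in that group
    cols_per_group = np.zeros(n_groups)
    for j in range(p):
        support = np.abs(X[:, j]) > 0
        for gi in range(n_groups):
            if support[group_ids == gi].any():
                cols_per_group[gi] += 1
    n_per_group = np.bincount(group_ids, minlength=n_groups)
    dof_g = n_per_group - cols_per_group
    if (dof_g <= 0).any():
        raise ValueError("not enough subjects per group for variance estimation")

    # pass 1: OLS
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    # per-group variances (voxel-wise)
    sigma2 = np.empty((n_groups, Y.shape[1]))
    for gi in range(n_groups):
        sel = group_ids == gi
        sigma2[gi] = (resid[sel] ** 2).sum(axis=0) / dof_g[gi]
    sigma2 = np.maximum(sigma2, 1e-30)

    if variance_model == "pooled":
        # group variance factors pooled over voxels; whiten once, df = n - p
        pooled_vox = (dof_g[:, None] * sigma2).sum(axis=0) / dof_g.sum()
        lam = (sigma2 / pooled_vox).mean(axis=1)
        lam = lam / (lam[group_ids].mean())
        sw = 1.0 / np.sqrt(lam[group_ids])
        Xw = X * sw[:, None]
        Yw = Y * sw[:, None]
        beta_w, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid_w = Yw - Xw @ beta_w
        df_val = float(n - p)
        sigma2_vox = np.maximum((resid_w**2).sum(axis=0) / df_val, 1e-30)
        gram_inv = np.linalg.inv(Xw.T @ Xw)
        var_c = sigma2_vox * float(contrast @ gram_inv @ contrast)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = (contrast @ beta_w) / np.sqrt(var_c)
        tval = np.nan_to_num(tval)

        t_full = np.zeros(v)
        t_full[mvec] = tval
        df_full = np.full(v, df_val)
        residuals = None
        if keep_residuals:
            full = np.zeros((n, v))
            full[:, mvec] = resid_w
            residuals = full.reshape((n,) + shape)
        return StatMap(
            t=t_full.reshape(shape),
            df=df_full.reshape(shape),
            contrast_name=contrast_name,
            mask=mvec.reshape(shape),
            residuals=residuals,
        )
    if variance_model != "welch":
        raise ValueError(f"unknown variance model {variance_model!r}")

    # pass 2: WLS, batched over voxels
    W = 1.0 / sigma2[group_ids]  # (n, v)
    XtWX = np.einsum("nv,np,nq->vpq", W, X, X)
    XtWY = np.einsum("nv,np,nv->vp", W, X, Y)
    beta_w = np.linalg.solve(XtWX, XtWY[..., None])[..., 0]  # (v, p)
    XtWX_inv = np.linalg.inv(XtWX)
    # g_i = row weights of the contrast estimate: c' (X'WX)^-1 X'W
    G = np.einsum("p,vpq,nq,nv->vn", contrast, XtWX_inv, X, W)  # (v, n)
    est = (G * Y.T).sum(axis=1)
    s_g = np.empty((n_groups, Y.shape[1]))
    for gi in range(n_groups):
        s_g[gi] = (G[:, group_ids == gi] ** 2).sum(axis=1)
    var_terms = s_g * sigma2  # (n_groups, v)
    var_c = var_terms.sum(axis=0)
    denom = (var_terms**2 / dof_g[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(denom > 0, var_c**2 / denom, np.sum(dof_g))
        tval = est / np.sqrt(var_c)
    tval = np.nan_to_num(tval)

    t_full = np.zeros(v)
    df_full = np.full(v, np.sum(dof_g))
    t_full[mvec] = tval
    df_full[mvec] = df
    mask_full = mvec.reshape(shape)

    residuals = None
    if keep_residuals:
        resid_w = Y - X @ beta_w.T
        # whiten by per-subject SD so residual fields are unit-scale
        resid_w = resid_w / np.sqrt(sigma2[group_ids])
        full = np.zeros((n, v))
        full[:, mvec] = resid_w
        residuals = full.reshape((n,) + shape)

    return StatMap(
        t=t_full.reshape(shape),
        df=df_full.reshape(shape),
        contrast_name=contrast_name,
        mask=mask_full,
        residuals=residuals,
    )
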