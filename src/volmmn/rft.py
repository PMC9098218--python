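"""Random-field family-wise error control for scalp-time t maps.

Smoothness (FWHM per axis, in voxels) is estimated from the spatial
derivatives of the variance-normalized residual images; resolution elements
(resels) are counted over the (masked) search volume by the standard
point/edge/face/cube decomposition. Peak-level corrected p-values use the
expected Euler characteristic of a t field:

    p_FWE(t) = 1 - exp(-sum_d R_d * rho_d(t))

with the Worsley t-field EC densities rho_d. A permutation max-T procedure
over group labels provides a nonparametric alternative with the same
interface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .glm import GroupDesign, StatMap, group_glm

_LN2_4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class Smoothness:
    fwhm_vox: tuple[float, float, float]  # per axis, in voxels
    resels: tuple[float, float, float, float]  # R_0 .. R_3


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray) -> Smoothness:
    """FWHM per axis from normalized residual derivatives, plus resel counts.

    ``residuals`` is (n_images, nx, ny, nt); images are normalized voxel-wise
    to unit sum of squares before differentiation, as in the standard
    residual-smoothness estimator.
    """
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual images")
    r = residuals.astype(float)
    ss = np.sqrt((r**2).sum(axis=0))
    if not np.all(ss[mask] > 0):
        raise ValueError("degenerate (constant) residuals inside the mask")
    u = np.where(mask[None], r / np.where(ss[None] == 0, 1.0, ss[None]), np.nan)

    n_img = residuals.shape[0]
    fwhm = []
    for axis in range(3):
        a = 1 + axis
        d = np.diff(u, axis=a)
        # normalization gives per-voxel sum of squares 1 across images, i.e.
        # per-image variance 1/n; rescale so lam refers to a unit-variance field
        lam = np.nanmean(d**2) * n_img
        fwhm.append(float(np.sqrt(_LN2_4 / lam)) if lam > 0 else np.inf)
    resels = resel_counts(mask, tuple(fwhm))
    return Smoothness(fwhm_vox=tuple(fwhm), resels=resels)


def resel_counts(mask: np.ndarray, fwhm_vox: tuple[float, float, float]) -> tuple[float, float, float, float]:
    """Resel counts R_0..R_3 of a 3D mask by point/edge/face/cube counting."""
    m = mask.astype(bool)
    P = int(m.sum())
    ex = np.logical_and(m[:-1], m[1:]).sum()
    ey = np.logical_and(m[:, :-1], m[:, 1:]).sum()
    ez = np.logical_and(m[:, :, :-1], m[:, :, 1:]).sum()
    fxy = np.logical_and.reduce([m[:-1, :-1], m[1:, :-1], m[:-1, 1:], m[1:, 1:]]).sum()
    fxz = np.logical_and.reduce(
        [m[:-1, :, :-1], m[1:, :, :-1], m[:-1, :, 1:], m[1:, :, 1:]]
    ).sum()
    fyz = np.logical_and.reduce(
        [m[:, :-1, :-1], m[:, 1:, :-1], m[:, :-1, 1:], m[:, 1:, 1:]]
    ).sum()
    C = np.logical_and.reduce(
        [
            m[:-1, :-1, :-1], m[1:, :-1, :-1], m[:-1, 1:, :-1], m[:-1, :-1, 1:],
            m[1:, 1:, :-1], m[1:, :-1, 1:], m[:-1, 1:, 1:], m[1:, 1:, 1:],
        ]
    ).sum()
    rx, ry, rz = (1.0 / f if np.isfinite(f) and f > 0 else 0.0 for f in fwhm_vox)
    r0 = float(P - (ex + ey + ez) + (fxy + fxz + fyz) - C)
    r1 = float((ex - fxy - fxz + C) * rx + (ey - fxy - fyz + C) * ry + (ez - fxz - fyz + C) * rz)
    r2 = float((fxy - C) * rx * ry + (fxz - C) * rx * rz + (fyz - C) * ry * rz)
    r3 = float(C * rx * ry * rz)
    return (r0, r1, r2, r3)


def ec_densities(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Worsley EC densities rho_0..rho_3 for a t field; shape (4, ...)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(df, dtype=float)
    base = (1.0 + t**2 / v) ** (-(v - 1) / 2.0)
    c = np.exp(special.gammaln((v + 1) / 2) - special.gammaln(v / 2)) / np.sqrt(v / 2)
    rho0 = stats.t.sf(t, v)
    rho1 = np.sqrt(_LN2_4) / (2 * np.pi) * base
    rho2 = _LN2_4 / (2 * np.pi) ** 1.5 * c * t * base
    rho3 = _LN2_4**1.5 / (2 * np.pi) ** 2 * ((v - 1) / v * t**2 - 1) * base
    return np.stack(np.broadcast_arrays(rho0, rho1, rho2, rho3))


def peak_p_fwe(t: np.ndarray, df: np.ndarray, resels: tuple[float, float, float, float]) -> np.ndarray:
    """Peak-level FWE-corrected p for a t value searched over ``resels``."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(df, dtype=float)
    tc = np.maximum(t, 0.0)
    # The high-threshold EC expansion is non-monotone (and rho_3 negative)
    # below the densities' modes; clamp each density at its mode so the
    # corrected p is monotone in t. Above the modes (the regime where
    # thresholds actually live) the formula is unchanged.
    t2 = np.maximum(tc, np.sqrt(v / np.maximum(v - 2, 1e-6)))
    t3 = np.maximum(tc, np.sqrt(3 * v / np.maximum(v - 3, 1e-6)))
    rho0 = ec_densities(tc, v)[0]
    rho1 = ec_densities(tc, v)[1]
    rho2 = ec_densities(t2, v)[2]
    rho3 = np.maximum(ec_densities(t3, v)[3], 0.0)
    expected = resels[0] * rho0 + resels[1] * rho1 + resels[2] * rho2 + resels[3] * rho3
    p = 1.0 - np.exp(-expected)
    # never below the voxel-wise (uncorrected) tail probability
    p = np.maximum(p, rho0)
    return np.where(t <= 0, 1.0, np.clip(p, 0.0, 1.0))


def critical_t(alpha: float, df: float, resels: tuple[float, float, float, float]) -> float:
    """t threshold whose peak-level corrected p equals alpha."""
    f = lambda t: peak_p_fwe(np.array(t), np.array(df), resels) - alpha
    lo, hi = 1.0, 50.0
    if f(lo) < 0:
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


@dataclass
class CorrectedMap:
    statmap: StatMap
    p_fwe: np.ndarray  # voxel-wise peak-level corrected p
    significant: np.ndarray  # boolean
    alpha: float
    resels: tuple[float, float, float, float]
    method: str


def fwe_peak_correct(
    statmap: StatMap,
    smoothness: Smoothness,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> CorrectedMap:
    """GRF peak-level correction over the whole volume or an SVC mask."""
    search = statmap.mask if mask is None else (statmap.mask & mask)
    resels = (
        smoothness.resels
        if mask is None
        else resel_counts(search, smoothness.fwhm_vox)
    )
    p = np.ones_like(statmap.t)
    p[search] = peak_p_fwe(statmap.t[search], statmap.df[search], resels)
    return CorrectedMap(
        statmap=statmap,
        p_fwe=p,
        significant=(p < alpha) & search,
        alpha=alpha,
        resels=resels,
        method="grf",
    )


def build_functional_mask(*corrected: CorrectedMap) -> np.ndarray:
    """Union (logical OR) of significant voxels across corrected maps,
    typically the positive and negative average-effect maps."""
    out = np.zeros_like(corrected[0].significant)
    for c in corrected:
        out |= c.significant
    return out


def _welch_t_groups(Y: np.ndarray, group_ids: np.ndarray, n_groups: int, a: int, b: int):
    """Vectorized Welch t for group a minus group b over (n, v) data."""
    ta = Y[group_ids == a]
    tb = Y[group_ids == b]
    na, nb = ta.shape[0], tb.shape[0]
    ma, mb = ta.mean(axis=0), tb.mean(axis=0)
    va = ta.var(axis=0, ddof=1) / na
    vb = tb.var(axis=0, ddof=1) / nb
    return (ma - mb) / np.sqrt(np.maximum(va + vb, 1e-30))


def permutation_maxT(
    images: np.ndarray,
    design: GroupDesign,
    contrast_groups: tuple[str, str],
    n_perm: int = 500,
    seed: int = 0,
    mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> CorrectedMap:
    """Max-statistic permutation test of a two-group difference contrast.

    Group labels are permuted across all subjects; per permutation the Welch
    t map is recomputed and its maximum recorded. The corrected p of a voxel
    is the rank of its observed t in the max-T null distribution (the
    identity permutation is included, so the smallest attainable p is
    1/(n_perm + 1)).
    """
    import warnings as _warnings

    if n_perm < 100:
        _warnings.warn(f"n_perm={n_perm} is low; corrected p-values are coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    shape = images.shape[1:]
    n = images.shape[0]
    Y = images.reshape(n, -1)
    mvec = np.ones(Y.shape[1], bool) if mask is None else mask.reshape(-1)
    Y = Y[:, mvec]
    names = list(design.group_names)
    gids = np.array([names.index(g) for g in design.groups])
    a, b = names.index(contrast_groups[0]), names.index(contrast_groups[1])

    t_obs = _welch_t_groups(Y, gids, len(names), a, b)
    max_null = np.empty(n_perm + 1)
    max_null[0] = t_obs.max()
    for i in range(n_perm):
        perm = rng.permutation(n)
        max_null[i + 1] = _welch_t_groups(Y, gids[perm], len(names), a, b).max()
    # corrected p = fraction of null maxima >= observed t
    order = np.sort(max_null)
    ranks = np.searchsorted(order, t_obs, side="left")
    p = (max_null.size - ranks) / max_null.size

    p_full = np.ones(int(np.prod(shape)))
    p_full[mvec] = p
    p_full = p_full.reshape(shape)
    dfmap = np.full(shape, float(n - len(names)))
    sm = StatMap(
        t=_expand(t_obs, mvec, shape),
        df=dfmap,
        contrast_name=f"{contrast_groups[0]}>{contrast_groups[1]}",
        mask=mvec.reshape(shape),
        residuals=None,
    )
    return CorrectedMap(
        statmap=sm,
        p_fwe=p_full,
        significant=(p_full < alpha) & sm.mask,
        alpha=alpha,
        resels=(np.nan,) * 4,
        method="permutation",
    )


def _expand(vals: np.ndarray, mvec: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)))
    out[mvec] = vals
    return out.reshape(shape)
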