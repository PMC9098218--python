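"""Hierarchical Bayesian ideal observer over the binary tone sequence.

A 3-level binary hierarchical Gaussian filter: level 1 is the observed tone
(coded u = 1 for tone 1), level 2 a Gaussian belief on the log-odds of
tone 1 (tendency x2), and level 3 a Gaussian belief on the log-volatility
of x2. Each tone triggers sequential (filtering) updates: the level-2 mean
moves by a precision-weighted prediction error on the tone outcome, the
level-3 mean by a precision-weighted prediction error on level 2's
volatility. The observer runs in ideal-observer mode with fixed a-priori
parameters; no look-ahead, no subject-wise fitting.

Parameters (log-variance units per trial): ``omega2`` is the tonic
log-volatility of the tendency, ``theta`` the evolution variance of the
log-volatility level, ``kappa`` the coupling between levels 2 and 3.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .paradigm import ToneSequence


class ObserverUpdateError(RuntimeError):
    """An update produced a non-positive posterior precision."""


@dataclass(frozen=True)
class ObserverParams:
    kappa: float = 1.0
    omega2: float = -3.0
    theta: float = 0.05
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0 or self.theta <= 0:
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class ObserverTrajectories:
    """Trial-wise beliefs and precision-weighted prediction errors."""

    p_hat: np.ndarray  # predicted probability of tone 1, before seeing it
    mu2: np.ndarray  # posterior tendency mean
    sigma2: np.ndarray  # posterior tendency variance
    mu3: np.ndarray  # posterior log-volatility mean
    sigma3: np.ndarray  # posterior log-volatility variance
    pwpe_low: np.ndarray  # level-2 update: sigma2 * (u - p_hat)
    pwpe_high: np.ndarray  # level-3 update

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.p_hat.size),
                "p_hat": self.p_hat,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "mu3": self.mu3,
                "sigma3": self.sigma3,
                "pwpe_low": self.pwpe_low,
                "pwpe_high": self.pwpe_high,
            }
        )


def run_observer(
    seq: ToneSequence | np.ndarray, params: ObserverParams | None = None
) -> ObserverTrajectories:
    """Filter the tone sequence with the 3-level binary observer.

    Raises :class:`ObserverUpdateError` (naming the trial and the offending
    quantity) if an update would produce a non-positive precision.
    """
    params = params or ObserverParams()
    tones = seq.tones if isinstance(seq, ToneSequence) else np.asarray(seq)
    u = (tones == 1).astype(float)
    n = u.size

    mu2, s2 = params.mu2_0, params.sigma2_0
    mu3, s3 = params.mu3_0, params.sigma3_0
    out = {k: np.empty(n) for k in ("p_hat", "mu2", "sigma2", "mu3", "sigma3", "pwpe_low", "pwpe_high")}

    for t in range(n):
        # predictions
        v2 = np.exp(params.kappa * mu3 + params.omega2)  # tendency evolution variance
        sigma2_hat = s2 + v2
        p_hat = float(special.expit(mu2))

        # level-2 update (binary outcome)
        delta1 = u[t] - p_hat
        pi2_hat = 1.0 / sigma2_hat
        pi2 = pi2_hat + p_hat * (1.0 - p_hat)
        if pi2 <= 0:
            raise ObserverUpdateError(f"trial {t}: level-2 precision {pi2} <= 0")
        s2_new = 1.0 / pi2
        mu2_new = mu2 + s2_new * delta1

        # level-3 update (volatility prediction error on level 2)
        w2 = v2 / sigma2_hat
        delta2 = (s2_new + (mu2_new - mu2) ** 2) / sigma2_hat - 1.0
        pi3_hat = 1.0 / (s3 + params.theta)
        pi3 = pi3_hat + (params.kappa**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0:
            raise ObserverUpdateError(
                f"trial {t}: level-3 precision {pi3:.3g} <= 0 (kappa/theta too aggressive)"
            )
        s3_new = 1.0 / pi3
        update3 = s3_new * (params.kappa / 2.0) * w2 * delta2
        mu3_new = mu3 + update3

        out["p_hat"][t] = p_hat
        out["mu2"][t] = mu2_new
        out["sigma2"][t] = s2_new
        out["mu3"][t] = mu3_new
        out["sigma3"][t] = s3_new
        out["pwpe_low"][t] = s2_new * delta1
        out["pwpe_high"][t] = update3
        mu2, s2, mu3, s3 = mu2_new, s2_new, mu3_new, s3_new

    return ObserverTrajectories(**out)


def pe_regressors(
    traj: ObserverTrajectories, retained: np.ndarray | None = None
) -> pd.DataFrame:
    """Trial-wise regressors: z-scored |low-level pwPE| and signed high-level
    pwPE, restricted to retained trials, with their collinearity reported
    in ``frame.attrs['correlation']``."""
    low = np.abs(traj.pwpe_low)
    high = traj.pwpe_high.copy()
    if retained is not None:
        retained = np.asarray(retained)
        if retained.dtype == bool and retained.size != low.size:
            raise ValueError("retained mask length mismatch")
        low, high = low[retained], high[retained]
        trials = np.flatnonzero(retained) if retained.dtype == bool else retained
    else:
        trials = np.arange(low.size)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    frame = pd.DataFrame({"trial": trials, "pwpe_low": z(low), "pwpe_high": z(high)})
    frame.attrs["correlation"] = float(np.corrcoef(frame["pwpe_low"], frame["pwpe_high"])[0, 1])
    return frame
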