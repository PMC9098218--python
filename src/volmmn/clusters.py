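"""Cluster tables from corrected statistical maps.

Significant voxels are grouped into 18-connected components (faces plus
edges in x, y, time); each cluster is reported with its peak coordinates
(x mm, y mm, z ms), peak t, z-equivalent, peak-level corrected p, extent,
and significant time window, mirroring the layout of published
scalp-time cluster tables.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .images import ImageGeometry
from .rft import CorrectedMap

# 18-connectivity in 3D: faces and edges, not corners
_STRUCT = ndimage.generate_binary_structure(3, 2)


def z_equivalent(t: float, df: float) -> float:
    """Standard-normal deviate with the same upper-tail probability.

    Computed in log space; probabilities beyond double range report inf,
    matching the "Inf" entries of published tables.
    """
    logp = stats.t.logsf(t, df)
    if logp < -745:  # tail probability underflows double precision
        return np.inf
    return float(-special.ndtri_exp(logp))


def extract_clusters(corrected: CorrectedMap, geometry: ImageGeometry) -> pd.DataFrame:
    """ClusterTable of the significant voxels of a corrected map.

    Peaks maximize t within the cluster; ties break deterministically
    (earliest time, then smallest x, then smallest y).
    """
    sig = corrected.significant
    labels, n = ndimage.label(sig, structure=_STRUCT)
    rows = []
    t = corrected.statmap.t
    for k in range(1, n + 1):
        vox = np.argwhere(labels == k)
        tvals = t[tuple(vox.T)]
        best = tvals.max()
        cand = vox[np.isclose(tvals, best)]
        # tie-break: earliest time bin, then smallest x, then y
        cand = cand[np.lexsort((cand[:, 1], cand[:, 0], cand[:, 2]))]
        px, py, pt = cand[0]
        df = corrected.statmap.df[px, py, pt]
        rows.append(
            {
                "x_mm": geometry.x_mm[px],
                "y_mm": geometry.y_mm[py],
                "z_ms": geometry.t_ms[pt],
                "peak_t": t[px, py, pt],
                "z_eq": z_equivalent(t[px, py, pt], df),
                "p_fwe": corrected.p_fwe[px, py, pt],
                "k_E": len(vox),
                "tw_min_ms": geometry.t_ms[vox[:, 2].min()],
                "tw_max_ms": geometry.t_ms[vox[:, 2].max()],
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["x_mm", "y_mm", "z_ms", "peak_t", "z_eq", "p_fwe", "k_E", "tw_min_ms", "tw_max_ms"],
    )
    return frame.sort_values("peak_t", ascending=False).reset_index(drop=True) if len(frame) else frame
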