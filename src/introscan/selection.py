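"""Population branch statistic and percentile outlier calling.

PBS expresses the allele-frequency branch length of a focal population
from three pairwise windowed F_ST values via the transform
T = -ln(1 - F_ST):

    PBS = (T_focal,ref1 + T_focal,ref2 - T_ref1,ref2) / 2

Negative windowed F_ST estimates are floored at 0 before the log (they are
sampling noise and would otherwise yield spurious negative branch
lengths); windows where any F_ST = 1 are +inf and flagged.  Outlier
calling for PBS/F_ST/ROD tracks uses an empirical top-percentile
threshold (type-7 linear interpolation) with a strict inequality, so ties
at the threshold are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import check_same_grid


def pbs_values(fst_focal_ref1, fst_focal_ref2, fst_ref1_ref2) -> np.ndarray:
    """Vectorized PBS from three arrays of windowed F_ST values."""
    def branch(f):
        f = np.asarray(f, dtype=float)
        f = np.where(np.isfinite(f), np.maximum(f, 0.0), np.nan)
        with np.errstate(divide="ignore"):
            return -np.log1p(-f)
    t1 = branch(fst_focal_ref1)
    t2 = branch(fst_focal_ref2)
    t3 = branch(fst_ref1_ref2)
    return (t1 + t2 - t3) / 2.0


def pbs_window(fst_focal_ref1: float, fst_focal_ref2: float,
               fst_ref1_ref2: float) -> float:
    return float(pbs_values([fst_focal_ref1], [fst_focal_ref2], [fst_ref1_ref2])[0])


def pbs_track(fst_focal_ref1: pd.DataFrame, fst_focal_ref2: pd.DataFrame,
              fst_ref1_ref2: pd.DataFrame) -> pd.DataFrame:
    """PBS per window from three F_ST tracks on the identical grid.

    Windows missing an F_ST value in any pair are skipped (NaN, flagged
    unusable); windows with any F_ST = 1 are +inf and flagged infinite.
    """
    check_same_grid(fst_focal_ref1, fst_focal_ref2)
    check_same_grid(fst_focal_ref1, fst_ref1_ref2)
    out = fst_focal_ref1[["chrom", "start", "end", "n_sites", "usable"]].copy()
    value = pbs_values(
        fst_focal_ref1["value"], fst_focal_ref2["value"], fst_ref1_ref2["value"]
    )
    out["value"] = value
    out["usable"] = out["usable"] & np.isfinite(value)
    out["infinite"] = np.isinf(value)
    return out


def percentile_outliers(track: pd.DataFrame, top_fraction: float,
                        value_col: str = "value") -> tuple[float, pd.DataFrame]:
    """Flag windows strictly above the empirical (1 - top_fraction) quantile.

    Only usable, finite windows enter the threshold; at least
    1/top_fraction of them are required.  Returns (threshold, track with an
    ``outlier`` column).
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    out = track.copy()
    values = out[value_col].to_numpy(dtype=float)
    usable = out["usable"].to_numpy(dtype=bool) & np.isfinite(values)
    n_min = int(np.ceil(1.0 / top_fraction))
    if usable.sum() < n_min:
        raise ValueError(
            f"need at least {n_min} usable windows for top fraction {top_fraction}"
        )
    threshold = float(np.quantile(values[usable], 1.0 - top_fraction))
    out["outlier"] = usable & (values > threshold)
    return threshold, out
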