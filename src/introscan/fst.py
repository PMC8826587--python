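"""Weir-Cockerham F_ST: per-site variance components, windowed, and global.

Windowed estimates are ratio-of-sums (sum of the among-population component
a over the sum of a+b+c across the window's sites), which is the weighted
windowed estimator of vcftools and is invariant to duplicating sites; a
mean-of-ratios mode is available for sensitivity checks.  Negative
estimates are reported as-is and never clipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


def wc_components(panel: GenotypePanel, pop_a: str, pop_b: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) two-population components.

    Returns ``(a, d)`` where ``a`` is the among-population component and
    ``d = a + b + c`` the total.  Skipped sites (a population without a
    called diploid, or mean sample size of one) hold NaN in both arrays;
    sites monomorphic in both populations yield (0, 0) and thus drop out
    of any ratio-of-sums.
    """
    n = np.empty((2, panel.n_sites))
    p = np.empty((2, panel.n_sites))
    h = np.empty((2, panel.n_sites))
    for k, pop in enumerate((pop_a, pop_b)):
        g = panel.geno[:, panel.sample_indices(pop)]
        called = g != MISSING
        n[k] = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called, g, 0).sum(axis=1) / (2 * n[k])
            h[k] = (g == 1).sum(axis=1) / n[k]
    r = 2.0
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = nbar / (nbar - 1.0) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    d = a + b + c
    skip = (n < 1).any(axis=0) | (nbar <= 1)
    a = np.where(skip, np.nan, a)
    d = np.where(skip, np.nan, d)
    return a, d


def fst_site(panel: GenotypePanel, pop_a: str, pop_b: str) -> np.ndarray:
    """Per-site F_ST estimates, NaN where skipped or uninformative."""
    a, d = wc_components(panel, pop_a, pop_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d != 0, a / d, np.nan)


def fst_window_value(a: np.ndarray, d: np.ndarray) -> float:
    """Ratio-of-sums over one window's per-site components."""
    ok = np.isfinite(a) & np.isfinite(d)
    den = d[ok].sum()
    return float(a[ok].sum() / den) if den != 0 else float("nan")


def fst_track(panel: GenotypePanel, pop_a: str, pop_b: str,
              windows: pd.DataFrame, mode: str = "ratio_of_sums") -> pd.DataFrame:
    """Windowed F_ST on a window grid.

    ``mode`` is ``"ratio_of_sums"`` (default) or ``"mean_of_ratios"``.
    Windows with a zero denominator (or, for mean-of-ratios, no informative
    site) are NaN.
    """
    if mode not in ("ratio_of_sums", "mean_of_ratios"):
        raise ValueError(f"unknown mode {mode!r}")
    a, d = wc_components(panel, pop_a, pop_b)
    values = []
    for w in windows.itertuples(index=False):
        idx = panel.sites_in(w.chrom, w.start, w.end)
        if mode == "ratio_of_sums":
            values.append(fst_window_value(a[idx], d[idx]))
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios = a[idx] / d[idx]
            ratios = ratios[np.isfinite(ratios)]
            values.append(float(ratios.mean()) if ratios.size else float("nan"))
    out = windows.copy()
    out["value"] = values
    return out


def global_fst(panel: GenotypePanel, pop_a: str, pop_b: str) -> float:
    """Genome-wide ratio-of-sums F_ST over all sites."""
    a, d = wc_components(panel, pop_a, pop_b)
    return fst_window_value(a, d)
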