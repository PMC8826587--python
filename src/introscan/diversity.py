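"""Windowed nucleotide diversity, absolute divergence, and the ROD contrast.

pi and d_xy are per-bp quantities: site terms are summed over the SNPs in a
window and divided by the window span in bp, so monomorphic positions count
as invariant.  The site term for pi carries the unbiased n/(n-1) sample-size
correction.  ROD = 1 - pi_improved / pi_landrace contrasts an improved
group's diversity against a source (landrace) group on a shared window grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import GenotypePanel, allele_freqs, check_same_grid


def _site_pi_terms(panel: GenotypePanel, population: str) -> np.ndarray:
    """Per-site unbiased heterozygosity 2p(1-p) * n/(n-1); 0 where n < 2."""
    p, n = allele_freqs(panel, population)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    term[~np.isfinite(term) | (n < 2)] = 0.0
    return term


def pi_window(panel: GenotypePanel, population: str, chrom: str,
              start: int, end: int) -> float:
    """Per-bp nucleotide diversity of one window."""
    terms = _site_pi_terms(panel, population)
    idx = panel.sites_in(chrom, start, end)
    return float(terms[idx].sum()) / (end - start + 1)


def dxy_window(panel: GenotypePanel, pop_a: str, pop_b: str, chrom: str,
               start: int, end: int) -> float:
    """Per-bp absolute divergence between two populations in one window."""
    pa, na = allele_freqs(panel, pop_a)
    pb, nb = allele_freqs(panel, pop_b)
    term = pa * (1.0 - pb) + pb * (1.0 - pa)
    term = np.where(np.isfinite(term), term, 0.0)
    idx = panel.sites_in(chrom, start, end)
    return float(term[idx].sum()) / (end - start + 1)


def _track(panel, windows: pd.DataFrame, site_terms: np.ndarray) -> pd.DataFrame:
    values = []
    for w in windows.itertuples(index=False):
        idx = panel.sites_in(w.chrom, w.start, w.end)
        values.append(site_terms[idx].sum() / (w.end - w.start + 1))
    out = windows.copy()
    out["value"] = values
    return out


def pi_track(panel: GenotypePanel, population: str, windows: pd.DataFrame) -> pd.DataFrame:
    """pi for every window of a grid; returns the grid plus a value column."""
    return _track(panel, windows, _site_pi_terms(panel, population))


def dxy_track(panel: GenotypePanel, pop_a: str, pop_b: str,
              windows: pd.DataFrame) -> pd.DataFrame:
    pa, _ = allele_freqs(panel, pop_a)
    pb, _ = allele_freqs(panel, pop_b)
    term = pa * (1.0 - pb) + pb * (1.0 - pa)
    term = np.where(np.isfinite(term), term, 0.0)
    return _track(panel, windows, term)


def rod(pi_improved: pd.DataFrame, pi_landrace: pd.DataFrame) -> pd.DataFrame:
    """Reduction of diversity, 1 - pi_improved / pi_landrace, per window.

    Both tracks must be on the identical window grid.  Windows where the
    landrace diversity is 0 are undefined (NaN) rather than +-inf and are
    excluded from any downstream ranking.
    """
    check_same_grid(pi_improved, pi_landrace)
    out = pi_improved[["chrom", "start", "end", "n_sites", "usable"]].copy()
    num = pi_improved["value"].to_numpy(dtype=float)
    den = pi_landrace["value"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = 1.0 - num / den
    value[den == 0] = np.nan
    out["value"] = value
    return out
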