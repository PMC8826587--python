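"""Independent loop-based reference implementations.

These deliberately avoid the vectorized code paths in the scan modules:
statistics are computed from explicit allele lists and per-site scalar
arithmetic, directly transcribing the defining formulas (mean pairwise
differences for pi and d_xy, the Weir & Cockerham 1984 variance components
for F_ST, site-pattern products for D and f_d).  They exist to generate
the expected-value table for the toy fixture and to cross-check the
pipeline in tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .panel import ANC_ALT, ANC_REF, GenotypePanel


def _alleles(panel: GenotypePanel, pop: str, site: int) -> list[int]:
    """Expanded allele calls (0 = ref, 1 = alt) for a population at a site."""
    out: list[int] = []
    for col in panel.sample_indices(pop):
        g = int(panel.geno[site, col])
        if g >= 0:
            out.extend([1] * g + [0] * (2 - g))
    return out


def _derived_freq(panel: GenotypePanel, pop: str, site: int) -> float | None:
    calls = _alleles(panel, pop, site)
    if not calls:
        return None
    anc = int(panel.ancestral[site])
    if anc == ANC_REF:
        return sum(calls) / len(calls)
    if anc == ANC_ALT:
        return 1.0 - sum(calls) / len(calls)
    return None  # unknown ancestral state: site excluded


def pi_window(panel: GenotypePanel, pop: str, chrom: str, start: int, end: int) -> float:
    total = 0.0
    for site in panel.sites_in(chrom, start, end):
        calls = _alleles(panel, pop, site)
        if len(calls) < 2:
            continue
        pairs = list(combinations(calls, 2))
        total += sum(1 for a, b in pairs if a != b) / len(pairs)
    return total / (end - start + 1)


def dxy_window(panel: GenotypePanel, pop_a: str, pop_b: str, chrom: str,
               start: int, end: int) -> float:
    total = 0.0
    for site in panel.sites_in(chrom, start, end):
        aa = _alleles(panel, pop_a, site)
        bb = _alleles(panel, pop_b, site)
        if not aa or not bb:
            continue
        diffs = sum(1 for x in aa for y in bb if x != y)
        total += diffs / (len(aa) * len(bb))
    return total / (end - start + 1)


def wc_site(panel: GenotypePanel, pop_a: str, pop_b: str, site: int):
    """Weir & Cockerham (1984) two-population components (a, a+b+c).

    Returns None for skipped sites (a population with no called diploid,
    or mean sample size of 1).
    """
    stats = []
    for pop in (pop_a, pop_b):
        gs = [int(panel.geno[site, c]) for c in panel.sample_indices(pop)]
        gs = [g for g in gs if g >= 0]
        if len(gs) < 1:
            return None
        n = len(gs)
        p = sum(gs) / (2 * n)
        h = sum(1 for g in gs if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def fst_window(panel: GenotypePanel, pop_a: str, pop_b: str, chrom: str,
               start: int, end: int) -> float:
    num = den = 0.0
    for site in panel.sites_in(chrom, start, end):
        comp = wc_site(panel, pop_a, pop_b, site)
        if comp is None:
            continue
        num += comp[0]
        den += comp[1]
    return num / den if den != 0 else float("nan")


def _site_patterns(panel: GenotypePanel, p1: str, p2: str, p3: str, site: int):
    f1 = _derived_freq(panel, p1, site)
    f2 = _derived_freq(panel, p2, site)
    f3 = _derived_freq(panel, p3, site)
    if f1 is None or f2 is None or f3 is None:
        return None
    abba = (1 - f1) * f2 * f3
    baba = f1 * (1 - f2) * f3
    fd_donor = max(f2, f3)
    abba_d = (1 - f1) * fd_donor * fd_donor
    baba_d = f1 * (1 - fd_donor) * fd_donor
    return abba, baba, abba_d, baba_d


def d_statistic(panel: GenotypePanel, p1: str, p2: str, p3: str) -> float:
    num = den = 0.0
    for site in range(panel.n_sites):
        pat = _site_patterns(panel, p1, p2, p3, site)
        if pat is None:
            continue
        num += pat[0] - pat[1]
        den += pat[0] + pat[1]
    return num / den


def fd_window(panel: GenotypePanel, p1: str, p2: str, p3: str, chrom: str,
              start: int, end: int):
    """(raw f_d, clipped f_d, window D) with the publication clipping rules."""
    num = den = den_d = 0.0
    for site in panel.sites_in(chrom, start, end):
        pat = _site_patterns(panel, p1, p2, p3, site)
        if pat is None:
            continue
        num += pat[0] - pat[1]
        den += pat[0] + pat[1]
        den_d += pat[2] - pat[3]
    window_d = num / den if den > 0 else float("nan")
    raw = num / den_d if den_d != 0 else float("nan")
    clipped = raw
    if not np.isfinite(raw) or raw < 0 or raw > 1 or not (window_d > 0):
        clipped = 0.0
    return raw, clipped, window_d


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, computed by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def expected_table(panel: GenotypePanel) -> pd.DataFrame:
    """Statistics table for the toy fixture, all values from this module."""
    windows = [(1, 25_000), (25_001, 50_000), (50_001, 75_000), (75_001, 100_000)]
    rows = []
    for start, end in windows:
        for pop in ("P1", "P2", "P3", "OUT"):
            rows.append(("pi", pop, "chr1", start, end,
                         pi_window(panel, pop, "chr1", start, end)))
        for a, b in (("P1", "P2"), ("P2", "P3")):
            rows.append(("dxy", f"{a},{b}", "chr1", start, end,
                         dxy_window(panel, a, b, "chr1", start, end)))
            rows.append(("fst", f"{a},{b}", "chr1", start, end,
                         fst_window(panel, a, b, "chr1", start, end)))
        raw, clipped, wd = fd_window(panel, "P1", "P2", "P3", "chr1", start, end)
        rows.append(("fd_raw", "P1,P2,P3,ANCESTRAL", "chr1", start, end, raw))
        rows.append(("fd", "P1,P2,P3,ANCESTRAL", "chr1", start, end, clipped))
        rows.append(("window_d", "P1,P2,P3,ANCESTRAL", "chr1", start, end, wd))
    rows.append(("d", "P1,P2,P3,ANCESTRAL", "chr1", 1, 100_000,
                 d_statistic(panel, "P1", "P2", "P3")))
    return pd.DataFrame(rows, columns=["stat", "scope", "chrom", "start", "end", "value"])
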