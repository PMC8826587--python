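"""Pairwise r^2, LD-decay curve, half-decay distance, and N_e from E(r^2).

r^2 is the composite genotypic estimate: the squared Pearson correlation
of 0/1/2 genotype codes over the samples called at both loci (inputs are
unphased diploids, so no haplotype phasing is assumed).  The decay curve
bins all intra-chromosomal pairs up to a maximum distance (300 kb preset)
by physical distance.  The linkage-based effective population size
inverts E(r^2) = 1 / (1 + 4 N_e c), giving an estimate of N_e at
t = 1/(2c) generations ago for the recombination fraction c of each
distance bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


class LdError(ValueError):
    pass


def r2_pair(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Composite genotypic r^2 between two loci; NaN if undefined.

    Samples missing at either locus are excluded; a locus monomorphic
    among the shared samples has no defined correlation.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _pop_geno(panel: GenotypePanel, population: str) -> np.ndarray:
    return panel.geno[:, panel.sample_indices(population)].astype(float)


def decay_curve(
    panel: GenotypePanel,
    population: str,
    max_distance: int = 300_000,
    bin_width: int = 10_000,
    min_maf: float = 0.05,
    max_snps_per_chrom: int | None = 2_000,
    sample_size_correction: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin for one population.

    SNPs below ``min_maf`` in the population are excluded; when a
    chromosome carries more than ``max_snps_per_chrom`` qualifying SNPs a
    deterministic random subsample keeps the pair count tractable.  With
    ``sample_size_correction`` the expectation 1/n is subtracted from each
    pair's r^2 (off by default).

    Returns a DataFrame with bin_left, bin_mid, bin_right, mean_r2, n_pairs.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(0, max_distance + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    geno_all = _pop_geno(panel, population)
    for chrom in panel.chromosomes:
        idx = panel.chrom_sites(chrom)
        g = geno_all[idx]
        called = g != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called, g, 0).sum(axis=1) / (2 * called.sum(axis=1))
        maf = np.minimum(freq, 1 - freq)
        keep = np.flatnonzero(np.isfinite(maf) & (maf >= min_maf))
        if max_snps_per_chrom is not None and keep.size > max_snps_per_chrom:
            keep = np.sort(rng.choice(keep, size=max_snps_per_chrom, replace=False))
        g = g[keep]
        pos = panel.pos[idx][keep]
        n_corr = g.shape[1]
        for i in range(len(keep)):
            j_hi = np.searchsorted(pos, pos[i] + max_distance, side="right")
            for j in range(i + 1, j_hi):
                r2 = r2_pair(g[i], g[j])
                if not np.isfinite(r2):
                    continue
                if sample_size_correction:
                    r2 = max(r2 - 1.0 / n_corr, 0.0)
                b = min(int((pos[j] - pos[i]) // bin_width), len(sums) - 1)
                sums[b] += r2
                counts[b] += 1
    if counts.sum() == 0:
        raise LdError("no qualifying SNP pair within max_distance")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_mid": (edges[:-1] + edges[1:]) / 2.0,
        "bin_right": edges[1:],
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })


def half_decay(curve: pd.DataFrame) -> tuple[float, float] | None:
    """First bin (ascending distance) whose mean r^2 drops to half the
    curve's maximum; returns (bin midpoint distance, r^2 there), or None
    for a curve that never decays to half (flagged undefined)."""
    ok = curve[np.isfinite(curve.mean_r2) & (curve.n_pairs > 0)]
    if ok.empty:
        return None
    half = ok.mean_r2.max() / 2.0
    below = ok[ok.mean_r2 <= half]
    if below.empty:
        return None
    row = below.iloc[0]
    return float(row.bin_mid), float(row.mean_r2)


def ne_from_r2(mean_r2: float, c: float) -> tuple[float, float]:
    """Invert E(r^2) = 1 / (1 + 4 N_e c).

    Returns (N_e, t) where t = 1/(2c) generations ago is the epoch the
    estimate refers to.  Requires 0 < r^2 < 1 and c > 0.
    """
    if not (0.0 < mean_r2 < 1.0):
        raise LdError("mean r^2 must be strictly between 0 and 1")
    if c <= 0:
        raise LdError("recombination fraction c must be positive")
    ne = (1.0 / mean_r2 - 1.0) / (4.0 * c)
    return ne, 1.0 / (2.0 * c)


def ne_series(curve: pd.DataFrame, cm_per_mb: float = 1.5) -> pd.DataFrame:
    """Per-bin N_e estimates, mapping bin midpoints to c with a constant
    cM/Mb rate (c = distance_bp * rate * 1e-8)."""
    rows = []
    for row in curve.itertuples(index=False):
        c = row.bin_mid * cm_per_mb * 1e-8
        if c <= 0 or not np.isfinite(row.mean_r2) or not (0 < row.mean_r2 < 1):
            continue
        ne, t = ne_from_r2(row.mean_r2, c)
        rows.append((row.bin_mid, c, row.mean_r2, ne, t))
    return pd.DataFrame(rows, columns=["distance_bp", "c", "mean_r2", "ne", "t_generations"])
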