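"""ABBA-BABA D, windowed f_d, significance, tract calling, PGI and RIS.

Site patterns are frequency-based: with derived-allele frequencies
p1..p4 on the topology ((P1, P2), P3, O),

    ABBA = (1 - p1) p2 p3 (1 - p4),    BABA = p1 (1 - p2) p3 (1 - p4),

and D = sum(ABBA - BABA) / sum(ABBA + BABA).  The standard error comes
from a delete-one block jackknife over contiguous genomic blocks, Z = D/se,
and |Z| > 3 is the conventional support threshold for gene flow.

f_d normalizes the windowed ABBA-BABA excess by the value expected under
complete sharing with a dynamic donor P_D whose derived frequency is
max(p2, p3) at each site.  Windows with negative window-D, negative raw
f_d, or raw f_d > 1 are clipped to 0 (those values carry no signal of
P3 -> P2 introgression).  Window p-values come from a per-scan z-transform
of the clipped values with an upper-tail normal p, BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import ANCESTRAL, GenotypePanel, PopulationRoles, allele_freqs
from .simulate import merge_intervals


class IntrogressionError(ValueError):
    pass


@dataclass
class DStatResult:
    roles: PopulationRoles
    d: float
    se: float
    z: float
    sum_abba: float
    sum_baba: float
    n_blocks: int


@dataclass
class TractSet:
    """Merged significant-introgression intervals for one recipient/donor."""

    recipient: str
    donor: str
    intervals: pd.DataFrame          # chrom, start, end (1-based closed)
    n_tracts: int
    per_chrom_bp: dict[str, int]
    accumulated_bp: int
    scanned_bp: int
    ris_proportion: float


def site_patterns(panel: GenotypePanel, roles: PopulationRoles
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (ABBA, BABA, ABBA_D, BABA_D) with NaN at unusable sites.

    With ``roles.outgroup == ANCESTRAL`` frequencies are polarized by the
    panel's ancestral flag and p4 = 0; otherwise the outgroup population's
    allele frequency enters the formulas directly, unpolarized.
    """
    polarized = roles.outgroup == ANCESTRAL
    p1, _ = allele_freqs(panel, roles.p1, polarize=polarized)
    p2, _ = allele_freqs(panel, roles.p2, polarize=polarized)
    p3, _ = allele_freqs(panel, roles.p3, polarize=polarized)
    if polarized:
        p4 = np.zeros(panel.n_sites)
    else:
        p4, _ = allele_freqs(panel, roles.outgroup, polarize=False)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    pd_ = np.maximum(p2, p3)
    abba_d = (1 - p1) * pd_ * pd_ * (1 - p4)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - p4)
    return abba, baba, abba_d, baba_d


def d_statistic(panel: GenotypePanel, roles: PopulationRoles,
                block_size: int = 5_000_000) -> DStatResult:
    """Genome-wide D with delete-one block-jackknife standard error."""
    abba, baba, _, _ = site_patterns(panel, roles)
    ok = np.isfinite(abba) & np.isfinite(baba)
    num = np.where(ok, abba - baba, 0.0)
    den = np.where(ok, abba + baba, 0.0)
    total_den = den.sum()
    if total_den == 0:
        raise IntrogressionError("sum(ABBA+BABA) is zero: D undefined")
    total_num = num.sum()
    d = total_num / total_den

    chrom_codes = pd.factorize(panel.chrom)[0]
    blocks = chrom_codes.astype(np.int64) * 10**7 + (panel.pos - 1) // block_size
    frame = pd.DataFrame({"b": blocks, "num": num, "den": den}).groupby("b").sum()
    frame = frame[frame.den > 0]
    n_blocks = len(frame)
    if n_blocks < 20:
        raise IntrogressionError(
            f"only {n_blocks} non-empty jackknife blocks; use a smaller block_size"
        )
    d_j = (total_num - frame.num.to_numpy()) / (total_den - frame.den.to_numpy())
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((d_j - d_j.mean()) ** 2).sum()))
    z = d / se if se > 0 else float("inf") * np.sign(d)
    return DStatResult(
        roles=roles, d=float(d), se=se, z=float(z),
        sum_abba=float(np.where(ok, abba, 0.0).sum()),
        sum_baba=float(np.where(ok, baba, 0.0).sum()),
        n_blocks=n_blocks,
    )


def _clip_fd(raw: float, window_d: float) -> float:
    if not np.isfinite(raw) or raw < 0 or raw > 1 or not (window_d > 0):
        return 0.0
    return raw


def fd_window(panel: GenotypePanel, roles: PopulationRoles, chrom: str,
              start: int, end: int) -> tuple[float, float]:
    """(raw f_d, clipped f_d) for one window."""
    track = fd_track(
        panel, roles,
        pd.DataFrame(
            [(chrom, start, end, 0, True)],
            columns=["chrom", "start", "end", "n_sites", "usable"],
        ),
    )
    return float(track.raw_fd.iloc[0]), float(track.fd.iloc[0])


def fd_track(panel: GenotypePanel, roles: PopulationRoles,
             windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed f_d over a grid; unusable windows get NaN statistics.

    Adds columns raw_fd, fd (clipped), window_d, numerator, denominator.
    """
    abba, baba, abba_d, baba_d = site_patterns(panel, roles)
    ok = np.isfinite(abba)
    num = np.where(ok, abba - baba, 0.0)
    den = np.where(ok, abba + baba, 0.0)
    den_d = np.where(ok, abba_d - baba_d, 0.0)
    rows = []
    for w in windows.itertuples(index=False):
        if not w.usable:
            rows.append((np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        idx = panel.sites_in(w.chrom, w.start, w.end)
        nu, de, dd = num[idx].sum(), den[idx].sum(), den_d[idx].sum()
        window_d = nu / de if de > 0 else np.nan
        raw = nu / dd if dd != 0 else np.nan
        rows.append((raw, _clip_fd(raw, window_d), window_d, nu, dd))
    out = windows.copy()
    out[["raw_fd", "fd", "window_d", "numerator", "denominator"]] = pd.DataFrame(
        rows, index=out.index
    )
    return out


def fd_significance(track: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-scan z-transform p-values, BH q-values and significance flags.

    The z-transform uses the mean and SD of the usable windows' clipped
    f_d values of this same scan; p is the one-sided upper-tail normal
    probability; BH runs across all usable windows; a window is
    significant when q < alpha.
    """
    out = track.copy()
    usable = out["usable"].to_numpy(dtype=bool) & np.isfinite(out["fd"].to_numpy())
    values = out.loc[usable, "fd"].to_numpy(dtype=float)
    if usable.sum() < 10:
        raise IntrogressionError("need at least 10 usable windows for significance")
    sd = values.std()
    if np.ptp(values) == 0 or sd == 0:
        raise IntrogressionError("all f_d values identical: z-transform undefined")
    z = (values - values.mean()) / sd
    p = stats.norm.sf(z)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    out["p"] = np.nan
    out["q"] = np.nan
    out["significant"] = False
    out.loc[usable, "p"] = p
    out.loc[usable, "q"] = q
    out.loc[usable, "significant"] = reject
    return out


def call_tracts(track: pd.DataFrame, recipient: str = "P2", donor: str = "P3",
                scanned_bp: int | None = None) -> TractSet:
    """Merge significant windows into introgression tracts.

    Overlapping or bookended significant windows join into one tract; the
    RIS proportion is the accumulated tract length over the scanned bp
    (total window-grid footprint by default).
    """
    sig = track[track["significant"].fillna(False)]
    intervals = merge_intervals(sig[["chrom", "start", "end"]]) if len(sig) else \
        pd.DataFrame(columns=["chrom", "start", "end"])
    lengths = (intervals.end - intervals.start + 1) if len(intervals) else pd.Series(dtype=int)
    per_chrom = {
        c: int(l.sum())
        for c, l in lengths.groupby(intervals.chrom)
    } if len(intervals) else {}
    accumulated = int(lengths.sum()) if len(intervals) else 0
    if scanned_bp is None:
        footprint = merge_intervals(track[["chrom", "start", "end"]])
        scanned_bp = int((footprint.end - footprint.start + 1).sum())
    return TractSet(
        recipient=recipient, donor=donor, intervals=intervals,
        n_tracts=len(intervals), per_chrom_bp=per_chrom,
        accumulated_bp=accumulated, scanned_bp=int(scanned_bp),
        ris_proportion=accumulated / scanned_bp if scanned_bp else float("nan"),
    )


def pgi(track: pd.DataFrame, genome_size: int) -> float:
    """Proportion of genome introgression, sum(fd_i * G_i) / G.

    Every usable window contributes its clipped f_d weighted by its span;
    overlapping windows are included as listed.
    """
    if genome_size <= 0:
        raise IntrogressionError("genome size must be positive")
    usable = track["usable"].to_numpy(dtype=bool) & np.isfinite(track["fd"].to_numpy())
    spans = (track["end"] - track["start"] + 1).to_numpy(dtype=float)
    fd = track["fd"].to_numpy(dtype=float)
    return float((fd[usable] * spans[usable]).sum() / genome_size)
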