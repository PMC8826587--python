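"""Genotype panel, population roles and window machinery.

The panel holds biallelic SNP genotypes as counts of the non-reference
allele (0/1/2, -1 for missing), one row per site, one column per sample,
together with per-site chromosome/position and an ancestral-allele flag.
All downstream scans (diversity, differentiation, introgression, selection,
LD) operate on allele frequencies derived from this container.

Coordinates are 1-based, fully closed intervals in memory; BED output
converts to 0-based half-open on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: token accepted in place of an outgroup population label: treat the
#: panel's ancestral-allele flag as a fixed outgroup (derived frequency 0).
ANCESTRAL = "ANCESTRAL"

# ancestral-flag codes
ANC_REF = 0
ANC_ALT = 1
ANC_UNKNOWN = -1

MISSING = -1


class PanelError(ValueError):
    """Raised for malformed input (unsorted VCF, unknown samples, ...)."""


@dataclass
class GenotypePanel:
    """Biallelic genotype matrix with population labels.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (n_sites,)
    pos : np.ndarray of int64, shape (n_sites,)
        1-based positions, strictly increasing within a chromosome.
    geno : np.ndarray of int8, shape (n_sites, n_samples)
        Count of non-reference alleles in {0, 1, 2}, -1 for missing.
    ancestral : np.ndarray of int8, shape (n_sites,)
        0 if the reference allele is ancestral, 1 if the alternate allele
        is ancestral, -1 unknown.
    samples : list of str
    popmap : dict mapping sample id -> population label
    """

    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    ancestral: np.ndarray
    samples: list[str]
    popmap: dict[str, str]
    _pop_cols: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_sites, n_samples = self.geno.shape
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise PanelError("chrom/pos length does not match genotype rows")
        if len(self.samples) != n_samples:
            raise PanelError("sample list does not match genotype columns")
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError("genotypes must be in {0,1,2} or -1 (missing)")
        missing_labels = [s for s in self.samples if s not in self.popmap]
        if missing_labels:
            raise PanelError(f"samples without population label: {missing_labels}")
        if len(set(self.popmap[s] for s in self.samples)) < 2:
            raise PanelError("panel must contain at least 2 populations")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise PanelError(f"positions not strictly increasing on {c}")

    # -- helpers ----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.geno.shape[0]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chrom))

    def sample_indices(self, population: str) -> np.ndarray:
        """Column indices of the samples belonging to ``population``."""
        if population not in self._pop_cols:
            cols = np.array(
                [i for i, s in enumerate(self.samples) if self.popmap[s] == population],
                dtype=np.int64,
            )
            if cols.size == 0:
                raise PanelError(f"unknown population: {population!r}")
            self._pop_cols[population] = cols
        return self._pop_cols[population]

    def chrom_sites(self, chrom: str) -> np.ndarray:
        """Row indices of the sites on ``chrom`` (in position order)."""
        return np.flatnonzero(self.chrom == chrom)

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of sites in the closed interval [start, end] on chrom."""
        idx = self.chrom_sites(chrom)
        p = self.pos[idx]
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="right")
        return idx[lo:hi]

    def span(self, chrom: str) -> int:
        """Maximum observed position on a chromosome (fallback contig length)."""
        idx = self.chrom_sites(chrom)
        return int(self.pos[idx].max()) if idx.size else 0


@dataclass(frozen=True)
class PopulationRoles:
    """Four-taxon role assignment ((P1, P2), P3, O).

    ``p1`` is the non-admixed reference population, ``p2`` the candidate
    recipient, ``p3`` the donor.  ``outgroup`` is either a population label
    or the token :data:`ANCESTRAL`, in which case the panel's ancestral
    flag is treated as a fixed outgroup and sites with unknown ancestral
    state are excluded.
    """

    p1: str
    p2: str
    p3: str
    outgroup: str = ANCESTRAL

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise PanelError(f"four distinct roles required, got {labels}")


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict[str, str]:
    """Read a two-column TSV (sample<TAB>population)."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise PanelError(f"malformed popmap line: {line!r}")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise PanelError(f"empty popmap: {path}")
    return popmap


def _read_ancestral_tsv(path) -> dict[tuple[str, int], str]:
    table: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, p, a = line.split()[:3]
            table[(c, int(p))] = a.upper()
    return table


_GT_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)  # cyvcf2 gt_types -> dosage


def load_panel(
    vcf_path,
    popmap_path,
    min_called_fraction: float = 0.9,
    ancestral_tsv=None,
) -> GenotypePanel:
    """Load a VCF plus popmap into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are dropped, as are sites whose
    called-genotype fraction among the popmap samples falls below
    ``min_called_fraction``.  The ancestral allele is taken from the AA
    INFO tag when present, or from ``ancestral_tsv`` (chrom, pos, allele);
    sites with neither get the unknown flag.

    Raises
    ------
    PanelError
        If the VCF is unsorted (first offending record is named) or a
        popmap sample is absent from the VCF header.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    reader = VCF(str(vcf_path))
    header_samples = list(reader.samples)
    absent = sorted(set(popmap) - set(header_samples))
    if absent:
        raise PanelError(f"popmap samples absent from VCF: {absent}")
    reader.close()

    samples = [s for s in header_samples if s in popmap]
    reader = VCF(str(vcf_path), samples=samples)
    samples = list(reader.samples)  # order as subset by cyvcf2

    anc_table = _read_ancestral_tsv(ancestral_tsv) if ancestral_tsv else {}

    chroms: list[str] = []
    positions: list[int] = []
    genos: list[np.ndarray] = []
    anc: list[int] = []
    n_dropped_nonbiallelic = 0
    n_dropped_missing = 0
    n_dropped_dup = 0
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()

    for rec in reader:
        key = (rec.CHROM, rec.POS)
        if last is not None:
            if rec.CHROM == last[0] and rec.POS < last[1]:
                raise PanelError(
                    f"VCF not sorted: {rec.CHROM}:{rec.POS} after {last[0]}:{last[1]}"
                )
            if rec.CHROM != last[0]:
                if rec.CHROM in seen_chroms:
                    raise PanelError(
                        f"VCF not sorted: chromosome {rec.CHROM} recurs at position {rec.POS}"
                    )
                seen_chroms.add(last[0])
        last = key

        if len(rec.ALT) != 1 or not rec.is_snp:
            n_dropped_nonbiallelic += 1
            continue
        g = _GT_CODE[rec.gt_types]
        called = (g != MISSING).mean()
        if called < min_called_fraction:
            n_dropped_missing += 1
            continue
        if positions and chroms[-1] == rec.CHROM and positions[-1] == rec.POS:
            n_dropped_dup += 1
            continue

        aa = rec.INFO.get("AA")
        if aa is None:
            aa = anc_table.get((rec.CHROM, rec.POS))
        if aa is None:
            code = ANC_UNKNOWN
        else:
            aa = str(aa).upper()
            if aa == rec.REF.upper():
                code = ANC_REF
            elif aa == rec.ALT[0].upper():
                code = ANC_ALT
            else:
                code = ANC_UNKNOWN

        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        genos.append(g)
        anc.append(code)
    reader.close()

    logger.info(
        "load_panel: kept %d sites (%d non-biallelic/non-SNP, %d high-missing, "
        "%d duplicate-position records dropped)",
        len(positions), n_dropped_nonbiallelic, n_dropped_missing, n_dropped_dup,
    )
    if not positions:
        raise PanelError(f"no usable biallelic SNPs in {vcf_path}")
    return GenotypePanel(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        geno=np.vstack(genos),
        ancestral=np.array(anc, dtype=np.int8),
        samples=samples,
        popmap={s: popmap[s] for s in samples},
    )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_freqs(
    panel: GenotypePanel,
    population: str,
    sites: np.ndarray | None = None,
    polarize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site allele frequency and called-allele count for a population.

    Returns ``(freq, n_called)``.  Without polarization the frequency is
    that of the non-reference (ALT) allele.  With ``polarize=True`` it is
    the derived-allele frequency according to the panel's ancestral flag;
    sites with unknown ancestral state get NaN (they are excluded, not
    silently zeroed).  Sites with zero called alleles also get NaN.
    Missing genotypes are excluded from numerator and denominator.
    """
    cols = panel.sample_indices(population)
    g = panel.geno[:, cols] if sites is None else panel.geno[np.ix_(sites, cols)]
    called = g != MISSING
    n_called = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    if polarize:
        anc = panel.ancestral if sites is None else panel.ancestral[sites]
        freq = np.where(anc == ANC_REF, freq, np.where(anc == ANC_ALT, 1.0 - freq, np.nan))
    return freq, n_called


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(
    panel: GenotypePanel,
    size: int,
    step: int | None = None,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Sliding-window grid anchored at position 1 on each chromosome.

    Windows advance by ``step`` (default: non-overlapping, step = size);
    the last window is truncated at the maximum observed position.  Windows
    with fewer than ``min_sites`` usable SNPs are listed but flagged
    unusable.

    Returns a DataFrame with columns chrom, start, end, n_sites, usable
    (1-based closed coordinates).
    """
    if step is None:
        step = size
    if not (size >= step >= 1):
        raise ValueError("require size >= step >= 1")
    rows = []
    for c in panel.chromosomes:
        idx = panel.chrom_sites(c)
        if idx.size == 0:
            logger.warning("chromosome %s has no sites; zero windows", c)
            continue
        p = panel.pos[idx]
        span = int(p.max())
        start = 1
        while start <= span:
            end = min(start + size - 1, span)
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="right")
            n = int(hi - lo)
            rows.append((c, start, end, n, n >= min_sites))
            if start + size - 1 >= span:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "usable"])


def check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    """Raise if two window tables are not on the identical grid."""
    key = ["chrom", "start", "end"]
    if len(a) != len(b) or not a[key].reset_index(drop=True).equals(
        b[key].reset_index(drop=True)
    ):
        raise ValueError("window grids differ between tracks")
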