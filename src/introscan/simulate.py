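"""Four-taxon coalescent simulator with a known introgression pulse.

Generates diploid VCFs under the topology ((P1, P2), P3, O) with a single
mass-migration pulse from the wild donor P3 into the domestic recipient P2,
and records the true donor tracts of the sampled recipient haplotypes from
the simulation's migration records.  This gives every pipeline stage a
ground truth without any external data.

The default scenario emulates a livestock-like system: two domestic breeds
(P1, P2) formed recently from a large landrace pool by a strong
breed-formation bottleneck, a moderately diverged wild donor (P3) and a
deeply diverged wild outgroup (O).  Mutation rate and recombination rate
follow genome-scale estimates for sheep (mu = 1.51e-8 per bp per
generation; 1.5 cM/Mb).  The recent breed effective size (40) matches
linkage-based estimates of recent N_e in domestic sheep breeds.  The
bottleneck is not a nuisance parameter: it coalesces the recipient sample
before the pulse, so the donor material carried by the sample concentrates
at a fraction close to the pulse fraction f, which is the regime in which
window scans can localize introgression.

Sweeps are emulated by post-hoc diversity scaling: within a sweep region a
fraction (1 - scaling) of sites have the focal population's genotypes set
to its major allele, reducing that population's diversity by approximately
the scaling factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .panel import ANC_REF, GenotypePanel

POPS = ("P1", "P2", "P3", "OUT")


class ScenarioError(ValueError):
    """Raised for infeasible demographic scenarios."""


@dataclass(frozen=True)
class SweepRegion:
    """Diversity-scaled region: local diversity of ``population`` is reduced
    to ``scaling`` times its neutral value (scaling in (0, 1])."""

    chrom: str
    start: int
    end: int
    scaling: float
    population: str = "P1"

    def __post_init__(self) -> None:
        if not (0.0 < self.scaling <= 1.0):
            raise ScenarioError("sweep scaling must be in (0, 1]")
        if self.population not in POPS:
            raise ScenarioError(f"sweep population must be one of {POPS}")


@dataclass(frozen=True)
class Scenario:
    """Parameters of the four-taxon simulation (times in generations)."""

    split_p1p2: float = 1_000.0
    split_p3: float = 10_000.0
    split_outgroup: float = 60_000.0
    pulse_fraction: float = 0.2
    pulse_time: float = 500.0
    n_dip: int | dict = 5
    seq_len: int = 10_000_000
    n_chrom: int = 1
    mu: float = 1.51e-8
    rho: float = 1.5e-8
    ne_breed: float = 40.0
    ne_breed_founder: float = 10_000.0
    breed_age: float = 300.0
    ne_wild: float = 5_000.0
    sweep_regions: tuple[SweepRegion, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.pulse_fraction <= 1.0):
            raise ScenarioError("pulse fraction must be in [0, 1]")
        if self.mu <= 0 or self.rho <= 0:
            raise ScenarioError("mu and rho must be positive")
        if not (self.split_p1p2 < self.split_p3 < self.split_outgroup):
            raise ScenarioError("require split_p1p2 < split_p3 < split_outgroup")
        if self.pulse_fraction > 0 and not (
            0 < self.pulse_time < self.split_p1p2
        ):
            raise ScenarioError(
                "pulse older than the recipient population: require "
                "0 < pulse_time < split_p1p2 (and hence < donor split)"
            )
        if not (0 < self.breed_age < self.split_p1p2):
            raise ScenarioError("require 0 < breed_age < split_p1p2")

    def samples(self) -> dict[str, int]:
        if isinstance(self.n_dip, dict):
            return {p: int(self.n_dip.get(p, 5)) for p in POPS}
        return {p: int(self.n_dip) for p in POPS}

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated data set.

    ``hap_tracts`` holds per-haplotype donor intervals (columns chrom,
    start, end, haplotype; 1-based closed), ``union_tracts`` their merged
    union per chromosome — the reference truth for window-level recovery.
    """

    scenario: Scenario
    hap_tracts: pd.DataFrame
    union_tracts: pd.DataFrame
    seg_sites: int

    def union_bp(self) -> int:
        if self.union_tracts.empty:
            return 0
        return int((self.union_tracts.end - self.union_tracts.start + 1).sum())


def _demography(sc: Scenario) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="P1", initial_size=sc.ne_breed)
    dem.add_population(name="P2", initial_size=sc.ne_breed)
    dem.add_population(name="P3", initial_size=sc.ne_wild)
    dem.add_population(name="OUT", initial_size=sc.ne_wild)
    dem.add_population(name="A12", initial_size=sc.ne_wild)
    dem.add_population(name="A123", initial_size=sc.ne_wild)
    dem.add_population(name="ROOT", initial_size=sc.ne_wild)
    for breed in ("P1", "P2"):
        dem.add_population_parameters_change(
            time=sc.breed_age, population=breed, initial_size=sc.ne_breed_founder
        )
    if sc.pulse_fraction > 0:
        dem.add_mass_migration(
            time=sc.pulse_time, source="P2", dest="P3", proportion=sc.pulse_fraction
        )
    dem.add_population_split(time=sc.split_p1p2, derived=["P1", "P2"], ancestral="A12")
    dem.add_population_split(time=sc.split_p3, derived=["A12", "P3"], ancestral="A123")
    dem.add_population_split(
        time=sc.split_outgroup, derived=["A123", "OUT"], ancestral="ROOT"
    )
    dem.sort_events()
    return dem


def _chrom_seeds(sc: Scenario, chrom_index: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence(entropy=sc.seed, spawn_key=(chrom_index,))
    a, b, c = ss.generate_state(3, dtype=np.uint64)
    m = 2**31 - 2
    return int(a % m) + 1, int(b % m) + 1, int(c % m) + 1


def _simulate_chrom(sc: Scenario, chrom_index: int):
    seed_anc, seed_mut, _ = _chrom_seeds(sc, chrom_index)
    ts = msprime.sim_ancestry(
        samples=sc.samples(),
        demography=_demography(sc),
        sequence_length=sc.seq_len,
        recombination_rate=sc.rho,
        record_migrations=True,
        random_seed=seed_anc,
    )
    mts = msprime.sim_mutations(ts, rate=sc.mu, random_seed=seed_mut)
    return mts


def _hap_names(sc: Scenario) -> tuple[list[str], dict[str, str]]:
    """Diploid sample names (pop order) and popmap."""
    names, popmap = [], {}
    for p, n in sc.samples().items():
        for i in range(n):
            name = f"{p}_{i}"
            names.append(name)
            popmap[name] = p
    return names, popmap


def _donor_tracts_chrom(ts, sc: Scenario, chrom: str) -> pd.DataFrame:
    """Per-haplotype donor intervals from migration records at the pulse."""
    if sc.pulse_fraction == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "haplotype"])
    donor_id = next(p.id for p in ts.populations() if p.metadata["name"] == "P3")
    recip_id = next(p.id for p in ts.populations() if p.metadata["name"] == "P2")
    recip_samples = set(ts.samples(population=recip_id))
    recs = [
        m
        for m in ts.migrations()
        if abs(m.time - sc.pulse_time) < 1e-9
        and m.dest == donor_id
        and m.source == recip_id
    ]
    rows = []
    for rec in recs:
        tree = ts.at(rec.left)
        while tree.interval.left < rec.right:
            lo = max(tree.interval.left, rec.left)
            hi = min(tree.interval.right, rec.right)
            if hi > lo:
                for s in tree.samples(rec.node):
                    if s in recip_samples:
                        rows.append((chrom, int(lo) + 1, int(hi), int(s)))
            if tree.interval.right >= rec.right:
                break
            tree.next()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "haplotype"])
    return df.sort_values(["haplotype", "start"]).reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended 1-based closed intervals per chrom."""
    out = []
    for c, grp in df.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in grp.sort_values("start")[["start", "end"]].itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((c, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _apply_sweeps(
    sc: Scenario,
    chrom: str,
    pos: np.ndarray,
    geno: np.ndarray,
    hap_pop: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Thin the focal population's variation inside sweep regions, in place."""
    for sw in sc.sweep_regions:
        if sw.chrom != chrom:
            continue
        cols = np.flatnonzero(hap_pop == sw.population)
        in_region = np.flatnonzero((pos >= sw.start) & (pos <= sw.end))
        hit = in_region[rng.random(in_region.size) < 1.0 - sw.scaling]
        for i in hit:
            sub = geno[i, cols]
            called = sub >= 0
            if not called.any():
                continue
            alt_frac = sub[called].sum() / (2 * called.sum())
            geno[i, cols] = 2 if alt_frac > 0.5 else 0


def simulate_panel(sc: Scenario) -> tuple[GenotypePanel, SimTruth]:
    """Run the scenario and return an in-memory panel plus ground truth."""
    names, popmap = _hap_names(sc)
    sample_pop = np.array([popmap[s] for s in names], dtype=object)
    chroms_all, pos_all, geno_all = [], [], []
    tract_frames = []
    seg = 0
    for ci, chrom in enumerate(sc.chrom_names()):
        mts = _simulate_chrom(sc, ci)
        biallelic = np.array([len(v.alleles) == 2 for v in mts.variants()])
        G = mts.genotype_matrix()[biallelic]
        pos = mts.tables.sites.position[biallelic].astype(np.int64) + 1
        geno = (G[:, 0::2] + G[:, 1::2]).astype(np.int8)
        seg += int(biallelic.sum())
        rng = np.random.default_rng(_chrom_seeds(sc, ci)[2])
        _apply_sweeps(sc, chrom, pos, geno, sample_pop, rng)
        chroms_all.append(np.full(pos.size, chrom, dtype=object))
        pos_all.append(pos)
        geno_all.append(geno)
        tract_frames.append(_donor_tracts_chrom(mts, sc, chrom))
    hap_tracts = pd.concat(tract_frames, ignore_index=True)
    union = merge_intervals(hap_tracts) if len(hap_tracts) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    panel = GenotypePanel(
        chrom=np.concatenate(chroms_all),
        pos=np.concatenate(pos_all),
        geno=np.vstack(geno_all),
        ancestral=np.zeros(seg, dtype=np.int8),  # REF is the true ancestral state
        samples=names,
        popmap=popmap,
    )
    return panel, SimTruth(sc, hap_tracts, union, seg)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

_VCF_NUC = "ACGT"


def write_vcf(panel: GenotypePanel, path, ref_alt: list[tuple[str, str]] | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write the panel as an uncompressed diploid VCF with the AA INFO tag."""
    path = Path(path)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan-simulate\n")
        for c in panel.chromosomes:
            length = (contig_lengths or {}).get(c, panel.span(c))
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for i in range(panel.n_sites):
            if ref_alt is not None:
                ref, alt = ref_alt[i]
            else:
                ref, alt = "A", "T"
            anc = panel.ancestral[i]
            info = f"AA={ref}" if anc == ANC_REF else (f"AA={alt}" if anc == 1 else ".")
            gts = "\t".join(gt_str[int(g)] for g in panel.geno[i])
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.items():
            fh.write(f"{s}\t{p}\n")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based closed intervals as a 0-based half-open BED file."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")


def simulate(sc: Scenario, out_dir) -> dict:
    """Run the scenario and write VCF + popmap + truth BED + scenario JSON.

    Returns a dict of output paths plus the in-memory panel and truth.
    Deterministic: the same scenario and seed give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(sc)
    # deterministic REF/ALT nucleotides so that files are byte-stable
    rng = np.random.default_rng(np.random.SeedSequence(entropy=sc.seed, spawn_key=(10**6,)))
    ref_idx = rng.integers(0, 4, size=panel.n_sites)
    alt_shift = rng.integers(1, 4, size=panel.n_sites)
    ref_alt = [
        (_VCF_NUC[r], _VCF_NUC[(r + s) % 4]) for r, s in zip(ref_idx, alt_shift)
    ]
    paths = {
        "vcf": out_dir / "sim.vcf",
        "popmap": out_dir / "popmap.tsv",
        "truth_bed": out_dir / "truth_tracts.bed",
        "scenario_json": out_dir / "scenario.json",
    }
    write_vcf(panel, paths["vcf"], ref_alt=ref_alt,
              contig_lengths={c: sc.seq_len for c in sc.chrom_names()})
    write_popmap(panel.popmap, paths["popmap"])
    write_bed(truth.union_tracts, paths["truth_bed"])
    record = dataclasses.asdict(sc)
    record["sweep_regions"] = [dataclasses.asdict(s) for s in sc.sweep_regions]
    record["seg_sites"] = truth.seg_sites
    record["union_tract_bp"] = truth.union_bp()
    with open(paths["scenario_json"], "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    paths["panel"] = panel
    paths["truth"] = truth
    return paths


# ---------------------------------------------------------------------------
# hand-built toy fixture
# ---------------------------------------------------------------------------

def _toy_panel() -> tuple[GenotypePanel, list[tuple[str, str]]]:
    """A small deterministic panel with known site patterns.

    40 sites on one 100-kb chromosome, 10 diploids in four populations.
    Patterns include ABBA-like sites (P2 and P3 share the derived allele),
    BABA-like sites, fixed differences between P1 and P2, monomorphic
    sites, a few alt-ancestral and unknown-ancestral sites, and scattered
    missing genotypes.
    """
    rng = np.random.default_rng(20211210)
    samples = [f"P1_{i}" for i in range(2)] + [f"P2_{i}" for i in range(3)] + \
              [f"P3_{i}" for i in range(3)] + [f"OUT_{i}" for i in range(2)]
    popmap = {s: s.split("_")[0] for s in samples}
    cols = {
        "P1": slice(0, 2), "P2": slice(2, 5), "P3": slice(5, 8), "OUT": slice(8, 10)
    }
    n_sites = 40
    pos = np.sort(rng.choice(np.arange(1, 100_001), size=n_sites, replace=False))
    geno = np.zeros((n_sites, 10), dtype=np.int8)

    def fill(i, pop_freqs):
        for p, f in pop_freqs.items():
            c = cols[p]
            n = c.stop - c.start
            g = rng.binomial(2, f, size=n)
            geno[i, c] = g

    for i in range(n_sites):
        kind = i % 8
        if kind == 0:      # ABBA-like: derived shared by P2 and P3
            fill(i, {"P1": 0.0, "P2": 0.8, "P3": 0.9, "OUT": 0.0})
        elif kind == 1:    # BABA-like: derived shared by P1 and P3
            fill(i, {"P1": 0.8, "P2": 0.0, "P3": 0.9, "OUT": 0.0})
        elif kind == 2:    # fixed difference P1 vs P2
            fill(i, {"P1": 0.0, "P2": 1.0, "P3": 0.5, "OUT": 0.0})
        elif kind == 3:    # shared intermediate polymorphism
            fill(i, {"P1": 0.5, "P2": 0.5, "P3": 0.5, "OUT": 0.5})
        elif kind == 4:    # monomorphic
            fill(i, {"P1": 0.0, "P2": 0.0, "P3": 0.0, "OUT": 0.0})
        elif kind == 5:    # donor-only derived
            fill(i, {"P1": 0.0, "P2": 0.1, "P3": 1.0, "OUT": 0.0})
        elif kind == 6:    # drifted everywhere
            fill(i, {"P1": 0.3, "P2": 0.7, "P3": 0.2, "OUT": 0.1})
        else:              # outgroup polymorphic
            fill(i, {"P1": 0.2, "P2": 0.4, "P3": 0.6, "OUT": 0.5})
    # sprinkle missing genotypes
    for _ in range(6):
        geno[rng.integers(0, n_sites), rng.integers(0, 10)] = -1
    ancestral = np.zeros(n_sites, dtype=np.int8)
    ancestral[[7, 15]] = 1    # alt-ancestral sites
    ancestral[[23, 31]] = -1  # unknown ancestral state
    panel = GenotypePanel(
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos=pos,
        geno=geno,
        ancestral=ancestral,
        samples=samples,
        popmap=popmap,
    )
    rng2 = np.random.default_rng(77)
    ref_idx = rng2.integers(0, 4, size=n_sites)
    alt_shift = rng2.integers(1, 4, size=n_sites)
    ref_alt = [(_VCF_NUC[r], _VCF_NUC[(r + s) % 4]) for r, s in zip(ref_idx, alt_shift)]
    return panel, ref_alt


def toy_fixture(out_dir) -> dict:
    """Write the toy VCF + popmap and a brute-force expected-statistics table.

    The expected values are computed by :mod:`introscan._bruteforce`, an
    independent loop-based implementation, and stored alongside the VCF so
    unit tests can compare the vectorized pipeline against them.
    """
    from . import _bruteforce as bf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel, ref_alt = _toy_panel()
    write_vcf(panel, out_dir / "toy.vcf", ref_alt=ref_alt,
              contig_lengths={"chr1": 100_000})
    write_popmap(panel.popmap, out_dir / "toy_popmap.tsv")
    table = bf.expected_table(panel)
    table.to_csv(out_dir / "toy_expected.tsv", sep="\t", index=False)
    return {
        "vcf": out_dir / "toy.vcf",
        "popmap": out_dir / "toy_popmap.tsv",
        "expected": out_dir / "toy_expected.tsv",
        "panel": panel,
    }
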