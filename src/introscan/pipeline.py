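"""Pipeline orchestration: run configured scans from one config object.

A :class:`ScanConfig` collects input paths, role/group assignments and the
per-scan window parameters; :func:`run` executes the requested stages in
dependency order (fdscan before tracts, fst tracks before pbs, ...) and
writes TSV/BED/JSON outputs plus a manifest recording the config hash,
seed and package version, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .panel import GenotypePanel, PopulationRoles, load_panel, make_windows
from .diversity import pi_track, rod
from .fst import fst_track, global_fst
from .introgression import call_tracts, d_statistic, fd_significance, fd_track, pgi
from .ils import IlsParams, expected_tract_length, ils_probability_from_params, \
    recomb_rate_from_cm_per_mb
from .ld import decay_curve, half_decay, ne_series
from .selection import pbs_track, percentile_outliers
from .simulate import Scenario, simulate, write_bed

logger = logging.getLogger(__name__)

STAGES = ("simulate", "diversity", "fst", "dstat", "fdscan", "tracts",
          "pbs", "rod", "ld", "ils")


class ConfigError(ValueError):
    pass


@dataclass
class ScanConfig:
    stages: list[str] = field(default_factory=lambda: ["dstat", "fdscan", "tracts"])
    vcf: str | None = None
    popmap: str | None = None
    out_dir: str = "introscan_out"
    seed: int = 1
    min_called_fraction: float = 0.9
    # roles for D / f_d
    p1: str = "P1"
    p2: str = "P2"
    p3: str = "P3"
    outgroup: str = "ANCESTRAL"
    # window parameters
    window: int = 100_000
    step: int = 50_000
    min_snps: int = 500
    block_size: int = 5_000_000
    alpha: float = 0.05
    top_fraction: float = 0.01
    # diversity / rod groups
    pop_a: str | None = None
    pop_b: str | None = None
    improved: str | None = None
    landrace: str | None = None
    # pbs
    focal: str | None = None
    ref1: str | None = None
    ref2: str | None = None
    # ld
    ld_population: str | None = None
    ld_max_distance: int = 300_000
    ld_bin_width: int = 10_000
    cm_per_mb: float = 1.5
    # ils
    ils_divergence_years: float | None = None
    ils_generation_years: float = 3.0
    ils_rec_cm_per_mb: float = 1.5
    ils_tract_bp: float | None = None
    # simulate
    scenario: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; known: {STAGES}")
        if "tracts" in self.stages and "fdscan" not in self.stages:
            raise ConfigError("stage 'tracts' requires stage 'fdscan'")
        needs_panel = set(self.stages) - {"ils", "simulate"}
        if needs_panel and self.vcf is None and "simulate" not in self.stages:
            raise ConfigError(f"stages {sorted(needs_panel)} require a VCF input")
        for name in ("window", "step", "min_snps", "block_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def _write_track(track: pd.DataFrame, path: Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: ScanConfig) -> dict:
    """Execute the configured stages; returns a result bundle dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    summary: dict = {}

    panel: GenotypePanel | None = None
    if "simulate" in config.stages:
        sc = Scenario(**{**config.scenario, "seed": config.seed})
        sim = simulate(sc, out / "sim")
        panel = sim["panel"]
        results["simulate"] = sim
        summary["simulate"] = {"seg_sites": sim["truth"].seg_sites,
                               "union_tract_bp": sim["truth"].union_bp()}
    elif config.vcf is not None:
        panel = load_panel(config.vcf, config.popmap, config.min_called_fraction)

    windows = None
    if panel is not None:
        windows = make_windows(panel, config.window, config.step, config.min_snps)

    if "diversity" in config.stages:
        pops = [p for p in (config.pop_a, config.pop_b) if p] or panel.populations
        for pop in pops:
            track = pi_track(panel, pop, windows)
            _write_track(track, out / f"pi_{pop}.tsv")
            results[f"pi_{pop}"] = track

    if "fst" in config.stages or "pbs" in config.stages:
        pairs = []
        if config.pop_a and config.pop_b:
            pairs.append((config.pop_a, config.pop_b))
        if "pbs" in config.stages:
            if not (config.focal and config.ref1 and config.ref2):
                raise ConfigError("pbs requires focal, ref1 and ref2")
            pairs += [(config.focal, config.ref1), (config.focal, config.ref2),
                      (config.ref1, config.ref2)]
        fst_tracks = {}
        for a, b in dict.fromkeys(pairs):
            track = fst_track(panel, a, b, windows)
            fst_tracks[(a, b)] = track
            _write_track(track, out / f"fst_{a}_{b}.tsv")
            summary[f"global_fst_{a}_{b}"] = global_fst(panel, a, b)
        results["fst"] = fst_tracks
        if "fst" in config.stages and config.pop_a and config.pop_b:
            thr, flagged = percentile_outliers(
                fst_tracks[(config.pop_a, config.pop_b)], config.top_fraction)
            write_bed(flagged[flagged.outlier][["chrom", "start", "end"]],
                      out / f"fst_top_{config.pop_a}_{config.pop_b}.bed")
            summary["fst_outlier_threshold"] = thr

    roles = None
    if {"dstat", "fdscan"} & set(config.stages):
        roles = PopulationRoles(config.p1, config.p2, config.p3, config.outgroup)

    if "dstat" in config.stages:
        res = d_statistic(panel, roles, config.block_size)
        results["dstat"] = res
        summary["dstat"] = {"D": res.d, "se": res.se, "Z": res.z,
                            "sum_abba": res.sum_abba, "sum_baba": res.sum_baba,
                            "n_blocks": res.n_blocks}

    if "fdscan" in config.stages:
        track = fd_significance(fd_track(panel, roles, windows), config.alpha)
        _write_track(track, out / "fd_scan.tsv")
        results["fdscan"] = track
        genome_bp = sum(panel.span(c) for c in panel.chromosomes)
        summary["pgi"] = pgi(track, genome_bp)

    if "tracts" in config.stages:
        tracts = call_tracts(results["fdscan"], config.p2, config.p3)
        write_bed(tracts.intervals, out / "introgression_tracts.bed")
        results["tracts"] = tracts
        summary["tracts"] = {"n_tracts": tracts.n_tracts,
                             "accumulated_bp": tracts.accumulated_bp,
                             "ris_proportion": tracts.ris_proportion,
                             "per_chrom_bp": tracts.per_chrom_bp}

    if "pbs" in config.stages:
        ft = results["fst"]
        track = pbs_track(ft[(config.focal, config.ref1)],
                          ft[(config.focal, config.ref2)],
                          ft[(config.ref1, config.ref2)])
        thr, flagged = percentile_outliers(track, config.top_fraction)
        _write_track(flagged, out / "pbs.tsv")
        write_bed(flagged[flagged.outlier][["chrom", "start", "end"]],
                  out / "pbs_top.bed")
        results["pbs"] = flagged
        summary["pbs"] = {"outlier_threshold": thr,
                          "n_outliers": int(flagged.outlier.sum())}

    if "rod" in config.stages:
        if not (config.improved and config.landrace):
            raise ConfigError("rod requires 'improved' and 'landrace' groups")
        track = rod(pi_track(panel, config.improved, windows),
                    pi_track(panel, config.landrace, windows))
        _write_track(track, out / "rod.tsv")
        results["rod"] = track

    if "ld" in config.stages:
        pop = config.ld_population or panel.populations[0]
        curve = decay_curve(panel, pop, config.ld_max_distance,
                            config.ld_bin_width, seed=config.seed)
        _write_track(curve, out / f"ld_decay_{pop}.tsv")
        hd = half_decay(curve)
        nes = ne_series(curve, config.cm_per_mb)
        _write_track(nes, out / f"ne_series_{pop}.tsv")
        results["ld"] = curve
        summary["ld"] = {"half_decay": hd}

    if "ils" in config.stages:
        if config.ils_divergence_years is None:
            raise ConfigError("ils requires ils_divergence_years")
        params = IlsParams(
            r=recomb_rate_from_cm_per_mb(config.ils_rec_cm_per_mb),
            divergence_time=config.ils_divergence_years,
            generation_time=config.ils_generation_years,
            m=config.ils_tract_bp,
        )
        length = expected_tract_length(params)
        summary["ils"] = {"expected_tract_length_bp": length}
        if config.ils_tract_bp is not None:
            summary["ils"]["p_ils_tract_longer"] = ils_probability_from_params(params)

    hashed = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": dataclasses.asdict(config),
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    results["summary"] = summary
    results["manifest"] = manifest
    return results
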