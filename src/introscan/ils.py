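"""Analytic incomplete-lineage-sorting tract-length model.

Under neutral recombination, the expected length of an ancestral sequence
tract shared across a species split is L = 1 / (r * t), with r the
recombination rate per bp per generation and t the branch length in
generations separating the two lineages — the TOTAL branch, i.e. twice the
divergence time (both descendant lineages accumulate recombination).  The
length of such a shared tract is approximately Gamma-distributed with
shape 2 and rate 1/L, so the probability that ILS alone produces a tract
longer than m is the Gamma survival function

    S(m) = 1 - GammaCDF(m; shape=2, rate=1/L) = (1 + m/L) * exp(-m/L).

A long observed haplotype shared with a diverged relative (e.g. tens of kb
against an expected L of tens of bp) therefore has an ILS probability that
underflows to zero, ruling out ILS in favour of introgression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IlsParams:
    """Units: r per bp per generation; times in years; tract length m in bp."""

    r: float
    divergence_time: float
    generation_time: float
    m: float | None = None

    def __post_init__(self) -> None:
        if self.r <= 0 or self.divergence_time <= 0 or self.generation_time <= 0:
            raise ValueError("r, divergence_time and generation_time must be positive")
        if self.m is not None and self.m <= 0:
            raise ValueError("tract length m must be positive")

    @property
    def branch_generations(self) -> float:
        """Total branch length: 2 x divergence time / generation time."""
        return 2.0 * self.divergence_time / self.generation_time


def recomb_rate_from_cm_per_mb(cm_per_mb: float) -> float:
    """Convert a cM/Mb rate to per-bp-per-generation (1.5 cM/Mb -> 1.5e-8)."""
    if cm_per_mb <= 0:
        raise ValueError("recombination rate must be positive")
    return cm_per_mb * 1e-8


def expected_tract_length(params: IlsParams) -> float:
    """Expected shared-tract length L = 1 / (r * t) in bp."""
    return 1.0 / (params.r * params.branch_generations)


def ils_probability(m: float, length: float) -> float:
    """P(shared tract > m) = (1 + m/L) exp(-m/L), Gamma(shape 2) survival."""
    if m <= 0 or length <= 0:
        raise ValueError("m and L must be positive")
    x = m / length
    with np.errstate(under="ignore"):
        return float((1.0 + x) * np.exp(-x))


def ils_probability_from_params(params: IlsParams) -> float:
    if params.m is None:
        raise ValueError("params.m (observed tract length) is required")
    return ils_probability(params.m, expected_tract_length(params))
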