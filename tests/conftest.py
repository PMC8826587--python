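import numpy as np
import pandas as pd
import pytest

import introscan as isc


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Toy fixture files plus the panel reloaded through the VCF reader."""
    out = tmp_path_factory.mktemp("toy")
    fx = isc.toy_fixture(out)
    fx["loaded"] = isc.load_panel(fx["vcf"], fx["popmap"], min_called_fraction=0.0)
    fx["expected"] = pd.read_csv(fx["expected"], sep="\t")
    return fx


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated data set with a pulse, shared across tests."""
    sc = isc.Scenario(seed=42, pulse_fraction=0.2, seq_len=4_000_000)
    panel, truth = isc.simulate_panel(sc)
    return sc, panel, truth


def panel_from_freqs(pop_sizes, site_rows, positions=None, chrom="chr1",
                     ancestral=None):
    """Build a panel from per-population diploid dosage rows.

    ``pop_sizes`` maps population -> number of diploids; ``site_rows`` is a
    list of dicts mapping population -> list of dosages (0/1/2/-1).
    """
    samples, popmap = [], {}
    for p, n in pop_sizes.items():
        for i in range(n):
            s = f"{p}_{i}"
            samples.append(s)
            popmap[s] = p
    geno = []
    for row in site_rows:
        g = []
        for p, n in pop_sizes.items():
            vals = row[p]
            assert len(vals) == n
            g.extend(vals)
        geno.append(g)
    n_sites = len(site_rows)
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if ancestral is None:
        ancestral = np.zeros(n_sites, dtype=np.int8)
    return isc.GenotypePanel(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(positions),
        geno=np.array(geno, dtype=np.int8),
        ancestral=np.asarray(ancestral, dtype=np.int8),
        samples=samples,
        popmap=popmap,
    )
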