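"""Panel loading, allele frequencies and the window grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introscan as isc
from introscan.panel import ANC_UNKNOWN

from conftest import panel_from_freqs

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


def write_vcf(tmp_path, body, popmap_samples=("S1", "S2", "S3", "S4")):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_HEADER + body)
    pm = tmp_path / "pm.tsv"
    pm.write_text("".join(f"{s}\tPOP{i % 2}\n" for i, s in enumerate(popmap_samples)))
    return vcf, pm


def row(pos, ref="A", alt="T", gts=("0/0", "0/1", "1/1", "0/0"), info="AA=A"):
    return f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"


class TestLoadPanel:
    def test_non_biallelic_records_dropped(self, tmp_path):
        body = "".join(row(p) for p in (100, 200, 300, 400, 500))
        body += row(600, alt="T,G", gts=("0/0", "1/2", "0/1", "0/0"))
        vcf, pm = write_vcf(tmp_path, body)
        panel = isc.load_panel(vcf, pm, min_called_fraction=0.9)
        assert panel.n_sites == 5
        assert len(panel.samples) == 4

    def test_high_missingness_site_dropped(self, tmp_path):
        body = "".join(row(p) for p in (100, 200, 300, 400))
        body += row(500, gts=("./.", "./.", "0/1", "0/0"))  # 0.5 < 0.9 called
        vcf, pm = write_vcf(tmp_path, body)
        panel = isc.load_panel(vcf, pm, min_called_fraction=0.9)
        assert panel.n_sites == 4

    def test_unsorted_vcf_names_offender(self, tmp_path):
        body = row(500) + row(100)
        vcf, pm = write_vcf(tmp_path, body)
        with pytest.raises(isc.PanelError, match="chr1:100"):
            isc.load_panel(vcf, pm)

    def test_missing_popmap_sample_listed(self, tmp_path):
        vcf, _ = write_vcf(tmp_path, row(100))
        pm = tmp_path / "bad.tsv"
        pm.write_text("S1\tA\nS2\tA\nGHOST\tB\n")
        with pytest.raises(isc.PanelError, match="GHOST"):
            isc.load_panel(vcf, pm)

    def test_ancestral_tag_parsed(self, tmp_path):
        body = row(100, info="AA=A") + row(200, info="AA=T") + row(300, info=".")
        vcf, pm = write_vcf(tmp_path, body)
        panel = isc.load_panel(vcf, pm, min_called_fraction=0.0)
        assert list(panel.ancestral) == [0, 1, ANC_UNKNOWN]

    def test_toy_fixture_round_trips_exactly(self, toy):
        assert np.array_equal(toy["loaded"].geno, toy["panel"].geno)
        assert np.array_equal(toy["loaded"].ancestral, toy["panel"].ancestral)
        assert np.array_equal(toy["loaded"].pos, toy["panel"].pos)


class TestAlleleFreqs:
    def panel(self, genos, anc=0):
        return panel_from_freqs({"A": 3, "B": 1}, [{"A": genos, "B": [0]}],
                                ancestral=[anc])

    def test_basic_frequency(self):
        p, n = isc.allele_freqs(self.panel([0, 1, 2]), "A", polarize=True)
        assert p[0] == 0.5 and n[0] == 6

    def test_alt_ancestral_complements(self):
        p, _ = isc.allele_freqs(self.panel([0, 1, 2], anc=1), "A", polarize=True)
        assert p[0] == 0.5  # 1 - 3/6

    def test_missing_excluded_from_both_counts(self):
        p, n = isc.allele_freqs(self.panel([0, 1, -1]), "A", polarize=True)
        assert p[0] == 0.25 and n[0] == 4

    def test_unknown_ancestral_excluded_not_zeroed(self):
        p, _ = isc.allele_freqs(self.panel([0, 1, 2], anc=-1), "A", polarize=True)
        assert np.isnan(p[0])

    def test_unpolarized_ignores_ancestral_flag(self):
        p, _ = isc.allele_freqs(self.panel([0, 1, 2], anc=1), "A", polarize=False)
        assert p[0] == 0.5

    def test_derived_plus_ancestral_equals_called(self, toy):
        panel = toy["panel"]
        for pop in panel.populations:
            p, n = isc.allele_freqs(panel, pop, polarize=True)
            ok = np.isfinite(p)
            derived = p[ok] * n[ok]
            ancestral = (1 - p[ok]) * n[ok]
            np.testing.assert_allclose(derived + ancestral, n[ok])


class TestMakeWindows:
    def grid_panel(self, span):
        rows = [{"A": [1], "B": [0]}] * 2
        return panel_from_freqs({"A": 1, "B": 1}, rows, positions=[1, span])

    def test_overlapping_grid_enumeration(self):
        w = isc.make_windows(self.grid_panel(250_000), 100_000, 50_000)
        assert list(map(tuple, w[["start", "end"]].values)) == [
            (1, 100_000), (50_001, 150_000), (100_001, 200_000), (150_001, 250_000)
        ]

    def test_non_overlapping_grid(self):
        w = isc.make_windows(self.grid_panel(30_000), 10_000)
        assert len(w) == 3
        assert (w.end - w.start + 1 == 10_000).all()

    def test_low_snp_window_flagged_but_listed(self, small_sim):
        _, panel, _ = small_sim
        w = isc.make_windows(panel, 100_000, 50_000, min_sites=10**6)
        assert len(w) > 0 and not w.usable.any()

    def test_site_counts_sum_on_disjoint_grid(self, small_sim):
        _, panel, _ = small_sim
        w = isc.make_windows(panel, 100_000)
        assert w.n_sites.sum() == panel.n_sites

    @given(k=st.integers(1, 6), step=st.integers(1, 5))
    @settings(max_examples=20, deadline=None)
    def test_interior_coverage_when_step_divides_size(self, k, step):
        size = k * step * 1_000
        span = 20 * size
        panel = self.grid_panel(span)
        w = isc.make_windows(panel, size, step * 1_000)
        for bp in (span // 2, span // 2 + 137, size + 1):
            n_cover = ((w.start <= bp) & (w.end >= bp)).sum()
            assert n_cover == size // (step * 1_000)

    def test_bad_size_step_rejected(self, small_sim):
        _, panel, _ = small_sim
        with pytest.raises(ValueError):
            isc.make_windows(panel, 1_000, 2_000)
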