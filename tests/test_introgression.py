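"""D statistic, f_d windows, significance, tracts, PGI."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import introscan as isc
from introscan import _bruteforce as bf
from introscan.introgression import IntrogressionError

from conftest import panel_from_freqs

ROLES = isc.PopulationRoles("P1", "P2", "P3")


def pattern_panel(n_abba=30, n_baba=10, spacing=1_000_000):
    """Haploid-like panel: frequencies fixed at 0/1, ABBA/BABA site counts."""
    abba = {"P1": [0], "P2": [2], "P3": [2], "OUT": [0]}
    baba = {"P1": [2], "P2": [0], "P3": [2], "OUT": [0]}
    rows = [abba] * n_abba + [baba] * n_baba
    pos = np.arange(1, len(rows) + 1) * spacing
    return panel_from_freqs({p: 1 for p in ("P1", "P2", "P3", "OUT")}, rows,
                            positions=pos)


class TestDStatistic:
    def test_count_formula_on_fixed_patterns(self):
        res = isc.d_statistic(pattern_panel(30, 10), ROLES, block_size=1_000_000)
        assert res.d == pytest.approx((30 - 10) / (30 + 10))
        assert res.sum_abba == pytest.approx(30)
        assert res.sum_baba == pytest.approx(10)

    def test_antisymmetry_under_p1_p2_swap(self, small_sim):
        _, panel, _ = small_sim
        d = isc.d_statistic(panel, ROLES, block_size=100_000).d
        d_swap = isc.d_statistic(
            panel, isc.PopulationRoles("P2", "P1", "P3"), block_size=100_000).d
        assert d_swap == pytest.approx(-d, abs=1e-12)

    def test_symmetric_panel_gives_exactly_zero(self):
        res = isc.d_statistic(pattern_panel(20, 20), ROLES, block_size=1_000_000)
        assert res.d == 0.0

    def test_matches_bruteforce_on_toy(self, toy):
        panel, exp = toy["panel"], toy["expected"]
        got = isc.d_statistic(panel, ROLES, block_size=2_500).d
        want = exp[exp.stat == "d"].value.iloc[0]
        assert got == pytest.approx(want, abs=1e-10)

    def test_too_few_blocks_rejected(self, toy):
        with pytest.raises(IntrogressionError, match="block"):
            isc.d_statistic(toy["panel"], ROLES, block_size=10**9)

    def test_zero_denominator_rejected(self):
        rows = [{"P1": [0], "P2": [0], "P3": [0], "OUT": [0]}] * 30
        panel = panel_from_freqs({p: 1 for p in ("P1", "P2", "P3", "OUT")}, rows)
        with pytest.raises(IntrogressionError, match="undefined"):
            isc.d_statistic(panel, ROLES, block_size=100)

    def test_outgroup_population_mode_runs_unpolarized(self, small_sim):
        _, panel, _ = small_sim
        res = isc.d_statistic(
            panel, isc.PopulationRoles("P1", "P2", "P3", "OUT"), block_size=100_000)
        assert np.isfinite(res.z)

    def test_jackknife_se_tracks_replicate_spread(self):
        """Jackknife se vs empirical SD over independent replicate genomes."""
        ds, ses = [], []
        for seed in range(12):
            panel, _ = isc.simulate_panel(
                isc.Scenario(seed=300 + seed, pulse_fraction=0.0, seq_len=4_000_000))
            r = isc.d_statistic(panel, ROLES, block_size=100_000)
            ds.append(r.d)
            ses.append(r.se)
        ratio = np.mean(ses) / np.std(ds)
        assert 1 / 1.5 < ratio < 1.5


class TestFdWindow:
    def test_single_site_martin_formula(self):
        # p1=0, p2=0.5, p3=1, O ancestral -> num 0.5, den 1
        rows = [{"P1": [0, 0], "P2": [1, 1], "P3": [2, 2], "OUT": [0, 0]}]
        panel = panel_from_freqs({p: 2 for p in ("P1", "P2", "P3", "OUT")}, rows)
        raw, clipped = isc.fd_window(panel, ROLES, "chr1", 1, 1_000)
        assert raw == pytest.approx(0.5)
        assert clipped == pytest.approx(0.5)

    def test_negative_window_d_clipped_to_zero(self):
        panel = pattern_panel(5, 20, spacing=10)
        raw, clipped = isc.fd_window(panel, ROLES, "chr1", 1, 1_000)
        assert raw < 0
        assert clipped == 0.0

    def test_complete_sharing_gives_one(self):
        rows = [{"P1": [0], "P2": [2], "P3": [2], "OUT": [0]}] * 5
        panel = panel_from_freqs({p: 1 for p in ("P1", "P2", "P3", "OUT")}, rows,
                                 positions=np.arange(1, 6) * 10)
        raw, clipped = isc.fd_window(panel, ROLES, "chr1", 1, 100)
        assert raw == pytest.approx(1.0)
        assert clipped == pytest.approx(1.0)

    def test_matches_bruteforce_on_toy_windows(self, toy):
        panel, exp = toy["panel"], toy["expected"]
        for r in exp[exp.stat == "fd"].itertuples():
            _, clipped = isc.fd_window(panel, ROLES, r.chrom, r.start, r.end)
            assert clipped == pytest.approx(r.value, abs=1e-10)

    def test_unusable_window_gets_nan(self, toy):
        w = isc.make_windows(toy["panel"], 25_000, min_sites=10**6)
        track = isc.fd_track(toy["panel"], ROLES, w)
        assert track.fd.isna().all()


class TestSignificance:
    def test_bh_matches_hand_computation(self):
        p = [0.01, 0.02, 0.04, 0.5]
        want = [0.04, 0.04, 0.04 * 4 / 3, 0.5]
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, want, atol=1e-12)
        np.testing.assert_allclose(bf.bh_adjust(p), want, atol=1e-12)

    def _track(self, fds):
        n = len(fds)
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(n) * 100 + 1,
            "end": np.arange(n) * 100 + 100,
            "n_sites": 10, "usable": True, "raw_fd": fds, "fd": fds,
            "window_d": 0.1, "numerator": 1.0, "denominator": 1.0,
        })

    def test_constant_fd_raises(self):
        with pytest.raises(IntrogressionError, match="identical"):
            isc.fd_significance(self._track([0.2] * 12))

    def test_too_few_windows_raises(self):
        with pytest.raises(IntrogressionError, match="10 usable"):
            isc.fd_significance(self._track([0.1, 0.2]))

    def test_outlier_window_flagged(self):
        fds = [0.0] * 30 + [0.95]
        out = isc.fd_significance(self._track(fds))
        assert bool(out.significant.iloc[-1])
        assert out.significant.sum() == 1
        assert (out.q.dropna() >= out.p.dropna()).all()

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(3)
        out = isc.fd_significance(self._track(rng.random(50)))
        s = out.dropna(subset=["p"]).sort_values("p")
        assert (np.diff(s.q) >= -1e-12).all()


class TestTractsAndPgi:
    def _sig_track(self, wins, sig):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [w[0] for w in wins], "end": [w[1] for w in wins],
            "n_sites": 10, "usable": True, "fd": 0.5, "significant": sig,
        })

    def test_bookended_windows_merge(self):
        t = self._sig_track([(100_001, 200_000), (150_001, 250_000)], [True, True])
        ts = isc.call_tracts(t)
        assert ts.n_tracts == 1
        assert ts.accumulated_bp == 150_000

    def test_gap_splits_tracts(self):
        t = self._sig_track(
            [(1, 100), (201, 300), (401, 500)], [True, False, True])
        assert isc.call_tracts(t).n_tracts == 2

    def test_accumulated_bp_matches_bitmap_union(self):
        rng = np.random.default_rng(9)
        wins = [(s, s + 999) for s in rng.integers(1, 50_000, 30)]
        sig = rng.random(30) < 0.5
        ts = isc.call_tracts(self._sig_track(wins, sig))
        bitmap = np.zeros(60_000, dtype=bool)
        for (s, e), flag in zip(wins, sig):
            if flag:
                bitmap[s:e + 1] = True
        assert ts.accumulated_bp == int(bitmap.sum())

    def test_ris_proportion_uses_scanned_footprint(self):
        t = self._sig_track([(1, 100), (101, 200)], [True, False])
        ts = isc.call_tracts(t)
        assert ts.ris_proportion == pytest.approx(100 / 200)

    def _pgi_track(self, fds, span=100_000):
        n = len(fds)
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * span + 1,
            "end": (np.arange(n) + 1) * span,
            "n_sites": 10, "usable": True, "fd": fds,
        })

    def test_pgi_weighted_sum(self):
        track = self._pgi_track([0.5, 0.25] + [0.0] * 8)
        assert isc.pgi(track, 1_000_000) == pytest.approx(0.075)

    def test_pgi_bounds(self):
        assert isc.pgi(self._pgi_track([0.0] * 10), 1_000_000) == 0.0
        assert isc.pgi(self._pgi_track([1.0] * 10), 1_000_000) == pytest.approx(1.0)

    def test_pgi_zero_genome_rejected(self):
        with pytest.raises(IntrogressionError):
            isc.pgi(self._pgi_track([0.1]), 0)
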