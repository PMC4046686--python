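import numpy as np
import pytest

import peakdeconv as pdc


def make_signal(kernel, placements, nbins=300):
    sig = np.zeros(nbins)
    m = len(kernel.values)
    for shift, coef in placements:
        sig[shift : shift + m] += coef * kernel.values
    return sig


class TestTileWindows:
    def test_three_window_tiling(self):
        wins = pdc.tile_windows(50_000, kernel_support=1500, window_len=20_000)
        assert [(w.start, w.end) for w in wins] == [
            (0, 20_000),
            (18_500, 38_500),
            (37_000, 50_000),
        ]

    def test_short_chromosome_single_window(self):
        (w,) = pdc.tile_windows(10_000, kernel_support=1500, window_len=20_000)
        assert (w.start, w.end, w.core_start, w.core_end) == (0, 10_000, 0, 10_000)

    @pytest.mark.parametrize("chrom_len", [10_000, 50_000, 50_001, 123_457])
    def test_cores_tile_chromosome_exactly(self, chrom_len):
        wins = pdc.tile_windows(chrom_len, kernel_support=1500, window_len=20_000)
        assert wins[0].core_start == 0
        assert wins[-1].core_end == chrom_len
        for a, b in zip(wins, wins[1:]):
            assert a.core_end == b.core_start
        for w in wins:
            assert w.start <= w.core_start and w.core_end <= w.end

    def test_window_overlap_covers_kernel_support(self):
        wins = pdc.tile_windows(100_000, kernel_support=1500, window_len=20_000)
        for a, b in zip(wins, wins[1:]):
            assert a.end - b.start >= 1500

    def test_too_small_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            pdc.tile_windows(50_000, kernel_support=12_000, window_len=20_000)


class TestDeconvolveWindow:
    def test_exact_single_copy(self, kernel340):
        sig = make_signal(kernel340, [(60, 2.5)])
        (site,) = pdc.deconvolve_window(sig, kernel340)
        assert site.position == (60 + kernel340.mode_bin) * 10
        assert site.coefficient == pytest.approx(2.5, abs=1e-9)

    def test_all_zero_signal(self, kernel340):
        assert pdc.deconvolve_window(np.zeros(200), kernel340) == []

    def test_signal_shorter_than_kernel(self, kernel340):
        with pytest.raises(ValueError, match="shorter"):
            pdc.deconvolve_window(np.zeros(10), kernel340)

    def test_two_separated_copies_match_oracle(self, kernel340):
        m = len(kernel340.values)
        sig = make_signal(kernel340, [(20, 2.0), (20 + m + 10, 4.0)], nbins=2 * m + 80)
        got = pdc.deconvolve_window(sig, kernel340)
        oracle = pdc.brute_force_deconvolve(sig, kernel340, max_sites=2)
        assert [s.position for s in got] == [s.position for s in oracle]
        for g, o in zip(got, oracle):
            assert g.coefficient == pytest.approx(o.coefficient, abs=1e-6)

    def test_half_support_overlap(self, kernel340):
        m = len(kernel340.values)
        sig = make_signal(kernel340, [(40, 2.0), (40 + m // 2, 4.0)], nbins=2 * m + 80)
        got = pdc.deconvolve_window(sig, kernel340)
        assert len(got) == 2
        truth = sorted([(40 + kernel340.mode_bin) * 10, (40 + m // 2 + kernel340.mode_bin) * 10])
        for site, (pos, coef) in zip(got, zip(truth, [2.0, 4.0])):
            assert abs(site.position - pos) <= 10
            assert site.coefficient == pytest.approx(coef, rel=0.05)

    def test_min_coef_stops_fitting(self, kernel340):
        sig = make_signal(kernel340, [(30, 10.0), (150, 1.0)])
        got = pdc.deconvolve_window(sig, kernel340, min_coef=5.0)
        assert len(got) == 1
        assert got[0].coefficient == pytest.approx(10.0, abs=1e-6)

    def test_max_sites_cap(self, kernel340):
        m = len(kernel340.values)
        placements = [(i * (m + 5), 5.0) for i in range(4)]
        sig = make_signal(kernel340, placements, nbins=4 * (m + 5) + m)
        got = pdc.deconvolve_window(sig, kernel340, max_sites=2)
        assert len(got) <= 2

    def test_translation_equivariance(self, kernel340):
        sig = make_signal(kernel340, [(40, 3.0), (120, 5.0)], nbins=400)
        shifted = np.roll(sig, 17)
        a = pdc.deconvolve_window(sig, kernel340)
        b = pdc.deconvolve_window(shifted, kernel340)
        assert [s.position + 170 for s in a] == [s.position for s in b]
        for x, y in zip(a, b):
            assert x.coefficient == pytest.approx(y.coefficient, abs=1e-9)

    def test_offset_and_chrom_propagate(self, kernel340):
        sig = make_signal(kernel340, [(60, 2.0)])
        (site,) = pdc.deconvolve_window(sig, kernel340, offset=50_000, chrom="chr9")
        assert site.chrom == "chr9"
        assert site.position == 50_000 + (60 + kernel340.mode_bin) * 10

    def test_reconstruction_identity(self, kernel340):
        rng = np.random.default_rng(0)
        sig = make_signal(kernel340, [(30, 8.0), (140, 12.0)], nbins=300)
        sig += rng.poisson(1.0, 300)
        sites = pdc.deconvolve_window(sig, kernel340, min_coef=2.0)
        model = np.zeros_like(sig)
        m = len(kernel340.values)
        for s in sites:
            a = s.position // 10 - kernel340.mode_bin
            model[a : a + m] += s.coefficient * kernel340.values
        resid = sig - model
        # residual plus fitted component reproduces the signal bin-exactly
        assert np.allclose(resid + model, sig)


class TestMergeWindowCalls:
    def make_windows(self):
        return pdc.tile_windows(50_000, kernel_support=1500, window_len=20_000)

    def test_core_rule_deduplicates(self, kernel340):
        wins = self.make_windows()
        # same site seen by both overlapping windows; core of window 1 owns it
        site = pdc.CandidateSite("chr1", 19_500, 5.0)
        merged = pdc.merge_window_calls([[site], [site], []], wins, 10)
        assert merged == [site]

    def test_nearby_sites_collapse_to_larger(self, kernel340):
        wins = self.make_windows()
        a = pdc.CandidateSite("chr1", 5_000, 3.0)
        b = pdc.CandidateSite("chr1", 5_010, 7.0)
        merged = pdc.merge_window_calls([[a, b], [], []], wins, 10)
        assert merged == [b]

    def test_distant_sites_both_kept(self):
        wins = self.make_windows()
        a = pdc.CandidateSite("chr1", 5_000, 3.0)
        b = pdc.CandidateSite("chr1", 5_050, 7.0)
        merged = pdc.merge_window_calls([[a, b], [], []], wins, 10)
        assert merged == [a, b]

    def test_boundary_belongs_to_half_open_core(self):
        wins = self.make_windows()
        boundary = wins[0].core_end
        site = pdc.CandidateSite("chr1", boundary, 5.0)
        merged = pdc.merge_window_calls([[site], [site], []], wins, 10)
        assert merged == [site]  # only window 1's core contains it

    def test_window_decomposition_invariance(self, kernel340):
        """Calls on one long window equal calls assembled from tiled windows
        when every site sits away from core boundaries."""
        chrom_len = 60_000
        nbins = chrom_len // 10
        m = len(kernel340.values)
        sig = np.zeros(nbins)
        shifts = [500, 2100, 3900, 5200]
        for i, sh in enumerate(shifts):
            sig[sh : sh + m] += (5.0 + i) * kernel340.values
        whole = pdc.deconvolve_window(sig, kernel340, min_coef=2.0, offset=0, chrom="c")

        wins = pdc.tile_windows(chrom_len, kernel340.support_len, 20_000)
        per_window = []
        for w in wins:
            seg = sig[w.start // 10 : -(-w.end // 10)]
            per_window.append(
                pdc.deconvolve_window(seg, kernel340, min_coef=2.0, offset=w.start, chrom="c")
            )
        tiled = pdc.merge_window_calls(per_window, wins, 10)
        assert [s.position for s in tiled] == [s.position for s in whole]
        for a, b in zip(tiled, whole):
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-9)
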