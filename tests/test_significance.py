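import numpy as np
import pytest
from scipy.stats import chi2, kstest

import peakdeconv as pdc
from peakdeconv import significance as sig
from peakdeconv.alignment_io import CoverageProfile


def profile_from(vector, bin_size=10, chrom="chr1"):
    return CoverageProfile(
        bin_size=bin_size,
        data={chrom: np.asarray(vector, dtype=np.float64)},
        elongation_used=150,
        sizes={chrom: len(vector) * bin_size},
    )


def null_of(values):
    v = np.sort(np.asarray(values, dtype=np.float64))
    return sig.NullDistribution(v, n_boot=len(v), seed=None)


class TestComputeResiduals:
    def test_exact_copy_leaves_zero(self, kernel340):
        m = len(kernel340.values)
        v = np.zeros(300)
        v[50 : 50 + m] = 4.0 * kernel340.values
        prof = profile_from(v)
        call = pdc.CandidateSite("chr1", (50 + kernel340.mode_bin) * 10, 4.0)
        resid = sig.compute_residuals(prof, [call], kernel340)
        assert np.allclose(resid["chr1"], 0.0, atol=1e-12)

    def test_no_calls_returns_profile(self, kernel340):
        prof = profile_from(np.arange(200, dtype=float))
        resid = sig.compute_residuals(prof, [], kernel340)
        assert np.array_equal(resid["chr1"], prof.data["chr1"])

    def test_conservation(self, kernel340):
        rng = np.random.default_rng(0)
        v = rng.poisson(2.0, 400).astype(float)
        prof = profile_from(v)
        calls = [
            pdc.CandidateSite("chr1", (60 + kernel340.mode_bin) * 10, 3.0),
            pdc.CandidateSite("chr1", (200 + kernel340.mode_bin) * 10, 5.0),
        ]
        resid = sig.compute_residuals(prof, calls, kernel340)
        m = len(kernel340.values)
        model = np.zeros(400)
        for c in calls:
            a = c.position // 10 - kernel340.mode_bin
            model[a : a + m] += c.coefficient * kernel340.values
        assert np.allclose(resid["chr1"] + model, v)


class TestBootstrapNull:
    def test_zero_segment_all_zero_maxima(self, kernel340):
        null = sig.bootstrap_null(np.zeros(200), kernel340, n_boot=20, seed=0)
        assert np.all(null.values == 0.0)

    def test_seeded_reproducibility(self, kernel340):
        rng = np.random.default_rng(3)
        seg = rng.poisson(1.0, 300).astype(float)
        a = sig.bootstrap_null(seg, kernel340, n_boot=25, seed=42)
        b = sig.bootstrap_null(seg, kernel340, n_boot=25, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_constant_segment_positive_maxima(self, kernel340):
        null = sig.bootstrap_null(np.full(300, 2.0), kernel340, n_boot=10, seed=1)
        assert np.all(null.values > 0)

    def test_short_segment_errors(self, kernel340):
        with pytest.raises(ValueError, match="shorter"):
            sig.bootstrap_null(np.zeros(20), kernel340, n_boot=5, seed=0)


class TestEmpiricalP:
    def test_exceeds_all(self):
        assert sig.empirical_p(1000.0, null_of(np.arange(99))) == pytest.approx(0.01)

    def test_zero_coefficient_is_one(self):
        assert sig.empirical_p(0.0, null_of(np.arange(99))) == 1.0

    def test_tie_counts_as_exceeding(self):
        null = null_of(np.arange(99))
        assert sig.empirical_p(98.0, null) == pytest.approx(2 / 100)

    def test_monotone_in_coefficient(self):
        null = null_of(np.arange(99))
        ps = [sig.empirical_p(c, null) for c in np.linspace(0, 120, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestLocalPvalues:
    def test_clean_background_gives_floor(self, kernel340):
        v = np.zeros(3000)
        site = pdc.CandidateSite("chr1", 15_000, 50.0)
        a = site.position // 10 - kernel340.mode_bin
        m = len(kernel340.values)
        v[a : a + m] += 50.0 * kernel340.values  # only the site itself
        ps = sig.local_pvalues(site, {"chr1": v}, kernel340, n_boot=50, seed=0)
        assert set(ps) == {5000, 10_000, 15_000}
        assert all(p == pytest.approx(1 / 51) for p in ps.values())

    def test_clipped_window_near_chrom_start(self, kernel340):
        v = np.zeros(3000)
        site = pdc.CandidateSite("chr1", 300, 10.0)
        ps = sig.local_pvalues(
            site, {"chr1": v}, kernel340, window_sizes=(1000, 10_000), n_boot=20, seed=0
        )
        assert ps[1000] == 1.0  # clipped below twice the kernel length
        assert ps[10_000] <= 1.0

    def test_deterministic_across_calls(self, kernel340):
        rng = np.random.default_rng(9)
        v = rng.poisson(1.0, 4000).astype(float)
        site = pdc.CandidateSite("chr1", 20_000, 6.0)
        a = sig.local_pvalues(site, {"chr1": v}, kernel340, n_boot=30, seed=7)
        b = sig.local_pvalues(site, {"chr1": v}, kernel340, n_boot=30, seed=7)
        assert a == b


class TestGlobalPvalue:
    def test_zero_profile_floor_for_positive_coefficient(self, kernel340):
        data = {"chr1": np.zeros(30_000)}
        p = sig.global_pvalue(
            pdc.CandidateSite("chr1", 1000, 5.0), data, kernel340, n_boot=50, seed=0
        )
        assert p == pytest.approx(1 / 51)

    def test_zero_coefficient_is_one(self, kernel340):
        data = {"chr1": np.zeros(30_000)}
        p = sig.global_pvalue(
            pdc.CandidateSite("chr1", 1000, 0.0), data, kernel340, n_boot=50, seed=0
        )
        assert p == 1.0

    def test_seed_determinism(self, kernel340):
        rng = np.random.default_rng(4)
        data = {"chr1": rng.poisson(1.0, 30_000).astype(float)}
        n1 = sig.build_global_null(data, kernel340, n_boot=25, seed=3)
        n2 = sig.build_global_null(data, kernel340, n_boot=25, seed=3)
        assert np.array_equal(n1.values, n2.values)


class TestFisherCombine:
    def test_all_ones(self):
        assert sig.fisher_combine([1.0, 1.0, 1.0, 1.0]) == 1.0

    @pytest.mark.parametrize("p", [0.9, 0.5, 0.1, 0.01, 1e-6])
    def test_single_p_identity(self, p):
        assert abs(sig.fisher_combine([p]) - p) < 1e-12

    def test_four_equal_pvalues_closed_form(self):
        x2 = -2.0 * 4 * np.log(0.05)
        expected = chi2.sf(x2, 8)
        got = sig.fisher_combine([0.05] * 4)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.00233, rel=5e-3)

    def test_cross_check_against_scipy(self):
        from scipy.stats import combine_pvalues

        ps = [0.2, 0.03, 0.7, 0.11]
        _, expected = combine_pvalues(ps, method="fisher")
        assert sig.fisher_combine(ps) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.2], []])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            sig.fisher_combine(bad)

    def test_uniform_inputs_give_uniform_output(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(size=(10_000, 4))
        combined = [sig.fisher_combine(row) for row in u]
        assert kstest(combined, "uniform").pvalue > 0.01


class TestControlCorrect:
    def make_site(self, kernel, coef=10.0):
        return pdc.CandidateSite("chr1", 15_000, coef)

    def test_flat_control_adds_confidence(self, kernel340):
        ctrl = profile_from(np.zeros(3000))
        site = self.make_site(kernel340)
        p = sig.control_correct(site, 0.05, ctrl, kernel340, n_boot=50, seed=0)
        assert p <= 0.05

    def test_strong_control_pattern_vetoes(self, kernel340):
        v = np.zeros(3000)
        a = 15_000 // 10 - kernel340.mode_bin
        m = len(kernel340.values)
        v[a : a + m] += 20.0 * kernel340.values  # control pattern above IP height
        ctrl = profile_from(v)
        site = self.make_site(kernel340, coef=10.0)
        assert sig.control_correct(site, 0.01, ctrl, kernel340, n_boot=20, seed=0) == 1.0

    def test_monotone_in_control_height(self, kernel340):
        ps = []
        for beta_c in (0.0, 4.0, 12.0):
            v = np.zeros(3000)
            a = 15_000 // 10 - kernel340.mode_bin
            m = len(kernel340.values)
            v[a : a + m] += beta_c * kernel340.values
            ps.append(
                sig.control_correct(
                    self.make_site(kernel340, 10.0), 0.05,
                    profile_from(v), kernel340, n_boot=30, seed=0,
                )
            )
        assert ps[0] <= ps[1] <= ps[2]
        assert ps[2] == 1.0

    def test_unusable_window_returns_input(self, kernel340):
        ctrl = profile_from(np.zeros(40))  # far too short
        site = pdc.CandidateSite("chr1", 200, 10.0)
        assert sig.control_correct(site, 0.07, ctrl, kernel340, n_boot=10, seed=0) == 0.07


class TestPvalueSummary:
    def test_deciles_of_ten_calls(self):
        ps = [0.1 * i for i in range(1, 11)]
        qtab, _ = sig.pvalue_summary(ps)
        median = qtab.loc[qtab["quantile"] == 0.5, "p_combined"].iloc[0]
        assert median == pytest.approx(0.55)

    def test_single_call_all_quantiles_equal(self):
        qtab, ttab = sig.pvalue_summary([0.2])
        assert (qtab["p_combined"] == 0.2).all()
        assert (ttab["n_p_le_threshold"] >= 0).all()

    def test_row_count_matches_request(self):
        qtab, _ = sig.pvalue_summary([0.5, 0.6], quantiles=(0.25, 0.5, 0.75))
        assert len(qtab) == 3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sig.pvalue_summary([])
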