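"""Periodicity test panel: periodogram, Fisher's g, autocorrelation, Pt-test."""

import math

import numpy as np
import pandas as pd
import pytest

from circaedes.periodicity import (
    autocorr_cutoff,
    circadian_autocorr_test,
    circular_autocorrelation,
    fisher_g,
    fisher_g_pvalue,
    n_pt_permutations,
    panel_summary,
    periodicity_safe_permutation,
    periodogram,
    pt_test,
    run_test_panel,
)


def dft_periodogram_oracle(y):
    """Brute-force O(N^2) DFT sums: I(w_k) = (1/N)|sum x_t e^{-i w_k t}|^2."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = y - y.mean()
    out = []
    for k in range(1, n // 2 + 1):
        w = 2 * np.pi * k / n
        s = sum(x[t] * np.exp(-1j * w * t) for t in range(n))
        out.append(abs(s) ** 2 / n)
    return np.array(out)


class TestPeriodogram:
    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 17))
            y = rng.standard_normal(n)
            pg = periodogram(y)
            assert np.allclose(pg.intensities, dft_periodogram_oracle(y), atol=1e-10)

    def test_constant_series_all_zero(self):
        assert np.allclose(periodogram(np.full(12, 5.0)).intensities, 0.0)

    def test_pure_cosine_concentrates_in_circadian_bin(self):
        t = np.arange(12)
        y = np.cos(2 * np.pi * 2 * t / 12)  # k = 2: the 24 h bin of a 48 h series
        pg = periodogram(y)
        assert pg.intensities[1] > 1e-10
        others = np.delete(pg.intensities, 1)
        assert np.allclose(others, 0.0, atol=1e-10)
        assert pg.circadian_bin(6) == 2

    def test_parseval_identity(self):
        """sum c_k I(w_k) = (N/2) var(Y), Nyquist weighted 1/2 for even N."""
        rng = np.random.default_rng(8)
        for n in (8, 11, 12, 16):
            y = rng.standard_normal(n)
            pg = periodogram(y)
            w = np.ones(len(pg.intensities))
            if n % 2 == 0:
                w[-1] = 0.5
            assert float(w @ pg.intensities) == pytest.approx(
                n / 2 * np.var(y), rel=1e-10
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            periodogram([1.0, 2.0, 3.0])


class TestFisherG:
    def test_pure_cosine_g_one_p_zero(self):
        t = np.arange(12)
        res = fisher_g(periodogram(np.cos(2 * np.pi * 2 * t / 12)))
        assert res.g == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)
        assert res.peak_index == 2

    def test_hand_evaluated_exact_sum(self):
        # n=6, g=0.5: b=2, p = C(6,1) 0.5^5 - C(6,2) 0^5 = 6/32
        assert fisher_g_pvalue(0.5, 6) == pytest.approx(0.1875)
        # n=5, g=0.3: b=3, p = 5(0.7)^4 - 10(0.4)^4 + 10(0.1)^4
        expected = 5 * 0.7**4 - 10 * 0.4**4 + 10 * 0.1**4
        assert fisher_g_pvalue(0.3, 5) == pytest.approx(expected)

    def test_p_monotone_decreasing_in_g(self):
        gs = np.linspace(0.21, 0.99, 40)
        ps = [fisher_g_pvalue(g, 6) for g in gs]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            fisher_g(periodogram(np.full(12, 2.0)))

    def test_nyquist_excluded_by_default_for_even_n(self):
        y = np.random.default_rng(9).standard_normal(12)
        res = fisher_g(periodogram(y))
        assert res.n == 5  # 6 ordinates minus the Nyquist
        assert fisher_g(periodogram(y), include_nyquist=True).n == 6


class TestAutocorrelation:
    def setup_method(self):
        t = np.arange(12) * 4.0
        self.cos24 = np.cos(2 * np.pi * t / 24.0)

    def test_full_period_lag_gives_unity(self):
        assert circular_autocorrelation(self.cos24, 6).R == pytest.approx(1.0)

    def test_half_period_lag_gives_antiphase(self):
        assert circular_autocorrelation(self.cos24, 3).R == pytest.approx(-1.0)

    def test_matches_explicit_wraparound_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            y = rng.standard_normal(12)
            k = int(rng.integers(1, 12))
            # brute-force pairing: f = i+k if i+k < N else i+k-N
            pairs = [(y[i], y[i + k if i + k < 12 else i + k - 12]) for i in range(12)]
            a, b = map(np.array, zip(*pairs))
            r_oracle = np.corrcoef(a, b)[0, 1]
            assert circular_autocorrelation(y, k).R == pytest.approx(r_oracle)

    @pytest.mark.parametrize("period, lag", [(24.0, 6), (12.0, 3)])
    def test_circadian_lag_from_sampling(self, period, lag):
        res = circadian_autocorr_test(self.cos24 + 0.01 * np.arange(12), 4.0, period)
        assert res.lag == lag

    def test_non_divisible_period_rejected(self):
        with pytest.raises(ValueError):
            circadian_autocorr_test(self.cos24, 4.0, period=18.0)

    def test_cutoff_from_t_distribution(self):
        # n=12: t_{0.975,10} = 2.2281..., r = t/sqrt(10 + t^2)
        t = 2.228138852
        assert autocorr_cutoff(12) == pytest.approx(t / math.sqrt(10 + t * t), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            circular_autocorrelation(np.ones(12), 6)


class TestPtTest:
    def test_permutation_count_rule(self):
        assert n_pt_permutations(12) == 100  # min(12!, 100)
        assert n_pt_permutations(3) == 6  # min(3!, 100)

    def test_swaps_never_span_one_period(self):
        """Every executed swap pair (a, b) has |a - b| != p."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            perm, swaps = periodicity_safe_permutation(rng, 12, 6)
            assert len(swaps) == 12
            assert all(a != b and abs(a - b) != 6 for a, b in swaps)
            assert sorted(perm) == list(range(12))

    def test_strong_cosine_detected(self):
        t = np.arange(12) * 4.0
        rng = np.random.default_rng(12)
        y = np.cos(2 * np.pi * t / 24.0) + 0.2 * rng.standard_normal(12)  # SNR 5
        res = pt_test(y, 6, seed=1)
        assert res.p_value <= 0.01
        assert res.n_permutations == 100 and res.n_series == 2

    def test_zero_circadian_peak_gives_p_one(self):
        y = np.array([1.0, -1.0] * 6)  # all power at Nyquist, none at k=2
        res = pt_test(y, 6, seed=2)
        assert res.observed_peak == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == 1.0

    def test_determinism_and_seed_required(self):
        y = np.random.default_rng(13).standard_normal(12)
        assert pt_test(y, 6, seed=5).p_value == pt_test(y, 6, seed=5).p_value
        with pytest.raises(ValueError, match="seed"):
            pt_test(y, 6)

    def test_period_too_long_rejected(self):
        with pytest.raises(ValueError):
            pt_test(np.random.default_rng(1).standard_normal(12), 12, seed=1)


class TestPanel:
    def _matrix(self, rows, prefix="p"):
        return pd.DataFrame(
            rows,
            index=[f"{prefix}{i:03d}.1" for i in range(len(rows))],
            columns=np.arange(12) * 4.0,
        )

    def test_all_strong_cosines_all_detected(self):
        t = np.arange(12) * 4.0
        rng = np.random.default_rng(14)
        rows = [
            np.cos(2 * np.pi * (t - 6 * (i % 4)) / 24.0)
            + 0.1 * rng.standard_normal(12)
            for i in range(40)
        ]
        res = run_test_panel(self._matrix(rows), seed=15)
        summ = panel_summary(res)
        assert (summ["direct_fraction"] == 1.0).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(16)
        mat = self._matrix(list(rng.standard_normal((30, 12))))
        res1 = run_test_panel(mat, seed=17)
        res2 = run_test_panel(mat.iloc[::-1], seed=17)
        pd.testing.assert_frame_equal(res1.sort_index(), res2.sort_index())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_test_panel(self._matrix([]), seed=1)

    def test_bh_columns_optional(self):
        rng = np.random.default_rng(18)
        mat = self._matrix(list(rng.standard_normal((20, 12))))
        res = run_test_panel(mat, seed=19)
        assert "p_g_bh" not in res.columns  # FDR off by default
        res_fdr = run_test_panel(mat, seed=19, fdr=True)
        assert {"p_g_bh", "pt_p_bh"} <= set(res_fdr.columns)
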