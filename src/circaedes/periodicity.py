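"""Per-profile periodicity test panel: periodogram + Fisher's exact
g-test, circular autocorrelation at the circadian lag, and the
permutation Pt-test.

All three tests operate on a short evenly-sampled series Y = x_0..x_{N-1}
(N = 12 in the study design: 48 h at 4 h sampling, so the 24 h circadian
component sits in periodogram bin k = 2 and at autocorrelation lag 6).

Periodogram convention: the series mean is removed before the transform
and

    I(w_k) = (1/N) |sum_t x_t exp(-i w_k t)|^2 ,   w_k = 2 pi k / N,

for k = 1..floor(N/2).  With this normalization the ordinates satisfy
Parseval's identity sum_k c_k I(w_k) = (N/2) * var(Y) with c_k = 1 and
the Nyquist term (even N) weighted 1/2.

Fisher's g is the largest periodogram ordinate over the ordinate sum;
its exact null distribution (i.i.d. exponential ordinates) gives

    P(G > g) = sum_{j=1}^{b} (-1)^{j-1} C(n, j) (1 - j g)^{n-1},
    b = min(n, floor(1/g)).

For even N the Nyquist ordinate is chi^2_1-distributed rather than
exponential, which makes the exact test anticonservative; the g-test
therefore excludes the Nyquist ordinate by default (include_nyquist=True
restores the full spectrum).

The Pt-test destroys the tested periodicity by repeatedly swapping
randomly chosen time points x_n <-> x_m constrained to |n - m| != p (p
the period in samples), stores the permuted periodogram's peak at the
tested frequency, and reports the fraction of stored peaks at least as
large as the observed one.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import t as t_dist

__all__ = [
    "Periodogram",
    "GTestResult",
    "AutocorrResult",
    "PtTestResult",
    "periodogram",
    "fisher_g_pvalue",
    "fisher_g",
    "autocorr_cutoff",
    "circular_autocorrelation",
    "circadian_autocorr_test",
    "periodicity_safe_permutation",
    "pt_test",
    "n_pt_permutations",
    "run_test_panel",
    "panel_summary",
]


@dataclass
class Periodogram:
    """Spectral power at the Fourier frequencies w_k = 2 pi k / N, k = 1..N//2."""

    n_samples: int
    frequencies: np.ndarray
    intensities: np.ndarray

    def circadian_bin(self, period_samples: int) -> int:
        """1-based index k of the bin holding a period of ``period_samples``."""
        if self.n_samples % period_samples != 0:
            raise ValueError(
                f"period of {period_samples} samples is not a Fourier frequency of N={self.n_samples}"
            )
        return self.n_samples // period_samples


@dataclass
class GTestResult:
    g: float
    p_value: float
    n: int  # number of ordinates entering the test
    peak_index: int  # 1-based frequency index k* of the maximum ordinate


@dataclass
class AutocorrResult:
    R: float
    lag: int
    significant: bool
    cutoff: float
    p_value: float
    max_positive_R: float | None = None


@dataclass
class PtTestResult:
    p_value: float
    observed_peak: float
    n_permutations: int  # per series
    n_series: int
    permutation_peaks: np.ndarray


def periodogram(values) -> Periodogram:
    """Mean-removed periodogram of a real series (N >= 4)."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError(f"series too short for spectral analysis (N={n} < 4)")
    y = y - y.mean()
    spec = np.fft.rfft(y)
    intens = (np.abs(spec) ** 2) / n
    k = np.arange(1, n // 2 + 1)
    return Periodogram(n, 2.0 * np.pi * k / n, intens[1 : n // 2 + 1])


def fisher_g_pvalue(g: float, n: int) -> float:
    """Exact upper-tail probability of Fisher's g over n exponential ordinates."""
    if not 0.0 < g <= 1.0:
        raise ValueError("g must lie in (0, 1]")
    b = min(n, int(math.floor(1.0 / g)))
    j = np.arange(1, b + 1)
    p = float(np.sum((-1.0) ** (j - 1) * comb(n, j) * (1.0 - j * g) ** (n - 1)))
    return min(max(p, 0.0), 1.0)


def fisher_g(pg: Periodogram, include_nyquist: bool = False) -> GTestResult:
    """Fisher's exact test of the maximum periodogram ordinate.

    Large g flags a non-random concentration of spectral power at a
    single frequency.  The Nyquist ordinate (even N) is excluded by
    default because the exact null assumes exponential ordinates.
    """
    intens = pg.intensities
    if pg.n_samples % 2 == 0 and not include_nyquist:
        intens = intens[:-1]
    total = intens.sum()
    if total == 0:
        raise ValueError("all-zero periodogram (flat profile)")
    k_star = int(np.argmax(intens))
    g = float(intens[k_star] / total)
    return GTestResult(g, fisher_g_pvalue(g, len(intens)), len(intens), k_star + 1)


def autocorr_cutoff(n: int, alpha: float = 0.05) -> float:
    """Tabulated two-sided correlation cutoff from the t-distribution, n-2 df."""
    if n <= 2:
        raise ValueError("need n > 2 for a correlation cutoff")
    tc = t_dist.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tc / math.sqrt(n - 2 + tc**2))


def _autocorr_pvalue(r: float, n: int) -> float:
    """One-sided (positive) p for a correlation r on n paired points."""
    r = min(max(r, -0.999999999), 0.999999999)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(t_dist.sf(t, n - 2))


def circular_autocorrelation(
    values, lag: int, alpha: float = 0.05, effective_n: int | None = None
) -> AutocorrResult:
    """Pearson correlation of the series with its wrap-around lag-k shift.

    The shifted partner of x_i is x_{i+k} when i+k < N and x_{i+k-N}
    otherwise, so every point participates and the correlation uses all
    N pairs.  Significance compares R to the tabulated two-sided cutoff
    at ``alpha`` for the effective sample size (default N).
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if not 0 < lag < n:
        raise ValueError(f"lag must be in (0, N); got {lag} for N={n}")
    if y.std() == 0:
        raise ValueError("zero-variance profile")
    shifted = np.roll(y, -lag)
    r = float(np.corrcoef(y, shifted)[0, 1])
    n_eff = n if effective_n is None else effective_n
    cut = autocorr_cutoff(n_eff, alpha)
    return AutocorrResult(
        R=r,
        lag=lag,
        significant=r >= cut,
        cutoff=cut,
        p_value=_autocorr_pvalue(r, n_eff),
    )


def circadian_autocorr_test(
    values, sampling_interval: float, period: float = 24.0, alpha: float = 0.05
) -> AutocorrResult:
    """Autocorrelation test at the lag of one circadian day.

    With 4 h sampling the 24 h period corresponds to a lag of 6 samples.
    A profile is called circadially expressed when R at that lag clears
    the tabulated positive cutoff.  The maximum positive R over all lags
    is reported alongside.
    """
    lag_f = period / sampling_interval
    if abs(lag_f - round(lag_f)) > 1e-9:
        raise ValueError(
            f"period {period} h is not a whole number of {sampling_interval} h samples"
        )
    lag = int(round(lag_f))
    res = circular_autocorrelation(values, lag, alpha)
    y = np.asarray(values, dtype=float)
    n = len(y)
    all_r = [float(np.corrcoef(y, np.roll(y, -k))[0, 1]) for k in range(1, n)]
    res.max_positive_R = max([r for r in all_r if r > 0], default=float("nan"))
    return res


def n_pt_permutations(n_samples: int, max_perm: int = 100) -> int:
    """Permutations generated per series: min(N!, max_perm)."""
    return min(math.factorial(n_samples), max_perm)


def periodicity_safe_permutation(
    rng: np.random.Generator, n: int, period_samples: int, n_swaps: int | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One permutation built from swaps that cannot preserve the period.

    Performs ``n_swaps`` (default N, one sweep) random transpositions of
    index pairs (a, b), redrawing any pair with a == b or |a - b| equal
    to the period in samples, so each swap mixes time points from
    different phases of the tested cycle.  Returns the permutation and
    the executed swap list (for auditing).
    """
    if n_swaps is None:
        n_swaps = n
    perm = np.arange(n)
    swaps: list[tuple[int, int]] = []
    for _ in range(n_swaps):
        while True:
            a, b = (int(v) for v in rng.integers(0, n, size=2))
            if a != b and abs(a - b) != period_samples:
                break
        perm[a], perm[b] = perm[b], perm[a]
        swaps.append((a, b))
    return perm, swaps


def _batch_permutations(
    rng: np.random.Generator, n_perm: int, n: int, period_samples: int
) -> np.ndarray:
    """Vectorized batch of periodicity-destroying permutations (n_perm, N)."""
    perms = np.tile(np.arange(n), (n_perm, 1))
    rows = np.arange(n_perm)
    for _ in range(n):  # one sweep of N swaps per permutation
        a = rng.integers(0, n, size=n_perm)
        b = rng.integers(0, n, size=n_perm)
        bad = (a == b) | (np.abs(a - b) == period_samples)
        while bad.any():
            a[bad] = rng.integers(0, n, size=int(bad.sum()))
            b[bad] = rng.integers(0, n, size=int(bad.sum()))
            bad = (a == b) | (np.abs(a - b) == period_samples)
        tmp = perms[rows, a].copy()
        perms[rows, a] = perms[rows, b]
        perms[rows, b] = tmp
    return perms


def pt_test(
    values,
    period_samples: int,
    n_series: int = 2,
    max_perm: int = 100,
    seed: int | None = None,
    peak_mode: str = "circadian",
) -> PtTestResult:
    """Permutation test of the periodogram peak at the tested period.

    Generates ``n_series`` independent series of min(N!, max_perm)
    permutations, each assembled by one sweep of random swaps
    constrained to |n - m| != p so no swap maps a point onto its own
    phase one period away.  For every permutation the periodogram peak
    at the tested circadian frequency (or the global maximum, with
    ``peak_mode='global'``) is stored; the pooled p-value is the
    fraction of stored peaks >= the observed peak (same-or-higher rule,
    no add-one correction).
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if period_samples >= n:
        raise ValueError("period must be shorter than the series")
    if n < 2 * period_samples:
        raise ValueError("series must cover at least two periods")
    if y.std() == 0:
        raise ValueError("zero-variance profile")
    if seed is None:
        raise ValueError("seed is required (reproducibility is mandatory)")
    if peak_mode not in ("circadian", "global"):
        raise ValueError("peak_mode must be 'circadian' or 'global'")

    pg = periodogram(y)
    k_circ = pg.circadian_bin(period_samples)
    observed = float(pg.intensities[k_circ - 1])

    n_perm = n_pt_permutations(n, max_perm)
    yc = y - y.mean()
    rng = np.random.default_rng(seed)
    peaks = []
    for _ in range(n_series):
        perms = _batch_permutations(rng, n_perm, n, period_samples)
        permuted = yc[perms]  # (n_perm, N); mean unchanged by permutation
        spec = np.fft.rfft(permuted, axis=1)
        intens = (np.abs(spec) ** 2) / n
        if peak_mode == "circadian":
            peaks.append(intens[:, k_circ])
        else:
            peaks.append(intens[:, 1 : n // 2 + 1].max(axis=1))
    all_peaks = np.concatenate(peaks)
    p = float(np.mean(all_peaks >= observed))
    return PtTestResult(p, observed, n_perm, n_series, all_peaks)


def _profile_seed(base_seed: int, profile_id: str) -> int:
    """Stable per-profile seed independent of input order (< 2**31)."""
    return (base_seed * 2654435761 + zlib.crc32(profile_id.encode())) % (2**31 - 1)


def run_test_panel(
    matrix: pd.DataFrame,
    sampling_interval: float = 4.0,
    period: float = 24.0,
    alpha: float = 0.05,
    pt_max_perm: int = 100,
    pt_n_series: int = 2,
    seed: int | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Apply all three periodicity tests to every profile.

    ``matrix`` holds conditioned profiles (rows) by timestamps (columns).
    Returns one row per profile with the g statistic and its exact p,
    the circadian-lag autocorrelation and its verdict, and the Pt-test
    p-value.  Per-profile Pt seeds derive from the profile id, so the
    result is independent of row order.  Optional Benjamini-Hochberg
    adjusted columns are off by default: periodicity hypotheses across a
    synchronized transcriptome are not independent, so no FDR correction
    is applied unless requested.
    """
    if len(matrix) == 0:
        raise ValueError("empty profile matrix")
    if seed is None:
        raise ValueError("seed is required (reproducibility is mandatory)")
    lag = int(round(period / sampling_interval))
    period_samples = lag
    rows = []
    for pid, values in matrix.iterrows():
        y = values.to_numpy(dtype=float)
        gt = fisher_g(periodogram(y))
        ac = circadian_autocorr_test(y, sampling_interval, period, alpha)
        pt = pt_test(
            y,
            period_samples,
            n_series=pt_n_series,
            max_perm=pt_max_perm,
            seed=_profile_seed(seed, str(pid)),
        )
        rows.append(
            {
                "profile_id": pid,
                "g": gt.g,
                "p_g": gt.p_value,
                "g_sig": gt.p_value < alpha,
                "autocorr_R": ac.R,
                "autocorr_sig": bool(ac.significant),
                "pt_p": pt.p_value,
                "pt_sig": pt.p_value < alpha,
            }
        )
    out = pd.DataFrame(rows).set_index("profile_id")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        for col, sig in (("p_g", "g"), ("pt_p", "pt")):
            rej, p_adj, _, _ = multipletests(out[col], alpha=alpha, method="fdr_bh")
            out[f"{col}_bh"] = p_adj
            out[f"{sig}_sig_bh"] = rej
    return out


def panel_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-test counts and fractions of profiles called rhythmic."""
    n = len(results)
    rows = []
    for test, col in (
        ("fisher_g", "g_sig"),
        ("pt_test", "pt_sig"),
        ("autocorrelation", "autocorr_sig"),
    ):
        c = int(results[col].sum())
        rows.append({"test": test, "direct_count": c, "direct_fraction": c / n})
    return pd.DataFrame(rows).set_index("test")
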