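"""Profile conditioning: circular Savitzky-Golay smoothing, median
subtraction, z-scoring.

Smoothing is a single pass of a 7-point, degree-3 Savitzky-Golay filter
applied circularly: the series is treated as one closed loop, so the
last points contribute to smoothing of the first.  This suits the
reconstructed two-cycle circadian series, whose end wraps naturally onto
its start.  Median subtraction centers each profile; z-scoring (used by
the phase continuum) equalizes variation between profiles so streams of
concatenated profiles have a common amplitude scale.

Conditioning changes the null distribution of downstream periodicity
tests: smoothing colors white noise (low-pass), so nominal test
calibration holds for unsmoothed profiles.  The pipeline therefore keeps
smoothing configurable per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

__all__ = [
    "savgol_circular",
    "median_subtract",
    "zscore",
    "ConditioningRecord",
    "condition_profiles",
]


def savgol_circular(values, window: int = 7, degree: int = 3) -> np.ndarray:
    """Single-pass Savitzky-Golay smoothing with wrap-around boundaries.

    Each output point is the value at the window center of the
    least-squares polynomial fit of the given degree over ``window``
    consecutive points, with indices taken modulo the series length.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if degree >= window:
        raise ValueError("degree must be < window")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    coeffs = savgol_coeffs(window, degree)
    half = window // 2
    padded = np.concatenate([y[-half:], y, y[:half]])
    # savgol_coeffs returns weights ordered for convolution
    return np.convolve(padded, coeffs[::-1], mode="valid")


def median_subtract(values) -> np.ndarray:
    """Center the series at zero median (even length: mean of central pair)."""
    y = np.asarray(values, dtype=float)
    if len(y) == 0:
        raise ValueError("empty series")
    return y - np.median(y)


def zscore(values) -> np.ndarray:
    """(y - mean)/sd with population (1/N) standard deviation.

    A flat profile has no rhythm to test; zero variance is an error.
    """
    y = np.asarray(values, dtype=float)
    sd = y.std()  # ddof=0: population convention, material at N=12
    if sd == 0:
        raise ValueError("zero-variance (flat) profile cannot be z-scored")
    return (y - y.mean()) / sd


@dataclass
class ConditioningRecord:
    """Which conditioning steps ran, with which parameters."""

    smooth: bool = True
    window: int = 7
    degree: int = 3
    circular: bool = True
    median_subtracted: bool = True
    zscored: bool = False


def condition_profiles(
    matrix: pd.DataFrame,
    smooth: bool = True,
    window: int = 7,
    degree: int = 3,
    subtract_median: bool = True,
    apply_zscore: bool = False,
) -> tuple[pd.DataFrame, ConditioningRecord]:
    """Apply one shared conditioning parameter set to every profile.

    The same smoothing and median-subtraction settings apply uniformly
    across the whole run; per-profile parameter choices are deliberately
    not supported.
    """
    out = matrix.to_numpy(dtype=float).copy()
    for i in range(out.shape[0]):
        if smooth:
            out[i] = savgol_circular(out[i], window, degree)
        if subtract_median:
            out[i] = median_subtract(out[i])
        if apply_zscore:
            out[i] = zscore(out[i])
    rec = ConditioningRecord(
        smooth=smooth,
        window=window,
        degree=degree,
        circular=True,
        median_subtracted=subtract_median,
        zscored=apply_zscore,
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), rec
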