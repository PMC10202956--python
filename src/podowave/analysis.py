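"""Trace analytics: FFT amplitude ratio, Pearson correlation versus pair
distance, correlation decay-length fit, and kymograph patch lifetimes.

These are the quantitative observables used to compare simulated podosome
dynamics with fluorescence time-lapse measurements: the amplitude ratio
(mean of the four largest non-DC FFT amplitudes over the mean intensity) as
the oscillation-strength metric, the pair-distance Pearson correlation
curve with an exp(−d/ξ)·cos(2πd/λ_f) fit as the spatial length-scale
metric, and the thresholded connected-component lifetime of kymograph
patches as the wave-persistence metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "SpectrumPeaks",
    "CorrelationCurve",
    "amplitude_ratio",
    "pearson",
    "correlation_vs_distance",
    "pattern_lifetime",
]


@dataclass(frozen=True)
class SpectrumPeaks:
    """Top-k discrete-Fourier peaks of a uniformly sampled trace.

    ``frequencies``/``amplitudes`` are sorted by amplitude, descending;
    amplitudes use one-sided sinusoid normalization (a pure sinusoid of
    amplitude A contributes a peak of height A).  ``ratio`` is the mean of
    the top-k amplitudes divided by the mean of the raw trace, and
    ``dominant_period`` is the reciprocal of the largest peak's frequency.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    dominant_period: float
    ratio: float


def amplitude_ratio(
    trace: np.ndarray, sample_interval: float, k: int = 4
) -> SpectrumPeaks:
    """FFT peak amplitudes and amplitude ratio of an intensity/height trace.

    The trace is mean-subtracted before the transform (the DC bin is
    excluded from the peak search regardless); no window or detrending is
    applied.  A constant trace returns ratio 0.

    Parameters
    ----------
    trace : array
        Uniformly sampled series, at least 64 samples.
    sample_interval : float
        Sampling interval (s).
    k : int
        Number of peaks to average (default 4).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if x.size < 64:
        raise ValueError("need at least 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains NaN or Inf")
    n = x.size
    mean = x.mean()
    spec = np.fft.rfft(x - mean)
    amps = np.abs(spec) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=sample_interval)
    # exclude DC; Nyquist bin keeps the same normalization for simplicity
    amps, freqs = amps[1:], freqs[1:]
    order = np.argsort(amps)[::-1][:k]
    top_a = amps[order]
    top_f = freqs[order]
    if top_a[0] == 0.0 or mean == 0.0:
        ratio = 0.0
        period = math.inf
    else:
        ratio = float(top_a.mean() / mean)
        period = float(1.0 / top_f[0])
    return SpectrumPeaks(
        frequencies=top_f, amplitudes=top_a, dominant_period=period, ratio=ratio
    )


def pearson(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation with the 1/(N−1), sample-standard-deviation
    convention: ρ(A,B) = 1/(N−1) Σ ((Ai−µA)/σA)((Bi−µB)/σB) ∈ [−1, 1]."""
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be one-dimensional with equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    sa = a.std(ddof=1)
    sb = b.std(ddof=1)
    if sa == 0.0 or sb == 0.0:
        raise ValueError("degenerate series: zero variance")
    rho = float(np.sum((a - a.mean()) * (b - b.mean())) / ((n - 1) * sa * sb))
    return min(1.0, max(-1.0, rho))


@dataclass
class CorrelationCurve:
    """Binned pair-distance correlation curve with a damped-cosine fit.

    ``xi`` is the fitted decay length of ρ(d) = exp(−d/ξ)·cos(2πd/λ_f) —
    the characteristic length scale of the wave patterns — and ``lambda_f``
    the fitted oscillatory wavelength.  ``xi_flagged`` marks degenerate
    fits (e.g. all traces identical, ξ → ∞).
    """

    distance: np.ndarray
    mean_rho: np.ndarray
    sem_rho: np.ndarray
    n_pairs: np.ndarray
    xi: float
    lambda_f: float
    xi_flagged: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance": self.distance,
                "mean_rho": self.mean_rho,
                "sem_rho": self.sem_rho,
                "n_pairs": self.n_pairs,
            }
        )


def _damped_cos(d, xi, lam):
    return np.exp(-d / xi) * np.cos(2.0 * np.pi * d / lam)


def correlation_vs_distance(
    traces: np.ndarray,
    positions: np.ndarray,
    bin_width: float = 0.5,
    max_fit_distance: float = 10.0,
    window: Optional[int] = None,
) -> CorrelationCurve:
    """Pair-distance correlation curve of podosome height/intensity traces.

    All unordered trace pairs are correlated over the analysis window
    (default: the first 25 min of samples when the sampling interval is
    unknown the caller passes ``window`` as a number of samples), binned by
    Euclidean pair distance, and the binned means are fit by
    exp(−d/ξ)·cos(2πd/λ_f) over d ≤ ``max_fit_distance`` (µm).

    Parameters
    ----------
    traces : array, shape (n, T)
        One row per podosome.
    positions : array, shape (n, 2)
        Podosome coordinates (µm).
    bin_width : float
        Distance bin width (µm).
    window : int, optional
        Number of leading samples to correlate (default: all).
    """
    traces = np.asarray(traces, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = traces.shape[0]
    if n < 10:
        raise ValueError("need at least 10 traces")
    if positions.shape != (n, 2):
        raise ValueError("positions must have shape (n, 2)")
    if window is not None:
        traces = traces[:, :window]

    # centred/normalised rows -> all pairwise correlations in one product
    x = traces - traces.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate series: zero variance")
    xn = x / sd[:, None]
    t_len = traces.shape[1]
    rho_mat = xn @ xn.T / (t_len - 1)
    iu, ju = np.triu_indices(n, k=1)
    rho = np.clip(rho_mat[iu, ju], -1.0, 1.0)
    dist = np.hypot(
        positions[iu, 0] - positions[ju, 0], positions[iu, 1] - positions[ju, 1]
    )

    edges = np.arange(0.0, dist.max() + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(dist, edges) - 1
    mean_rho = np.full(centers.size, np.nan)
    sem_rho = np.full(centers.size, np.nan)
    n_pairs = np.zeros(centers.size, dtype=int)
    for b in range(centers.size):
        sel = idx == b
        n_pairs[b] = sel.sum()
        if n_pairs[b] > 0:
            vals = rho[sel]
            mean_rho[b] = vals.mean()
            sem_rho[b] = vals.std(ddof=1) / math.sqrt(n_pairs[b]) if n_pairs[b] > 1 else 0.0
    if not np.any(n_pairs >= 3):
        raise ValueError("fewer than 3 pairs in every distance bin")

    keep = (n_pairs > 0) & (centers <= max_fit_distance)
    d_fit = centers[keep]
    r_fit = mean_rho[keep]

    xi_flagged = False
    if np.all(r_fit > 0.99):
        # identical (or near-identical) traces: no decay to fit
        xi, lam = math.inf, math.inf
        xi_flagged = True
    else:
        try:
            popt, _ = optimize.curve_fit(
                _damped_cos,
                d_fit,
                r_fit,
                p0=(2.0, max(4.0 * bin_width, 2.0 * float(d_fit[np.argmin(r_fit)]))),
                bounds=([1e-2, 1e-1], [1e3, 1e4]),
                maxfev=20000,
            )
            xi, lam = float(popt[0]), float(popt[1])
        except RuntimeError:
            warnings.warn("correlation decay fit did not converge", RuntimeWarning)
            xi, lam = math.nan, math.nan
            xi_flagged = True

    return CorrelationCurve(
        distance=centers,
        mean_rho=mean_rho,
        sem_rho=sem_rho,
        n_pairs=n_pairs,
        xi=xi,
        lambda_f=lam,
        xi_flagged=xi_flagged,
    )


def pattern_lifetime(
    kymo,
    steady_height: float,
    threshold: float = 0.05,
    min_spatial_extent: int = 2,
) -> float:
    """Mean temporal persistence (minutes) of wave patches in a kymograph.

    The kymograph is binarized at ``steady_height·(1 + threshold)``;
    connected components in the (position, time) plane are extracted, and
    the lifetime of each component is its extent along the time axis.
    Components narrower than ``min_spatial_extent`` grid cells are ignored.

    Parameters
    ----------
    kymo : Kymograph
        Position × time height map with ``frame_interval`` (s) calibration.
    steady_height : float
        Reference (steady-state) height in the same units as the map.

    Raises
    ------
    ValueError
        If no patch exceeds the threshold ("no wave patches").
    """
    data = np.asarray(kymo.data, dtype=float)  # (n_position, n_time)
    mask = data > steady_height * (1.0 + threshold)
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        raise ValueError("no wave patches above threshold")
    lifetimes = []
    for sl in ndimage.find_objects(labels):
        pos_extent = sl[0].stop - sl[0].start
        if pos_extent >= min_spatial_extent:
            t_extent = sl[1].stop - sl[1].start
            lifetimes.append(t_extent * kymo.frame_interval)
    if not lifetimes:
        raise ValueError("no wave patches with sufficient spatial extent")
    return float(np.mean(lifetimes) / 60.0)
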