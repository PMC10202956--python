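"""Spatio-temporal image correlation spectroscopy (STICS).

A movie is tiled into overlapping spatial regions of interest (ROIs) and
overlapping temporal windows (TOIs).  For every ROI × TOI the spatial
cross-correlation function between frame pairs is computed at each time
lag, its central peak is fit with a symmetric 2-D Gaussian, and the peak
displacements versus lag are fit with a linear model; the slope is the
local flow velocity.  Vectors with a poor linear fit (R² below threshold
after adaptive lag reduction), too few displacement points, or an
implausible speed are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .imaging import MovieStack

__all__ = [
    "SticsConfig",
    "VectorMap",
    "st_correlation",
    "fit_peak",
    "flow_vector",
    "stics_map",
]


@dataclass(frozen=True)
class SticsConfig:
    """Tiling, fitting, and quality-control settings.

    Defaults follow the analysis of 15-s LifeAct time series: 32×32-px
    ROIs shifted by 4 px, 5-frame TOIs shifted by 1 frame, Gaussian fits
    within 8 px of the correlation-function centre, a linear lag fit over
    up to 5 lags gated at R² ≥ 0.9 with at least 3 displacement points.
    """

    roi_size: int = 32
    roi_shift: int = 4
    toi_length: int = 5
    toi_shift: int = 1
    fit_radius: int = 8
    max_lag: int = 5
    r2_min: float = 0.9
    min_points: int = 3
    max_speed: float = 2.0          # µm/min plausibility cap
    immobile_filter: str = "roi-mean-subtract"
    prefilter_sigma: float = 0.0    # px; 7 px for wave-propagation movies

    def __post_init__(self) -> None:
        if self.immobile_filter not in ("none", "roi-mean-subtract"):
            raise ValueError("immobile_filter must be 'none' or 'roi-mean-subtract'")
        if self.fit_radius >= self.roi_size / 2:
            raise ValueError("fit_radius must be < roi_size/2")


@dataclass
class VectorMap:
    """STICS output: one velocity vector per (ROI, TOI) tile.

    ``table`` columns: x_um, y_um, t_s (tile centres), vx, vy (µm/min),
    speed, r2, n_lags, qc_pass, reason.  ``vectors()`` returns only the
    rows passing quality control.
    """

    table: pd.DataFrame
    config: SticsConfig
    pixel_size: float
    frame_interval: float

    def vectors(self) -> pd.DataFrame:
        return self.table[self.table["qc_pass"]].reset_index(drop=True)

    def mean_speed(self) -> float:
        v = self.vectors()
        return float(v["speed"].mean()) if len(v) else math.nan

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None, scale: float = 1.0):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        v = self.vectors()
        fig, ax = plt.subplots(figsize=(5, 5))
        q = ax.quiver(
            v["x_um"], v["y_um"], v["vx"], v["vy"], v["speed"],
            angles="xy", scale_units="xy", scale=scale, cmap="inferno",
        )
        fig.colorbar(q, ax=ax, label="speed (µm/min)")
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.set_aspect("equal")
        ax.invert_yaxis()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def st_correlation(roi_stack: np.ndarray) -> np.ndarray:
    """Spatiotemporal correlation function of a (frames, H, W) ROI stack.

    For each lag τ the normalized spatial cross-correlation between frame
    pairs (t, t+τ) is computed by Fourier cross-correlation with per-frame
    mean subtraction and averaged over pairs.  Returns CF with shape
    (τ, H, W), zero spatial lag at the centre (fftshift layout).  For a
    zero-variance stack a ValueError is raised (the tile is skipped by
    :func:`stics_map`).
    """
    stack = np.asarray(roi_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("roi_stack must be (frames, H, W)")
    n_t, H, W = stack.shape
    x = stack - stack.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2))
    if np.any(sd == 0):
        raise ValueError("zero-variance ROI")
    F = np.fft.fft2(x)
    cf = np.empty((n_t, H, W))
    npix = H * W
    for tau in range(n_t):
        acc = np.zeros((H, W))
        n_pairs = n_t - tau
        for t in range(n_pairs):
            cross = np.fft.ifft2(np.conj(F[t]) * F[t + tau]).real
            acc += cross / (npix * sd[t] * sd[t + tau])
        cf[tau] = np.fft.fftshift(acc / n_pairs)
    return cf


def _gauss2d(coords, amp, x0, y0, width, offset):
    x, y = coords
    return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * width**2)) + offset


def fit_peak(cf_slice: np.ndarray, fit_radius: int):
    """Fit a symmetric 2-D Gaussian to the central peak of a CF slice.

    Only pixels within ``fit_radius`` of the slice centre enter the
    least-squares fit.  Returns (x0, y0, amplitude, width, offset) with
    x0/y0 relative to the slice centre (positive x to the right), or
    ``None`` when the fit does not converge or the peak is degenerate.
    """
    cf = np.asarray(cf_slice, dtype=float)
    H, W = cf.shape
    cy, cx = H // 2, W // 2
    yy, xx = np.mgrid[0:H, 0:W]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= fit_radius**2
    x = (xx[mask] - cx).astype(float)
    y = (yy[mask] - cy).astype(float)
    z = cf[mask]
    amp0 = z.max() - z.min()
    if amp0 <= 0 or not np.all(np.isfinite(z)):
        return None
    imax = np.argmax(z)
    p0 = (amp0, x[imax], y[imax], max(1.0, fit_radius / 4.0), float(z.min()))
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (x, y),
            z,
            p0=p0,
            bounds=(
                [0.0, -fit_radius, -fit_radius, 0.1, -np.inf],
                [np.inf, fit_radius, fit_radius, 4.0 * fit_radius, np.inf],
            ),
            maxfev=5000,
        )
    except RuntimeError:
        return None
    amp, x0, y0, width, offset = popt
    if amp <= 0:
        return None
    return float(x0), float(y0), float(amp), float(width), float(offset)


def flow_vector(
    displacements: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    r2_min: float = 0.9,
    min_points: int = 3,
):
    """Velocity from Gaussian-peak displacements versus time lag.

    ``displacements`` has shape (n_lags, 2) holding (dx, dy) in pixels at
    lags τ = 0 … n_lags−1.  Both components are fit with a linear model in
    τ; if the combined R² falls below ``r2_min`` the largest lag is
    dropped and the fit repeated, down to ``min_points`` points.  The
    slope is converted to µm/min.

    Returns a dict with vx, vy, speed, r2, n_lags, ok, reason.
    """
    disp = np.asarray(displacements, dtype=float)
    if disp.ndim != 2 or disp.shape[1] != 2 or disp.shape[0] < 2:
        raise ValueError("need at least 2 lags of (dx, dy) displacements")
    n = disp.shape[0]
    scale = pixel_size / frame_interval * 60.0  # px/frame -> µm/min

    def linfit(k):
        tau = np.arange(k, dtype=float)
        A = np.vstack([tau, np.ones(k)]).T
        coef_x, res_x = np.linalg.lstsq(A, disp[:k, 0], rcond=None)[:2]
        coef_y, res_y = np.linalg.lstsq(A, disp[:k, 1], rcond=None)[:2]
        ss_res = float((res_x.sum() if res_x.size else 0.0) + (res_y.sum() if res_y.size else 0.0))
        ss_tot = float(
            np.sum((disp[:k, 0] - disp[:k, 0].mean()) ** 2)
            + np.sum((disp[:k, 1] - disp[:k, 1].mean()) ** 2)
        )
        if ss_tot <= 1e-12:
            # no measurable displacement trend: undefined fit quality
            return coef_x[0], coef_y[0], 0.0
        return coef_x[0], coef_y[0], 1.0 - ss_res / ss_tot

    k = n
    while True:
        sx, sy, r2 = linfit(k)
        if r2 >= r2_min or k <= min_points:
            break
        k -= 1
    ok = r2 >= r2_min and k >= min_points
    return {
        "vx": float(sx * scale),
        "vy": float(sy * scale),
        "speed": float(math.hypot(sx, sy) * scale),
        "r2": float(r2),
        "n_lags": int(k),
        "ok": bool(ok),
        "reason": "" if ok else "r2_below_threshold",
    }


def stics_map(stack: MovieStack, config: Optional[SticsConfig] = None) -> VectorMap:
    """Full STICS velocity map of a movie.

    ROIs tile the frame with the configured oversampling; TOIs tile the
    series in time.  Per tile: optional immobile-population filtering
    (subtraction of the TOI-mean image), the spatiotemporal CF, Gaussian
    peak fits per lag, and the gated linear lag fit.  Failed tiles are
    recorded with a reason code; the call fails only if no tile fits.
    """
    if config is None:
        config = SticsConfig()
    frames = stack.frames
    T, H, W = frames.shape
    if H < config.roi_size or W < config.roi_size:
        raise ValueError("movie smaller than one ROI")
    if T < config.toi_length:
        raise ValueError("movie shorter than one TOI")
    if config.prefilter_sigma > 0:
        frames = np.stack(
            [ndimage.gaussian_filter(f, config.prefilter_sigma, mode="nearest") for f in frames]
        )

    max_lag = min(config.max_lag, config.toi_length - 1)
    rows = []
    roi_starts_y = range(0, H - config.roi_size + 1, config.roi_shift)
    roi_starts_x = range(0, W - config.roi_size + 1, config.roi_shift)
    toi_starts = range(0, T - config.toi_length + 1, config.toi_shift)

    for t0 in toi_starts:
        toi = frames[t0 : t0 + config.toi_length]
        t_mid = (t0 + (config.toi_length - 1) / 2.0) * stack.frame_interval
        for y0 in roi_starts_y:
            for x0 in roi_starts_x:
                tile = toi[:, y0 : y0 + config.roi_size, x0 : x0 + config.roi_size]
                if config.immobile_filter == "roi-mean-subtract":
                    tile = tile - tile.mean(axis=0, keepdims=True)
                x_um = (x0 + config.roi_size / 2.0) * stack.pixel_size
                y_um = (y0 + config.roi_size / 2.0) * stack.pixel_size
                rec = {
                    "x_um": x_um, "y_um": y_um, "t_s": t_mid,
                    "vx": np.nan, "vy": np.nan, "speed": np.nan,
                    "r2": np.nan, "n_lags": 0, "qc_pass": False, "reason": "",
                }
                try:
                    cf = st_correlation(tile)
                except ValueError:
                    rec["reason"] = "zero_variance"
                    rows.append(rec)
                    continue
                disp = []
                for tau in range(max_lag + 1):
                    fit = fit_peak(cf[tau], config.fit_radius)
                    if fit is None:
                        break
                    # a peak at the edge of the fit window is unreliable;
                    # stop extending the lag series there
                    if math.hypot(fit[0], fit[1]) > config.fit_radius - 1.0:
                        break
                    disp.append(fit[:2])
                if len(disp) < 2:
                    rec["reason"] = "peak_fit_failed"
                    rows.append(rec)
                    continue
                res = flow_vector(
                    np.asarray(disp),
                    stack.pixel_size,
                    stack.frame_interval,
                    r2_min=config.r2_min,
                    min_points=config.min_points,
                )
                rec.update(
                    vx=res["vx"], vy=res["vy"], speed=res["speed"],
                    r2=res["r2"], n_lags=res["n_lags"],
                )
                if not res["ok"]:
                    rec["reason"] = res["reason"]
                elif res["speed"] > config.max_speed:
                    rec["reason"] = "speed_above_cap"
                else:
                    rec["qc_pass"] = True
                rows.append(rec)

    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no STICS tiles could be formed")
    return VectorMap(
        table=table,
        config=config,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )
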