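"""Spatiotemporal podosome-cluster simulations coupled by G-actin diffusion.

Two representations of a cluster are supported:

* ``discrete`` — an array of individual podosomes on a lattice with
  spacing ``d0``; each podosome carries its own (Fp, Fm) state, consumes or
  releases G-actin into its containing grid cell, and reads the local
  polymerization speed Vpm = Vp0 + β·ca from that cell.
* ``continuum`` — a coarse-grained field where every grid cell carries the
  full (Fp, Fm) state and an areal consumption coefficient µ.

In both modes the G-actin concentration obeys
∂ca/∂t = Da·∇²ca − µ·d(l+l1)/dt with no-flux boundaries, integrated by an
explicit method of lines (classical RK4, fixed step).  Because the
consumption term is exactly the height rate and height is an affine
function of (Fp, Fm), the total ∫ca dA + µ·∫height dA is a linear invariant
and is conserved to round-off by the integrator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .analysis import correlation_vs_distance
from .params import (
    ModelParams,
    characteristic_quantities,
    steady_state,
    stiffness_variant,
)

__all__ = [
    "ClusterConfig",
    "ClusterField",
    "Kymograph",
    "simulate_cluster",
    "kymograph",
    "stiffness_sweep",
    "wavefront_radius",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Geometry, initial condition, and integration settings of a run.

    ``init`` is one of ``uniform`` (homogeneous steady state), ``radial``
    (+``init_amplitude`` height within ``radial_radius`` µm of the domain
    centre), or ``random`` (heights uniform within ±``init_amplitude`` of
    steady, seeded).  ``output_every`` is the trace sampling interval (s),
    matching the 15-s frame interval of the emulated time-lapse data.
    """

    mode: str = "continuum"
    Lx: float = 30.0
    Ly: float = 30.0
    h: float = 0.5
    d0: float = 1.0
    init: str = "random"
    init_amplitude: float = 0.3
    radial_radius: float = 3.0
    seed: int = 0
    t_end: float = 4000.0
    dt: Optional[float] = None
    output_every: float = 15.0
    deposition: str = "cic"

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuum"):
            raise ValueError("mode must be 'discrete' or 'continuum'")
        if self.deposition not in ("cic", "cell"):
            raise ValueError("deposition must be 'cic' (area-weighted) or 'cell'")
        if self.init not in ("uniform", "radial", "random"):
            raise ValueError("init must be 'uniform', 'radial' or 'random'")
        if self.h <= 0 or self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("geometry must be positive")
        if self.mode == "discrete" and self.h > self.d0 / 2 + 1e-12:
            raise ValueError("discrete mode requires h <= d0/2")


@dataclass
class ClusterField:
    """Recorded spatial fields of a cluster run.

    ``heights``/``Fp``/``Fm`` have shape (T, ny, nx) in continuum mode and
    (T, n_podosomes) in discrete mode; ``ca`` is always (T, ny, nx).
    """

    mode: str
    times: np.ndarray
    heights: np.ndarray
    Fp: np.ndarray
    Fm: np.ndarray
    ca: np.ndarray
    h: float
    params: ModelParams
    config: ClusterConfig
    positions: Optional[np.ndarray] = None  # (n_podosomes, 2), discrete mode
    steady_height: float = 0.0
    clip_warnings: int = 0

    @property
    def extent(self):
        return (0.0, self.config.Lx, 0.0, self.config.Ly)

    def height_traces_at(self, positions: np.ndarray) -> np.ndarray:
        """Height traces (n, T) at physical positions (µm).

        Continuum: bilinear interpolation of the height field; discrete:
        the nearest podosome's trace.
        """
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if self.mode == "continuum":
            # grid-cell centres sit at (index + 0.5)·h
            cols = positions[:, 0] / self.h - 0.5
            rows = positions[:, 1] / self.h - 0.5
            out = np.empty((positions.shape[0], self.times.size))
            coords = np.vstack([rows, cols])
            for t in range(self.times.size):
                out[:, t] = ndimage.map_coordinates(
                    self.heights[t], coords, order=1, mode="nearest"
                )
            return out
        d2 = (
            (self.positions[None, :, 0] - positions[:, None, 0]) ** 2
            + (self.positions[None, :, 1] - positions[:, None, 1]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        return self.heights[:, nearest].T

    def conserved_total(self) -> np.ndarray:
        """∫ca dA + µ·∫height dA at every output time (per-area units)."""
        cell = self.h * self.h
        ca_tot = self.ca.sum(axis=(1, 2)) * cell
        if self.mode == "continuum":
            h_tot = self.heights.sum(axis=(1, 2)) * cell
        else:
            h_tot = self.heights.sum(axis=1)
        return ca_tot + self.params.mu * h_tot

    def to_tiff(self, path) -> None:
        """Export height and ca channels as a multi-page float32 TIFF with a
        JSON sidecar carrying the grid calibration."""
        import json
        from pathlib import Path

        import tifffile

        if self.mode == "continuum":
            hs = self.heights
        else:  # rasterize podosome heights onto the ca grid
            ny, nx = self.ca.shape[1:]
            hs = np.zeros((self.times.size, ny, nx), dtype=float)
            ix = np.clip((self.positions[:, 0] / self.h).astype(int), 0, nx - 1)
            iy = np.clip((self.positions[:, 1] / self.h).astype(int), 0, ny - 1)
            hs[:, iy, ix] = self.heights
        stack = np.stack([hs, self.ca], axis=1).astype(np.float32)  # T,C,Y,X
        path = Path(path)
        tifffile.imwrite(path, stack, imagej=False)
        sidecar = {
            "mode": self.mode,
            "grid_spacing_um": self.h,
            "Lx_um": self.config.Lx,
            "Ly_um": self.config.Ly,
            "frame_interval_s": float(self.times[1] - self.times[0])
            if self.times.size > 1
            else 0.0,
            "steady_height_um": self.steady_height,
            "channels": ["height", "ca"],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


@dataclass
class Kymograph:
    """Height map along a rectangle's long axis versus time."""

    data: np.ndarray          # (n_position, n_time)
    positions: np.ndarray     # µm along the long axis
    frame_interval: float     # s
    pixel_size: float         # µm per position sample
    rect: tuple

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.data, index=self.positions)
        df.index.name = "position_um"
        df.columns = np.arange(self.data.shape[1]) * self.frame_interval
        return df

    def plot(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        t_max = self.data.shape[1] * self.frame_interval / 60.0
        im = ax.imshow(
            self.data,
            aspect="auto",
            origin="lower",
            extent=(0.0, t_max, self.positions[0], self.positions[-1]),
            cmap="inferno",
        )
        fig.colorbar(im, ax=ax, label="height (µm)")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("position (µm)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _laplacian_no_flux(f: np.ndarray, h: float) -> np.ndarray:
    p = np.pad(f, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    ) / (h * h)


def _lattice_positions(config: ClusterConfig) -> np.ndarray:
    """Podosome lattice with spacing d0, centred in the domain."""
    nx = int(math.floor(config.Lx / config.d0))
    ny = int(math.floor(config.Ly / config.d0))
    x0 = 0.5 * (config.Lx - (nx - 1) * config.d0)
    y0 = 0.5 * (config.Ly - (ny - 1) * config.d0)
    xs = x0 + config.d0 * np.arange(nx)
    ys = y0 + config.d0 * np.arange(ny)
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def simulate_cluster(params: ModelParams, config: ClusterConfig) -> ClusterField:
    """Integrate a podosome cluster with G-actin reaction–diffusion.

    Raises
    ------
    ValueError
        On a CFL violation (dt > h²/(4·Da)), with a suggested step.
    FloatingPointError
        If any field becomes non-finite.
    """
    ch = characteristic_quantities(params)
    fps, fms, obs_s = steady_state(params)
    height_s = float(obs_s.height)
    period = 2.0 * math.pi * math.sqrt(params.tau_m * ch.tau_p)
    if config.mode == "continuum" and config.h > math.sqrt(params.Da * period) / 5:
        warnings.warn(
            "grid spacing exceeds sqrt(Da*T)/5; wave fields may be under-resolved",
            RuntimeWarning,
        )

    cfl = config.h**2 / (4.0 * params.Da)
    dt = config.dt if config.dt is not None else min(0.5, 0.8 * cfl)
    if dt > cfl:
        raise ValueError(
            f"CFL violation: dt={dt:g} exceeds h^2/(4*Da)={cfl:g}; "
            f"use dt <= {0.8 * cfl:g}"
        )

    nx = int(round(config.Lx / config.h))
    ny = int(round(config.Ly / config.h))
    rng = np.random.default_rng(config.seed)
    compliance = 1.0 / params.kf + 1.0 / params.ks
    cos_t = math.cos(params.theta)
    g = 1.0 - params.gamma / params.kf
    a_cross = params.alpha - params.gamma / params.kf

    # cell-centre coordinates
    xc = (np.arange(nx) + 0.5) * config.h
    yc = (np.arange(ny) + 0.5) * config.h
    xx, yy = np.meshgrid(xc, yc)

    def height_perturbation(shape, coords):
        """Initial height offset per site (fraction of steady height)."""
        if config.init == "uniform":
            return np.zeros(shape)
        if config.init == "radial":
            cx, cy = config.Lx / 2.0, config.Ly / 2.0
            r = np.hypot(coords[0] - cx, coords[1] - cy)
            return np.where(r <= config.radial_radius, config.init_amplitude, 0.0) * height_s
        return rng.uniform(-config.init_amplitude, config.init_amplitude, shape) * height_s

    if config.mode == "continuum":
        dh0 = height_perturbation((ny, nx), (xx, yy))
    else:
        positions = _lattice_positions(config)
        n_pod = positions.shape[0]
        dh0 = height_perturbation(n_pod, (positions[:, 0], positions[:, 1]))
        if config.deposition == "cell":
            # nearest-cell: all exchange happens in the containing cell
            ix = np.clip((positions[:, 0] / config.h).astype(int), 0, nx - 1)
            iy = np.clip((positions[:, 1] / config.h).astype(int), 0, ny - 1)
            dep_idx = (iy, ix)
            dep_w = np.ones((1, n_pod))
        else:
            # cloud-in-cell: area-weighted over the 4 surrounding cells,
            # which keeps the podosome's self-coupling consistent with the
            # coarse-grained limit
            fx = positions[:, 0] / config.h - 0.5
            fy = positions[:, 1] / config.h - 0.5
            ix0 = np.clip(np.floor(fx).astype(int), 0, nx - 1)
            iy0 = np.clip(np.floor(fy).astype(int), 0, ny - 1)
            ix1 = np.clip(ix0 + 1, 0, nx - 1)
            iy1 = np.clip(iy0 + 1, 0, ny - 1)
            wx1 = np.clip(fx - ix0, 0.0, 1.0)
            wy1 = np.clip(fy - iy0, 0.0, 1.0)
            wx0, wy0 = 1.0 - wx1, 1.0 - wy1
            dep_idx = (
                np.concatenate([iy0, iy0, iy1, iy1]),
                np.concatenate([ix0, ix1, ix0, ix1]),
            )
            dep_w = np.stack(
                [wy0 * wx0, wy0 * wx1, wy1 * wx0, wy1 * wx1]
            )  # (4, n_pod)

    # convert the height offset to a protrusive-force offset at fixed Fm
    fp0_field = fps + dh0 / compliance
    fm0_field = np.full_like(fp0_field, fms)
    ca0 = np.full((ny, nx), params.ca_ref)

    inv_tau_m = 1.0 / params.tau_m
    fsp0 = ch.Fsp0
    clip_count = 0

    if config.mode == "continuum":

        def rhs(fp, fm, ca):
            vpm = params.Vp0 + params.beta * ca
            dfm = (params.Fm0 + a_cross * fp / cos_t - g * fm) * inv_tau_m
            dh_rate = vpm * (1.0 - fp / fsp0) - params.Vd
            tau0 = (fsp0 / vpm) * compliance
            dfp = (fsp0 * (1.0 - params.Vd / vpm) - fp + fsp0 * cos_t / (vpm * params.kf) * dfm) / tau0
            dca = params.Da * _laplacian_no_flux(ca, config.h) - params.mu * dh_rate
            return dfp, dfm, dca

    else:
        inv_h2 = 1.0 / (config.h * config.h)
        n_dep = dep_w.shape[0]

        def read_ca(ca):
            vals = ca[dep_idx].reshape(n_dep, n_pod)
            return (dep_w * vals).sum(axis=0)

        def rhs(fp, fm, ca):
            vpm = params.Vp0 + params.beta * read_ca(ca)
            dfm = (params.Fm0 + a_cross * fp / cos_t - g * fm) * inv_tau_m
            dh_rate = vpm * (1.0 - fp / fsp0) - params.Vd
            tau0 = (fsp0 / vpm) * compliance
            dfp = (fsp0 * (1.0 - params.Vd / vpm) - fp + fsp0 * cos_t / (vpm * params.kf) * dfm) / tau0
            sink = np.zeros((ny, nx))
            np.add.at(sink, dep_idx, (dep_w * (params.mu * dh_rate)).ravel())
            dca = params.Da * _laplacian_no_flux(ca, config.h) - sink * inv_h2
            return dfp, dfm, dca

    n_steps = int(round(config.t_end / dt))
    out_stride = max(1, int(round(config.output_every / dt)))
    n_out = n_steps // out_stride + 1
    times = np.empty(n_out)
    rec_fp = np.empty((n_out,) + fp0_field.shape)
    rec_fm = np.empty_like(rec_fp)
    rec_ca = np.empty((n_out, ny, nx))

    fp, fm, ca = fp0_field.astype(float), fm0_field.astype(float), ca0
    k_out = 0
    for step in range(n_steps + 1):
        if step % out_stride == 0 and k_out < n_out:
            times[k_out] = step * dt
            rec_fp[k_out] = fp
            rec_fm[k_out] = fm
            rec_ca[k_out] = ca
            k_out += 1
        if step == n_steps:
            break
        k1 = rhs(fp, fm, ca)
        k2 = rhs(fp + 0.5 * dt * k1[0], fm + 0.5 * dt * k1[1], ca + 0.5 * dt * k1[2])
        k3 = rhs(fp + 0.5 * dt * k2[0], fm + 0.5 * dt * k2[1], ca + 0.5 * dt * k2[2])
        k4 = rhs(fp + dt * k3[0], fm + dt * k3[1], ca + dt * k3[2])
        fp = fp + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        fm = fm + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        ca = ca + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if np.min(ca) < 0.0:
            clip_count += int(np.sum(ca < 0.0))
            ca = np.maximum(ca, 0.0)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm)) and np.all(np.isfinite(ca))):
            raise FloatingPointError(f"non-finite field at step {step + 1}")

    if clip_count:
        warnings.warn(
            f"G-actin concentration clipped at zero {clip_count} times", RuntimeWarning
        )

    xr = params.xr0 + (rec_fp / cos_t - rec_fm) / params.kf
    heights = xr * cos_t + rec_fp / params.ks
    return ClusterField(
        mode=config.mode,
        times=times[:k_out],
        heights=heights[:k_out],
        Fp=rec_fp[:k_out],
        Fm=rec_fm[:k_out],
        ca=rec_ca[:k_out],
        h=config.h,
        params=params,
        config=config,
        positions=None if config.mode == "continuum" else positions,
        steady_height=height_s,
        clip_warnings=clip_count,
    )


def kymograph(field: ClusterField, rect: Sequence[float]) -> Kymograph:
    """Extract a kymograph from an axis-aligned rectangle (x0, x1, y0, y1) µm.

    Heights are averaged across the rectangle's short axis and sampled
    along its long axis at the grid resolution, one column per output
    frame.
    """
    x0, x1, y0, y1 = rect
    if not (0 <= x0 < x1 <= field.config.Lx and 0 <= y0 < y1 <= field.config.Ly):
        raise ValueError("rectangle must lie inside the domain")
    along_x = (x1 - x0) >= (y1 - y0)
    h = field.h
    if field.mode == "continuum":
        i0, i1 = int(math.floor(x0 / h)), max(int(math.floor(x0 / h)) + 1, int(math.ceil(x1 / h)))
        j0, j1 = int(math.floor(y0 / h)), max(int(math.floor(y0 / h)) + 1, int(math.ceil(y1 / h)))
        block = field.heights[:, j0:j1, i0:i1]  # (T, ny_sel, nx_sel)
        if block.size == 0:
            raise ValueError("empty rectangle")
        data = (block.mean(axis=1) if along_x else block.mean(axis=2)).T
        pos = ((np.arange(i0, i1) + 0.5) * h) if along_x else ((np.arange(j0, j1) + 0.5) * h)
        step = h
    else:
        pts = field.positions
        sel = (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        if not np.any(sel):
            raise ValueError("empty rectangle")
        coord = pts[sel, 0] if along_x else pts[sel, 1]
        step = field.config.d0
        edges = np.arange(coord.min() - step / 2, coord.max() + step, step)
        idx = np.digitize(coord, edges) - 1
        n_bins = edges.size - 1
        data = np.full((n_bins, field.times.size), np.nan)
        for b in range(n_bins):
            m = idx == b
            if np.any(m):
                data[b] = field.heights[:, sel][:, m].mean(axis=1)
        keep = ~np.isnan(data[:, 0])
        data = data[keep]
        pos = (0.5 * (edges[:-1] + edges[1:]))[keep]
    frame_interval = float(field.times[1] - field.times[0]) if field.times.size > 1 else 0.0
    return Kymograph(
        data=np.asarray(data),
        positions=np.asarray(pos),
        frame_interval=frame_interval,
        pixel_size=step,
        rect=tuple(rect),
    )


def wavefront_radius(
    field: ClusterField, frac: float = 0.05, envelope: bool = True
) -> np.ndarray:
    """Outermost radius (µm) of the propagating height disturbance, per frame.

    With ``envelope=True`` (default) a site counts as disturbed when
    |height − steady| exceeds ``frac``·steady, which tracks the wavefront
    through the retraction half of each oscillation cycle; with
    ``envelope=False`` only height > steady·(1+frac) counts (crests only).
    Frames with no site above threshold report 0.
    """
    cx, cy = field.config.Lx / 2.0, field.config.Ly / 2.0
    thr = field.steady_height * frac
    if field.mode == "continuum":
        ny, nx = field.heights.shape[1:]
        xc = (np.arange(nx) + 0.5) * field.h
        yc = (np.arange(ny) + 0.5) * field.h
        xx, yy = np.meshgrid(xc, yc)
        r = np.hypot(xx - cx, yy - cy)
    else:
        r = np.hypot(field.positions[:, 0] - cx, field.positions[:, 1] - cy)
    out = np.zeros(field.times.size)
    for t in range(field.times.size):
        dev = field.heights[t] - field.steady_height
        mask = np.abs(dev) > thr if envelope else dev > thr
        out[t] = r[mask].max() if np.any(mask) else 0.0
    return out


def stiffness_sweep(
    params: ModelParams,
    config: ClusterConfig,
    ks_values: Sequence[float],
    n_sample: int = 100,
    sample_seed: int = 1,
):
    """Rerun the cluster for each substrate stiffness and summarize.

    For each ks the stall force follows Fsp0(ks) and the consumption
    coefficient scales as µ ∝ ks (see :func:`stiffness_variant`).  The
    summary per stiffness contains the steady protrusive force and
    substrate displacement, the RMS height fluctuation (wave activity),
    the correlation decay length ξ for random-init runs, and the mean
    wavefront speed for radial-init runs.
    """
    results = []
    ks_ref = params.ks
    rng = np.random.default_rng(sample_seed)
    for ks in ks_values:
        p = stiffness_variant(params, ks, ks_ref=ks_ref)
        fps, _, obs = steady_state(p)
        fld = simulate_cluster(p, config)
        summary = {
            "ks": float(ks),
            "Fps": float(fps),
            "l1s": float(obs.l1),
            "height_rms": float(
                np.sqrt(np.mean((fld.heights - fld.steady_height) ** 2))
            ),
            "field": fld,
        }
        if config.init == "random":
            pos = rng.uniform(
                [0.05 * config.Lx, 0.05 * config.Ly],
                [0.95 * config.Lx, 0.95 * config.Ly],
                size=(n_sample, 2),
            )
            traces = fld.height_traces_at(pos)
            n_win = max(64, int(round(25 * 60 / config.output_every)))
            n_frames = traces.shape[1]
            curve = correlation_vs_distance(
                traces[:, max(0, n_frames - n_win) :], pos, window=n_win
            )
            summary["xi"] = curve.xi
        if config.init == "radial":
            radii = wavefront_radius(fld)
            period = 2.0 * math.pi * math.sqrt(
                p.tau_m * characteristic_quantities(p).tau_p
            )
            n_t = int(np.searchsorted(fld.times, 2 * period))
            if n_t >= 2:
                coef = np.polyfit(fld.times[:n_t], radii[:n_t], 1)
                summary["wavefront_speed"] = float(coef[0])
        results.append(summary)
    return results
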