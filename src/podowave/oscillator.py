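"""Single-podosome dynamics: deterministic and noise-driven integration.

The coupled force-variable ODE pair is

    τ0·dFp/dt = Fsp0·(1 − Vd/Vpm) − Fp + (Fsp0·cosθ/(Vpm·kf))·dFm/dt + (Fsp0/Vpm)·χp
    τm·dFm/dt = Fm0 + (α − γ/kf)·Fp/cosθ − (1 − γ/kf)·Fm + χm

with τ0 = (Fsp0/Vpm)(1/kf + 1/ks).  Eliminating dFm/dt from the first
equation yields the explicit two-dimensional system integrated here; the
effective protrusion relaxation time that appears in the linearized theory
is τp = τ0·(1 − γ/kf).  Noise-free runs use a fixed-step classical
Runge–Kutta scheme; runs with ``sigma_p > 0`` or ``sigma_m > 0`` use
Euler–Maruyama with additive Gaussian increments of standard deviation
σ·√dt, which is exact in distribution for this additive-noise system up to
the drift discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import (
    DerivedObservables,
    ModelParams,
    characteristic_quantities,
    derived_observables,
    steady_state,
)

__all__ = ["PodosomeState", "PodosomeTrace", "simulate_single"]


@dataclass(frozen=True)
class PodosomeState:
    """Instantaneous dynamical state: protrusive and myosin force (nN)."""

    Fp: float
    Fm: float
    t: float = 0.0


@dataclass
class PodosomeTrace:
    """A uniformly sampled trajectory of the podosome oscillator."""

    times: np.ndarray
    Fp: np.ndarray
    Fm: np.ndarray
    obs: DerivedObservables
    params: ModelParams
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.Fp) == len(self.Fm)):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def height(self) -> np.ndarray:
        return self.obs.height

    def to_frame(self) -> pd.DataFrame:
        o = self.obs
        return pd.DataFrame(
            {
                "t": self.times,
                "Fp": self.Fp,
                "Fm": self.Fm,
                "l": o.l,
                "l1": o.l1,
                "height": o.height,
                "xr": o.xr,
                "Fr": o.Fr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def resample(self, interval: float) -> "PodosomeTrace":
        """Subsample the trace at (approximately) the given interval (s)."""
        dt = self.times[1] - self.times[0]
        stride = max(1, int(round(interval / dt)))
        sl = slice(None, None, stride)
        return PodosomeTrace(
            times=self.times[sl],
            Fp=self.Fp[sl],
            Fm=self.Fm[sl],
            obs=derived_observables(self.params, self.Fp[sl], self.Fm[sl]),
            params=self.params,
            seed=self.seed,
        )


def _drift_terms(params: ModelParams):
    """Precompute the constant coefficients of the explicit RHS."""
    ch = characteristic_quantities(params)
    cos_t = math.cos(params.theta)
    g = 1.0 - params.gamma / params.kf
    a_cross = params.alpha - params.gamma / params.kf
    tau0 = (ch.Fsp0 / ch.Vpms) * (1.0 / params.kf + 1.0 / params.ks)
    couple = ch.Fsp0 * cos_t / (ch.Vpms * params.kf)
    target = ch.Fsp0 * (1.0 - params.Vd / ch.Vpms)

    def rhs(fp, fm):
        dfm = (params.Fm0 + a_cross * fp / cos_t - g * fm) / params.tau_m
        dfp = (target - fp + couple * dfm) / tau0
        return dfp, dfm

    return rhs, tau0, ch


def _height_form_rhs(params: ModelParams):
    """RHS of the equivalent (height, Fm) representation.

    height = xr0·cosθ + Fp·(1/kf + 1/ks) − Fm·cosθ/kf, so Fp is algebraic
    in (height, Fm); dheight/dt = Vpm·(1 − Fp/Fsp0) − Vd.
    """
    ch = characteristic_quantities(params)
    cos_t = math.cos(params.theta)
    g = 1.0 - params.gamma / params.kf
    a_cross = params.alpha - params.gamma / params.kf
    compliance = 1.0 / params.kf + 1.0 / params.ks

    def fp_of(height, fm):
        return (height - params.xr0 * cos_t + fm * cos_t / params.kf) / compliance

    def rhs(height, fm):
        fp = fp_of(height, fm)
        dfm = (params.Fm0 + a_cross * fp / cos_t - g * fm) / params.tau_m
        dh = ch.Vpms * (1.0 - fp / ch.Fsp0) - params.Vd
        return dh, dfm

    return rhs, fp_of


def simulate_single(
    params: ModelParams,
    init: Optional[PodosomeState] = None,
    t_end: float = 6000.0,
    dt: Optional[float] = None,
    seed: Optional[int] = None,
    form: str = "force",
) -> PodosomeTrace:
    """Integrate the single-podosome system.

    Parameters
    ----------
    params : ModelParams
        Model constants, including the noise intensities ``sigma_p``
        and ``sigma_m``; both zero selects the deterministic RK4 path.
    init : PodosomeState, optional
        Initial condition; defaults to the steady state.
    t_end : float
        Duration (s); must be at least ``10·dt``.
    dt : float, optional
        Fixed step (s); defaults to ``min(tau_m, tau_p)/100``.
    seed : int, optional
        Seed for the noise stream; identical seeds give bit-identical
        traces.
    form : {"force", "height"}
        Integrate the force-variable pair (default) or the equivalent
        (height, Fm) representation; both return the same trace layout.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite, naming the first bad step.
    """
    ch = characteristic_quantities(params)
    if dt is None:
        dt = min(params.tau_m, ch.tau_p) / 100.0
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < 10 * dt:
        raise ValueError("t_end must be at least 10*dt")
    if init is None:
        fps, fms, _ = steady_state(params)
        init = PodosomeState(Fp=fps, Fm=fms)

    n_steps = int(round(t_end / dt))
    times = init.t + dt * np.arange(n_steps + 1)
    fp = np.empty(n_steps + 1)
    fm = np.empty(n_steps + 1)

    noisy = params.sigma_p > 0 or params.sigma_m > 0
    if form == "height":
        rhs, fp_of = _height_form_rhs(params)
        obs0 = derived_observables(params, init.Fp, init.Fm)
        x, y = float(obs0.height), init.Fm
    elif form == "force":
        rhs, tau0, _ = _drift_terms(params)
        x, y = init.Fp, init.Fm
    else:
        raise ValueError("form must be 'force' or 'height'")

    if noisy:
        # Additive-noise mapping of (χp, χm) into the force variables:
        # χm drives Fm directly and leaks into Fp through the dFm/dt
        # coupling term; χp enters Fp scaled by 1/(1/kf + 1/ks).
        if form != "force":
            raise ValueError("noisy runs are integrated in force variables")
        rng = np.random.default_rng(seed)
        compliance = 1.0 / params.kf + 1.0 / params.ks
        cos_t = math.cos(params.theta)
        s_m = params.sigma_m / params.tau_m
        g_fm = s_m
        g_fp_m = (cos_t / params.kf) / compliance * s_m
        g_fp_p = params.sigma_p / compliance
        sq = math.sqrt(dt)
        fp[0], fm[0] = x, y
        for i in range(1, n_steps + 1):
            dfp, dfm = rhs(x, y)
            xi_p, xi_m = rng.standard_normal(2)
            x = x + dfp * dt + (g_fp_p * xi_p + g_fp_m * xi_m) * sq
            y = y + dfm * dt + g_fm * xi_m * sq
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FloatingPointError(
                    f"non-finite state at step {i} (t={times[i]:.3f} s)"
                )
            fp[i], fm[i] = x, y
    else:
        fp[0], fm[0] = (x, y)
        for i in range(1, n_steps + 1):
            k1 = rhs(x, y)
            k2 = rhs(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1])
            k3 = rhs(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1])
            k4 = rhs(x + dt * k3[0], y + dt * k3[1])
            x = x + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            y = y + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FloatingPointError(
                    f"non-finite state at step {i} (t={times[i]:.3f} s)"
                )
            fp[i], fm[i] = x, y

    if form == "height":
        # fp currently holds the height variable; recover Fp algebraically.
        heights = fp.copy()
        fp = np.array([fp_of(h, m) for h, m in zip(heights, fm)])

    obs = derived_observables(params, fp, fm)
    return PodosomeTrace(times=times, Fp=fp, Fm=fm, obs=obs, params=params, seed=seed)


def read_trace_csv(path, params: ModelParams) -> PodosomeTrace:
    """Load a trace written by :meth:`PodosomeTrace.to_csv`."""
    df = pd.read_csv(Path(path))
    fp = df["Fp"].to_numpy()
    fm = df["Fm"].to_numpy()
    return PodosomeTrace(
        times=df["t"].to_numpy(),
        Fp=fp,
        Fm=fm,
        obs=derived_observables(params, fp, fm),
        params=params,
    )
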