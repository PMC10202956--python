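"""Closed-form results for the damped G-actin diffusion wave.

Linearizing the G-actin reaction–diffusion equation around steady state
gives a diffusion-wave equation whose complementary solution
δca ~ e^{iωt + iqr} has complex wavenumber

    q = √(−(iω + ωp)/Da),

with ω the podosome oscillation frequency and ωp = µβVd/Vpms the effective
G-actin consumption rate.  The real part of q sets the wavelength
λ = 2π/|Re(q)|, the imaginary part the spatial damping, and the wavefront
speed is v_c = λ/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DispersionResult",
    "wavenumber",
    "wave_speed_surface",
    "phase_angle",
    "export_table",
    "plot_speed_surface",
]


@dataclass(frozen=True)
class DispersionResult:
    omega: float          # rad/s
    omega_p: float        # 1/s
    Da: float             # µm²/s
    q: complex            # 1/µm, decaying branch (Im(q) <= 0)
    wavelength: float     # µm, 2π/|Re(q)| (inf in the non-oscillatory limit)
    phase_angle: float    # rad, arctan(ω/ωp) − π
    damping_length: float  # µm, 1/|Im(q)|
    wave_speed: float     # µm/s, λ/T


def phase_angle(omega: float, omega_p: float) -> float:
    """φ = arctan(ω/ωp) − π, with the ωp → 0 limit φ = −π/2 taken explicitly."""
    if omega_p == 0.0:
        return -math.pi / 2.0
    return math.atan(omega / omega_p) - math.pi


def wavenumber(omega: float, omega_p: float, Da: float) -> DispersionResult:
    """Complex wavenumber and derived wave observables at (ω, ωp, Da).

    The principal square root of −(iω + ωp)/Da already lies on the
    decaying branch (Im(q) < 0 for ω > 0 under the e^{iωt+iqr} convention);
    the sign is flipped if a non-decaying root is returned.
    """
    if Da <= 0:
        raise ValueError("Da must be > 0")
    if omega < 0 or omega_p < 0:
        raise ValueError("omega and omega_p must be >= 0")
    if omega == 0.0 and omega_p == 0.0:
        raise ValueError("degenerate: omega and omega_p cannot both be zero")

    q = np.sqrt(complex(-omega_p, -omega) / Da)
    if q.imag > 0:
        q = -q

    lam = 2.0 * math.pi / abs(q.real) if q.real != 0.0 else math.inf
    damp = 1.0 / abs(q.imag) if q.imag != 0.0 else math.inf
    phi = phase_angle(omega, omega_p)
    if omega > 0.0:
        period = 2.0 * math.pi / omega
        v_c = lam / period
    else:
        v_c = 0.0  # non-oscillatory limit: nothing propagates
    return DispersionResult(
        omega=omega,
        omega_p=omega_p,
        Da=Da,
        q=q,
        wavelength=lam,
        phase_angle=phi,
        damping_length=damp,
        wave_speed=v_c,
    )


def export_table(omega_grid, omega_p_grid, Da: float, path) -> None:
    """Write a CSV of (omega, omega_p, wavelength, wave_speed) rows."""
    import pandas as pd

    rows = []
    for w in np.asarray(omega_grid, dtype=float):
        for wp in np.asarray(omega_p_grid, dtype=float):
            res = wavenumber(w, wp, Da)
            rows.append(
                {
                    "omega": w,
                    "omega_p": wp,
                    "wavelength_um": res.wavelength,
                    "wave_speed_um_per_s": res.wave_speed,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_speed_surface(omega_grid, omega_p_grid, Da: float, path=None):
    """Render the wavefront-speed surface v_c(ω, ωp) to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = wave_speed_surface(omega_grid, omega_p_grid, Da)
    fig, ax = plt.subplots(figsize=(5, 4))
    m = ax.pcolormesh(omega_p_grid, omega_grid, v * 60.0, shading="nearest")
    fig.colorbar(m, ax=ax, label=r"$v_c$ (µm/min)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$\omega_p$ (1/s)")
    ax.set_ylabel(r"$\omega$ (rad/s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def wave_speed_surface(omega_grid, omega_p_grid, Da: float) -> np.ndarray:
    """Wavefront speed v_c = λ/T on an (ω, ωp) grid.

    Returns an array of shape ``(len(omega_grid), len(omega_p_grid))``.
    v_c decreases with decreasing ω (treatments that abrogate oscillations)
    and with decreasing ωp (softer substrates).
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    omega_p_grid = np.asarray(omega_p_grid, dtype=float)
    if np.any(omega_grid <= 0) or np.any(omega_p_grid <= 0):
        raise ValueError("grids must be positive")
    out = np.empty((omega_grid.size, omega_p_grid.size))
    for i, w in enumerate(omega_grid):
        for j, wp in enumerate(omega_p_grid):
            out[i, j] = wavenumber(w, wp, Da).wave_speed
    return out
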