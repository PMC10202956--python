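"""Linear stability of the podosome oscillator and the (Γ, τm/τp) phase diagram.

Perturbing the steady state gives a quadratic characteristic equation whose
roots are

    ω₁,₂ = [Γ − 1 − τm/τp ± √((Γ − 1 − τm/τp)² − 4·τm/τp)] / (2·τm).

Oscillatory dynamics require a negative discriminant; the real part changes
sign on Γ = 1 + τm/τp (sustained-amplitude boundary, unstable above).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, characteristic_quantities, treatment_preset

__all__ = [
    "EigenResult",
    "PhaseDiagram",
    "eigenvalues",
    "classify_regime",
    "phase_diagram",
    "REGIME_LABELS",
    "OSCILLATORY_LABELS",
]

REGIME_LABELS = (
    "oscillatory_damped",
    "oscillatory_sustained_boundary",
    "oscillatory_unstable",
    "monotonic_stable",
    "unstable",
)
OSCILLATORY_LABELS = frozenset(
    {"oscillatory_damped", "oscillatory_sustained_boundary", "oscillatory_unstable"}
)


@dataclass(frozen=True)
class EigenResult:
    """Eigenvalues of the linearized oscillator and the regime they imply."""

    omega1: complex
    omega2: complex
    regime: str
    period_exact: Optional[float]
    period_approx: float

    @property
    def oscillatory(self) -> bool:
        return self.regime in OSCILLATORY_LABELS


def eigenvalues(Gamma: float, tau_ratio: float, tau_m: float) -> EigenResult:
    """Roots of the characteristic quadratic for feedback ``Gamma`` and
    timescale ratio ``tau_ratio = τm/τp``.

    Regime labelling (ties are deterministic): a discriminant of exactly
    zero is critically damped and labelled ``monotonic_stable`` when the
    repeated root is non-positive; a real part of exactly zero with
    non-zero imaginary part is the ``oscillatory_sustained_boundary``.
    """
    if tau_m <= 0 or tau_ratio <= 0:
        raise ValueError("tau_m and tau_ratio must be > 0")
    b = Gamma - 1.0 - tau_ratio
    disc = b * b - 4.0 * tau_ratio
    sq = cmath.sqrt(complex(disc, 0.0))
    w1 = (b + sq) / (2.0 * tau_m)
    w2 = (b - sq) / (2.0 * tau_m)

    if disc < 0.0:
        re = b / (2.0 * tau_m)
        if re < 0.0:
            regime = "oscillatory_damped"
        elif re == 0.0:
            regime = "oscillatory_sustained_boundary"
        else:
            regime = "oscillatory_unstable"
        period_exact: Optional[float] = 2.0 * math.pi / abs(w1.imag)
    else:
        regime = "monotonic_stable" if b <= 0.0 else "unstable"
        period_exact = None

    period_approx = 2.0 * math.pi * tau_m / math.sqrt(tau_ratio)
    return EigenResult(
        omega1=w1,
        omega2=w2,
        regime=regime,
        period_exact=period_exact,
        period_approx=period_approx,
    )


def classify_regime(params: ModelParams) -> str:
    """Regime label of a parameter set via its (Γ, τm/τp) coordinates."""
    ch = characteristic_quantities(params)
    return eigenvalues(ch.Gamma, params.tau_m / ch.tau_p, params.tau_m).regime


@dataclass
class PhaseDiagram:
    """Regime map over a (Γ, τm/τp) grid plus the analytic boundary curves."""

    Gamma: np.ndarray          # shape (nG,)
    tau_ratio: np.ndarray      # shape (nr,)
    labels: np.ndarray         # shape (nG, nr), dtype=object
    boundaries: dict           # name -> (ratio, Gamma) polylines

    def to_frame(self) -> pd.DataFrame:
        gg, rr = np.meshgrid(self.Gamma, self.tau_ratio, indexing="ij")
        return pd.DataFrame(
            {"Gamma": gg.ravel(), "tau_ratio": rr.ravel(), "label": self.labels.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None):
        """Render the phase diagram to a matplotlib figure (optionally PNG)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = {lab: i for i, lab in enumerate(REGIME_LABELS)}
        codes = np.vectorize(order.get)(self.labels)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.pcolormesh(
            self.tau_ratio, self.Gamma, codes, shading="nearest", cmap="viridis",
            vmin=0, vmax=len(REGIME_LABELS) - 1,
        )
        for name, (rr, gg) in self.boundaries.items():
            ax.plot(rr, gg, "k-", lw=1, label=name)
        ax.set_xscale("log")
        ax.set_xlabel(r"$\tau_m/\tau_p$")
        ax.set_ylabel(r"$\Gamma$")
        ax.legend(fontsize=7, loc="upper left")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def phase_diagram(
    gamma_range: Sequence[float] = (0.0, 4.0),
    ratio_range: Sequence[float] = (0.01, 100.0),
    resolution: int = 101,
    tau_m: float = 64.0,
) -> PhaseDiagram:
    """Dense regime map, Γ linear and τm/τp log-spaced.

    The two analytic boundaries are exported as polylines: the oscillatory
    envelope (discriminant zero, Γ = (1 ± √r)²) and the stability line
    Γ = 1 + r.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    g0, g1 = gamma_range
    r0, r1 = ratio_range
    if r0 <= 0 or r1 <= 0:
        raise ValueError("ratio_range must be positive")
    gammas = np.linspace(g0, g1, resolution) if resolution > 1 else np.array([g0])
    ratios = (
        np.geomspace(r0, r1, resolution) if resolution > 1 else np.array([r0])
    )
    labels = np.empty((gammas.size, ratios.size), dtype=object)
    for i, g in enumerate(gammas):
        for j, r in enumerate(ratios):
            labels[i, j] = eigenvalues(g, r, tau_m).regime

    r_dense = np.geomspace(r0, r1, 512)
    boundaries = {
        "disc=0 (upper)": (r_dense, (1.0 + np.sqrt(r_dense)) ** 2),
        "disc=0 (lower)": (r_dense, (1.0 - np.sqrt(r_dense)) ** 2),
        "Gamma=1+ratio": (r_dense, 1.0 + r_dense),
    }
    return PhaseDiagram(Gamma=gammas, tau_ratio=ratios, labels=labels, boundaries=boundaries)


def treatment_arrows(params: ModelParams) -> pd.DataFrame:
    """(Γ, τm/τp) coordinates of control and each treatment preset."""
    rows = []
    for name in ("control", "cytochalasinD", "blebbistatin", "Y27632"):
        p = treatment_preset(name, params)
        ch = characteristic_quantities(p)
        rows.append(
            {
                "treatment": name,
                "Gamma": ch.Gamma,
                "tau_ratio": p.tau_m / ch.tau_p,
                "regime": classify_regime(p),
            }
        )
    return pd.DataFrame(rows)
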