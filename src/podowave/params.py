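"""Model parameters, characteristic scales, and steady states.

The podosome is modelled as two coupled force-generating processes: actin
polymerization pushing the core against the substrate (protrusive force
``Fp``) and mechanosensitive myosin contraction of the ventral actin
filaments (active force ``Fm``).  Units are fixed package-wide: seconds,
micrometres, nanonewtons; G-actin concentration is in arbitrary units with
the reference (steady-state) concentration ``ca_ref = 1``.

The default parameter set is calibrated so that the steady protrusive force
is 10 nN, the steady ventral-filament length is 1 µm, the steady total core
height is 0.7 µm, and the protrusion and myosin timescales are both 64 s,
placing the oscillation period 2π√(τm·τp) ≈ 400 s; see ``docs/methods.md``
for the calibration procedure.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "CharacteristicScales",
    "DerivedObservables",
    "characteristic_quantities",
    "steady_state",
    "derived_observables",
    "treatment_preset",
    "stiffness_variant",
    "load_params",
    "save_params",
    "TREATMENTS",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the podosome chemo-mechanical model.

    Attributes
    ----------
    Vp0 : float
        Base maximum polymerization speed (µm/s) at zero G-actin.
    beta : float
        Sensitivity of polymerization speed to G-actin concentration
        (µm/s per concentration unit).
    Vd : float
        Constant depolymerization speed (µm/s).
    Fp0 : float
        Characteristic protrusive force on a rigid substrate (nN).
    kc, ks, kf : float
        Core, substrate, and ventral-filament passive stiffness (nN/µm).
    gamma : float
        Length–contractility coupling γ (nN/µm): loss of myosin binding
        sites as the actomyosin filament contracts.
    alpha : float
        Dimensionless mechanosensitive (Rho-ROCK) feedback of ring tension
        on myosin recruitment.
    Fm0 : float
        Base-level myosin force (nN).
    tau_m : float
        Myosin turnover time τm (s).
    theta : float
        Angle between ventral filaments and the core axis (rad).
    sigma_p, sigma_m : float
        White-noise intensities of the polymerization-rate noise χp
        (µm·s^-1/2) and the myosin-force noise χm (nN·s^1/2).
    mu : float
        G-actin consumption coefficient µ (concentration units per µm of
        height change).
    Da : float
        G-actin diffusion constant (µm²/s).
    xr0 : float
        Rest (unloaded) ventral filament length (µm).
    ca_ref : float
        Reference / steady-state G-actin concentration (arbitrary units).
    """

    Vp0: float = 0.00375
    beta: float = 0.015
    Vd: float = 0.009375
    Fp0: float = 40.0
    kc: float = 50.0
    ks: float = 50.0
    kf: float = 25.0
    gamma: float = 0.0
    alpha: float = 2.75
    Fm0: float = 4.0
    tau_m: float = 64.0
    theta: float = math.pi / 3
    sigma_p: float = 0.0
    sigma_m: float = 0.0
    mu: float = 2.05
    Da: float = 0.0275
    xr0: float = 2.56
    ca_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kc", "ks", "kf", "tau_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.Vp0 <= 0 or self.Da <= 0:
            raise ValueError("speeds and diffusion constant must be > 0")
        if self.gamma >= self.kf:
            raise ValueError(
                "unstable passive element: gamma must be < kf "
                f"(gamma={self.gamma}, kf={self.kf})"
            )
        if not 0.0 < self.theta < math.pi / 2:
            raise ValueError("theta must lie in (0, pi/2)")
        if self.sigma_p < 0 or self.sigma_m < 0:
            raise ValueError("noise intensities must be >= 0")
        vpms = self.Vp0 + self.beta * self.ca_ref
        if not 0.0 <= self.Vd <= vpms:
            raise ValueError(
                "require 0 <= Vd <= Vp0 + beta*ca_ref so that the steady "
                f"protrusive force is non-negative (Vd={self.Vd}, Vpms={vpms})"
            )

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CharacteristicScales:
    """Composite quantities governing the podosome dynamics.

    ``Fsp0`` is the stall force on the current substrate, ``Vpms`` the
    steady maximum polymerization speed, ``tau_p`` the protrusion
    timescale, ``Gamma`` the dimensionless signalling feedback, and
    ``omega_p`` the effective G-actin consumption rate (1/s).
    """

    Fsp0: float
    Vpms: float
    tau_p: float
    Gamma: float
    omega_p: float


@dataclass(frozen=True)
class DerivedObservables:
    """Observables derived algebraically from (Fp, Fm).

    All fields may be scalars or arrays.  ``l1 = Fp/ks`` is the substrate
    displacement, ``Fr = Fp/cosθ`` the ring tensile force, ``xr`` the
    ventral-filament length, ``l = xr·cosθ`` the core height above the
    undeformed substrate, ``height = l + l1`` the total core height, and
    ``Fpa = kf·(xr − xr0)`` the passive elastic force; the exact force
    balance ``Fr = Fm + Fpa`` holds by construction.
    """

    l1: np.ndarray
    Fr: np.ndarray
    xr: np.ndarray
    l: np.ndarray
    height: np.ndarray
    Fpa: np.ndarray


def characteristic_quantities(params: ModelParams) -> CharacteristicScales:
    """Compute the composite scales (Fsp0, Vpms, τp, Γ, ωp).

    Fsp0 = Fp0·ks/(kc+ks); Vpms = Vp0 + β·ca_ref;
    τp = (Fsp0/Vpms)·(1/kf + 1/ks)·(1 − γ/kf);
    Γ = (α·kf − γ)/(kf − γ) · ks/(ks + kf);
    ωp = µ·β·Vd/Vpms.
    """
    fsp0 = params.Fp0 * params.ks / (params.kc + params.ks)
    vpms = params.Vp0 + params.beta * params.ca_ref
    tau_p = (
        (fsp0 / vpms)
        * (1.0 / params.kf + 1.0 / params.ks)
        * (1.0 - params.gamma / params.kf)
    )
    gamma_fb = (
        (params.alpha * params.kf - params.gamma)
        / (params.kf - params.gamma)
        * params.ks
        / (params.ks + params.kf)
    )
    omega_p = params.mu * params.beta * params.Vd / vpms
    return CharacteristicScales(
        Fsp0=fsp0, Vpms=vpms, tau_p=tau_p, Gamma=gamma_fb, omega_p=omega_p
    )


def derived_observables(params: ModelParams, Fp, Fm) -> DerivedObservables:
    """Map force variables to geometric observables (heights, lengths)."""
    Fp = np.asarray(Fp, dtype=float)
    Fm = np.asarray(Fm, dtype=float)
    cos_t = math.cos(params.theta)
    l1 = Fp / params.ks
    Fr = Fp / cos_t
    xr = params.xr0 + (Fr - Fm) / params.kf
    l = xr * cos_t
    height = l + l1
    Fpa = params.kf * (xr - params.xr0)
    return DerivedObservables(l1=l1, Fr=Fr, xr=xr, l=l, height=height, Fpa=Fpa)


def steady_state(params: ModelParams):
    """Steady state of the noise-free oscillator.

    Returns
    -------
    (Fps, Fms, observables)
        Steady protrusive force ``Fps = Fsp0·(1 − Vd/Vpms)`` (nN), steady
        myosin force, and the derived observables at steady state.

    Raises
    ------
    ValueError
        If ``Vd > Vpms`` (net depolymerization; no non-negative steady
        protrusion).  ``Vd == Vpms`` is allowed and yields ``Fps = 0``.
    """
    ch = characteristic_quantities(params)
    if params.Vd > ch.Vpms:
        raise ValueError("net depolymerization; no positive steady protrusion")
    fps = ch.Fsp0 * (1.0 - params.Vd / ch.Vpms)
    cos_t = math.cos(params.theta)
    fms = (
        params.kf
        / (params.kf - params.gamma)
        * (params.Fm0 + (params.alpha - params.gamma / params.kf) * fps / cos_t)
    )
    return fps, fms, derived_observables(params, fps, fms)


# Default multiplicative factors of the in-silico pharmacological presets.
TREATMENTS = ("control", "cytochalasinD", "blebbistatin", "Y27632")


def treatment_preset(
    name: str,
    params: ModelParams,
    *,
    cytoD_factor: float = 0.1,
    bleb_factor: float = 20.0,
    y27632_factor: float = 0.05,
) -> ModelParams:
    """Apply an in-silico pharmacological treatment to a parameter set.

    ``cytochalasinD`` inhibits actin polymerization: Vp0, beta and Vd are
    scaled down (default ×0.1) so that τm/τp ≪ 1.  ``blebbistatin``
    inhibits myosin: τm is scaled up (default ×20) so that τm/τp ≫ 1.
    ``Y27632`` inhibits ROCK signalling: α is scaled down (default ×0.05)
    so that the feedback Γ → 0.  ``control`` is the identity.
    """
    if name == "control":
        return params
    if name == "cytochalasinD":
        # Vd is scaled with Vp0/beta so the poisoned machinery still
        # satisfies Vd <= Vpms; the tau_m/tau_p << 1 signature is preserved.
        return params.replace(
            Vp0=params.Vp0 * cytoD_factor,
            beta=params.beta * cytoD_factor,
            Vd=params.Vd * cytoD_factor,
        )
    if name == "blebbistatin":
        return params.replace(tau_m=params.tau_m * bleb_factor)
    if name == "Y27632":
        return params.replace(alpha=params.alpha * y27632_factor)
    raise ValueError(f"unknown treatment {name!r}; valid presets: {TREATMENTS}")


def stiffness_variant(
    params: ModelParams, ks: float, *, ks_ref: float | None = None
) -> ModelParams:
    """Parameter set for a substrate of stiffness ``ks``.

    The stall force follows Fsp0(ks) = Fp0·ks/(kc+ks) automatically through
    ``ks``; the G-actin consumption coefficient scales with stiffness,
    µ(ks) = µ_ref·ks/ks_ref, because stiffer substrates build denser cores
    that turn over more G-actin.
    """
    if ks <= 0:
        raise ValueError("ks must be > 0")
    ref = params.ks if ks_ref is None else ks_ref
    return params.replace(ks=ks, mu=params.mu * ks / ref)


PathLike = Union[str, Path]


def save_params(params: ModelParams, path: PathLike) -> None:
    """Write parameters as a flat YAML or JSON key-value file."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_params(path: PathLike) -> ModelParams:
    """Read a parameter file written by :func:`save_params`."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return ModelParams(**data)
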