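"""End-to-end experiment pipelines with manifests and metrics JSON.

Each experiment runs simulate → analyze → (optionally render) → report and
writes, into its output directory, a ``manifest.json`` (inputs, seed,
package version), a ``metrics.json`` with the headline numbers, and CSV/PNG
artifacts.  Reruns with the same seed produce byte-identical metrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .analysis import amplitude_ratio, correlation_vs_distance, pattern_lifetime
from .cluster import ClusterConfig, kymograph, simulate_cluster, stiffness_sweep
from .fixtures import FixtureSpec, make_fixture
from .imaging import render_movie
from .oscillator import PodosomeState, simulate_single
from .params import (
    ModelParams,
    characteristic_quantities,
    steady_state,
    treatment_preset,
)
from .stability import classify_regime, phase_diagram, treatment_arrows
from .stics import SticsConfig, stics_map

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = (
    "single",
    "phase-diagram",
    "cluster-radial",
    "cluster-random",
    "treatments",
    "stiffness",
    "stics-validation",
)

# noise intensities used when an experiment needs noise-sustained
# oscillations (the noise-free defaults leave sigma_p = sigma_m = 0)
NOISE_SIGMA_P = 0.001   # µm s^-1/2
NOISE_SIGMA_M = 10.0    # nN s^1/2


@dataclass
class ExperimentConfig:
    name: str
    outdir: Path
    seed: int = 1
    params: Optional[ModelParams] = None
    cluster: Optional[ClusterConfig] = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; valid: {EXPERIMENTS}")
        self.outdir = Path(self.outdir)
        if self.params is None:
            self.params = ModelParams()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _single_metrics(params: ModelParams, seed: int, t_end: float = 6000.0) -> dict:
    fps, fms, obs = steady_state(params)
    trace = simulate_single(
        params, init=PodosomeState(Fp=1.1 * fps, Fm=fms), t_end=t_end, dt=0.5
    )
    sampled = trace.resample(15.0)
    peaks = amplitude_ratio(sampled.height[:-1], 15.0)
    tail = sampled.times >= t_end - 4000.0
    return {
        "period_s": peaks.dominant_period,
        "amplitude_ratio": peaks.ratio,
        "mean_Fp_nN": float(sampled.Fp[tail].mean()),
        "mean_xr_um": float(sampled.obs.xr[tail].mean()),
        "mean_height_nm": float(sampled.height[tail].mean() * 1000.0),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a named pipeline end-to-end; returns the metrics dict.

    Any stage failure raises with the stage name prefixed; partial outputs
    written before the failure are preserved in ``outdir``.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    metrics: dict = {"experiment": config.name, "seed": config.seed}
    stage = "setup"
    try:
        if config.name == "single":
            stage = "simulate"
            metrics.update(_single_metrics(params, config.seed))
            ch = characteristic_quantities(params)
            metrics["tau_p_s"] = ch.tau_p
            metrics["tau_m_s"] = params.tau_m
            metrics["Gamma"] = ch.Gamma
            metrics["regime"] = classify_regime(params)
            trace = simulate_single(
                params.replace(sigma_p=NOISE_SIGMA_P, sigma_m=NOISE_SIGMA_M),
                t_end=6000.0,
                dt=0.5,
                seed=config.seed,
            )
            trace.resample(15.0).to_csv(out / "noisy_trace.csv")

        elif config.name == "phase-diagram":
            stage = "phase-diagram"
            pd_res = phase_diagram(tau_m=params.tau_m)
            pd_res.to_csv(out / "phase_diagram.csv")
            pd_res.plot(out / "phase_diagram.png")
            arrows = treatment_arrows(params)
            arrows.to_csv(out / "treatment_arrows.csv", index=False)
            metrics["regimes"] = dict(zip(arrows["treatment"], arrows["regime"]))

        elif config.name in ("cluster-radial", "cluster-random"):
            stage = "simulate-cluster"
            init = "radial" if config.name == "cluster-radial" else "random"
            ccfg = config.cluster or ClusterConfig(init=init, seed=config.seed)
            field = simulate_cluster(params, ccfg)
            stage = "analyze"
            rng = np.random.default_rng(config.seed)
            pos = rng.uniform(
                [0.05 * ccfg.Lx, 0.05 * ccfg.Ly],
                [0.95 * ccfg.Lx, 0.95 * ccfg.Ly],
                size=(100, 2),
            )
            traces = field.height_traces_at(pos)
            # correlate over the last 25 minutes: the developed wave field,
            # not the spatially white initial transient
            n_win = int(round(25 * 60 / ccfg.output_every))
            n_frames = traces.shape[1]
            curve = correlation_vs_distance(
                traces[:, max(0, n_frames - n_win) :], pos, window=n_win
            )
            curve.to_frame().to_csv(out / "correlation_curve.csv", index=False)
            metrics["xi_um"] = curve.xi
            metrics["lambda_f_um"] = curve.lambda_f
            cy = ccfg.Ly / 2.0
            kymo = kymograph(
                field,
                (ccfg.Lx / 2 - 10.0, ccfg.Lx / 2 + 10.0, cy - 1.0, cy + 1.0),
            )
            kymo.to_frame().to_csv(out / "kymograph.csv")
            kymo.plot(out / "kymograph.png")
            try:
                metrics["pattern_lifetime_min"] = pattern_lifetime(
                    kymo, field.steady_height
                )
            except ValueError:
                metrics["pattern_lifetime_min"] = None
            stage = "render"
            movie = render_movie(field, seed=config.seed)
            movie.to_tiff(out / "movie.tif")

        elif config.name == "treatments":
            stage = "simulate-treatments"
            noisy = params.replace(sigma_p=NOISE_SIGMA_P, sigma_m=NOISE_SIGMA_M)
            ratios = {}
            for name in ("control", "blebbistatin", "Y27632"):
                p = treatment_preset(name, noisy)
                trace = simulate_single(p, t_end=6000.0, dt=0.5, seed=config.seed)
                sampled = trace.resample(15.0)
                ratios[name] = amplitude_ratio(sampled.height[:-1], 15.0).ratio
            metrics["amplitude_ratios"] = ratios
            # cytochalasin D makes the linearized single podosome unstable
            # (monotonic growth); report its regime instead of a ratio
            metrics["cytochalasinD_regime"] = classify_regime(
                treatment_preset("cytochalasinD", params)
            )

        elif config.name == "stiffness":
            stage = "stiffness-sweep"
            ccfg = config.cluster or ClusterConfig(
                Lx=15.0, Ly=15.0, t_end=2000.0, seed=config.seed
            )
            ks_values = config.options.get("ks_values", [10.0, params.ks])
            results = stiffness_sweep(params, ccfg, ks_values)
            stage = "stics"
            summary = []
            for res in results:
                movie = render_movie(res.pop("field"), seed=config.seed)
                # wave displacements accumulate slowly: longer TOIs are
                # needed for the lag fit to rise above the fit noise
                vm = stics_map(
                    movie,
                    SticsConfig(roi_shift=16, toi_shift=3, toi_length=8,
                                max_lag=7, prefilter_sigma=3.0, max_speed=10.0),
                )
                res["mean_stics_speed_um_per_min"] = vm.mean_speed()
                summary.append(res)
            metrics["stiffness"] = summary

        elif config.name == "stics-validation":
            stage = "fixture"
            speed = config.options.get("speed", 0.3)
            fx = make_fixture(
                FixtureSpec(kind="translating-movie", speed=speed, seed=config.seed)
            )
            stage = "stics"
            vm = stics_map(
                fx.data, SticsConfig(roi_shift=16, toi_shift=5, immobile_filter="none")
            )
            vm.to_csv(out / "vectors.csv")
            metrics["true_speed_um_per_min"] = speed
            metrics["mean_recovered_speed_um_per_min"] = vm.mean_speed()

    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"experiment {config.name!r} failed at stage {stage!r}") from exc

    manifest = {
        "experiment": config.name,
        "seed": config.seed,
        "version": __version__,
        "params": params.to_dict(),
        "cluster": asdict(config.cluster) if config.cluster else None,
        "options": config.options,
    }
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "metrics.json", metrics)
    return metrics
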