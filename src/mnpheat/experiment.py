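"""End-to-end experiment orchestration: config -> run -> spectra -> fits.

A "run" executes simulate -> autocorrelation -> susceptibility (in the
principal frame of the static tensor) -> Debye fits -> ordering
diagnostics, and persists traces, spectra, fits and a machine-readable
summary.  Sweeps repeat runs over particle radius or surface density with
step counts auto-scaled to the predicted relaxation time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import MagnetizationTrace, simulate
from .lattice import build_square_lattice
from .observables import (field_map_from_diagnostics, net_order,
                          principal_frame, staggered_order, static_tensor)
from .params import SimulationParams, load_config, predicted_relaxation_time
from .response import (DebyeFit, FitFailureError, SusceptibilitySpectrum,
                       autocorrelation, fit_debye, susceptibility)

log = logging.getLogger("mnpheat")

SUMMARY_KEYS = [
    "component", "amplitude", "tau_s", "peak_frequency_rad_s",
    "peak_absorption", "residual",
]


def analyze_trace(trace: MagnetizationTrace, temperature: float,
                  max_lag: float | None = None,
                  use_principal_frame: bool = True):
    """Correlation -> susceptibility -> per-component Debye fits.

    Returns ``(spectrum, fits, tensor, frame)`` where the spectrum and fits
    are expressed in the (n, p, z) principal frame of the static tensor when
    ``use_principal_frame`` (falls back to the lab frame for isotropic or
    degenerate cases).
    """
    tensor = static_tensor(trace, temperature, trace.n_particles)
    frame = np.eye(3)
    names = ["x", "y", "z"]
    if use_principal_frame:
        frame = principal_frame(tensor)
        names = ["n", "p", "z"]
        trace = trace.rotated(frame)
    if max_lag is None:
        max_lag = trace.duration / 8.0
    corr = autocorrelation(trace, max_lag=max_lag)
    spec = susceptibility(corr, temperature, trace.n_particles)
    fits: dict[str, DebyeFit | None] = {}
    for k, name in enumerate(names):
        try:
            fit = fit_debye(spec, k)
            fits[name] = DebyeFit(fit.amplitude, fit.tau, name, fit.residual,
                                  fit.fit_window)
        except FitFailureError as err:
            log.warning("Debye fit failed for %s: %s", name, err)
            fits[name] = None
    return spec, fits, tensor, frame


def _spectrum_frame(spec: SusceptibilitySpectrum, names) -> pd.DataFrame:
    data = {"omega_rad_s": spec.angular_frequencies}
    for k, name in enumerate(names):
        data[f"re_alpha_{name}"] = spec.real(k)
        data[f"im_alpha_{name}"] = spec.imag(k)
    return pd.DataFrame(data)


def run_experiment(config, outdir, output_format: str = "csv",
                   n_steps: int | None = None,
                   seed: int | None = None) -> dict:
    """Execute one full experiment from a config file or dict.

    Writes ``trace.csv`` (or ``.h5``), ``spectrum.csv``, ``field_map.csv``,
    ``params.json`` and ``summary.json`` into ``outdir`` and returns the
    summary dict.
    """
    if isinstance(config, (str, Path)):
        params, extras = load_config(config)
    else:
        extras = dict(config)
        params, extras = _params_from_dict(extras)
    if seed is not None:
        params = params.replace(seed=int(seed))
    errors = []
    n_side = extras.get("n_side")
    spacing = extras.get("spacing")
    if n_side is None:
        errors.append("missing n_side")
    if spacing is None and extras.get("interactions", True):
        errors.append("missing spacing_nm (or set interactions: false)")
    if errors:
        raise ValueError("config errors: " + "; ".join(errors))
    interactions = bool(extras.get("interactions", True)) and n_side > 1
    lattice = build_square_lattice(
        n_side, spacing if spacing is not None else 1.0,
        particle_radius=params.particle_radius if interactions else None)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trace = simulate(
        params, lattice,
        record_stride=extras.get("record_stride"),
        n_steps=n_steps if n_steps is not None else extras.get("n_steps_run"),
        burn_in_steps=extras.get("burn_in_steps"),
        interactions=interactions)

    if output_format == "hdf5":
        trace.save_hdf5(outdir / "trace.h5")
    else:
        trace.save_csv(outdir / "trace.csv")

    spec, fits, tensor, frame = analyze_trace(trace, params.temperature)
    names = ["n", "p", "z"]
    _spectrum_frame(spec, names).to_csv(outdir / "spectrum.csv", index=False)
    field_map_from_diagnostics(trace).to_csv(outdir / "field_map.csv",
                                             index=False)

    diag = trace.diagnostics
    final = diag["final_state"]
    summary = {
        "n_particles": lattice.n_particles,
        "surface_density_nm2": lattice.surface_density_nm2 if interactions else 0.0,
        "seed": params.seed,
        "n_steps": trace.n_samples * diag["record_stride"],
        "record_stride": diag["record_stride"],
        "burn_in_steps": diag["burn_in_steps"],
        "knudsen": diag["knudsen"],
        "equipartition": [float(v) for v in diag["equipartition"]],
        "tau_predicted_s": diag["tau_predicted"],
        "static_eigenvalues": [float(v) for v in tensor.eigenvalues],
        "principal_frame": frame.tolist(),
        "net_order": net_order(final),
        "staggered_order": staggered_order(final) if lattice.n_side ** 2
        == lattice.n_particles else None,
        "components": {},
    }
    for name, fit in fits.items():
        if fit is None:
            summary["components"][name] = None
        else:
            summary["components"][name] = {
                "component": name,
                "amplitude": fit.amplitude,
                "tau_s": fit.tau,
                "peak_frequency_rad_s": fit.peak_frequency,
                "peak_absorption": fit.peak_value,
                "residual": fit.residual,
            }
    (outdir / "params.json").write_text(json.dumps(params.to_dict(), indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _params_from_dict(extras: dict):
    keys = {f.name for f in dataclasses.fields(SimulationParams)}
    kwargs = {k: extras.pop(k) for k in list(extras) if k in keys}
    if "external_field" in kwargs:
        kwargs["external_field"] = tuple(kwargs["external_field"])
    return SimulationParams(**kwargs), extras


@dataclass
class SweepSpec:
    """A one-variable scan: particle radius (m) or surface density (m^-2)."""

    variable: str                       # "radius" | "density"
    values: list[float]                 # SI units, sorted ascending
    seeds: list[int] = field(default_factory=lambda: [0])
    n_side: int = 10
    relaxation_times_recorded: float = 200.0
    outdir: str | Path | None = None

    def __post_init__(self):
        if self.variable not in ("radius", "density"):
            raise ValueError("variable must be 'radius' or 'density'")
        vals = list(self.values)
        if any(v < 0 for v in vals) or sorted(vals) != vals:
            raise ValueError("values must be non-negative and sorted")
        if self.variable == "radius" and any(v <= 0 for v in vals):
            raise ValueError("radii must be strictly positive")
        if not self.seeds:
            raise ValueError("need at least one seed")


def run_sweep(spec: SweepSpec, params: SimulationParams,
              min_steps: int = 100_000) -> pd.DataFrame:
    """Run one experiment per (value, seed) and tabulate the fits.

    Step counts scale with the predicted relaxation time so that at least
    ``spec.relaxation_times_recorded`` relaxation times are recorded at
    every point; dt is reduced automatically when a small radius tightens
    the dt <= I/zeta stability guard.
    """
    rows = []
    for value in spec.values:
        for seed_i in spec.seeds:
            p = params.replace(seed=int(seed_i))
            if spec.variable == "radius":
                # I/zeta = rho_m R^2 / (15 eta); shrink dt with the radius
                mom_relax = (params.mass_density * value ** 2
                             / (15.0 * params.viscosity))
                p = p.replace(particle_radius=value,
                              time_step=min(params.time_step, 0.9 * mom_relax))
                rho, interactions, spacing = 0.0, False, 1.0
                n_side = spec.n_side
            else:
                rho = value
                interactions = rho > 0
                spacing = rho ** -0.5 if rho > 0 else 1.0
                n_side = spec.n_side if interactions else spec.n_side
            tau_pred = predicted_relaxation_time(p, rho)
            n_steps = max(min_steps,
                          int(spec.relaxation_times_recorded * tau_pred
                              / p.time_step))
            cfg = p.to_dict() | {"n_side": n_side, "spacing": spacing,
                                 "interactions": interactions,
                                 "n_steps_run": n_steps,
                                 "burn_in_steps": max(int(20 * tau_pred
                                                          / p.time_step),
                                                      10_000)}
            cfg["external_field"] = tuple(cfg["external_field"])
            outdir = (Path(spec.outdir) / f"{spec.variable}_{value:g}_s{seed_i}"
                      if spec.outdir else Path(".mnpheat_tmp"))
            summary = run_experiment(cfg, outdir, seed=seed_i)
            for name, comp in summary["components"].items():
                if comp is None:
                    continue
                rows.append({
                    "variable": spec.variable, "value": value,
                    "seed": seed_i, "component": name,
                    "rho_nm2": summary["surface_density_nm2"],
                    **{k: comp[k] for k in SUMMARY_KEYS if k != "component"},
                    "tau_predicted_s": summary["tau_predicted_s"],
                    "staggered_order": summary["staggered_order"],
                    "net_order": summary["net_order"],
                })
    df = pd.DataFrame(rows)
    if spec.outdir:
        df.to_csv(Path(spec.outdir) / "sweep_summary.csv", index=False)
    return df
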