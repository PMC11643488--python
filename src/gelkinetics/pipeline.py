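"""End-to-end runs (generate -> analyze -> report) from one structured config.

A run config names a generator (one of the synthetic models) and an ordered
list of analysis stages.  Each stage writes tabular output under the run
directory and contributes fitted parameters to a JSON report that is
bit-identically re-creatable from the same config: all randomness flows
through explicit seeds and the report carries the config hash, seed(s) and
package version as provenance.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .chemistry import hydration_spec, named_polymer
from .dynamics import (detect_modes, diffusion_coefficient, fit_power_law, msd,
                       van_hove_self)
from .errors import GelKineticsError
from .structure import (HBondCriteria, detect_hbonds, first_peak, free_volume,
                        rdf, strip_selection)
from .synthetic import (BilinearVTParams, RouseParams, WalkerParams,
                        gen_bilinear_vt, gen_brownian, gen_cage_hopper,
                        gen_ctrw, gen_fbm, gen_hbond_fixture, gen_packing,
                        gen_rouse)
from .thermo import fit_bilinear, thermal_expansion
from .trajectory import write_xyz

log = logging.getLogger("gelkinetics")

_WALKER_GENERATORS = {
    "brownian": gen_brownian,
    "fbm": gen_fbm,
    "ctrw": gen_ctrw,
    "cage_hop": gen_cage_hopper,
}

KNOWN_STAGES = ("msd", "fit_alpha", "diffusion", "vanhove", "modes",
                "rdf", "hbond", "freevol", "strip", "tg", "hydrate")


@dataclass
class RunConfig:
    generator: Optional[dict] = None
    analyses: list = field(default_factory=list)
    output_dir: str = "run"
    log_level: str = "INFO"
    overwrite: bool = False

    def validate(self):
        for stage in self.analyses:
            if not isinstance(stage, dict) or "stage" not in stage:
                raise GelKineticsError(f"each analysis entry needs a 'stage' key: {stage!r}")
            if stage["stage"] not in KNOWN_STAGES:
                raise GelKineticsError(
                    f"unknown stage {stage['stage']!r}; known: {KNOWN_STAGES}")
        if self.generator is not None:
            if "model" not in self.generator:
                raise GelKineticsError("generator section needs a 'model' key")
            if "seed" not in self.generator and self.generator["model"] not in ("hbond_fixture",):
                raise GelKineticsError("generator seeds must be explicit")

    def canonical_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "analyses": self.analyses},
            sort_keys=True, separators=(",", ":"))

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"generator", "analyses", "output_dir", "log_level", "overwrite"}
    extra = set(raw) - known
    if extra:
        raise GelKineticsError(f"unknown config keys: {sorted(extra)}")
    return RunConfig(**raw)


def _generate(gen: dict):
    """Dispatch the generator section; returns a state dict."""
    params = dict(gen)
    model = params.pop("model")
    if model in _WALKER_GENERATORS:
        traj = _WALKER_GENERATORS[model](WalkerParams(model=model, **params))
        return {"trajectory": traj, "model": model}
    if model == "rouse":
        return {"trajectory": gen_rouse(RouseParams(**params)), "model": model}
    if model == "packing":
        return {"configuration": gen_packing(**params), "model": model}
    if model == "hbond_fixture":
        geoms = [tuple(g) for g in params.pop("geometries")]
        return {"configuration": gen_hbond_fixture(geoms, **params), "model": model}
    if model == "bilinear_vt":
        grid = params.pop("t_grid", None)
        if grid is not None:
            params["t_grid"] = np.asarray(grid, dtype=float)
        return {"vtseries": gen_bilinear_vt(BilinearVTParams(**params)), "model": model}
    raise GelKineticsError(f"unknown generator model {model!r}")


def _need(state, key, stage):
    if key not in state:
        raise GelKineticsError(f"stage {stage!r} needs a {key} (check generator/stage order)")
    return state[key]


def _write_table(path: Path, header: str, columns) -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, header=header, fmt="%.8g")


def run(config: RunConfig) -> dict:
    """Execute a run config; returns the report dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.json"
    if report_path.exists() and not config.overwrite:
        raise GelKineticsError(
            f"{report_path} exists; set overwrite: true to replace it")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    state: dict[str, Any] = {}
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": (config.generator or {}).get("seed"),
        "stages": [],
    }
    if config.generator is not None:
        state.update(_generate(config.generator))
        log.info("generated %s", state["model"])
        if "trajectory" in state:
            write_xyz(state["trajectory"], outdir / "trajectory.xyz")
        elif "configuration" in state:
            write_xyz(state["configuration"], outdir / "configuration.xyz")

    for entry in config.analyses:
        params = dict(entry)
        name = params.pop("stage")
        try:
            result = _run_stage(name, params, state, outdir)
        except GelKineticsError as exc:
            raise GelKineticsError(f"stage {name!r} failed: {exc}") from exc
        report["stages"].append({"stage": name, "params": params, "result": result})
        log.info("stage %s: %s", name, result)

    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_stage(name: str, p: dict, state: dict, outdir: Path) -> dict:
    if name == "msd":
        traj = _need(state, "trajectory", name)
        curve = msd(traj, selection=p.get("selection"),
                    max_lag=p.get("max_lag"), origin_stride=p.get("origin_stride", 1))
        state["msd"] = curve
        _write_table(outdir / "msd.tsv", "lag_ps msd_A2", (curve.lag_times, curve.msd))
        return {"output": "msd.tsv", "n_lags": int(len(curve.lag_times))}
    if name == "fit_alpha":
        curve = _need(state, "msd", name)
        window = tuple(p["window"]) if "window" in p else None
        fit = fit_power_law(curve, window)
        return {"alpha": fit.alpha, "k_alpha": fit.k_alpha,
                "window_ps": list(fit.window), "r_squared": fit.r_squared}
    if name == "diffusion":
        curve = _need(state, "msd", name)
        window = tuple(p["window"]) if "window" in p else None
        res = diffusion_coefficient(curve, window)
        return {"d_cm2_s": res.d, "window_ps": list(res.window),
                "slope_se": res.slope_se, "nonlinear_warning": res.nonlinear_warning}
    if name == "vanhove":
        traj = _need(state, "trajectory", name)
        vh = van_hove_self(traj, selection=p.get("selection"),
                           lag_times=p.get("lags", (10.0,)),
                           dr=p.get("dr", 0.1), r_max=p.get("r_max", 10.0))
        state["vanhove"] = vh
        for i, lag in enumerate(vh.lag_times):
            _write_table(outdir / f"vanhove_lag{lag:g}.tsv", "r_A shell_mass gs",
                         (vh.bin_centers, vh.shell_mass[i], vh.gs[i]))
        return {"lags_ps": [float(x) for x in vh.lag_times]}
    if name == "modes":
        vh = _need(state, "vanhove", name)
        lag = p.get("lag", float(vh.lag_times[0]))
        radii = detect_modes(vh, lag, smooth_width=p.get("smooth_width", 3),
                             min_prominence=p.get("min_prominence", 0.05))
        return {"lag_ps": lag, "mode_radii_A": [float(r) for r in radii]}
    if name == "rdf":
        frames = state.get("configuration") or _need(state, "trajectory", name)
        curve = rdf(frames, p.get("selection_a"), p.get("selection_b"),
                    dr=p.get("dr", 0.1), r_max=p.get("r_max"))
        state["rdf"] = curve
        _write_table(outdir / "rdf.tsv", "r_A g", (curve.bin_centers, curve.g))
        peak = first_peak(curve, p.get("min_height", 1.0))
        return {"output": "rdf.tsv", "first_peak_A": peak}
    if name == "hbond":
        conf = state.get("configuration")
        if conf is None:
            conf = _need(state, "trajectory", name).frame(0)
        crit = HBondCriteria(**p.get("criteria", {}))
        hb = detect_hbonds(conf, crit)
        return {"n_bonds": len(hb),
                "donor_classes": hb.donor_class_counts,
                "acceptor_classes": hb.acceptor_class_counts}
    if name == "freevol":
        conf = state.get("configuration")
        if conf is None:
            conf = _need(state, "trajectory", name).frame(0)
        res = free_volume(conf, probe_radius=p.get("probe_radius", 0.0),
                          grid_spacing=p.get("grid_spacing", 0.25))
        _write_table(outdir / "channels.tsv", "channel_volume_A3",
                     (res.channel_volumes,)) if res.n_channels else None
        return {"ffv_percent": res.ffv, "n_channels": res.n_channels,
                "probe_radius_A": res.probe_radius}
    if name == "strip":
        conf = _need(state, "configuration", name)
        state["configuration"] = strip_selection(conf, p.get("selection", []))
        return {"n_atoms": state["configuration"].n_atoms}
    if name == "tg":
        series = _need(state, "vtseries", name)
        fit = fit_bilinear(series, n_boot=p.get("n_boot", 100), seed=p.get("seed", 0))
        below, above, physical = thermal_expansion(series, fit)
        return {"tg_K": fit.tg, "tg_se_K": fit.tg_se,
                "slope_below": below[0], "slope_above": above[0],
                "degenerate": fit.degenerate, "physical": physical}
    if name == "hydrate":
        spec = hydration_spec(named_polymer(p["polymer"]),
                              p["mass_fraction"], density=p.get("density", 1.1))
        return {"polymer": p["polymer"], "mass_fraction": p["mass_fraction"],
                "n_water": spec.n_water, "cell_edge_A": spec.cell_edge}
    raise GelKineticsError(f"unknown stage {name!r}")  # pragma: no cover
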