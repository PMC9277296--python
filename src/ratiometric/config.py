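"""Run configuration, experiment presets, and on-disk artifacts.

A :class:`RunConfig` fully specifies one experiment: the layer to run
(normal-form population, toggle-switch chamber, or an analytic bound
evaluation), its parameters and the seed.  Configs load from YAML or JSON
with unknown keys rejected (reported with their key path), and every run
writes a metadata echo sufficient to reproduce it.

Presets reproduce the reference experiments of the framework, e.g.
``fig3_relay1`` (400 controllable cells, shutdown relay, u_max 5) or
``fig4_pi`` (mixed controllable/uncontrollable population, PI with k_P=30,
k_I=10).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .error_analysis import residual_bound, verify_event_equivalence
from .population_sim import draw_population, simulate, steady_state_error
from .toggle_consortium import ActuationConstraints, Chamber, run_closed_loop

__all__ = ["RunConfig", "ConfigError", "load_config", "run_experiment", "list_presets", "preset"]


class ConfigError(ValueError):
    pass


@dataclass
class NormalFormSection:
    n: int = 400
    eta_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": 1.0, "high": 5.0})
    x0_dist: dict = field(default_factory=lambda: {"kind": "normal", "mean": 0.0, "variance": 4.0})
    controller: dict = field(default_factory=lambda: {"kind": "relay_shutdown", "u_max": 5.0})
    r_d: float = 0.5
    t_end: float = 1.0
    dt: float = 1e-3
    record_every: int = 10


@dataclass
class ConsortiumSection:
    capacity: int = 200
    controller: str = "relay"
    r_d: float = 0.5
    t_end: float = 2000.0
    dt: float = 0.5
    div_rate_A: float = 1.0 / 42.0
    div_rate_B: float = 1.0 / 42.0
    noise_sigma: float = 0.05
    param_cv: float = 0.2
    pi_gains: list = field(default_factory=lambda: [100.0, 1.5, 1.5, 0.05])
    dead_zone: float = 0.0
    constraints: dict = field(default_factory=dict)


@dataclass
class BoundSection:
    eta_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": -1.0, "high": 14.0})
    u_max: float = 5.0
    r_d: float = 0.5


@dataclass
class RunConfig:
    kind: str = "normal_form"  # normal_form | consortium | bound
    seed: int = 0
    name: str = "custom"
    normal_form: NormalFormSection = field(default_factory=NormalFormSection)
    consortium: ConsortiumSection = field(default_factory=ConsortiumSection)
    bound: BoundSection = field(default_factory=BoundSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)


def _build_section(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) at {path}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    data = dict(data)
    sections = {"normal_form": NormalFormSection, "consortium": ConsortiumSection,
                "bound": BoundSection}
    kwargs: dict[str, Any] = {}
    for key, cls in sections.items():
        if key in data:
            sec = data.pop(key)
            if not isinstance(sec, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(cls, sec, key)
    top_fields = {"kind", "seed", "name"}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown key(s) at top level: {sorted(unknown)}")
    kwargs.update(data)
    cfg = RunConfig(**kwargs)
    if cfg.kind not in ("normal_form", "consortium", "bound"):
        raise ConfigError(f"kind must be normal_form|consortium|bound, got {cfg.kind!r}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config file."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data or {})


# ---------------------------------------------------------------------------
# Presets


def _nf(name, eta, x0, controller, r_d=0.5, t_end=1.0):
    cfg = RunConfig(kind="normal_form", name=name)
    cfg.normal_form = NormalFormSection(
        n=400, eta_dist=eta, x0_dist=x0, controller=controller, r_d=r_d, t_end=t_end
    )
    return cfg


_U15 = {"kind": "uniform", "low": 1.0, "high": 5.0}
_U114 = {"kind": "uniform", "low": -1.0, "high": 14.0}
_N04 = {"kind": "normal", "mean": 0.0, "variance": 4.0}
_N21 = {"kind": "normal", "mean": -2.0, "variance": 1.0}


def _presets() -> dict[str, RunConfig]:
    out = {
        "fig3_relay1": _nf("fig3_relay1", _U15, _N04, {"kind": "relay_shutdown", "u_max": 5.0}),
        "fig3_relay2": _nf("fig3_relay2", _U15, _N04, {"kind": "relay_bangbang", "u_max": 5.0}),
        "fig3_pi": _nf("fig3_pi", _U15, _N04,
                       {"kind": "pi", "u_max": 5.0, "k_p": 30.0, "k_i": 50.0}),
        "fig4_relay1": _nf("fig4_relay1", _U114, _N21,
                           {"kind": "relay_shutdown", "u_max": 5.0}, t_end=3.0),
        "fig4_relay2": _nf("fig4_relay2", _U114, _N21,
                           {"kind": "relay_bangbang", "u_max": 5.0}, t_end=3.0),
        "fig4_pi": _nf("fig4_pi", _U114, _N21,
                       {"kind": "pi", "u_max": 5.0, "k_p": 30.0, "k_i": 10.0}, t_end=3.0),
        "openloop": _nf("openloop", _U15, _N04, {"kind": "open_loop", "u_max": 5.0}),
    }
    cons_relay = RunConfig(kind="consortium", name="consortium_relay")
    cons_relay.consortium = ConsortiumSection(
        controller="relay",
        constraints={"U_aTc": 60.0, "U_IPTG": 0.5, "mode": "t_junction"},
    )
    cons_pi = RunConfig(kind="consortium", name="consortium_pi")
    cons_pi.consortium = ConsortiumSection(
        controller="pi",
        constraints={"U_aTc": 100.0, "U_IPTG": 1.0, "mode": "dial_a_wave"},
    )
    cons_pen = RunConfig(kind="consortium", name="consortium_growth_penalty")
    cons_pen.consortium = ConsortiumSection(
        controller="relay",
        div_rate_A=0.5 / 42.0,  # LacI-high grows at half the TetR-high rate
        constraints={"U_aTc": 60.0, "U_IPTG": 0.5, "mode": "t_junction"},
    )
    out["consortium_relay"] = cons_relay
    out["consortium_pi"] = cons_pi
    out["consortium_growth_penalty"] = cons_pen
    bound = RunConfig(kind="bound", name="fig4_bound")
    out["fig4_bound"] = bound
    return out


def list_presets() -> list[str]:
    return sorted(_presets())


def preset(name: str, seed: int = 0) -> RunConfig:
    try:
        cfg = _presets()[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {list_presets()}") from None
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# Experiment runner


def run_experiment(config: RunConfig, outdir: str | Path, plots: bool = False) -> dict[str, Path]:
    """Execute a config and write its artifacts; returns paths by role.

    Normal-form runs write ``trajectory.csv``, ``events.csv`` and, when the
    population is not fully controllable, ``bound.json``.  Consortium runs
    write ``trajectory.csv``.  Bound runs write ``bound.json`` only.  Every
    run writes ``metadata.json`` with the config echo, seed and version.
    CSV numbers use full double precision so reruns are byte-identical for
    the deterministic layers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta: dict[str, Any] = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "time_units": "a.u." if config.kind == "normal_form" else "min",
    }

    def _write_csv(df: pd.DataFrame, name: str) -> Path:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.17g")
        paths[name.split(".")[0]] = p
        return p

    if config.kind == "normal_form":
        sec = config.normal_form
        pop = draw_population(sec.n, sec.eta_dist, sec.x0_dist, config.seed)
        traj = simulate(pop, sec.controller, sec.r_d, sec.t_end, dt=sec.dt,
                        record_every=sec.record_every)
        _write_csv(traj.samples.rename(columns={"r_A": "rA", "r_B": "rB"}), "trajectory.csv")
        _write_csv(traj.events_frame(), "events.csv")
        report = verify_event_equivalence(traj)
        meta["event_map_equivalent"] = report.passed
        meta["steady_state_error"] = steady_state_error(traj)
        u_max = sec.controller.get("u_max", 0.0) if isinstance(sec.controller, dict) else 0.0
        if u_max:
            rb = residual_bound(sec.eta_dist, u_max, sec.r_d)
            (outdir / "bound.json").write_text(rb.to_json())
            paths["bound"] = outdir / "bound.json"
        if plots:
            paths["plot"] = _plot_error(traj, outdir / "error.png")
    elif config.kind == "consortium":
        sec = config.consortium
        constraints = _build_section(ActuationConstraints, dict(sec.constraints), "consortium.constraints")
        chamber = Chamber(
            capacity=sec.capacity, div_rate_A=sec.div_rate_A, div_rate_B=sec.div_rate_B,
            noise_sigma=sec.noise_sigma, param_cv=sec.param_cv, seed=config.seed,
        ).seed_cells()
        traj = run_closed_loop(
            chamber, constraints, r_d=sec.r_d, t_end=sec.t_end, dt=sec.dt,
            controller=sec.controller, pi_gains=tuple(sec.pi_gains), dead_zone=sec.dead_zone,
        )
        _write_csv(
            traj.samples[["t", "N", "r_A", "r_B", "e_A", "e_B", "u_aTc_norm", "u_IPTG_norm"]]
            .rename(columns={"r_A": "rA", "r_B": "rB", "e_A": "eA", "e_B": "eB"}),
            "trajectory.csv",
        )
        meta["steady_state_error"] = steady_state_error(traj, window_fraction=0.5)
        if plots:
            paths["plot"] = _plot_error(traj, outdir / "error.png")
    else:  # bound
        sec = config.bound
        rb = residual_bound(sec.eta_dist, sec.u_max, sec.r_d)
        (outdir / "bound.json").write_text(rb.to_json())
        paths["bound"] = outdir / "bound.json"

    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    paths["metadata"] = outdir / "metadata.json"
    return paths


def _plot_error(traj, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    ax1.plot(traj.samples["t"], traj.samples["e"], lw=1)
    ax1.axhline(0.0, color="k", lw=0.5)
    ax1.set_ylabel("error e(t)")
    ax2.plot(traj.samples["t"], traj.samples["u"], lw=1, color="C1")
    ax2.set_ylabel("input u(t)")
    ax2.set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
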