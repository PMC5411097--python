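"""Configuration files: strict parsing and round-trip serialization.

YAML is the primary dialect (JSON is valid YAML and therefore also accepted).
Validation is strict — unknown keys are rejected — because the most common
configuration mistake in this model is a unit slip in a rate ratio, and silent
key typos would mask it.  By default all rates are interpreted relative to the
growth rate (kappa means kappa/f0 and so on), matching how parameter values
are conventionally quoted for this model; set ``units: absolute`` to pass raw
rates instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import MultiSpacerParams, MultiState, SingleSpacerParams, SingleState
from .simulate import SimulationConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "params_from_dict",
    "params_to_dict",
    "load_run_config",
    "dump_run_config",
    "run_config_to_dict",
]

_RELATIVE_RATE_KEYS = ("kappa", "g", "mu", "dilution", "phage_decay")

_SINGLE_REQUIRED = ("f0", "r", "K", "kappa", "g", "eta", "alpha", "mu", "b")
_SINGLE_OPTIONAL = ("dilution", "phage_decay")
_MULTI_REQUIRED = ("f", "K", "kappa", "g", "mu", "b", "alpha_vec", "eta_vec")
_MULTI_OPTIONAL = ("dilution", "phage_decay")

_SINGLE_STATE_KEYS = ("n0", "n1", "I0", "I1", "v")
_MULTI_STATE_KEYS = ("n0", "n_vec", "I0", "I_vec", "v")

_SIM_KEYS = (
    "t_max",
    "n_outputs",
    "rel_tol",
    "abs_tol",
    "steady_tol",
    "extinction_threshold",
    "grid",
)

_RUN_KEYS = ("model", "params", "initial_state", "simulation", "sweep", "units", "outputs")


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


def _check_keys(d: dict, required, optional, where: str) -> None:
    unknown = set(d) - set(required) - set(optional)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = set(required) - set(d)
    if missing:
        raise ConfigError(f"missing keys in {where}: {sorted(missing)}")


def params_from_dict(model: str, d: dict, units: str = "relative"):
    """Build a parameter object from a flat config mapping.

    With ``units="relative"`` (default) the rate entries kappa, g, mu,
    dilution, phage_decay are ratios to the growth rate and are rescaled by
    f0 (resp. f); with ``units="absolute"`` they are used verbatim.
    """
    if units not in ("relative", "absolute"):
        raise ConfigError(f"units must be 'relative' or 'absolute', got {units!r}")
    d = dict(d)
    if model == "single":
        _check_keys(d, _SINGLE_REQUIRED, _SINGLE_OPTIONAL, "params (single)")
        base = float(d["f0"])
    elif model == "multi":
        _check_keys(d, _MULTI_REQUIRED, _MULTI_OPTIONAL, "params (multi)")
        base = float(d["f"])
    else:
        raise ConfigError(f"model must be 'single' or 'multi', got {model!r}")
    if units == "relative":
        for k in _RELATIVE_RATE_KEYS:
            if k in d:
                d[k] = float(d[k]) * base
    try:
        if model == "single":
            return SingleSpacerParams(**{k: float(v) for k, v in d.items()})
        return MultiSpacerParams(
            alpha_vec=np.asarray(d.pop("alpha_vec"), dtype=float),
            eta_vec=np.asarray(d.pop("eta_vec"), dtype=float),
            **{k: float(v) for k, v in d.items()},
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e


def params_to_dict(params, units: str = "relative") -> dict:
    """Inverse of :func:`params_from_dict` (keys in canonical order)."""
    d = params.to_dict()
    base = d.get("f0", d.get("f"))
    if units == "relative":
        for k in _RELATIVE_RATE_KEYS:
            if k in d:
                d[k] = d[k] / base
    order = (
        _SINGLE_REQUIRED + _SINGLE_OPTIONAL
        if isinstance(params, SingleSpacerParams)
        else _MULTI_REQUIRED + _MULTI_OPTIONAL
    )
    return {k: d[k] for k in order}


def _state_from_dict(model: str, d: dict, N: int | None):
    if model == "single":
        _check_keys(d, (), _SINGLE_STATE_KEYS, "initial_state (single)")
        return SingleState(**{k: float(v) for k, v in d.items()})
    _check_keys(d, ("n0", "v"), ("n_vec", "I_vec", "I0"), "initial_state (multi)")
    n_vec = np.asarray(d.get("n_vec", np.zeros(N)), dtype=float)
    I_vec = np.asarray(d.get("I_vec", np.zeros(N)), dtype=float)
    return MultiState(
        n0=float(d["n0"]),
        n_vec=n_vec,
        I0=float(d.get("I0", 0.0)),
        I_vec=I_vec,
        v=float(d["v"]),
    )


def _state_to_dict(state) -> dict:
    if isinstance(state, SingleState):
        return {k: getattr(state, k) for k in _SINGLE_STATE_KEYS}
    return {
        "n0": state.n0,
        "n_vec": [float(x) for x in state.n_vec],
        "I0": state.I0,
        "I_vec": [float(x) for x in state.I_vec],
        "v": state.v,
    }


@dataclass(frozen=True)
class RunConfig:
    """One fully-specified run: model choice, parameters, initial condition,
    solver settings, and optionally a sweep block mapping parameter names to
    value grids."""

    model: str
    params: SingleSpacerParams | MultiSpacerParams
    initial_state: SingleState | MultiState
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sweep: dict | None = None
    units: str = "relative"


def run_config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, ("model", "params", "initial_state"), _RUN_KEYS, "config")
    model = raw["model"]
    units = raw.get("units", "relative")
    params = params_from_dict(model, raw["params"], units=units)
    N = params.N if isinstance(params, MultiSpacerParams) else None
    state = _state_from_dict(model, raw["initial_state"], N)
    sim_raw = dict(raw.get("simulation", {}))
    _check_keys(sim_raw, (), _SIM_KEYS, "simulation")
    try:
        sim = SimulationConfig(**sim_raw)
    except ValueError as e:
        raise ConfigError(str(e)) from e
    sweep = raw.get("sweep")
    if sweep is not None:
        if not isinstance(sweep, dict) or not sweep:
            raise ConfigError("sweep block must be a non-empty mapping of param -> grid")
        for k, grid in sweep.items():
            if not isinstance(grid, (list, tuple)) or len(grid) == 0:
                raise ConfigError(f"sweep grid for {k!r} must be a non-empty list")
    return RunConfig(
        model=model,
        params=params,
        initial_state=state,
        simulation=sim,
        sweep=sweep,
        units=units,
    )


def load_run_config(path) -> RunConfig:
    """Parse a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    return run_config_from_dict(raw)


def run_config_to_dict(cfg: RunConfig) -> dict:
    out = {
        "model": cfg.model,
        "units": cfg.units,
        "params": params_to_dict(cfg.params, units=cfg.units),
        "initial_state": _state_to_dict(cfg.initial_state),
        "simulation": cfg.simulation.to_dict(),
    }
    if cfg.sweep is not None:
        out["sweep"] = cfg.sweep
    return out


def dump_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(run_config_to_dict(cfg), sort_keys=False))
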