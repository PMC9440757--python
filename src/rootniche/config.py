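"""Run configuration: load, validate, save.

Configs are TOML (preferred) or JSON with sections ``model``, ``params``,
``solver``, ``grid`` and optional ``scan``, ``sim2d``.  Parameter keys use
the field symbols (``alpha_L``, ``lambda``, ``c``, ...); unknown keys are
rejected so that typos never silently fall back to defaults.  Packaged
default configs for the four 1D variants and the 2D run ship under
``rootniche/configs`` and are accessible through :func:`default_config`.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional

from .models import ConfigError, FullModelParams, Grid1D, ModelParams, ModelSpec

__all__ = [
    "RunConfig",
    "load_config",
    "default_config",
    "config_hash",
    "save_config",
    "params2d_from_config",
]

#: config key -> dataclass field name (lambda is a Python keyword)
_PARAM_ALIASES = {"lambda": "lam"}
_PARAM_ALIASES_INV = {v: k for k, v in _PARAM_ALIASES.items()}


@dataclass
class RunConfig:
    """Fully validated configuration of one run."""

    spec: ModelSpec
    params: ModelParams
    grid: Grid1D
    solver: Dict[str, Any] = field(default_factory=dict)
    scan: Optional[Dict[str, Any]] = None
    sim2d: Optional[Dict[str, Any]] = None
    full_params: Optional[FullModelParams] = None
    seed: int = 0

    def to_dict(self) -> Dict[str, Any]:
        params = {}
        for k, v in asdict(self.params).items():
            params[_PARAM_ALIASES_INV.get(k, k)] = v
        out: Dict[str, Any] = {
            "model": asdict(self.spec),
            "params": params,
            "grid": {"x_min": self.grid.x_min, "x_max": self.grid.x_max, "dx": self.grid.dx},
            "solver": dict(self.solver),
            "seed": self.seed,
        }
        if self.scan is not None:
            out["scan"] = dict(self.scan)
        if self.sim2d is not None:
            out["sim2d"] = dict(self.sim2d)
        if self.full_params is not None:
            out["full_params"] = asdict(self.full_params)
        return out


def _build_params(raw: Dict[str, Any]) -> ModelParams:
    valid = {f.name for f in dc_fields(ModelParams)}
    kwargs = {}
    for key, value in raw.items():
        name = _PARAM_ALIASES.get(key, key)
        if name not in valid:
            raise ConfigError(f"unknown parameter key {key!r}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"parameter {key!r} must be a number, got {value!r}")
        kwargs[name] = float(value)
    return ModelParams(**kwargs)


def _build_spec(raw: Dict[str, Any]) -> ModelSpec:
    valid = {f.name for f in dc_fields(ModelSpec)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown model keys {sorted(unknown)}")
    return ModelSpec(**raw)


def _build_grid(raw: Dict[str, Any]) -> Grid1D:
    valid = {"x_min", "x_max", "dx"}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown grid keys {sorted(unknown)}")
    return Grid1D(**{k: float(v) for k, v in raw.items()})


_TOP_KEYS = {"model", "params", "grid", "solver", "scan", "sim2d", "full_params", "seed"}


def _from_dict(data: Dict[str, Any]) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config sections {sorted(unknown)}")
    spec = _build_spec(dict(data.get("model", {})))
    params = _build_params(dict(data.get("params", {})))
    grid = _build_grid(dict(data.get("grid", {}))) if "grid" in data else Grid1D.euler_default()
    solver = dict(data.get("solver", {}))
    solver.setdefault("method", "euler")
    if solver["method"] not in ("euler", "bvp"):
        raise ConfigError(f"solver.method must be 'euler' or 'bvp', got {solver['method']!r}")
    solver.setdefault("dt", 0.01)
    solver.setdefault("t_final", 1000.0)
    if solver["dt"] <= 0:
        raise ConfigError("solver.dt must be positive")
    scan = data.get("scan")
    if scan is not None:
        allowed = {"axis1", "axis2", "n_points", "dt", "t_final", "method"}
        unknown = set(scan) - allowed
        if unknown:
            raise ConfigError(f"unknown scan keys {sorted(unknown)}")
    sim2d = data.get("sim2d")
    if sim2d is not None:
        allowed = {
            "template", "dt", "t_end", "face_average",
            "D_B_cyt", "D_B_wall", "D_W_cyt", "D_W_wall", "D_Z_cyt", "D_Z_wall",
            "D_GFP_cyt", "D_GFP_wall", "d_GFP",
        }
        unknown = set(sim2d) - allowed
        if unknown:
            raise ConfigError(f"unknown sim2d keys {sorted(unknown)}")
    fp = None
    if "full_params" in data:
        fp = FullModelParams(**{k: float(v) for k, v in data["full_params"].items()})
    return RunConfig(
        spec=spec,
        params=params,
        grid=grid,
        solver=solver,
        scan=scan,
        sim2d=sim2d,
        full_params=fp,
        seed=int(data.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return _from_dict(data)


def default_config(variant: str) -> RunConfig:
    """Packaged default configuration for a model variant
    ("sequestration", "sequestration_z", "repression", "mixed", "mixed2d")."""
    ref = resources.files("rootniche") / "configs" / f"{variant}.toml"
    if not ref.is_file():
        raise ConfigError(f"no packaged config for variant {variant!r}")
    data = tomllib.loads(ref.read_text())
    return _from_dict(data)


def params2d_from_config(sim2d: Dict[str, Any]):
    """Build :class:`rootniche.sim2d.Params2D` from a ``sim2d`` config
    section (ignores non-transport keys like template/dt/t_end)."""
    from .sim2d import Params2D

    defaults = Params2D()
    g = sim2d.get
    return Params2D(
        D_cyt={
            "B": float(g("D_B_cyt", defaults.D_cyt["B"])),
            "W": float(g("D_W_cyt", defaults.D_cyt["W"])),
            "Z": float(g("D_Z_cyt", defaults.D_cyt["Z"])),
        },
        D_wall={
            "B": float(g("D_B_wall", defaults.D_wall["B"])),
            "W": float(g("D_W_wall", defaults.D_wall["W"])),
            "Z": float(g("D_Z_wall", defaults.D_wall["Z"])),
        },
        D_GFP_cyt=float(g("D_GFP_cyt", defaults.D_GFP_cyt)),
        D_GFP_wall=float(g("D_GFP_wall", defaults.D_GFP_wall)),
        d_GFP=float(g("d_GFP", defaults.d_GFP)),
        face_average=str(g("face_average", defaults.face_average)),
    )


def save_config(cfg: RunConfig, path) -> None:
    """Write a config as JSON (loadable by :func:`load_config`)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash embedded in run artifacts for provenance."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
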