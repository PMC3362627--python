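"""Run configuration: load/merge/dump, parameter construction, seeding.

A run configuration is a plain nested mapping with sections ``model``,
``stimulus``, ``analysis`` and ``output`` plus a global ``seed``.  Every
command writes the fully resolved configuration (and the package version)
beside its outputs, so a run can be reproduced bit-exactly from the sidecar
alone.  The global seed expands into per-component seeds through a
``numpy.random.SeedSequence`` spawn tree, which avoids seed collisions
between trials without manual bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .encoding import OUParams
from .gating import CoopGateParams
from .neuron import CWBParams, WBParams

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "resolve_config",
    "dump_config",
    "build_params",
    "build_ou",
    "spawn_seeds",
]

try:
    __version__ = version("coopna")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "model": {
        "wb": dataclasses.asdict(WBParams()),
        "p": CWBParams().p,
        "coop": dataclasses.asdict(CWBParams().coop),
        "kappa": CWBParams().kappa,
        "alpha_hc": CWBParams().alpha_hc,
        "beta_hc": CWBParams().beta_hc,
        "coop_inact": "open-state",
        "q_noncoop": 3,
        "coop_curve": "boltzmann",
    },
    "stimulus": {
        "kind": "step",          # step | ou | ou+sine
        "i0": 0.5,               # µA/cm²
        "i1": 0.0,
        "f": 0.0,                # Hz
        "ou": dataclasses.asdict(OUParams()),
        "t_end": 500.0,          # ms
        "dt": 0.01,              # ms
    },
    "analysis": {
        "criterion_vdot": 10.0,  # mV/ms
        "v_cross": 0.0,          # mV spike detection
        "refractory": 2.0,       # ms
        "jump_tol": 0.2,
        "available_fraction": 1.0,
        "v_grid": [-75.0, 5.0, 0.1],   # start, stop, step for activation curves
        "mu_list": [0.0, 12.0, 24.0, 36.0],
        "p_grid": [0.05, 0.1, 0.2, 0.5],
        "mu_grid": [0.0, 48.0, 96.0, 192.0],
        "f_list": [1.0, 10.0, 100.0],
        "target_rate": 5.0,      # Hz
        "n_trials": 10,
        "t_trial": 5000.0,       # ms
    },
    "output": {"dir": "coopna_out", "format": "csv"},
}


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    """Read a JSON or YAML configuration file (by suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def resolve_config(user: dict | None = None, **overrides) -> dict:
    """Merge user config over the defaults; scalar keyword overrides win.

    ``overrides`` accepts dotted keys, e.g. ``resolve_config(cfg,
    **{"stimulus.dt": 0.005})``.
    """
    import copy

    cfg = _deep_update(copy.deepcopy(DEFAULT_CONFIG), user or {})
    for key, val in overrides.items():
        if val is None:
            continue
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return cfg


def dump_config(cfg: dict, out_dir) -> Path:
    """Write the resolved config (+ tool version) beside the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(cfg)
    payload["coopna_version"] = __version__
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def build_params(cfg: dict) -> CWBParams:
    """Construct CWBParams from the ``model`` section (with validation)."""
    m = cfg["model"]
    try:
        return CWBParams(
            wb=WBParams(**m["wb"]),
            p=m["p"],
            coop=CoopGateParams(**m["coop"]),
            kappa=m["kappa"],
            alpha_hc=m.get("alpha_hc", CWBParams().alpha_hc),
            beta_hc=m.get("beta_hc", CWBParams().beta_hc),
            coop_inact=m.get("coop_inact", "open-state"),
            q_noncoop=m["q_noncoop"],
            coop_curve=m.get("coop_curve", "boltzmann"),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid model configuration: {exc}") from exc


def build_ou(cfg: dict) -> OUParams:
    return OUParams(**cfg["stimulus"]["ou"])


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one global seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]
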