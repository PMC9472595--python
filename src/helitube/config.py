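"""Run configuration: TOML round-trip, validation, batch running.

A :class:`RunConfig` collects the Hamiltonian constants, bath state, kinetic
parameters and trial bookkeeping of a simulation campaign.  Configurations
round-trip losslessly through a flat dotted-section TOML file, and every
output carries the resolved configuration, a config hash and the master
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field

from .analysis import DistributionSummary, aggregate, classify_outcome
from .energetics import EnergyParams
from .lattice import TubuleIndices
from .simulator import AssemblySimulator, BathConditions, SimulationConfig
from .util import spawn_seed

SCHEMA_VERSION = 1

_ENERGY_KEYS = {"E_B": 6.0, "B": 20.0, "k_S": 200.0, "l0": 1.0}
_BATH_KEYS = {"mu": -3.0, "c_SS": 10e-6, "T": 1.0}
_SIM_KEYS = {
    "f_fusion": 1e-3,
    "p_exchange": 0.02,
    "delta_v": 0.1,
    "h_insert": 0.25,
    "r_c": 0.35,
    "stop_length_factor": 3.0,
    "max_sweeps": 1e5,
    "record_every": 20.0,
}
_RUN_KEYS = {"target": [10, 0], "n_trials": 1, "seed": 1}


@dataclass
class RunConfig:
    """Validated, nested run configuration with study-default values."""

    target: TubuleIndices = field(default_factory=lambda: TubuleIndices(10, 0))
    n_trials: int = 1
    seed: int = 1
    energy: dict = field(default_factory=lambda: dict(_ENERGY_KEYS))
    bath: dict = field(default_factory=lambda: dict(_BATH_KEYS))
    sim: dict = field(default_factory=lambda: dict(_SIM_KEYS))

    def energy_params(self) -> EnergyParams:
        return EnergyParams.for_target(self.target, **self.energy)

    def bath_conditions(self) -> BathConditions:
        return BathConditions(**self.bath)

    def sim_config(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(seed=self.seed if seed is None else seed, **self.sim)

    def to_dict(self) -> dict:
        return {
            "run": {
                "target": [self.target.m, self.target.n],
                "n_trials": self.n_trials,
                "seed": self.seed,
            },
            "energy": dict(self.energy),
            "bath": dict(self.bath),
            "sim": dict(self.sim),
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class ConfigError(ValueError):
    """Unknown key or out-of-range value in a configuration file."""


def _take(section: dict, defaults: dict, name: str) -> dict:
    out = dict(defaults)
    for k, v in section.items():
        if k not in defaults:
            raise ConfigError(f"unknown key '{k}' in section [{name}]")
        if not isinstance(v, (int, float, list)):
            raise ConfigError(f"bad value type for '{name}.{k}'")
        out[k] = v
    return out


def parse_config(data: dict) -> RunConfig:
    known = {"run", "energy", "bath", "sim"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown sections {sorted(unknown)}")
    run = _take(data.get("run", {}), _RUN_KEYS, "run")
    energy = _take(data.get("energy", {}), _ENERGY_KEYS, "energy")
    bath = _take(data.get("bath", {}), _BATH_KEYS, "bath")
    sim = _take(data.get("sim", {}), _SIM_KEYS, "sim")
    if energy["E_B"] < 0 or energy["B"] < 0 or energy["k_S"] <= 0:
        raise ConfigError("energy constants out of range")
    if bath["c_SS"] <= 0 or bath["T"] <= 0:
        raise ConfigError("bath constants out of range")
    if sim["f_fusion"] < 0 or sim["p_exchange"] < 0 or sim["r_c"] <= 0:
        raise ConfigError("kinetic frequencies out of range")
    if run["n_trials"] < 1:
        raise ConfigError("n_trials must be >= 1")
    m, n = run["target"]
    return RunConfig(
        target=TubuleIndices(int(m), int(n)),
        n_trials=int(run["n_trials"]),
        seed=int(run["seed"]),
        energy={k: float(v) for k, v in energy.items()},
        bath={k: float(v) for k, v in bath.items()},
        sim={k: float(v) for k, v in sim.items()},
    )


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration (defaults for absent keys)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parse_config(data)


def _toml_scalar(v):
    if isinstance(v, list):
        return "[" + ", ".join(str(x) for x in v) + "]"
    if isinstance(v, float) and (math.isinf(v) or math.isnan(v)):
        raise ConfigError("non-finite value in config")
    return repr(v) if isinstance(v, float) else str(v)


def save_config(cfg: RunConfig, path) -> None:
    lines = []
    for section, values in cfg.to_dict().items():
        lines.append(f"[{section}]")
        for k, v in values.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# --------------------------------------------------------------------------
# batch running
# --------------------------------------------------------------------------

def run_batch(cfg: RunConfig, progress=None):
    """Run ``cfg.n_trials`` independent trajectories and aggregate outcomes.

    Per-trial seeds derive deterministically from (master seed, trial index),
    so any scheduling would give identical results; trials are executed
    serially.  Returns (records, summary).
    """
    p = cfg.energy_params()
    bath = cfg.bath_conditions()
    records = []
    for i in range(cfg.n_trials):
        seed = spawn_seed(cfg.seed, i)
        sim = AssemblySimulator(cfg.target, p, bath, cfg.sim_config(seed=seed))
        traj = sim.run()
        rec = classify_outcome(traj)
        records.append(rec)
        if progress is not None:
            progress(i, rec, traj)
    finished = [r for r in records if r.category != "unfinished"]
    if finished:
        summary = aggregate(finished, target=cfg.target)
    else:
        summary = DistributionSummary(
            n_trials=0,
            frac_defect_free=0.0,
            frac_defective=0.0,
            frac_open=0.0,
            geometry_fractions={},
            target=cfg.target,
            target_yield=0.0,
            mean_D=None,
            delta_D=None,
            mean_L_close=None,
        )
    return records, summary


def summary_payload(cfg: RunConfig, summary) -> dict:
    """Summary JSON object with schema version, config and hash embedded."""
    return {
        "schema_version": SCHEMA_VERSION,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "summary": summary.to_dict(),
    }
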