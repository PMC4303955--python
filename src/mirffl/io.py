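"""Configuration files and artifact readers/writers.

All outputs are plain text: trajectory CSV (``time,w,q,s,r,p``) with a JSON
sidecar of the fully resolved run metadata, epsilon summaries as JSON, and
noise tables as tidy CSV.  Every file embeds enough provenance (parameters,
seeds, settings) to regenerate it.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .integrate import SimulationSettings, Trajectory
from .models import ConfigurationError, Mechanism, ParameterSet, SPECIES, Topology, default_parameters
from .noise import EpsilonSummary
from .sweeps import TableCell, table_to_frame

__all__ = [
    "NoiseConfig",
    "RunConfig",
    "default_parameters",
    "load_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_epsilon_summary",
    "write_table",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Settings of the TF-noise experiment."""

    n_rep: int = 100
    amplitude: float = 0.10
    amplitude_mode: str = "relative"
    master_seed: int = 0
    normalization: str = "steady_state"
    innovation: str = "sqrt"


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run: model selection, coefficients, solver, noise."""

    mechanism: Mechanism = Mechanism.STOP
    topology: Topology = Topology.IN1
    params: ParameterSet = field(default_factory=ParameterSet)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism.name,
            "topology": self.topology.label,
            "params": self.params.as_dict(),
            "settings": dataclasses.asdict(self.settings),
            "noise": dataclasses.asdict(self.noise),
        }


_TOP_KEYS = {"mechanism", "topology", "params", "settings", "noise"}


def _check_keys(given: dict, allowed: set[str], section: str) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {section}: {', '.join(unknown)}")


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Every key is optional (an empty file yields all defaults); unknown keys
    are rejected, listing every offender.  Steady-state preconditions are
    surfaced at load time: all degradation rates must be positive.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    params_over = raw.get("params") or {}
    _check_keys(params_over, set(ParameterSet().as_dict()), "params")
    # YAML 1.1 reads bare scientific notation like 2e-5 as a string
    for key, value in list(params_over.items()):
        if isinstance(value, str):
            params_over[key] = float(value)
        if key == "c":
            params_over[key] = int(params_over[key])
    params = ParameterSet(**{**default_parameters().as_dict(), **params_over})
    for name in ("gw", "gq", "gs", "gr", "gp"):
        if getattr(params, name) <= 0:
            raise ConfigurationError(
                f"validation error: degradation rate {name} must be > 0 "
                f"(got {getattr(params, name)})"
            )
    settings_over = raw.get("settings") or {}
    _check_keys(settings_over, set(dataclasses.asdict(SimulationSettings())), "settings")
    noise_over = raw.get("noise") or {}
    _check_keys(noise_over, set(dataclasses.asdict(NoiseConfig())), "noise")
    return RunConfig(
        mechanism=Mechanism.from_name(raw.get("mechanism", "stop")),
        topology=Topology.from_name(raw.get("topology", "1In")),
        params=params,
        settings=SimulationSettings(**settings_over),
        noise=NoiseConfig(**noise_over),
    )


def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_config(config: RunConfig, path: str | os.PathLike) -> None:
    _atomic_write_text(Path(path), yaml.safe_dump(config.to_dict(), sort_keys=False))


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Trajectory CSV (``time,w,q,s,r,p``) plus a ``.meta.json`` sidecar.

    Floats are written with shortest round-trip precision, so reading the
    file back reproduces grids and states bit-exactly.
    """
    path = Path(path)
    lines = ["time," + ",".join(SPECIES)]
    for t, row in zip(traj.times, traj.states):
        lines.append(",".join(repr(float(v)) for v in (t, *row)))
    _atomic_write_text(path, "\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    _atomic_write_text(sidecar, json.dumps(traj.meta, indent=2, cls=_NumpyJSONEncoder))


def read_trajectory(path: str | os.PathLike) -> Trajectory:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["time", *SPECIES]:
            raise ConfigurationError(f"unexpected trajectory header {header!r} in {path}")
        rows = [[float(v) for v in row] for row in reader if row]
    arr = np.asarray(rows)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trajectory(times=arr[:, 0], states=arr[:, 1:], meta=meta)


def write_epsilon_summary(summary: EpsilonSummary, path: str | os.PathLike) -> None:
    """Full epsilon ensemble as JSON: replicate values, summary, config."""
    payload = {
        "epsilons": list(map(float, summary.epsilons)),
        "mean": summary.mean,
        "n_positive": summary.n_positive,
        "config": summary.config,
    }
    _atomic_write_text(Path(path), json.dumps(payload, indent=2, cls=_NumpyJSONEncoder))


def write_table(cells: Sequence[TableCell], path: str | os.PathLike) -> None:
    """Noise table as tidy CSV: loop,model,param,value,eps_mean,n_positive."""
    frame = table_to_frame(cells)
    _atomic_write_text(Path(path), frame.to_csv(index=False))
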