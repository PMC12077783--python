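"""CSV/JSON/YAML input and output.

Trajectories, COM series and event logs are written as plain CSV;
configurations round-trip through JSON or YAML files that mirror
:class:`~cohesim.core.SimulationConfig` field for field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ClusterConfig, Ensemble, SimulationConfig
from .protrusion import ProtrusionConfig
from .rheology import RheologyParams

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "write_ensemble",
]


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    cluster = ClusterConfig(**data.pop("cluster", {}))
    rheology = RheologyParams(**data.pop("rheology", {}))
    protrusion = ProtrusionConfig(**data.pop("protrusion", {}))
    return SimulationConfig(
        cluster=cluster, rheology=rheology, protrusion=protrusion, **data
    )


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as JSON or YAML, selected by file suffix."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_config(path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return config_from_dict(data)


def _positions_frame(ensemble: Ensemble) -> pd.DataFrame:
    n_rep, n_t, n_a = ensemble.positions.shape
    return pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(n_rep), n_t * n_a),
            "timestep": np.tile(np.repeat(np.arange(n_t), n_a), n_rep),
            "agent_index": np.tile(np.arange(1, n_a + 1), n_rep * n_t),
            "x": ensemble.positions.ravel(),
        }
    )


def _com_frame(ensemble: Ensemble) -> pd.DataFrame:
    com = ensemble.com
    n_rep, n_t = com.shape
    return pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(n_rep), n_t),
            "timestep": np.tile(np.arange(n_t), n_rep),
            "com": com.ravel(),
        }
    )


def write_ensemble(ensemble: Ensemble, out_dir, summary: dict | None = None) -> None:
    """Write trajectories.csv, com.csv, events.csv and metadata.json.

    ``metadata.json`` records the full configuration, the replicate seeds and
    the RNG algorithm (PCG64), plus any summary statistics supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _positions_frame(ensemble).to_csv(out / "trajectories.csv", index=False)
    _com_frame(ensemble).to_csv(out / "com.csv", index=False)
    ensemble.events.to_csv(out / "events.csv", index=False)
    meta = {
        "config": config_to_dict(ensemble.config),
        "replicate_seeds": list(ensemble.seeds),
        "rng": "numpy.random.Generator(PCG64)",
    }
    if summary:
        meta["summary"] = summary
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
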