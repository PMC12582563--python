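"""Configuration loading, trajectory serialization and run manifests.

Configs are YAML with explicit units in key names; unknown keys are rejected
with their path. Trajectories round-trip through a columnar CSV with a
JSON-in-comment header and a trailing checksum, so truncated or edited files
are detected on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationConfig, Trajectory
from .regulation import RegulationConfig
from .sensors import SensorConfig


@dataclass
class ConfigBundle:
    sensors: SensorConfig
    regulation: RegulationConfig
    simulation: SimulationConfig


_SCHEMA = {
    "sensors": {
        "target_f": "target_f", "target_s": "target_s", "target_d": "target_d",
        "delta_f": "delta_f", "delta_s": "delta_s", "delta_d": "delta_d",
        "tau_error_ms": "tau_error_ms", "rho": "rho", "delta_alpha": "delta_alpha",
        "norm_order": "norm_order", "tau_alpha_ms": "tau_alpha_ms",
    },
    "regulation": {
        "tau_g_s": "tau_g_s", "tau_half_s": "tau_half_s",
        "gamma": "gamma", "gamma_hat": "gamma_hat",
    },
    "simulation": {
        "rtol": "rtol", "atol": "atol", "save_dt_ms": "save_dt_ms",
        "snapshot_dt_ms": "snapshot_dt_ms", "max_steps": "max_steps",
        "alpha_threshold": "alpha_threshold", "alpha_smooth_s": "alpha_smooth_s",
        "sustain_min": "sustain_min", "freeze_verify_s": "freeze_verify_s",
    },
}


def _coerce(value):
    if isinstance(value, str) and value.strip().lower() in ("inf", "infinity", "∞"):
        return math.inf
    return value


def load_config(path=None) -> ConfigBundle:
    """Load a configuration bundle; unspecified keys get the model defaults.

    ``path`` may be None (all defaults), a YAML file path, or a dict.
    Unknown sections or keys raise ``ValueError`` naming the offending path.
    """
    if path is None:
        raw = {}
    elif isinstance(path, dict):
        raw = path
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")

    kwargs = {"sensors": {}, "regulation": {}, "simulation": {}}
    for section, entries in raw.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section {section!r}")
        if entries is None:
            continue
        for key, value in entries.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            kwargs[section][_SCHEMA[section][key]] = _coerce(value)
    return ConfigBundle(
        sensors=SensorConfig(**kwargs["sensors"]),
        regulation=RegulationConfig(**kwargs["regulation"]),
        simulation=SimulationConfig(**kwargs["simulation"]),
    )


def config_hash(bundle: ConfigBundle) -> str:
    payload = json.dumps(
        {k: dataclasses.asdict(getattr(bundle, k)) for k in ("sensors", "regulation", "simulation")},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


_TRAJ_COLUMNS = ("time_ms", "v_mV", "ca_uM", "alpha")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the fixed-grid series plus coarse full-state snapshots and a checksum."""
    path = Path(path)
    df = pd.DataFrame({
        "time_ms": traj.t_ms, "v_mV": traj.v, "ca_uM": traj.ca, "alpha": traj.alpha,
    })
    meta = {
        "columns": list(_TRAJ_COLUMNS),
        "seed": traj.seed,
        "snapshots_t_ms": np.asarray(traj.snapshots_t_ms).tolist(),
        "snapshots": np.asarray(traj.snapshots).tolist(),
        "final_state": np.asarray(traj.final_state).tolist(),
    }
    body = "# " + json.dumps(meta) + "\n" + df.to_csv(index=False, float_format="%.17g")
    digest = hashlib.sha256(body.encode()).hexdigest()
    path.write_text(body + f"# sha256 {digest}\n")


def read_trajectory(path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; raises on checksum mismatch."""
    text = Path(path).read_text()
    head, _, tail = text.rpartition("# sha256 ")
    if not head or not tail:
        raise ValueError(f"{path}: missing checksum — truncated or not a trajectory file")
    if hashlib.sha256(head.encode()).hexdigest() != tail.strip():
        raise ValueError(f"{path}: checksum mismatch — file corrupt")
    meta_line, _, csv_body = head.partition("\n")
    meta = json.loads(meta_line.lstrip("# "))
    from io import StringIO

    df = pd.read_csv(StringIO(csv_body), float_precision="round_trip")
    if list(df.columns) != list(_TRAJ_COLUMNS):
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    return Trajectory(
        t_ms=df["time_ms"].to_numpy(),
        v=df["v_mV"].to_numpy(),
        ca=df["ca_uM"].to_numpy(),
        alpha=df["alpha"].to_numpy(),
        snapshots_t_ms=np.asarray(meta["snapshots_t_ms"], dtype=float),
        snapshots=np.asarray(meta["snapshots"], dtype=float),
        final_state=np.asarray(meta["final_state"], dtype=float),
        seed=meta.get("seed"),
    )


@dataclass
class RunManifest:
    """Everything needed to re-run a workflow bit-compatibly."""

    command: str
    seed: Optional[int]
    config_hash: str
    outputs: list
    start_biological_ms: float = 0.0
    end_biological_ms: float = 0.0

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @staticmethod
    def read(path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))
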