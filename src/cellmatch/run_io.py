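"""Configuration parsing, run manifests, and artifact readers/writers.

All artifacts are plain text: configurations, trajectories, profiles and
sweep tables as CSV (UTF-8, '.' decimal), run manifests as JSON.  A manifest
records the package version, master seed and full parameter dump, which is
sufficient to replay any output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import AdhesionParameters, gamma as gamma_of
from .errors import ConfigurationError
from .geometry import (
    DEFAULT_LENGTH_PARAMS,
    TissueConfiguration,
    TypeLengthParams,
    WILDTYPE_N_CELLS,
    WILDTYPE_PATTERN,
)
from .metropolis import MCMCSettings
from .vertex_dynamics import VertexDynamicsParameters

_KNOWN_KEYS = {
    "N", "pattern", "pattern_row2",
    "eps_SS", "eps_TT", "eps_ST", "K", "E0", "deltaX", "n_steps",
    "record_every", "seed",
    "L0_S_mean", "L0_S_std", "L0_T_mean", "L0_T_std",
    "lengths_csv",
    "T_SS", "T_TT", "T_ST", "t0", "xi", "dt", "t_end",
    "n_replicates",
}


@dataclasses.dataclass
class ParameterBundle:
    """Validated parameters assembled from a config file plus defaults."""

    n_cells: int
    pattern: str
    pattern_row2: str | None
    length_params: Mapping[str, TypeLengthParams]
    adhesion: AdhesionParameters
    mcmc: MCMCSettings
    dynamics: VertexDynamicsParameters
    n_replicates: int
    seed: int
    lengths_csv: str | None
    defaulted: list[str]
    gamma: float

    def as_dict(self) -> dict[str, Any]:
        d = {
            "n_cells": self.n_cells,
            "pattern": self.pattern,
            "pattern_row2": self.pattern_row2,
            "length_params": {
                k: {"mean": v.mean, "std": v.std} for k, v in self.length_params.items()
            },
            "adhesion": dataclasses.asdict(self.adhesion),
            "mcmc": dataclasses.asdict(self.mcmc),
            "dynamics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in dataclasses.asdict(self.dynamics).items()
            },
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "lengths_csv": self.lengths_csv,
            "defaulted": self.defaulted,
            "gamma": self.gamma,
        }
        return d


def load_config(path: str | Path) -> ParameterBundle:
    """Read and validate a YAML (or TOML) run configuration.

    Unknown keys are an error, as are unit violations (K <= 0, dt <= 0, ...).
    Omitted keys fall back to documented defaults and are listed in the
    bundle's ``defaulted`` record; notably ``E0`` defaults to ``0.1 * K``
    (effective temperature a tenth of the elastic scale per μm²).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        raw = tomllib.loads(text)
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping of keys to values")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")

    defaulted: list[str] = []

    def get(key: str, default):
        if key in raw:
            return raw[key]
        defaulted.append(key)
        return default

    K = float(get("K", 1.0))
    if not K > 0:
        raise ConfigurationError(f"K must be > 0, got {K}")
    adhesion = AdhesionParameters(
        eps_SS=float(get("eps_SS", 0.0)),
        eps_TT=float(get("eps_TT", 0.0)),
        eps_ST=float(get("eps_ST", 0.0)),
        K=K,
    )
    E0 = float(get("E0", 0.1 * K))
    mcmc = MCMCSettings(
        deltaX=float(get("deltaX", 0.05)),
        E0=E0,
        n_steps=int(get("n_steps", 4_000_000)),
        record_every=raw.get("record_every"),
        seed=int(get("seed", 0)),
    )
    t0 = raw.get("t0")
    if t0 is not None:
        dynamics = VertexDynamicsParameters.from_t0(
            float(t0),
            K=float(get("K", 100.0)) if "K" in raw else 100.0,
            xi=float(get("xi", 1000.0)),
            dt=float(get("dt", 0.01)),
            t_end=float(get("t_end", 600.0)),
        )
    else:
        dynamics = VertexDynamicsParameters(
            T_SS=float(get("T_SS", 0.0)),
            T_TT=float(get("T_TT", 0.0)),
            T_ST=float(get("T_ST", 0.0)),
            K=100.0,
            xi=float(get("xi", 1000.0)),
            dt=float(get("dt", 0.01)),
            t_end=float(get("t_end", 600.0)),
        )
    length_params = {
        "S": TypeLengthParams(
            mean=float(get("L0_S_mean", DEFAULT_LENGTH_PARAMS["S"].mean)),
            std=float(get("L0_S_std", DEFAULT_LENGTH_PARAMS["S"].std)),
        ),
        "T": TypeLengthParams(
            mean=float(get("L0_T_mean", DEFAULT_LENGTH_PARAMS["T"].mean)),
            std=float(get("L0_T_std", DEFAULT_LENGTH_PARAMS["T"].std)),
        ),
    }
    return ParameterBundle(
        n_cells=int(get("N", WILDTYPE_N_CELLS)),
        pattern=str(get("pattern", WILDTYPE_PATTERN)),
        pattern_row2=raw.get("pattern_row2"),
        length_params=length_params,
        adhesion=adhesion,
        mcmc=mcmc,
        dynamics=dynamics,
        n_replicates=int(get("n_replicates", 30)),
        seed=int(get("seed", 0)),
        lengths_csv=raw.get("lengths_csv"),
        defaulted=defaulted,
        gamma=gamma_of(adhesion),
    )


# ----------------------------------------------------------------- manifests
def make_manifest(
    bundle: ParameterBundle | None = None,
    extra: Mapping[str, Any] | None = None,
    input_files: Mapping[str, str | Path] | None = None,
) -> dict[str, Any]:
    """Assemble a JSON-serialisable run manifest."""
    manifest: dict[str, Any] = {
        "tool": "cellmatch",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if bundle is not None:
        manifest["parameters"] = bundle.as_dict()
        manifest["seed"] = bundle.seed
    if input_files:
        manifest["input_hashes"] = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in input_files.items()
        }
    if extra:
        manifest.update(extra)
    return manifest


def write_outputs(
    prefix: str | Path,
    tables: Mapping[str, pd.DataFrame],
    manifest: Mapping[str, Any],
) -> list[Path]:
    """Write tidy CSVs plus a JSON manifest under a common prefix.

    ``tables`` maps suffixes (e.g. ``"trajectory"``) to DataFrames; each is
    written to ``<prefix>_<suffix>.csv``.  Empty frames produce header-only
    files.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for suffix, df in tables.items():
        p = prefix.parent / f"{prefix.name}_{suffix}.csv"
        df.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
    mp = prefix.parent / f"{prefix.name}_manifest.json"
    mp.write_text(json.dumps(_jsonify(manifest), indent=2, sort_keys=True))
    written.append(mp)
    return written


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_config_csv(config: TissueConfiguration, path: str | Path) -> Path:
    """Write a configuration as ``row,index,type,x_left,x_right,L0``.

    Floats are written with 17 significant digits, which round-trips IEEE
    doubles exactly.
    """
    path = Path(path)
    config.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_config_csv(path: str | Path) -> TissueConfiguration:
    """Inverse of :func:`write_config_csv` (exact round-trip)."""
    return TissueConfiguration.from_frame(
        pd.read_csv(path, float_precision="round_trip")
    )
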