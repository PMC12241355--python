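"""Tabular I/O, run configuration, and run manifests.

All trial tables are UTF-8 CSV with a header row, 0-based action indices,
string session labels (PBO/MPH/SUL) and 0/1 booleans — deliberately plain so
fixtures diff cleanly and round-trip bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitConfig
from .model import ModelOptions
from .simulate import PopulationSpec
from .task import TaskConfig

__all__ = [
    "SCHEMAS",
    "read_trials",
    "write_trials",
    "RunConfig",
    "load_config",
    "write_manifest",
]

# required column -> pandas dtype used on read
SCHEMAS: dict[str, dict[str, str]] = {
    "training": {
        "block_id": "int64",
        "set_size": "int64",
        "trial_index": "int64",
        "stimulus_id": "int64",
        "action": "int64",
        "correct": "int64",
        "points": "int64",
    },
    "test": {
        "left_stimulus": "int64",
        "right_stimulus": "int64",
        "choice": "object",
        "rt": "float64",
    },
    "subjects": {
        "subject_id": "int64",
        "da": "float64",
    },
}


def read_trials(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a trial table; unknown columns are preserved.

    Raises a schema error naming any missing required column and an ordering
    error for non-time-ordered training trials.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema '{schema}' (expected one of {list(SCHEMAS)})")
    df = pd.read_csv(path, float_precision="round_trip")
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    for col, dtype in required.items():
        if len(df):
            df[col] = df[col].astype(dtype)
    if schema == "training" and len(df):
        keys = [k for k in ("subject_id", "session_label", "block_id") if k in df.columns]
        diffs = df.groupby(keys, sort=False)["trial_index"].diff().dropna()
        if (diffs <= 0).any():
            raise ValueError(f"{path}: training trials are not time-ordered within block")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Everything a pipeline stage needs; no hidden globals.

    The global seed is split into independent per-stage streams with
    :meth:`stage_rng`, so adding draws to one stage never perturbs another.
    """

    seed: int = 0
    out_dir: Path = Path("rlwm_out")
    task: TaskConfig = field(default_factory=TaskConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    model_options: ModelOptions = field(default_factory=ModelOptions)
    n_ppc_draws: int = 20
    recovery_n_subjects: int = 30
    verbosity: int = 1

    _STAGES = ("simulate", "fit", "recover", "ppc", "analyze")

    def stage_rng(self, stage: str) -> np.random.Generator:
        if stage not in self._STAGES:
            raise ValueError(f"unknown stage '{stage}'")
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(self._STAGES))
        return np.random.default_rng(children[self._STAGES.index(stage)])


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file; absent keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "out_dir" in raw:
        cfg.out_dir = Path(raw["out_dir"])
    if "n_ppc_draws" in raw:
        cfg.n_ppc_draws = int(raw["n_ppc_draws"])
    if "recovery_n_subjects" in raw:
        cfg.recovery_n_subjects = int(raw["recovery_n_subjects"])
    for key, obj in (
        ("task", cfg.task),
        ("fit", cfg.fit),
        ("model_options", cfg.model_options),
    ):
        for k, v in (raw.get(key) or {}).items():
            if not hasattr(obj, k):
                raise ValueError(f"unknown {key} option '{k}'")
            if k == "blocks_per_set_size":
                v = {int(a): int(b) for a, b in v.items()}
            elif k == "reward_points":
                v = {int(a): float(b) for a, b in v.items()}
            elif k == "set_sizes":
                v = tuple(int(x) for x in v)
            setattr(obj, k, v)
    pop = raw.get("population") or {}
    for k, v in pop.items():
        if k == "base_params":
            from .model import ModelParams

            cfg.population.base_params = ModelParams(**v)
            continue
        if not hasattr(cfg.population, k):
            raise ValueError(f"unknown population option '{k}'")
        if k == "sessions":
            v = tuple(v)
        setattr(cfg.population, k, v)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    config_echo: dict,
    outputs: list[Path],
    started: float,
) -> Path:
    """Write a JSON run manifest: config echo, versions, wall time, checksums."""
    import rlwm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": config_echo,
        "versions": {
            "rlwm": rlwm.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "wall_time_s": round(time.time() - started, 3),
        "outputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in outputs
        ],
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
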