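"""Run configuration: one YAML schema, strict validation, per-stage
seed derivation."""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "paths": {
        "out_dir": "connfact_out",
        "matrices_dir": None,
        "parcellation": None,
        "phenotypes": None,
        "scales": None,
        "model_dir": None,
    },
    "model": {
        "k": 4,
        "alpha": None,          # defaults to symmetric 50/K
        "eta": 0.01,
        "n_restarts": 10,
        "max_iter": 500,
        "tol": 1e-5,
    },
    "encoding": {
        "scale": 10.0,
        "clip": 3.0,
        "fisher_z": False,
        "reference": "normalized",   # or "raw"
    },
    "stats": {
        "n_perm": 10000,
        "n_boot": 100,
        "fdr_alpha": 0.05,
        "fraction_top": 0.10,
        "site_column": "site",
        "covariate_columns": [],
        "paired_test": "ranksum",    # or "signed_rank"
    },
    "simulate": {
        "n_patients": 215,
        "n_controls": 173,
        "k": 4,
        "n_regions": 128,
        "sparsity": 0.15,
        "block_bias": 4.0,
        "noise_sd": 0.5,
        "dirichlet_alpha": None,     # defaults to ones
        "n_sites": 3,
        "phenotype_noise_sd": 1.0,
        "coupling_effect": 1.0,
    },
}

_RANGES = {
    ("model", "k"): (2, 64),
    ("model", "eta"): (1e-8, 100.0),
    ("model", "n_restarts"): (1, 1000),
    ("model", "max_iter"): (1, 100000),
    ("encoding", "scale"): (1e-6, 1e6),
    ("encoding", "clip"): (1e-6, 100.0),
    ("stats", "n_perm"): (1, 10**7),
    ("stats", "n_boot"): (0, 10**5),
    ("stats", "fdr_alpha"): (0.0, 1.0),
    ("stats", "fraction_top"): (0.0, 1.0),
    ("simulate", "n_patients"): (1, 10**6),
    ("simulate", "n_controls"): (2, 10**6),
    ("simulate", "sparsity"): (0.0, 1.0),
    ("simulate", "noise_sd"): (1e-9, 100.0),
}

# stage codes used to derive independent per-stage RNG streams
STAGE_CODES = {"simulate": 1, "fit": 2, "infer": 3, "associate": 4,
               "dice": 5, "bootstrap": 6}


@dataclass(frozen=True)
class RunConfig:
    data: Mapping[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: SeedSequence(root, stage_code)."""
        ss = np.random.SeedSequence([self.seed, STAGE_CODES[stage]])
        return int(ss.generate_state(1)[0])

    def out_dir(self) -> Path:
        return Path(self.data["paths"]["out_dir"])


def _merge(defaults: Mapping, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in out:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value, here)
        else:
            out[key] = value
    return out


def _check_ranges(data: Mapping) -> None:
    for (section, key), (lo, hi) in _RANGES.items():
        value = data[section][key]
        if value is None:
            continue
        if not (lo <= float(value) <= hi):
            raise ValueError(
                f"config {section}.{key}={value} outside [{lo}, {hi}]")


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load YAML config merged over defaults; unknown keys are rejected
    and numeric parameters range-checked."""
    data: Mapping[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, Mapping):
                raise ValueError("config file must contain a mapping")
            data = loaded
    merged = _merge(DEFAULTS, data)
    if overrides:
        merged = _merge(merged, overrides)
    _check_ranges(merged)
    return RunConfig(merged)
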