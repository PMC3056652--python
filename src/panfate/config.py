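"""Run configuration: JSON/YAML loading, validation and report writing.

JSON is the canonical on-disk format; YAML is accepted on input.  A
configuration document may specify any subset of keys; everything else is
filled from the published defaults.  Unknown keys are rejected with the
offending key path in the error message.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import Ensemble, ensemble_to_frame
from .fates import classify_ensemble, count_attractors, detect_branchings, marker_thresholds
from .network import (
    GENES,
    GeneNetwork,
    ParameterSet,
    build_alternative_network,
    build_master_network,
)
from .perturb import PRESETS, Schedule

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "write_report"]

log = logging.getLogger("panfate")

_TOP_KEYS = {"variant", "toggles", "params", "schedule", "preset", "output_dir"}
_PARAM_KEYS = {
    "a", "k", "eta_single", "eta_multi", "n", "lambda_mat", "D", "dt",
    "t_end", "save_interval", "n_cells", "seed", "self_hill", "self_scale",
    "mat_gate_scale", "mat_gate_hill", "hnf6_mode",
}


@dataclass(frozen=True)
class RunConfig:
    network: GeneNetwork
    params: ParameterSet
    schedule: Schedule = field(default_factory=Schedule)
    output_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "variant": self.network.variant,
            "toggles": list(self.network.toggles),
            "params": self.params.to_dict(),
            "schedule": self.schedule.to_dict(),
            "output_dir": self.output_dir,
        }


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _validate(doc: dict, path: str = "") -> None:
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    params = doc.get("params", {})
    bad = set(params) - _PARAM_KEYS
    if bad:
        raise ValueError(f"unknown key(s) under 'params': {sorted(bad)}")
    for g in params.get("a", {}):
        if g not in GENES:
            raise ValueError(f"params.a names unknown gene {g!r}")
    for key in ("k", "eta_single", "eta_multi", "lambda_mat", "D", "dt", "t_end"):
        if key in params and params[key] < 0:
            raise ValueError(f"params.{key} must be nonnegative, got {params[key]}")


def from_dict(doc: dict) -> RunConfig:
    _validate(doc)
    variant = doc.get("variant", "master")
    toggles = doc.get("toggles", ())
    if variant == "master":
        network = build_master_network(toggles)
    elif variant == "alternative":
        network = build_alternative_network(toggles)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    pdoc = dict(doc.get("params", {}))
    if "a" in pdoc:
        a = ParameterSet().a
        a.update({g: float(v) for g, v in pdoc["a"].items()})
        pdoc["a"] = a
    params = ParameterSet.from_dict(pdoc) if pdoc else ParameterSet()
    if "preset" in doc and "schedule" in doc:
        raise ValueError("specify either 'preset' or 'schedule', not both")
    if "preset" in doc:
        name = doc["preset"]
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
        schedule = PRESETS[name]
    elif "schedule" in doc:
        schedule = Schedule.from_dict(doc["schedule"])
    else:
        schedule = Schedule()
    return RunConfig(network, params, schedule, doc.get("output_dir", "."))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            doc = yaml.safe_load(text) or {}
        else:
            doc = json.loads(text) if text.strip() else {}
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"{path} must contain a mapping at top level")
    return from_dict(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, default=float) + "\n")


def write_report(ens: Ensemble, cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write trajectory CSV, per-cell classification CSV and summary JSON.

    Filenames embed the config hash; the summary records seed and hash for
    provenance.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    paths = {}

    traj_path = out / f"trajectories_{h}.csv"
    ensemble_to_frame(ens).to_csv(traj_path, index=False, float_format="%.6g")
    paths["trajectories"] = traj_path

    thr = marker_thresholds(ens.network, ens.params)
    calls = classify_ensemble(ens, thr)
    cells = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in ens.trajectories],
            "cell_type": [c.label for c in calls],
            "marker_pattern": ["".join(map(str, c.marker_vector)) for c in calls],
        }
    )
    cell_path = out / f"cell_types_{h}.csv"
    cells.to_csv(cell_path, index=False)
    paths["cell_types"] = cell_path

    n_att, patterns = count_attractors(ens, thr)
    branch = detect_branchings(ens, thr)
    summary = {
        "n_attractors": n_att,
        "patterns": ["".join(map(str, p)) for p in patterns],
        "cell_type_counts": cells["cell_type"].value_counts().to_dict(),
        "branchings": [
            {
                "pair": list(b.switch_pair),
                "split": b.split_detected,
                "sizes": list(b.subpopulation_sizes),
                "time": b.detection_time,
            }
            for b in branch
        ],
        "seed": ens.params.seed,
        "config_hash": h,
    }
    sum_path = out / f"summary_{h}.json"
    sum_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    paths["summary"] = sum_path
    log.info(
        "run %s: variant=%s n_cells=%d D=%g seed=%d -> %d attractors",
        h, cfg.network.variant, len(ens), ens.params.D, ens.params.seed, n_att,
    )
    return paths
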