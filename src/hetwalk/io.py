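"""Config and result serialization: YAML/JSON problem descriptions, CSV time
series, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SpecificationError
from .heterogeneity import HeterogeneitySet
from .lattice import LatticeSpec

__all__ = [
    "load_problem",
    "problem_from_dict",
    "problem_to_dict",
    "write_timeseries",
    "read_timeseries",
    "write_summary",
]


def problem_to_dict(spec: LatticeSpec, hset: HeterogeneitySet | None = None) -> dict:
    out = {"lattice": spec.to_dict()}
    if hset is not None:
        out["defects"] = hset.to_json()
    return out


def problem_from_dict(data: dict) -> tuple[LatticeSpec, HeterogeneitySet]:
    if "lattice" not in data:
        raise SpecificationError("problem description needs a 'lattice' section")
    spec = LatticeSpec.from_dict(data["lattice"])
    hset = HeterogeneitySet.from_declarative(spec, data.get("defects", []))
    return spec, hset


def load_problem(path) -> tuple[LatticeSpec, HeterogeneitySet]:
    """Read a lattice + defect description from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return problem_from_dict(data)


def write_timeseries(path, values: np.ndarray, column: str = "probability") -> None:
    """Write a time series as CSV with columns ``(t, <column>)``."""
    pd.DataFrame(
        {"t": np.arange(len(values)), column: np.asarray(values)}
    ).to_csv(path, index=False)


def read_timeseries(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[df.columns[1]].to_numpy()


def write_summary(path, summary: dict) -> None:
    """JSON summary writer (means, reach probabilities, metadata)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, float) and (o != o or o in (float("inf"), float("-inf"))):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(summary, indent=2, default=default) + "\n")
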