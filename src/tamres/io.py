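"""File formats: tidy CSV for datasets and reports, JSON for parameters/fits.

CSV dialects
------------
* growth file: columns ``week`` (int), ``condition`` (``tam``/``ctrl``),
  ``growth_rate`` (float) — both arms in one file;
* proportions file: columns ``week`` (int), ``subpopulation``
  (``S``/``P``/``R1``/``R2``), ``fraction`` (float);
* fit ensembles: a JSON array of fit records.

Floats are serialized with 12 significant digits so repeated runs with the
same seeds produce byte-identical files.  Every writer also drops a
``<path>.meta.json`` sidecar carrying a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fitting import SUBPOPULATIONS, ExperimentDataset, FitResult

__all__ = [
    "config_hash",
    "write_dataframe",
    "write_growth_csv",
    "write_proportions_csv",
    "read_growth_csv",
    "read_proportions_csv",
    "load_dataset",
    "save_fits",
    "load_fits",
]

FLOAT_FORMAT = "%.12g"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _write_sidecar(path: Path, meta: dict | None) -> None:
    if meta is not None:
        sidecar = path.with_name(path.name + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def write_dataframe(frame: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    _write_sidecar(path, meta)


def write_growth_csv(data: ExperimentDataset, path: str | Path, meta: dict | None = None) -> None:
    weeks = np.arange(1, data.n_weeks + 1)
    frame = pd.DataFrame(
        {
            "week": np.concatenate([weeks, weeks]),
            "condition": ["tam"] * data.n_weeks + ["ctrl"] * data.n_weeks,
            "growth_rate": np.concatenate([data.growth_tam, data.growth_ctrl]),
        }
    )
    write_dataframe(frame, path, meta)


def write_proportions_csv(data: ExperimentDataset, path: str | Path, meta: dict | None = None) -> None:
    rows = []
    for j, week in enumerate(data.proportion_weeks):
        for k, sub in enumerate(SUBPOPULATIONS):
            rows.append({"week": week, "subpopulation": sub,
                         "fraction": data.proportions[j, k]})
    write_dataframe(pd.DataFrame(rows), path, meta)


def _require_columns(frame: pd.DataFrame, required: set[str], path: Path) -> None:
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def read_growth_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a growth file; returns (growth_tam, growth_ctrl) by ascending week."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"growth file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, {"week", "condition", "growth_rate"}, path)
    out = {}
    for cond in ("tam", "ctrl"):
        sub = frame[frame["condition"] == cond].sort_values("week")
        if sub.empty:
            raise SchemaError(f"{path}: no rows for condition {cond!r}")
        weeks = sub["week"].to_numpy()
        expected = np.arange(1, len(weeks) + 1)
        if not np.array_equal(weeks, expected):
            raise SchemaError(
                f"{path}: condition {cond!r} must cover weeks 1..{len(weeks)} "
                "contiguously"
            )
        out[cond] = sub["growth_rate"].to_numpy(dtype=float)
    return out["tam"], out["ctrl"]


def read_proportions_csv(path: str | Path) -> tuple[np.ndarray, tuple[int, ...]]:
    """Read a proportions file; returns (matrix, weeks) with rows by week."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"proportions file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, {"week", "subpopulation", "fraction"}, path)
    weeks = tuple(sorted(frame["week"].unique()))
    matrix = np.empty((len(weeks), len(SUBPOPULATIONS)))
    for j, week in enumerate(weeks):
        sub = frame[frame["week"] == week]
        for k, name in enumerate(SUBPOPULATIONS):
            rows = sub[sub["subpopulation"] == name]
            if len(rows) != 1:
                raise SchemaError(
                    f"{path}: week {week} needs exactly one row for "
                    f"subpopulation {name!r}, found {len(rows)}"
                )
            matrix[j, k] = float(rows["fraction"].iloc[0])
    return matrix, tuple(int(w) for w in weeks)


def load_dataset(growth_path: str | Path, proportions_path: str | Path) -> ExperimentDataset:
    """Assemble an ExperimentDataset from the two CSV files."""
    growth_tam, growth_ctrl = read_growth_csv(growth_path)
    proportions, weeks = read_proportions_csv(proportions_path)
    return ExperimentDataset(
        growth_tam=growth_tam,
        growth_ctrl=growth_ctrl,
        proportions=proportions,
        proportion_weeks=weeks,
    )


def save_fits(fits: list[FitResult], path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.write_text(json.dumps([f.to_dict() for f in fits], indent=2) + "\n")
    _write_sidecar(path, meta)


def load_fits(path: str | Path) -> list[FitResult]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"fits file not found: {path}")
    records = json.loads(path.read_text())
    if not isinstance(records, list):
        raise SchemaError(f"{path}: expected a JSON array of fit records")
    return [FitResult.from_dict(r) for r in records]
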