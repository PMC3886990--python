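"""Delimited-text I/O for trajectories and time courses, plus run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Trajectory
from .synthetic import SyntheticTimeCourse

_REQUIRED_COLUMNS = ("time_days", "csc_proportion")


class SchemaError(ValueError):
    """A time-course file violates the expected CSV schema."""


def write_timecourse(path, obj, include_generations: bool = False) -> None:
    """Write a :class:`Trajectory`, :class:`SyntheticTimeCourse` or DataFrame
    as CSV (columns time_days, csc_count, nscc_total, csc_proportion, ...)."""
    if isinstance(obj, Trajectory):
        frame = obj.to_frame(include_generations=include_generations)
    elif isinstance(obj, SyntheticTimeCourse):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} as a time course")
    frame.to_csv(path, index=False)


def read_timecourse(path) -> pd.DataFrame:
    """Read and validate a time-course CSV.

    Requires the columns ``time_days`` and ``csc_proportion``, a non-empty
    body and strictly increasing times.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"time-course file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path} lacks required columns: {', '.join(missing)}")
    if frame.empty:
        raise SchemaError(f"{path} has a header but no rows")
    times = frame["time_days"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SchemaError(f"{path}: time_days must be strictly increasing")
    return frame


def write_manifest(out_dir, *, seed: int, config_text: str = "",
                   extra: dict | None = None) -> Path:
    """Record what produced a run: config hash, seed and library versions."""
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "versions": {
            "cscdyn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
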