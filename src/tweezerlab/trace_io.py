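"""Trace and table I/O.

Traces are stored as CSV with unit-annotated headers
(``time_s,bead_nm,trap_nm,force_pN``) plus a JSON sidecar
``<name>.meta.json`` carrying trap/motor parameters and the simulation seed.
Bead-count tables are CSV with columns ``concentration,n_total,n_motile``.
All writers round-trip finite values bit-identically (full ``repr``
precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .processivity import MotileFractionSeries
from .simulate import BeadTrace

__all__ = ["read_trace", "write_trace", "read_bead_counts", "write_bead_counts"]

_TRACE_COLUMNS = ["time_s", "bead_nm", "trap_nm", "force_pN"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_trace(trace: BeadTrace, path) -> Path:
    """Write a trace as CSV plus its JSON metadata sidecar."""
    path = Path(path)
    df = trace.to_dataframe()
    with open(path, "w") as fh:
        fh.write(",".join(_TRACE_COLUMNS) + "\n")
        np.savetxt(
            fh,
            np.column_stack([df[c].to_numpy() for c in _TRACE_COLUMNS]),
            fmt="%.17g",  # exact float64 round-trip
            delimiter=",",
        )
    meta = dict(trace.metadata)
    meta.setdefault("schema_version", 1)
    meta["stiffness_pN_per_nm"] = trace.stiffness
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trace(path, stiffness: float | None = None) -> BeadTrace:
    """Read and validate a trace.

    The force column is recomputed from the stored positions and stiffness
    and must agree with the stored force to within 1e-6 pN; the time grid
    must be uniform and strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    meta_path = _sidecar(path)
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if stiffness is None:
        stiffness = metadata.get("stiffness_pN_per_nm")
        if stiffness is None:
            trap = metadata.get("trap", {})
            stiffness = trap.get("stiffness")
    if stiffness is None:
        raise ValueError("stiffness not given and not present in sidecar metadata")
    trace = BeadTrace(
        time=df["time_s"].to_numpy(),
        bead_position=df["bead_nm"].to_numpy(),
        trap_position=df["trap_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        stiffness=float(stiffness),
        metadata=metadata,
    )
    trace.validate(rtol=1e-6)
    return trace


def write_bead_counts(series: MotileFractionSeries, path) -> Path:
    path = Path(path)
    series.table[["concentration", "n_total", "n_motile"]].to_csv(path, index=False)
    return path


def read_bead_counts(path) -> MotileFractionSeries:
    """Read a ``concentration,n_total,n_motile`` table and populate
    fractions and exact Clopper–Pearson intervals."""
    df = pd.read_csv(path)
    missing = [c for c in MotileFractionSeries.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if (df["n_total"] < 1).any() or (df["n_motile"] < 0).any():
        raise ValueError("negative or zero counts")
    if (df["n_motile"] > df["n_total"]).any():
        raise ValueError("n_motile exceeds n_total")
    return MotileFractionSeries.from_counts(
        df["concentration"].to_numpy(),
        df["n_total"].to_numpy(),
        df["n_motile"].to_numpy(),
    )
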