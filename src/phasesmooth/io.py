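"""Readers and writers for signals, decompositions and reports.

Interchange formats are deliberately plain: comma-separated text with a
header row for time series ('.' decimal, UTF-8), JSON for reports and
configuration.  The sampling rate travels either as a function argument /
CLI flag or in a JSON sidecar ``{"fs": <Hz>, ...}`` next to the data file.
EDF reading for EEG recordings is available when ``mne`` is installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .analytic import PhaseDecomposition, RealSignal
from .evaluate import BenchmarkConfig, BenchmarkResult, ChangePointReport

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_decomposition",
    "write_report",
    "read_benchmark",
    "write_benchmark",
]

_DECOMP_COLUMNS = [
    "time",
    "envelope",
    "wrapped_phase",
    "unwrapped_phase",
    "residual",
    "inst_frequency",
]


def _read_sidecar_fs(path: Path) -> Optional[float]:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        if "fs" in meta:
            return float(meta["fs"])
    return None


def read_timeseries(path, fs: Optional[float] = None, format: Optional[str] = None) -> List[RealSignal]:
    """Read one or more channels from delimited text (or EDF).

    CSV: one column per channel, header row with channel ids; the sampling
    rate comes from ``fs`` or a ``<file>.json`` sidecar.  Rows with
    non-finite values are rejected with their row numbers reported.
    EDF (``format='edf'`` or a ``.edf`` suffix): channels and fs from the
    header, via mne.
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        try:
            import mne
        except ImportError as e:  # pragma: no cover - depends on extras
            raise ImportError("EDF support requires the 'mne' package") from e
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data()
        return [
            RealSignal(data[i], fs=float(raw.info["sfreq"]), channel_id=name)
            for i, name in enumerate(raw.ch_names)
        ]
    if fmt != "csv":
        raise ValueError(f"unknown format: {fmt!r}")
    if fs is None:
        fs = _read_sidecar_fs(path)
    if fs is None:
        raise ValueError(
            f"sampling rate for {path} not given and no sidecar {path.name}.json found"
        )
    frame = pd.read_csv(path)
    bad = frame.index[~np.isfinite(frame).all(axis=1)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"non-finite values in {path} at file row(s) {rows}")
    return [RealSignal(frame[c].to_numpy(), fs=float(fs), channel_id=str(c)) for c in frame.columns]


def write_timeseries(signals: List[RealSignal], path, meta: Optional[dict] = None) -> None:
    """Write channels as CSV plus a JSON sidecar holding fs and metadata."""
    path = Path(path)
    frame = pd.DataFrame(
        {s.channel_id or f"ch{i}": s.samples for i, s in enumerate(signals)}
    )
    frame.to_csv(path, index=False)
    sidecar = {"fs": signals[0].fs}
    if meta:
        sidecar.update(meta)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(_jsonable(sidecar), fh, indent=2, sort_keys=True)


def write_decomposition(d: PhaseDecomposition, path) -> None:
    """Write a phase decomposition as CSV with a fixed column order."""
    n = len(d)
    frame = pd.DataFrame(
        {
            "time": np.arange(n) / d.fs,
            "envelope": d.envelope,
            "wrapped_phase": d.wrapped_phase,
            "unwrapped_phase": d.unwrapped_phase,
            "residual": d.residual,
            "inst_frequency": d.inst_frequency,
        },
        columns=_DECOMP_COLUMNS,
    )
    frame.to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(result, path) -> None:
    """Write a JSON-serializable report (deterministic key order).

    Accepts :class:`ChangePointReport`, dataclasses, dicts and nested
    numpy-bearing structures.
    """
    if isinstance(result, ChangePointReport):
        payload = result.to_dict()
    else:
        payload = _jsonable(result)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_benchmark(result: BenchmarkResult, path) -> None:
    """Write the tidy benchmark table as CSV."""
    result.table.to_csv(path, index=False)


def read_benchmark(path, config: Optional[BenchmarkConfig] = None) -> BenchmarkResult:
    """Read a benchmark table back into a :class:`BenchmarkResult`."""
    table = pd.read_csv(path)
    return BenchmarkResult(table=table, config=config or BenchmarkConfig())
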